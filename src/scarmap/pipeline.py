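"""End-to-end workflow: input → (shift correction) → (upsampling) → scar
segmentation → wall coordinate → transmurality map → quantification.

The pipeline is driven by a :class:`RunConfig` (constructable from YAML or
JSON) and writes a reproducible bundle: NIfTI volumes, the map mesh as
ASCII PLY, CSV tables and JSON reports, each accompanied by a provenance
block (tool version, config hash, seed).  The same config and seed always
produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .boundaries import classify_boundaries, keep_largest_wall_component
from .laplace import solve_laplace
from .phantom import PhantomSpec, make_phantom
from .quantify import DEFAULT_THRESHOLDS, layer_partition, scar_area_at_thresholds
from .resample import correct_slice_shifts, downsample_throughplane, upsample_topologic
from .scar import ScarCriteria, scar_volumes, segment_scar
from .surface import extract_surface, write_ply
from .tracing import trace_correspondences, transmurality_map
from .volumes import ImageVolume, LabelVolume, read_volume, write_volume

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``phantom`` holds :class:`PhantomSpec` keyword arguments, or
    ``image_path``/``labels_path`` point to NIfTI inputs.
    """

    outdir: str = "scarmap_out"
    seed: int = 0
    phantom: dict | None = None
    image_path: str | None = None
    labels_path: str | None = None
    slice_thickness_mm: float | None = None  # emulate a thick-slice acquisition
    correct_shifts: bool = False
    upsample_to_mm: float | None = None
    segment_scar_from_image: bool = True
    scar_cutoff: float = 0.45
    dense_cutoff: float = 0.67
    slab_mm: float = 8.0
    laplace_tol: float = 1e-5
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    step_frac: float = 0.25
    eps_endo: float = 0.02

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "thresholds" in payload:
            payload["thresholds"] = tuple(payload["thresholds"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def digest(self) -> str:
        """Hash of the analysis parameters (the output location is excluded
        so that reruns of the same analysis share a provenance hash)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"tool": "scarmap", "version": __version__, "config_hash": config.digest(), "seed": config.seed}


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the output bundle.

    Returns a dict with the in-memory results and the paths written.  Any
    stage error is re-raised as :class:`PipelineError` naming the stage;
    outputs produced before the failure are retained on disk together with
    a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    results: dict = {"provenance": prov, "outdir": outdir}
    stage = "setup"
    try:
        stage = "input"
        if config.phantom is not None:
            spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
            seg, img, truth = make_phantom(spec)
            truth.to_json(outdir / "truth.json")
            results["truth"] = truth
        else:
            if config.labels_path is None:
                raise ValueError("config needs either a phantom block or labels_path")
            seg = read_volume(config.labels_path, kind="label")
            img = (
                read_volume(config.image_path, kind="image")
                if config.image_path
                else None
            )

        if config.slice_thickness_mm is not None:
            stage = "downsample"
            seg = downsample_throughplane(seg, config.slice_thickness_mm)
            if img is not None:
                img = downsample_throughplane(img, config.slice_thickness_mm)

        if config.correct_shifts:
            stage = "shift_correction"
            seg = correct_slice_shifts(seg)

        if config.upsample_to_mm is not None:
            stage = "upsample"
            seg = upsample_topologic(seg, config.upsample_to_mm)
            seg = keep_largest_wall_component(seg)
            img = None  # intensity upsampling is out of scope; use labels

        stage = "scar_segmentation"
        criteria = ScarCriteria(
            cutoff=config.scar_cutoff, dense_cutoff=config.dense_cutoff, slab_mm=config.slab_mm
        )
        if img is not None and config.segment_scar_from_image:
            seg, hetero, dense = segment_scar(img, seg, criteria)
        else:
            dense = None
        volumes = scar_volumes(seg, dense)
        write_volume(seg, outdir / "seg_scar.nii.gz")
        _write_json({**volumes.as_dict(), "provenance": prov}, outdir / "volumes.json")
        results["volumes"] = volumes

        stage = "laplace"
        bc = classify_boundaries(seg)
        fld = solve_laplace(seg, bc, tol=config.laplace_tol)
        write_volume(
            ImageVolume(fld.s, seg.spacing, seg.origin), outdir / "field.nii.gz"
        )
        results["field"] = fld

        stage = "transmurality"
        epi = extract_surface(seg, "epi")
        corrs = trace_correspondences(
            fld, epi, step_frac=config.step_frac, eps_endo=config.eps_endo
        )
        tmap = transmurality_map(corrs)
        epi.vertex_values = tmap.masked_tsm()
        write_ply(epi, outdir / "map.ply")
        _write_json(
            {
                **corrs.qc_report(),
                "laplace_residual": fld.residual,
                "laplace_iterations": fld.iterations,
                "provenance": prov,
            },
            outdir / "qc.json",
        )
        results["epi_mesh"] = epi
        results["tsm_map"] = tmap

        stage = "quantification"
        areas = scar_area_at_thresholds(tmap, epi, config.thresholds)
        areas.to_csv(outdir / "areas.csv", index=False, float_format="%.6f")
        layers = layer_partition(seg, fld)
        layers.to_frame().to_csv(outdir / "layers.csv", index=False, float_format="%.6f")
        results["areas"] = areas
        results["layers"] = layers
        results["seg"] = seg
        return results
    except Exception as exc:  # noqa: BLE001 — annotate with the failing stage
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
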