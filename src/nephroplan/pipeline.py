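"""End-to-end run: segment (or load) the three structures, plan all margins,
write artifacts with a provenance record.

Every run is driven by a single :class:`RunConfig` (JSON file + CLI
overrides) so that the per-patient choices the workflow requires — the
region-growing threshold r, scribbles, contours — are explicit and recorded.
Two runs with the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__, mesh_geometry, resection_planner, segmentation, volume_io
from .resection_planner import MarginSchedule, OpeningReport
from .volume_io import CTVolume, LabelMask

logger = logging.getLogger(__name__)


class StructureInput(BaseModel):
    """Exactly one of an annotation file (to segment) or a mask file (to load)."""

    annotations: Optional[str] = None
    mask: Optional[str] = None

    @model_validator(mode="after")
    def _one_of(self):
        if (self.annotations is None) == (self.mask is None):
            raise ValueError("supply exactly one of 'annotations' or 'mask'")
        return self


class RunConfig(BaseModel):
    ct: str
    kidney: StructureInput
    tumor: StructureInput
    tract: StructureInput
    out_dir: str
    margins_mm: list[float] = Field(default=list(resection_planner.DEFAULT_MARGINS_MM))
    lambda_region: float = 0.1
    sigma_boundary: Optional[float] = None
    neighborhood: Literal[6, 26] = 6
    region_growing_r: Optional[float] = None  # None -> value stored in the seed file
    connectivity: Literal[6, 26] = 6
    contour_smoothness: float = 0.0
    rng_seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _schedule_valid(self):
        MarginSchedule(tuple(self.margins_mm))  # raises if invalid
        return self

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


# --- report schema (shipped as pydantic models; JSON Schema via report_schema())

class PerMarginEntry(BaseModel):
    margin_mm: float
    open: bool
    opening_voxel_count: int
    opening_centroid_mm: Optional[list[float]]
    opening_extent_mm: Optional[float]


class ReportModel(BaseModel):
    min_opening_margin_mm: Optional[float]
    min_tract_distance_mm: float
    status_text: str
    per_margin: list[PerMarginEntry]


def report_schema() -> dict:
    """JSON Schema of the planning report (for external validation)."""
    return ReportModel.model_json_schema()


# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _segment_structure(
    name: str, inp: StructureInput, ct: CTVolume, config: RunConfig
) -> LabelMask:
    if inp.mask is not None:
        mask = volume_io.read_mask(inp.mask)
        volume_io.check_aligned(mask, ct, what=f"{name} mask / CT")
        return mask
    path = inp.annotations
    if name == "kidney":
        fg, bg = volume_io.load_scribbles(path)
        params = segmentation.GraphCutParams(
            config.lambda_region, config.sigma_boundary, config.neighborhood
        )
        return segmentation.segment_graph_cut(
            ct, segmentation.ScribbleSet(fg, bg), params
        )
    if name == "tract":
        seeds, r_file = volume_io.load_seeds(path)
        r = config.region_growing_r if config.region_growing_r is not None else r_file
        logger.info("region growing threshold r=%.1f", r)
        return segmentation.segment_region_growing(
            ct, segmentation.SeedSet(seeds, r), config.connectivity
        )
    if name == "tumor":
        contours = volume_io.load_contours(path)
        stack = segmentation.ContourStack(
            [segmentation.Contour(ax, pi, pts) for ax, pi, pts in contours]
        )
        return segmentation.segment_contour_based(ct, stack, config.contour_smoothness)
    raise ValueError(f"unknown structure {name!r}")


def _opening_vertex_flags(
    surface: mesh_geometry.SurfaceMesh, opening: LabelMask
) -> np.ndarray:
    """1.0 at surface vertices whose nearest voxel is an opening voxel."""
    if surface.is_empty() or not opening.data.any():
        return np.zeros(surface.n_vertices)
    idx = np.rint(opening.world_to_index(surface.vertices)).astype(int)
    idx = np.clip(idx, 0, np.asarray(opening.shape) - 1)
    return opening.data[tuple(idx.T)].astype(float)


def write_report_json(report: OpeningReport, path) -> None:
    """Deterministic (byte-stable for fixed inputs) report serialization."""
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> OpeningReport:
    """Execute the full planning workflow and write all artifacts.

    Artifacts in ``out_dir``: the three masks (NIfTI), per-margin removed
    regions (NIfTI) and resection surfaces (PLY with ``ct_value`` and
    ``opening`` vertex properties), ``report.json``, ``provenance.json``
    and ``run.log``. Raises with a stage-named message on any failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nephroplan")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        try:
            ct = volume_io.read_volume(config.ct)
        except Exception as exc:
            raise RuntimeError(f"stage volume_io: {exc}") from exc

        masks: dict[str, LabelMask] = {}
        for name in ("kidney", "tumor", "tract"):
            inp = getattr(config, name if name != "tract" else "tract")
            try:
                masks[name] = _segment_structure(name, inp, ct, config)
            except Exception as exc:
                raise RuntimeError(f"stage segmentation ({name}): {exc}") from exc
            volume_io.write_mask(masks[name], out_dir / f"{name}_mask.nii.gz")

        try:
            plans, report = resection_planner.plan_all_margins(
                masks["kidney"], masks["tumor"], masks["tract"],
                MarginSchedule(tuple(config.margins_mm)), ct,
            )
        except Exception as exc:
            raise RuntimeError(f"stage resection_planner: {exc}") from exc

        for plan in plans:
            tag = f"margin_{plan.margin:g}mm"
            volume_io.write_mask(plan.removed_region, out_dir / f"removed_{tag}.nii.gz")
            if not plan.resection_surface.is_empty():
                opening = masks["tract"].like(
                    masks["tract"].data & plan.removed_region.data
                )
                flags = _opening_vertex_flags(plan.resection_surface, opening)
                plan.resection_surface.export(
                    out_dir / f"resection_{tag}.ply",
                    extra_scalars={"opening": flags},
                )

        write_report_json(report, out_dir / "report.json")
        provenance = {
            "software": {"name": "nephroplan", "version": __version__},
            "config": json.loads(config.model_dump_json()),
            "input_checksums": {
                "ct": _sha256(config.ct),
                **{
                    name: _sha256(inp.mask or inp.annotations)
                    for name, inp in (
                        ("kidney", config.kidney),
                        ("tumor", config.tumor),
                        ("tract", config.tract),
                    )
                },
            },
        }
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )
        logger.info("pipeline complete: %s", report.status_text)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
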