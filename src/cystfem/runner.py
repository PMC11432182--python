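"""Orchestrate the experiment grid: scenarios x body weights x projections.

The default grid is the full study design — 7 cyst scenarios, 6 body
weights (70..170 kg), frontal and sagittal projections, 84 solves in all.
One stiffness factorization per scenario x projection serves every weight
(the stiffness does not depend on the load level); each weight is still an
independent triangular solve and stress recovery.  The per-cell summary is
the region-of-interest SMax, averaged over the two projections, assembled
into a weights-by-scenarios stress table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    GeometryParams,
    LabelImage,
    ScenarioSpec,
    generate_geometry,
    insert_cysts,
    standard_scenarios,
)
from .materials import MaterialTable, build_attribute_map, default_material_table
from .fem import (
    FactorizedModel,
    LoadCase,
    StressSummary,
    build_model,
    periarticular_roi,
    summarize,
)

__all__ = [
    "ExperimentConfig",
    "DEFAULT_WEIGHTS",
    "run_grid",
    "load_stress_table",
    "write_stress_table",
    "packaged_table1",
]

logger = logging.getLogger("cystfem")

DEFAULT_WEIGHTS: tuple[float, ...] = (70.0, 90.0, 110.0, 130.0, 150.0, 170.0)

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one grid run."""

    scenarios: Sequence[str] = tuple(f"S{i}" for i in range(1, 8))
    weights: Sequence[float] = DEFAULT_WEIGHTS
    projections: Sequence[str] = ("frontal", "sagittal")
    geometry: GeometryParams = dfield(default_factory=GeometryParams)
    materials: MaterialTable = dfield(default_factory=default_material_table)
    formulation: str = "plane_strain"
    boundary_layer: int = 2
    roi_distance_mm: float = 12.0  # subchondral ROI half-height around the joint line
    roi_axis_half_width_mm: float = 5.0  # limb-axis core: cyst radius + 1 mm rim
    qualitative_band: float = 0.5  # relative band for "peripheral ~ control"
    seed: int = 0
    fast: bool = False  # single solve per scenario/projection + exact rescale
    output_dir: Path | None = None
    write_fields: bool = False
    write_contours: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("scenarios", "weights", "projections", "formulation",
                    "boundary_layer", "roi_distance_mm", "roi_axis_half_width_mm", "qualitative_band",
                    "seed", "fast", "write_fields", "write_contours"):
            if key in doc:
                kwargs[key] = doc[key]
        if "geometry" in doc:
            kwargs["geometry"] = GeometryParams(**doc["geometry"])
        if "materials" in doc:
            kwargs["materials"] = MaterialTable.from_dict(doc["materials"])
        if "output_dir" in doc and doc["output_dir"]:
            kwargs["output_dir"] = Path(doc["output_dir"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable fingerprint of all run-determining settings."""
        payload = {
            "scenarios": list(self.scenarios),
            "weights": [float(w) for w in self.weights],
            "projections": list(self.projections),
            "geometry": {k: (str(v) if isinstance(v, bool) else v)
                         for k, v in vars(self.geometry).items()},
            "materials": self.materials.to_dict(),
            "formulation": self.formulation,
            "boundary_layer": self.boundary_layer,
            "roi_distance_mm": self.roi_distance_mm,
            "roi_axis_half_width_mm": self.roi_axis_half_width_mm,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class GridResult:
    table: pd.DataFrame  # index: weight, columns: scenario ids (SMax, MPa)
    mean_table: pd.DataFrame  # same shape, ROI mean stress
    manifest: dict
    summaries: dict  # (scenario, projection, weight) -> StressSummary


def run_grid(config: ExperimentConfig | None = None) -> GridResult:
    """Run the scenario x weight x projection grid and build the table.

    Any failed solve aborts the grid with the offending cell named.  The
    manifest records the config hash, per-run residuals and element counts.
    """
    cfg = config or ExperimentConfig()
    scen_defs = standard_scenarios()
    t0 = time.time()
    smax = {s: {} for s in cfg.scenarios}
    mean = {s: {} for s in cfg.scenarios}
    summaries: dict = {}
    runs = []
    base_load = LoadCase(pressure_override=1.0)  # unit pressure; rescaled per weight

    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    for projection in cfg.projections:
        base_img = generate_geometry(projection, cfg.seed, cfg.geometry)
        for sid in cfg.scenarios:
            if sid not in scen_defs:
                raise ValueError(f"unknown scenario {sid!r}")
            try:
                img = insert_cysts(base_img, scen_defs[sid])
                attrs = build_attribute_map(img, cfg.materials)
                model = build_model(img, attrs, base_load, formulation=cfg.formulation)
                roi = periarticular_roi(
                    img, model, cfg.roi_distance_mm, cfg.roi_axis_half_width_mm
                )
                fact = FactorizedModel(model)
            except Exception as e:
                raise RuntimeError(f"grid cell ({sid}, {projection}) failed: {e}") from e
            ref = None  # (pressure, field, summary) of the first weight
            for w in cfg.weights:
                p = LoadCase(body_weight=w).pressure
                try:
                    if cfg.fast and ref is not None:
                        # linearity: one solve per scenario/projection, rescale
                        p0, field, s0 = ref
                        scale = p / p0
                        summary = StressSummary(
                            smax=s0.smax * scale,
                            mean=s0.mean * scale,
                            n_elements=s0.n_elements,
                            argmax_pixel=s0.argmax_pixel,
                        )
                    else:
                        field = fact.stresses(model.forces * p)
                        summary = summarize(field, roi=roi)
                        if ref is None:
                            ref = (p, field, summary)
                except Exception as e:
                    raise RuntimeError(
                        f"grid cell ({sid}, {projection}, {w} kg) failed: {e}"
                    ) from e
                summaries[(sid, projection, w)] = summary
                smax[sid].setdefault(w, []).append(summary.smax)
                mean[sid].setdefault(w, []).append(summary.mean)
                runs.append(
                    {
                        "scenario": sid,
                        "projection": projection,
                        "weight_kg": w,
                        "pressure_MPa": p,
                        "n_elements": model.n_elements,
                        "residual": getattr(field, "residual", 0.0),
                        "smax_MPa": summary.smax,
                        "mean_MPa": summary.mean,
                        "argmax_pixel": list(summary.argmax_pixel),
                    }
                )
                logger.info(
                    "%s %s %g kg: SMax=%.4f MPa (%d elements)",
                    sid, projection, w, summary.smax, model.n_elements,
                )
                if out and cfg.write_fields and not cfg.fast:
                    from .io import export_field_csv

                    export_field_csv(
                        field, out / f"field_{sid}_{projection}_{int(w)}kg.csv"
                    )
                if out and cfg.write_contours and not cfg.fast:
                    from .io import render_contour_png

                    render_contour_png(
                        field,
                        out / f"contour_{sid}_{projection}_{int(w)}kg.png",
                        title=f"{sid} {projection} {int(w)} kg",
                    )

    # plane averaging: arithmetic mean of the projections' summaries
    weights = [float(w) for w in cfg.weights]
    table = pd.DataFrame(
        {s: [float(np.mean(smax[s][w])) for w in cfg.weights] for s in cfg.scenarios},
        index=pd.Index(weights, name="weight"),
    )
    mean_table = pd.DataFrame(
        {s: [float(np.mean(mean[s][w])) for w in cfg.weights] for s in cfg.scenarios},
        index=pd.Index(weights, name="weight"),
    )
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "fast": cfg.fast,
        "elapsed_s": round(time.time() - t0, 3),
        "max_residual": max((r["residual"] for r in runs), default=0.0),
        "runs": runs,
    }
    if out:
        write_stress_table(table, out / "stress_table.csv")
        write_stress_table(mean_table, out / "stress_table_mean.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return GridResult(table=table, mean_table=mean_table, manifest=manifest, summaries=summaries)


def write_stress_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index = [int(w) if float(w).is_integer() else w for w in out.index]
    out.index.name = "weight"
    out.to_csv(path)


def load_stress_table(path) -> pd.DataFrame:
    """Read a weights-by-scenarios stress table CSV and validate it.

    Expected dialect: header ``weight,S1,...``, comma separator, period
    decimals.  Raises on missing cells, non-numeric or non-positive values.
    """
    df = pd.read_csv(path)
    if df.columns[0].lower() != "weight":
        raise ValueError(f"first column must be 'weight', got {df.columns[0]!r}")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(float)
    df.index.name = "weight"
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric stress entry: {e}") from None
    if df.isna().any().any():
        missing = [(w, c) for (w, c) in zip(*np.nonzero(df.isna().values))]
        raise ValueError(f"missing cells in stress table: {missing}")
    if (df.values <= 0).any():
        raise ValueError("stress table contains non-positive values")
    return df


def packaged_table1() -> pd.DataFrame:
    """The published scenario x weight stress table shipped with the package."""
    return load_stress_table(_DATA_DIR / "table1.csv")
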