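"""Pipeline orchestration: configuration, the full study run, and outputs.

``run_study`` composes the whole analysis: project inputs into the local
planar frame, censor candidate points against the land-use grid, apply
verification removals, assign dwellings to census blocks, estimate the
population at risk around every well with both ABODE and PPA, aggregate
per state with dissolved-union totals, compute the comparison metrics, and
write the report tables plus a JSON run manifest.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import (
    BlockIndex,
    abode_population,
    block_rhu_totals,
    build_well_area,
    classify_agreement,
    ppa_population,
    setback_conflicts,
    universe_totals,
)
from .geometry import ProjectionSpec
from .io import (
    geojson_centroid_spec,
    load_blocks,
    load_candidates,
    load_removals,
    load_setback_rules,
    load_wells,
)
from .landuse import LandUseGrid
from .metrics import agreement_summary, compute_report
from .reports import setback_table, summarize_by_state, top_wells_table
from .rhu import apply_verification, assign_block, censor_nonresidential

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one full study run."""

    blocks: str
    candidates: str
    land_use: str
    wells: str
    out_dir: str
    setback_rules: str | None = None
    removals: str | None = None
    radius_m: float = 200.0
    cap_mode: str = "scale"  # scale | hard
    ppa_density: str = "total"  # total | household
    fb_standard: bool = False
    excluded_classes: tuple[int, ...] = (2,)
    keep_unknown: bool = True
    dedupe_building_centroids: bool = False
    n_segments: int = 64
    center_lon: float | None = None
    center_lat: float | None = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        if self.cap_mode not in ("scale", "hard"):
            raise ValueError(f"unknown cap_mode {self.cap_mode!r}")
        if self.ppa_density not in ("total", "household"):
            raise ValueError(f"unknown ppa_density {self.ppa_density!r}")

    @classmethod
    def from_ini(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a flat INI file ([run] section); kwargs override keys."""
        cp = configparser.ConfigParser()
        with Path(path).open() as fh:
            cp.read_file(fh)
        sec = cp["run"] if cp.has_section("run") else cp[cp.sections()[0]]
        kwargs: dict = dict(sec)
        for key in ("radius_m", "center_lon", "center_lat"):
            if key in kwargs:
                kwargs[key] = float(kwargs[key])
        for key in ("n_segments", "seed"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        for key in ("fb_standard", "keep_unknown", "dedupe_building_centroids", "verbose"):
            if key in kwargs:
                kwargs[key] = str(kwargs[key]).lower() in ("1", "true", "yes")
        if "excluded_classes" in kwargs:
            kwargs["excluded_classes"] = tuple(
                int(v) for v in str(kwargs["excluded_classes"]).split(",") if v.strip()
            )
        kwargs.update(overrides)
        return cls(**kwargs)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_study(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write reports under ``cfg.out_dir``.

    Returns a dict with the per-well table, state summary, setback table
    (when rules are given), metrics report, universe totals, and output
    paths.  Re-running with identical inputs produces byte-identical CSVs.
    """
    for what in ("blocks", "candidates", "land_use", "wells"):
        _require(getattr(cfg, what), what)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.DEBUG if cfg.verbose else logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("abode")
    root.addHandler(handler)
    try:
        return _run(cfg, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out_dir: Path) -> dict:
    if cfg.center_lon is not None and cfg.center_lat is not None:
        spec = ProjectionSpec(cfg.center_lon, cfg.center_lat)
    else:
        spec = geojson_centroid_spec(cfg.blocks)
    log.info("projection centre: (%.6f, %.6f)", spec.center_lon, spec.center_lat)

    blocks = load_blocks(cfg.blocks, spec)
    candidates = load_candidates(cfg.candidates, spec)
    grid = LandUseGrid.from_ascii(cfg.land_use, excluded_classes=set(cfg.excluded_classes))
    wells = load_wells(cfg.wells, spec)
    log.info(
        "inputs: %d blocks, %d candidates, %d wells, %dx%d land-use grid",
        len(blocks), len(candidates), len(wells), grid.n_rows, grid.n_cols,
    )

    rhus = censor_nonresidential(
        candidates,
        grid,
        keep_unknown=cfg.keep_unknown,
        dedupe_building_centroids=cfg.dedupe_building_centroids,
    )
    if cfg.removals:
        rhus = apply_verification(rhus, load_removals(cfg.removals))
    rhus = assign_block(rhus, blocks)
    n_assigned = sum(1 for r in rhus if r.block_id is not None)
    log.info("RHUs: %d total, %d assigned to blocks", len(rhus), n_assigned)

    index = BlockIndex(blocks, density_mode=cfg.ppa_density)
    rhu_totals = block_rhu_totals(rhus)

    per_rows = []
    areas = []
    for w in wells:
        area = build_well_area(w, cfg.radius_m, index, cfg.n_segments)
        areas.append(area)
        cap = abode_population(area, index, rhus, True, cfg.cap_mode, rhu_totals)
        unc = abode_population(area, index, rhus, False)
        ppa = ppa_population(area.polygon, index, cfg.ppa_density, w.well_id)
        per_rows.append(
            {
                "well_id": w.well_id,
                "facility_id": w.facility_id,
                "state": w.state,
                "radius_m": cfg.radius_m,
                "rhu_count": unc.rhu_count,
                "abode_capped": cap.population,
                "abode_uncapped": unc.population,
                "ppa": ppa.population,
                "diff": cap.population - ppa.population,
                "agreement_class": classify_agreement(cap.population, ppa.population),
                "gq_warning": cap.gq_warning,
            }
        )
    per_well = pd.DataFrame(per_rows)

    universe_by_state: dict[str, dict] = {}
    states = sorted({w.state for w in wells if w.state is not None})
    for state in states:
        sub = [a for a, w in zip(areas, wells) if w.state == state]
        universe_by_state[state] = {
            m: universe_totals(sub, index, rhus, m, cfg.cap_mode, cfg.ppa_density, rhu_totals)
            for m in ("ppa", "abode_capped", "abode_uncapped")
        }
    universe_all = {
        m: universe_totals(areas, index, rhus, m, cfg.cap_mode, cfg.ppa_density, rhu_totals)
        for m in ("ppa", "abode_capped", "abode_uncapped")
    }

    wells_by_state = per_well.groupby("state")["well_id"].count().to_dict()
    summary = summarize_by_state(per_well, wells_by_state, universe_by_state)
    top = top_wells_table(per_well, k=10)

    report = compute_report(
        per_well["abode_capped"].to_numpy(),
        per_well["ppa"].to_numpy(),
        fb_standard=cfg.fb_standard,
    )
    agreement = agreement_summary(
        list(zip(per_well["state"].fillna("?"), per_well["agreement_class"]))
    )

    outputs = {
        "per_well": per_well,
        "state_summary": summary,
        "top_wells": top,
        "metrics": report,
        "agreement": agreement,
        "universe": universe_all,
    }

    per_well.to_csv(out_dir / "per_well.csv", index=False)
    summary.to_csv(out_dir / "state_summary.csv", index=False)
    top.to_csv(out_dir / "top_wells.csv", index=False)
    pd.DataFrame(report.to_rows()).to_csv(out_dir / "metrics.csv", index=False)
    agr_rows = [
        {"state": s, "category": c, "count": n}
        for s, cats in sorted(agreement.items())
        for c, n in sorted(cats.items())
    ]
    pd.DataFrame(agr_rows, columns=["state", "category", "count"]).to_csv(
        out_dir / "agreement.csv", index=False
    )

    if cfg.setback_rules:
        rules = load_setback_rules(cfg.setback_rules)
        records = setback_conflicts(
            wells, rules, rhus, index, cfg.cap_mode, cfg.ppa_density, cfg.n_segments
        )
        sb = setback_table(records)
        sb.to_csv(out_dir / "setbacks.csv", index=False)
        outputs["setbacks"] = sb
        outputs["setback_records"] = records

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "projection_center": [spec.center_lon, spec.center_lat],
        "counts": {
            "blocks": len(blocks),
            "candidates": len(candidates),
            "rhus": len(rhus),
            "rhus_assigned": n_assigned,
            "wells": len(wells),
        },
        "universe": {
            m: {"population": r.population, "rhu_count": r.rhu_count}
            for m, r in universe_all.items()
        },
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    outputs["out_dir"] = out_dir
    return outputs
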