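"""End-to-end orchestration: generate -> index -> classify -> sweep -> predict.

One YAML config (or a :class:`RunConfig`) drives every stage; all
randomness flows from the single configured seed and the manifest records
the seed, stage counts and prevalences so a run is reproducible
byte-for-byte (timestamps appear only in logs, never in data files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ogtt_screen import __version__
from ogtt_screen.cohort import Cohort, GeneratorParams, attach_outcomes, generate_cohort
from ogtt_screen.criteria import GDM_CRITERIA, apply_criteria, get_criterion
from ogtt_screen.indices import panel_frame
from ogtt_screen.prediabetes import joint_and_interaction_models, standardize_log
from ogtt_screen.sweep import (
    DEFAULT_N_STEPS,
    crossing_point,
    percentile_sweep,
    scaled_cutoff_grid,
    sweep_accuracy,
)

log = logging.getLogger("ogtt_screen")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one cohort source: either ``generator`` parameters (a mapping
    of :class:`GeneratorParams` fields) or ``cohort_csv`` (path to an
    existing cohort table).
    """

    out_dir: str = "ogtt_run"
    seed: int = 0
    generator: dict | None = None
    cohort_csv: str | None = None
    criteria: tuple = GDM_CRITERIA
    sweep_steps: int = DEFAULT_N_STEPS
    percentile_step: float = 5.0
    targets: tuple = ("GDM", "LGA")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generator is not None and self.cohort_csv is not None:
            raise ValueError("configure exactly one cohort source, not both")
        if self.generator is None and self.cohort_csv is None:
            self.generator = {}  # default generator parameters
        for name in self.criteria:
            get_criterion(name)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _build_cohort(config: RunConfig) -> Cohort:
    if config.cohort_csv is not None:
        return Cohort.from_csv(config.cohort_csv)
    gen = dict(config.generator or {})
    gen.setdefault("seed", config.seed)
    params = GeneratorParams.from_dict(gen)
    cohort = generate_cohort(params)
    return attach_outcomes(cohort, params)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Emits ``cohort.csv``, ``index_panel.csv``, ``classifications.csv``,
    one sweep profile CSV per criterion per target, ``prediab_fits.json``
    and ``manifest.json``; returns the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _build_cohort(config)
    table = cohort.table
    n = len(table)
    cohort.to_csv(out / "cohort.csv")
    log.info("cohort of %d subjects written", n)

    # index panels for the two pregnancy visits
    panel = pd.concat(
        [table[["id"]], panel_frame(table, "w14"), panel_frame(table, "w30")], axis=1
    )
    panel.to_csv(out / "index_panel.csv", index=False, float_format="%.6g")

    # classifications (reference + early screen) per criterion
    cls_frames = []
    prevalences = {}
    counts = {"subjects": n}
    for name in config.criteria:
        for timing in ("reference", "early"):
            cls = apply_criteria(table, name, timing=timing)
            cls.insert(0, "id", table["id"].to_numpy())
            cls.insert(1, "criterion", name)
            cls.insert(2, "timing", timing)
            cls_frames.append(cls)
            evaluable = cls["positive"].notna()
            pos_rate = float(cls.loc[evaluable, "positive"].astype(bool).mean()) if evaluable.any() else float("nan")
            prevalences[f"{name}_{timing}"] = round(100 * pos_rate, 1)
            counts[f"{name}_{timing}_undefined"] = int((~evaluable).sum())
    pd.concat(cls_frames).to_csv(out / "classifications.csv", index=False)

    # sweeps: scaled cut-off grids per criterion against GDM and LGA
    crossings = {}
    lga = table["lga"]
    for name in config.criteria:
        reference = apply_criteria(table, name, timing="reference")["positive"]
        grid = scaled_cutoff_grid(name, config.sweep_steps)
        for target, ref in (("GDM", reference), ("LGA", lga)):
            if target not in config.targets:
                continue
            if ref.isna().all():
                log.warning("no %s reference labels; skipping sweep", target)
                continue
            profile = sweep_accuracy(cohort, grid, ref, target=target)
            profile.frame().to_csv(
                out / f"sweep_scaled_{name}_{target}.csv", index=False, float_format="%.6g"
            )
            cp = crossing_point(profile)
            crossings[f"{name}_{target}"] = None if cp is None else {
                "step": round(cp[0], 3), "value": round(cp[1], 4), "degenerate": cp[2]
            }

    # percentile sweeps of the early markers against each GDM reference
    panel14 = panel_frame(table, "w14")
    markers = {
        "betacell": (panel14["issi2_w14"], False),   # risk = low beta-cell function
        "auc_glucose": (panel14["auc_glucose_w14"], True),
        "fasting_glucose": (table["glu_w14_0"], True),
    }
    for name in config.criteria:
        reference = apply_criteria(table, name, timing="reference")["positive"]
        for mname, (marker, higher) in markers.items():
            prof = percentile_sweep(
                marker, reference, higher_is_positive=higher,
                step_percent=config.percentile_step, marker_name=mname,
            )
            prof.frame().to_csv(
                out / f"sweep_percentile_{mname}_{name}.csv", index=False, float_format="%.6g"
            )

    # pre-diabetes models on the follow-up subsample
    prediab_block = _prediabetes_stage(table, out, config.criteria)
    counts["prediab_analyzed"] = prediab_block.get("n", 0)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "counts": counts,
        "prevalence_percent": prevalences,
        "lga_rate_percent": round(100 * float(lga.mean()), 1) if lga.notna().any() else None,
        "crossings": crossings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _prediabetes_stage(table: pd.DataFrame, out: Path, criteria) -> dict:
    """Fit the second-study models if follow-up outcomes are present."""
    y = table["prediab_5y"]
    if y.notna().sum() < 30 or y.dropna().nunique() < 2:
        log.warning("insufficient follow-up outcomes; skipping pre-diabetes stage")
        (out / "prediab_fits.json").write_text(json.dumps({"skipped": True}))
        return {"skipped": True}
    panel14 = panel_frame(table, "w14")
    panel30 = panel_frame(table, "w30")
    sub = y.notna() & panel14["issi2_w14"].notna() & panel30["issi2_w30"].notna()
    # standardization SDs computed within the analysis subsample
    b14 = standardize_log(panel14.loc[sub, "issi2_w14"].to_numpy())
    b30 = standardize_log(panel30.loc[sub, "issi2_w30"].to_numpy())
    outcome = y[sub].to_numpy()
    fits = {}
    for name in criteria:
        gdm = apply_criteria(table, name, timing="reference")["positive"][sub].to_numpy(dtype=float)
        models = joint_and_interaction_models(b14, b30, gdm, outcome)
        fits[name] = {
            key: (m.as_dict() if hasattr(m, "as_dict") else dataclasses.asdict(m))
            for key, m in models.items()
        }
    block = {"n": int(sub.sum()), "models_by_gdm_criterion": fits}
    (out / "prediab_fits.json").write_text(json.dumps(block, indent=2, sort_keys=True))
    return block
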