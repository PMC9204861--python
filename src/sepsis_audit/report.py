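"""Cohort summary tables and end-to-end pipeline orchestration.

The pipeline binds the stages together: generate or load a cohort, select and
relevel, label under the six criteria, build the prevalence forest table,
split 7:3, fit the classifier battery, and run the disparity audit. Every
intermediate table is written to the output directory and a manifest records
the master seed, derived stage seeds, a config hash, and per-stage row counts,
so an identical config reproduces an identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .cohort import (
    CohortSpec,
    SubgroupEffect,
    default_spec,
    generate_cohort,
    inject_subgroup_effect,
    read_cohort_csv,
    spec_from_dict,
    write_cohort_csv,
)
from .criteria import (
    DETERMINANT_CATEGORIES,
    criteria_from_config,
    default_criteria,
    label_matrix,
    relevel_determinants,
    select_cohort,
)
from .models import MODEL_NAMES, default_model_specs, run_model_battery, split_cohort
from .permutation import disparity_report
from .prevalence import forest_table

log = logging.getLogger("sepsis_audit")


def _pct(numerator: int, denominator: int) -> float:
    """Exact rational percentage, rounded half-up to 2 decimals."""
    if denominator == 0:
        return float("nan")
    q = (Decimal(int(numerator)) * 100 / Decimal(int(denominator))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add the percentage columns to a per-category count table.

    ``counts`` needs determinant, category, n, deaths (and optionally n_train,
    n_test). Percent of cohort and percent deaths are computed per determinant
    and rounded half-up to 2 decimals.
    """
    out = counts.copy()
    totals = out.groupby("determinant")["n"].transform("sum")
    out["pct_cohort"] = [
        _pct(n, t) for n, t in zip(out["n"].astype(int), totals.astype(int))
    ]
    out["pct_deaths"] = [
        _pct(d, n) for d, n in zip(out["deaths"].astype(int), out["n"].astype(int))
    ]
    cols = ["determinant", "category", "n", "pct_cohort", "deaths", "pct_deaths"]
    for extra in ("n_train", "n_test"):
        if extra in out.columns:
            cols.append(extra)
    return out[cols]


def summarize_cohort(patients: pd.DataFrame, in_train: Sequence | None = None
                     ) -> pd.DataFrame:
    """Per-determinant category summary of a patient table.

    For every enumerated category: n, percent of cohort, deaths, percent
    deaths, and (when a train membership vector is given) train/test counts.
    """
    rows = []
    death = patients["in_hospital_death"].astype(int).to_numpy()
    train_mask = (
        np.asarray(in_train, dtype=bool) if in_train is not None else None
    )
    for det, cats in DETERMINANT_CATEGORIES.items():
        group = patients[det].to_numpy()
        for cat in cats:
            members = group == cat
            row = dict(
                determinant=det,
                category=cat,
                n=int(members.sum()),
                deaths=int(death[members].sum()),
            )
            if train_mask is not None:
                row["n_train"] = int((members & train_mask).sum())
                row["n_test"] = int((members & ~train_mask).sum())
            rows.append(row)
    return summarize_counts(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    cohort_source: Mapping = field(default_factory=lambda: {"synthetic": {}})
    criteria_config: str | None = None
    mapping_config: str | None = None
    models: Sequence[str] | None = None  # None = all sixteen configurations
    train_fraction: float = 0.7
    n_boot: int = 1000
    n_perm: int = 1000
    ci_level: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    modeling_criterion: str = "Sepsis-3"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models) if self.models is not None else None
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _build_cohort(config: RunConfig, seed: int) -> pd.DataFrame:
    src = dict(config.cohort_source)
    if "csv" in src:
        cohort = read_cohort_csv(src["csv"])
        mapping = None
        if config.mapping_config:
            with open(config.mapping_config) as fh:
                mapping = yaml.safe_load(fh)
        return relevel_determinants(cohort, mapping)
    syn = dict(src.get("synthetic", {}))
    if "spec_file" in syn:
        with open(syn["spec_file"]) as fh:
            spec = spec_from_dict(yaml.safe_load(fh))
        spec = dataclasses.replace(spec, seed=seed)
    else:
        spec = default_spec(n_patients=int(syn.get("n_patients", 5783)), seed=seed)
    for inj in syn.get("inject", []):
        spec = inject_subgroup_effect(
            spec,
            inj["determinant"],
            inj["category"],
            SubgroupEffect(
                coef_multipliers=inj.get("coef_multipliers", {}),
                logit_shift=float(inj.get("logit_shift", 0.0)),
                label_noise=float(inj.get("label_noise", 0.0)),
            ),
        )
    return generate_cohort(spec)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute every stage and return the artifact bundle as DataFrames.

    When ``out_dir`` (or ``config.out_dir``) is set, every table is written as
    CSV alongside a ``manifest.json``.
    """
    t0 = time.time()
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: derive_seed(config.seed, stage)
        for stage in ("cohort", "split", "forest", "models", "disparity")
    }
    bundle: dict = {}
    counts: dict[str, int] = {}

    def _stage(name):
        log.info("stage %-10s t=%.1fs", name, time.time() - t0)

    _stage("cohort")
    cohort = _build_cohort(config, seeds["cohort"])
    bundle["cohort"] = cohort
    counts["cohort"] = len(cohort)

    _stage("select")
    selected = select_cohort(cohort)
    if len(selected) == 0:
        raise RuntimeError("stage 'select' retained no patients")
    bundle["selected"] = selected
    counts["selected"] = len(selected)

    _stage("label")
    criteria = (
        criteria_from_config(config.criteria_config)
        if config.criteria_config
        else default_criteria()
    )
    labels = label_matrix(selected, criteria)
    bundle["labels"] = labels
    counts["labels"] = len(labels)

    _stage("forest")
    forest = forest_table(
        labels, selected, n_boot=config.n_boot, ci_level=config.ci_level,
        seed=seeds["forest"],
    )
    bundle["forest"] = forest
    counts["forest"] = len(forest)

    _stage("model")
    flags = labels[config.modeling_criterion].to_numpy(dtype=bool)
    modeling = selected.iloc[np.flatnonzero(flags)]
    if len(modeling) < 2:
        raise RuntimeError(
            f"stage 'model': criterion {config.modeling_criterion!r} retained "
            f"{len(modeling)} patients"
        )
    train, test = split_cohort(
        modeling, train_fraction=config.train_fraction, seed=seeds["split"]
    )
    in_train = modeling["patient_id"].isin(train["patient_id"]).to_numpy()
    summary = summarize_cohort(modeling, in_train)
    bundle["summary"] = summary
    counts["summary"] = len(summary)

    specs = default_model_specs(seed=seeds["models"])
    if config.models is not None:
        wanted = list(config.models)
        unknown = set(wanted) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")
        specs = [s for s in specs if s.name in wanted]
    metrics, scores = run_model_battery(train, test, specs=specs, seed=seeds["models"])
    bundle["metrics"] = metrics
    bundle["scores"] = scores
    counts["metrics"] = len(metrics)
    counts["scores"] = len(scores)

    _stage("disparity")
    disparity = disparity_report(
        scores,
        models=[s.name for s in specs],
        n_perm=config.n_perm,
        seed=seeds["disparity"],
        alpha=config.alpha,
    )
    bundle["disparity"] = disparity
    counts["disparity"] = len(disparity)

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "row_counts": counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    bundle["manifest"] = manifest

    if out is not None:
        write_cohort_csv(cohort, out / "cohort.csv")
        write_cohort_csv(selected, out / "selected.csv")
        labels.astype(int).to_csv(out / "labels.csv")
        forest.to_csv(out / "forest.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        metrics.to_csv(out / "metrics.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        disparity.to_csv(out / "disparity.csv", index=False)
        manifest_no_time = {k: v for k, v in manifest.items() if k != "elapsed_s"}
        (out / "manifest.json").write_text(
            json.dumps(manifest_no_time, indent=2, sort_keys=True, default=str)
        )
    _stage("done")
    return bundle


def demo_config(
    out_dir: str | None = None,
    n_patients: int = 2000,
    models: Sequence[str] | None = None,
    n_perm: int = 200,
    n_boot: int = 200,
    seed: int = 0,
    inject: Sequence[Mapping] | None = None,
) -> RunConfig:
    """The packaged demo: a 2,000-patient synthetic cohort run end to end."""
    synthetic: dict = {"n_patients": n_patients}
    if inject:
        synthetic["inject"] = list(inject)
    return RunConfig(
        cohort_source={"synthetic": synthetic},
        models=list(models) if models is not None else None,
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        out_dir=out_dir,
    )
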