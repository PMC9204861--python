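"""Seeded synthetic ICU cohort generator.

Emulates the structure of the reference sepsis cohort: five social determinants
with configurable category marginals, three clinical features (first-24 h SOFA,
first-24 h SIRS, age), suspected-infection timing, ICD-9 code carriage per
code-set criterion, and an in-hospital death outcome generated from a logistic
model in the (0-1 scaled) features. Per-subgroup mortality targets, when given,
are hit by numerically solving additive log-odds offsets per determinant
category on the realised cohort. Subgroup effects (coefficient multipliers,
log-odds shifts, outcome label noise) can be injected to create disparity
scenarios; with no effects and no subgroup targets the cohort is exchangeable
across every determinant, the exact null of the downstream permutation tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort_summary import reference_summary
from .criteria import (
    CRITERION_NAMES,
    DETERMINANT_CATEGORIES,
    _ILLUSTRATIVE_CODE_SETS,
)

#: fixed bounds used to put features on a common 0-1 scale inside the
#: mortality model (generator-internal; the modelling pipeline learns its own
#: scaling bounds from training data)
_FEATURE_BOUNDS = {"sofa": (0.0, 24.0), "sirs": (0.0, 4.0), "age": (18.0, 100.0)}

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sofa_24h",
    "sirs_24h",
    "race",
    "sex",
    "marital",
    "insurance",
    "language",
    "icd9_codes",
    "infection_offset_h",
    "cardiothoracic_service",
    "in_hospital_death",
]


@dataclass(frozen=True)
class SubgroupEffect:
    """A distortion of the feature->outcome relationship for one subgroup.

    ``coef_multipliers`` rescales the mortality-model coefficients (keys
    "sofa", "sirs", "age"; a multiplier of -1 flips the feature's effect),
    ``logit_shift`` adds to the subgroup's log-odds, and ``label_noise`` is the
    probability that a member's outcome is replaced by a fair coin flip
    (1.0 makes the outcome independent of the features, so any score's
    expected AUC in the subgroup is 0.5).
    """

    coef_multipliers: Mapping[str, float] = field(default_factory=dict)
    logit_shift: float = 0.0
    label_noise: float = 0.0

    def is_null(self) -> bool:
        return (
            self.logit_shift == 0.0
            and self.label_noise == 0.0
            and all(v == 1.0 for v in self.coef_multipliers.values())
        )


def _default_marginals() -> dict[str, dict[str, float]]:
    summ = reference_summary()
    total = summ.groupby("determinant")["n"].transform("sum")
    out: dict[str, dict[str, float]] = {}
    for (det, cat), frac in zip(
        zip(summ["determinant"], summ["category"]), summ["n"] / total
    ):
        out.setdefault(det, {})[cat] = float(frac)
    return out


def _default_feature_distributions() -> dict[str, dict[str, float]]:
    # age ~ truncated normal; sofa ~ discretized gamma clipped to [0,24];
    # sirs ~ binomial(4, p)
    return {
        "age": {"mean": 65.0, "sd": 16.0, "low": 18.0, "high": 100.0},
        "sofa": {"shape": 1.6, "scale": 2.5},
        "sirs": {"n": 4, "p": 0.55},
    }


def _default_mortality_model() -> dict[str, float]:
    # logistic model on 0-1 scaled features; gives overall in-hospital
    # mortality ~0.14 and true-score discrimination (AUC) ~0.75
    return {"intercept": -4.0, "sofa": 5.0, "sirs": 1.0, "age": 1.5}


def _default_code_rates() -> dict[str, float]:
    # marginal carriage probability of a qualifying code per code-set
    # criterion; ordered roughly by the sensitivity spread seen across
    # claims-based definitions (Angus broadest, Explicit narrowest)
    return {"Explicit": 0.10, "Angus": 0.40, "Martin": 0.28, "CMS": 0.18, "CDC": 0.33}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one synthetic cohort draw."""

    n_patients: int
    determinant_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_marginals
    )
    mortality_model: Mapping[str, float] = field(default_factory=_default_mortality_model)
    subgroup_effects: Mapping[tuple[str, str], SubgroupEffect] = field(
        default_factory=dict
    )
    feature_distributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_feature_distributions
    )
    infection_timing: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 0.0, "sd": 12.0}
    )
    sepsis_code_rates: Mapping[str, float] = field(default_factory=_default_code_rates)
    mortality_targets: Mapping[tuple[str, str], float] | None = None
    p_cardiothoracic: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        for det, marg in self.determinant_marginals.items():
            if det not in DETERMINANT_CATEGORIES:
                raise ValueError(f"unknown determinant {det!r}")
            for cat in marg:
                if cat not in DETERMINANT_CATEGORIES[det]:
                    raise ValueError(f"unknown category {cat!r} for determinant {det!r}")
            total = float(sum(marg.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"marginals for determinant {det!r} sum to {total!r}, not 1"
                )
        missing = set(DETERMINANT_CATEGORIES) - set(self.determinant_marginals)
        if missing:
            raise ValueError(f"marginals missing for determinants {sorted(missing)}")
        for det, cat in self.subgroup_effects:
            if cat not in DETERMINANT_CATEGORIES.get(det, ()):
                raise ValueError(f"unknown subgroup ({det!r}, {cat!r})")
        if self.mortality_targets:
            for (det, cat), t in self.mortality_targets.items():
                if cat not in DETERMINANT_CATEGORIES.get(det, ()):
                    raise ValueError(f"unknown target subgroup ({det!r}, {cat!r})")
                if not 0.0 < t < 1.0:
                    raise ValueError(f"mortality target for ({det}, {cat}) not in (0,1)")


def spec_from_summary(
    summary: pd.DataFrame, n_patients: int | None = None, seed: int = 0, **overrides
) -> CohortSpec:
    """Calibrate a CohortSpec to a cohort summary table.

    ``summary`` must carry columns determinant, category, n, deaths with every
    enumerated category present for each determinant. Marginals become
    n_category / n_total per determinant and mortality targets deaths / n.
    """
    needed = {"determinant", "category", "n", "deaths"}
    if not needed.issubset(summary.columns):
        raise ValueError(f"summary must have columns {sorted(needed)}")
    marginals: dict[str, dict[str, float]] = {}
    targets: dict[tuple[str, str], float] = {}
    totals = summary.groupby("determinant")["n"].sum()
    for det, cats in DETERMINANT_CATEGORIES.items():
        sub = summary[summary["determinant"] == det].set_index("category")
        missing = set(cats) - set(sub.index)
        if missing or set(sub.index) - set(cats):
            raise ValueError(
                f"determinant {det!r}: summary categories {sorted(sub.index)} do not "
                f"cover the enumerated set {list(cats)}"
            )
        marginals[det] = {c: float(sub.loc[c, "n"] / totals[det]) for c in cats}
        for c in cats:
            if sub.loc[c, "n"] > 0:
                targets[(det, c)] = float(sub.loc[c, "deaths"] / sub.loc[c, "n"])
    n = int(n_patients if n_patients is not None else totals.iloc[0])
    spec = CohortSpec(
        n_patients=n,
        determinant_marginals=marginals,
        mortality_targets=targets,
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


def default_spec(n_patients: int = 5783, seed: int = 0, **overrides) -> CohortSpec:
    """Spec calibrated to the packaged reference cohort summary."""
    return spec_from_summary(reference_summary(), n_patients=n_patients, seed=seed,
                             **overrides)


def null_spec(n_patients: int, seed: int = 0, subgroup_share: float = 0.2) -> CohortSpec:
    """An exchangeable-null spec for operating-characteristic simulations.

    No subgroup effects and no per-subgroup mortality targets, so every
    determinant label is independent of (features, outcome). One determinant
    (race) has a two-category marginal {Asian: subgroup_share, White: rest} so
    a subgroup of controlled relative size exists; infection timing is kept
    well inside the selection window and the surgical-service rate is zero so
    cohort selection retains (essentially) everyone.
    """
    marginals = _default_marginals()
    marginals["race"] = {"Asian": subgroup_share, "White": 1.0 - subgroup_share}
    spec = CohortSpec(
        n_patients=n_patients,
        determinant_marginals=marginals,
        infection_timing={"mean": 0.0, "sd": 5.0},
        p_cardiothoracic=0.0,
        seed=seed,
    )
    spec.validate()
    return spec


def inject_subgroup_effect(
    spec: CohortSpec, determinant: str, category: str, distortion: SubgroupEffect
) -> CohortSpec:
    """Return a spec identical to ``spec`` except for one subgroup distortion."""
    if category not in DETERMINANT_CATEGORIES.get(determinant, ()):
        raise ValueError(f"unknown subgroup ({determinant!r}, {category!r})")
    effects = dict(spec.subgroup_effects)
    effects[(determinant, category)] = distortion
    return dataclasses.replace(spec, subgroup_effects=effects)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _scaled(values: np.ndarray, feature: str) -> np.ndarray:
    lo, hi = _FEATURE_BOUNDS[feature]
    return (values - lo) / (hi - lo)


def _linear_predictor(spec: CohortSpec, feats: dict[str, np.ndarray],
                      groups: dict[str, np.ndarray]) -> np.ndarray:
    mm = spec.mortality_model
    n = len(feats["sofa"])
    lp = np.full(n, float(mm["intercept"]))
    base_coef = {k: float(mm[k]) for k in ("sofa", "sirs", "age")}
    coef = {k: np.full(n, v) for k, v in base_coef.items()}
    shift = np.zeros(n)
    for (det, cat), eff in sorted(spec.subgroup_effects.items()):
        members = groups[det] == cat
        for k, mult in eff.coef_multipliers.items():
            coef[k][members] = base_coef[k] * float(mult)
        shift[members] += float(eff.logit_shift)
    for k in ("sofa", "sirs", "age"):
        lp += coef[k] * _scaled(feats[k], k)
    return lp + shift


def _calibrate_offsets(
    lp: np.ndarray,
    groups: dict[str, np.ndarray],
    targets: Mapping[tuple[str, str], float],
    n_rounds: int = 8,
) -> np.ndarray:
    """Additive per-category log-odds offsets hitting the mortality targets.

    Cyclic coordinate updates: for each (determinant, category) in turn, solve
    the scalar offset increment that makes the members' mean death probability
    equal the target, holding all other offsets fixed. The constraints overlap
    (every patient belongs to one category per determinant) so a few rounds are
    iterated; residuals shrink geometrically and are far below sampling noise.
    """
    total = np.zeros_like(lp)
    offsets = {key: 0.0 for key in targets}
    member_idx = {
        (det, cat): np.flatnonzero(groups[det] == cat) for (det, cat) in targets
    }
    for _ in range(n_rounds):
        for key in sorted(targets):
            idx = member_idx[key]
            if idx.size == 0:
                continue
            t = targets[key]
            base = lp[idx] + total[idx]

            def f(x):
                return float(expit(base + x).mean() - t)

            delta = brentq(f, -30.0, 30.0, xtol=1e-10)
            offsets[key] += delta
            total[idx] += delta
    return total


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort. Identical spec (including seed) => identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    groups: dict[str, np.ndarray] = {}
    for det in DETERMINANT_CATEGORIES:  # fixed iteration order
        marg = spec.determinant_marginals[det]
        cats = list(marg)
        p = np.array([marg[c] for c in cats], dtype=float)
        p = p / p.sum()
        groups[det] = rng.choice(np.array(cats, dtype=object), size=n, p=p)

    fd = spec.feature_distributions
    a = (fd["age"]["low"] - fd["age"]["mean"]) / fd["age"]["sd"]
    b = (fd["age"]["high"] - fd["age"]["mean"]) / fd["age"]["sd"]
    age = truncnorm.rvs(
        a, b, loc=fd["age"]["mean"], scale=fd["age"]["sd"], size=n, random_state=rng
    )
    sofa = np.clip(
        np.rint(rng.gamma(fd["sofa"]["shape"], fd["sofa"]["scale"], size=n)), 0, 24
    ).astype(int)
    sirs = rng.binomial(int(fd["sirs"]["n"]), float(fd["sirs"]["p"]), size=n)
    offset_h = rng.normal(
        float(spec.infection_timing.get("mean", 0.0)),
        float(spec.infection_timing.get("sd", 12.0)),
        size=n,
    )
    service = rng.random(n) < float(spec.p_cardiothoracic)

    # ICD-9 code carriage: one Bernoulli per code-set criterion, independent
    # across criteria; a qualifying patient carries that criterion's
    # representative (lexicographically first) code
    code_crits = [c for c in CRITERION_NAMES if c in spec.sepsis_code_rates]
    carries = rng.random((n, len(code_crits))) < np.array(
        [float(spec.sepsis_code_rates[c]) for c in code_crits]
    )
    rep_codes = [sorted(_ILLUSTRATIVE_CODE_SETS[c])[0] for c in code_crits]
    icd9 = [
        frozenset(rep_codes[j] for j in np.flatnonzero(carries[i]))
        for i in range(n)
    ]

    feats = {"sofa": sofa.astype(float), "sirs": sirs.astype(float), "age": age}
    lp = _linear_predictor(spec, feats, groups)
    if spec.mortality_targets:
        lp = lp + _calibrate_offsets(lp, groups, spec.mortality_targets)
    death = rng.random(n) < expit(lp)

    for (det, cat), eff in sorted(spec.subgroup_effects.items()):
        if eff.label_noise > 0.0:
            members = np.flatnonzero(groups[det] == cat)
            noisy = members[rng.random(members.size) < float(eff.label_noise)]
            death[noisy] = rng.random(noisy.size) < 0.5

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "sofa_24h": sofa,
            "sirs_24h": sirs,
            "race": groups["race"],
            "sex": groups["sex"],
            "marital": groups["marital"],
            "insurance": groups["insurance"],
            "language": groups["language"],
            "icd9_codes": icd9,
            "infection_offset_h": offset_h,
            "cardiothoracic_service": service,
            "in_hospital_death": death.astype(int),
        },
        columns=PATIENT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort_csv(patients: pd.DataFrame, path) -> None:
    """One header row, one row per patient; codes semicolon-joined, death 0/1."""
    out = patients.copy()
    out["icd9_codes"] = [";".join(sorted(c)) for c in out["icd9_codes"]]
    out["cardiothoracic_service"] = out["cardiothoracic_service"].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    df["icd9_codes"] = [
        frozenset(str(s).split(";")) if isinstance(s, str) and s else frozenset()
        for s in df["icd9_codes"].fillna("")
    ]
    df["cardiothoracic_service"] = df["cardiothoracic_service"].astype(bool)
    return df


def spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "n_patients": spec.n_patients,
        "determinant_marginals": {k: dict(v) for k, v in spec.determinant_marginals.items()},
        "mortality_model": dict(spec.mortality_model),
        "feature_distributions": {k: dict(v) for k, v in spec.feature_distributions.items()},
        "infection_timing": dict(spec.infection_timing),
        "sepsis_code_rates": dict(spec.sepsis_code_rates),
        "p_cardiothoracic": spec.p_cardiothoracic,
        "seed": spec.seed,
        "subgroup_effects": [
            {
                "determinant": det,
                "category": cat,
                "coef_multipliers": dict(eff.coef_multipliers),
                "logit_shift": eff.logit_shift,
                "label_noise": eff.label_noise,
            }
            for (det, cat), eff in sorted(spec.subgroup_effects.items())
        ],
        "mortality_targets": (
            None
            if spec.mortality_targets is None
            else [
                {"determinant": det, "category": cat, "rate": rate}
                for (det, cat), rate in sorted(spec.mortality_targets.items())
            ]
        ),
    }
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    effects = {
        (e["determinant"], e["category"]): SubgroupEffect(
            coef_multipliers=e.get("coef_multipliers", {}),
            logit_shift=float(e.get("logit_shift", 0.0)),
            label_noise=float(e.get("label_noise", 0.0)),
        )
        for e in d.get("subgroup_effects", [])
    }
    targets = d.get("mortality_targets")
    if targets is not None:
        targets = {(t["determinant"], t["category"]): float(t["rate"]) for t in targets}
    kwargs = {}
    for key in (
        "determinant_marginals",
        "mortality_model",
        "feature_distributions",
        "infection_timing",
        "sepsis_code_rates",
        "p_cardiothoracic",
        "seed",
    ):
        if key in d:
            kwargs[key] = d[key]
    spec = CohortSpec(
        n_patients=int(d["n_patients"]),
        subgroup_effects=effects,
        mortality_targets=targets,
        **kwargs,
    )
    spec.validate()
    return spec


def write_spec_yaml(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_spec_yaml(path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
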