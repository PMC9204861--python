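"""Operating-characteristic simulations for the resampling procedures.

These drive the package's own validity checks: the empirical type-I error of
the one-tailed subgroup-vs-whole AUC permutation test under an exchangeable
null cohort, and the empirical coverage of the percentile bootstrap CI for a
subgroup sepsis proportion. Both run the same code paths as a real analysis
(cohort generation, selection, split, model fitting, testing) with all
randomness derived from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._seeds import derive_seed
from .cohort import generate_cohort, null_spec
from .criteria import select_cohort
from .models import (
    FEATURES,
    OUTCOME,
    YoudenThresholdClassifier,
    apply_scaler,
    fit_scaler,
    split_cohort,
)
from .permutation import permutation_test_vs_whole
from .prevalence import bootstrap_ci


@dataclass(frozen=True)
class TypeIResult:
    rejection_rate: float
    n_replicates: int
    n_tested: int
    alpha: float
    p_values: np.ndarray


def simulate_null_type_i(
    n_replicates: int = 500,
    cohort_size: int = 2000,
    subgroup_share: float = 0.2,
    train_fraction: float = 0.7,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    tail: str = "less",
) -> TypeIResult:
    """Type-I error of the one-tailed test under an exchangeable null cohort.

    Each replicate: draw a null cohort (no subgroup effects, no subgroup
    mortality targets; one race category holds ``subgroup_share`` of the
    cohort), apply cohort selection, split 7:3, fit a logistic mortality model
    on the training set, score the test set, and run the subgroup-vs-whole
    permutation test for the minority category with a fixed tail. The
    rejection fraction at ``alpha`` estimates the test's size.
    """
    base = null_spec(cohort_size, subgroup_share=subgroup_share)
    rejections = 0
    tested = 0
    p_values = np.full(n_replicates, np.nan)
    for r in range(n_replicates):
        spec = replace(base, seed=derive_seed(seed, "cohort", r))
        cohort = select_cohort(generate_cohort(spec))
        train, test = split_cohort(
            cohort, train_fraction=train_fraction, seed=derive_seed(seed, "split", r)
        )
        bounds = fit_scaler(train)
        clf = YoudenThresholdClassifier(random_state=derive_seed(seed, "fit", r))
        clf.fit(apply_scaler(bounds, train), train[OUTCOME].to_numpy(dtype=int))
        scores = clf.decision_function(apply_scaler(bounds, test))
        membership = (test["race"] == "Asian").to_numpy()
        res = permutation_test_vs_whole(
            scores,
            test[OUTCOME].to_numpy(dtype=int),
            membership,
            n_perm=n_perm,
            seed=derive_seed(seed, "perm", r),
            tail=tail,
        )
        if res.undefined:
            continue
        tested += 1
        p_values[r] = res.p_value
        if res.p_value <= alpha:
            rejections += 1
    return TypeIResult(
        rejection_rate=rejections / tested if tested else float("nan"),
        n_replicates=n_replicates,
        n_tested=tested,
        alpha=alpha,
        p_values=p_values,
    )


@dataclass(frozen=True)
class CoverageResult:
    coverage: float
    n_replicates: int
    nominal: float


def simulate_bootstrap_coverage(
    n_replicates: int = 500,
    n_subgroup: int = 200,
    true_proportion: float = 0.3,
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
) -> CoverageResult:
    """Empirical coverage of the percentile bootstrap CI for a proportion.

    Each replicate draws a subgroup of ``n_subgroup`` independent sepsis flags
    with success probability ``true_proportion``, builds the percentile CI
    from ``n_boot`` resamples, and checks whether it contains the truth.
    """
    covered = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, "flags", r))
        flags = rng.random(n_subgroup) < true_proportion
        est = bootstrap_ci(
            flags, n_boot=n_boot, ci_level=ci_level, seed=derive_seed(seed, "boot", r)
        )
        if est.ci_low <= true_proportion <= est.ci_high:
            covered += 1
    return CoverageResult(
        coverage=covered / n_replicates, n_replicates=n_replicates, nominal=ci_level
    )
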