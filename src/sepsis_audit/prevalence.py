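"""Subgroup sepsis prevalence with percentile-bootstrap confidence intervals.

For every (determinant category x criterion) cell the proportion of subgroup
members flagged as sepsis is reported with a percentile bootstrap CI built by
resampling the subgroup's flags with replacement (subgroup size preserved).
The within-subgroup resampling scheme and the percentile method are the
simplest choices consistent with per-subgroup intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .criteria import DETERMINANT_CATEGORIES


class EmptySubgroupError(ValueError):
    """Raised when a proportion is requested for a subgroup with no members."""


@dataclass(frozen=True)
class ProportionEstimate:
    determinant: str
    category: str
    criterion_name: str
    n_subgroup: int
    proportion: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    seed: int


def subgroup_proportion(flags: Sequence, membership: Sequence) -> float:
    """Fraction of subgroup members whose sepsis flag is set."""
    flags = np.asarray(flags, dtype=bool)
    membership = np.asarray(membership, dtype=bool)
    if flags.shape != membership.shape:
        raise ValueError("flags and membership must have equal length")
    m = int(membership.sum())
    if m == 0:
        raise EmptySubgroupError("subgroup has no members")
    return float(flags[membership].sum() / m)


_MAX_CHUNK_ELEMENTS = 5_000_000  # bound resampling-matrix memory


def bootstrap_ci(
    flags: Sequence,
    membership: Sequence | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    *,
    determinant: str = "",
    category: str = "",
    criterion_name: str = "",
) -> ProportionEstimate:
    """Percentile bootstrap CI for a subgroup sepsis proportion.

    Resamples the subgroup's flags with replacement ``n_boot`` times and takes
    the (1-ci_level)/2 and 1-(1-ci_level)/2 percentiles of the resampled
    proportions. ``ci_level=0`` collapses both endpoints onto the resampling
    median.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 <= ci_level < 1.0:
        raise ValueError("ci_level must be in [0, 1)")
    flags = np.asarray(flags, dtype=bool)
    if membership is None:
        membership = np.ones_like(flags, dtype=bool)
    prop = subgroup_proportion(flags, membership)
    member_flags = flags[np.asarray(membership, dtype=bool)].astype(np.float64)
    m = member_flags.size
    rng = np.random.default_rng(seed)
    props = np.empty(n_boot)
    chunk = max(1, _MAX_CHUNK_ELEMENTS // m)
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, m, size=(stop - start, m))
        props[start:stop] = member_flags[idx].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(props, [100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)])
    # the interval always brackets the point estimate (percentile quantiles
    # from few resamples can otherwise land entirely on one side of it)
    if ci_level > 0.0:
        lo, hi = min(lo, prop), max(hi, prop)
    return ProportionEstimate(
        determinant=determinant,
        category=category,
        criterion_name=criterion_name,
        n_subgroup=m,
        proportion=prop,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        ci_level=ci_level,
        seed=-1 if seed is None else int(seed),
    )


def forest_table(
    labels: pd.DataFrame,
    patients: pd.DataFrame,
    determinants: Sequence[str] | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot-ready long table of per-subgroup, per-criterion proportions.

    One row per (determinant category x criterion), enumerated from the
    canonical category sets so the table is rectangular; a category with no
    members yields a flagged row with NaN estimates rather than being dropped.
    """
    if len(labels) != len(patients):
        raise ValueError("label matrix and patient table are not aligned")
    determinants = list(determinants) if determinants is not None else list(
        DETERMINANT_CATEGORIES
    )
    rows = []
    for det in determinants:
        cats = DETERMINANT_CATEGORIES[det]
        group = patients[det].to_numpy()
        for cat, crit in product(cats, labels.columns):
            membership = group == cat
            cell_seed = derive_seed(seed, "forest", det, cat, crit)
            flags = labels[crit].to_numpy(dtype=bool)
            if membership.sum() == 0:
                rows.append(
                    dict(
                        determinant=det, category=cat, criterion=crit, n=0,
                        proportion=np.nan, ci_low=np.nan, ci_high=np.nan,
                        n_boot=n_boot, ci_level=ci_level, seed=cell_seed,
                        flag="no_members",
                    )
                )
                continue
            est = bootstrap_ci(
                flags, membership, n_boot=n_boot, ci_level=ci_level, seed=cell_seed,
                determinant=det, category=cat, criterion_name=crit,
            )
            rows.append(
                dict(
                    determinant=det, category=cat, criterion=crit, n=est.n_subgroup,
                    proportion=est.proportion, ci_low=est.ci_low, ci_high=est.ci_high,
                    n_boot=n_boot, ci_level=ci_level, seed=cell_seed, flag="",
                )
            )
    return pd.DataFrame(rows)


def plot_forest(forest: pd.DataFrame, path) -> None:
    """Render the forest table (one panel, colors by criterion) to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = forest[forest["flag"] == ""].copy()
    plotted["label"] = plotted["determinant"] + ": " + plotted["category"]
    ylabels = list(dict.fromkeys(plotted["label"]))
    ypos = {lab: i for i, lab in enumerate(ylabels)}
    criteria = list(dict.fromkeys(plotted["criterion"]))
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(ylabels) + 2))
    for k, crit in enumerate(criteria):
        sub = plotted[plotted["criterion"] == crit]
        y = np.array([ypos[lab] for lab in sub["label"]]) + 0.12 * (
            k - (len(criteria) - 1) / 2
        )
        ax.errorbar(
            sub["proportion"], y,
            xerr=[sub["proportion"] - sub["ci_low"], sub["ci_high"] - sub["proportion"]],
            fmt="o", ms=3, lw=1, color=cmap(k % 10), label=crit,
        )
    ax.set_yticks(range(len(ylabels)), ylabels)
    ax.invert_yaxis()
    ax.set_xlabel("proportion identified as sepsis")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
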