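"""Permutation tests for subgroup disparities in classifier AUC.

Two resampling nulls, both preserving group sizes:

* subgroup vs. whole test set — for each permutation a uniformly random
  subset of the test set of the subgroup's size replaces the subgroup and the
  AUC difference (subset minus whole) is recomputed. This is the minimal
  exchangeability null for "does this subgroup's AUC differ from the whole
  test set's".
* pairwise — the two groups' (score, label) pairs are pooled and randomly
  re-split into the original sizes; the statistic is AUC(A) - AUC(B) and the
  test is two-tailed on its absolute value.

p-values use the add-one convention (1 + #extreme) / (n_perm + 1), which is
never 0 and keeps the tests valid at any level. A permutation whose resampled
group is single-class leaves the AUC undefined; such draws are redrawn and the
redraw count is surfaced (it matters for very small subgroups).

The one-tailed test's tail can be fixed ("less"/"greater") or follow the sign
of the observed difference ("auto", the reporting convention of disparity
tables). Note that the sign-adaptive variant is equivalent to reporting the
smaller of the two one-tailed p-values, so reading it at level alpha yields a
procedure with size close to 2*alpha; fix the tail (or halve alpha) when
strict size control is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .criteria import DETERMINANT_CATEGORIES
from .models import auc


@dataclass(frozen=True)
class PermutationResult:
    model_name: str
    determinant: str
    category: str | tuple[str, str]
    observed_diff: float
    p_value: float
    n_perm: int
    tail: str  # "one_tailed" | "two_tailed"
    direction: str  # "less" | "greater" | "" (two-tailed)
    n_undefined_permutations: int
    seed: int | None
    undefined: bool = False


def _undefined_result(model, det, cat, n_perm, tail, seed) -> PermutationResult:
    return PermutationResult(
        model_name=model, determinant=det, category=cat,
        observed_diff=float("nan"), p_value=float("nan"), n_perm=n_perm,
        tail=tail, direction="", n_undefined_permutations=0, seed=seed,
        undefined=True,
    )


def observed_diff_vs_whole(
    scores: Sequence, labels: Sequence, membership: Sequence
) -> float:
    """AUC(subgroup) - AUC(whole test set); NaN if the subgroup is single-class."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    m = np.asarray(membership, dtype=bool)
    whole = auc(s, y)
    if np.isnan(whole):
        raise ValueError("whole test set must contain both outcome classes")
    return auc(s[m], y[m]) - whole


def permutation_test_vs_whole(
    scores: Sequence,
    labels: Sequence,
    membership: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "auto",
    *,
    model_name: str = "",
    determinant: str = "",
    category: str = "",
    max_redraws: int | None = None,
) -> PermutationResult:
    """One-tailed subgroup-vs-whole AUC permutation test."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("auto", "less", "greater"):
        raise ValueError("tail must be 'auto', 'less' or 'greater'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    m = np.asarray(membership, dtype=bool)
    n = s.size
    m_size = int(m.sum())
    if m_size < 2 or np.isnan(auc(s[m], y[m])):
        return _undefined_result(model_name, determinant, category, n_perm,
                                 "one_tailed", seed)
    obs = observed_diff_vs_whole(s, y, m)
    whole = auc(s, y)
    rng = np.random.default_rng(seed)
    if max_redraws is None:
        max_redraws = 100 * n_perm
    diffs = np.empty(n_perm)
    redraws = 0
    for i in range(n_perm):
        while True:
            idx = rng.choice(n, size=m_size, replace=False)
            a = auc(s[idx], y[idx])
            if not np.isnan(a):
                break
            redraws += 1
            if redraws > max_redraws:
                return _undefined_result(model_name, determinant, category,
                                         n_perm, "one_tailed", seed)
        diffs[i] = a - whole
    direction = tail if tail != "auto" else ("less" if obs < 0 else "greater")
    if direction == "less":
        extreme = int(np.sum(diffs <= obs))
    else:
        extreme = int(np.sum(diffs >= obs))
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        model_name=model_name, determinant=determinant, category=category,
        observed_diff=float(obs), p_value=float(p), n_perm=n_perm,
        tail="one_tailed", direction=direction,
        n_undefined_permutations=redraws, seed=seed,
    )


def pairwise_permutation_test(
    scores_a: Sequence,
    labels_a: Sequence,
    scores_b: Sequence,
    labels_b: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    model_name: str = "",
    determinant: str = "",
    categories: tuple[str, str] = ("", ""),
    max_redraws: int | None = None,
) -> PermutationResult:
    """Two-tailed pairwise AUC permutation test between two subgroups.

    The pooled (score, label) pairs are put in a canonical order before
    re-splitting, so the permutation null does not depend on which group is
    passed first: swapping A and B under the same seed negates the observed
    difference and leaves the p-value unchanged when the group sizes match.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sa = np.asarray(scores_a, dtype=float)
    ya = np.asarray(labels_a).astype(bool)
    sb = np.asarray(scores_b, dtype=float)
    yb = np.asarray(labels_b).astype(bool)
    auc_a, auc_b = auc(sa, ya), auc(sb, yb)
    if np.isnan(auc_a) or np.isnan(auc_b):
        return _undefined_result(model_name, determinant, categories, n_perm,
                                 "two_tailed", seed)
    obs = auc_a - auc_b
    pool_s = np.concatenate([sa, sb])
    pool_y = np.concatenate([ya, yb])
    order = np.lexsort((pool_y, pool_s))
    pool_s, pool_y = pool_s[order], pool_y[order]
    na, nb = sa.size, sb.size
    n = na + nb
    rng = np.random.default_rng(seed)
    if max_redraws is None:
        max_redraws = 100 * n_perm
    diffs = np.empty(n_perm)
    redraws = 0
    for i in range(n_perm):
        while True:
            perm = rng.permutation(n)
            ia, ib = perm[:na], perm[na:]
            a1 = auc(pool_s[ia], pool_y[ia])
            a2 = auc(pool_s[ib], pool_y[ib])
            if not (np.isnan(a1) or np.isnan(a2)):
                break
            redraws += 1
            if redraws > max_redraws:
                return _undefined_result(model_name, determinant, categories,
                                         n_perm, "two_tailed", seed)
        diffs[i] = a1 - a2
    extreme = int(np.sum(np.abs(diffs) >= abs(obs)))
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        model_name=model_name, determinant=determinant, category=categories,
        observed_diff=float(obs), p_value=float(p), n_perm=n_perm,
        tail="two_tailed", direction="",
        n_undefined_permutations=redraws, seed=seed,
    )


def disparity_report(
    scores: pd.DataFrame,
    determinants: Sequence[str] | None = None,
    models: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tail: str = "auto",
) -> pd.DataFrame:
    """Full disparity audit from the per-patient score table.

    For every model x determinant category: the one-tailed subgroup-vs-whole
    test; for every model x category pair within a determinant: the two-tailed
    pairwise test. Categories are enumerated from the canonical sets;
    undefined cells (empty or single-class subgroups) appear as flagged rows,
    never silently dropped. Deterministic under the master ``seed``.
    """
    determinants = list(determinants) if determinants is not None else list(
        DETERMINANT_CATEGORIES
    )
    available = set(scores["model"].unique())
    models = list(models) if models is not None else sorted(available)
    missing = [m for m in models if m not in available]
    if missing:
        raise ValueError(f"models missing from score file: {missing}")
    rows = []

    def _append(res: PermutationResult, comparison: str, cat, cat_b) -> None:
        rows.append(
            dict(
                model=res.model_name, determinant=res.determinant,
                comparison=comparison, category=cat, category_b=cat_b,
                observed_diff=res.observed_diff, p_value=res.p_value,
                tail=res.tail, direction=res.direction, n_perm=res.n_perm,
                n_undefined_permutations=res.n_undefined_permutations,
                undefined=res.undefined,
                significant=bool((not res.undefined) and res.p_value <= alpha),
                seed=res.seed,
            )
        )

    for model in models:
        sub = scores[scores["model"] == model]
        s = sub["score"].to_numpy(dtype=float)
        y = sub["label"].to_numpy(dtype=int)
        for det in determinants:
            group = sub[det].to_numpy()
            cats = DETERMINANT_CATEGORIES[det]
            for cat in cats:
                membership = group == cat
                cell_seed = derive_seed(seed, "vs_whole", model, det, cat)
                if membership.sum() == 0:
                    res = _undefined_result(model, det, cat, n_perm, "one_tailed",
                                            cell_seed)
                else:
                    res = permutation_test_vs_whole(
                        s, y, membership, n_perm=n_perm, seed=cell_seed, tail=tail,
                        model_name=model, determinant=det, category=cat,
                    )
                _append(res, "vs_whole", cat, "")
            for cat_a, cat_b in combinations(cats, 2):
                ma, mb = group == cat_a, group == cat_b
                cell_seed = derive_seed(seed, "pairwise", model, det, cat_a, cat_b)
                if ma.sum() == 0 or mb.sum() == 0:
                    res = _undefined_result(model, det, (cat_a, cat_b), n_perm,
                                            "two_tailed", cell_seed)
                else:
                    res = pairwise_permutation_test(
                        s[ma], y[ma], s[mb], y[mb], n_perm=n_perm, seed=cell_seed,
                        model_name=model, determinant=det,
                        categories=(cat_a, cat_b),
                    )
                _append(res, "pairwise", cat_a, cat_b)
    return pd.DataFrame(rows)
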