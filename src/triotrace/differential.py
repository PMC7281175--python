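"""Pairwise group comparisons: fold changes, t-tests, discrete relations.

Fold changes are reported on the linear intensity scale as
``mean(first-named group) / mean(second-named group)`` — the convention of
the study's metabolite summary tables (e.g. glucose-1-phosphate W vs P:
0.109/0.148 → fold 0.74). The discrete relation (``>``, ``<``, ``=``)
combines the p-value with the sign of the mean difference: ``=`` means "not
significant at alpha", not numerically equal.

Differential calling follows the two published criteria: metabolites are
called on p < alpha alone; genes additionally require a fold change ≥ 1.5
or ≤ 0.67. No multiple-testing correction is applied by default, matching
the per-comparison p < 0.05 criterion; a Benjamini–Hochberg option exists.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import DesignError, PeakTable

__all__ = [
    "PairwiseResult",
    "DemCriteria",
    "pairwise_compare",
    "call_dem",
    "fold_change_report",
]


@dataclasses.dataclass
class DemCriteria:
    """Significance and (for genes) fold-change cut-offs.

    alpha: per-comparison significance level (strict inequality).
    fc_low / fc_high: gene-mode fold window — a gene is differential only if
    its fold is ≤ fc_low or ≥ fc_high in addition to p < alpha.
    """

    alpha: float = 0.05
    fc_low: float = 0.67
    fc_high: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.fc_low < 1.0 < self.fc_high:
            raise ValueError("need fc_low < 1 < fc_high")


@dataclasses.dataclass
class PairwiseResult:
    analyte_id: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean_a / mean_b, linear scale; NaN if mean_b == 0
    p_value: float
    relation: str  # group_a vs group_b: one of ">", "<", "="

    @property
    def fold_undefined(self) -> bool:
        return math.isnan(self.fold_change)


def _relation(mean_a: float, mean_b: float, p: float, alpha: float) -> str:
    if not (p < alpha):  # NaN p counts as not significant
        return "="
    return ">" if mean_a > mean_b else "<"


def pairwise_compare(
    table: PeakTable,
    group_a: str,
    group_b: str,
    criteria: DemCriteria | None = None,
    test: str = "student",
    log_scale: bool = False,
) -> list[PairwiseResult]:
    """Compare two groups analyte-by-analyte with a two-sample t-test.

    ``test`` selects the classic Student's t-test (pooled variance) or
    Welch's unequal-variance variant. Means and fold changes are always
    computed on the linear scale; with ``log_scale`` the t-test itself runs
    on log-transformed intensities (all values must then be positive).
    """
    criteria = criteria or DemCriteria()
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    a = table.group_values(group_a)
    b = table.group_values(group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError("each group needs at least 2 samples")
    a_arr, b_arr = a.to_numpy(float), b.to_numpy(float)
    if np.isnan(a_arr).any() or np.isnan(b_arr).any():
        raise ValueError("missing values present; impute first")
    mean_a, mean_b = a_arr.mean(axis=1), b_arr.mean(axis=1)
    ta, tb = (np.log(a_arr), np.log(b_arr)) if log_scale else (a_arr, b_arr)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # zero-variance analytes give 0/0 t statistics -> NaN p (no evidence)
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(ta, tb, axis=1, equal_var=(test == "student"))
        fold = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.nan)
    # identical groups give 0/0 t statistics -> NaN p; treat as no evidence
    out = []
    for i, analyte in enumerate(table.analyte_ids):
        p_i = float(p[i])
        out.append(
            PairwiseResult(
                analyte_id=analyte,
                group_a=group_a,
                group_b=group_b,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                fold_change=float(fold[i]),
                p_value=p_i,
                relation=_relation(mean_a[i], mean_b[i], p_i, criteria.alpha),
            )
        )
    return out


def call_dem(
    results: list[PairwiseResult],
    criteria: DemCriteria | None = None,
    mode: str = "metabolite",
    bh_correct: bool = False,
) -> list[PairwiseResult]:
    """Filter pairwise results down to the differential ones.

    metabolite mode: p < alpha. gene mode: p < alpha AND (fold ≥ fc_high OR
    fold ≤ fc_low). ``bh_correct`` optionally applies Benjamini–Hochberg
    across the result list before thresholding (off by default).
    """
    criteria = criteria or DemCriteria()
    if mode not in ("metabolite", "gene"):
        raise ValueError(f"unknown mode {mode!r}")
    pvals = np.array([r.p_value for r in results], dtype=float)
    if bh_correct and len(pvals):
        finite = ~np.isnan(pvals)
        adj = pvals.copy()
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adj
    kept = []
    for r, p in zip(results, pvals):
        if not (p < criteria.alpha):
            continue
        if mode == "gene":
            f = r.fold_change
            if math.isnan(f) or not (f >= criteria.fc_high or f <= criteria.fc_low):
                continue
        kept.append(r)
    return kept


def fold_change_report(
    table: PeakTable,
    groups: tuple[str, str, str] = ("W", "P", "T"),
    criteria: DemCriteria | None = None,
    test: str = "student",
) -> "pd.DataFrame":
    """Three-group summary mirroring the published table layout.

    One row per analyte with the three group means and the three fold/p
    pairs for (first vs second), (second vs third), (first vs third) — for
    the default trio: W vs P, P vs T, W vs T. Folds are given both at full
    precision and rounded to 2 decimals.
    """
    import pandas as pd

    g1, g2, g3 = groups
    pairs = [(g1, g2), (g2, g3), (g1, g3)]
    per_pair = {
        pair: pairwise_compare(table, *pair, criteria=criteria, test=test)
        for pair in pairs
    }
    rows = []
    for i, analyte in enumerate(table.analyte_ids):
        row: dict = {"analyte_id": analyte}
        for g in groups:
            row[f"mean_{g}"] = float(table.group_values(g).to_numpy(float)[i].mean())
        for pair in pairs:
            r = per_pair[pair][i]
            key = f"{pair[0]}_vs_{pair[1]}"
            row[f"fold_{key}"] = r.fold_change
            row[f"fold_{key}_2dp"] = round(r.fold_change, 2)
            row[f"p_{key}"] = r.p_value
            row[f"relation_{key}"] = r.relation
        rows.append(row)
    return pd.DataFrame(rows).set_index("analyte_id")
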