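"""Bundled worked-example summary statistics.

Published group-level summaries from a Hras12V transgenic mouse liver
study of hepatocarcinogenesis — the study whose design this package's
defaults mirror. Three summaries are provided, each across the trio
W (normal liver, wild-type), P (precancerous liver, transgenic) and
T (hepatocellular carcinoma, transgenic):

* :data:`METABOLITES` — GC-MS metabolite group means (n = 8/group) with
  pairwise fold changes (first-named / second-named group) and Student
  t-test p-values;
* :data:`GENES` — FPKM group means (n = 5/group) with pairwise folds and
  p-values (mouse gene symbols);
* :data:`TRACER` — [U-¹³C]glucose labeled fractions ([labeled]/[total])
  for the diagnostic mass isotopologue of each central-carbon metabolite,
  with pairwise p-values.

These are summary statistics, not raw per-animal data; helpers below
convert them into the package's in-memory types for worked examples and
regression checks.
"""

from __future__ import annotations

import pandas as pd

from .differential import PairwiseResult
from .tables import PeakTable

__all__ = [
    "METABOLITES",
    "GENES",
    "TRACER",
    "metabolite_mean_table",
    "pairwise_results_for",
]

_MET_COLS = [
    "metabolite", "rt_min", "mean_W", "mean_P", "mean_T",
    "fold_W_vs_P", "p_W_vs_P", "fold_P_vs_T", "p_P_vs_T",
    "fold_W_vs_T", "p_W_vs_T",
]

METABOLITES = pd.DataFrame(
    [
        ["Glucose-1p", 16.7179, 1.09e-1, 1.48e-1, 2.14e-1, 0.74, 1.38e-2, 0.69, 1.97e-2, 0.51, 2.81e-3],
        ["Xanthosine", 24.2838, 1.73e0, 1.10e0, 4.54e-1, 1.57, 2.81e-3, 2.43, 9.13e-4, 3.81, 7.11e-5],
        ["Glucose-6p", 21.4070, 1.69e-2, 4.56e-2, 1.68e-1, 0.37, 6.57e-3, 0.27, 3.77e-6, 0.10, 1.50e-5],
        ["Fructose-6p", 21.2896, 2.67e-2, 7.82e-2, 2.39e-1, 0.34, 1.15e-3, 0.33, 1.15e-2, 0.11, 9.13e-4],
        ["Fructose", 17.8171, 9.71e-1, 3.36e0, 3.30e0, 0.29, 1.12e-2, 1.02, 9.37e-1, 0.29, 2.45e-2],
        ["Citrate", 17.2200, 1.00e-2, 1.21e-2, 4.55e-2, 0.83, 6.84e-1, 0.27, 3.91e-2, 0.22, 3.18e-2],
        ["Succinate", 11.8994, 1.40e-1, 6.65e-2, 6.21e-2, 2.11, 4.43e-3, 1.07, 7.65e-1, 2.26, 2.41e-3],
        ["Fumarate", 12.2976, 1.56e-1, 1.33e-1, 2.29e-1, 1.17, 3.28e-2, 0.53, 7.11e-5, 0.68, 5.66e-4],
        ["Malate", 13.8313, 2.08e0, 1.81e0, 3.39e0, 1.15, 9.40e-2, 0.53, 2.68e-4, 0.61, 1.45e-3],
        ["Glycine", 11.8509, 2.22e0, 1.47e0, 1.63e0, 1.51, 3.34e-5, 0.90, 5.04e-1, 1.37, 2.26e-2],
        ["Taurine", 15.9588, 4.25e-1, 7.66e-1, 3.44e-1, 0.55, 4.97e-2, 2.23, 3.18e-2, 1.24, 4.32e-1],
        ["5-oxoproline", 14.4595, 1.49e-1, 1.10e-1, 3.16e-1, 1.35, 3.48e-3, 0.34, 1.60e-4, 0.47, 1.97e-2],
        ["L-glutamate", 15.2758, 6.10e-3, 5.40e-3, 1.55e-2, 1.13, 4.75e-1, 0.35, 1.47e-2, 0.39, 2.02e-2],
        ["cys-Gly", 17.2563, 5.49e-2, 4.74e-2, 8.88e-2, 1.16, 5.06e-1, 0.53, 7.09e-3, 0.62, 1.79e-2],
    ],
    columns=_MET_COLS,
).set_index("metabolite")

_GENE_COLS = [
    "gene", "mean_W", "mean_P", "mean_T",
    "fold_W_vs_P", "p_W_vs_P", "fold_P_vs_T", "p_P_vs_T",
    "fold_W_vs_T", "p_W_vs_T",
]

GENES = pd.DataFrame(
    [
        ["Acly", 2.54e1, 4.57e1, 4.98e1, 0.56, 2.45e-2, 1.09, 9.89e-2, 0.51, 1.09e-4],
        ["Fh1", 1.37e2, 1.24e2, 5.65e1, 1.10, 4.58e-1, 0.45, 9.75e-4, 2.42, 6.23e-5],
        ["G6pc", 2.18e2, 9.61e1, 1.13e1, 2.27, 5.01e-12, 0.12, 3.62e-13, 19.33, 1.98e-39],
        ["G6pdx", 1.42e0, 3.65e0, 1.69e1, 0.39, 6.88e-1, 0.22, 6.03e-4, 0.08, 6.17e-5],
        ["Pgd", 7.74e0, 1.28e1, 1.00e1, 1.02, 1.00e0, 3.43, 8.58e-10, 0.30, 9.60e-10],
        ["Pkm", 5.32e0, 7.12e0, 2.58e1, 0.75, 7.91e-1, 3.62, 1.66e-4, 0.21, 1.76e-5],
        ["Lss", 2.29e1, 1.35e1, 5.84e1, 1.69, 1.42e-1, 4.32, 9.60e-11, 0.39, 2.61e-7],
        ["Dhcr7", 4.91e1, 1.79e1, 6.65e1, 2.74, 8.36e-5, 3.72, 3.19e-11, 0.74, 2.80e-3],
        ["Mvd", 1.48e1, 3.57e0, 1.96e1, 4.14, 1.16e-2, 5.50, 9.23e-5, 0.75, 1.25e-1],
        ["Acsl4", 8.57e0, 1.22e1, 3.44e1, 0.70, 2.01e-1, 0.36, 5.76e-6, 0.25, 9.19e-4],
        ["Baat", 1.50e2, 1.09e2, 3.50e1, 1.37, 1.30e-2, 0.32, 3.45e-6, 4.28, 6.06e-12],
        ["Cyp27a1", 1.94e2, 1.13e2, 2.69e1, 1.71, 4.56e-6, 0.24, 2.09e-9, 7.21, 1.04e-23],
        ["Cyp7b1", 3.64e2, 1.91e2, 7.32e0, 1.90, 1.38e-13, 0.04, 4.09e-37, 49.71, 7.72e-78],
        ["Cyp8b1", 1.40e2, 1.06e1, 2.08e0, 13.17, 4.69e-30, 0.20, 1.13e-1, 67.17, 1.61e-30],
        ["Hsd3b7", 2.79e2, 7.90e1, 4.26e1, 3.53, 1.30e-27, 0.54, 6.85e-2, 5.47, 2.05e-31],
        ["Hmgcr", 3.18e1, 2.31e1, 8.69e1, 1.38, 2.88e-1, 3.76, 6.22e-14, 0.37, 8.95e-11],
        ["Abat", 8.37e1, 4.87e1, 1.67e1, 1.72, 2.31e-3, 0.34, 4.02e-3, 5.02, 1.61e-8],
        ["Gpx4", 1.83e2, 1.67e2, 3.12e2, 1.10, 3.64e-1, 1.87, 5.35e-22, 0.59, 1.86e-18],
        ["Anpep", 2.57e1, 2.93e1, 5.17e1, 0.88, 6.89e-1, 1.76, 3.11e-4, 0.50, 4.85e-5],
        ["Gss", 2.87e1, 3.21e1, 5.37e1, 0.90, 7.04e-1, 1.68, 4.86e-4, 0.53, 8.80e-5],
    ],
    columns=_GENE_COLS,
).set_index("gene")

_TRACER_COLS = [
    "metabolite", "network_id", "mass_shift", "n_carbons",
    "mean_W", "mean_P", "mean_T", "p_P_vs_W", "p_W_vs_T", "p_P_vs_T",
]

TRACER = pd.DataFrame(
    [
        ["Phosphoenolpyruvic acid", "PEP", 3, 3, 2.19e-1, 1.49e-1, 9.82e-2, 2.32e-4, 3.10e-7, 1.35e-3],
        ["Lactic acid", "LAC", 3, 3, 1.48e-1, 1.27e-1, 8.77e-2, 7.31e-2, 3.51e-5, 1.02e-3],
        ["Citric acid", "CIT", 2, 6, 1.47e-1, 1.44e-1, 1.54e-1, 2.71e-1, 1.06e-2, 5.26e-3],
        ["Succinic acid", "SUC", 2, 4, 1.68e-1, 1.14e-1, 1.21e-1, 2.45e-6, 6.11e-6, 7.27e-2],
        ["Fumaric acid", "FUM", 2, 4, 1.03e-1, 9.71e-2, 1.16e-1, 8.87e-3, 2.19e-5, 6.08e-8],
        ["Malic acid", "MAL", 2, 4, 1.30e-1, 1.23e-1, 1.37e-1, 1.06e-3, 2.98e-3, 7.25e-7],
        ["Glyceraldehyde 3-phosphate", "GAP", 3, 3, 7.55e-2, 6.31e-2, 5.79e-2, 1.77e-1, 6.51e-2, 5.70e-1],
        ["Erythrose 4-phosphate", "E4P", 4, 4, 7.02e-3, 1.64e-3, 0.0, 1.07e-3, 8.30e-5, 2.00e-5],
        ["Ribulose-5-phosphate", "Ru5P", 5, 5, 2.78e-3, 2.00e-3, 1.83e-3, 4.34e-1, 2.52e-1, 8.79e-1],
        ["Glucose 6-phosphate", "G6P", 6, 6, 1.99e-1, 1.22e-1, 4.87e-2, 5.31e-3, 5.67e-7, 1.21e-3],
        ["Sedoheptulose 7-phosphate", "S7P", 7, 7, 7.26e-3, 4.71e-3, 1.20e-3, 2.29e-2, 2.42e-6, 8.75e-5],
        ["Glucose", "GLC", 6, 6, 2.65e-1, 1.63e-1, 1.36e-1, 2.60e-5, 3.79e-6, 2.04e-1],
        ["Ribose 5-phosphate", "R5P", 5, 5, 5.05e-3, 2.75e-3, 5.11e-3, 7.39e-3, 9.44e-1, 2.17e-2],
        ["Fructose 6-phosphate", "F6P", 6, 6, 1.70e-1, 1.01e-1, 3.78e-2, 1.11e-4, 2.66e-11, 1.85e-4],
    ],
    columns=_TRACER_COLS,
).set_index("metabolite")


def metabolite_mean_table(kind: str = "metabolite") -> PeakTable:
    """Group means as a PeakTable (two identical samples per group).

    With every sample equal to its group mean, group means — and therefore
    fold changes — are exactly the published values; within-group variance
    is zero, so the table supports fold arithmetic but not t-tests.
    """
    df = METABOLITES if kind == "metabolite" else GENES
    data = {}
    for g in ("W", "P", "T"):
        for i in (1, 2):
            data[f"{g}{i}"] = df[f"mean_{g}"]
    values = pd.DataFrame(data)
    group_of = {s: s[0] for s in values.columns}
    return PeakTable(values=values, group_of=group_of)


def pairwise_results_for(
    analyte: str, kind: str = "metabolite", alpha: float = 0.05
) -> list[PairwiseResult]:
    """The three published pairwise comparisons for one analyte.

    Reconstructs PairwiseResult objects from the published group means and
    p-values (relations re-derived at ``alpha``) — the input the trajectory
    classifier expects.
    """
    df = METABOLITES if kind == "metabolite" else GENES
    row = df.loc[analyte]
    out = []
    for a, b in (("W", "P"), ("P", "T"), ("W", "T")):
        mean_a, mean_b = float(row[f"mean_{a}"]), float(row[f"mean_{b}"])
        p = float(row[f"p_{a}_vs_{b}"])
        if p < alpha:
            relation = ">" if mean_a > mean_b else "<"
        else:
            relation = "="
        out.append(
            PairwiseResult(
                analyte_id=analyte,
                group_a=a,
                group_b=b,
                mean_a=mean_a,
                mean_b=mean_b,
                fold_change=mean_a / mean_b,
                p_value=p,
                relation=relation,
            )
        )
    return out
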