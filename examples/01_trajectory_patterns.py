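"""Classify published liver metabolite trajectories across W/P/T.

Uses the bundled group-level summary (normal, precancerous, tumor liver;
n = 8 mice/group) to rebuild each metabolite's three pairwise relations at
alpha = 0.05 and assign its trajectory pattern. "HCC_pos T>P=W" reads:
significantly elevated in tumor only — a tumor-associated metabolite;
"RAS_neg T=P<W": suppressed in both oncogene-bearing tissues.
"""

from triotrace import build_trajectory, classify_pattern, fold_change_report
from triotrace.liver_study import METABOLITES, metabolite_mean_table, pairwise_results_for

report = fold_change_report(metabolite_mean_table())
print(f"{'metabolite':14s} {'W vs P':>7s} {'P vs T':>7s} {'W vs T':>7s}  pattern")
for metabolite in METABOLITES.index:
    call = classify_pattern(build_trajectory(pairwise_results_for(metabolite)))
    row = report.loc[metabolite]
    label = f"{call.category} {call.subtype}" if call.subtype else "unclassified"
    print(
        f"{metabolite:14s} {row['fold_W_vs_P_2dp']:7.2f} "
        f"{row['fold_P_vs_T_2dp']:7.2f} {row['fold_W_vs_T_2dp']:7.2f}  {label}"
    )
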