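"""Over-representation of the published differential metabolites.

Takes the bundled differential-metabolite list as hits against a universe
padded with unrelated analytes, and tests each built-in central-carbon
pathway by the hypergeometric upper tail with Benjamini-Hochberg
correction. k/K is pathway hits over pathway size within the universe.
"""

from triotrace import builtin_pathways, enrich
from triotrace.liver_study import METABOLITES

hits = list(METABOLITES.index)
universe = hits + [f"unrelated_{i:03d}" for i in range(120)]

results = enrich(hits, universe, builtin_pathways())
print(f"{'pathway':28s} {'k/K':>6s} {'p':>10s} {'q (BH)':>10s}")
for r in results:
    print(f"{r.pathway:28s} {r.k:3d}/{r.K:<2d} {r.p_value:10.2e} {r.q_value:10.2e}")
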