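"""Hypergeometric over-representation analysis against a built-in pathway map.

An open replacement for web-service enrichment (MSEA/DAVID): given a hit
list and a universe, each pathway's p-value is the hypergeometric upper tail
P(X ≥ k) for drawing k pathway members in a list of n from a universe of N
containing K members, with Benjamini–Hochberg correction across pathways.

The built-in map covers the six central-carbon and detox pathways implicated
in Hras12V-driven hepatocarcinogenesis — glycolysis, TCA cycle with the
citrate-malate shuttle, pentose phosphate pathway, lipid biosynthesis,
cholesterol/bile-acid metabolism, and glutathione metabolism — with both
metabolite and gene members. Pathways can also be loaded from standard
GMT files.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayDef", "EnrichmentResult", "enrich", "builtin_pathways", "read_gmt"]


@dataclasses.dataclass
class PathwayDef:
    name: str
    metabolite_members: frozenset[str] = frozenset()
    gene_members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.metabolite_members = frozenset(self.metabolite_members)
        self.gene_members = frozenset(self.gene_members)
        if not (self.metabolite_members | self.gene_members):
            raise ValueError(f"pathway {self.name!r} has no members")

    @property
    def members(self) -> frozenset[str]:
        return self.metabolite_members | self.gene_members


@dataclasses.dataclass
class EnrichmentResult:
    pathway: str
    k: int  # hits in pathway
    K: int  # pathway size within universe
    n: int  # hit-list size
    N: int  # universe size
    p_value: float
    q_value: float


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    pathways: Sequence[PathwayDef],
) -> list[EnrichmentResult]:
    """Over-representation of ``hits`` within ``universe`` for each pathway.

    Pathways are intersected with the universe before testing; hits outside
    the universe are dropped with a warning. Results are sorted by p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    hit_set = set(hits)
    stray = hit_set - universe_set
    if stray:
        warnings.warn(f"dropping hits outside the universe: {sorted(stray)}")
        hit_set &= universe_set
    N, n = len(universe_set), len(hit_set)
    rows = []
    for pw in pathways:
        members = pw.members & universe_set
        K = len(members)
        k = len(members & hit_set)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((pw.name, k, K, p))
    qs = multipletests([r[3] for r in rows], method="fdr_bh")[1] if rows else []
    out = [
        EnrichmentResult(pathway=name, k=k, K=K, n=n, N=N, p_value=p, q_value=float(q))
        for (name, k, K, p), q in zip(rows, qs)
    ]
    out.sort(key=lambda r: (r.p_value, r.pathway))
    return out


def read_gmt(path: str | Path) -> list[PathwayDef]:
    """Read gene sets from a GMT file (name, description, members...)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out.append(PathwayDef(name=parts[0], gene_members=frozenset(parts[2:])))
    return out


def builtin_pathways() -> list[PathwayDef]:
    """The six curated central-carbon/detox pathways with their members.

    Metabolite names follow the GC-MS annotations of the liver study this
    package's worked examples come from; gene symbols are mouse.
    """
    return [
        PathwayDef(
            name="glycolysis",
            metabolite_members=frozenset(
                {
                    "Glucose-1p",
                    "Glucose-6p",
                    "Fructose-6p",
                    "Fructose",
                    "Pyruvate",
                    "Lactate",
                }
            ),
            gene_members=frozenset({"G6pc", "Pkm", "Acly"}),
        ),
        PathwayDef(
            name="tca_citrate_malate_shuttle",
            metabolite_members=frozenset(
                {"Citrate", "Succinate", "Fumarate", "Malate", "Pyruvate"}
            ),
            gene_members=frozenset({"Fh1", "Acly", "Slc25a1"}),
        ),
        PathwayDef(
            name="pentose_phosphate",
            metabolite_members=frozenset(
                {"Glucose-6p", "Ribose-5p", "Xanthosine"}
            ),
            gene_members=frozenset({"G6pdx", "Pgd"}),
        ),
        PathwayDef(
            name="lipid_biosynthesis",
            metabolite_members=frozenset({"Citrate", "Malate"}),
            gene_members=frozenset({"Acly", "Lss", "Dhcr7", "Mvd", "Acsl4"}),
        ),
        PathwayDef(
            name="cholesterol_bile_acid",
            metabolite_members=frozenset({"Glycine", "Taurine", "Cholate"}),
            gene_members=frozenset(
                {
                    "Baat",
                    "Cyp27a1",
                    "Cyp7b1",
                    "Cyp8b1",
                    "Hsd3b7",
                    "Hmgcr",
                    "Lss",
                    "Dhcr7",
                    "Mvd",
                }
            ),
        ),
        PathwayDef(
            name="glutathione",
            metabolite_members=frozenset(
                {"5-oxoproline", "L-glutamate", "Succinate", "Glycine", "cys-Gly"}
            ),
            gene_members=frozenset({"Abat", "Gpx4", "Anpep", "Gss", "Pgd", "G6pdx"}),
        ),
    ]
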