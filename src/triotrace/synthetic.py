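"""Ground-truth synthetic data for every pipeline stage.

Peak tables are generated by planting one of the ten trajectory subtypes
(or a null, all-groups-equal profile) per analyte: group means walk the
subtype's inequalities in steps of ``effect_size`` (groups joined by ``=``
share a mean), and each observation is the group mean times multiplicative
log-normal noise of a given coefficient of variation — GC-MS peak
intensities are positive and right-skewed, so log-normal is the natural
noise family, and the cv parameterization keeps power statements readable.

Defaults mirror the study conditions the pipeline targets: three groups
(W/P/T) of n = 8 animals, fold 2 between adjacent unequal groups, cv 0.25.

Isotopologue tables are generated from the atom-mapped tracer simulator:
per-sample areas are total_pool × simulated fraction × log-normal noise,
with the simulator's distributions retained as ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import PATTERN_TABLE, PatternCall
from .tables import IsotopologueTable, PeakTable
from .tracing import IsotopologueVector, build_network, simulate_isotopomers

__all__ = [
    "SyntheticSpec",
    "generate_peak_table",
    "generate_isotopologue_table",
    "TRACER_BASE_CONFIG",
    "tracer_group_configs",
]

#: default tracer-network setting for synthetic isotopologue data: a
#: steady-state [U-13C]glucose delivery with 50% plasma enrichment, modest
#: unlabeled influx at pyruvate (alanine/other carbon), oxaloacetate
#: (anaplerosis) and acetyl-CoA (fatty-acid oxidation). In this regime the
#: acetyl-derived M2 dominates citrate labeling, so citrate-malate-shuttle
#: activity is read out by the citrate M2 fraction.
TRACER_BASE_CONFIG: dict = {
    "tracer_purity": 0.5,
    "f_ppp": 0.05,
    "f_lactate": 0.2,
    "f_pdh": 0.6,
    "dilution": {"PYR": 0.1, "OAA": 0.15, "AcCoA": 0.1},
}


def tracer_group_configs(
    f_shuttle_by_group: Mapping[str, float] | None = None,
) -> dict[str, dict]:
    """Per-group network configs differing only in citrate-export share.

    Defaults mirror the study contrast: basal shuttle (0.1) in normal and
    precancerous liver, strongly enhanced (0.6) in tumor.
    """
    shares = dict(f_shuttle_by_group or {"W": 0.1, "P": 0.1, "T": 0.6})
    return {
        g: {**TRACER_BASE_CONFIG, "f_shuttle": fs} for g, fs in shares.items()
    }

#: canonical subtype strings (default W/P/T labels) -> category
SUBTYPE_CATEGORY: dict[str, str] = {
    template.format(w="W", p="P", t="T"): category
    for category, template in PATTERN_TABLE.values()
}


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for a planted-pattern peak table.

    ``planted`` gives one subtype string (e.g. ``"T>P=W"``) or ``None``
    (null analyte, all groups equal) per analyte; if omitted, the ten
    subtypes are cycled with every 11th analyte a null.
    """

    n_analytes: int = 200
    groups: tuple[str, ...] = ("W", "P", "T")
    n_per_group: int = 8
    planted: Sequence[str | None] | None = None
    effect_size: float = 2.0
    cv: float = 0.25
    base_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must be > 1")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.planted is not None and len(self.planted) != self.n_analytes:
            raise ValueError("planted must have one entry per analyte")

    def resolved_planted(self) -> list[str | None]:
        if self.planted is not None:
            return list(self.planted)
        cycle: list[str | None] = list(SUBTYPE_CATEGORY) + [None]
        return [cycle[i % len(cycle)] for i in range(self.n_analytes)]


def _means_from_subtype(
    subtype: str | None, groups: Sequence[str], effect: float, base: float
) -> dict[str, float]:
    """Walk the subtype's inequalities; ``=``-joined groups share a mean."""
    if subtype is None:
        return {g: base for g in groups}
    tokens = subtype.replace(">", " > ").replace("<", " < ").replace("=", " = ").split()
    names = tokens[0::2]
    ops = tokens[1::2]
    if sorted(names) != sorted(groups):
        raise ValueError(f"subtype {subtype!r} does not cover groups {groups}")
    # assign integer levels right-to-left, then exponentiate
    levels = {names[-1]: 0}
    for name, op in zip(reversed(names[:-1]), reversed(ops)):
        right = levels[names[names.index(name) + 1]]
        if op == ">":
            levels[name] = right + 1
        elif op == "<":
            levels[name] = right - 1
        else:
            levels[name] = right
    low = min(levels.values())
    return {g: base * effect ** (levels[g] - low) for g in groups}


def generate_peak_table(spec: SyntheticSpec) -> tuple[PeakTable, list[PatternCall]]:
    """Generate a peak table with known per-analyte trajectory ground truth."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.cv**2))
    planted = spec.resolved_planted()
    samples = [f"{g}{i + 1}" for g in spec.groups for i in range(spec.n_per_group)]
    group_of = {s: s.rstrip("0123456789") for s in samples}
    data = np.empty((spec.n_analytes, len(samples)))
    truth = []
    for i, subtype in enumerate(planted):
        means = _means_from_subtype(subtype, spec.groups, spec.effect_size, spec.base_mean)
        mu = np.array([means[group_of[s]] for s in samples])
        data[i] = mu * np.exp(rng.normal(0.0, sigma, size=len(samples)))
        truth.append(
            PatternCall(
                analyte_id=f"analyte_{i:04d}",
                category=SUBTYPE_CATEGORY.get(subtype, "unclassified")
                if subtype
                else "unclassified",
                subtype=subtype or "",
            )
        )
    values = pd.DataFrame(
        data, index=[f"analyte_{i:04d}" for i in range(spec.n_analytes)], columns=samples
    )
    return PeakTable(values=values, group_of=group_of), truth


def generate_isotopologue_table(
    group_configs: Mapping[str, Mapping],
    noise_cv: float = 0.1,
    n_per_group: int = 8,
    seed: int = 0,
    total_pool: float = 1e4,
    metabolites: Sequence[str] | None = None,
) -> tuple[IsotopologueTable, dict[str, dict[str, IsotopologueVector]]]:
    """Generate isotopologue areas from per-group tracer network configs.

    For each group, the network built from its config is simulated to steady
    state; each sample's peak areas are ``total_pool`` × fraction ×
    log-normal noise. Returns the table plus the noise-free ground-truth
    fractions per group.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    truth: dict[str, dict[str, IsotopologueVector]] = {}
    group_of: dict[str, str] = {}
    n_carbons: dict[str, int] = {}
    for group, config in group_configs.items():
        network = build_network(config)
        vectors = simulate_isotopomers(network)
        if metabolites is not None:
            vectors = {m: vectors[m] for m in metabolites}
        truth[group] = vectors
        for i in range(n_per_group):
            sample = f"{group}{i + 1}"
            group_of[sample] = group
            for met, vec in vectors.items():
                n_carbons[met] = vec.n_carbons
                noise = (
                    np.exp(rng.normal(0.0, sigma, size=vec.n_carbons + 1))
                    if sigma > 0
                    else np.ones(vec.n_carbons + 1)
                )
                for k in range(vec.n_carbons + 1):
                    rows.append(
                        {
                            "metabolite": met,
                            "mass_shift": k,
                            "sample": sample,
                            "area": total_pool * vec[k] * noise[k],
                        }
                    )
    table = IsotopologueTable(
        records=pd.DataFrame(rows), n_carbons=n_carbons, group_of=group_of
    )
    return table, truth
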