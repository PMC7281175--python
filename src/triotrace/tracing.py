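"""¹³C labeled-fraction analysis and atom-mapped isotopologue simulation.

Two halves:

1. **Measurement side** — :func:`labeled_fraction` computes the enrichment of
   a mass isotopologue M+k as the ratio of its peak area to the summed areas
   of all isotopologues of that metabolite ([labeled]/[total]), per sample
   and averaged per group; :func:`natural_abundance_correct` optionally
   strips the binomial contribution of naturally occurring ¹³C (~1.1%).

2. **Simulation side** — an atom-mapped network of central carbon metabolism
   (glycolysis, oxidative and non-oxidative pentose phosphate pathway, TCA
   cycle, and the mitochondrial citrate-malate shuttle) through which a
   [U-¹³C]glucose tracer is propagated to steady state. Metabolites carry
   full positional isotopomer distributions (≤ 2⁷ states; the largest
   metabolite, sedoheptulose-7-phosphate, has 7 carbons), so every carbon
   rearrangement — transketolase/transaldolase exchanges, the succinate and
   fumarate rotational symmetry, CO₂ losses — is exact. Branch fractions
   (PPP share, lactate vs pyruvate-dehydrogenase share, citrate-export
   share) are the interpretable parameters; per-metabolite dilution models
   unlabeled influx from unmodeled pools.

The deterministic solver iterates the isotopomer-balance fixed point; an
independent molecule-level Monte-Carlo simulator over the same network
serves as a stochastic cross-check.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import comb

from .tables import IsotopologueTable

__all__ = [
    "IsotopologueVector",
    "LabeledFractionRecord",
    "TracerReaction",
    "TracerNetwork",
    "ConvergenceError",
    "labeled_fraction",
    "natural_abundance_correct",
    "build_network",
    "simulate_positional",
    "simulate_isotopomers",
    "monte_carlo_oracle",
    "N_CARBONS",
]


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class IsotopologueVector:
    """Mass-isotopologue fractions f0..fn for one metabolite (sum = 1)."""

    metabolite_id: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (self.n_carbons + 1,):
            raise ValueError("fractions must have length n_carbons + 1")
        if np.any(f < -1e-9):
            raise ValueError("negative isotopologue fraction")
        if abs(float(f.sum()) - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {f.sum():.12f}, not 1")
        self.fractions = np.clip(f, 0.0, None)

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])


@dataclasses.dataclass
class LabeledFractionRecord:
    """[labeled]/[total] for one (metabolite, M+k) within one group."""

    metabolite_id: str
    mass_shift: int
    group: str | None
    mean_fraction: float
    sample_fractions: dict[str, float]
    flagged_samples: list[str]  # samples with zero total area (undefined)


def labeled_fraction(
    table: IsotopologueTable,
    metabolite: str,
    mass_shift: int,
    by_group: bool = True,
) -> list[LabeledFractionRecord]:
    """Per-sample M+k fraction = area(M+k) / Σ_j area(M+j), averaged per group.

    Samples whose total area is zero have no defined fraction; they are
    excluded from the mean and listed in ``flagged_samples``.
    """
    if metabolite not in table.n_carbons:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    n = table.n_carbons[metabolite]
    if not 0 <= mass_shift <= n:
        raise ValueError(f"mass shift {mass_shift} outside 0..{n}")
    per_sample: dict[str, float] = {}
    flagged: list[str] = []
    met_samples = set(
        table.records.loc[table.records["metabolite"] == metabolite, "sample"]
    )
    samples = [s for s in table.sample_ids if s in met_samples]
    for s in samples:
        areas = table.areas(metabolite, s)
        total = float(areas.sum())
        if total <= 0:
            flagged.append(s)
            continue
        per_sample[s] = float(areas[mass_shift]) / total
    if by_group and table.group_of:
        groups = dict.fromkeys(table.group_of[s] for s in per_sample)
        out = []
        for g in groups:
            sf = {s: v for s, v in per_sample.items() if table.group_of[s] == g}
            fl = [s for s in flagged if table.group_of.get(s) == g]
            out.append(
                LabeledFractionRecord(
                    metabolite_id=metabolite,
                    mass_shift=mass_shift,
                    group=g,
                    mean_fraction=float(np.mean(list(sf.values()))) if sf else math.nan,
                    sample_fractions=sf,
                    flagged_samples=fl,
                )
            )
        return out
    return [
        LabeledFractionRecord(
            metabolite_id=metabolite,
            mass_shift=mass_shift,
            group=None,
            mean_fraction=float(np.mean(list(per_sample.values())))
            if per_sample
            else math.nan,
            sample_fractions=per_sample,
            flagged_samples=flagged,
        )
    ]


def natural_abundance_correct(
    vector: IsotopologueVector, p13: float = 0.0107, enabled: bool = True
) -> IsotopologueVector:
    """Remove natural ¹³C abundance from an observed isotopologue vector.

    The observed vector is modeled as M @ true where
    M[i, j] = C(n−j, i−j) · p13^(i−j) · (1−p13)^(n−i) — each of the n−j
    unlabeled carbons of a j-labeled molecule is independently ¹³C with
    probability ``p13``. The lower-triangular system is solved exactly,
    negatives (noise) are clipped and the result renormalized. Disabled, the
    function is the identity — matching raw [labeled]/[total] reporting.
    """
    if not enabled:
        return vector
    if not 0.0 <= p13 <= 0.05:
        raise ValueError("p13 must be in [0, 0.05]")
    n = vector.n_carbons
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    with np.errstate(invalid="ignore"):
        M = np.where(
            i >= j,
            comb(n - j, np.maximum(i - j, 0)) * p13 ** np.maximum(i - j, 0) * (1 - p13) ** (n - i),
            0.0,
        )
    corrected = solve_triangular(M, vector.fractions, lower=True)
    corrected = np.clip(corrected, 0.0, None)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("correction annihilated the vector")
    return IsotopologueVector(vector.metabolite_id, n, corrected / total)


# ---------------------------------------------------------------------------
# Network definition

#: carbon counts of the modeled metabolites
N_CARBONS: dict[str, int] = {
    "GLC": 6, "G6P": 6, "F6P": 6, "F16BP": 6, "DHAP": 3, "GAP": 3,
    "3PG": 3, "PEP": 3, "PYR": 3, "LAC": 3, "AcCoA": 2, "OAA": 4,
    "CIT": 6, "2OG": 5, "SUC": 4, "FUM": 4, "MAL": 4,
    "Ru5P": 5, "X5P": 5, "R5P": 5, "S7P": 7, "E4P": 4,
    "CIT_cyt": 6, "AcCoA_cyt": 2, "OAA_cyt": 4, "MAL_cyt": 4,
}

# carbon indices are 0-based: carbon 1 of the biochemical numbering is bit 0
CMap = tuple[tuple[int, int] | None, ...]


@dataclasses.dataclass(frozen=True)
class TracerReaction:
    """One atom-mapped reaction.

    ``products`` maps each product metabolite to a carbon map: entry j gives
    the (substrate index, substrate carbon) feeding product carbon j, or
    ``None`` for an unlabeled entry (e.g. fixed CO₂). ``co2`` lists substrate
    carbons released as CO₂. Every substrate carbon must appear exactly once
    across products and CO₂ losses (checked at network build).
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[tuple[str, CMap], ...]
    co2: tuple[tuple[int, int], ...] = ()
    flux: float = 0.0
    reversible: bool = False


@dataclasses.dataclass
class TracerNetwork:
    reactions: list[TracerReaction]
    branch_fractions: dict[str, float]
    dilution: dict[str, float]
    tracer_purity: float
    n_carbons: dict[str, int] = dataclasses.field(default_factory=lambda: dict(N_CARBONS))
    #: metabolite update order for the fixed-point sweep
    order: list[str] = dataclasses.field(default_factory=list)

    def producers(self, metabolite: str) -> list[tuple[float, TracerReaction, CMap]]:
        out = []
        for r in self.reactions:
            for met, cmap in r.products:
                if met == metabolite and r.flux > 0:
                    out.append((r.flux, r, cmap))
        return out


def _ident(sub_idx: int, n: int) -> CMap:
    return tuple((sub_idx, c) for c in range(n))


def _audit_reaction(r: TracerReaction, n_carbons: Mapping[str, int]) -> None:
    used: list[tuple[int, int]] = list(r.co2)
    for met, cmap in r.products:
        if len(cmap) != n_carbons[met]:
            raise ValueError(f"{r.name}: carbon map length mismatch for {met}")
        used.extend(e for e in cmap if e is not None)
    expected = sorted(
        (si, c) for si, sub in enumerate(r.substrates) for c in range(n_carbons[sub])
    )
    if sorted(used) != expected:
        raise ValueError(f"{r.name}: substrate carbons not conserved")


_VALID_CONFIG = {
    "f_ppp", "f_lactate", "f_pdh", "f_shuttle", "f_pc",
    "tracer_purity", "dilution", "disable",
}


def build_network(config: Mapping | None = None) -> TracerNetwork:
    """Build the default central-carbon tracer network.

    ``config`` keys (all optional): branch fractions ``f_ppp`` (share of
    glucose-6-phosphate entering the oxidative PPP), ``f_lactate`` and
    ``f_pdh`` (pyruvate shares to lactate and to acetyl-CoA; the remainder
    leaves the modeled network), ``f_shuttle`` (share of citrate exported to
    the cytosol vs continuing around the TCA cycle), ``f_pc`` (optional
    pyruvate-carboxylase anaplerosis, default 0); ``tracer_purity`` (fraction
    of glucose that is fully labeled M6); ``dilution`` (per-metabolite
    unlabeled-influx fraction); ``disable`` (reaction names to remove —
    unknown names are an error).
    """
    cfg = dict(config or {})
    unknown = set(cfg) - _VALID_CONFIG
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    f_ppp = float(cfg.get("f_ppp", 0.0))
    f_lac = float(cfg.get("f_lactate", 0.0))
    f_pdh = float(cfg.get("f_pdh", 0.0))
    f_shu = float(cfg.get("f_shuttle", 0.0))
    f_pc = float(cfg.get("f_pc", 0.0))
    purity = float(cfg.get("tracer_purity", 1.0))
    dilution = {str(k): float(v) for k, v in dict(cfg.get("dilution", {})).items()}
    for name, val in [
        ("f_ppp", f_ppp), ("f_lactate", f_lac), ("f_pdh", f_pdh),
        ("f_shuttle", f_shu), ("f_pc", f_pc), ("tracer_purity", purity),
    ]:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if f_lac + f_pdh + f_pc > 1.0 + 1e-12:
        raise ValueError("pyruvate branch fractions exceed 1")
    for met, d in dilution.items():
        if met not in N_CARBONS:
            raise ValueError(f"dilution for unknown metabolite {met!r}")
        if not 0.0 <= d <= 1.0:
            raise ValueError("dilution fractions must be in [0, 1]")

    v_ox = f_ppp
    v_pgi = 1.0 - f_ppp
    v_nox = v_ox / 3.0  # each transketolase/transaldolase step
    v_pfk = v_pgi + 2.0 * v_nox  # F6P from PGI + transaldolase + TK2
    v_low = 2.0 * v_pfk + v_nox  # lower glycolysis (GAP -> pyruvate)
    v_cs = f_pdh * v_low  # citrate synthase

    R = TracerReaction
    reactions = [
        R("hexokinase", ("GLC",), (("G6P", _ident(0, 6)),), flux=1.0),
        R("pgi", ("G6P",), (("F6P", _ident(0, 6)),), flux=v_pgi, reversible=True),
        # oxidative PPP: carbon 1 of G6P leaves as CO2, carbons 2-6 -> Ru5P
        R(
            "oxidative_ppp",
            ("G6P",),
            (("Ru5P", tuple((0, c) for c in range(1, 6))),),
            co2=((0, 0),),
            flux=v_ox,
        ),
        R("rpe", ("Ru5P",), (("X5P", _ident(0, 5)),), flux=2 * v_ox / 3, reversible=True),
        R("rpi", ("Ru5P",), (("R5P", _ident(0, 5)),), flux=v_ox / 3, reversible=True),
        # transketolase 1: X5P C1-C2 onto R5P -> S7P; X5P C3-C5 -> GAP
        R(
            "transketolase_1",
            ("X5P", "R5P"),
            (
                ("S7P", ((0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (1, 3), (1, 4))),
                ("GAP", ((0, 2), (0, 3), (0, 4))),
            ),
            flux=v_nox,
            reversible=True,
        ),
        # transaldolase: S7P C1-C3 onto GAP -> F6P; S7P C4-C7 -> E4P
        R(
            "transaldolase",
            ("S7P", "GAP"),
            (
                ("F6P", ((0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2))),
                ("E4P", ((0, 3), (0, 4), (0, 5), (0, 6))),
            ),
            flux=v_nox,
            reversible=True,
        ),
        # transketolase 2: X5P C1-C2 onto E4P -> F6P; X5P C3-C5 -> GAP
        R(
            "transketolase_2",
            ("X5P", "E4P"),
            (
                ("F6P", ((0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (1, 3))),
                ("GAP", ((0, 2), (0, 3), (0, 4))),
            ),
            flux=v_nox,
            reversible=True,
        ),
        R("pfk", ("F6P",), (("F16BP", _ident(0, 6)),), flux=v_pfk),
        # aldolase: F16BP C1-C3 -> DHAP (reversed order), C4-C6 -> GAP
        R(
            "aldolase",
            ("F16BP",),
            (
                ("DHAP", ((0, 2), (0, 1), (0, 0))),
                ("GAP", ((0, 3), (0, 4), (0, 5))),
            ),
            flux=v_pfk,
        ),
        R("tpi", ("DHAP",), (("GAP", _ident(0, 3)),), flux=v_pfk, reversible=True),
        R("gapdh_pgk", ("GAP",), (("3PG", _ident(0, 3)),), flux=v_low),
        R("enolase", ("3PG",), (("PEP", _ident(0, 3)),), flux=v_low),
        R("pyruvate_kinase", ("PEP",), (("PYR", _ident(0, 3)),), flux=v_low),
        R("ldh", ("PYR",), (("LAC", _ident(0, 3)),), flux=f_lac * v_low, reversible=True),
        # PDH: pyruvate C1 (carboxyl) -> CO2; C2,C3 -> acetyl-CoA
        R(
            "pdh",
            ("PYR",),
            (("AcCoA", ((0, 1), (0, 2))),),
            co2=((0, 0),),
            flux=f_pdh * v_low,
        ),
        # citrate synthase: CIT carbons 1-4 from OAA, 5-6 from acetyl-CoA
        R(
            "citrate_synthase",
            ("OAA", "AcCoA"),
            (("CIT", ((0, 0), (0, 1), (0, 2), (0, 3), (1, 0), (1, 1))),),
            flux=v_cs,
        ),
        # aconitase + IDH: OAA-derived carboxyl (OAA C1) leaves as CO2;
        # 2OG = [OAA C4, OAA C3, OAA C2, AcCoA C1, AcCoA C2]
        R(
            "idh",
            ("CIT",),
            (("2OG", ((0, 3), (0, 2), (0, 1), (0, 4), (0, 5))),),
            co2=((0, 0),),
            flux=(1 - f_shu) * v_cs,
        ),
        # KGDH: 2OG C1 (second OAA carboxyl) -> CO2; succinate is symmetric,
        # modeled as a 50/50 mix of the two carbon orientations
        R(
            "kgdh_fwd",
            ("2OG",),
            (("SUC", ((0, 1), (0, 2), (0, 3), (0, 4))),),
            co2=((0, 0),),
            flux=0.5 * (1 - f_shu) * v_cs,
        ),
        R(
            "kgdh_rev",
            ("2OG",),
            (("SUC", ((0, 4), (0, 3), (0, 2), (0, 1))),),
            co2=((0, 0),),
            flux=0.5 * (1 - f_shu) * v_cs,
        ),
        # SDH: fumarate is likewise 2-fold rotationally symmetric
        R("sdh_fwd", ("SUC",), (("FUM", _ident(0, 4)),), flux=0.5 * (1 - f_shu) * v_cs, reversible=True),
        R(
            "sdh_rev",
            ("SUC",),
            (("FUM", ((0, 3), (0, 2), (0, 1), (0, 0))),),
            flux=0.5 * (1 - f_shu) * v_cs,
            reversible=True,
        ),
        R("fumarase", ("FUM",), (("MAL", _ident(0, 4)),), flux=(1 - f_shu) * v_cs, reversible=True),
        R("mdh", ("MAL",), (("OAA", _ident(0, 4)),), flux=v_cs),
        # citrate-malate shuttle: export, ATP-citrate lyase cleavage,
        # cytosolic MDH, malate re-import
        R("citrate_export", ("CIT",), (("CIT_cyt", _ident(0, 6)),), flux=f_shu * v_cs),
        R(
            "acly",
            ("CIT_cyt",),
            (
                ("OAA_cyt", ((0, 0), (0, 1), (0, 2), (0, 3))),
                ("AcCoA_cyt", ((0, 4), (0, 5))),
            ),
            flux=f_shu * v_cs,
        ),
        R("mdh_cyt", ("OAA_cyt",), (("MAL_cyt", _ident(0, 4)),), flux=f_shu * v_cs),
        R("malate_import", ("MAL_cyt",), (("MAL", _ident(0, 4)),), flux=f_shu * v_cs),
        # optional anaplerosis: pyruvate + CO2 -> OAA (fixed carbon unlabeled)
        R(
            "pyruvate_carboxylase",
            ("PYR",),
            (("OAA", ((0, 0), (0, 1), (0, 2), None)),),
            flux=f_pc * v_low,
        ),
    ]

    disable = set(cfg.get("disable", ()))
    names = {r.name for r in reactions}
    unknown_rxn = disable - names
    if unknown_rxn:
        raise ValueError(f"unknown reactions in disable: {sorted(unknown_rxn)}")
    reactions = [r for r in reactions if r.name not in disable]
    for r in reactions:
        _audit_reaction(r, N_CARBONS)

    order = [
        "G6P", "Ru5P", "X5P", "R5P", "S7P", "E4P", "F6P", "F16BP", "DHAP",
        "GAP", "3PG", "PEP", "PYR", "LAC", "AcCoA", "CIT", "CIT_cyt",
        "AcCoA_cyt", "OAA_cyt", "MAL_cyt", "2OG", "SUC", "FUM", "MAL", "OAA",
    ]
    return TracerNetwork(
        reactions=reactions,
        branch_fractions={
            "f_ppp": f_ppp, "f_lactate": f_lac, "f_pdh": f_pdh,
            "f_shuttle": f_shu, "f_pc": f_pc,
        },
        dilution=dilution,
        tracer_purity=purity,
        order=order,
    )


# ---------------------------------------------------------------------------
# Deterministic isotopomer solver


def _delta0(n: int) -> np.ndarray:
    d = np.zeros(2**n)
    d[0] = 1.0
    return d


def _joint_product_states(
    reaction: TracerReaction, cmap: CMap, sub_bits: Sequence[int]
) -> np.ndarray:
    """Product positional state for every joint substrate state."""
    offsets = np.cumsum([0] + list(sub_bits[:-1]))
    total = 1 << int(sum(sub_bits))
    joint = np.arange(total, dtype=np.int64)
    pstate = np.zeros(total, dtype=np.int64)
    for j, entry in enumerate(cmap):
        if entry is None:
            continue
        si, c = entry
        pstate |= ((joint >> (offsets[si] + c)) & 1) << j
    return pstate


def _reaction_dist(
    reaction: TracerReaction,
    cmap: CMap,
    dists: Mapping[str, np.ndarray],
    n_carbons: Mapping[str, int],
    n_prod: int,
) -> np.ndarray:
    sub_bits = [n_carbons[s] for s in reaction.substrates]
    joint = dists[reaction.substrates[0]]
    for s in reaction.substrates[1:]:
        joint = np.kron(dists[s], joint)  # later substrates occupy high bits
    pstate = _joint_product_states(reaction, cmap, sub_bits)
    return np.bincount(pstate, weights=joint, minlength=2**n_prod)


def simulate_positional(
    network: TracerNetwork,
    tolerance: float = 1e-10,
    max_iter: int = 500,
    allow_partial: bool = False,
) -> dict[str, np.ndarray]:
    """Fixed-point positional isotopomer distributions for every metabolite.

    Gauss–Seidel sweeps in network order, starting from unlabeled pools;
    each metabolite's distribution is the flux-weighted mixture of its
    producing reactions' atom-mapped substrate distributions, diluted by its
    unlabeled-influx fraction. Raises :class:`ConvergenceError` if the sweep
    residual has not dropped below ``tolerance`` within ``max_iter`` sweeps
    (unless ``allow_partial``, which returns the partial solution — e.g. a
    single-pass first-turn distribution at ``max_iter=1``).
    """
    nc = network.n_carbons
    dists: dict[str, np.ndarray] = {m: _delta0(nc[m]) for m in nc}
    glc = np.zeros(2 ** nc["GLC"])
    glc[0] = 1.0 - network.tracer_purity
    glc[-1] = network.tracer_purity
    dists["GLC"] = glc
    producers = {m: network.producers(m) for m in network.order}
    residual = math.inf
    for _ in range(max_iter):
        residual = 0.0
        for met in network.order:
            prods = producers[met]
            total = sum(w for w, _, _ in prods)
            if total <= 0:
                continue
            new = np.zeros_like(dists[met])
            for w, rxn, cmap in prods:
                new += (w / total) * _reaction_dist(rxn, cmap, dists, nc, nc[met])
            d = network.dilution.get(met, 0.0)
            if d > 0:
                new = (1 - d) * new
                new[0] += d
            residual = max(residual, float(np.max(np.abs(new - dists[met]))))
            dists[met] = new
        if residual < tolerance:
            break
    else:
        if not allow_partial:
            raise ConvergenceError(
                f"no convergence in {max_iter} sweeps (residual {residual:.3e})"
            )
    return dists


def _marginalize(dist: np.ndarray, n: int, metabolite: str) -> IsotopologueVector:
    states = np.arange(len(dist))
    popcount = np.array([bin(s).count("1") for s in states])
    fractions = np.bincount(popcount, weights=dist, minlength=n + 1)
    return IsotopologueVector(metabolite, n, fractions / fractions.sum())


def simulate_isotopomers(
    network: TracerNetwork,
    tolerance: float = 1e-10,
    max_iter: int = 500,
    allow_partial: bool = False,
) -> dict[str, IsotopologueVector]:
    """Steady-state mass-isotopologue distributions (M0..Mn) per metabolite."""
    dists = simulate_positional(network, tolerance, max_iter, allow_partial)
    return {
        m: _marginalize(dists[m], network.n_carbons[m], m)
        for m in network.n_carbons
    }


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def monte_carlo_oracle(
    network: TracerNetwork,
    n_molecules: int = 100_000,
    seed: int = 0,
    n_burn_in: int = 50,
    n_average: int = 25,
) -> dict[str, IsotopologueVector]:
    """Molecule-level stochastic atom tracking through the same network.

    Each metabolite pool holds ``n_molecules`` positional labeling states as
    bitmasks. Sweeps resample every pool from its producing reactions:
    reaction choice is flux-weighted per molecule, substrate molecules are
    drawn uniformly from the current pools, atom maps are applied bitwise,
    and dilution replaces a random subset with unlabeled molecules. After
    ``n_burn_in`` equilibration sweeps, isotopologue counts are accumulated
    over ``n_average`` further sweeps — pool resampling makes a single
    snapshot noisier than a binomial draw, and sweep-averaging brings the
    estimator back inside the ~3/√n-per-fraction envelope. The sampling
    pathway is fully independent of the deterministic solver's vector
    arithmetic; agreement validates both.
    """
    if n_molecules < 10_000:
        raise ValueError("n_molecules must be at least 10^4")
    rng = np.random.default_rng(seed)
    nc = network.n_carbons
    pools: dict[str, np.ndarray] = {
        m: np.zeros(n_molecules, dtype=np.int64) for m in nc
    }
    pools["GLC"] = np.where(
        rng.random(n_molecules) < network.tracer_purity, (1 << nc["GLC"]) - 1, 0
    ).astype(np.int64)
    producers = {m: network.producers(m) for m in network.order}
    popcounts = {
        m: np.array([bin(s).count("1") for s in range(2 ** nc[m])]) for m in nc
    }
    counts = {m: np.zeros(nc[m] + 1) for m in nc}

    def sweep() -> None:
        for met in network.order:
            prods = producers[met]
            total = sum(w for w, _, _ in prods)
            if total <= 0:
                continue
            weights = np.array([w for w, _, _ in prods]) / total
            choice = rng.choice(len(prods), size=n_molecules, p=weights)
            new = np.zeros(n_molecules, dtype=np.int64)
            for ri, (_, rxn, cmap) in enumerate(prods):
                mask = choice == ri
                m = int(mask.sum())
                if m == 0:
                    continue
                sub_states = [
                    pools[s][rng.integers(0, n_molecules, size=m)]
                    for s in rxn.substrates
                ]
                state = np.zeros(m, dtype=np.int64)
                for j, entry in enumerate(cmap):
                    if entry is None:
                        continue
                    si, c = entry
                    state |= ((sub_states[si] >> c) & 1) << j
                new[mask] = state
            d = network.dilution.get(met, 0.0)
            if d > 0:
                new[rng.random(n_molecules) < d] = 0
            pools[met] = new

    for _ in range(n_burn_in):
        sweep()
    for _ in range(max(n_average, 1)):
        sweep()
        for m in nc:
            counts[m] += np.bincount(popcounts[m][pools[m]], minlength=nc[m] + 1)
    return {
        m: IsotopologueVector(m, nc[m], counts[m] / counts[m].sum()) for m in nc
    }
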