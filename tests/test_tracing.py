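import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from triotrace import (
    IsotopologueTable,
    IsotopologueVector,
    build_network,
    labeled_fraction,
    monte_carlo_oracle,
    natural_abundance_correct,
    simulate_isotopomers,
)
from triotrace.tracing import (
    ConvergenceError,
    _reaction_dist,
    simulate_positional,
)

FULL_CONFIG = {
    "tracer_purity": 0.5,
    "f_ppp": 0.15,
    "f_lactate": 0.2,
    "f_pdh": 0.5,
    "f_shuttle": 0.4,
    "f_pc": 0.05,
    "dilution": {"PYR": 0.2, "OAA": 0.2, "AcCoA": 0.1, "GLC": 0.1},
}


def iso_table(rows, n_carbons, group_of=None):
    return IsotopologueTable(
        records=pd.DataFrame(rows, columns=["metabolite", "mass_shift", "sample", "area"]),
        n_carbons=n_carbons,
        group_of=group_of or {},
    )


class TestLabeledFraction:
    def test_basic_ratio(self):
        t = iso_table([("pyr", 0, "s1", 900.0), ("pyr", 3, "s1", 100.0)], {"pyr": 3})
        (rec,) = labeled_fraction(t, "pyr", 3, by_group=False)
        assert rec.mean_fraction == pytest.approx(0.100)

    def test_unlabeled_pool_gives_zero(self):
        t = iso_table([("pyr", 0, "s1", 500.0)], {"pyr": 3})
        (rec,) = labeled_fraction(t, "pyr", 2, by_group=False)
        assert rec.mean_fraction == 0.0

    def test_hand_arithmetic_three_isotopologues(self):
        rows = [("x", 0, "s1", 50.0), ("x", 1, "s1", 25.0), ("x", 2, "s1", 25.0)]
        t = iso_table(rows, {"x": 2})
        (rec,) = labeled_fraction(t, "x", 2, by_group=False)
        assert rec.mean_fraction == pytest.approx(0.25)

    def test_zero_total_sample_flagged(self):
        rows = [("x", 0, "s1", 0.0), ("x", 1, "s1", 0.0), ("x", 0, "s2", 10.0)]
        t = iso_table(rows, {"x": 1})
        (rec,) = labeled_fraction(t, "x", 1, by_group=False)
        assert rec.flagged_samples == ["s1"]
        assert "s1" not in rec.sample_fractions

    def test_group_means(self):
        rows = [
            ("x", 0, "w1", 90.0), ("x", 1, "w1", 10.0),
            ("x", 0, "w2", 80.0), ("x", 1, "w2", 20.0),
            ("x", 0, "t1", 50.0), ("x", 1, "t1", 50.0),
        ]
        t = iso_table(rows, {"x": 1}, group_of={"w1": "W", "w2": "W", "t1": "T"})
        recs = {r.group: r for r in labeled_fraction(t, "x", 1)}
        assert recs["W"].mean_fraction == pytest.approx(0.15)
        assert recs["T"].mean_fraction == pytest.approx(0.5)


class TestNaturalAbundance:
    @staticmethod
    def forward(true, n, p13):
        """Forward binomial convolution (independent oracle)."""
        observed = np.zeros(n + 1)
        for j, fj in enumerate(true):
            for extra in range(n - j + 1):
                observed[j + extra] += (
                    fj * comb(n - j, extra) * p13**extra * (1 - p13) ** (n - j - extra)
                )
        return observed

    def test_disabled_is_identity(self):
        v = IsotopologueVector("x", 2, np.array([0.5, 0.3, 0.2]))
        assert natural_abundance_correct(v, enabled=False) is v

    def test_unlabeled_two_carbon_recovers_delta(self):
        observed = self.forward([1.0, 0.0, 0.0], 2, 0.011)
        v = IsotopologueVector("x", 2, observed)
        corrected = natural_abundance_correct(v, p13=0.011)
        assert corrected.fractions == pytest.approx([1.0, 0.0, 0.0], abs=1e-9)

    def test_fully_labeled_fixed_point(self):
        v = IsotopologueVector("x", 3, np.array([0.0, 0.0, 0.0, 1.0]))
        corrected = natural_abundance_correct(v, p13=0.011)
        assert corrected.fractions[3] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_forward_then_correct_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        true = rng.dirichlet(np.ones(n + 1))
        observed = self.forward(true, n, 0.0107)
        corrected = natural_abundance_correct(IsotopologueVector("x", n, observed))
        assert np.abs(corrected.fractions - true).max() < 1e-6

    def test_out_of_range_abundance_rejected(self):
        v = IsotopologueVector("x", 1, np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            natural_abundance_correct(v, p13=0.2)


class TestNetwork:
    def test_oxidative_ppp_takes_carbons_2_to_6(self):
        net = build_network({"f_ppp": 0.3})
        (rxn,) = [r for r in net.reactions if r.name == "oxidative_ppp"]
        (product,) = rxn.products
        assert product[0] == "Ru5P"
        assert product[1] == tuple((0, c) for c in range(1, 6))
        assert rxn.co2 == ((0, 0),)

    def test_citrate_carbons_trace_to_oaa_and_accoa(self):
        net = build_network({"f_pdh": 0.5})
        (cs,) = [r for r in net.reactions if r.name == "citrate_synthase"]
        cmap = cs.products[0][1]
        sources = {cs.substrates[si] for si, _ in cmap}
        assert sources == {"OAA", "AcCoA"}

    def test_disable_shuttle_removes_only_cytosolic_steps(self):
        full = {r.name for r in build_network({}).reactions}
        shuttle = {"citrate_export", "acly", "mdh_cyt", "malate_import"}
        pruned = {
            r.name for r in build_network({"disable": sorted(shuttle)}).reactions
        }
        assert full - pruned == shuttle

    def test_unknown_disable_name_is_error(self):
        with pytest.raises(ValueError, match="unknown reactions"):
            build_network({"disable": ["warp_drive"]})

    def test_unknown_config_key_is_error(self):
        with pytest.raises(ValueError, match="unknown config"):
            build_network({"f_warp": 0.5})

    def test_branch_fraction_bounds(self):
        with pytest.raises(ValueError):
            build_network({"f_lactate": 0.7, "f_pdh": 0.5})
        with pytest.raises(ValueError):
            build_network({"f_ppp": 1.4})

    @pytest.mark.parametrize("seed", range(3))
    def test_carbon_conservation_on_random_inputs(self, seed):
        # expected labeled carbons in products + CO2 losses == in substrates
        rng = np.random.default_rng(seed)
        net = build_network(FULL_CONFIG)
        nc = net.n_carbons
        dists = {m: rng.dirichlet(np.ones(2 ** nc[m])) for m in nc}

        def expected_labels(dist):
            states = np.arange(len(dist))
            pop = np.array([bin(s).count("1") for s in states])
            return float((pop * dist).sum())

        def carbon_prob(metabolite, carbon):
            dist = dists[metabolite]
            states = np.arange(len(dist))
            return float(dist[(states >> carbon) & 1 == 1].sum())

        for rxn in net.reactions:
            into = sum(expected_labels(dists[s]) for s in rxn.substrates)
            out = sum(
                expected_labels(_reaction_dist(rxn, cmap, dists, nc, nc[met]))
                for met, cmap in rxn.products
            )
            out += sum(carbon_prob(rxn.substrates[si], c) for si, c in rxn.co2)
            assert out == pytest.approx(into, abs=1e-9)


class TestSimulate:
    def test_zero_tracer_gives_all_m0(self):
        net = build_network({"tracer_purity": 0.0, "f_pdh": 0.5, "f_lactate": 0.3})
        vectors = simulate_isotopomers(net)
        assert all(v[0] == pytest.approx(1.0) for v in vectors.values())

    def test_pure_glycolysis_conservation(self):
        net = build_network({"tracer_purity": 1.0, "f_lactate": 1.0})
        v = simulate_isotopomers(net)
        for met in ("PEP", "PYR", "LAC"):
            assert v[met][3] == pytest.approx(1.0)

    def test_every_vector_sums_to_one(self):
        vectors = simulate_isotopomers(build_network(FULL_CONFIG))
        for v in vectors.values():
            assert float(v.fractions.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_single_pass_citrate_is_m2(self):
        # first turn: labeled acetyl onto still-unlabeled oxaloacetate
        net = build_network({"tracer_purity": 1.0, "f_pdh": 1.0})
        v = simulate_isotopomers(net, max_iter=1, allow_partial=True)
        assert v["CIT"][2] == pytest.approx(1.0)

    def test_nonconvergence_raises(self):
        net = build_network({"tracer_purity": 1.0, "f_pdh": 1.0})
        with pytest.raises(ConvergenceError):
            simulate_isotopomers(net, max_iter=1)

    def test_r5p_fully_labeled_at_pure_tracer(self):
        net = build_network({"tracer_purity": 1.0, "f_ppp": 0.2, "f_lactate": 0.5})
        v = simulate_isotopomers(net)
        assert v["R5P"][5] == pytest.approx(1.0)

    def test_succinate_positional_reversal_symmetry(self):
        dists = simulate_positional(build_network(FULL_CONFIG))
        suc = dists["SUC"]
        for state in range(16):
            reversed_state = int(f"{state:04b}"[::-1], 2)
            assert suc[state] == pytest.approx(suc[reversed_state], abs=1e-12)

    def test_pyr_m3_monotone_in_purity(self):
        fractions = []
        for purity in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = {**FULL_CONFIG, "tracer_purity": purity}
            fractions.append(simulate_isotopomers(build_network(cfg))["PYR"][3])
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestMonteCarlo:
    def test_seed_determinism(self):
        net = build_network({"tracer_purity": 0.6, "f_pdh": 0.5, "f_lactate": 0.2})
        a = monte_carlo_oracle(net, n_molecules=10_000, seed=5, n_burn_in=15, n_average=5)
        b = monte_carlo_oracle(net, n_molecules=10_000, seed=5, n_burn_in=15, n_average=5)
        for m in a:
            assert np.array_equal(a[m].fractions, b[m].fractions)

    def test_degenerate_glycolysis(self):
        net = build_network({"tracer_purity": 1.0, "f_lactate": 1.0})
        mc = monte_carlo_oracle(net, n_molecules=20_000, seed=1, n_burn_in=20, n_average=10)
        assert abs(mc["PYR"][3] - 1.0) < 0.01

    def test_agrees_with_deterministic_solver(self):
        net = build_network(FULL_CONFIG)
        det = simulate_isotopomers(net)
        mc = monte_carlo_oracle(net, n_molecules=20_000, seed=2)
        bound = 3 / np.sqrt(20_000)
        for m in det:
            assert np.abs(det[m].fractions - mc[m].fractions).max() <= bound
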