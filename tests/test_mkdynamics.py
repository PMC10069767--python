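"""Inheritance-model expectations, line classification, population
simulators and field statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from duet import mkdynamics as mk


class TestCrossOutcome:
    def test_incompatible_cross_hatch(self):
        out = mk.expected_cross_outcome(
            mk.female(0, ()), mk.male(0, ("CI",)), mk.ModelParams()
        )
        assert out.expected_hatch == pytest.approx(0.0617)

    def test_null_cross(self):
        p = mk.ModelParams()
        out = mk.expected_cross_outcome(mk.female(0, ()), mk.male(0, ()), p)
        assert out.expected_hatch == p.h_0
        assert out.expected_prop_female == pytest.approx(0.5)
        assert out.expected_egg_to_adult == pytest.approx(p.v_0)

    def test_mk_mother_halves_viability(self):
        p = mk.ModelParams(tau_mk=1.0, v_0=0.8)
        out = mk.expected_cross_outcome(
            mk.female(0, ("CI", "MK")), mk.male(0, ("CI",)), p
        )
        assert out.expected_egg_to_adult == pytest.approx(0.40)
        assert out.expected_prop_female == pytest.approx(1.0)

    def test_ci_carrying_mother_is_rescued(self):
        p = mk.ModelParams()
        out = mk.expected_cross_outcome(
            mk.female(0, ("CI", "MK")), mk.male(0, ("CI",)), p
        )
        assert out.expected_hatch == p.h_0

    def test_distribution_sums_to_one(self):
        p = mk.ModelParams(tau_mk=0.9, mu=0.8, leak=0.1)
        for mother_cyto in ((), ("CI",), ("CI", "MK")):
            for s in (0, 1):
                out = mk.expected_cross_outcome(
                    mk.female(s, mother_cyto), mk.male(1, ("CI",)), p
                )
                assert sum(w for _, w in out.offspring_dist) == \
                    pytest.approx(1.0)

    @pytest.mark.parametrize(
        "mu, leak", [(0.25, 0.0), (0.6, 0.2), (1.0, 0.0), (0.5, 0.5)]
    )
    def test_viability_identity(self, mu, leak):
        # MK mother, compatible cross: v_0 * (1 - (1 - leak) * mu / 2)
        p = mk.ModelParams(tau_mk=1.0, tau_ci=1.0, mu=mu, leak=leak)
        out = mk.expected_cross_outcome(
            mk.female(0, ("CI", "MK")), mk.male(0, ()), p
        )
        assert out.expected_egg_to_adult == \
            pytest.approx(p.v_0 * (1 - (1 - leak) * mu / 2))

    def test_surviving_males_carry_suppressor(self):
        # full transmission and penetrance: any adult male descending from
        # an MK mother must carry at least one S allele
        p = mk.ModelParams(tau_mk=1.0, mu=1.0, leak=0.0)
        for ms, fs in itertools.product((0, 1, 2), repeat=2):
            out = mk.expected_cross_outcome(
                mk.female(ms, ("CI", "MK")), mk.male(fs, ("CI",)), p
            )
            for geno, w in out.offspring_dist:
                if geno.sex == mk.MALE and w > 0 and "MK" in geno.cytotype:
                    assert geno.s_alleles >= 1

    @given(
        h_ci=st.floats(0.0, 0.76),
        tau=st.floats(0.0, 1.0),
        mu=st.floats(0.0, 1.0),
    )
    def test_incompatible_hatch_never_exceeds_compatible(self, h_ci, tau, mu):
        p = mk.ModelParams(h_ci=h_ci, tau_mk=tau, mu=mu)
        incompatible = mk.expected_cross_outcome(
            mk.female(0, ()), mk.male(0, ("CI",)), p
        )
        compatible = mk.expected_cross_outcome(
            mk.female(0, ("CI",)), mk.male(0, ("CI",)), p
        )
        assert incompatible.expected_hatch <= compatible.expected_hatch

    def test_sex_roles_enforced(self):
        with pytest.raises(ValueError):
            mk.expected_cross_outcome(
                mk.male(0, ()), mk.male(0, ()), mk.ModelParams()
            )


class TestClassifier:
    @pytest.mark.parametrize(
        "n_f, n_m, expected",
        [
            (30, 0, "MK"),
            (12, 2, "excluded"),   # total under 15
            (18, 14, "MKS"),       # 56% female
            (20, 4, "excluded"),   # 83% female: ambiguous, possibly leaky MK
            (15, 0, "MK"),
        ],
    )
    def test_rules(self, n_f, n_m, expected):
        assert mk.classify_line_phenotype(n_f, n_m) == expected


class TestBackcrossPanel:
    def test_f1_is_never_female_only(self):
        df = mk.simulate_backcross_panel(
            n_lines=20, generations=2, p=mk.ModelParams(tau_mk=1.0), seed=1
        )
        assert df.loc[df.generation == "F1", "pct_mk"].iloc[0] == 0.0
        assert df.loc[df.generation == "F1", "expected_pct_mk"].iloc[0] == 0.0

    def test_bc2_expectation_is_mendelian_half(self):
        df = mk.simulate_backcross_panel(
            n_lines=29, generations=2, p=mk.ModelParams(tau_mk=1.0), seed=42
        )
        assert df.loc[df.generation == "BC2",
                      "expected_pct_mk"].iloc[0] == pytest.approx(50.0)

    def test_uninfected_control_never_reverts(self):
        df = mk.simulate_backcross_panel(
            n_lines=20, generations=3, p=mk.ModelParams(),
            donor=mk.female(0, ()), seed=3,
        )
        assert (df.pct_mk == 0.0).all()


class TestMixedPopulations:
    def test_all_mks_vials_stay_balanced(self):
        traj = mk.simulate_mixed_population(0.0, n_replicates=5, seed=2)
        final = traj[traj.generation == 5].pct_female
        assert abs(final.mean() - 50.0) < 5.0

    def test_all_mk_vials_stay_female_biased(self):
        traj = mk.simulate_mixed_population(1.0, n_replicates=5, seed=2)
        final = traj[traj.generation == 5].pct_female
        assert final.mean() > 80.0

    def test_suppressor_frequency_nondecreasing_in_expectation(self):
        # deterministic recursion over a random-mating population with the
        # MK strain fixed: the S allele frequency never declines when MK
        # mortality is positive
        p = mk.ModelParams(tau_mk=1.0, mu=0.7)
        for s0 in (0.05, 0.2, 0.5, 0.8):
            # genotype frequencies at Hardy-Weinberg for the start
            freqs = {0: (1 - s0) ** 2, 1: 2 * s0 * (1 - s0), 2: s0 ** 2}
            s_freq = [s0]
            female_g = dict(freqs)
            male_g = dict(freqs)
            for _ in range(4):
                next_counts = {}
                total_m = sum(male_g.values())
                for ms, mw in female_g.items():
                    for fs, fw in male_g.items():
                        pair_w = mw * fw / total_m
                        out = mk.expected_cross_outcome(
                            mk.female(ms, ("CI", "MK")),
                            mk.male(fs, ("CI", "MK")), p,
                        )
                        for geno, w in out.offspring_dist:
                            key = (geno.sex, geno.s_alleles)
                            next_counts[key] = next_counts.get(key, 0.0) + \
                                pair_w * w * out.expected_egg_to_adult
                female_g = {s: next_counts.get((mk.FEMALE, s), 0.0)
                            for s in (0, 1, 2)}
                male_g = {s: next_counts.get((mk.MALE, s), 0.0)
                          for s in (0, 1, 2)}
                tot = sum(female_g.values()) + sum(male_g.values())
                alleles = sum(
                    (female_g.get(s, 0) + male_g.get(s, 0)) * s
                    for s in (0, 1, 2)
                )
                s_freq.append(alleles / (2 * tot))
            assert all(b >= a - 1e-12 for a, b in zip(s_freq, s_freq[1:]))

    def test_neutral_model_matches_binomial_sex_ratio(self):
        # with MK mortality and CI switched off, offspring sex is a fair
        # coin: per-generation female counts should look binomial
        p = mk.ModelParams(mu=0.0, h_ci=0.76)
        traj = mk.simulate_mixed_population(
            0.5, vial_size=30, generations=3, n_replicates=40, seed=7, p=p
        )
        n = (traj.n_adults * traj.pct_female / 100).round()
        z = (n - traj.n_adults / 2) / np.sqrt(traj.n_adults / 4)
        assert sps.kstest(z, "norm").pvalue > 0.01


class TestFieldStatistics:
    def test_g_equal_proportions_is_zero(self):
        g, dof, _ = mk.g_test([[10, 90], [20, 180]])
        assert g == pytest.approx(0.0, abs=1e-9)
        assert dof == 1

    def test_g_against_hand_oracle(self):
        # brute-force likelihood-ratio computation for (10,90 / 20,80)
        obs = np.array([[10.0, 90.0], [20.0, 80.0]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = 2 * np.sum(obs * np.log(obs / expected))
        g, dof, p = mk.g_test(obs)
        assert g == pytest.approx(oracle)
        assert g == pytest.approx(3.9866, abs=1e-3)
        assert dof == 1

    def test_incidence_counts_give_known_g(self):
        # six collection sites screened for female-biased lines
        table = [[1, 33], [0, 3], [3, 71], [0, 10], [3, 41], [0, 23]]
        g, dof, p = mk.g_test(table)
        assert g == pytest.approx(3.767, abs=1e-3)
        assert dof == 5
        assert p > 0.5

    def test_g_validation(self):
        with pytest.raises(ValueError):
            mk.g_test([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            mk.g_test([[1, 0], [2, 0]])

    @pytest.mark.parametrize(
        "n_f, n_m, chi2",
        [(50, 50, 0.0), (90, 10, 64.0), (143, 0, 143.0)],
    )
    def test_sex_ratio_chisq(self, n_f, n_m, chi2):
        stat, p = mk.sex_ratio_chisq(n_f, n_m)
        assert stat == pytest.approx(chi2)
        if chi2 > 10:
            assert p < 0.001

    def test_relative_density(self):
        assert mk.relative_density([20.0, 20.0], [20.0, 20.0])[0] == \
            pytest.approx(1.0)
        density, _ = mk.relative_density([20.0], [23.3219])
        assert density == pytest.approx(10.0, abs=1e-3)

    def test_density_qc_flag(self):
        density, flag = mk.relative_density([20.0, 25.5], [21.0, 21.0])
        assert flag is True
        _, ok = mk.relative_density([20.0, 21.0], [21.0, 21.5])
        assert ok is False

    def test_density_empty_error(self):
        with pytest.raises(ValueError):
            mk.relative_density([], [20.0])

    def test_incidence_table(self):
        counts = {
            "Nowra": (1, 34), "Moorland": (0, 3), "Mount Tamborine": (3, 74),
            "Cedar Creek": (0, 10), "Mount Glorious": (3, 44),
            "Northern Queensland": (0, 23),
        }
        df = mk.incidence_table(counts)
        overall = df.loc[df.site == "overall"].iloc[0]
        assert overall.pct == 3.72
        assert df.loc[df.site == "Mount Glorious", "pct"].iloc[0] == 6.82
        assert df.attrs["g"] == pytest.approx(3.767, abs=1e-3)
        assert df.attrs["df"] == 5
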