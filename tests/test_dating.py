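"""Dating relaxation: binomial pseudogene-count model and omega methods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genedecay import (
    OmegaShiftInputs,
    PseudogeneDatingModel,
    Regime,
    SimulationScenario,
    fixation_probability,
    generate_gene_set,
    mixed_branch_time,
    mixture_proportion_time,
    simulated_dating_curve,
)

from conftest import PRINTED_MU


class TestFixationProbability:
    def test_zero_time_zero_probability(self):
        assert fixation_probability(0.0, 1e-6) == 0.0

    def test_closed_form_value(self):
        mu = 7.81e-7
        assert fixation_probability(np.log(4) / mu, mu) == pytest.approx(0.75)

    def test_monotone_approach_to_one(self):
        mu = 1e-6
        ts = np.linspace(0, 1e7, 50)
        ps = [fixation_probability(t, mu) for t in ts]
        assert np.all(np.diff(ps) > 0)
        assert ps[-1] < 1.0

    def test_negative_inputs_fatal(self):
        with pytest.raises(ValueError):
            fixation_probability(-1.0, 1e-6)


class TestPseudogeneDating:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        T=st.integers(5, 200),
        mu_exp=st.floats(-8.0, -5.0),
        data=st.data(),
    )
    def test_closed_form_mle_is_grid_argmax(self, T, mu_exp, data):
        D = data.draw(st.integers(1, T - 1))
        mu_lof = 10.0 ** mu_exp
        model = PseudogeneDatingModel(T, D, mu_lof)
        mle = model.mle()
        grid = np.linspace(mle * 0.5, mle * 1.5, 2001)
        argmax = grid[np.argmax(model.pmf(grid))]
        assert argmax == pytest.approx(mle, rel=1e-3)

    def test_pmf_at_mle_is_binomial_mode(self):
        model = PseudogeneDatingModel(76, 19, 7.81e-7)
        assert model.pmf(model.mle()) == pytest.approx(
            stats.binom.pmf(19, 76, 19 / 76), rel=1e-9
        )

    def test_no_pseudogenes_dates_to_zero(self):
        res = PseudogeneDatingModel(76, 0, 7.81e-7).fit()
        assert res.mle_t == 0.0
        assert np.all(np.diff(res.pmf) <= 0)

    def test_all_pseudogenes_unbounded(self):
        res = PseudogeneDatingModel(76, 76, 7.81e-7).fit()
        assert res.unbounded

    def test_interval_nesting_in_threshold(self):
        model = PseudogeneDatingModel(76, 19, 7.81e-7)
        wide = model.fit(threshold=0.02).interval
        narrow = model.fit(threshold=0.08).interval
        assert wide[0] < narrow[0] < narrow[1] < wide[1]

    def test_threshold_above_mode_gives_no_interval(self):
        model = PseudogeneDatingModel(76, 19, 7.81e-7)
        res = model.fit(threshold=0.99)
        assert res.interval is None

    def test_generation_time_reporting(self):
        res = PseudogeneDatingModel(76, 19, 7.81e-7).fit()
        years = res.to_years(4.0)
        assert years["mle_years"] == pytest.approx(res.mle_t * 4.0)


class TestSimulatedCurve:
    MU_LOF = 7.81156e-7

    def test_matches_analytic_pmf_without_lag(self):
        model = PseudogeneDatingModel(76, 19, self.MU_LOF)
        grid = np.linspace(1.5e5, 7.5e5, 25)
        curve = simulated_dating_curve(
            np.full(76, self.MU_LOF), 19, grid, n_sims=4000, seed=3
        )
        assert np.abs(curve["prob"] - model.pmf(grid)).max() < 0.02

    @pytest.mark.parametrize("ne", [100, 1000])
    def test_fixation_lag_shift_is_marginal(self, ne):
        """A 4*Ne fixation lag moves the curve by at most a few thousand
        generations — under 5% of the estimate for Ne up to 1,000."""
        grid = np.linspace(2.0e5, 6.0e5, 81)
        base = simulated_dating_curve(
            np.full(76, self.MU_LOF), 19, grid, n_sims=6000, seed=5
        )
        lagged = simulated_dating_curve(
            np.full(76, self.MU_LOF), 19, grid, n_sims=6000, ne=ne, seed=5
        )
        shift = abs(lagged["argmax_t"] - base["argmax_t"]) / base["argmax_t"]
        assert shift < 0.05

    def test_single_sim_reproducible(self):
        grid = np.linspace(1e5, 5e5, 5)
        a = simulated_dating_curve(np.full(76, self.MU_LOF), 19, grid, n_sims=1, seed=8)
        b = simulated_dating_curve(np.full(76, self.MU_LOF), 19, grid, n_sims=1, seed=8)
        np.testing.assert_array_equal(a["prob"], b["prob"])


class TestIntervalCoverage:
    def test_empirical_coverage_matches_binomial_theory(self):
        """Genes evolved for a known t*: the fraction of replicates whose
        pmf>0.05 likelihood range covers t* equals the binomial prediction
        sum_k { pmf(k; T, p*) : pmf(k; T, p*) > 0.05 } within Monte-Carlo
        error. (The range is a likelihood region, not a calibrated
        confidence interval, so its coverage sits near 77% here.)"""
        from genedecay import evolve_sequences
        from genedecay.rates import build_rate_table

        scen = SimulationScenario(n_genes=76, intron_mean=0.0, seed=41)
        gs = generate_gene_set(scen)
        table = build_rate_table(gs.cds, gs.models, kappa=scen.kappa, mu=scen.mu,
                                 frameshift_rate=0.0)
        mu_lof = table.mean_mu_lof
        t_star = np.log(76 / 57) / mu_lof  # E[D] = 19
        covered = 0
        n_rep = 120
        for rep in range(n_rep):
            run = SimulationScenario(
                n_genes=76, intron_mean=0.0, mu=scen.mu, generations=t_star,
            )
            _, truth = evolve_sequences(gs, Regime.NEUTRAL, run, seed=1000 + rep)
            D = truth.pseudogene_count(gs.gene_ids)
            if D in (0, 76):
                continue
            res = PseudogeneDatingModel(76, D, mu_lof).fit(threshold=0.05)
            if res.interval is not None and res.interval[0] <= t_star <= res.interval[1]:
                covered += 1
        p_star = 19 / 76
        pmf = stats.binom.pmf(np.arange(77), 76, p_star)
        theory = pmf[pmf > 0.05].sum()
        se = np.sqrt(theory * (1 - theory) / n_rep)
        assert abs(covered / n_rep - theory) < 3.5 * se


class TestOmegaDating:
    def test_mixed_branch_printed_values(self):
        """omega 0.27 functional vs 0.50 mixed over 4.1 My dates the shift to
        1.3 My (ratio 0.32)."""
        res = mixed_branch_time(
            OmegaShiftInputs(omega_functional=0.27, omega_mixed=0.50,
                             divergence_time=4.1)
        )
        assert round(res.t_n, 1) == 1.3
        assert round(res.ratio, 2) == 0.32

    def test_mixed_branch_boundaries(self):
        base = dict(omega_functional=0.27, divergence_time=4.1)
        assert mixed_branch_time(
            OmegaShiftInputs(omega_mixed=0.27, **base)
        ).t_n == 0.0
        assert mixed_branch_time(
            OmegaShiftInputs(omega_mixed=1.0, **base)
        ).t_n == pytest.approx(4.1)

    def test_mixed_branch_out_of_range_fatal(self):
        with pytest.raises(ValueError, match="outside"):
            mixed_branch_time(
                OmegaShiftInputs(omega_functional=0.27, omega_mixed=1.2,
                                 divergence_time=4.1)
            )

    def test_mixture_proportions_printed_values(self):
        """66% neutral / 34% selected substitutions with omega_s=0.27 over
        4.1 My date relaxation to 1.4 My (ratio 0.34)."""
        res = mixture_proportion_time(
            OmegaShiftInputs(omega_functional=0.27, divergence_time=4.1,
                             p_selected=0.34, p_neutral=0.66)
        )
        assert round(res.t_n, 1) == 1.4
        assert round(res.ratio, 2) == 0.34

    def test_mixture_no_neutral_fraction_gives_zero(self):
        res = mixture_proportion_time(
            OmegaShiftInputs(omega_functional=0.27, divergence_time=4.1,
                             p_selected=1.0, p_neutral=0.0)
        )
        assert res.t_n == 0.0

    def test_mixture_equal_omegas_is_proportional_clock(self):
        res = mixture_proportion_time(
            OmegaShiftInputs(omega_functional=1.0, omega_neutral=1.0,
                             divergence_time=10.0, p_selected=0.4, p_neutral=0.6)
        )
        assert res.t_n == pytest.approx(6.0)

    @pytest.mark.parametrize("scale", [1.0, 4.1, 1e6])
    def test_time_unit_invariance(self, scale):
        mixed = mixed_branch_time(
            OmegaShiftInputs(omega_functional=0.27, omega_mixed=0.50,
                             divergence_time=scale)
        )
        mixt = mixture_proportion_time(
            OmegaShiftInputs(omega_functional=0.27, divergence_time=scale,
                             p_selected=0.34, p_neutral=0.66)
        )
        assert mixed.ratio == pytest.approx(0.23 / 0.73)
        assert mixt.ratio == pytest.approx(0.34388, abs=1e-4)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            OmegaShiftInputs(omega_functional=0.27, divergence_time=4.1,
                             p_selected=0.3, p_neutral=0.6)
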