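import itertools

import numpy as np
import pandas as pd
import pytest

from lfqtobit.config import MCMCConfig, SimConfig
from lfqtobit.containers import ALL_ZERO, CENSORED, OBSERVED, TobitPosterior
from lfqtobit.simulate import simulate_abundance, simulate_design
from lfqtobit.normalize import log10_transform
from lfqtobit.tobit import (
    apply_censoring_rule,
    build_design_matrix,
    derive_protein_seed,
    fit_all_proteins,
    gibbs_tobit,
    summarize_posterior,
)

FAST_MCMC = MCMCConfig(iterations=4000, burnin=500)


class TestBuildDesignMatrix:
    def test_column_sums(self, pellet_design, design_matrix):
        assert design_matrix.shape == (12, 4)
        np.testing.assert_allclose(design_matrix.sum(axis=0), [12.0, 6.0, 6.0, 3.0])

    def test_reference_and_opposite_cells(self, pellet_design, design_matrix):
        ref = (pellet_design["substrate"] == "Whatman") & (pellet_design["time"] == "46h")
        np.testing.assert_allclose(design_matrix[ref.to_numpy()][0], [1.0, 0.0, 0.0, 0.0])
        top = (pellet_design["substrate"] == "Tissue") & (pellet_design["time"] == "70h")
        np.testing.assert_allclose(design_matrix[top.to_numpy()][0], [1.0, 1.0, 1.0, 1.0])

    def test_rejects_more_than_two_levels(self):
        cfg = SimConfig(substrates=("A", "B", "C"), fractions=("pellet",))
        design = simulate_design(cfg)
        with pytest.raises(ValueError):
            build_design_matrix(design)


class TestCensoringRule:
    def test_all_detected_unchanged(self, pellet_design):
        y = np.linspace(5.0, 6.0, 12)
        r = apply_censoring_rule(y, pellet_design)
        np.testing.assert_array_equal(r.y, y)
        assert (r.flags == OBSERVED).all()
        assert r.threshold == 5.0

    def test_worked_example(self, pellet_design):
        # cells in design order: Whatman/46, Whatman/70, Tissue/46, Tissue/70
        values = {
            ("Tissue", "46h"): [5.1, 0.0, 5.3],
            ("Tissue", "70h"): [0.0, 0.0, 0.0],
            ("Whatman", "46h"): [4.8, 4.9, 5.0],
            ("Whatman", "70h"): [5.2, 5.4, 0.0],
        }
        y = np.empty(12)
        for (sub, time), vals in values.items():
            idx = pellet_design[
                (pellet_design["substrate"] == sub) & (pellet_design["time"] == time)
            ].index
            y[idx] = vals
        r = apply_censoring_rule(y, pellet_design)
        assert r.threshold == pytest.approx(4.8)
        t46 = pellet_design[(pellet_design["substrate"] == "Tissue") & (pellet_design["time"] == "46h")].index
        assert r.y[t46[1]] == pytest.approx(4.8) and r.flags[t46[1]] == CENSORED
        w70 = pellet_design[(pellet_design["substrate"] == "Whatman") & (pellet_design["time"] == "70h")].index
        assert r.y[w70[2]] == pytest.approx(4.8) and r.flags[w70[2]] == CENSORED
        t70 = pellet_design[(pellet_design["substrate"] == "Tissue") & (pellet_design["time"] == "70h")].index
        assert (r.flags[t70] == ALL_ZERO).all()
        assert (r.y[t70] == 0.0).all()

    def test_single_detected_value_sets_threshold(self, pellet_design):
        y = np.zeros(12)
        y[0] = 7.2
        r = apply_censoring_rule(y, pellet_design)
        assert r.threshold == pytest.approx(7.2)
        cell0 = pellet_design[
            (pellet_design["substrate"] == pellet_design.loc[0, "substrate"])
            & (pellet_design["time"] == pellet_design.loc[0, "time"])
        ].index
        assert (r.y[cell0] == 7.2).all()

    def test_all_zero_signalled(self, pellet_design):
        with pytest.raises(ValueError):
            apply_censoring_rule(np.zeros(12), pellet_design)

    def test_random_patterns_match_brute_force(self, pellet_design):
        """Random detect patterns agree with the literal rule (exhaustive
        enumeration lives in the acceptance suite)."""
        from _oracles import brute_force_censoring

        rng = np.random.default_rng(4)
        base = np.linspace(5.0, 6.1, 12)
        for _ in range(64):
            y = base * rng.integers(0, 2, size=12)
            expected = brute_force_censoring(y, pellet_design)
            if expected is None:
                continue
            r = apply_censoring_rule(y, pellet_design)
            np.testing.assert_allclose(r.y, expected[0])
            np.testing.assert_array_equal(r.flags, expected[1])
            assert r.threshold == pytest.approx(expected[2])


class TestGibbsTobit:
    def test_matches_ols_without_censoring(self, pellet_design, design_matrix):
        rng = np.random.default_rng(0)
        ok = 0
        n_prot = 20
        for i in range(n_prot):
            beta = np.array([6.0, 0.3, -0.2, 0.1])
            y = design_matrix @ beta + rng.normal(0, 0.15, 12)
            r = apply_censoring_rule(y, pellet_design)
            post = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=i)
            ols = np.linalg.lstsq(design_matrix, y, rcond=None)[0]
            draws = post.draws[:, :4]
            nb = 50
            bm = draws.reshape(nb, -1, 4).mean(axis=1)
            mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb)
            ok += int(np.all(np.abs(draws.mean(axis=0) - ols) <= 3 * mcse))
        assert ok >= int(0.85 * n_prot)

    def test_constant_response_centers_on_intercept(self, pellet_design, design_matrix):
        y = np.full(12, 5.5)
        r = apply_censoring_rule(y, pellet_design)
        post = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=3)
        means = post.draws[:, :4].mean(axis=0)
        np.testing.assert_allclose(means, [5.5, 0.0, 0.0, 0.0], atol=1e-3)

    def test_same_seed_identical_chain(self, pellet_design, design_matrix):
        y = np.linspace(5.0, 6.0, 12)
        y[3] = 0.0
        r = apply_censoring_rule(y, pellet_design)
        p1 = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=9)
        p2 = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=9)
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_all_censored_flagged_unconverged(self, pellet_design, design_matrix):
        y = np.zeros(12)
        y[0] = 6.0
        r = apply_censoring_rule(y, pellet_design)
        r.flags[:] = CENSORED  # force a fully censored response
        post = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=1)
        assert not post.converged
        with pytest.raises(ValueError):
            summarize_posterior(post)

    def test_alpha_recovery_under_moderate_censoring(self, pellet_design, design_matrix):
        """Posterior means track a known substrate effect at ~20% censoring."""
        rng = np.random.default_rng(5)
        errs = []
        for i in range(60):
            beta = np.array([6.0, 0.4, 0.0, 0.0])
            lat = design_matrix @ beta + rng.normal(0, 0.15, 12)
            lim = np.quantile(lat, 0.2)
            y = np.where(lat >= lim, lat, 0.0)
            r = apply_censoring_rule(y, pellet_design)
            if (r.flags == ALL_ZERO).any():
                continue  # qualitative regime: effect not quantitatively identified
            post = gibbs_tobit(r, design_matrix, FAST_MCMC, seed=i)
            errs.append(post.chain("alpha").mean() - 0.4)
        errs = np.asarray(errs)
        assert len(errs) > 40
        assert abs(np.median(errs)) < 0.1


class TestSummarizePosterior:
    def _posterior(self, alpha_draws):
        n = len(alpha_draws)
        draws = np.zeros((n, 5))
        draws[:, 1] = alpha_draws
        draws[:, 4] = 1.0
        return TobitPosterior(draws=draws, converged=True)

    def test_one_sided_floor(self):
        post = self._posterior(np.ones(100))
        p = summarize_posterior(post).set_index("coefficient")["p_value"]
        assert p["alpha"] == pytest.approx(2 / 101)

    def test_symmetric_draws_near_one(self):
        post = self._posterior(np.r_[np.ones(50), -np.ones(50)])
        p = summarize_posterior(post).set_index("coefficient")["p_value"]
        assert p["alpha"] == pytest.approx(1.0)

    def test_counted_example(self):
        post = self._posterior(np.array([-1.0, 1.0, 1.0, 1.0]))
        p = summarize_posterior(post).set_index("coefficient")["p_value"]
        assert p["alpha"] == pytest.approx(0.8)


class TestFitAllProteins:
    def test_partition_and_determinism(self):
        cfg = SimConfig(n_proteins=25, seed=6, fractions=("pellet",), detection_quantile=0.3,
                        qualitative_fraction=0.0)
        design = simulate_design(cfg)
        matrix, _ = simulate_abundance(design, cfg)
        nm = log10_transform(matrix)
        fits, discards = fit_all_proteins(nm, design, "pellet", mcmc=FAST_MCMC, master_seed=6)
        fitted = set(fits["protein_id"])
        discarded = set(discards["protein_id"])
        assert fitted.isdisjoint(discarded)
        assert fitted | discarded == set(matrix.values.index)
        fits2, discards2 = fit_all_proteins(nm, design, "pellet", mcmc=FAST_MCMC, master_seed=6)
        pd.testing.assert_frame_equal(fits, fits2)
        pd.testing.assert_frame_equal(discards, discards2)

    def test_all_zero_protein_discarded_with_reason(self):
        cfg = SimConfig(n_proteins=5, seed=6, fractions=("pellet",), qualitative_fraction=0.0)
        design = simulate_design(cfg)
        matrix, _ = simulate_abundance(design, cfg)
        matrix.values.iloc[0] = 0.0
        nm = log10_transform(matrix)
        fits, discards = fit_all_proteins(nm, design, "pellet", mcmc=FAST_MCMC, master_seed=6)
        pid = matrix.values.index[0]
        assert pid not in set(fits["protein_id"])
        assert discards.set_index("protein_id").loc[pid, "reason"] == "no detections"

    def test_protein_seed_stable(self):
        assert derive_protein_seed(1, 0) == derive_protein_seed(1, 0)
        assert derive_protein_seed(1, 0) != derive_protein_seed(1, 1)
        assert 0 <= derive_protein_seed(123, 456) < 2**31
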