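import numpy as np
import pytest

import clamap
from clamap.icim_scan import ScanResult, _design_matrix
from oracles import (
    chain_conditional_prob,
    direct_ml_mixture_lod,
    marker_regression_lod,
    plain_interval_mapping_lod,
)


def _sim(h2=0.2, n=200, seed=0, model="I"):
    return clamap.simulate_population(clamap.model_catalog(model, h2, n_lines=n), seed)


class TestStepwiseSelect:
    def test_null_phenotype_rarely_selects(self):
        # with p_in = 0.001 and ~51 correlated candidates the no-signal
        # selection rate should stay in the few-percent range
        design = clamap.model_catalog("I", 0.2)
        empty = 0
        reps = 150
        master = np.random.default_rng(11)
        for _ in range(reps):
            pop = clamap.simulate_population(design, master)
            geno, gmap = clamap.map_scenario(pop, "individual")
            y = master.normal(size=pop.design.n_lines)
            sel, _, _ = clamap.stepwise_select(y, _design_matrix(geno))
            empty += not sel
        assert empty / reps >= 0.90

    def test_strong_signal_marker_found(self, rng):
        pop = _sim(seed=5)
        geno, gmap = clamap.map_scenario(pop, "individual")
        X = _design_matrix(geno)
        y = 2.0 * X[:, 17] + rng.normal(0, 0.5, X.shape[0])
        sel, betas, _ = clamap.stepwise_select(y, X)
        # marker 17 or a tightly linked neighbour
        assert any(abs(j - 17) <= 1 for j in sel)
        assert betas[0] == pytest.approx(2.0, abs=0.3)

    def test_duplicate_columns_only_one_enters(self, rng):
        n = 120
        x = rng.choice([-1.0, 1.0], n)
        X = np.column_stack([x, x, rng.choice([-1.0, 1.0], n)])
        y = 1.5 * x + rng.normal(0, 0.5, n)
        sel, _, _ = clamap.stepwise_select(y, X)
        assert sel == [0]

    def test_backward_elimination_runs(self, rng):
        # two correlated predictors; after the second enters, the weaker
        # may be dropped -- final set must satisfy p_out throughout
        n = 300
        x1 = rng.choice([-1.0, 1.0], n)
        flip = rng.random(n) < 0.05
        x2 = np.where(flip, -x1, x1)
        X = np.column_stack([x1, x2])
        y = 2.0 * x2 + rng.normal(0, 1.0, n)
        sel, _, _ = clamap.stepwise_select(y, X)
        assert 1 in sel and len(sel) <= 2


class TestAdjustPhenotype:
    def test_no_cofactors_identity(self, rng):
        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], (50, 5))
        np.testing.assert_array_equal(
            clamap.icim_scan.__globals__["adjust_phenotype"](y, X, [], np.empty(0)), y
        )

    def test_single_cofactor_exact(self, rng):
        from clamap.icim_scan import adjust_phenotype

        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], (50, 5))
        dy = adjust_phenotype(y, X, [3], np.array([0.7]))
        np.testing.assert_allclose(dy, y - 0.7 * X[:, 3])

    def test_excluded_flank_not_subtracted(self, rng):
        from clamap.icim_scan import adjust_phenotype

        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], (50, 5))
        dy = adjust_phenotype(y, X, [3], np.array([0.7]), exclude=[3])
        np.testing.assert_array_equal(dy, y)


class TestConditionalProbs:
    def test_qtl_at_marker(self):
        p = clamap.conditional_qtl_probs(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.0, 0.02
        )
        np.testing.assert_allclose(p, [1.0, 0.0])

    def test_both_flanks_missing_gives_half(self):
        p = clamap.conditional_qtl_probs(
            np.array([np.nan]), np.array([np.nan]), 0.01, 0.01
        )
        assert p[0] == 0.5

    @pytest.mark.parametrize("ptype", ["RIL_selfing", "DH"])
    def test_matches_chain_enumeration(self, ptype):
        for rl, rr in [(0.005, 0.005), (0.01, 0.03), (0.1, 0.2)]:
            for gl in (0, 1):
                for gr in (0, 1):
                    ours = clamap.conditional_qtl_probs(
                        np.array([float(gl)]), np.array([float(gr)]), rl, rr, ptype
                    )[0]
                    oracle = chain_conditional_prob(rl, rr, gl, gr, ptype)
                    assert ours == pytest.approx(oracle, abs=1e-12)

    def test_tight_interval_agreeing_flanks_near_certain(self):
        r = float(clamap.inverse_map_distance(1.0, "haldane"))
        p = clamap.conditional_qtl_probs(np.array([0.0]), np.array([0.0]), r, r)
        assert p[0] >= 0.999


class TestEMIntervalMapping:
    def test_uninformative_probs_give_zero(self, rng):
        y = rng.normal(size=100)
        fit = clamap.em_interval_mapping(y, np.full(100, 0.5))
        assert fit["lod"] == 0.0 and fit["additive"] == 0.0

    def test_known_genotypes_match_regression_lod(self, rng):
        x = rng.choice([-1.0, 1.0], 200)
        y = 0.8 * x + rng.normal(0, 1.5, 200)
        probs = (x + 1) / 2  # certainty
        fit = clamap.em_interval_mapping(y, probs)
        assert fit["lod"] == pytest.approx(marker_regression_lod(y, x), abs=1e-6)
        assert fit["additive"] == pytest.approx(0.8, abs=2 * 1.5 / np.sqrt(200))

    def test_agrees_with_direct_likelihood_maximization(self, rng):
        # 20 random mixed instances vs Nelder-Mead multistart on the
        # observed-data likelihood
        for i in range(20):
            n = 120
            x = rng.choice([-1.0, 1.0], n)
            q = np.clip((x + 1) / 2 + rng.normal(0, 0.15, n), 0.02, 0.98)
            y = rng.normal(0, 1.0, n) + rng.uniform(0.3, 1.2) * x
            fit = clamap.em_interval_mapping(y, q)
            oracle = direct_ml_mixture_lod(y, q, seed=i)
            assert fit["lod"] == pytest.approx(oracle, abs=1e-4)

    def test_em_loglik_monotone(self, rng):
        # EM observed-data log-likelihood is non-decreasing; verify by
        # running with increasing iteration caps
        x = rng.choice([-1.0, 1.0], 150)
        q = np.clip((x + 1) / 2 + rng.normal(0, 0.2, 150), 0.05, 0.95)
        y = 0.6 * x + rng.normal(0, 1.0, 150)
        lls = [
            clamap.em_interval_mapping(y, q, tol=0.0, max_iter=k)["loglik"]
            for k in (1, 2, 3, 5, 10, 50)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestIcimScan:
    def test_matches_plain_interval_mapping_without_cofactors(self):
        # spike p_in so no cofactor enters: ICIM reduces to simple IM
        rng = np.random.default_rng(2)
        design = clamap.SimulationDesign(
            chromosome_length_cM=20.0,
            marker_positions_cM=np.arange(0.0, 21.0, 2.0),
            qtls=(clamap.QTL(7.0, 0.8),),
            heritability=0.3,
            n_lines=100,
        )
        for seed in range(5):
            pop = clamap.simulate_population(design, seed)
            settings = clamap.ScanSettings(step=0.5, p_in=1e-12, p_out=2e-12)
            scan = clamap.icim_scan(pop.phenotype, pop.geno, pop.design.truth_map(), settings)
            assert scan.cofactors == []
            oracle = plain_interval_mapping_lod(
                pop.phenotype,
                pop.geno.codes,
                design.marker_positions_cM,
                scan.positions,
            )
            np.testing.assert_allclose(scan.lod, oracle, atol=1e-6)

    def test_lod_at_marker_equals_marker_regression(self):
        pop = _sim(seed=9)
        settings = clamap.ScanSettings(step=1.0, p_in=1e-12, p_out=2e-12)
        geno, gmap = clamap.map_scenario(pop, "individual")
        scan = clamap.icim_scan(pop.phenotype, geno, gmap, settings)
        X = _design_matrix(geno)
        for mpos, col in [(34.0, 17), (60.0, 30)]:
            i = np.where(scan.positions == mpos)[0][0]
            assert scan.lod[i] == pytest.approx(
                marker_regression_lod(pop.phenotype, X[:, col]), abs=1e-6
            )

    def test_location_scale_invariance(self):
        pop = _sim(seed=3)
        geno, gmap = clamap.map_scenario(pop, "individual")
        settings = clamap.ScanSettings(step=1.0)
        a = clamap.icim_scan(pop.phenotype, geno, gmap, settings)
        b = clamap.icim_scan(3.0 * pop.phenotype + 7.0, geno, gmap, settings)
        np.testing.assert_allclose(a.lod, b.lod, atol=1e-6)
        np.testing.assert_allclose(3.0 * a.additive, b.additive, atol=1e-6)

    def test_peak_near_true_qtl_model_I(self):
        pop = _sim(seed=1)
        geno, gmap = clamap.map_scenario(pop, "individual")
        scan = clamap.icim_scan(
            pop.phenotype, geno, gmap, clamap.ScanSettings(step=0.1)
        )
        peak = scan.positions[np.argmax(scan.lod)]
        assert abs(peak - 34.5) < 4.0
        assert scan.lod.max() > 4.0

    def test_consensus_scenario_runs_with_fully_missing_markers(self):
        pop = _sim(seed=4)
        geno, gmap = clamap.map_scenario(pop, "consensus")
        scan = clamap.icim_scan(
            pop.phenotype, geno, gmap, clamap.ScanSettings(step=0.5)
        )
        assert np.all(np.isfinite(scan.lod))
        assert scan.positions[-1] == 100.0

    def test_permuted_phenotype_rarely_exceeds_threshold(self):
        rng = np.random.default_rng(8)
        pop = _sim(seed=6)
        geno, gmap = clamap.map_scenario(pop, "individual")
        hits = 0
        reps = 40
        for _ in range(reps):
            yp = rng.permutation(pop.phenotype)
            scan = clamap.icim_scan(yp, geno, gmap, clamap.ScanSettings(step=1.0))
            hits += scan.lod.max() >= 2.5
        assert hits / reps <= 0.25

    def test_map_marker_mismatch_raises(self):
        pop = _sim(seed=0)
        gmap = clamap.GeneticMap.from_positions(["nope"], [0.0])
        with pytest.raises(ValueError):
            clamap.icim_scan(pop.phenotype, pop.geno, gmap)


class TestCallQtls:
    def _scan(self, lod, step=1.0):
        n = len(lod)
        return ScanResult(
            chromosomes=np.array(["1"] * n, dtype=object),
            positions=np.arange(n, dtype=float) * step,
            lod=np.asarray(lod, float),
            additive=np.ones(n),
            pve=np.ones(n),
        )

    def test_profile_below_threshold_no_calls(self):
        scan = self._scan([0.1, 0.5, 1.0, 2.0, 1.0])
        assert clamap.call_qtls(scan) == []

    def test_single_peak_one_lod_support(self):
        lod = [0, 1, 2, 4, 6, 4.8, 3, 1, 0]
        calls = clamap.call_qtls(self._scan(lod))
        assert len(calls) == 1
        c = calls[0]
        assert c.position_cM == 4.0
        # one-LOD drop: positions with LOD >= 5 around the peak
        assert (c.ci_lo, c.ci_hi) == (4.0, 4.0)

    def test_two_separated_peaks_both_called(self):
        lod = [0, 3, 0.5] + [0] * 4 + [0.5, 4, 0.5]
        calls = clamap.call_qtls(self._scan(lod))
        assert len(calls) == 2
        assert [c.position_cM for c in calls] == [1.0, 8.0]

    def test_shoulder_within_dip_and_distance_suppressed(self):
        # secondary maximum 2 cM away with shallow dip: one call only
        lod = [0, 2, 5, 4.7, 4.9, 2, 0]
        calls = clamap.call_qtls(self._scan(lod))
        assert len(calls) == 1 and calls[0].position_cM == 2.0

    def test_close_twin_peaks_with_deep_dip_both_called(self):
        lod = [0, 5, 1.0, 4.5, 0]
        calls = clamap.call_qtls(self._scan(lod))
        assert len(calls) == 2

    def test_ci_clipped_at_chromosome_ends(self):
        lod = [6, 5.5, 3, 1, 0]
        calls = clamap.call_qtls(self._scan(lod))
        assert calls[0].ci_lo == 0.0
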