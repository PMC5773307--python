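import itertools

import numpy as np
import pytest
from scipy import stats

from keyhabitat import occurrence as occ
from keyhabitat import synth
from keyhabitat.grid import BinaryMask, GridLayer
from keyhabitat.occurrence import (CovariateStack, EvalMetrics, MaxLikeFit,
                                   PresenceSet, aicc, cluster_covariates,
                                   evaluate_fit, fit_maxlike,
                                   generate_pseudoabsences,
                                   partition_records, predict_surface,
                                   rank_replicates, select_best_model,
                                   select_threshold, threshold_metrics,
                                   transform_and_standardize)


def _stack_from_arrays(arrays: dict, cell_size=1.0) -> CovariateStack:
    layers = {n: GridLayer(v.astype(float), cell_size)
              for n, v in arrays.items()}
    return CovariateStack(sorted(arrays), layers)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)

def oracle_confusion_scan(psi_pres, psi_abs):
    """Exhaustive scan over every threshold in a dense grid; returns
    (max kappa, best sss, auc by pair counting)."""
    psi = np.concatenate([psi_pres, psi_abs])
    # every distinct classification outcome is realized at some observed
    # value or just below it
    cands = sorted(set(psi)) + [(a + b) / 2 for a, b in
                                itertools.pairwise(sorted(set(psi)))]
    best_kappa, best_sss = -np.inf, -np.inf
    for t in cands:
        tp = sum(p >= t for p in psi_pres)
        fp = sum(p >= t for p in psi_abs)
        fn = len(psi_pres) - tp
        tn = len(psi_abs) - fp
        n = tp + fp + fn + tn
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        kappa = 0.0 if pe == 1 else (po - pe) / (1 - pe)
        sss = tp / len(psi_pres) + tn / len(psi_abs)
        best_kappa = max(best_kappa, kappa)
        best_sss = max(best_sss, sss)
    wins = sum((p > a) + 0.5 * (p == a)
               for p in psi_pres for a in psi_abs)
    auc = wins / (len(psi_pres) * len(psi_abs))
    return best_kappa, best_sss, auc


class TestClusterCovariates:
    def test_perfectly_correlated_pair_is_one_cluster(self, rng):
        base = rng.normal(size=(20, 20))
        stack = _stack_from_arrays({"TREE": base, "AI": 3 * base + 1})
        clusters, reps = cluster_covariates(stack, always_keep=())
        assert len(clusters) == 1
        assert reps == ["TREE"]

    def test_independent_layers_stay_separate(self, rng):
        stack = _stack_from_arrays({"TREE": rng.normal(size=(30, 30)),
                                    "AI": rng.normal(size=(30, 30))})
        clusters, reps = cluster_covariates(stack)
        assert len(clusters) == 2
        assert sorted(reps) == ["AI", "TREE"]

    def test_three_engineered_blocks(self, rng):
        # eight layers in 3 blocks with within-block r ~ 0.9
        shape = (40, 40)
        seeds = [rng.normal(size=shape) for _ in range(3)]
        blocks = {0: ["TREE", "BIO02", "BIO03"],
                  1: ["AI", "BIO07", "BIO10"],
                  2: ["BIO17", "BIO19"]}
        arrays = {}
        for b, names in blocks.items():
            for n in names:
                arrays[n] = seeds[b] + 0.33 * rng.normal(size=shape)
        stack = _stack_from_arrays(arrays)
        clusters, reps = cluster_covariates(stack, threshold=0.6,
                                            always_keep=())
        assert len(clusters) == 3
        assert len(reps) == 3

    def test_constant_layer_raises_with_name(self, rng):
        stack = _stack_from_arrays({"TREE": rng.normal(size=(5, 5)),
                                    "AI": np.ones((5, 5))})
        with pytest.raises(ValueError, match="AI"):
            cluster_covariates(stack)

    def test_always_keep_retained(self, rng):
        base = rng.normal(size=(20, 20))
        stack = _stack_from_arrays({"TREE": base, "AI": base * 2 + 5})
        _, reps = cluster_covariates(stack)  # default keeps TREE and AI
        assert set(reps) == {"TREE", "AI"}


class TestTransformAndStandardize:
    def test_zero_mean_unit_sd(self, rng):
        stack = _stack_from_arrays({"TREE": 5 + rng.normal(size=(20, 20))})
        out = transform_and_standardize(stack, [])
        vals = out.design_matrix()
        assert abs(vals.mean()) < 1e-8
        assert abs(vals.std() - 1) < 1e-8

    def test_all_zeros_layer_raises(self):
        stack = _stack_from_arrays({"TREE": np.zeros((4, 4))})
        with pytest.raises(ValueError, match="zero variance"):
            transform_and_standardize(stack, ["TREE"])

    def test_negative_under_sqrt_raises(self):
        stack = _stack_from_arrays({"TREE": np.array([[-1.0, 2.0]])})
        with pytest.raises(ValueError, match="negative"):
            transform_and_standardize(stack, ["TREE"])

    def test_sqrt_reduces_lognormal_skew(self, rng):
        vals = rng.lognormal(0, 1, size=(50, 50))
        stack = _stack_from_arrays({"TREE": vals})
        out = transform_and_standardize(stack, ["TREE"])
        raw_skew = stats.skew(vals.ravel())
        new_skew = stats.skew(np.sqrt(vals).ravel())
        assert abs(new_skew) < abs(raw_skew)
        assert out.transforms["TREE"] == "sqrt"


class TestPartitionRecords:
    @staticmethod
    def _records(n):
        return PresenceSet(np.arange(n, dtype=float),
                           np.zeros(n), np.full(n, 2000))

    def test_88_records_split_66_22(self):
        splits = partition_records(self._records(88), 0.75, 5, seed=1)
        assert len(splits) == 5
        for s in splits:
            assert len(s.calibration) == 66
            assert len(s.validation) == 22

    def test_4_records_not_enough(self):
        with pytest.raises(ValueError):
            partition_records(self._records(4), 0.75)

    def test_8_records_split_6_2(self):
        splits = partition_records(self._records(8), 0.75, 2, seed=0)
        assert len(splits[0].calibration) == 6
        assert len(splits[0].validation) == 2

    def test_partition_is_disjoint_and_exhaustive(self):
        splits = partition_records(self._records(88), 0.75, 5, seed=3)
        for s in splits:
            cal = set(s.calibration.x)
            val = set(s.validation.x)
            assert not cal & val
            assert cal | val == set(range(88))

    def test_seeds_differ(self):
        a = partition_records(self._records(88), 0.75, 1, seed=1)[0]
        b = partition_records(self._records(88), 0.75, 1, seed=2)[0]
        assert not np.array_equal(a.calibration.x, b.calibration.x)

    def test_bad_frac(self):
        with pytest.raises(ValueError):
            partition_records(self._records(88), 1.5)


class TestFitMaxlike:
    def test_loglik_at_optimum_beats_zero(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 200, seed=0)
        fit = fit_maxlike(pres, truth_stack, list(landscape.truth_covariates))
        X = truth_stack.values_at(pres, fit.formula)
        Z = truth_stack.design_matrix(fit.formula)
        ll_zero = -occ._neg_loglik_and_grad(np.zeros(len(fit.beta)), X, Z)[0]
        assert fit.loglik >= ll_zero

    def test_aicc_matches_definition(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 100, seed=1)
        fit = fit_maxlike(pres, truth_stack, list(landscape.truth_covariates))
        k = len(fit.beta)
        n = fit.n_calibration
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_separation_flags_nonconvergence(self, small_landscape):
        pres = synth.simulate_presences(small_landscape, 40, seed=2,
                                        replace=False)
        grid = small_landscape.coarse_grid
        ind = np.zeros(grid.shape)
        r, c = grid.cell_of(pres.x, pres.y)
        ind[r, c] = 1.0
        layers = {n: small_landscape.layers[n] for n in ("TREE", "AI")}
        layers["BIO02"] = GridLayer(ind * 10 + 1, grid.cell_size)
        stack = transform_and_standardize(
            CovariateStack(["TREE", "AI", "BIO02"], layers), [])
        fit = fit_maxlike(pres, stack, ["TREE", "AI", "BIO02"])
        assert not fit.converged

    def test_parameter_recovery(self):
        errs = []
        for rep in range(10):
            land = synth.generate_landscape(300 + rep)
            pres = synth.simulate_presences(land, 2000, seed=rep)
            names = list(land.truth_covariates)
            stack = transform_and_standardize(
                CovariateStack(names, {n: land.layers[n] for n in names}), [])
            fit = fit_maxlike(pres, stack, names)
            assert fit.converged
            errs.append(np.abs(fit.beta[1:] - land.truth_beta[1:]))
        assert np.mean(errs) < 0.15

    def test_constant_shift_moves_only_intercept(self, landscape):
        # likelihood invariance: adding a constant to a covariate changes
        # the intercept but not the slopes at the optimum
        pres = synth.simulate_presences(landscape, 500, seed=3)
        names = list(landscape.truth_covariates)
        layers = {n: landscape.layers[n] for n in names}
        stack = CovariateStack(names, layers)
        fit = fit_maxlike(pres, stack, names)

        shifted = dict(layers)
        shifted["TREE"] = layers["TREE"].with_values(
            layers["TREE"].values + 100.0)
        fit2 = fit_maxlike(pres, CovariateStack(names, shifted), names)
        assert np.allclose(fit.beta[1:], fit2.beta[1:], atol=1e-4)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_aicc_ordering_invariant_to_standardization(self, landscape):
        pres = synth.simulate_presences(landscape, 300, seed=4)
        names = list(landscape.truth_covariates)
        raw = CovariateStack(names,
                             {n: landscape.layers[n] for n in names})
        std = transform_and_standardize(
            CovariateStack(names, {n: landscape.layers[n] for n in names}),
            [])
        formulas = [["TREE"], ["AI"], ["TREE", "AI"]]
        aicc_raw = [fit_maxlike(pres, raw, f).aicc for f in formulas]
        aicc_std = [fit_maxlike(pres, std, f).aicc for f in formulas]
        assert np.argsort(aicc_raw).tolist() == np.argsort(aicc_std).tolist()


class TestSelectBestModel:
    @staticmethod
    def _fit(formula, aicc_val, converged, rep):
        return MaxLikeFit(formula=formula, beta=np.zeros(len(formula) + 1),
                          loglik=0.0, aicc=aicc_val, converged=converged,
                          replicate_id=rep)

    def test_table1_pattern(self):
        # rich models never converge; the 2-covariate model always does and
        # wins despite larger AICc values
        mdl1 = [self._fit(["TREE", "AI", "BIO02", "BIO03", "BIO07", "BIO10",
                           "BIO17", "BIO19"], a, False, r + 1)
                for r, a in enumerate([647.982, 647.691, 635.865, 635.463,
                                       695.351])]
        mdl2 = [self._fit(["BIO02", "BIO03", "BIO07", "BIO10", "BIO17",
                           "BIO19"], a, False, r + 1)
                for r, a in enumerate([650.621, 642.334, 633.761, 634.553,
                                       692.630])]
        mdl3 = [self._fit(["TREE", "AI"], a, True, r + 1)
                for r, a in enumerate([696.733, 676.306, 677.510, 678.468,
                                       738.753])]
        assert select_best_model({"mdl1": mdl1, "mdl2": mdl2,
                                  "mdl3": mdl3}) == "mdl3"

    def test_single_converged_formula(self):
        fits = {"only": [self._fit(["TREE"], 10.0, True, 1)]}
        assert select_best_model(fits) == "only"

    def test_tie_prefers_smaller_formula(self):
        a = [self._fit(["TREE", "AI"], 5.0, True, 1),
             self._fit(["TREE", "AI"], 9.0, True, 2)]
        b = [self._fit(["TREE"], 9.0, True, 1),
             self._fit(["TREE"], 5.0, True, 2)]
        assert select_best_model({"big": a, "small": b}) == "small"

    def test_nothing_converges_raises(self):
        fits = {"a": [self._fit(["TREE"], 1.0, False, 1)],
                "b": [self._fit(["AI"], 2.0, False, 1)]}
        with pytest.raises(ValueError):
            select_best_model(fits)


class TestEvaluateFit:
    @staticmethod
    def _metrics_from_scores(psi_pres, psi_abs):
        tm = threshold_metrics(np.asarray(psi_pres, dtype=float),
                               np.asarray(psi_abs, dtype=float))
        return tm

    def test_toy_six_points_against_oracle(self):
        # 3 presences psi = .9,.8,.4; 3 absences psi = .5,.2,.1
        psi_pres = np.array([0.9, 0.8, 0.4])
        psi_abs = np.array([0.5, 0.2, 0.1])
        kappa_o, sss_o, auc_o = oracle_confusion_scan(psi_pres, psi_abs)
        tm = self._metrics_from_scores(psi_pres, psi_abs)
        assert tm["kappa"].max() == pytest.approx(kappa_o)
        assert tm["sss"].max() == pytest.approx(sss_o)
        # oracle-verified frozen values
        assert auc_o == pytest.approx(8 / 9)
        assert kappa_o == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_scores(self, seed):
        rng = np.random.default_rng(seed)
        psi_pres = np.round(rng.random(60), 2)
        psi_abs = np.round(rng.random(80), 2)
        kappa_o, sss_o, _ = oracle_confusion_scan(psi_pres, psi_abs)
        tm = self._metrics_from_scores(psi_pres, psi_abs)
        assert tm["kappa"].max() == pytest.approx(kappa_o, abs=1e-12)
        assert tm["sss"].max() == pytest.approx(sss_o, abs=1e-12)

    def test_full_evaluate_on_fit(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 120, seed=5)
        splits = partition_records(pres, 0.75, 1, seed=5)
        fit = fit_maxlike(splits[0].calibration, truth_stack,
                          list(landscape.truth_covariates))
        grid = landscape.coarse_grid
        outside = BinaryMask(np.ones(grid.shape, dtype=int), grid.cell_size)
        pseudo = generate_pseudoabsences(outside, 88, seed=6)
        m = evaluate_fit(fit, splits[0].validation, pseudo, truth_stack)
        assert 0 <= m.auc <= 1
        assert -1 <= m.max_kappa <= 1
        psi_all = np.concatenate([
            occ.predict_points(fit, splits[0].validation, truth_stack),
            occ.predict_points(fit, pseudo, truth_stack)])
        assert psi_all.min() <= m.maxsss_threshold <= psi_all.max()

    def test_identical_predictions_give_chance_metrics(self):
        tm = self._metrics_from_scores([0.5, 0.5], [0.5, 0.5])
        assert tm["kappa"].max() == pytest.approx(0.0)
        auc = oracle_confusion_scan(np.array([0.5, 0.5]),
                                    np.array([0.5, 0.5]))[2]
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_auc_one(self):
        _, _, auc = oracle_confusion_scan(np.array([0.9, 0.8]),
                                          np.array([0.1, 0.2]))
        assert auc == 1.0
        tm = self._metrics_from_scores([0.9, 0.8], [0.1, 0.2])
        assert tm["kappa"].max() == pytest.approx(1.0)

    def test_empty_validation_raises(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 20, seed=7)
        fit = fit_maxlike(pres, truth_stack,
                          list(landscape.truth_covariates))
        empty = PresenceSet(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            evaluate_fit(fit, empty, pres, truth_stack)


class TestSelectThreshold:
    @staticmethod
    def _m(rep, kappa, auc=0.5):
        return EvalMetrics(auc=auc, cor=0.0, maxsss_threshold=0.5,
                           maxsss_value=1.0, max_kappa=kappa,
                           replicate_id=rep, kappa_argmax_threshold=0.5)

    def test_printed_replicates_mean(self):
        metrics = [self._m(1, 0.786), self._m(2, 0.692), self._m(3, 0.544),
                   self._m(4, 0.139), self._m(5, 0.751)]
        sel = select_threshold(metrics, [1, 2, 5])
        assert round(sel.t_psi, 3) == 0.743

    def test_single_replicate(self):
        sel = select_threshold([self._m(1, 0.42)], [1])
        assert sel.t_psi == pytest.approx(0.42)

    def test_all_equal(self):
        metrics = [self._m(i, 0.3) for i in range(1, 4)]
        assert select_threshold(metrics, [1, 2, 3]).t_psi == pytest.approx(0.3)

    def test_empty_choice_raises(self):
        with pytest.raises(ValueError):
            select_threshold([self._m(1, 0.5)], [])

    def test_rank_replicates_by_auc_then_cor(self):
        metrics = [self._m(1, 0.5, auc=0.7), self._m(2, 0.5, auc=0.9),
                   self._m(3, 0.5, auc=0.8)]
        assert rank_replicates(metrics) == [2, 3, 1]


class TestPredictSurface:
    def test_zero_beta_gives_uniform_half(self, truth_stack):
        fit = MaxLikeFit(formula=list(truth_stack.names),
                         beta=np.zeros(len(truth_stack.names) + 1),
                         loglik=0.0, aicc=0.0, converged=True,
                         transforms=dict(truth_stack.transforms),
                         standardization=dict(truth_stack.standardization))
        surf = predict_surface(fit, truth_stack)
        assert np.allclose(surf.values[surf.mask], 0.5)

    def test_monotone_in_positive_covariate(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 300, seed=8)
        fit = fit_maxlike(pres, truth_stack, list(truth_stack.names))
        i = fit.formula.index("TREE")
        sign = np.sign(fit.beta[1 + i])
        bumped_layers = dict(truth_stack.layers)
        bumped_layers["TREE"] = truth_stack.layers["TREE"].with_values(
            truth_stack.layers["TREE"].values + 1.0)
        bumped = CovariateStack(list(truth_stack.names), bumped_layers,
                                transforms=dict(truth_stack.transforms),
                                standardization=dict(
                                    truth_stack.standardization))
        s0 = predict_surface(fit, truth_stack)
        s1 = predict_surface(fit, bumped)
        diff = s1.values[s1.mask] - s0.values[s0.mask]
        assert (sign * diff >= -1e-12).all()

    def test_surface_matches_in_likelihood_psi(self, landscape, truth_stack):
        pres = synth.simulate_presences(landscape, 300, seed=9)
        fit = fit_maxlike(pres, truth_stack, list(truth_stack.names))
        surf = predict_surface(fit, truth_stack)
        Z = truth_stack.design_matrix(fit.formula)
        from scipy.special import expit
        psi_lik = expit(fit.beta[0] + Z @ fit.beta[1:])
        assert np.allclose(surf.values[truth_stack.cell_mask()], psi_lik,
                           atol=1e-10)

    def test_missing_covariate_raises(self, landscape, truth_stack):
        fit = MaxLikeFit(formula=["BIO02"], beta=np.zeros(2), loglik=0.0,
                         aicc=0.0, converged=True)
        with pytest.raises(KeyError):
            predict_surface(fit, truth_stack)


class TestAicc:
    def test_small_sample_guard(self):
        assert aicc(0.0, 3, 4) == float("inf")

    def test_value(self):
        assert aicc(-10.0, 3, 66) == pytest.approx(20 + 6 + 24 / 62)
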