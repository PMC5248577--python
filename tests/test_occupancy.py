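import warnings
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import (
    brute_force_site_loglik,
    random_history,
    random_params,
    single_species_mle,
)
from sympatry import occupancy as occ
from sympatry.records import TwoSpeciesHistory
from sympatry.synthetic import SimDesign, simulate_occupancy

probs = st.floats(min_value=0.01, max_value=0.99)


class TestLinks:
    def test_inverse_pair(self):
        for x in range(-5, 6):
            assert occ.logit(occ.inv_logit(float(x))) == pytest.approx(x, abs=1e-9)

    def test_symmetry_and_limits(self):
        assert occ.inv_logit(0.0) == 0.5
        assert occ.inv_logit(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            occ.logit(1.0)


class TestStateProbs:
    def test_boundary_column(self):
        # psiBA = psiBa = 1: B everywhere, so only (both, B-only) states
        assert occ.state_probs(0.28, 1.0, 1.0) == pytest.approx([0.28, 0.0, 0.72, 0.0])

    def test_symmetric_half(self):
        assert occ.state_probs(0.5, 0.5, 0.5) == pytest.approx([0.25] * 4)

    @given(probs, probs, probs)
    def test_conservation(self, a, ba, b):
        assert occ.state_probs(a, ba, b).sum() == pytest.approx(1.0)


class TestOccasionProb:
    def test_joint_detection_given_both(self):
        p = occ.OccupancyParams(0.5, 0.5, 0.5, 0.5, 0.5, 0.03, 0.04, 0.04)
        assert occ.occasion_prob("AB", (1, 1), p) == pytest.approx(0.0012)

    def test_no_false_positives(self):
        p = occ.OccupancyParams(*[0.5] * 8)
        assert occ.occasion_prob("none", (1, 0), p) == 0.0
        assert occ.occasion_prob("A", (0, 1), p) == 0.0
        assert occ.occasion_prob("B", (1, 0), p) == 0.0

    @given(st.sampled_from(["AB", "A", "B", "none"]), probs, probs, probs, probs, probs)
    def test_normalises_over_outcomes(self, state, pa, pb, ra, rba, rba2):
        p = occ.OccupancyParams(0.5, 0.5, 0.5, pa, pb, ra, rba, rba2)
        total = sum(
            occ.occasion_prob(state, obs, p)
            for obs in [(0, 0), (0, 1), (1, 0), (1, 1)]
        )
        assert total == pytest.approx(1.0)

    def test_missing_occasion_contributes_one(self):
        p = occ.OccupancyParams(*[0.3] * 8)
        assert occ.occasion_prob("AB", None, p) == 1.0


class TestSiteLoglik:
    def test_hand_enumerated_single_occasion(self):
        # (0,0) under all-0.5 params: 0.25*0.25 + 0.25*0.5 + 0.25*0.5 + 0.25
        p = occ.OccupancyParams(*[0.5] * 8)
        assert occ.site_loglik([0.0], [0.0], p) == pytest.approx(np.log(0.5625))

    def test_joint_detection_forces_both_state(self):
        p = occ.OccupancyParams(0.4, 0.6, 0.3, 0.2, 0.2, 0.25, 0.35, 0.15)
        ll = occ.site_loglik([1.0, 0.0], [1.0, 0.0], p)
        both_only = (
            0.4 * 0.6 * (0.25 * 0.35) * ((1 - 0.25) * (1 - 0.15))
        )
        assert ll == pytest.approx(np.log(both_only))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            yA, yB = random_history(rng)
            prm = random_params(rng)
            p = occ.OccupancyParams(**prm)
            for a_row, b_row in zip(yA, yB):
                assert occ.site_loglik(a_row, b_row, p) == pytest.approx(
                    brute_force_site_loglik(a_row, b_row, prm), abs=1e-10
                )

    def test_estimator_likelihood_matches_oracle(self):
        # the vectorised sufficient-statistic likelihood inside the
        # estimator must agree with state-by-state enumeration
        rng = np.random.default_rng(7)
        for _ in range(20):
            yA, yB = random_history(rng, max_sites=3, max_occ=4)
            prm = random_params(rng)
            sites = pd.DataFrame(
                {"station": [f"s{i}" for i in range(len(yA))], "year": 2009}
            )
            hist = TwoSpeciesHistory(yA=yA, yB=yB, sites=sites)
            est = occ.ConditionalTwoSpeciesOccupancy(n_starts=1, maxiter=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(hist)
            beta = np.array([occ.logit(prm[k]) for k in occ.PARAM_NAMES])
            expected = sum(
                brute_force_site_loglik(a, b, prm) for a, b in zip(yA, yB)
            )
            assert -est._negloglik(beta) == pytest.approx(expected, abs=1e-9)

    def test_site_reordering_invariance(self):
        rng = np.random.default_rng(3)
        yA, yB = random_history(rng, max_sites=3, max_occ=4, allow_missing=False)
        prm = random_params(rng)
        sites = pd.DataFrame({"station": [f"s{i}" for i in range(len(yA))], "year": 2009})
        hist = TwoSpeciesHistory(yA=yA, yB=yB, sites=sites)
        perm = rng.permutation(len(yA))
        hist_p = TwoSpeciesHistory(yA=yA[perm], yB=yB[perm], sites=sites)
        beta = np.array([occ.logit(prm[k]) for k in occ.PARAM_NAMES])
        vals = []
        for h in (hist, hist_p):
            est = occ.ConditionalTwoSpeciesOccupancy(n_starts=1, maxiter=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(h)
            vals.append(est._negloglik(beta))
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)


class TestAicc:
    def test_formula_value(self):
        assert occ.aicc(-1176.0, 8, 400) == pytest.approx(2352 + 16 + 144 / 391)

    def test_no_parameters_no_penalty(self):
        assert occ.aicc(-100.0, 0, 50) == 200.0

    def test_large_n_approaches_aic(self):
        assert occ.aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-6)

    def test_deficient_sample_size_rejected(self):
        with pytest.raises(ValueError, match="n=9"):
            occ.aicc(-10.0, 8, 9)


class TestModelSelectionTable:
    @staticmethod
    def _mock(name, aicc_val, k):
        return SimpleNamespace(
            model_spec_=SimpleNamespace(name=name), aicc_=aicc_val, loglik_=-aicc_val / 2, K_=k
        )

    def test_equal_models_split_weight(self):
        tab = occ.model_selection_table([self._mock("a", 100.0, 3), self._mock("b", 100.0, 3)])
        assert tab["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_delta_530_model_likelihood(self):
        tab = occ.model_selection_table(
            [self._mock("best", 2368.11, 8), self._mock("second", 2373.41, 9)]
        )
        assert tab["model_likelihood"].iloc[1] == pytest.approx(np.exp(-2.65), rel=1e-3)
        assert round(tab["model_likelihood"].iloc[1], 2) == 0.07

    def test_weights_sum_to_one(self):
        fits = [self._mock(f"m{i}", 100.0 + 3 * i, i + 1) for i in range(5)]
        tab = occ.model_selection_table(fits)
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab["AICc"].is_monotonic_increasing


class TestSif:
    def test_boundary_year_is_independent(self):
        assert occ.sif(0.28, 1.0, 1.0) == pytest.approx(1.0)

    @given(probs, probs)
    def test_equal_conditionals_mean_independence(self, a, b):
        assert occ.sif(a, b, b) == pytest.approx(1.0)

    def test_unequal_conditionals_give_aggregation(self):
        assert occ.sif(0.28, 1.0, 0.91) == pytest.approx(1.06929, abs=1e-4)

    def test_joint_occupancy(self):
        assert occ.psi2(0.28, 1.0) == pytest.approx(0.28)
        assert occ.psi2(0.5, 0.0) == 0.0

    @given(probs, probs, probs)
    def test_psi2_bounded_by_marginals(self, a, ba, b):
        psi_b_marginal = a * ba + (1 - a) * b
        assert occ.psi2(a, ba) <= min(a, psi_b_marginal) + 1e-12


class TestModelSpec:
    def test_parse_full_string(self):
        s = "psiA(deer) psiBA(y*peccary) psiBa(y*peccary) pA=rA(.) pB=rBA=rBa(.)"
        spec = occ.ModelSpec.from_string(s)
        assert spec.design["psiBA"] == "y*peccary"
        assert ("pA", "rA") in spec.constraints
        assert ("pB", "rBA", "rBa") in spec.constraints

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            occ.ModelSpec.from_string("psiX(.)")

    def test_constraint_groups_share_coefficients(self, small_bundle):
        _, _, hist, _ = small_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = occ.fit_model(
                "psiA(.) psiBA(.) psiBa(.) pA=rA(.) pB=rBA=rBa(.)", hist, n_starts=2
            )
        assert fit.K_ == 5
        reals = fit.reals_[fit.reals_["year"] == 2009].set_index("param")["estimate"]
        assert reals["pA"] == pytest.approx(reals["rA"])
        assert reals["pB"] == pytest.approx(reals["rBA"])


class TestFit:
    def test_single_species_reduction_matches_independent_mle(self):
        # B never detected, psiBA=psiBa shared: the A-side of the model
        # collapses to the standard one-species occupancy likelihood
        rng = np.random.default_rng(10)
        S, J = 200, 10
        z = rng.random(S) < 0.55
        yA = (rng.random((S, J)) < 0.35) * z[:, None]
        yB = np.zeros_like(yA)
        sites = pd.DataFrame({"station": [f"s{i}" for i in range(S)], "year": 2009})
        hist = TwoSpeciesHistory(yA=yA.astype(float), yB=yB.astype(float), sites=sites)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = occ.fit_model(
                "psiA(.) psiBA=psiBa(.) pA=rA(.) pB=rBA=rBa(.)", hist, n_starts=3
            )
        psi_hat, p_hat, _ = single_species_mle(yA)
        reals = fit.reals_[fit.reals_["year"] == 2009].set_index("param")["estimate"]
        assert reals["psiA"] == pytest.approx(psi_hat, abs=1e-3)
        assert reals["pA"] == pytest.approx(p_hat, abs=1e-3)

    def test_multistart_reaches_same_optimum(self):
        prs, hist, truth = simulate_occupancy(SimDesign.recovery(seed=21, n_stations=150))
        f1 = occ.fit_model(None, hist, seed=0, n_starts=1)
        f5 = occ.fit_model(None, hist, seed=123, n_starts=5)
        assert f1.loglik_ == pytest.approx(f5.loglik_, abs=1e-6)

    def test_covariate_never_hurts_loglik(self):
        prs, hist, truth = simulate_occupancy(SimDesign.recovery(seed=22, n_stations=150))
        f0 = occ.fit_model(None, hist, seed=0, n_starts=2)
        f1 = occ.fit_model(
            "psiA(deer) psiBA(.) psiBa(.) pA(.) pB(.) rA(.) rBA(.) rBa(.)",
            hist, seed=0, n_starts=2,
        )
        assert f1.loglik_ >= f0.loglik_ - 1e-6

    def test_boundary_data_flagged_not_failed(self):
        # generated at psiBA = 1 (subordinate present wherever dominant is)
        design = SimDesign.recovery(seed=23, n_stations=300, psiBA=0.999)
        prs, hist, truth = simulate_occupancy(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = occ.fit_model(None, hist, seed=0, n_starts=1)
        reals = fit.reals_[fit.reals_["year"] == 2009].set_index("param")["estimate"]
        assert reals["psiBA"] > 0.95
        assert fit.loglik_ < 0  # fit completed

    def test_delta_method_se_tracks_replicate_spread(self):
        # SIF delta-method SE vs the spread of estimates over replicates
        ests, ses = [], []
        for seed in range(200):
            prs, hist, truth = simulate_occupancy(
                SimDesign.recovery(seed=3000 + seed, n_stations=120)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = occ.fit_model(None, hist, seed=0, n_starts=1)
            ests.append(f.sif_["estimate"].iloc[0])
            ses.append(f.sif_["se"].iloc[0])
        ratio = np.nanmean(ses) / np.std(ests)
        assert 0.75 < ratio < 1.25

    def test_sif_se_nonnegative_and_accessor(self, small_bundle):
        _, _, hist, _ = small_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = occ.fit_model(None, hist, n_starts=2)
        se = occ.sif_se(fit)
        assert ((se >= 0) | se.isna()).all()
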