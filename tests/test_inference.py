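"""Design construction, IRLS fitting, sandwich SEs, simple effects, trimming."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from twostep.inference import (
    MB_TERM,
    DesignError,
    ModelSpec,
    SeparationError,
    age_match_trim,
    build_design,
    cluster_robust_se,
    fit_logistic,
    mb_index_spec,
    omnibus_model,
    omnibus_spec,
    significance_gate,
    simple_effects,
    simulate_stay_features,
)


def random_instance(n, k, seed, beta=None):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(scale=0.8, size=k) if beta is None else np.asarray(beta)
    y = (rng.random(n) < special.expit(X @ beta)).astype(float)
    return X, y, beta


class TestModelSpec:
    def test_interactions_require_main_effects(self):
        with pytest.raises(DesignError):
            ModelSpec(terms=((("prev_reward", "prev_transition")),))

    def test_omnibus_contains_five_way_and_covariates(self):
        spec = omnibus_spec()
        names = [":".join(t) for t in spec.terms]
        assert "prev_reward:prev_transition:condition:delay:group" in names
        assert "site" in names and "iq" in names
        assert "age:prev_reward:prev_transition:condition:delay:group" in names
        # full factorial over six factors + site + iq + age family crossing
        assert len(names) == 63 + 1 + 1 + 32


class TestBuildDesign:
    def make_features(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(4)], n // 4),
                "stay": rng.integers(0, 2, n),
                "prev_reward": rng.choice([0.5, -0.5], n),
                "prev_transition": rng.choice([0.5, -0.5], n),
                "condition": rng.choice(["light", "moderate"], n),
                "age": rng.uniform(21, 50, n),
            }
        )

    def test_single_term_design(self):
        f = self.make_features()
        X, y, clusters, names = build_design(f, ModelSpec(terms=(("prev_reward",),)))
        assert names == ["intercept", "prev_reward"]
        assert X.shape == (40, 2)
        assert set(np.unique(X[:, 1])) == {-0.5, 0.5}

    def test_interaction_is_elementwise_product(self):
        f = self.make_features()
        spec = ModelSpec(
            terms=(("prev_reward",), ("prev_transition",),
                   ("prev_reward", "prev_transition"))
        )
        X, *_ = build_design(f, spec)
        np.testing.assert_allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_age_centered_to_sample_mean(self):
        f = self.make_features()
        X, _, _, names = build_design(f, ModelSpec(terms=(("age",),)))
        assert abs(X[:, names.index("age")].mean()) < 1e-12

    def test_missing_variable_named_in_error(self):
        f = self.make_features().drop(columns=["condition"])
        with pytest.raises(DesignError, match="condition"):
            build_design(f, ModelSpec(terms=(("condition",),)))

    def test_unknown_factor_level_rejected(self):
        f = self.make_features()
        f.loc[0, "condition"] = "vigorous"
        with pytest.raises(DesignError, match="vigorous"):
            build_design(f, ModelSpec(terms=(("condition",),)))


class TestFitLogistic:
    def test_balanced_intercept_only_fit_is_zero(self):
        X = np.ones((10, 1))
        y = np.array([0, 1] * 5, dtype=float)
        fit = fit_logistic(X, y)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_consistency_and_grid_search_oracle(self):
        X, y, _ = random_instance(50_000, 2, seed=1, beta=[0.3, 0.8])
        fit = fit_logistic(X, y)
        assert abs(fit.coef[0] - 0.3) < 3 * fit.se[0]
        assert abs(fit.coef[1] - 0.8) < 3 * fit.se[1]
        # coarse grid over the 2-D likelihood cannot beat the IRLS optimum
        def loglik(b):
            eta = X @ b
            return float(y @ eta - np.logaddexp(0, eta).sum())

        grid = [
            np.array([b0, b1])
            for b0 in np.linspace(0.1, 0.5, 21)
            for b1 in np.linspace(0.6, 1.0, 21)
        ]
        lls = np.array([loglik(b) for b in grid])
        assert fit.loglik >= lls.max()
        best = grid[int(lls.argmax())]
        assert np.all(np.abs(best - fit.coef) <= np.array([0.02, 0.02]) + 1e-9)

    def test_mle_beats_generating_parameters(self):
        X, y, beta = random_instance(2_000, 3, seed=2)
        fit = fit_logistic(X, y)
        eta = X @ beta
        ll_true = float(y @ eta - np.logaddexp(0, eta).sum())
        assert fit.loglik >= ll_true

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = random_instance(500, 4, seed=3)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_rank_deficiency_names_columns(self):
        X, y, _ = random_instance(200, 3, seed=4)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(DesignError, match="x"):
            fit_logistic(X, y, names=["intercept", "x1", "x2", "x1_copy"])


class TestClusterRobust:
    def test_singleton_clusters_match_hc0(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = random_instance(400, 3, seed=5)
        fit = fit_logistic(X, y)
        robust = cluster_robust_se(fit, X, y, np.arange(400))
        ref = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(robust.se, ref.bse, rtol=1e-5)
        np.testing.assert_allclose(robust.coef, fit.coef)  # estimates untouched

    def test_matches_statsmodels_cluster_cov(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = random_instance(600, 3, seed=6)
        groups = np.repeat(np.arange(30), 20)
        fit = fit_logistic(X, y)
        robust = cluster_robust_se(fit, X, y, groups)
        ref = sm.Logit(y, X).fit(
            disp=0, cov_type="cluster",
            cov_kwds={"groups": groups, "use_correction": False},
        )
        np.testing.assert_allclose(robust.se, ref.bse, rtol=1e-5)

    def test_duplicating_rows_preserves_z_statistics(self):
        X, y, _ = random_instance(100, 3, seed=7)
        groups = np.repeat(np.arange(5), 20)
        fit = fit_logistic(X, y)
        z1 = cluster_robust_se(fit, X, y, groups).statistic
        X2, y2, g2 = np.tile(X, (2, 1)), np.tile(y, 2), np.tile(groups, 2)
        fit2 = fit_logistic(X2, y2)
        z2 = cluster_robust_se(fit2, X2, y2, g2).statistic
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    def test_independent_homogeneous_clusters_near_model_se(self):
        X, y, _ = random_instance(4_000, 3, seed=8)
        groups = np.repeat(np.arange(200), 20)
        fit = fit_logistic(X, y)
        robust = cluster_robust_se(fit, X, y, groups)
        ratio = robust.se / fit.se
        assert np.all(ratio > 0.8) and np.all(ratio < 1.2)

    def test_single_cluster_rejected(self):
        X, y, _ = random_instance(50, 2, seed=9)
        fit = fit_logistic(X, y)
        with pytest.raises(ValueError):
            cluster_robust_se(fit, X, y, np.zeros(50))


class TestSimulatedRecovery:
    def test_known_coefficients_recovered(self):
        truth = {"intercept": 0.3, "prev_reward": 0.5,
                 "prev_transition": 0.1, MB_TERM: 1.0}
        f = simulate_stay_features(truth, n_subjects=30, seed=0)
        X, y, clusters, names = build_design(f, mb_index_spec())
        fit = cluster_robust_se(fit_logistic(X, y, names), X, y, clusters)
        for name, value in truth.items():
            got = fit[name]
            assert abs(got["estimate"] - value) < 3 * got["se"], name


@pytest.fixture(scope="module")
def null_features():
    # enough subjects that the CR0 sandwich is well calibrated per subset
    truth = {"intercept": 0.5, "prev_reward": 0.4, MB_TERM: 0.8}
    f = simulate_stay_features(truth, n_subjects=80, seed=1)
    # attach balanced design metadata so simple effects can filter
    meta = {}
    for i, sid in enumerate(sorted(f["subject_id"].unique())):
        meta[sid] = {
            "group": "PTSD" if i % 2 else "control",
            "delay": "long" if (i // 2) % 2 else "short",
        }
    f["group"] = f["subject_id"].map(lambda s: meta[s]["group"])
    f["delay"] = f["subject_id"].map(lambda s: meta[s]["delay"])
    # condition alternates within subject across trial halves (visit proxy)
    f["condition"] = np.where(f.index % 2 == 0, "light", "moderate")
    return f


class TestSimpleEffectsAndGate:
    def test_null_subset_contrast_near_zero(self, null_features):
        fit = simple_effects(
            null_features, {"group": "PTSD"},
            ("prev_reward", "prev_transition", "condition"),
        )
        c = fit["prev_reward:prev_transition:condition"]
        assert abs(c["statistic"]) < 3

    def test_contrast_variable_must_vary(self, null_features):
        with pytest.raises(DesignError):
            simple_effects(
                null_features, {"condition": "light"},
                ("prev_reward", "condition"),
            )

    def test_gate_partitions_coefficients(self, null_features):
        fit = simple_effects(
            null_features, {}, ("prev_reward", "prev_transition")
        )
        gated = significance_gate(fit, alpha=0.05)
        rest = set(fit.names) - set(gated["term"])
        assert set(gated["term"]) | rest == set(fit.names)
        assert (gated["p"] < 0.05).all()
        assert len(significance_gate(fit, alpha=1.0)) == len(fit.names)
        assert significance_gate(fit, alpha=1e-300).empty
        # ordered by |statistic| descending
        s = gated["statistic"].abs().to_numpy()
        assert np.all(s[:-1] >= s[1:])


class TestAgeMatchTrim:
    def test_identical_distributions_need_no_trim(self):
        ages = pd.Series([25, 30, 35, 25, 30, 35],
                         index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["control"] * 3 + ["PTSD"] * 3, index=ages.index)
        retained, removed = age_match_trim(ages, groups)
        assert removed == 0 and len(retained) == 6

    def test_stepwise_oracle_on_constructed_example(self):
        control = {"C1": 25, "C2": 26, "C3": 27, "C4": 30, "C5": 31}
        ptsd = {"P1": 30, "P2": 31, "P3": 32, "P4": 44, "P5": 45}
        ages = pd.Series({**control, **ptsd}, dtype=float)
        groups = pd.Series(
            {**{k: "control" for k in control}, **{k: "PTSD" for k in ptsd}}
        )
        retained, removed = age_match_trim(ages, groups)

        # exhaustive oracle: recompute the Welch test after each paired removal
        c_sorted = sorted(control, key=lambda k: (control[k], k))
        p_sorted = sorted(ptsd, key=lambda k: (-ptsd[k], k))
        expected_removed = None
        for k in range(len(c_sorted)):
            c_kept = [control[x] for x in c_sorted[k:]]
            p_kept = [ptsd[x] for x in p_sorted[k:]]
            if len(c_kept) < 2 or len(p_kept) < 2:
                break
            p_val = stats.ttest_ind(c_kept, p_kept, equal_var=False).pvalue
            if p_val >= 0.05:
                expected_removed = k
                break
        assert expected_removed is not None
        assert removed == expected_removed
        expected_ids = sorted(c_sorted[removed:] + p_sorted[removed:])
        assert retained == expected_ids
        final_p = stats.ttest_ind(
            ages[retained][groups[retained] == "control"],
            ages[retained][groups[retained] == "PTSD"],
            equal_var=False,
        ).pvalue
        assert final_p >= 0.05

    def test_output_subset_and_equal_counts(self):
        rng = np.random.default_rng(2)
        ids = [f"S{i}" for i in range(40)]
        groups = pd.Series(["control"] * 20 + ["PTSD"] * 20, index=ids)
        ages = pd.Series(
            np.concatenate([rng.normal(28, 5, 20), rng.normal(40, 5, 20)]),
            index=ids,
        )
        retained, removed = age_match_trim(ages, groups)
        assert set(retained) <= set(ids)
        kept = groups[retained].value_counts()
        assert kept["control"] == 20 - removed and kept["PTSD"] == 20 - removed

    def test_exhaustion_raises(self):
        ages = pd.Series([20.0, 21.0, 22.0, 60.0, 61.0, 62.0],
                         index=list("abcdef"))
        groups = pd.Series(["control"] * 3 + ["PTSD"] * 3, index=ages.index)
        with pytest.raises(ValueError):
            age_match_trim(ages, groups)


class TestOmnibusChecks:
    def test_empty_design_cell_reported(self):
        truth = {"intercept": 0.5}
        f = simulate_stay_features(truth, n_subjects=8, seed=3)
        f["group"] = "control"  # no PTSD anywhere
        f["condition"] = "light"
        f["delay"] = "short"
        f["visit"] = 1
        f["site"] = "UW"
        f["age"] = 30.0
        f["iq"] = 110.0
        with pytest.raises(DesignError, match="cells"):
            omnibus_model(f)
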