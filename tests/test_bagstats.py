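import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dynbag.bagstats import (
    AssociationSpec,
    SingularDesignError,
    bh_fdr,
    build_design,
    compute_bag,
    fit_association,
    run_suite,
)
from dynbag.partition import NETWORK_ORDER
from dynbag.synthcohort import CohortSpec, generate_phenotypes


def _bag_frame(pheno, bag_values, modality="sfnc", scope="wide"):
    return pd.DataFrame({
        "subject_id": pheno["id"],
        "modality": modality,
        "scope": scope,
        "predicted_age": pheno["age"] + bag_values,
        "chronological_age": pheno["age"],
        "bag": bag_values,
    })


class TestComputeBag:
    def test_definition(self, assoc_pheno):
        preds = pd.Series(assoc_pheno["age"].to_numpy() + 3.0,
                          index=assoc_pheno["id"])
        bags = compute_bag(preds, assoc_pheno, "sfnc", "wide")
        np.testing.assert_allclose(bags["bag"], 3.0)
        np.testing.assert_allclose(
            bags["bag"], bags["predicted_age"] - bags["chronological_age"]
        )

    def test_null_predictions_give_zero_bags(self, assoc_pheno):
        preds = pd.Series(assoc_pheno["age"].to_numpy(), index=assoc_pheno["id"])
        bags = compute_bag(preds, assoc_pheno, "dfnc", "wide")
        np.testing.assert_array_equal(bags["bag"], 0.0)

    def test_unbiased_predictor_gives_mean_bag_near_zero(self):
        spec = CohortSpec(n_subjects=500, prop_patients=0.0, seed=21)
        pheno = generate_phenotypes(spec)
        rng = np.random.default_rng(22)
        noise = rng.normal(0, 3.0, len(pheno))
        preds = pd.Series(pheno["age"].to_numpy() + noise, index=pheno["id"])
        bags = compute_bag(preds, pheno, "sfnc", "wide")
        se = bags["bag"].std() / np.sqrt(len(bags))
        assert abs(bags["bag"].mean()) < 3 * se

    def test_missing_prediction_rejected(self, assoc_pheno):
        preds = pd.Series(50.0, index=assoc_pheno["id"][:-1])
        with pytest.raises(ValueError, match="missing predictions"):
            compute_bag(preds, assoc_pheno, "sfnc", "wide")


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.032])[0] == pytest.approx(0.032)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_matches_bruteforce_step_up(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=15)
        # independent brute-force: adj(i) = min over p(j) >= p(i) of p(j)*m/rank(j)
        m = len(p)
        order = np.argsort(p)
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        oracle = np.array([
            min(min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]), 1.0)
            for i in range(m)
        ])
        np.testing.assert_allclose(bh_fdr(p), oracle, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(24)
        p = rng.uniform(size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_never_decreases_and_order_invariant(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_fdr(np.asarray(p)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFitAssociation:
    def test_matches_normal_equations_oracle_on_hand_design(self):
        # 12 fixed rows with both sexes, two sites, both diagnoses
        pheno = pd.DataFrame({
            "id": [f"S{k}" for k in range(12)],
            "age": [40, 45, 50, 55, 60, 65, 42, 47, 52, 57, 62, 67],
            "sex": ["M", "F"] * 6,
            "site": ["siteA"] * 6 + ["siteB"] * 6,
            "dx": ["HC", "HC", "SZ", "SZ"] * 3,
            "attention": [50.1, 48.2, 51.0, 47.5, 49.9, 46.8,
                          50.5, 47.9, 51.2, 48.8, 49.1, 47.2],
            "working_memory": [50.0] * 12,
        })
        bag = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 2.0,
                        0.0, 1.5, -0.5, 2.5, -2.5, 1.0])
        bags = _bag_frame(pheno, bag)
        res = fit_association(bags, pheno, AssociationSpec(min_age=0.0),
                              ("sfnc", "wide"), "attention")
        # independent normal-equations solve
        df = bags.merge(pheno, left_on="subject_id", right_on="id")
        x = build_design(df).to_numpy()
        y = df["attention"].to_numpy()
        beta_hat = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta_hat
        dof = len(y) - x.shape[1]
        cov = resid @ resid / dof * np.linalg.inv(x.T @ x)
        k = 1  # bag column
        assert res.beta == pytest.approx(beta_hat[k], abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(cov[k, k]), abs=1e-8)
        assert res.ci_low == pytest.approx(res.beta - 1.96 * res.se, abs=1e-10)
        t = beta_hat[k] / np.sqrt(cov[k, k])
        assert res.r == pytest.approx(t / np.sqrt(t * t + dof), abs=1e-10)

    def test_exact_linear_signal_recovered(self, assoc_pheno):
        rng = np.random.default_rng(25)
        bag = rng.normal(0, 2, len(assoc_pheno))
        pheno = assoc_pheno.copy()
        # outcome exactly 2*bag plus covariate contributions, zero residual
        pheno["attention"] = (2.0 * bag + 0.1 * pheno["age"]
                              + 0.5 * (pheno["sex"] == "M"))
        bags = _bag_frame(pheno, bag)
        res = fit_association(bags, pheno, AssociationSpec(),
                              ("sfnc", "wide"), "attention")
        assert res.beta == pytest.approx(2.0, abs=1e-8)
        assert res.se < 1e-8

    def test_coverage_of_injected_gamma_across_seeds(self):
        hits = 0
        for seed in range(50):
            spec = CohortSpec(n_subjects=400, gamma_attention=-0.5, seed=seed)
            pheno = generate_phenotypes(spec)
            # oracle predictor: predicted age = age + latent acceleration
            bags = _bag_frame(pheno, pheno["true_bag"].to_numpy())
            res = fit_association(bags, pheno, AssociationSpec(),
                                  ("sfnc", "wide"), "attention")
            if abs(res.beta - (-0.5)) <= 1.96 * res.se:
                hits += 1
        assert hits >= 45  # 90% of 50

    def test_singular_design_names_collinear_columns(self, assoc_pheno):
        pheno = assoc_pheno.copy()
        pheno["sex"] = "M"  # constant indicator collides with the intercept
        bags = _bag_frame(pheno, np.random.default_rng(26).normal(size=len(pheno)))
        with pytest.raises(SingularDesignError, match="sex_M"):
            fit_association(bags, pheno, AssociationSpec(),
                            ("sfnc", "wide"), "attention")

    def test_age_filter_is_strict(self):
        rng = np.random.default_rng(27)
        n = 60
        pheno = pd.DataFrame({
            "id": [f"S{k}" for k in range(n)],
            "age": np.concatenate([np.full(10, 38.0), rng.uniform(39, 80, n - 10)]),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "site": np.where(rng.random(n) < 0.5, "siteA", "siteB"),
            "dx": np.where(rng.random(n) < 0.5, "SZ", "HC"),
            "attention": rng.normal(50, 1, n),
            "working_memory": rng.normal(50, 1, n),
        })
        bags = _bag_frame(pheno, rng.normal(size=n))
        res = fit_association(bags, pheno, AssociationSpec(min_age=38.0),
                              ("sfnc", "wide"), "attention")
        assert res.n == n - 10  # subjects at exactly 38 are excluded

    def test_covariate_set_is_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            AssociationSpec(covariates=("age", "sex"))


class TestRunSuite:
    @pytest.fixture()
    def full_bags(self, assoc_pheno):
        rng = np.random.default_rng(28)
        frames = []
        for modality in ("sfnc", "dfnc"):
            for scope in ("wide",) + NETWORK_ORDER:
                frames.append(_bag_frame(assoc_pheno,
                                         rng.normal(size=len(assoc_pheno)),
                                         modality, scope))
        return pd.concat(frames, ignore_index=True)

    def test_family_sizes(self, full_bags, assoc_pheno):
        table = run_suite(full_bags, assoc_pheno)
        for outcome in ("attention", "working_memory"):
            sub = table[table.outcome == outcome]
            assert (sub.family == "subnetwork").sum() == 14
            assert (sub.family == "wide").sum() == 2

    def test_fdr_never_below_raw(self, full_bags, assoc_pheno):
        table = run_suite(full_bags, assoc_pheno)
        assert np.all(table["p_fdr"] >= table["p_raw"] - 1e-15)

    def test_fdr_corrected_within_family(self, full_bags, assoc_pheno):
        table = run_suite(full_bags, assoc_pheno)
        sub = table[(table.outcome == "attention") & (table.family == "subnetwork")]
        np.testing.assert_allclose(sub["p_fdr"], bh_fdr(sub["p_raw"].to_numpy()),
                                   atol=1e-12)

    def test_empty_bag_table_rejected(self, assoc_pheno):
        with pytest.raises(ValueError, match="empty"):
            run_suite(pd.DataFrame(), assoc_pheno)

    def test_missing_combination_listed(self, full_bags, assoc_pheno):
        bags = full_bags[~((full_bags.modality == "dfnc")
                           & (full_bags.scope == "DMN"))]
        with pytest.raises(ValueError, match="DMN"):
            run_suite(bags, assoc_pheno)
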