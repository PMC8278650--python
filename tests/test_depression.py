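import numpy as np
import pandas as pd
import pytest

from inbreedage import (DepressionModel, ModelSpec, Pedigree,
                        VarianceComponents, build_a_inverse, fit_fixed,
                        fit_mixed, relationship_matrix, significance,
                        standardize)
from inbreedage.depression import _build_design

from conftest import random_general_pedigree


def pheno_frame(rng, n, ped=None):
    if ped is None:
        animals = [f"a{i}" for i in range(n)]
        dams = [None] * n
    else:
        nonf = [ped.ids[i] for i in range(ped.n_animals)
                if ped.sire[i] >= 0 and ped.dam[i] >= 0]
        animals = list(rng.choice(nonf, n))
        dams = [ped.ids[ped.dam[ped.index[a]]] for a in animals]
    return pd.DataFrame({
        "animal_id": animals, "dam_id": dams,
        "sex": rng.choice(["M", "F"], n),
        "birth_year": rng.choice([2001, 2002, 2003], n),
        "f_new": rng.random(n), "f_old": rng.random(n),
        "trait": rng.normal(100, 10, n)})


class TestStandardize:
    def test_simple_triplet(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(5, 3, 500))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([2.0, 2.0, 2.0])

    def test_slope_identity_on_standardized_covariate(self):
        # beta on z-scored x equals raw beta times sd(x)
        rng = np.random.default_rng(1)
        x = rng.random(200)
        y = 3.0 - 2.0 * x + rng.normal(0, 0.1, 200)
        braw = np.polyfit(x, y, 1)[0]
        bstd = np.polyfit(standardize(x), y, 1)[0]
        assert bstd == pytest.approx(braw * x.std(ddof=1), rel=1e-10)


class TestFitFixed:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(2)
        df = pheno_frame(rng, 80)
        z_new, z_old = standardize(df.f_new), standardize(df.f_old)
        df["trait"] = 50 + 2 * (df.sex == "M") - 3 * z_new + 1 * z_old
        spec = ModelSpec("trait", ("sex",), ("f_new", "f_old"))
        fit = fit_fixed(spec, df)
        assert fit.criteria["rmse"] == pytest.approx(0.0, abs=1e-9)
        assert fit.beta("f_new") == pytest.approx(-3.0)
        assert fit.beta("f_old") == pytest.approx(1.0)

    def test_intercept_only_criteria_closed_form(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, 60)
        df = pd.DataFrame({"animal_id": range(60), "y": y,
                           "c1": rng.random(60), "c2": rng.random(60)})
        spec = ModelSpec("y", fixed_terms=(), inbreeding_covariates=("c1", "c2"))
        fit = fit_fixed(spec, df)
        n, k = 60, 3
        X = np.column_stack([np.ones(60), standardize(df.c1), standardize(df.c2)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = ((y - X @ beta) ** 2).sum()
        ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.criteria["aic"] == pytest.approx(-2 * ll + 2 * (k + 1))
        assert fit.criteria["bic"] == pytest.approx(-2 * ll + (k + 1) * np.log(n))
        assert fit.criteria["rmse"] == pytest.approx(np.sqrt(rss / n))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        df = pheno_frame(rng, 120)
        spec = ModelSpec("trait", ("sex", "birth_year"), ("f_new", "f_old"))
        fit = fit_fixed(spec, df)
        X, y, _ = _build_design(spec, df)
        Xm = X.to_numpy()
        XtXi = np.linalg.inv(Xm.T @ Xm)
        beta = XtXi @ Xm.T @ y
        resid = y - Xm @ beta
        s2 = resid @ resid / (len(y) - Xm.shape[1])
        assert np.allclose(fit.coefficients["beta"], beta, atol=1e-10)
        assert np.allclose(fit.coefficients["se"], np.sqrt(s2 * np.diag(XtXi)),
                           atol=1e-10)

    def test_aic_bic_differ_by_p_logn_minus_2(self):
        rng = np.random.default_rng(5)
        df = pheno_frame(rng, 90)
        spec = ModelSpec("trait", ("sex",), ("f_new", "f_old"))
        fit = fit_fixed(spec, df)
        n = fit.n_obs
        p = 4 + 1  # intercept, sex dummy, two covariates, residual variance
        assert fit.criteria["bic"] - fit.criteria["aic"] == \
            pytest.approx(p * (np.log(n) - 2))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(6)
        df = pheno_frame(rng, 50)
        df["f_old"] = 2.0 * df["f_new"]  # perfectly collinear after z-scoring
        spec = ModelSpec("trait", ("sex",), ("f_new", "f_old"))
        with pytest.raises(ValueError, match="collinear.*f_"):
            fit_fixed(spec, df)


class TestSignificance:
    @pytest.mark.parametrize("beta,se,expected", [
        (1.0, 0.6, False), (-3.0, 1.0, True), (2.0, 1.0, False)])
    def test_t_rule(self, beta, se, expected):
        fit = fit_fixed(
            ModelSpec("y", (), ("c1", "c2")),
            pd.DataFrame({"y": np.random.default_rng(0).normal(size=30),
                          "c1": np.random.default_rng(1).random(30),
                          "c2": np.random.default_rng(2).random(30)}))
        fit.coefficients.loc["c1", "t_stat"] = beta / se
        assert significance(fit)["c1"] is expected


class TestAInverse:
    def test_unrelated_founders_identity(self):
        ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(6)])
        Ainv = build_a_inverse(ped).toarray()
        assert np.allclose(Ainv, np.eye(6))

    def test_product_with_tabular_a_is_identity(self):
        ped = random_general_pedigree(8, n=40)
        A = relationship_matrix(ped)
        Ainv = build_a_inverse(ped).toarray()
        assert np.abs(A @ Ainv - np.eye(len(A))).max() < 1e-8

    def test_sire_offspring_closed_form(self):
        # one known parent: Mendelian variance 3/4, alpha = 4/3
        ped = Pedigree.from_records([("S", None, None), ("X", "S", None)])
        Ainv = build_a_inverse(ped).toarray()
        a = 4.0 / 3.0
        want = np.array([[1 + a / 4, -a / 2], [-a / 2, a]])
        assert np.allclose(Ainv, want)

    def test_id_not_in_pedigree(self, trio_ped):
        with pytest.raises(KeyError):
            build_a_inverse(trio_ped, ids=["A", "B", "Z"])


@pytest.fixture(scope="module")
def ped():
    return random_general_pedigree(12, n=80, founder_prob=0.25,
                                   missing_prob=0.0)


class TestFitMixed:

    def test_vanishing_genetic_variance_reduces_to_ols(self, ped):
        rng = np.random.default_rng(7)
        df = pheno_frame(rng, 50, ped)
        vc = VarianceComponents(sigma2_u=1e-8, sigma2_e=50.0)
        mixed = fit_mixed(ModelSpec("trait", ("sex",), ("f_new", "f_old"),
                                    ("direct",), vc), df, ped)
        ols = fit_fixed(ModelSpec("trait", ("sex",), ("f_new", "f_old")), df)
        assert np.allclose(mixed.coefficients["beta"], ols.coefficients["beta"],
                           atol=1e-6)

    def test_matches_dense_gls_oracle(self, ped):
        rng = np.random.default_rng(8)
        df = pheno_frame(rng, 45, ped)
        vc = VarianceComponents(sigma2_u=30, sigma2_m=8, sigma2_p=5, sigma2_e=60)
        spec = ModelSpec("trait", ("sex", "birth_year"), ("f_new", "f_old"),
                         ("direct", "maternal_genetic", "maternal_pe"), vc)
        fit = fit_mixed(spec, df, ped)

        X, y, rows = _build_design(spec, df)
        A = relationship_matrix(ped)
        n = len(y)
        Z = np.zeros((n, ped.n_animals))
        W = np.zeros((n, ped.n_animals))
        dams = sorted(rows["dam_id"].unique())
        S = np.zeros((n, len(dams)))
        for r, (a, d) in enumerate(zip(rows["animal_id"], rows["dam_id"])):
            Z[r, ped.index[a]] = 1
            W[r, ped.index[d]] = 1
            S[r, dams.index(d)] = 1
        V = Z @ A @ Z.T * 30 + W @ A @ W.T * 8 + S @ S.T * 5 + np.eye(n) * 60
        Vi = np.linalg.inv(V)
        Xm = X.to_numpy()
        C = np.linalg.inv(Xm.T @ Vi @ Xm)
        beta = C @ Xm.T @ Vi @ y
        assert np.allclose(fit.coefficients["beta"], beta, atol=1e-6)
        assert np.allclose(fit.coefficients["se"], np.sqrt(np.diag(C)), atol=1e-6)

    def test_missing_dam_rejected(self, ped):
        rng = np.random.default_rng(9)
        df = pheno_frame(rng, 30, ped)
        df.loc[df.index[0], "dam_id"] = None
        vc = VarianceComponents(sigma2_u=10, sigma2_m=5, sigma2_e=50)
        with pytest.raises(ValueError, match="dam"):
            fit_mixed(ModelSpec("trait", ("sex",), ("f_new", "f_old"),
                                ("direct", "maternal_genetic"), vc), df, ped)


class TestEstimatorFacade:
    def test_fit_sets_attributes_and_params_roundtrip(self):
        rng = np.random.default_rng(10)
        df = pheno_frame(rng, 60)
        m = DepressionModel(trait="trait", fixed_terms=("sex",))
        assert m.get_params()["trait"] == "trait"
        m.fit(df)
        assert set(m.significant_) == set(m.coefficients_.index)
        m2 = m.set_params(fixed_terms=("sex", "birth_year")).fit(df)
        assert any(c.startswith("birth_year") for c in m2.coefficients_.index)

    def test_random_terms_require_pedigree(self):
        rng = np.random.default_rng(11)
        df = pheno_frame(rng, 30)
        m = DepressionModel(random_terms=("direct",),
                            variance_components=VarianceComponents(
                                sigma2_u=1, sigma2_e=1))
        with pytest.raises(ValueError, match="pedigree"):
            m.fit(df)
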