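"""Inbreeding-depression regression: fixed-effects and pedigree mixed models.

The depression model regresses a growth trait on standardized new and old
inbreeding covariates plus systematic effects::

    y = Xb + Zu + Wm + Sp + e

with u ~ N(0, A sigma2_u) the direct genetic effects, m ~ N(0, A sigma2_m)
the maternal genetic effects, p ~ N(0, I sigma2_p) the maternal permanent
environment (maternal terms for early-growth traits only), and A the
numerator relationship matrix.  Fixed effects are sex, birth year (factor),
an age covariate where relevant, and the two inbreeding regressions.

New and old inbreeding are always fitted jointly, z-scored within the
analysed records, so coefficients are trait units per covariate SD and
directly comparable across thresholds.  A coefficient is called significant
when |beta/SE| > 2 (no multiple-testing adjustment).

Variance components are configuration inputs, not estimated here.  The mixed
model is solved by Henderson's mixed-model equations with A-inverse built by
Henderson's rules including inbreeding.  For model comparison across
classification methods, fixed-effects-only fits report Adj.R2,
RMSE = sqrt(RSS/n), and Gaussian-likelihood AIC/BIC counting the residual
variance as a parameter (p = k + 1, the R stats convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .pedigree import UNKNOWN, Pedigree, inbreeding_coefficients


@dataclass
class VarianceComponents:
    sigma2_u: float = 0.0
    sigma2_m: float = 0.0
    sigma_um: float = 0.0
    sigma2_p: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self):
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        for nm in ("sigma2_u", "sigma2_m", "sigma2_p"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


@dataclass
class ModelSpec:
    """Specification of one trait/threshold depression model."""

    trait: str
    fixed_terms: tuple = ("sex", "birth_year")
    inbreeding_covariates: tuple = ("f_new", "f_old")
    random_terms: tuple = ()          # subset of direct/maternal_genetic/maternal_pe
    variance_components: VarianceComponents = field(default_factory=VarianceComponents)

    def __post_init__(self):
        bad = set(self.random_terms) - {"direct", "maternal_genetic", "maternal_pe"}
        if bad:
            raise ValueError(f"unknown random terms {bad}")
        if len(set(self.inbreeding_covariates)) != len(self.inbreeding_covariates):
            raise ValueError("covariate labels must be unique")


@dataclass
class DepressionFit:
    """Coefficients (label -> beta, se, t_stat) and fit summaries."""

    coefficients: pd.DataFrame      # index label, columns beta/se/t_stat
    n_obs: int
    rss: float | None = None
    loglik: float | None = None
    criteria: dict | None = None    # adj_r2, rmse, aic, bic (fixed-only)
    method: str = "fixed"

    def beta(self, label):
        return float(self.coefficients.loc[label, "beta"])

    def se(self, label):
        return float(self.coefficients.loc[label, "se"])


def standardize(values) -> np.ndarray:
    """(x - mean)/sd with the n-1 sample standard deviation."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[~np.isnan(x)])) < 2:
        raise ValueError("covariate is constant; cannot standardize")
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def significance(fit: DepressionFit, threshold: float = 2.0) -> dict:
    """label -> True when |beta/SE| strictly exceeds the threshold."""
    t = fit.coefficients["t_stat"]
    return {lab: bool(abs(v) > threshold) for lab, v in t.items()}


# ---------------------------------------------------------------------------
# Design matrix


def _build_design(model: ModelSpec, data: pd.DataFrame):
    needed = [model.trait, *model.inbreeding_covariates]
    needed += [t for t in model.fixed_terms if t in data.columns]
    rows = data.dropna(subset=[c for c in needed if c in data.columns]).copy()
    if rows.empty:
        raise ValueError("no complete records for this model")

    parts = [pd.Series(1.0, index=rows.index, name="intercept")]
    for term in model.fixed_terms:
        if term not in data.columns:
            raise ValueError(f"fixed term {term!r} not in data")
        if term in ("sex", "birth_year"):
            dummies = pd.get_dummies(rows[term].astype(str), prefix=term,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(rows[term].astype(float))
    for lab in model.inbreeding_covariates:
        parts.append(pd.Series(standardize(rows[lab]), index=rows.index, name=lab))
    X = pd.concat(parts, axis=1)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name offending columns via pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [X.columns[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-8 * diag[0]] + list(X.columns[piv[len(diag):]])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    y = rows[model.trait].astype(float).to_numpy()
    return X, y, rows


# ---------------------------------------------------------------------------
# Fixed-effects model


def fit_fixed(model: ModelSpec, data: pd.DataFrame) -> DepressionFit:
    """Ordinary least squares with the comparison criteria of the module docstring."""
    X, y, _ = _build_design(model, data)
    res = sm.OLS(y, X.to_numpy()).fit()
    n, k = X.shape
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    if rss > 0:
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    else:
        loglik = np.inf
    p = k + 1
    criteria = {
        "adj_r2": adj_r2,
        "rmse": float(np.sqrt(rss / n)),
        "aic": float(-2 * loglik + 2 * p),
        "bic": float(-2 * loglik + p * np.log(n)),
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        coefs = pd.DataFrame({
            "beta": res.params, "se": res.bse,
            "t_stat": res.params / res.bse,
        }, index=X.columns)
    return DepressionFit(coefs, n_obs=n, rss=rss, loglik=float(loglik),
                         criteria=criteria, method="fixed")


# ---------------------------------------------------------------------------
# Pedigree mixed model


def build_a_inverse(ped: Pedigree, ids=None) -> sp.csr_matrix:
    """Inverse numerator relationship matrix by Henderson's rules with inbreeding.

    ``ids`` may reorder the pedigree's animals; every id must be in the
    pedigree and the matrix covers all of them.
    """
    if ids is None:
        ids = list(ped.ids)
    pos = {}
    for r, a in enumerate(ids):
        if a not in ped.index:
            raise KeyError(f"id {a!r} not in pedigree")
        pos[ped.index[a]] = r
    if len(pos) != ped.n_animals:
        raise ValueError("ids must cover every pedigree animal exactly once")

    F = inbreeding_coefficients(ped).to_numpy()
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(ped.n_animals):
        s, d = ped.sire[i], ped.dam[i]
        known = [p for p in (s, d) if p != UNKNOWN]
        dvar = 1.0 - 0.25 * sum(1.0 + F[p] for p in known)
        alpha = 1.0 / dvar
        ii = pos[i]
        add(ii, ii, alpha)
        for p in known:
            add(ii, pos[p], -alpha / 2)
            add(pos[p], ii, -alpha / 2)
        for p in known:
            for q in known:
                add(pos[p], pos[q], alpha / 4)
    n = ped.n_animals
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _incidence(levels, values):
    """Sparse 0/1 matrix mapping records to levels (list), by value."""
    lookup = {v: j for j, v in enumerate(levels)}
    rows = np.arange(len(values))
    cols = np.array([lookup[v] for v in values])
    return sp.coo_matrix((np.ones(len(values)), (rows, cols)),
                         shape=(len(values), len(levels))).tocsr()


def fit_mixed(model: ModelSpec, data: pd.DataFrame, ped: Pedigree) -> DepressionFit:
    """Solve Henderson's mixed-model equations for the spec'd random structure.

    Fixed-effect standard errors come from the fixed block of the inverse
    coefficient matrix times sigma2_e.  With no random terms this is plain OLS.
    """
    if not model.random_terms:
        return fit_fixed(model, data)
    vc = model.variance_components
    X, y, rows = _build_design(model, data)
    Xs = sp.csr_matrix(X.to_numpy())
    n, k = X.shape

    needs_dam = {"maternal_genetic", "maternal_pe"} & set(model.random_terms)
    if needs_dam:
        if "dam_id" not in rows.columns or rows["dam_id"].isna().any():
            raise ValueError("maternal random terms require a dam_id for every record")
        missing = [d for d in rows["dam_id"] if d not in ped.index]
        if missing:
            raise ValueError(f"dam(s) not in pedigree: {missing[:5]}")

    blocks = [Xs]
    penalties = []  # (slice offset handled later) list of sparse penalty blocks
    q = ped.n_animals
    genetic_terms = [t for t in ("direct", "maternal_genetic")
                     if t in model.random_terms]
    Ainv = build_a_inverse(ped) if genetic_terms else None

    if "direct" in model.random_terms:
        if vc.sigma2_u <= 0:
            raise ValueError("direct random term requires sigma2_u > 0")
        blocks.append(_incidence(list(ped.ids), rows["animal_id"]))
    if "maternal_genetic" in model.random_terms:
        if vc.sigma2_m <= 0:
            raise ValueError("maternal_genetic requires sigma2_m > 0")
        blocks.append(_incidence(list(ped.ids), rows["dam_id"]))
    if "maternal_pe" in model.random_terms:
        if vc.sigma2_p <= 0:
            raise ValueError("maternal_pe requires sigma2_p > 0")
        dams = sorted(rows["dam_id"].unique())
        blocks.append(_incidence(dams, rows["dam_id"]))

    # genetic penalty: sigma2_e * Ginv kron Ainv over the genetic blocks
    if genetic_terms:
        if len(genetic_terms) == 2:
            G = np.array([[vc.sigma2_u, vc.sigma_um],
                          [vc.sigma_um, vc.sigma2_m]])
        elif genetic_terms == ["direct"]:
            G = np.array([[vc.sigma2_u]])
        else:
            G = np.array([[vc.sigma2_m]])
        Ginv = np.linalg.inv(G) * vc.sigma2_e
        penalties.append(sp.kron(sp.csr_matrix(Ginv), Ainv, format="csr"))
    if "maternal_pe" in model.random_terms:
        lam_p = vc.sigma2_e / vc.sigma2_p
        penalties.append(sp.identity(blocks[-1].shape[1], format="csr") * lam_p)

    W = sp.hstack(blocks, format="csr")
    penalty = sp.block_diag([sp.csr_matrix((k, k))] + penalties, format="csc")
    C = (W.T @ W).tocsc() + penalty
    rhs = W.T @ y
    try:
        lu = spla.splu(C)
    except RuntimeError as exc:  # pragma: no cover - singularity reporting
        raise ValueError(f"mixed-model coefficient matrix is singular: {exc}")
    sol = lu.solve(rhs)

    # covariance of fixed effects: sigma2_e * (C^-1)[0:k, 0:k]
    cov = np.empty((k, k))
    eye = np.zeros(C.shape[0])
    for j in range(k):
        eye[j] = 1.0
        cov[:, j] = lu.solve(eye)[:k]
        eye[j] = 0.0
    se = np.sqrt(np.maximum(np.diag(cov), 0) * vc.sigma2_e)

    beta = sol[:k]
    with np.errstate(invalid="ignore", divide="ignore"):
        coefs = pd.DataFrame({"beta": beta, "se": se, "t_stat": beta / se},
                             index=X.columns)
    resid = y - W @ sol
    return DepressionFit(coefs, n_obs=n, rss=float(resid @ resid),
                         loglik=None, criteria=None, method="mixed")


# ---------------------------------------------------------------------------
# Estimator facade


class DepressionModel(BaseEstimator):
    """sklearn-style wrapper: fit(data[, pedigree]) -> coefficients_.

    Parameters mirror ModelSpec; ``random_terms`` empty gives the OLS model
    with comparison criteria, otherwise the pedigree BLUP mixed model.
    """

    def __init__(self, trait="trait", fixed_terms=("sex", "birth_year"),
                 inbreeding_covariates=("f_new", "f_old"), random_terms=(),
                 variance_components=None):
        self.trait = trait
        self.fixed_terms = fixed_terms
        self.inbreeding_covariates = inbreeding_covariates
        self.random_terms = random_terms
        self.variance_components = variance_components

    def _spec(self):
        return ModelSpec(
            trait=self.trait,
            fixed_terms=tuple(self.fixed_terms),
            inbreeding_covariates=tuple(self.inbreeding_covariates),
            random_terms=tuple(self.random_terms),
            variance_components=self.variance_components or VarianceComponents(),
        )

    def fit(self, data: pd.DataFrame, pedigree: Pedigree | None = None):
        spec = self._spec()
        if spec.random_terms:
            if pedigree is None:
                raise ValueError("random terms require a pedigree")
            result = fit_mixed(spec, data, pedigree)
        else:
            result = fit_fixed(spec, data)
        self.result_ = result
        self.coefficients_ = result.coefficients
        self.criteria_ = result.criteria
        self.significant_ = significance(result)
        return self

    def predict(self, data: pd.DataFrame):  # fixed-effect mean prediction
        spec = self._spec()
        X, _, _ = _build_design(spec, data)
        return X.to_numpy() @ self.coefficients_["beta"].to_numpy()
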