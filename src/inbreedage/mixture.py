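"""Two-component Gaussian mixture classification of ROH segment lengths.

A model-based alternative to a fixed length threshold: ROH lengths are
assumed to come from a "short" (old inbreeding) and a "long" (recent
inbreeding) class.  The mixture is fitted on log10(length in Mb) because raw
segment lengths are heavily right-skewed; the short/long boundary is the
length at which posterior membership of the two components is equal, solved
in closed form on the log scale and reported in Mb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .roh import ROHSet, partition_roh_inbreeding


class MixtureError(RuntimeError):
    pass


class ROHLengthMixture(BaseEstimator):
    """Seeded EM fit of a 2-component unequal-variance Gaussian mixture.

    Parameters
    ----------
    n_init : int
        Number of seeded restarts (quantile-based means with jitter); the fit
        with the best log-likelihood is kept, making the result deterministic
        for a given ``random_state``.
    tol : float
        Absolute log-likelihood convergence tolerance.
    var_floor : float
        Lower bound on component variances; hitting it repeatedly raises
        ``MixtureError`` (degenerate fit, typically too few segments).

    Fitted attributes (components sorted by mean, short first):
    ``weights_``, ``means_``, ``variances_`` (log10-Mb scale),
    ``boundary_mb_``, ``loglik_``, ``loglik_path_``, ``n_iter_``.
    """

    def __init__(self, n_init: int = 5, max_iter: int = 500, tol: float = 1e-8,
                 var_floor: float = 1e-6, random_state: int = 0):
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    # -- EM core ---------------------------------------------------------

    @staticmethod
    def _log_gauss(x, mean, var):
        return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)

    def _em(self, x, means0):
        n = len(x)
        w = np.array([0.5, 0.5])
        means = means0.copy()
        var = np.array([np.var(x), np.var(x)]) / 2 + self.var_floor
        path = []
        for it in range(1, self.max_iter + 1):
            logp = np.log(w)[:, None] + self._log_gauss(x[None, :], means[:, None],
                                                        var[:, None])
            mx = logp.max(axis=0)
            lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
            ll = float(lse.sum())
            resp = np.exp(logp - lse)
            nk = resp.sum(axis=1)
            if np.any(nk < 1e-10):
                raise MixtureError("a mixture component collapsed to zero weight")
            w = nk / n
            means = resp @ x / nk
            var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
            if np.any(var < self.var_floor):
                raise MixtureError(
                    "variance collapse during EM; more segments are needed")
            path.append(ll)
            if len(path) > 1 and abs(path[-1] - path[-2]) < self.tol:
                break
        return w, means, var, path

    def fit(self, lengths_mb, y=None):
        lengths_mb = np.asarray(lengths_mb, dtype=float)
        if len(lengths_mb) < 10:
            raise ValueError("need at least 10 segment lengths")
        if np.any(lengths_mb <= 0):
            raise ValueError("lengths must be positive")
        x = np.log10(lengths_mb)
        rng = np.random.default_rng(self.random_state)
        q25, q75 = np.quantile(x, [0.25, 0.75])
        spread = max(q75 - q25, 1e-3)

        best = None
        for k in range(self.n_init):
            jitter = rng.normal(0, 0.1 * spread, size=2) if k else np.zeros(2)
            means0 = np.array([q25, q75]) + jitter
            try:
                w, means, var, path = self._em(x, means0)
            except MixtureError:
                continue
            if best is None or path[-1] > best[3][-1]:
                best = (w, means, var, path)
        if best is None:
            raise MixtureError("EM degenerate for every start; more data needed")
        w, means, var, path = best

        order = np.argsort(means)
        self.weights_, self.means_, self.variances_ = w[order], means[order], var[order]
        self.loglik_path_ = np.array(path)
        self.loglik_ = float(path[-1])
        self.n_iter_ = len(path)
        self.boundary_mb_ = self._posterior_boundary()
        return self

    def _posterior_boundary(self) -> float:
        """Length (Mb) where the two components' posteriors are both 0.5.

        Solves w1 N(x; m1, v1) = w2 N(x; m2, v2) on the log10 scale — a
        quadratic in x — and keeps the root between the two means.
        """
        (m1, m2), (v1, v2), (w1, w2) = self.means_, self.variances_, self.weights_
        a = 0.5 * (1 / v1 - 1 / v2)
        b = m2 / v2 - m1 / v1
        c = (0.5 * (m1 ** 2 / v1 - m2 ** 2 / v2)
             - np.log(w1 / w2) - 0.5 * np.log(v2 / v1))
        if abs(a) < 1e-12:
            roots = np.array([-c / b]) if abs(b) > 1e-12 else np.array([])
        else:
            disc = b ** 2 - 4 * a * c
            if disc < 0:
                roots = np.array([])
            else:
                roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
        inside = roots[(roots > m1) & (roots < m2)] if len(roots) else roots
        if len(inside) == 0:
            # components too entangled for a crossing between the means;
            # fall back to the midpoint (flagged by equal posteriors failing)
            x = 0.5 * (m1 + m2)
        else:
            x = float(inside[0])
        return float(10 ** x)


def fit_length_mixture(lengths_mb, seed: int = 0, **kwargs) -> ROHLengthMixture:
    """Fit the 2-component length mixture; thin wrapper over ROHLengthMixture."""
    return ROHLengthMixture(random_state=seed, **kwargs).fit(lengths_mb)


def partition_by_mixture(rohs: ROHSet, fit: ROHLengthMixture,
                         animals=None) -> pd.DataFrame:
    """Partition F_ROH at the mixture's posterior-0.5 boundary."""
    out = partition_roh_inbreeding(rohs, fit.boundary_mb_, animals=animals)
    out["method"] = "mixture"
    return out
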