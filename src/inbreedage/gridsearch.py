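"""Trait-driven grid search for the recent/ancient inbreeding threshold.

Rather than fixing the boundary between recent and ancient inbreeding by
convention (five generations, five megabases), the threshold is chosen from
the data under the purging assumption that recently arisen autozygosity is
more harmful than old autozygosity.  For every candidate threshold the trait
is regressed jointly on the standardized new and old inbreeding covariates;
scanning from the most recent boundary outwards (ascending generations t for
pedigree partitions, descending segment length m for ROH partitions), the
selected threshold is the first at which new inbreeding is at least as
detrimental as old (for a higher-is-better trait: beta_new <= beta_old, ties
included).  If the rule never fires the search reports no threshold.

Competing classification methods (fixed literature thresholds, Kalinowski
gene dropping, mixture clustering, the proposed threshold) are compared with
identical fixed-effects-only models differing solely in the two inbreeding
covariates, via Adj.R2, RMSE, AIC and BIC; an AIC difference above 2 is
treated as meaningful.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .depression import DepressionModel, VarianceComponents, fit_fixed, ModelSpec
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_T_GRID = tuple(range(3, 17))
DEFAULT_M_GRID = (3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0)

TRACE_COLUMNS = ["threshold", "beta_new", "se_new", "beta_old", "se_old",
                 "new_at_least_as_detrimental", "skipped", "flagged_low_info"]


class ThresholdGridSearch(BaseEstimator):
    """Scan candidate thresholds and select the trait-specific boundary.

    Parameters
    ----------
    trait, fixed_terms, random_terms, variance_components :
        Passed through to the depression model fitted at each threshold
        (mixed model by default when random terms are given).
    source : 'pedigree' or 'roh'
        Controls scan order: t ascending / m descending (most recent first).
    orientation : 'higher_is_better'
        For all supported traits a more detrimental effect is a more negative
        coefficient.
    flag_zero_fraction : float
        Thresholds where at least this fraction of animals have f_new == 0
        are still fitted but flagged as information-poor.

    Fitted attributes: ``trace_`` (per-threshold coefficients and rule
    evaluations), ``selected_threshold_`` (None when the rule never fires)
    and ``crossings_`` (every threshold where the rule holds).
    """

    def __init__(self, trait="trait", source="pedigree",
                 fixed_terms=("sex", "birth_year"), random_terms=(),
                 variance_components=None, orientation="higher_is_better",
                 flag_zero_fraction=0.5):
        self.trait = trait
        self.source = source
        self.fixed_terms = fixed_terms
        self.random_terms = random_terms
        self.variance_components = variance_components
        self.orientation = orientation
        self.flag_zero_fraction = flag_zero_fraction

    def fit(self, partitions_by_threshold: dict, data: pd.DataFrame,
            pedigree: Pedigree | None = None):
        if not partitions_by_threshold:
            raise ValueError("empty threshold grid")
        if self.orientation != "higher_is_better":
            raise ValueError("only higher_is_better traits are supported")
        thresholds = sorted(partitions_by_threshold,
                            reverse=(self.source == "roh"))
        rows = []
        for thr in thresholds:
            part = partitions_by_threshold[thr]
            merged = data.merge(
                part[["animal_id", "f_new", "f_old"]], on="animal_id", how="inner")
            model = DepressionModel(
                trait=self.trait, fixed_terms=self.fixed_terms,
                inbreeding_covariates=("f_new", "f_old"),
                random_terms=self.random_terms,
                variance_components=self.variance_components)
            zero_frac = float((part["f_new"] == 0).mean())
            try:
                model.fit(merged, pedigree)
            except ValueError as exc:
                logger.warning("threshold %s skipped: %s", thr, exc)
                rows.append((thr, np.nan, np.nan, np.nan, np.nan, False, True,
                             zero_frac >= self.flag_zero_fraction))
                continue
            fit = model.result_
            b_new, b_old = fit.beta("f_new"), fit.beta("f_old")
            # ties count as firing; tolerate floating noise in exact ties
            fired = bool(b_new <= b_old or np.isclose(b_new, b_old,
                                                      rtol=1e-9, atol=1e-12))
            rows.append((thr, b_new, fit.se("f_new"), b_old, fit.se("f_old"),
                         fired, False, zero_frac >= self.flag_zero_fraction))
        self.trace_ = pd.DataFrame(rows, columns=TRACE_COLUMNS)
        ok = self.trace_[~self.trace_["skipped"]]
        firing = ok.loc[ok["new_at_least_as_detrimental"], "threshold"]
        self.crossings_ = list(firing)
        self.selected_threshold_ = firing.iloc[0] if len(firing) else None
        if self.selected_threshold_ is None:
            logger.info("grid search: new inbreeding never at least as "
                        "detrimental as old on trait %s", self.trait)
        return self


def threshold_search(partitions_by_threshold, model: ModelSpec,
                     data: pd.DataFrame, ped: Pedigree | None = None,
                     source: str = "pedigree",
                     orientation: str = "higher_is_better") -> ThresholdGridSearch:
    """Functional wrapper over ThresholdGridSearch using a ModelSpec."""
    gs = ThresholdGridSearch(
        trait=model.trait, source=source, fixed_terms=model.fixed_terms,
        random_terms=model.random_terms,
        variance_components=model.variance_components, orientation=orientation)
    return gs.fit(partitions_by_threshold, data, ped)


def contribution_curve(partitions_by_threshold: dict) -> pd.DataFrame:
    """Population mean new inbreeding and its share of total per threshold."""
    rows = []
    for thr in sorted(partitions_by_threshold):
        part = partitions_by_threshold[thr]
        mean_new = float(part["f_new"].mean())
        mean_tot = float(part["f_total"].mean())
        rows.append((thr, mean_new, mean_tot,
                     mean_new / mean_tot if mean_tot > 0 else np.nan))
    return pd.DataFrame(rows, columns=["threshold", "mean_f_new", "mean_f_total",
                                       "contribution"])


def partition_correlation(a: pd.DataFrame, b: pd.DataFrame,
                          column: str = "f_new") -> float:
    """Pearson correlation of a partition column over the shared animals."""
    merged = a[["animal_id", column]].merge(
        b[["animal_id", column]], on="animal_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least 3 shared animals")
    xa = merged[f"{column}_a"].to_numpy()
    xb = merged[f"{column}_b"].to_numpy()
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        raise ValueError("zero variance in one of the partitions")
    return float(stats.pearsonr(xa, xb).statistic)


def compare_methods(methods: dict, model: ModelSpec,
                    data: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects-only model comparison across classification methods.

    All methods share the same systematic effects and differ only in the two
    standardized inbreeding covariates.  Returns per-method criteria plus
    aic_delta against the best method and the AIC-difference > 2 convention.
    """
    rows = []
    for label, part in methods.items():
        merged = data.merge(part[["animal_id", "f_new", "f_old"]],
                            on="animal_id", how="inner")
        spec = ModelSpec(trait=model.trait, fixed_terms=model.fixed_terms,
                         inbreeding_covariates=("f_new", "f_old"),
                         random_terms=(),
                         variance_components=model.variance_components
                         or VarianceComponents())
        fit = fit_fixed(spec, merged)
        rows.append({"method": label, "n_obs": fit.n_obs, **fit.criteria})
    out = pd.DataFrame(rows).set_index("method")
    out["aic_delta"] = out["aic"] - out["aic"].min()
    out["significant_delta"] = out["aic_delta"] > 2.0
    return out
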