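"""Gene dropping through a pedigree: total, new and ancestral inbreeding.

Kalinowski's decomposition splits classical inbreeding F into a component due
to alleles that are IBD for the first time (F_new) and a component due to
alleles that were already IBD in an ancestor and therefore exposed to
selection before (F_anc):  F = F_new + F_anc.

Both are estimated by single-locus gene dropping: every founder receives two
unique allele labels, each non-founder inherits one uniformly random allele
from each parent (in topological order), and an individual is autozygous when
its two labels match.  Exposure bookkeeping: whenever an individual is
autozygous, both of its allele copies acquire a sticky "exposed" flag that is
inherited with transmission; autozygosity involving an exposed copy counts as
ancestral, otherwise as new.  A Ballou-style ancestral inbreeding probability
(either parental allele ever exposed, regardless of autozygosity) is emitted
as an additional column.

``exact_drop_small`` enumerates every equally likely transmission pattern for
small pedigrees and serves as the exact oracle for the Monte Carlo estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

RESULT_COLUMNS = ["animal_id", "f_hat", "f_new_kal", "f_anc_kal", "f_anc_ballou",
                  "n_reps", "mc_se_f", "mc_se_new", "mc_se_anc"]


def _mc_se(p, n):
    return np.sqrt(np.clip(p * (1 - p), 0, None) / n)


def gene_drop(ped: Pedigree, n_reps: int = 100_000, seed: int = 0,
              chunk: int = 20_000) -> pd.DataFrame:
    """Monte Carlo gene dropping; deterministic given ``seed``.

    Returns one row per animal with f_hat (P(autozygous)), its Kalinowski
    partition, the Ballou ancestral probability, and binomial Monte-Carlo
    standard errors sqrt(p(1-p)/n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = ped.n_animals
    auto_ct = np.zeros(n)
    new_ct = np.zeros(n)
    anc_ct = np.zeros(n)
    ballou_ct = np.zeros(n)

    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        labels = np.empty((n, 2, r), dtype=np.int32)
        exposed = np.zeros((n, 2, r), dtype=bool)
        next_unique = 2 * n  # labels for unknown-parent sides
        for i in range(n):
            for side, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent == UNKNOWN:
                    labels[i, side] = next_unique
                    next_unique += 1
                else:
                    pick = rng.integers(0, 2, size=r)
                    cols = np.arange(r)
                    labels[i, side] = labels[parent, pick, cols]
                    exposed[i, side] = exposed[parent, pick, cols]
            auto = labels[i, 0] == labels[i, 1]
            prior = exposed[i, 0] | exposed[i, 1]
            auto_ct[i] += auto.sum()
            anc_ct[i] += (auto & prior).sum()
            new_ct[i] += (auto & ~prior).sum()
            ballou_ct[i] += prior.sum()
            exposed[i, 0] |= auto
            exposed[i, 1] |= auto
        done += r

    f = auto_ct / n_reps
    fn = new_ct / n_reps
    fa = anc_ct / n_reps
    return pd.DataFrame({
        "animal_id": ped.ids,
        "f_hat": f,
        "f_new_kal": fn,
        "f_anc_kal": fa,
        "f_anc_ballou": ballou_ct / n_reps,
        "n_reps": n_reps,
        "mc_se_f": _mc_se(f, n_reps),
        "mc_se_new": _mc_se(fn, n_reps),
        "mc_se_anc": _mc_se(fa, n_reps),
    })


def exact_drop_small(ped: Pedigree, max_bits: int = 22) -> pd.DataFrame:
    """Exact Kalinowski decomposition by exhausting all transmission patterns.

    Each known-parent transmission contributes one binary choice; pedigrees
    with more than ``max_bits`` such meioses are rejected.  mc_se columns are 0.
    """
    n = ped.n_animals
    meioses = [(i, side) for i in range(n)
               for side, p in enumerate((ped.sire[i], ped.dam[i])) if p != UNKNOWN]
    bits = len(meioses)
    if bits > max_bits:
        raise ValueError(
            f"pedigree has {bits} meioses; exact enumeration limited to {max_bits}")
    meiosis_of = {(i, side): k for k, (i, side) in enumerate(meioses)}

    auto_p = np.zeros(n)
    new_p = np.zeros(n)
    anc_p = np.zeros(n)
    ballou_p = np.zeros(n)
    n_pat = 2 ** bits
    chunk = min(n_pat, 1 << 16)
    for start in range(0, n_pat, chunk):
        patterns = np.arange(start, min(start + chunk, n_pat), dtype=np.int64)
        r = len(patterns)
        labels = np.empty((n, 2, r), dtype=np.int32)
        exposed = np.zeros((n, 2, r), dtype=bool)
        cols = np.arange(r)
        next_unique = 2 * n
        for i in range(n):
            for side, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent == UNKNOWN:
                    labels[i, side] = next_unique
                    next_unique += 1
                else:
                    pick = (patterns >> meiosis_of[(i, side)]) & 1
                    labels[i, side] = labels[parent, pick, cols]
                    exposed[i, side] = exposed[parent, pick, cols]
            auto = labels[i, 0] == labels[i, 1]
            prior = exposed[i, 0] | exposed[i, 1]
            auto_p[i] += auto.sum()
            anc_p[i] += (auto & prior).sum()
            new_p[i] += (auto & ~prior).sum()
            ballou_p[i] += prior.sum()
            exposed[i, 0] |= auto
            exposed[i, 1] |= auto
    for arr in (auto_p, new_p, anc_p, ballou_p):
        arr /= n_pat
    zeros = np.zeros(n)
    return pd.DataFrame({
        "animal_id": ped.ids,
        "f_hat": auto_p,
        "f_new_kal": new_p,
        "f_anc_kal": anc_p,
        "f_anc_ballou": ballou_p,
        "n_reps": n_pat,
        "mc_se_f": zeros,
        "mc_se_new": zeros,
        "mc_se_anc": zeros,
    })
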