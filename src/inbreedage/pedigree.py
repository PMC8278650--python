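"""Pedigree data model, completeness statistics, and inbreeding coefficients.

The central quantity is Wright's inbreeding coefficient F: the probability
that the two alleles an animal carries at a locus are identical by descent
(IBD) from a common ancestor of its parents.  F equals the kinship
(coancestry) coefficient between sire and dam.

Recent ("new") inbreeding is isolated with a changing-base-generation
truncation: the pedigree of a focal animal is cut ``t`` generations above it
(every ancestor at minimum depth ``t`` has its parents set to unknown) and F
is recomputed on that subset.  Inbreeding then partitions additively::

    F_ped = F_new_t + F_old_t,   F_new_t = F_ped_t,   F_old_t = F_ped - F_ped_t

Truncation removes ancestral paths, so F_new_t is non-decreasing in t and
F_old_t is always non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = -1
_DEFAULT_UNKNOWN_CODES = ("0", "NA", ".", "")


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Acyclic parent map over animals, stored in topological order.

    Attributes
    ----------
    ids : list of str
        Animal identifiers, parents always before offspring.
    sire, dam : int arrays
        Index of the parent in ``ids`` or ``UNKNOWN`` (-1).
    sex : object array of 'M', 'F' or 'U'.
    birth_year : float array (NaN when missing).
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n_animals(self):
        return len(self.ids)

    def is_founder(self, i: int) -> bool:
        return self.sire[i] == UNKNOWN and self.dam[i] == UNKNOWN

    @classmethod
    def from_records(cls, records, strict: bool = False) -> "Pedigree":
        """Build a validated pedigree from (animal, sire, dam[, sex, year]) tuples.

        Unknown parents are ``None``.  Parents referenced but never defined are
        auto-added as founders with a warning (error in strict mode).  Raises
        ``PedigreeError`` on duplicate ids or cycles (naming one animal on the
        cycle).
        """
        rows = []
        for rec in records:
            rec = tuple(rec)
            animal, sire, dam = rec[0], rec[1], rec[2]
            sex = rec[3] if len(rec) > 3 else "U"
            year = rec[4] if len(rec) > 4 else None
            rows.append((animal, sire, dam, sex, year))

        seen = set()
        for animal, *_ in rows:
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            seen.add(animal)

        dangling = []
        for _, sire, dam, _, _ in rows:
            for p in (sire, dam):
                if p is not None and p not in seen:
                    seen.add(p)
                    dangling.append(p)
        if dangling:
            if strict:
                raise PedigreeError(
                    f"parents referenced but never defined: {dangling[:5]}"
                )
            logger.warning(
                "%d parent(s) referenced but never defined; added as founders "
                "(first: %r)", len(dangling), dangling[0]
            )
            rows = [(p, None, None, "U", None) for p in dangling] + rows

        parents = {a: (s, d) for a, s, d, _, _ in rows}
        meta = {a: (sex, year) for a, _, _, sex, year in rows}

        # Kahn topological sort on parent -> offspring edges; leftover = cycle.
        children = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        order = [a for a in parents if indeg[a] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) < len(parents):
            cyclic = next(a for a in parents if indeg[a] > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {cyclic!r}")

        index = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        sex = np.empty(n, dtype=object)
        year = np.full(n, np.nan)
        for a, i in index.items():
            s, d = parents[a]
            sire[i] = index[s] if s is not None else UNKNOWN
            dam[i] = index[d] if d is not None else UNKNOWN
            sx, yr = meta[a]
            sex[i] = sx if sx in ("M", "F") else "U"
            if yr is not None:
                try:
                    year[i] = float(yr)
                except (TypeError, ValueError):
                    pass
        return cls(order, sire, dam, sex, year, index)

    # -- generational structure ------------------------------------------------

    def generation_numbers(self) -> np.ndarray:
        """g(i) = 0 for founders, 1 + max(g(parents)) otherwise (== MaxGen)."""
        g = np.zeros(self.n_animals, dtype=np.int64)
        for i in range(self.n_animals):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    g[i] = max(g[i], g[p] + 1)
        return g

    def is_generational(self) -> bool:
        """True when the pedigree has strict discrete generations.

        Every non-founder must have both parents known and both in the
        immediately preceding generation.  This structure allows the fast
        cohort-wise kinship recursion used for truncated inbreeding.
        """
        g = self.generation_numbers()
        for i in range(self.n_animals):
            s, d = self.sire[i], self.dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                continue
            if s == UNKNOWN or d == UNKNOWN:
                return False
            if g[s] != g[i] - 1 or g[d] != g[i] - 1:
                return False
        return True


# ---------------------------------------------------------------------------
# IO


def read_pedigree(path, unknown_codes=_DEFAULT_UNKNOWN_CODES,
                  strict: bool = False) -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam[, sex, birth_year]).

    Comma or whitespace delimited; a header row is detected if the first
    field is a recognisable column name.  Unknown parents coded per
    ``unknown_codes`` (default "0", "NA", ".").
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    records = []
    for lineno, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in (line.split(",") if "," in line else line.split())]
        if lineno == 0 and fields[0].lower() in ("animal", "id", "animal_id", "iid"):
            continue
        if len(fields) < 3:
            raise PedigreeError(f"line {lineno + 1}: expected >= 3 columns")
        animal, sire, dam = fields[0], fields[1], fields[2]
        sire = None if sire in unknown_codes else sire
        dam = None if dam in unknown_codes else dam
        sex = fields[3].upper()[:1] if len(fields) > 3 else "U"
        year = fields[4] if len(fields) > 4 else None
        records.append((animal, sire, dam, sex, year))
    return Pedigree.from_records(records, strict=strict)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame({
        "animal": ped.ids,
        "sire": [ped.ids[s] if s != UNKNOWN else "0" for s in ped.sire],
        "dam": [ped.ids[d] if d != UNKNOWN else "0" for d in ped.dam],
        "sex": ped.sex,
        "birth_year": ["" if np.isnan(y) else int(y) for y in ped.birth_year],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pedigree-quality statistics


def pedigree_stats(ped: Pedigree) -> pd.DataFrame:
    """Per-animal MaxGen and ECG (equivalent complete generations).

    MaxGen is the longest ancestor chain to a founder.  ECG is the sum of
    (1/2)^n over all ancestor paths, computed with the recursion
    ecg(i) = 0.5*(1 + ecg(sire)) + 0.5*(1 + ecg(dam)), terms dropped for
    unknown parents; founders have ECG 0.
    """
    n = ped.n_animals
    max_gen = ped.generation_numbers()
    ecg = np.zeros(n)
    for i in range(n):
        v = 0.0
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                v += 0.5 * (1.0 + ecg[p])
        ecg[i] = v
    return pd.DataFrame({"animal_id": ped.ids, "max_gen": max_gen, "ecg": ecg})


# ---------------------------------------------------------------------------
# Inbreeding coefficients


def _pair_kinship_ml(ped: Pedigree, F: np.ndarray, a: int, b: int) -> float:
    """Kinship(a, b) via genetic-contribution (L) vectors: A = L D L'.

    a(a,b) = sum_j L_aj * L_bj * D_j with D_j the Mendelian-sampling variance
    of ancestor j (uses F of j's parents, already available in topological
    order); kinship = a(a,b)/2.
    """
    if a == UNKNOWN or b == UNKNOWN:
        return 0.0

    def contributions(x):
        # upward accumulation young -> old; parents always have a smaller
        # topological index, so a max-first sweep of pending keys is valid
        pending = {x: 1.0}
        out = {}
        while pending:
            j = max(pending)
            out[j] = pending.pop(j)
            for p in (ped.sire[j], ped.dam[j]):
                if p != UNKNOWN:
                    pending[p] = pending.get(p, 0.0) + 0.5 * out[j]
        return out

    La = contributions(a)
    Lb = contributions(b)
    if len(Lb) < len(La):
        La, Lb = Lb, La
    total = 0.0
    for j, la in La.items():
        lb = Lb.get(j)
        if lb:
            total += la * lb * _mendelian_variance(ped, F, j)
    return 0.5 * total


def _mendelian_variance(ped: Pedigree, F: np.ndarray, j: int) -> float:
    s, d = ped.sire[j], ped.dam[j]
    if s != UNKNOWN and d != UNKNOWN:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s != UNKNOWN:
        return 0.75 - 0.25 * F[s]
    if d != UNKNOWN:
        return 0.75 - 0.25 * F[d]
    return 1.0


def _inbreeding_general(ped: Pedigree) -> np.ndarray:
    """Meuwissen-Luo-style O(N * ancestors) inbreeding for arbitrary pedigrees."""
    n = ped.n_animals
    F = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
        else:
            F[i] = _pair_kinship_ml(ped, F, s, d)
    return F


def _cohort_kinship_f(ped: Pedigree, cut: int, g: np.ndarray) -> np.ndarray:
    """F for all animals of a generational pedigree with founders reset at
    generation ``cut`` (animals at generation <= cut treated as unrelated,
    non-inbred).  Vectorized cohort-by-cohort kinship recursion."""
    n = ped.n_animals
    F = np.zeros(n)
    gmax = int(g.max()) if n else 0
    cohorts = [np.flatnonzero(g == k) for k in range(gmax + 1)]
    prev = cohorts[cut] if cut <= gmax else np.array([], dtype=int)
    K_prev = 0.5 * np.eye(len(prev))
    pos_prev = {int(a): i for i, a in enumerate(prev)}
    for k in range(cut + 1, gmax + 1):
        cur = cohorts[k]
        if len(cur) == 0:
            break
        si = np.array([pos_prev[int(ped.sire[a])] for a in cur])
        di = np.array([pos_prev[int(ped.dam[a])] for a in cur])
        F[cur] = K_prev[si, di]
        K = 0.25 * (K_prev[np.ix_(si, si)] + K_prev[np.ix_(si, di)]
                    + K_prev[np.ix_(di, si)] + K_prev[np.ix_(di, di)])
        np.fill_diagonal(K, 0.5 * (1.0 + K_prev[si, di]))
        K_prev, pos_prev = K, {int(a): i for i, a in enumerate(cur)}
    return F


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """F_ped for every animal (kinship of its parents; 0 if a parent is unknown).

    Uses the vectorized cohort recursion on strictly generational pedigrees and
    a Meuwissen-Luo-style recursion otherwise.
    """
    if ped.n_animals and ped.is_generational():
        F = _cohort_kinship_f(ped, 0, ped.generation_numbers())
    else:
        F = _inbreeding_general(ped)
    return pd.Series(F, index=pd.Index(ped.ids, name="animal_id"), name="f_ped")


def kinship(ped: Pedigree, a, b) -> float:
    """Kinship (coancestry) coefficient between two animals."""
    F = _inbreeding_general(ped)
    ia, ib = ped.index[a], ped.index[b]
    if ia == ib:
        return 0.5 * (1.0 + F[ia])
    return _pair_kinship_ml(ped, F, ia, ib)


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended for modest pedigrees and as an
    independent check of the recursive algorithms (diag(A) - 1 = F).
    """
    n = ped.n_animals
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for j in range(i):
            v = 0.0
            if s != UNKNOWN:
                v += 0.5 * A[j, s]
            if d != UNKNOWN:
                v += 0.5 * A[j, d]
            A[j, i] = A[i, j] = v
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


# ---------------------------------------------------------------------------
# Changing-base-generation truncation


def _truncated_subpedigree(ped: Pedigree, focal: int, t: int):
    """Ancestors of ``focal`` within minimum depth <= t; parents are cut for
    animals whose minimum depth equals t.  Returns (members, sire, dam) with
    indices into the original pedigree."""
    depth = {focal: 0}
    frontier = [focal]
    for d in range(1, t + 1):
        nxt = []
        for x in frontier:
            for p in (ped.sire[x], ped.dam[x]):
                if p != UNKNOWN and p not in depth:
                    depth[p] = d
                    nxt.append(p)
        frontier = nxt
    members = sorted(depth)  # topological: original order preserved
    sire, dam = {}, {}
    for x in members:
        if depth[x] >= t:
            sire[x] = dam[x] = UNKNOWN
        else:
            s, d = ped.sire[x], ped.dam[x]
            sire[x] = s if (s != UNKNOWN and s in depth) else UNKNOWN
            dam[x] = d if (d != UNKNOWN and d in depth) else UNKNOWN
    return members, sire, dam


def truncated_inbreeding(ped: Pedigree, focal, t: int) -> float:
    """F of ``focal`` on the pedigree truncated ``t`` generations above it.

    Equals full F_ped when t >= MaxGen(focal); see module docstring for the
    partition this induces.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if focal not in ped.index:
        raise KeyError(f"unknown animal id {focal!r}")
    fi = ped.index[focal]
    members, sire, dam = _truncated_subpedigree(ped, fi, t)
    sub = Pedigree(
        ids=[ped.ids[m] for m in members],
        sire=np.array([members.index(sire[m]) if sire[m] != UNKNOWN else UNKNOWN
                       for m in members], dtype=np.int64),
        dam=np.array([members.index(dam[m]) if dam[m] != UNKNOWN else UNKNOWN
                      for m in members], dtype=np.int64),
        sex=np.array(["U"] * len(members), dtype=object),
        birth_year=np.full(len(members), np.nan),
    )
    F = _inbreeding_general(sub)
    return float(F[sub.index[focal]])


def partition_pedigree_inbreeding(ped: Pedigree, t: int,
                                  animals=None) -> pd.DataFrame:
    """Partition F_ped into new (within t generations) and old components.

    Returns a DataFrame with columns animal_id, f_total, f_new, f_old,
    method ('pedigree_t'), threshold (t).  Animals with an unknown parent have
    F fixed at 0 and are flagged in the ``incomplete`` column.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    f_total = inbreeding_coefficients(ped)
    if animals is None:
        animals = list(ped.ids)
    idx = np.array([ped.index[a] for a in animals])

    if ped.n_animals and ped.is_generational():
        g = ped.generation_numbers()
        f_new = np.empty(len(idx))
        cache = {}
        for pos, i in enumerate(idx):
            cut = max(int(g[i]) - t, 0)
            if cut not in cache:
                cache[cut] = _cohort_kinship_f(ped, cut, g)
            f_new[pos] = cache[cut][i]
    else:
        f_new = np.array([truncated_inbreeding(ped, ped.ids[i], t) for i in idx])

    ft = f_total.to_numpy()[idx]
    incomplete = np.array([(ped.sire[i] == UNKNOWN) != (ped.dam[i] == UNKNOWN)
                           for i in idx])
    return pd.DataFrame({
        "animal_id": animals,
        "f_total": ft,
        "f_new": f_new,
        "f_old": ft - f_new,
        "method": "pedigree_t",
        "threshold": float(t),
        "incomplete": incomplete,
    })
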