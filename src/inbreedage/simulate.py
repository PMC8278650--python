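"""Synthetic closed-herd generator: pedigree, genomes, true IBD, phenotypes.

The generator emulates a small closed line-bred herd: discrete generations,
a limited sire pool, and a configurable rate of deliberately consanguineous
matings (full sibs, half sibs, cousins).  Genomes are produced by linked gene
dropping: founder chromosomes carry unique haplotype labels, meioses place
crossovers by a Poisson process at 1 cM/Mb (Haldane model, no interference),
and every transmitted chromosome chunk is a node in a "copy tree" whose
parent is the chunk it was copied from.  An individual is autozygous over an
interval when its two haplotypes carry the same founder label there; the age
of that autozygosity is read off the copy tree as g = (k1 + k2) / 2, where
k1 and k2 are the meiosis counts from the individual up to the most recent
common copy (in a discrete-generation pedigree k1 = k2, so g is the integer
generation distance to the common ancestor).  The expected length of an
age-g segment is 1/(2g) Morgan.

SNP genotypes are read off the haplotype mosaics at evenly spaced markers
whose founder-allele frequencies are drawn from a truncated Beta, so chance
(non-IBD) homozygosity exists and short-ROH false positives are possible, as
in real medium-density panels.

Phenotypes follow the depression model's own generative form: fixed sex,
birth-year and age effects, pedigree-structured direct (and optionally
maternal) genetic effects built by Mendelian-sampling recursion, and
depression coefficients applied to the standardized new/old inbreeding of a
caller-supplied "truth" partition, with recent inbreeding more harmful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, inbreeding_coefficients

TRACK_COLUMNS = ["animal_id", "chromosome", "start_bp", "end_bp",
                 "coalescence_generation"]


class ExtinctionError(RuntimeError):
    pass


@dataclass
class TraitConfig:
    """Generative trait model; betas are trait units per covariate SD."""

    name: str = "trait"
    mu: float = 200.0
    phenotypic_sd: float = 30.0
    h2_direct: float = 0.35
    h2_maternal: float = 0.0
    pe_maternal: float = 0.0
    sex_effect: float = 7.5           # added for males
    year_sd: float = 3.0              # SD of random birth-year effects
    age_mean: float = 180.0
    age_sd: float = 6.0
    age_slope: float = 0.3            # trait units per day
    t_star: int = 6
    beta_new_sd: float = -0.8         # trait SD per SD of new inbreeding
    beta_old_sd: float = -0.2
    residual_sd_value: float | None = None  # overrides the h2 budget when set

    def residual_sd(self) -> float:
        if self.residual_sd_value is not None:
            return self.residual_sd_value
        frac = 1.0 - self.h2_direct - self.h2_maternal - self.pe_maternal
        if frac < 0:
            raise ValueError("variance fractions exceed 1")
        return self.phenotypic_sd * np.sqrt(frac)


@dataclass
class SimConfig:
    """Closed-herd study conditions.

    The default herd mimics a small line-bred population managed to avoid
    close matings: a limited sire pool drives steady drift inbreeding whose
    loops coalesce over a range of generation depths, occasional deliberate
    consanguineous matings add recent loops, and mates sharing an ancestor
    within ``avoidance_depth`` generations are otherwise avoided.
    """

    n_founders: int = 80
    n_generations: int = 12
    n_matings: int = 200
    offspring_per_mating: int = 2
    n_sires: int = 40
    consanguinity_rate: float = 0.35
    avoidance_depth: int = 4
    # shared-ancestor depth of deliberate consanguineous matings: depth j
    # (generations above the mates) creates inbreeding loops of age j + 1
    # in the offspring; depth 1 = half/full sibs, 2 = first cousins, ...
    consang_weights: dict = field(default_factory=lambda: {4: 0.5, 5: 0.5})
    n_chromosomes: int = 29
    chrom_length_mb: float = 100.0
    marker_spacing_kb: float = 80.0
    mb_per_morgan: float = 100.0
    maf_beta: tuple = (2.0, 2.0)
    maf_min: float = 0.05
    n_phenotype_generations: int = 5
    trait: TraitConfig = field(default_factory=TraitConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.consanguinity_rate <= 1:
            raise ValueError("consanguinity_rate must be in [0,1]")
        if self.trait.t_star >= self.n_generations:
            raise ValueError("t_star must be below n_generations")
        if self.marker_spacing_kb <= 0 or self.chrom_length_mb <= 0:
            raise ValueError("spacing and chromosome length must be positive")


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg_seed, stream)))


# ---------------------------------------------------------------------------
# Pedigree


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation closed herd with a consanguineous-mating mixture."""
    rng = _rng(cfg.seed, 0)
    records = []
    parents = {}
    males, females = [], []
    for i in range(cfg.n_founders):
        aid = f"G00A{i:04d}"
        sex = "M" if i % 2 == 0 else "F"
        records.append((aid, None, None, sex, 0))
        parents[aid] = (None, None)
        (males if sex == "M" else females).append(aid)

    categories = [int(c) for c in cfg.consang_weights]
    weights = np.array([cfg.consang_weights[c] for c in cfg.consang_weights],
                       dtype=float)
    weights /= weights.sum()

    # ancestor sets by exact depth for mate choice/avoidance
    depth_k = max([cfg.avoidance_depth, 1, *categories])
    anc_by_depth = {a: [set()] * depth_k for a, _ in parents.items()}

    def register(aid, sire, dam):
        levels = [{sire, dam}]
        for j in range(1, depth_k):
            levels.append(anc_by_depth[sire][j - 1] | anc_by_depth[dam][j - 1])
        anc_by_depth[aid] = levels

    def shared_depth(a, b):
        """Generation depth of the closest common ancestor, capped at K+1."""
        for j in range(depth_k):
            if anc_by_depth[a][j] & anc_by_depth[b][j]:
                return j + 1
        return depth_k + 1

    for g in range(1, cfg.n_generations + 1):
        if not males or not females:
            raise ExtinctionError(
                "no eligible mates; increase the founder pool or litter size")
        sires_pool = list(rng.choice(males, size=min(cfg.n_sires, len(males)),
                                     replace=False))
        new_males, new_females = [], []
        counter = 0
        for _ in range(cfg.n_matings):
            dam = str(rng.choice(females))
            sire = None
            if rng.random() < cfg.consanguinity_rate:
                j = categories[int(rng.choice(len(categories), p=weights))]
                cands = [m for m in males if shared_depth(m, dam) == j]
                if cands:
                    sire = str(rng.choice(cands))
            if sire is None:
                if cfg.avoidance_depth > 0:
                    depths = np.array([shared_depth(m, dam) for m in sires_pool])
                    if depths.max() <= cfg.avoidance_depth:
                        # no sufficiently unrelated sire in the pool: the herd
                        # manager brings in any sufficiently distant male
                        distant = [m for m in males
                                   if shared_depth(m, dam) > cfg.avoidance_depth]
                        if distant:
                            sire = str(rng.choice(distant))
                    if sire is None:
                        best = np.flatnonzero(depths == depths.max())
                        sire = str(sires_pool[int(rng.choice(best))])
                else:
                    sire = str(rng.choice(sires_pool))
            for _ in range(cfg.offspring_per_mating):
                aid = f"G{g:02d}A{counter:04d}"
                counter += 1
                sex = "M" if rng.random() < 0.5 else "F"
                records.append((aid, sire, dam, sex, g))
                parents[aid] = (sire, dam)
                register(aid, sire, dam)
                (new_males if sex == "M" else new_females).append(aid)
        males, females = new_males, new_females
    return Pedigree.from_records(records)


# ---------------------------------------------------------------------------
# Linked gene dropping


class _CopyTree:
    """Ancestry of transmitted chromosome chunks (one node per transmission)."""

    __slots__ = ("parent", "founder", "depth", "n_roots")

    def __init__(self):
        self.parent = []
        self.founder = []   # contiguous root (founder haplotype) label
        self.depth = []
        self.n_roots = 0

    def new_root(self) -> int:
        cid = len(self.parent)
        self.parent.append(-1)
        self.founder.append(self.n_roots)
        self.depth.append(0)
        self.n_roots += 1
        return cid

    def child(self, source: int) -> int:
        cid = len(self.parent)
        self.parent.append(source)
        self.founder.append(self.founder[source])
        self.depth.append(self.depth[source] + 1)
        return cid

    def coalescence(self, c1: int, c2: int):
        """(k1, k2) meiosis counts from each copy to their common copy, or None."""
        if self.founder[c1] != self.founder[c2]:
            return None
        d1, d2 = self.depth[c1], self.depth[c2]
        k1 = k2 = 0
        while c1 != c2:
            if self.depth[c1] >= self.depth[c2]:
                c1 = self.parent[c1]
                k1 += 1
            else:
                c2 = self.parent[c2]
                k2 += 1
        return k1, k2


def _meiosis(hap_a, hap_b, length_bp, morgans, rng, tree):
    """One gamete: recombine two parental haplotypes (lists of (start, copy))."""
    n_x = rng.poisson(morgans)
    cuts = np.sort(rng.integers(1, length_bp, size=n_x)) if n_x else np.array([], int)
    phase = int(rng.integers(0, 2))
    sources = (hap_a, hap_b)
    bounds = [0] + [int(c) for c in cuts] + [length_bp]
    out = []
    for bi in range(len(bounds) - 1):
        a, b = bounds[bi], bounds[bi + 1]
        if a == b:
            phase ^= 1
            continue
        src = sources[phase]
        # pieces of src overlapping [a, b)
        for si, (s, cid) in enumerate(src):
            e = src[si + 1][0] if si + 1 < len(src) else length_bp
            if e <= a or s >= b:
                continue
            out.append((max(s, a), tree.child(cid)))
        phase ^= 1
    return out


def simulate_genomes(ped: Pedigree, cfg: SimConfig, samples=None,
                     with_genotypes: bool = True):
    """Drop linked genomes through the pedigree.

    Returns ``(GenotypeDataset, tracks)`` where tracks is a DataFrame of true
    autozygous segments (animal_id, chromosome, start_bp, end_bp,
    coalescence_generation) for the requested samples (default: all animals).
    With ``with_genotypes=False`` the dataset is None (tracks only); the same
    seed still yields identical tracks.
    """
    from .roh import GenotypeDataset

    rng = _rng(cfg.seed, 1)
    if samples is None:
        samples = list(ped.ids)
    sample_set = set(samples)
    length_bp = int(cfg.chrom_length_mb * 1e6)
    morgans = cfg.chrom_length_mb / cfg.mb_per_morgan
    spacing = cfg.marker_spacing_kb * 1e3
    marker_pos = np.arange(spacing / 2, length_bp, spacing).astype(np.int64)
    n_mark = len(marker_pos)
    n_haps = 2 * sum(1 for i in range(ped.n_animals) if ped.is_founder(i))

    marker_frames, call_blocks, track_rows = [], [], []
    sample_rows = {s: i for i, s in enumerate(samples)}

    for chrom in range(1, cfg.n_chromosomes + 1):
        tree = _CopyTree()
        haps = [None] * ped.n_animals
        founder_hap_ids = {}
        for i in range(ped.n_animals):
            if ped.is_founder(i):
                c0, c1 = tree.new_root(), tree.new_root()
                haps[i] = ([(0, c0)], [(0, c1)])
            else:
                gametes = []
                for parent in (ped.sire[i], ped.dam[i]):
                    if parent == UNKNOWN:
                        gametes.append([(0, tree.new_root())])
                    else:
                        pa, pb = haps[parent]
                        gametes.append(_meiosis(pa, pb, length_bp, morgans,
                                                rng, tree))
                haps[i] = tuple(gametes)

        if with_genotypes:
            # founder allele draws for this chromosome
            maf = rng.beta(*cfg.maf_beta, size=n_mark)
            maf = np.clip(maf, cfg.maf_min, 1 - cfg.maf_min)
            founder_alleles = (rng.random((tree.n_roots, n_mark)) < maf).astype(np.int8)
            calls = np.empty((len(samples), n_mark), dtype=np.int8)
        for sid in samples:
            i = ped.index[sid]
            if with_genotypes:
                dose = np.zeros(n_mark, dtype=np.int8)
                for side in (0, 1):
                    hap = haps[i][side]
                    for si, (s, cid) in enumerate(hap):
                        e = hap[si + 1][0] if si + 1 < len(hap) else length_bp
                        lo = np.searchsorted(marker_pos, s, side="left")
                        hi = np.searchsorted(marker_pos, e, side="left")
                        dose[lo:hi] += founder_alleles[tree.founder[cid], lo:hi]
                calls[sample_rows[sid]] = dose
            track_rows.extend(_ibd_segments(sid, chrom, haps[i], length_bp, tree))
        if with_genotypes:
            call_blocks.append(calls)
            marker_frames.append(pd.DataFrame({
                "marker_id": [f"chr{chrom}_m{j}" for j in range(n_mark)],
                "chromosome": chrom,
                "position_bp": marker_pos,
            }))

    tracks = pd.DataFrame(track_rows, columns=TRACK_COLUMNS)
    if not with_genotypes:
        return None, tracks
    markers = pd.concat(marker_frames, ignore_index=True)
    data = GenotypeDataset(list(samples), markers,
                           np.concatenate(call_blocks, axis=1))
    return data, tracks


def _ibd_segments(sid, chrom, hap_pair, length_bp, tree):
    """Intersect the two haplotypes; emit constant-age autozygous intervals."""
    h0, h1 = hap_pair
    bounds = sorted({0, length_bp} | {s for s, _ in h0} | {s for s, _ in h1})

    def copy_at(hap, x):
        lo, hi = 0, len(hap) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if hap[mid][0] <= x:
                lo = mid
            else:
                hi = mid - 1
        return hap[lo][1]

    out = []
    prev = None
    for bi in range(len(bounds) - 1):
        a, b = bounds[bi], bounds[bi + 1]
        if a >= b:
            continue
        c0, c1 = copy_at(h0, a), copy_at(h1, a)
        coal = tree.coalescence(c0, c1)
        if coal is None:
            prev = None
            continue
        g = (coal[0] + coal[1]) / 2.0
        # One tract continues across an ancestral mosaic boundary: such a
        # boundary was inherited by BOTH descent copies, so both copy ids
        # change at the same position and the age is unchanged.  A crossover
        # in one of the loop meioses changes only one side and ends the tract
        # (even if same-age IBD resumes through a different loop).
        if (out and prev is not None and out[-1][1] == a and out[-1][2] == g
                and c0 != prev[0] and c1 != prev[1]):
            out[-1] = (out[-1][0], b, g)
        else:
            out.append((a, b, g))
        prev = (c0, c1)
    return [(sid, chrom, s, e, g) for s, e, g in out]


def true_autozygosity(tracks: pd.DataFrame, l_auto_bp: int,
                      animals) -> pd.Series:
    lengths = (tracks["end_bp"] - tracks["start_bp"]).groupby(
        tracks["animal_id"]).sum()
    return lengths.reindex(animals).fillna(0.0) / l_auto_bp


def true_partition(tracks: pd.DataFrame, t_star: float, l_auto_bp: int,
                   animals=None) -> pd.DataFrame:
    """Ground-truth partition: segments with age <= t_star are new."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    if animals is None:
        animals = sorted(tracks["animal_id"].unique())
    lens = tracks["end_bp"] - tracks["start_bp"]
    new_mask = tracks["coalescence_generation"] <= t_star
    f_new = lens[new_mask].groupby(tracks.loc[new_mask, "animal_id"]).sum()
    f_tot = lens.groupby(tracks["animal_id"]).sum()
    f_new = f_new.reindex(animals).fillna(0.0).to_numpy() / l_auto_bp
    f_tot = f_tot.reindex(animals).fillna(0.0).to_numpy() / l_auto_bp
    return pd.DataFrame({
        "animal_id": list(animals),
        "f_total": f_tot,
        "f_new": f_new,
        "f_old": f_tot - f_new,
        "method": "true_ibd",
        "threshold": float(t_star),
    })


# ---------------------------------------------------------------------------
# Phenotypes


def _z_or_zero(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(ped: Pedigree, truth: pd.DataFrame,
                        cfg: SimConfig) -> pd.DataFrame:
    """Phenotypes for the animals of ``truth`` (see module docstring).

    Depression betas act on the z-scored f_new/f_old of the truth partition;
    a constant component contributes nothing (its effect is absorbed by the
    intercept).  Deterministic given cfg.seed.
    """
    rng = _rng(cfg.seed, 2)
    tc = cfg.trait
    F = inbreeding_coefficients(ped).to_numpy()
    s2 = tc.phenotypic_sd ** 2

    def genetic_effects(sigma2):
        u = np.zeros(ped.n_animals)
        for i in range(ped.n_animals):
            s, d = ped.sire[i], ped.dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                mean = 0.5 * (u[s] + u[d])
                var = sigma2 * (0.5 - 0.25 * (F[s] + F[d]))
            elif s != UNKNOWN or d != UNKNOWN:
                p = s if s != UNKNOWN else d
                mean = 0.5 * u[p]
                var = sigma2 * (0.75 - 0.25 * F[p])
            else:
                mean, var = 0.0, sigma2
            u[i] = mean + rng.normal(0, np.sqrt(var))
        return u

    u = genetic_effects(tc.h2_direct * s2) if tc.h2_direct > 0 else np.zeros(ped.n_animals)
    m = genetic_effects(tc.h2_maternal * s2) if tc.h2_maternal > 0 else np.zeros(ped.n_animals)

    idx = np.array([ped.index[a] for a in truth["animal_id"]])
    dam_idx = ped.dam[idx]
    if tc.h2_maternal > 0 or tc.pe_maternal > 0:
        if np.any(dam_idx == UNKNOWN):
            raise ValueError("maternal effects require known dams")
    pe = {}
    if tc.pe_maternal > 0:
        for d in np.unique(dam_idx):
            pe[d] = rng.normal(0, np.sqrt(tc.pe_maternal * s2))

    years = ped.birth_year[idx]
    year_levels = np.unique(years[~np.isnan(years)])
    year_eff = {y: rng.normal(0, tc.year_sd) for y in year_levels}

    z_new = _z_or_zero(truth["f_new"].to_numpy(dtype=float))
    z_old = _z_or_zero(truth["f_old"].to_numpy(dtype=float))
    sex = np.array([ped.sex[i] for i in idx])
    age = rng.normal(tc.age_mean, tc.age_sd, size=len(idx))

    y = (tc.mu
         + tc.sex_effect * (sex == "M")
         + np.array([year_eff.get(v, 0.0) for v in years])
         + tc.age_slope * (age - tc.age_mean)
         + tc.beta_new_sd * tc.phenotypic_sd * z_new
         + tc.beta_old_sd * tc.phenotypic_sd * z_old
         + u[idx]
         + (m[dam_idx] if tc.h2_maternal > 0 else 0.0)
         + np.array([pe.get(d, 0.0) for d in dam_idx])
         + rng.normal(0, tc.residual_sd(), size=len(idx)))

    return pd.DataFrame({
        "animal_id": truth["animal_id"].to_numpy(),
        "dam_id": [ped.ids[d] if d != UNKNOWN else None for d in dam_idx],
        "sex": sex,
        "birth_year": years,
        "age": age,
        tc.name: y,
    })


def phenotyped_animals(ped: Pedigree, cfg: SimConfig) -> list:
    """Animals of the last ``n_phenotype_generations`` generations."""
    g = ped.generation_numbers()
    gmax = g.max()
    keep = g > gmax - cfg.n_phenotype_generations
    return [ped.ids[i] for i in np.flatnonzero(keep)]
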