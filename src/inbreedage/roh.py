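"""Genotype data model, ROH detection, F_ROH and its length partition.

Runs of homozygosity (ROH) are contiguous stretches of homozygous SNP calls.
Long ROH arise from recent common ancestors (little time for recombination to
erode them), short ROH from old ones: the length of an IBD segment whose
common ancestor lived g generations ago is exponential with mean 1/(2g)
Morgan.  Under a uniform map of ``mb_per_morgan`` (default 100 Mb/Morgan,
i.e. 1 cM/Mb) this gives the conversion g = mb_per_morgan / (2 * length_mb).

Detection uses a deterministic maximal-run scan: within each animal x
chromosome, a run is a maximal marker window containing at most
``max_het_per_segment`` heterozygous and ``max_missing_per_segment`` missing
calls and no adjacent-marker gap above ``max_gap_bp``; surviving runs must
meet the minimum SNP count, minimum length and marker-density filters.
Overlapping maximal runs (possible because of the het/missing budgets) are
resolved greedily from the left so reported segments never overlap.

Genome-wide ROH inbreeding is F_ROH = sum(L_ROH) / L_AUTO with L_AUTO the
SNP-covered autosomal span, and it partitions additively by any length
threshold m: F_ROH = F_short_m + F_long_m (segments >= m Mb are "long"/new).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

SEGMENT_COLUMNS = ["animal_id", "chromosome", "start_bp", "end_bp",
                   "length_bp", "n_snps", "n_het", "n_missing"]


@dataclass
class GenotypeDataset:
    """SNP genotypes: samples x markers, calls in {0 hom-ref, 1 het, 2 hom-alt, -1 missing}."""

    samples: list
    markers: pd.DataFrame  # marker_id, chromosome, position_bp (sorted)
    calls: np.ndarray      # int8, shape (n_samples, n_markers)

    def __post_init__(self):
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError("call matrix does not match samples x markers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for _, grp in self.markers.groupby("chromosome"):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions not strictly increasing")

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_markers(self):
        return len(self.markers)

    def autosome_span_bp(self) -> int:
        """L_AUTO: sum over chromosomes of (last - first marker position)."""
        spans = self.markers.groupby("chromosome")["position_bp"].agg(["min", "max"])
        return int((spans["max"] - spans["min"]).sum())


@dataclass
class ROHParams:
    """Filters for ROH detection (defaults follow medium-density panels)."""

    min_length_bp: int = 1_000_000
    min_snps: int = 15
    max_het_per_segment: int = 2
    max_missing_per_segment: int = 5
    max_gap_bp: int = 500_000
    min_density_bp_per_snp: int = 500_000

    def __post_init__(self):
        for name in ("min_length_bp", "min_snps", "max_gap_bp",
                     "min_density_bp_per_snp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_segment < 0 or self.max_missing_per_segment < 0:
            raise ValueError("het/missing budgets must be >= 0")


@dataclass
class ROHSet:
    """Detected segments plus the SNP-covered genome length they refer to."""

    segments: pd.DataFrame
    l_auto_bp: int
    params: ROHParams | None = field(default=None, compare=False)

    def lengths_mb(self) -> np.ndarray:
        return self.segments["length_bp"].to_numpy() / 1e6


# ---------------------------------------------------------------------------
# PLINK text IO


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK .ped/.map text files into a GenotypeDataset.

    The two alleles per marker are identified from the data; the
    lexicographically smaller allele is taken as the reference.  "0 0" is
    missing.  Markers are sorted by (chromosome, position).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "marker_id", "cm", "position_bp"])
    if mp["marker_id"].duplicated().any():
        raise ValueError("duplicate marker ids in .map")
    if not np.issubdtype(mp["position_bp"].dtype, np.number):
        raise ValueError("non-numeric positions in .map")
    n_markers = len(mp)

    samples, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ValueError(
                    f".ped row has {len(fields) - 6} allele fields, expected "
                    f"{2 * n_markers} for {n_markers} markers")
            samples.append(fields[1])
            rows.append(fields[6:])
    alleles = np.array(rows, dtype=object).reshape(len(samples), n_markers, 2)

    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for m in range(n_markers):
        col = alleles[:, m, :]
        obs = sorted(set(col.ravel()) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"marker {mp['marker_id'][m]}: >2 alleles {obs}")
        ref = obs[0] if obs else "A"
        a, b = col[:, 0], col[:, 1]
        known = (a != "0") & (b != "0")
        n_ref = (a == ref).astype(np.int8) + (b == ref).astype(np.int8)
        calls[known, m] = np.int8(2) - n_ref[known]  # 2 ref alleles -> HOM_REF(0)

    order = np.lexsort((mp["position_bp"], mp["chromosome"]))
    mp = mp.iloc[order].reset_index(drop=True)[["marker_id", "chromosome", "position_bp"]]
    return GenotypeDataset(samples, mp, calls[:, order])


def write_plink_text(data: GenotypeDataset, ped_path, map_path) -> None:
    """Write PLINK text files with alleles 'A' (ref) and 'B'; missing '0 0'."""
    with open(map_path, "w") as fh:
        for _, m in data.markers.iterrows():
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    geno_map = {HOM_REF: "A A", HET: "A B", HOM_ALT: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(data.samples):
            geno = " ".join(geno_map[int(c)] for c in data.calls[i])
            fh.write(f"{sid} {sid} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# Detection


def _maximal_runs(calls: np.ndarray, pos: np.ndarray, params: ROHParams):
    """Yield all maximal feasible (start, end) marker windows (inclusive).

    Feasible: het count <= budget, missing count <= budget, no internal
    adjacent gap > max_gap_bp.  Feasibility is hereditary, so a two-pointer
    scan over gap-delimited blocks enumerates exactly the maximal windows.
    """
    n = len(pos)
    gaps = np.diff(pos)
    block_starts = [0] + [i + 1 for i in np.flatnonzero(gaps > params.max_gap_bp)]
    block_ends = [s - 1 for s in block_starts[1:]] + [n - 1]
    for bs, be in zip(block_starts, block_ends):
        j = bs - 1
        het = miss = 0
        prev_j = -2
        for i in range(bs, be + 1):
            if j < i - 1:  # window emptied
                j, het, miss = i - 1, 0, 0
            while j < be:
                c = calls[j + 1]
                nh = het + (c == HET)
                nm = miss + (c == MISSING)
                if nh > params.max_het_per_segment or nm > params.max_missing_per_segment:
                    break
                j, het, miss = j + 1, nh, nm
            if j >= i and (prev_j < j):
                yield i, j
                prev_j = j
            if j >= i:  # drop marker i from the window before advancing
                c = calls[i]
                het -= (c == HET)
                miss -= (c == MISSING)


def detect_roh(data: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Detect ROH segments per animal and chromosome (see module docstring).

    Segment bounds are the first/last marker positions of the run and
    length = end_bp - start_bp.
    """
    params = params or ROHParams()
    records = []
    chroms = data.markers["chromosome"].to_numpy()
    positions = data.markers["position_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        pos = positions[cols]
        for si, sid in enumerate(data.samples):
            calls = data.calls[si, cols]
            last_end = -1
            for i, j in _maximal_runs(calls, pos, params):
                if i <= last_end:
                    continue  # overlap with an already accepted run
                length = int(pos[j] - pos[i])
                n_snps = j - i + 1
                if n_snps < params.min_snps or length < params.min_length_bp:
                    continue
                if length / n_snps > params.min_density_bp_per_snp:
                    continue
                window = calls[i:j + 1]
                records.append((sid, chrom, int(pos[i]), int(pos[j]), length,
                                n_snps, int(np.sum(window == HET)),
                                int(np.sum(window == MISSING))))
                last_end = j
    segments = pd.DataFrame(records, columns=SEGMENT_COLUMNS)
    return ROHSet(segments, data.autosome_span_bp(), params)


# ---------------------------------------------------------------------------
# F_ROH and partitions


def roh_inbreeding(rohs: ROHSet) -> pd.Series:
    """F_ROH = sum of segment lengths / L_AUTO per animal (0 when no segments)."""
    if rohs.l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    totals = rohs.segments.groupby("animal_id")["length_bp"].sum()
    return (totals / rohs.l_auto_bp).rename("f_roh")


def partition_roh_inbreeding(rohs: ROHSet, m_mb: float,
                             animals=None) -> pd.DataFrame:
    """Split F_ROH at threshold m (Mb): segments >= m are long (new/recent).

    A segment exactly m Mb long is classified long, consistent with long
    segments indicating recent common ancestors.  Animals without long
    segments get f_new = 0.
    """
    if m_mb <= 0:
        raise ValueError("m_mb must be positive")
    seg = rohs.segments
    if animals is None:
        animals = sorted(seg["animal_id"].unique())
    cutoff = m_mb * 1e6
    lengths = seg["length_bp"].astype(float)
    long_sum = lengths[lengths >= cutoff].groupby(seg["animal_id"]).sum()
    tot_sum = lengths.groupby(seg["animal_id"]).sum()
    f_new = long_sum.reindex(animals).fillna(0.0).to_numpy() / rohs.l_auto_bp
    f_tot = tot_sum.reindex(animals).fillna(0.0).to_numpy() / rohs.l_auto_bp
    return pd.DataFrame({
        "animal_id": animals,
        "f_total": f_tot,
        "f_new": f_new,
        "f_old": f_tot - f_new,
        "method": "roh_m",
        "threshold": float(m_mb),
    })


# ---------------------------------------------------------------------------
# Length <-> age conversion


def length_to_generations(l_mb, mb_per_morgan: float = 100.0):
    """Expected age (generations to common ancestor) of an IBD segment of the
    given length: g = mb_per_morgan / (2 * l_mb)."""
    l_mb = np.asarray(l_mb, dtype=float)
    if np.any(l_mb <= 0):
        raise ValueError("length must be positive")
    out = mb_per_morgan / (2.0 * l_mb)
    return float(out) if out.ndim == 0 else out


def generations_to_length(g, mb_per_morgan: float = 100.0):
    """Expected segment length (Mb) for age g: l = mb_per_morgan / (2 * g)."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("g must be positive")
    out = mb_per_morgan / (2.0 * g)
    return float(out) if out.ndim == 0 else out


def write_roh_table(rohs: ROHSet, path) -> None:
    """Write segments as a PLINK .hom-style TSV."""
    df = rohs.segments.rename(columns={
        "animal_id": "IID", "chromosome": "CHR", "start_bp": "POS1",
        "end_bp": "POS2", "n_snps": "NSNP", "n_het": "NHET", "n_missing": "NMISS"})
    df["KB"] = rohs.segments["length_bp"] / 1e3
    df[["IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET", "NMISS"]].to_csv(
        path, sep="\t", index=False)
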