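"""Runs of homozygosity (ROH) and the genomic inbreeding coefficient F_ROH.

Detection mirrors the PLINK ``--homozyg`` sliding-window scan: 50-SNP
windows pass when they contain at most two heterozygous and at most two
missing calls; each SNP's hit rate is the fraction of passing windows
among the windows that contain it (fewer near chromosome ends), and a SNP
is ROH-eligible when that rate strictly exceeds the threshold. Maximal
stretches of eligible SNPs are split at large inter-marker gaps and kept
when they satisfy the minimum SNP count, physical length and SNP density.

F_ROH is the fraction of the autosomal genome covered by ROH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHSet",
    "FrohTable",
    "window_scan",
    "detect_roh",
    "detect_roh_oracle",
    "froh",
    "autosomal_genome_length",
]


@dataclass
class ROHParams:
    """Sliding-window ROH criteria (defaults match the CanineHD analysis).

    window_snps x step-1 windows; a window tolerates ``window_max_het``
    heterozygous and ``window_max_missing`` missing calls. Runs must span at
    least ``min_snps`` SNPs and ``min_length_bp`` base pairs, at a density of
    at least one SNP per ``1/min_density`` bp, with no gap between
    consecutive SNPs above ``max_gap_bp``.
    """

    window_snps: int = 50
    window_max_het: int = 2
    window_max_missing: int = 2
    hit_rate_threshold: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 100_000
    min_density: float = 1.0 / 50_000  # SNPs per bp
    max_gap_bp: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_rate_threshold <= 1.0:
            raise ValueError("hit_rate_threshold must be in (0, 1]")
        for name in ("window_snps", "min_snps", "min_length_bp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    snp_count: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ROHSet:
    segments: list[ROHSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def for_sample(self, sample_id: str) -> list[ROHSegment]:
        return [s for s in self.segments if s.sample_id == sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.snp_count, s.length_bp)
                for s in self.segments
            ],
            columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FrohTable:
    table: pd.DataFrame  # sample_id, roh_length_bp, genome_length_bp, froh

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over all length-w windows of x (len(x) - w + 1 values)."""
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def window_scan(
    sample_dosages: np.ndarray, params: ROHParams | None = None
) -> np.ndarray:
    """Per-SNP ROH eligibility for one sample on one sorted chromosome.

    Returns a boolean array; all-False when the chromosome has fewer SNPs
    than one window.
    """
    params = params or ROHParams()
    x = np.asarray(sample_dosages)
    m = len(x)
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    het = (x == 1).astype(np.int64)
    mis = (x == MISSING).astype(np.int64)
    passing = (
        (_sliding_sum(het, w) <= params.window_max_het)
        & (_sliding_sum(mis, w) <= params.window_max_missing)
    ).astype(np.int64)
    n_windows = m - w + 1
    # SNP j is contained in windows max(0, j-w+1) .. min(j, n_windows-1)
    lo = np.maximum(0, np.arange(m) - w + 1)
    hi = np.minimum(np.arange(m), n_windows - 1)
    cpass = np.concatenate([[0], np.cumsum(passing)])
    hits = cpass[hi + 1] - cpass[lo]
    containing = hi - lo + 1
    return hits / containing > params.hit_rate_threshold


def _run_filters(
    pos: np.ndarray, runs: list[tuple[int, int]], params: ROHParams
) -> list[tuple[int, int]]:
    """Split candidate index runs at large gaps, then apply run-level filters."""
    out: list[tuple[int, int]] = []
    for a, b in runs:  # inclusive index range
        start = a
        for j in range(a + 1, b + 1):
            if pos[j] - pos[j - 1] > params.max_gap_bp:
                out.append((start, j - 1))
                start = j
        out.append((start, b))
    kept = []
    for a, b in out:
        n_snps = b - a + 1
        length = int(pos[b] - pos[a] + 1)
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_bp
            and n_snps / length >= params.min_density
        ):
            kept.append((a, b))
    return kept


def _index_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def _by_chromosome(dataset: GenotypeDataset):
    chrom = dataset.markers.chromosome
    pos = dataset.markers.position_bp
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        yield str(c), idx, pos[idx]


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Sliding-window ROH detection for every sample and chromosome.

    Segment coordinates are the positions of the first and last SNP of the
    run (no extrapolation beyond flanking markers).
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for c, idx, pos in _by_chromosome(dataset):
        block = dataset.dosage[:, idx]
        for i, sid in enumerate(dataset.sample_ids):
            eligible = window_scan(block[i], params)
            for a, b in _run_filters(pos, _index_runs(eligible), params):
                segments.append(
                    ROHSegment(sid, c, int(pos[a]), int(pos[b]), b - a + 1)
                )
    return ROHSet(segments)


def detect_roh_oracle(dataset: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Exhaustive reference detector for small fixtures.

    Candidate runs are maximal stretches of strictly homozygous,
    non-missing genotypes; the same gap/length/count/density filters are
    then applied. On error-free planted data it agrees with
    :func:`detect_roh`; an interior heterozygote splits the oracle's run
    while the windowed detector may bridge it (a documented difference).
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for c, idx, pos in _by_chromosome(dataset):
        block = dataset.dosage[:, idx]
        for i, sid in enumerate(dataset.sample_ids):
            hom = (block[i] == 0) | (block[i] == 2)
            for a, b in _run_filters(pos, _index_runs(hom), params):
                segments.append(
                    ROHSegment(sid, c, int(pos[a]), int(pos[b]), b - a + 1)
                )
    return ROHSet(segments)


def autosomal_genome_length(dataset: GenotypeDataset) -> int:
    """Sum over chromosomes of (last SNP bp - first SNP bp + 1) on the map."""
    total = 0
    for _, _, pos in _by_chromosome(dataset):
        if len(pos):
            total += int(pos[-1] - pos[0] + 1)
    return total


def froh(rohset: ROHSet, genome_length_bp: int, sample_ids: list[str]) -> FrohTable:
    """Per-sample F_ROH = total ROH length / autosomal genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    totals = {s: 0 for s in sample_ids}
    for seg in rohset.segments:
        if seg.sample_id in totals:
            totals[seg.sample_id] += seg.length_bp
    for s, t in totals.items():
        if t > genome_length_bp:
            raise ValueError(
                f"sample {s!r}: total ROH length {t} exceeds genome length "
                f"{genome_length_bp} (overlapping segments?)"
            )
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "roh_length_bp": [totals[s] for s in sample_ids],
            "genome_length_bp": genome_length_bp,
        }
    )
    df["froh"] = df["roh_length_bp"] / genome_length_bp
    return FrohTable(df)
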