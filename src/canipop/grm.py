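"""Genomic relationships and identity-by-state distances.

The genomic relationship matrix follows the locus-by-locus scaled
estimator of Yang et al. (as in GCTA): each locus contributes
``(x_i - 2p)(x_j - 2p) / (2p(1-p))`` off-diagonal, while the diagonal uses
``1 + [x^2 - (1+2p)x + 2p^2] / (2p(1-p))``, an unbiased estimator of
1 + F under Hardy-Weinberg. Allele frequencies come from the analyzed
sample itself. Missing genotypes are handled pairwise-complete: each pair
of animals averages over the loci typed in both.

IBS distance between two animals is the proportion of alleles not shared:
D = 1 - (mean shared-allele score)/2, with score 2 for identical genotypes,
0 for opposite homozygotes and 1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset
from .pedigree import RelationshipMatrix

__all__ = [
    "AlleleFrequencies",
    "DistanceMatrix",
    "allele_frequencies",
    "genomic_relationship_matrix",
    "ibs_distance_matrix",
    "matrix_correlation",
]


@dataclass
class AlleleFrequencies:
    """Per-marker allele2 frequency over non-missing calls."""

    marker_id: np.ndarray
    p: np.ndarray
    n_calls: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "p": self.p, "n_calls": self.n_calls}
        )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def allele_frequencies(dataset: GenotypeDataset) -> AlleleFrequencies:
    """p_k = (sum of non-missing dosages) / (2 x number of calls); markers
    with zero calls get NaN."""
    if dataset.n_markers == 0:
        raise ValueError("empty dataset")
    x = dataset.dosage_float()
    n_calls = np.sum(~np.isnan(x), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(x, axis=0) / (2.0 * n_calls)
    p[n_calls == 0] = np.nan
    return AlleleFrequencies(dataset.markers.marker_id.copy(), p, n_calls)


def genomic_relationship_matrix(dataset: GenotypeDataset) -> RelationshipMatrix:
    """Yang-estimator GRM with pairwise-complete missing handling.

    Monomorphic loci (p of 0 or 1) and loci with no calls are excluded.
    Raises if any pair of samples shares no typed polymorphic locus.
    """
    freqs = allele_frequencies(dataset)
    p = freqs.p
    usable = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("no polymorphic loci available for the GRM")
    x = dataset.dosage_float()[:, usable]
    p = p[usable]
    obs = ~np.isnan(x)

    denom = 2.0 * p * (1.0 - p)
    w = (np.nan_to_num(x) - 2.0 * p) / np.sqrt(denom)
    w[~obs] = 0.0
    m_pair = obs.astype(float) @ obs.astype(float).T
    if (m_pair == 0).any():
        i, j = np.argwhere(m_pair == 0)[0]
        raise ValueError(
            f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
            "share no typed polymorphic locus"
        )
    G = (w @ w.T) / m_pair

    # diagonal: per-individual estimator of 1 + F
    diag_terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom
    m_i = obs.sum(axis=1)
    np.fill_diagonal(G, 1.0 + np.nansum(diag_terms, axis=1) / m_i)
    return RelationshipMatrix(list(dataset.sample_ids), G, role="genomic_G")


def ibs_distance_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """1 - mean proportion of alleles shared identical-by-state.

    The per-locus shared score is 2 - |x_i - x_j|, so the distance is the
    mean of |x_i - x_j| / 2 over loci typed in both samples.
    """
    x = dataset.dosage
    obs = (x != MISSING).astype(float)
    shared = obs @ obs.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
            "share no typed locus"
        )
    # sum |x_i - x_j| over shared loci via genotype-class indicator products
    ind = [((x == g) & (x != MISSING)).astype(float) for g in (0, 1, 2)]
    absdiff = np.zeros_like(shared)
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (ind[a] @ ind[b].T)
    D = absdiff / (2.0 * shared)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(dataset.sample_ids), D)


def matrix_correlation(
    G: RelationshipMatrix, A: RelationshipMatrix, mode: str = "off_diagonal"
) -> float:
    """Pearson correlation between two relationship matrices on shared ids.

    ``mode='off_diagonal'`` uses the strict upper triangle (the default:
    relationships between distinct animals); ``mode='all'`` includes the
    diagonal (self-relationships, 1 + F).
    """
    shared = [l for l in G.labels if l in set(A.labels)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared labels between matrices")
    g = G.align(shared).values
    a = A.align(shared).values
    iu = np.triu_indices(len(shared), k=0 if mode == "all" else 1)
    if mode not in ("all", "off_diagonal"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(iu[0]) < 3:
        raise ValueError("fewer than 3 entries to correlate")
    r, _ = stats.pearsonr(g[iu], a[iu])
    return float(r)
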