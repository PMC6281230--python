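"""Pedigree-based additive relationships and inbreeding.

The numerator relationship matrix A is built with Henderson's tabular
method: processing animals so parents come first,

    a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2        for j processed before i
    a_ii = 1 + a_{sire(i),dam(i)} / 2

with missing-parent terms zero. The diagonal is 1 + F_i, where F_i is the
pedigree inbreeding coefficient (probability that the two alleles at a
locus are identical by descent). A is the covariance matrix of breeding
values up to the additive variance, hence positive semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "GenerationTable",
    "additive_relationship_matrix",
    "pedigree_inbreeding",
    "generation_number",
    "per_generation_inbreeding",
]


@dataclass
class RelationshipMatrix:
    """Symmetric labelled relationship matrix (pedigree A or genomic G)."""

    labels: list[str]
    values: np.ndarray
    role: str = "pedigree_A"  # or "genomic_G"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("relationship matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def align(self, labels: list[str]) -> "RelationshipMatrix":
        idx = [self.labels.index(l) for l in labels]
        return RelationshipMatrix(list(labels), self.values[np.ix_(idx, idx)], self.role)


@dataclass
class GenerationTable:
    """Generation number per animal: founders 0, else 1 + max(parent generations)."""

    animal_id: list[str]
    generation: np.ndarray

    def mean_depth(self, focal: list[str] | None = None) -> float:
        if focal is None:
            return float(np.mean(self.generation))
        idx = {a: i for i, a in enumerate(self.animal_id)}
        return float(np.mean([self.generation[idx[a]] for a in focal]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal_id": self.animal_id, "generation": self.generation})


def _parent_indices(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    """Sire/dam row indices (-1 if unknown or not listed; unlisted parents
    are treated as founders and hence contribute nothing)."""
    pos = {a: i for i, a in enumerate(ped.animal_id)}
    sire = np.array([pos.get(s, -1) if s != ped.unknown_code else -1 for s in ped.sire_id])
    dam = np.array([pos.get(d, -1) if d != ped.unknown_code else -1 for d in ped.dam_id])
    return sire, dam


def additive_relationship_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A via the tabular method."""
    n = len(ped)
    sire, dam = _parent_indices(ped)
    A = np.zeros((n, n))
    for i in ped.order:
        s, d = sire[i], dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(list(ped.animal_id), A, role="pedigree_A")


def pedigree_inbreeding(ped: PedigreeTable) -> pd.DataFrame:
    """Per-animal pedigree inbreeding F_i = diag(A) - 1, with summary stats
    attached as ``.attrs['mean_F']`` / ``.attrs['sd_F']``."""
    A = additive_relationship_matrix(ped)
    F = np.diag(A.values) - 1.0
    df = pd.DataFrame({"animal_id": ped.animal_id, "F": F})
    df.attrs["mean_F"] = float(F.mean()) if len(F) else float("nan")
    df.attrs["sd_F"] = float(F.std(ddof=1)) if len(F) > 1 else float("nan")
    return df


def generation_number(ped: PedigreeTable) -> GenerationTable:
    """Maximum-generations-traced depth: founders 0, else 1 + max over known parents."""
    sire, dam = _parent_indices(ped)
    gen = np.zeros(len(ped), dtype=np.int64)
    for i in ped.order:
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        if parents:
            gen[i] = 1 + max(gen[p] for p in parents)
    return GenerationTable(list(ped.animal_id), gen)


def per_generation_inbreeding(ped: PedigreeTable) -> pd.DataFrame:
    """Mean pedigree F per generation number; empty generations omitted."""
    F = pedigree_inbreeding(ped)["F"].to_numpy()
    gen = generation_number(ped).generation
    df = pd.DataFrame({"generation": gen, "F": F})
    out = (
        df.groupby("generation")["F"]
        .agg(mean_F="mean", n="size")
        .reset_index()
        .sort_values("generation", ignore_index=True)
    )
    return out
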