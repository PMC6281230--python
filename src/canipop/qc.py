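"""Marker and sample quality control.

Filters follow the order used in array-based breed-diversity studies:
unmapped markers out, non-autosomal markers out, call-rate, minor allele
frequency, then sample missingness. Thresholds are exclusive exactly as
conventionally printed ("call-rate < 95%" removes, "> 10% missing" removes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

__all__ = ["QCThresholds", "QCReport", "marker_qc", "sample_qc", "apply_qc"]


@dataclass
class QCThresholds:
    """Filter settings.

    min_call_rate
        Markers with call rate strictly below this are removed (default 0.95).
    min_maf
        Markers with MAF strictly below this are removed; 0.01 for the merged
        multi-breed panel, 0.05 for within-breed analyses.
    max_sample_missing
        Samples with missing fraction strictly above this are removed.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    max_sample_missing: float = 0.10
    autosomes_only: bool = True
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts removed per criterion, in application order."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0

    def add(self, criterion: str, removed: int) -> None:
        self.steps.append((criterion, int(removed)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "removed"])

    def log_lines(self) -> list[str]:
        lines = [f"{c}: removed {r}" for c, r in self.steps]
        lines.append(
            f"final dimensions: {self.n_samples_out} samples x {self.n_markers_out} markers"
        )
        return lines


def _maf(dataset: GenotypeDataset) -> np.ndarray:
    """min(p, 1-p) of the allele2 frequency over non-missing calls; NaN if no calls."""
    x = dataset.dosage_float()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def marker_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply marker filters in order: unmapped, non-autosomal, call-rate, MAF.

    MAF is computed over non-missing genotypes of markers surviving the
    earlier steps. All markers removed is a legal (warning-level) outcome.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        n_markers_in=dataset.n_markers,
        n_samples_in=dataset.n_samples,
        n_samples_out=dataset.n_samples,
    )
    ds = dataset

    if thresholds.drop_unmapped:
        keep = ds.markers.is_mapped()
        report.add("unmapped", (~keep).sum())
        ds = ds.subset(markers=keep)
    if thresholds.autosomes_only:
        keep = ds.markers.is_autosomal()
        report.add("non_autosomal", (~keep).sum())
        ds = ds.subset(markers=keep)

    call_rate = 1.0 - (ds.dosage == MISSING).mean(axis=0) if ds.n_samples else np.ones(ds.n_markers)
    keep = call_rate >= thresholds.min_call_rate  # "< threshold" removed
    report.add(f"call_rate<{thresholds.min_call_rate:g}", (~keep).sum())
    ds = ds.subset(markers=keep)

    maf = _maf(ds)
    keep = ~np.isnan(maf) & (maf >= thresholds.min_maf)
    report.add(f"maf<{thresholds.min_maf:g}", (~keep).sum())
    ds = ds.subset(markers=keep)

    report.n_markers_out = ds.n_markers
    return ds, report


def sample_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Remove samples whose missing-genotype fraction exceeds the threshold."""
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        n_markers_in=dataset.n_markers,
        n_markers_out=dataset.n_markers,
        n_samples_in=dataset.n_samples,
    )
    if dataset.n_markers:
        missing_frac = (dataset.dosage == MISSING).mean(axis=1)
    else:
        missing_frac = np.zeros(dataset.n_samples)
    keep = missing_frac <= thresholds.max_sample_missing  # "> threshold" removed
    report.add(f"sample_missing>{thresholds.max_sample_missing:g}", (~keep).sum())
    ds = dataset.subset(samples=keep)
    report.n_samples_out = ds.n_samples
    return ds, report


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Marker QC followed by sample QC (single pass, no MAF recomputation)."""
    thresholds = thresholds or QCThresholds()
    ds, rep_m = marker_qc(dataset, thresholds)
    ds, rep_s = sample_qc(ds, thresholds)
    report = QCReport(
        steps=rep_m.steps + rep_s.steps,
        n_markers_in=dataset.n_markers,
        n_markers_out=ds.n_markers,
        n_samples_in=dataset.n_samples,
        n_samples_out=ds.n_samples,
    )
    return ds, report
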