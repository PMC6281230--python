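"""Linkage disequilibrium decay and Sved-equation Ne trajectories.

LD between syntenic SNP pairs is the squared Pearson correlation of
genotype dosages (composite/genotypic r-squared; the data are unphased).
Binned mean r-squared by physical distance gives the LD-decay curve, and
Sved's drift-recombination relationship

    E[r2] ~ 1 / (alpha + 4 N c)

is inverted per distance bin to yield an effective-size trajectory: a bin
whose midpoint maps to c Morgans informs on Ne roughly t = 1/(2c)
generations ago, with

    Ne(t) = (1 / (4 c)) * (1 / r2_adj - alpha),

where r2_adj subtracts the finite-sample term 1/(beta n) and alpha absorbs
the treatment of mutation (2 for the mutation-adjusted variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset

__all__ = [
    "NeParams",
    "pairwise_r2",
    "ld_decay",
    "estimate_ne",
    "default_bin_edges",
]


@dataclass
class NeParams:
    """Sved-equation settings.

    bp_to_morgan
        Physical-to-map conversion; default 1e-8 Morgan/bp = 1 cM/Mb.
    alpha
        Mutation adjustment in E[r2] = 1/(alpha + 4Nc); 1, 2 or 2.2.
    beta
        Sample-size correction r2_adj = r2 - 1/(beta n); 1 for unphased
        genotypic correlations, 2 for phased haplotype counts.
    """

    bp_to_morgan: float = 1e-8
    alpha: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.bp_to_morgan <= 0:
            raise ValueError("bp_to_morgan must be positive")
        if self.alpha not in (1.0, 2.0, 2.2):
            raise ValueError("alpha must be one of 1, 2, 2.2")
        if self.beta not in (1.0, 2.0):
            raise ValueError("beta must be 1 or 2")


def default_bin_edges(max_bp: int = 1_000_000, step_bp: int = 20_000) -> np.ndarray:
    """0 to 1 Mb in 20-kb steps."""
    return np.arange(0, max_bp + step_bp, step_bp)


def pairwise_r2(
    dataset: GenotypeDataset, max_distance_bp: int = 1_000_000, chunk: int = 512
) -> pd.DataFrame:
    """r-squared for every within-chromosome pair closer than the cutoff.

    Correlations are pairwise-complete over samples typed at both loci;
    pairs involving a zero-variance marker are skipped. Returns columns
    chromosome, distance_bp, r2.
    """
    rows_c, rows_d, rows_r = [], [], []
    x = dataset.dosage_float()
    chrom = dataset.markers.chromosome
    pos = dataset.markers.position_bp
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        xc, pc = x[:, idx], pos[idx]
        m = len(idx)
        obs = ~np.isnan(xc)
        x0 = np.nan_to_num(xc)
        for a0 in range(0, m, chunk):
            a1 = min(a0 + chunk, m)
            # pairs (j, k) with j in [a0, a1), k >= j, within distance
            b1 = int(np.searchsorted(pc, pc[a1 - 1] + max_distance_bp, side="right"))
            J = slice(a0, a1)
            K = slice(a0, b1)
            oJ, oK = obs[:, J].astype(float), obs[:, K].astype(float)
            n = oJ.T @ oK
            sx = x0[:, J].T @ oK
            sy = oJ.T @ x0[:, K]
            sxy = x0[:, J].T @ x0[:, K]
            sxx = (x0[:, J] ** 2).T @ oK
            syy = oJ.T @ (x0[:, K] ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = n * sxy - sx * sy
                varx = n * sxx - sx**2
                vary = n * syy - sy**2
                r2 = cov**2 / (varx * vary)
            dj = pc[K][None, :] - pc[J][:, None]
            valid = (dj > 0) & (dj <= max_distance_bp) & (varx > 0) & (vary > 0) & (n >= 2)
            jj, kk = np.nonzero(valid)
            rows_c.append(np.full(len(jj), str(c), dtype=object))
            rows_d.append(dj[jj, kk])
            rows_r.append(r2[jj, kk])
    if rows_c:
        out = pd.DataFrame(
            {
                "chromosome": np.concatenate(rows_c),
                "distance_bp": np.concatenate(rows_d).astype(np.int64),
                "r2": np.clip(np.concatenate(rows_r), 0.0, 1.0),
            }
        )
    else:
        out = pd.DataFrame(columns=["chromosome", "distance_bp", "r2"])
    return out


def ld_decay(pairs: pd.DataFrame, bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Mean r-squared and pair count per distance bin; empty bins omitted.

    Bins are half-open (lo, hi]: columns bin_lo, bin_hi, mean_r2, n_pairs.
    """
    if pairs.empty:
        raise ValueError("empty LD pair table")
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges())
    which = np.digitize(pairs["distance_bp"].to_numpy(), edges, right=True) - 1
    ok = (which >= 0) & (which < len(edges) - 1)
    df = pd.DataFrame({"bin": which[ok], "r2": pairs["r2"].to_numpy()[ok]})
    g = df.groupby("bin")["r2"].agg(mean_r2="mean", n_pairs="size").reset_index()
    g["bin_lo"] = edges[g["bin"]]
    g["bin_hi"] = edges[g["bin"] + 1]
    return g[["bin_lo", "bin_hi", "mean_r2", "n_pairs"]].sort_values(
        "bin_lo", ignore_index=True
    )


def estimate_ne(
    decay_table: pd.DataFrame, n_samples: int, params: NeParams | None = None
) -> pd.DataFrame:
    """Invert Sved's equation per distance bin.

    Returns columns t (generations ago, rounded), ne, c_morgan, bin_lo,
    bin_hi, mean_r2. Bins where the sample-corrected r-squared or the
    resulting Ne is non-positive are dropped.
    """
    params = params or NeParams()
    lo = decay_table["bin_lo"].to_numpy(dtype=float)
    hi = decay_table["bin_hi"].to_numpy(dtype=float)
    r2 = decay_table["mean_r2"].to_numpy(dtype=float)
    c = (lo + hi) / 2.0 * params.bp_to_morgan
    r2_adj = r2 - 1.0 / (params.beta * n_samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - params.alpha)
        t = np.rint(1.0 / (2.0 * c))
    keep = (c > 0) & (r2_adj > 0) & (ne > 0)
    out = pd.DataFrame(
        {
            "t": t[keep].astype(np.int64),
            "ne": ne[keep],
            "c_morgan": c[keep],
            "bin_lo": lo[keep].astype(np.int64),
            "bin_hi": hi[keep].astype(np.int64),
            "mean_r2": r2[keep],
        }
    )
    return out.sort_values("t", ignore_index=True)
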