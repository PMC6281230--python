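"""Between-population structure: classical MDS, neighbor-joining trees and
model-based admixture clustering.

The admixture model treats each genotype dosage x_il as Binomial(2, pi_il)
with pi_il = sum_k q_ik f_kl: individual i draws each of its two alleles
from ancestral population k with probability q_ik, where population k
carries allele frequency f_kl at locus l. The log-likelihood

    l(Q, P) = sum_il [ x_il log pi_il + (2 - x_il) log(1 - pi_il) ]

is maximized by plain EM over the latent allele origins (frappe-style EM on
the same likelihood ADMIXTURE accelerates with quasi-Newton steps). The
number of ancestral populations K is chosen by masking genotype entries in
cross-validation folds and minimizing held-out prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as _skbio_nj

from .grm import DistanceMatrix
from .io import MISSING, GenotypeDataset

__all__ = [
    "MDSCoordinates",
    "AdmixtureResult",
    "CVReport",
    "classical_mds",
    "nj_tree",
    "admixture_fit",
    "admixture_cv",
]

_EPS = 1e-10


@dataclass
class MDSCoordinates:
    """Torgerson-scaling coordinates with the eigenvalues of the solution."""

    labels: list[str]
    coords: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, decreasing

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"dim{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.index.name = "sample_id"
        return df


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    P: np.ndarray  # K x markers, ancestral allele frequencies
    loglik: float
    loglik_path: np.ndarray
    iterations: int
    seed: int
    sample_ids: list[str]

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, index=self.sample_ids, columns=[f"K{k + 1}" for k in range(self.K)]
        )
        df.index.name = "sample_id"
        return df


@dataclass
class CVReport:
    table: pd.DataFrame  # K, cv_error
    selected_K: int


def classical_mds(distance_matrix: DistanceMatrix, k: int = 3) -> MDSCoordinates:
    """Torgerson classical scaling of a distance matrix.

    B = -J (D*D) J / 2 with J the centering projector; coordinates are
    V Lambda^1/2 over the top-k positive eigenvalues. If fewer than k
    eigenvalues are positive, fewer columns come back.
    """
    D = distance_matrix.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]) if n else 0)
    use = min(k, int(pos.sum()))
    coords = evecs[:, :use] * np.sqrt(evals[:use])
    return MDSCoordinates(list(distance_matrix.labels), coords, evals)


def nj_tree(distance_matrix: DistanceMatrix, labels: list[str] | None = None) -> str:
    """Neighbor-joining (Saitou-Nei) tree as a newick string.

    Negative branch lengths arising from non-additive inputs are clamped
    to zero. Exact on additive matrices: the induced path metric equals
    the input.
    """
    labels = list(labels if labels is not None else distance_matrix.labels)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate taxon labels")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    dm = SkbioDM(distance_matrix.values, ids=labels)
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def _init_qf(n: int, m: int, K: int, rng: np.random.Generator):
    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, m))
    return Q, P


def _loglik(x, valid, Q, P) -> float:
    pi = np.clip(Q @ P, _EPS, 1 - _EPS)
    ll = np.where(valid, x * np.log(pi) + (2 - x) * np.log(1 - pi), 0.0)
    return float(ll.sum())


def admixture_fit(
    dataset: GenotypeDataset,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
    n_restarts: int = 3,
) -> AdmixtureResult:
    """EM fit of the K-population admixture model.

    Runs ``n_restarts`` seeded initializations and keeps the best final
    log-likelihood (ties broken by the lowest restart index). ``tol`` is
    the absolute log-likelihood increase below which iteration stops.
    Missing genotypes are skipped in all sums.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > dataset.n_samples:
        raise ValueError(f"K={K} exceeds sample count {dataset.n_samples}")
    x = dataset.dosage.astype(float)
    valid = dataset.dosage != MISSING
    x[~valid] = 0.0
    n, m = x.shape
    L_i = valid.sum(axis=1).astype(float)
    if (L_i == 0).any():
        raise ValueError("sample with no observed genotypes")

    if K == 1:
        with np.errstate(invalid="ignore"):
            p = x.sum(axis=0) / np.maximum(2.0 * valid.sum(axis=0), _EPS)
        Q = np.ones((n, 1))
        P = p[None, :]
        ll = _loglik(x, valid, Q, P)
        return AdmixtureResult(1, Q, P, ll, np.array([ll]), 0, seed, list(dataset.sample_ids))

    best: AdmixtureResult | None = None
    x2 = 2.0 - x
    x2[~valid] = 0.0
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        Q, P = _init_qf(n, m, K, rng)
        path = []
        ll_old = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            pi = np.clip(Q @ P, _EPS, 1 - _EPS)
            ll_terms = x * np.log(pi) + x2 * np.log1p(-pi)
            ll = float(ll_terms.sum())
            path.append(ll)
            if ll - ll_old < tol and it > 1:
                break
            ll_old = ll
            # expected allele-origin counts; x and x2 are zero at missing
            # entries, so those contribute nothing to any sum
            rx = x / pi
            ry = x2 / (1.0 - pi)
            num_a = Q * (rx @ P.T)  # sum_l x*a, per (i, k)
            num_b = Q * (ry @ (1.0 - P).T)  # sum_l (2-x)*b
            Q_new = (num_a + num_b) / (2.0 * L_i[:, None])
            fa = P * (Q.T @ rx)  # sum_i x*a, per (k, l)
            fb = (1.0 - P) * (Q.T @ ry)
            P_new = fa / np.maximum(fa + fb, _EPS)
            Q = np.clip(Q_new, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)
            P = np.clip(P_new, _EPS, 1 - _EPS)
        res = AdmixtureResult(
            K, Q, P, path[-1], np.array(path), it, seed, list(dataset.sample_ids)
        )
        if best is None or res.loglik > best.loglik + 1e-9:
            best = res
    return best


def admixture_cv(
    dataset: GenotypeDataset,
    K_list: list[int],
    folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> CVReport:
    """Choose K by masking genotype entries and scoring held-out prediction.

    Non-missing entries are partitioned into ``folds`` random folds
    (identical masks for every K). For each fold the masked entries are
    hidden, the model refit, and the error is the mean of
    (x - 2 pi_hat)^2 over the masked entries. The selected K minimizes the
    mean error across folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    # held-out scoring only needs the fits ranked, not polished to the
    # final digit: coarser convergence than admixture_fit's default
    fit_kwargs.setdefault("tol", 1e-2)
    fit_kwargs.setdefault("max_iter", 500)
    rng = np.random.default_rng([seed, 7919])
    obs_idx = np.argwhere(dataset.dosage != MISSING)
    perm = rng.permutation(len(obs_idx))
    fold_of = np.empty(len(obs_idx), dtype=np.int64)
    fold_of[perm] = np.arange(len(obs_idx)) % folds

    errors = {K: [] for K in K_list}
    for f in range(folds):
        mask = obs_idx[fold_of == f]
        masked = dataset.dosage.copy()
        masked[mask[:, 0], mask[:, 1]] = MISSING
        ds_f = GenotypeDataset(
            list(dataset.sample_ids), dataset.markers, masked, dataset.sample_info
        )
        truth = dataset.dosage[mask[:, 0], mask[:, 1]].astype(float)
        for K in K_list:
            fit = admixture_fit(ds_f, K, seed=seed * 1000 + f, **fit_kwargs)
            pi = np.clip(fit.Q @ fit.P, _EPS, 1 - _EPS)
            pred = 2.0 * pi[mask[:, 0], mask[:, 1]]
            errors[K].append(float(np.mean((truth - pred) ** 2)))
    table = pd.DataFrame(
        {"K": list(K_list), "cv_error": [float(np.mean(errors[K])) for K in K_list]}
    )
    selected = int(table.loc[table["cv_error"].idxmin(), "K"])
    return CVReport(table, selected)
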