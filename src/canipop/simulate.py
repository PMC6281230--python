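"""Synthetic genotype panels with known truth.

Every pipeline stage is validated against data generated here: founder
panels with chosen allele-frequency spectra, gene dropping down a pedigree
with exact identity-by-descent tracking (so realized inbreeding and
autozygous segments are known), discrete-generation Wright-Fisher forward
simulation (LD generated by finite population size), Balding-Nichols
admixture panels with known Q and P, and planted homozygous segments for
ROH detectors.

Recombination uses the Haldane (no-interference) model: the switch
probability between adjacent markers d Morgans apart is (1 - e^(-2d))/2,
and independent chromosomes switch with probability 1/2. Physical-to-map
conversion defaults to 1 cM/Mb. All generators are bit-reproducible given
a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, MarkerMap, PedigreeTable

__all__ = [
    "SimulationTruth",
    "make_marker_map",
    "sim_founders",
    "gene_drop",
    "sim_wright_fisher",
    "sim_breed_panel",
    "random_pedigree",
    "sim_admixture",
    "plant_roh",
]


@dataclass
class SimulationTruth:
    """Ground truth recorded next to a generated dataset (fields as applicable)."""

    params: dict = field(default_factory=dict)
    realized_F: pd.DataFrame | None = None  # animal_id, realized_F
    ibd_segments: pd.DataFrame | None = None  # sample_id, chromosome, start_bp, end_bp
    ne_history: pd.DataFrame | None = None  # generation_ago, N
    Q: np.ndarray | None = None
    P: np.ndarray | None = None
    planted_segments: pd.DataFrame | None = None


def random_pedigree(
    n_founders: int,
    n_generations: int,
    per_generation: int,
    seed: int = 0,
    allow_inbreeding: bool = True,
) -> PedigreeTable:
    """Random discrete-generation pedigree for validation runs.

    Each new animal draws its sire and dam uniformly (and independently,
    so matings between relatives arise freely when ``allow_inbreeding``)
    from the previous generation, or from distinct parents otherwise.
    """
    rng = np.random.default_rng(seed)
    animal = [f"A{i + 1}" for i in range(n_founders)]
    sire = ["0"] * n_founders
    dam = ["0"] * n_founders
    prev = list(animal)
    nxt = n_founders + 1
    for _ in range(n_generations):
        cur = []
        for _ in range(per_generation):
            if len(prev) < 2:
                raise ValueError("need at least 2 animals per generation")
            s, d = rng.choice(len(prev), size=2, replace=allow_inbreeding)
            if not allow_inbreeding and s == d:
                d = (d + 1) % len(prev)
            a = f"A{nxt}"
            nxt += 1
            animal.append(a)
            sire.append(prev[s])
            dam.append(prev[d])
            cur.append(a)
        prev = cur
    return PedigreeTable(animal, sire, dam)


def make_marker_map(
    m: int, chromosomes: int = 38, spacing_bp: int = 100_000, start_bp: int = 1
) -> MarkerMap:
    """Evenly spaced markers split as equally as possible across chromosomes."""
    if m % chromosomes:
        raise ValueError(f"m={m} not divisible across {chromosomes} chromosomes")
    per = m // chromosomes
    chrom = np.repeat([str(c) for c in range(1, chromosomes + 1)], per).astype(object)
    pos = np.tile(start_bp + spacing_bp * np.arange(per, dtype=np.int64), chromosomes)
    ids = np.array([f"snp{c}_{i}" for c in range(1, chromosomes + 1) for i in range(per)], dtype=object)
    a = np.array(["A"] * m, dtype=object)
    g = np.array(["G"] * m, dtype=object)
    return MarkerMap(ids, chrom, pos, a, g)


def _switch_probs(markers: MarkerMap, bp_to_morgan: float = 1e-8) -> np.ndarray:
    """Haldane switch probability for each of the m-1 marker intervals."""
    pos = markers.position_bp.astype(float)
    d = np.diff(pos) * bp_to_morgan
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    same = markers.chromosome[1:] == markers.chromosome[:-1]
    return np.where(same, r, 0.5)


def _meioses(parent_haps: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row pair of ``parent_haps`` (2G x m) -> (G x m).

    Row 2j / 2j+1 are the two haplotypes of the parent of gamete j.
    """
    G = parent_haps.shape[0] // 2
    m = parent_haps.shape[1]
    start = rng.integers(0, 2, size=(G, 1), dtype=np.int8)
    if m > 1:
        switches = (rng.random((G, m - 1), dtype=np.float32) < r).astype(np.int8)
    else:
        switches = np.zeros((G, 0), np.int8)
    # int8 cumsum may wrap at 256, which preserves parity, the only thing used
    cum = np.cumsum(switches, axis=1, dtype=np.int8)
    phase = np.empty((G, m), dtype=np.int8)
    phase[:, :1] = start
    phase[:, 1:] = start + cum
    phase &= 1
    hapA = parent_haps[0::2]
    hapB = parent_haps[1::2]
    return np.where(phase == 0, hapA, hapB)


def sim_founders(
    n: int,
    m: int,
    chromosomes: int = 38,
    freq_dist: tuple = ("uniform", 0.05, 0.5),
    seed: int = 0,
    spacing_bp: int = 100_000,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Unrelated founder diploids with i.i.d. haplotypes.

    Per-marker allele frequencies are drawn from ``freq_dist``:
    ``("uniform", lo, hi)`` or ``("beta", a, b)``. Returns the dataset and
    the 2n x m founder haplotype array (rows 2i, 2i+1 belong to sample i).
    """
    rng = np.random.default_rng(seed)
    markers = make_marker_map(m, chromosomes, spacing_bp)
    kind, a, b = freq_dist
    if kind == "uniform":
        p = rng.uniform(a, b, size=m)
    elif kind == "beta":
        if a <= 0 or b <= 0:
            raise ValueError("beta parameters must be positive")
        p = rng.beta(a, b, size=m)
    else:
        raise ValueError(f"unknown freq_dist kind {kind!r}")
    haps = (rng.random((2 * n, m)) < p).astype(np.int8)
    dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
    ds = GenotypeDataset([f"F{i + 1}" for i in range(n)], markers, dosage)
    return ds, haps


def gene_drop(
    founder_haps: np.ndarray,
    ped: PedigreeTable,
    markers: MarkerMap,
    seed: int = 0,
    bp_to_morgan: float = 1e-8,
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Drop founder alleles down a pedigree with recombination.

    Founder haplotypes (2 per founder, ordered as ``ped.founders()``) are
    transmitted with Haldane crossovers; the descent of founder-allele
    labels is tracked exactly, so realized autozygosity (both haplotypes
    carrying the same founder allele) is known per marker. The truth
    records per-animal realized F (fraction of markers autozygous) and the
    autozygous segments.
    """
    founders = ped.founders()
    if founder_haps.shape[0] != 2 * len(founders):
        raise ValueError(
            f"founder haplotypes rows ({founder_haps.shape[0]}) != 2 x founders ({len(founders)})"
        )
    m = founder_haps.shape[1]
    if m != len(markers):
        raise ValueError("founder haplotypes and marker map disagree on marker count")
    rng = np.random.default_rng(seed)
    r = _switch_probs(markers, bp_to_morgan)
    n = len(ped)
    pos = {a: i for i, a in enumerate(ped.animal_id)}
    lab = np.zeros((2 * n, m), dtype=np.int32)  # founder-allele labels
    fidx = {f: i for i, f in enumerate(founders)}
    sire = [pos.get(s, -1) if s != ped.unknown_code else -1 for s in ped.sire_id]
    dam = [pos.get(d, -1) if d != ped.unknown_code else -1 for d in ped.dam_id]
    for i in ped.order:
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            f = fidx[ped.animal_id[i]]
            lab[2 * i] = 2 * f
            lab[2 * i + 1] = 2 * f + 1
        elif s >= 0 and d >= 0:
            lab[2 * i] = _meioses(lab[2 * s : 2 * s + 2], r, rng)[0]
            lab[2 * i + 1] = _meioses(lab[2 * d : 2 * d + 2], r, rng)[0]
        else:
            raise ValueError(
                f"animal {ped.animal_id[i]!r} has exactly one known parent; "
                "gene dropping needs both or neither"
            )
    content = founder_haps.astype(np.int8)  # row = founder-allele label
    col = np.arange(m)
    dosage = (content[lab[0::2], col] + content[lab[1::2], col]).astype(np.int8)
    auto = lab[0::2] == lab[1::2]
    realized = pd.DataFrame(
        {"animal_id": ped.animal_id, "realized_F": auto.mean(axis=1)}
    )
    segs = _mask_segments(auto, ped.animal_id, markers)
    ds = GenotypeDataset(list(ped.animal_id), markers, dosage)
    truth = SimulationTruth(
        params={"seed": seed, "bp_to_morgan": bp_to_morgan},
        realized_F=realized,
        ibd_segments=segs,
    )
    return ds, truth


def _mask_segments(mask: np.ndarray, ids: list[str], markers: MarkerMap) -> pd.DataFrame:
    """Runs of True per sample and chromosome as (start_bp, end_bp) rows."""
    rows = []
    chrom = markers.chromosome
    pos = markers.position_bp
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        sub = mask[:, idx]
        for i, sid in enumerate(ids):
            v = sub[i]
            if not v.any():
                continue
            d = np.diff(v.astype(np.int8))
            starts = list(np.flatnonzero(d == 1) + 1)
            ends = list(np.flatnonzero(d == -1))
            if v[0]:
                starts.insert(0, 0)
            if v[-1]:
                ends.append(len(v) - 1)
            for a, b in zip(starts, ends):
                rows.append((sid, str(c), int(pos[idx][a]), int(pos[idx][b]), b - a + 1))
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps"]
    )


def _evolve(
    H: np.ndarray, phases: list[tuple[int, int]], r: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Run Wright-Fisher phases [(n_generations, N), ...] on haplotypes H."""
    m = H.shape[1]
    cur_N = H.shape[0] // 2
    rows = []
    g = 0
    for n_gen, size in phases:
        for _ in range(n_gen):
            mothers = rng.integers(0, cur_N, size=size)
            fathers = rng.integers(0, cur_N, size=size)
            par = np.concatenate([mothers, fathers])
            parent_haps = np.empty((2 * len(par), m), dtype=np.int8)
            parent_haps[0::2] = H[2 * par]
            parent_haps[1::2] = H[2 * par + 1]
            gam = _meioses(parent_haps, r, rng)
            H = np.empty((2 * size, m), dtype=np.int8)
            H[0::2] = gam[:size]
            H[1::2] = gam[size:]
            cur_N = size
            g += 1
            rows.append((g, size))
    return H, rows


def sim_wright_fisher(
    N: int,
    generations: int = 0,
    n_sample: int = 50,
    m: int = 2000,
    chromosomes: int = 20,
    seed: int = 0,
    spacing_bp: int = 100_000,
    burn_in: int | None = None,
    size_history: list[tuple[int, int]] | None = None,
    freq_dist: tuple = ("uniform", 0.1, 0.9),
    bp_to_morgan: float = 1e-8,
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Discrete-generation Wright-Fisher forward simulation, no mutation.

    The population runs ``burn_in`` (default 4N) plus ``generations``
    generations at constant size N, or follows ``size_history`` — a list of
    (n_generations, N) phases executed after the burn-in — to model
    bottlenecks. Each offspring is a random union of one gamete from a
    random mother and one from a random father (sampling with
    replacement). Monomorphic markers in the emitted sample are dropped
    and counted in the truth parameters.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    markers = make_marker_map(m, chromosomes, spacing_bp)
    r = _switch_probs(markers, bp_to_morgan)
    kind, a, b = freq_dist
    p = rng.uniform(a, b, size=m) if kind == "uniform" else rng.beta(a, b, size=m)
    H = (rng.random((2 * N, m)) < p).astype(np.int8)

    phases = [(4 * N if burn_in is None else burn_in, N)]
    if generations:
        phases.append((generations, N))
    if size_history:
        phases.extend(size_history)

    H, ne_rows = _evolve(H, phases, r, rng)
    cur_N = H.shape[0] // 2
    gen_counter = len(ne_rows)

    if n_sample > cur_N:
        raise ValueError(f"n_sample={n_sample} exceeds final population size {cur_N}")
    pick = rng.choice(cur_N, size=n_sample, replace=False)
    dosage = (H[2 * pick] + H[2 * pick + 1]).astype(np.int8)
    freq = dosage.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    n_fixed = int((~poly).sum())
    if not poly.any():
        raise ValueError(
            "all markers fixed by drift; use a shorter run, larger N or more markers"
        )
    ds = GenotypeDataset(
        [f"S{i + 1}" for i in range(n_sample)], markers, dosage
    ).subset(markers=poly)
    total_gens = gen_counter
    ne_hist = pd.DataFrame(
        [(total_gens - g, n) for g, n in ne_rows], columns=["generation_ago", "N"]
    )
    truth = SimulationTruth(
        params={
            "seed": seed,
            "N": N,
            "phases": phases,
            "n_fixed_dropped": n_fixed,
            "bp_to_morgan": bp_to_morgan,
            "spacing_bp": spacing_bp,
        },
        ne_history=ne_hist,
    )
    return ds, truth


def sim_breed_panel(
    n_breeds: int = 3,
    n_per_breed: int = 15,
    m: int = 2000,
    chromosomes: int = 10,
    N: int = 50,
    generations: int = 25,
    seed: int = 0,
    spacing_bp: int = 100_000,
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Multi-breed panel: breeds drift independently from one ancestral pool.

    A single ancestral allele-frequency vector (uniform 0.1-0.9, i.e. a
    large outbred source population at linkage equilibrium) seeds every
    breed, which then evolves ``generations`` Wright-Fisher generations at
    size ``N`` in isolation — the breed-formation bottleneck that drives
    both between-breed differentiation and within-breed LD. Breed labels
    are stored in ``sample_info['family_id']``. Markers monomorphic across
    the combined panel are dropped.
    """
    rng = np.random.default_rng(seed)
    markers = make_marker_map(m, chromosomes, spacing_bp)
    r = _switch_probs(markers)
    p = rng.uniform(0.1, 0.9, size=m)
    dosages, ids, breeds = [], [], []
    for b in range(n_breeds):
        H = (rng.random((2 * N, m)) < p).astype(np.int8)
        H, _ = _evolve(H, [(generations, N)], r, rng)
        pick = rng.choice(N, size=n_per_breed, replace=False)
        dosages.append((H[2 * pick] + H[2 * pick + 1]).astype(np.int8))
        name = f"B{b + 1}"
        ids += [f"{name}_{i + 1}" for i in range(n_per_breed)]
        breeds += [name] * n_per_breed
    dosage = np.vstack(dosages)
    freq = dosage.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    info = pd.DataFrame(
        {
            "family_id": breeds,
            "sample_id": ids,
            "sire_id": "0",
            "dam_id": "0",
            "sex": "0",
            "phenotype": "-9",
        }
    )
    ds = GenotypeDataset(ids, markers, dosage, info).subset(markers=poly)
    truth = SimulationTruth(
        params={
            "seed": seed,
            "n_breeds": n_breeds,
            "N": N,
            "generations": generations,
            "n_dropped_monomorphic": int((~poly).sum()),
        }
    )
    return ds, truth


def sim_admixture(
    K: int,
    n: int,
    m: int,
    fst: float = 0.1,
    dirichlet_alpha: float = 0.5,
    seed: int = 0,
    chromosomes: int = 10,
    spacing_bp: int = 100_000,
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Balding-Nichols admixture panel with known Q and P.

    Ancestral frequencies are uniform(0.05, 0.95); each of the K
    populations draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst``; individual ancestries are Dirichlet(``dirichlet_alpha``);
    dosages are Binomial(2, q_i . f_l). Loci are simulated independently
    (no LD), which is what the admixture likelihood assumes.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    if K < 2:
        raise ValueError("K must be >= 2")
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    markers = make_marker_map(m, chromosomes, spacing_bp)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    shape1 = p_anc * (1.0 - fst) / fst
    shape2 = (1.0 - p_anc) * (1.0 - fst) / fst
    P = rng.beta(shape1, shape2, size=(K, m))
    Q = rng.dirichlet(np.full(K, dirichlet_alpha), size=n)
    pi = Q @ P
    dosage = rng.binomial(2, pi).astype(np.int8)
    ds = GenotypeDataset([f"S{i + 1}" for i in range(n)], markers, dosage)
    truth = SimulationTruth(
        params={"seed": seed, "K": K, "fst": fst, "dirichlet_alpha": dirichlet_alpha},
        Q=Q,
        P=P,
    )
    return ds, truth


def plant_roh(
    dataset: GenotypeDataset,
    segments: list[tuple[str, str, int, int]],
    het_error_rate: float = 0.0,
    seed: int = 0,
    background: str = "hw",
) -> tuple[GenotypeDataset, SimulationTruth]:
    """Plant homozygous segments into a regenerated genotype panel.

    ``segments`` rows are (sample_id, chromosome, start_bp, end_bp);
    overlapping segments of one sample are merged with a warning. Outside
    the segments, genotypes are drawn at Hardy-Weinberg from per-marker
    frequencies uniform(0.05, 0.5) (``background="hw"``) or set fully
    heterozygous (``background="het"``, the error-free construction for
    detector-equivalence fixtures). Inside a segment every genotype is
    homozygous, the allele drawn by its frequency, except for independent
    per-SNP flips to heterozygote at ``het_error_rate`` emulating
    genotyping error.
    """
    if background not in ("hw", "het"):
        raise ValueError("background must be 'hw' or 'het'")
    rng = np.random.default_rng(seed)
    markers = dataset.markers
    n, m = dataset.n_samples, dataset.n_markers
    pos = markers.position_bp
    chrom = markers.chromosome
    lo = int(pos.min()) if m else 0
    hi = int(pos.max()) if m else 0
    merged: dict[str, list[list]] = {s: [] for s in dataset.sample_ids}
    for sid, c, a, b in segments:
        if sid not in merged:
            raise ValueError(f"unknown sample {sid!r} in planted segments")
        if a > b or a < lo or b > hi:
            raise ValueError(f"segment ({sid}, {c}, {a}, {b}) outside map bounds")
        merged[sid].append([str(c), a, b])
    for sid, segs in merged.items():
        segs.sort()
        out = []
        for seg in segs:
            if out and out[-1][0] == seg[0] and seg[1] <= out[-1][2]:
                warnings.warn(f"overlapping planted segments for {sid}; merged")
                out[-1][2] = max(out[-1][2], seg[2])
            else:
                out.append(seg)
        merged[sid] = out

    p = rng.uniform(0.05, 0.5, size=m)
    if background == "hw":
        u = rng.random((n, m))
        dosage = np.where(u < (1 - p) ** 2, 0, np.where(u < (1 - p) ** 2 + 2 * p * (1 - p), 1, 2)).astype(np.int8)
    else:
        dosage = np.ones((n, m), dtype=np.int8)
    hom_allele = (rng.random((n, m)) < p).astype(np.int8) * 2  # 0 or 2 per (sample, marker)
    err = rng.random((n, m)) < het_error_rate
    truth_rows = []
    for i, sid in enumerate(dataset.sample_ids):
        for c, a, b in merged[sid]:
            inseg = (chrom == c) & (pos >= a) & (pos <= b)
            dosage[i, inseg] = hom_allele[i, inseg]
            if het_error_rate > 0:
                flip = inseg & err[i]
                dosage[i, flip] = 1
            truth_rows.append((sid, c, a, b, int(inseg.sum())))
    ds = GenotypeDataset(list(dataset.sample_ids), markers, dosage, dataset.sample_info)
    truth = SimulationTruth(
        params={"seed": seed, "het_error_rate": het_error_rate, "background": background},
        planted_segments=pd.DataFrame(
            truth_rows, columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps"]
        ),
    )
    return ds, truth
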