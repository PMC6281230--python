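"""Genotype and pedigree I/O.

Reads and writes the standard exchange formats of SNP-array population
genetics: PLINK text (``.ped``/``.map``), PLINK-1 binary
(``.bed``/``.bim``/``.fam``, SNP-major) and delimited pedigree tables.
Genotypes are held as a samples x markers dosage matrix counting copies of
the second (A2) allele, with ``-1`` marking missing calls.

Canine autosomes are chromosomes 1-38; any other chromosome code (X, Y, MT,
0, unplaced contigs) is carried through but flagged non-autosomal for QC.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeDataset",
    "PedigreeTable",
    "GenotypeFormatError",
    "PedigreeError",
    "N_AUTOSOMES",
    "read_plink_text",
    "read_plink_binary",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
]

#: Number of canine autosomes on the CanineHD array.
N_AUTOSOMES = 38

MISSING = -1

PLINK_MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"


class GenotypeFormatError(ValueError):
    """Malformed genotype file (ragged lines, bad magic bytes, >2 alleles...)."""


class PedigreeError(ValueError):
    """Malformed pedigree (cycles, duplicate ids)."""


@dataclass
class MarkerMap:
    """Per-marker annotation: id, chromosome, physical position, alleles.

    Positions are 1-based base pairs as in PLINK ``.map``/``.bim`` files.
    ``allele1``/``allele2`` follow PLINK's A1/A2 convention; dosage counts
    copies of allele2.
    """

    marker_id: np.ndarray  # str
    chromosome: np.ndarray  # str codes; "1".."38" are autosomes
    position_bp: np.ndarray  # int64
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(
            [str(c) for c in np.asarray(self.chromosome)], dtype=object
        )
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        n = len(self.marker_id)
        if not all(
            len(a) == n
            for a in (self.chromosome, self.position_bp, self.allele1, self.allele2)
        ):
            raise ValueError("marker map columns have unequal lengths")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker ids are not unique")

    def __len__(self) -> int:
        return len(self.marker_id)

    def is_autosomal(self) -> np.ndarray:
        """Boolean mask of markers on canine autosomes 1-38."""
        out = np.zeros(len(self), dtype=bool)
        for i, c in enumerate(self.chromosome):
            try:
                out[i] = 1 <= int(c) <= N_AUTOSOMES
            except ValueError:
                out[i] = False
        return out

    def is_mapped(self) -> np.ndarray:
        """Markers with a usable genomic location (chrom != 0, pos >= 1)."""
        chrom_ok = np.array([c not in ("0", "") for c in self.chromosome])
        return chrom_ok & (self.position_bp >= 1)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.position_bp[idx],
            self.allele1[idx],
            self.allele2[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele1": self.allele1,
                "allele2": self.allele2,
            }
        )


@dataclass
class GenotypeDataset:
    """Samples x markers dosage matrix with marker map and sample metadata.

    ``dosage[i, k]`` counts copies of ``markers.allele2[k]`` carried by
    sample ``i``: 0, 1 or 2, with -1 for a missing call. ``sample_info``
    carries optional per-sample metadata (family/breed label, sex, ...).
    """

    sample_ids: list[str]
    markers: MarkerMap
    dosage: np.ndarray  # int8, samples x markers
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x markers)")
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN at missing calls."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def subset(
        self, samples: np.ndarray | None = None, markers: np.ndarray | None = None
    ) -> "GenotypeDataset":
        ds = self
        if samples is not None:
            samples = np.asarray(samples)
            if samples.dtype == bool:
                samples = np.flatnonzero(samples)
            info = ds.sample_info.iloc[samples].reset_index(drop=True) if ds.sample_info is not None else None
            ds = GenotypeDataset(
                [ds.sample_ids[i] for i in samples], ds.markers, ds.dosage[samples], info
            )
        if markers is not None:
            markers = np.asarray(markers)
            if markers.dtype == bool:
                markers = np.flatnonzero(markers)
            ds = GenotypeDataset(
                ds.sample_ids, ds.markers.subset(markers), ds.dosage[:, markers], ds.sample_info
            )
        return ds

    def sort_markers(self) -> "GenotypeDataset":
        """Order markers by (chromosome, position); chromosomes numerically when possible."""

        def chrom_key(c: str):
            try:
                return (0, int(c), "")
            except ValueError:
                return (1, 0, c)

        keys = [
            (chrom_key(c), p)
            for c, p in zip(self.markers.chromosome, self.markers.position_bp)
        ]
        order = np.array(sorted(range(self.n_markers), key=lambda i: keys[i]))
        return self.subset(markers=order)

    def recode_minor(self) -> "GenotypeDataset":
        """Flip markers so allele2 is the minor allele on this dataset.

        Makes dosage orientation reproducible regardless of how alleles were
        listed in the source files; ties (p = 0.5) are left as loaded.
        """
        x = self.dosage_float()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(x, axis=0) / 2.0
        flip = p > 0.5
        dosage = self.dosage.copy()
        cols = np.flatnonzero(flip)
        for k in cols:
            obs = dosage[:, k] != MISSING
            dosage[obs, k] = 2 - dosage[obs, k]
        markers = MarkerMap(
            self.markers.marker_id.copy(),
            self.markers.chromosome.copy(),
            self.markers.position_bp.copy(),
            np.where(flip, self.markers.allele2, self.markers.allele1),
            np.where(flip, self.markers.allele1, self.markers.allele2),
        )
        return GenotypeDataset(list(self.sample_ids), markers, dosage, self.sample_info)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and list(self.markers.marker_id) == list(other.markers.marker_id)
            and list(self.markers.chromosome) == list(other.markers.chromosome)
            and np.array_equal(self.markers.position_bp, other.markers.position_bp)
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class PedigreeTable:
    """Animal / sire / dam links with parents topologically before offspring.

    Unknown parents are normalized to ``unknown_code`` ("0"). ``order``
    indexes animals so that every known parent precedes its offspring.
    """

    animal_id: list[str]
    sire_id: list[str]
    dam_id: list[str]
    unknown_code: str = "0"
    sex: list[str] | None = None
    order: np.ndarray = field(default=None)  # topological order, computed

    def __post_init__(self) -> None:
        ids = self.animal_id
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate animal id(s): {dup[:5]}")
        if self.order is None:
            self.order = self._toposort()

    def _toposort(self) -> np.ndarray:
        g = nx.DiGraph()
        g.add_nodes_from(self.animal_id)
        known = set(self.animal_id)
        for a, s, d in zip(self.animal_id, self.sire_id, self.dam_id):
            for p in (s, d):
                if p != self.unknown_code and p in known:
                    g.add_edge(p, a)
        try:
            topo = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            chain = [e[0] for e in nx.find_cycle(g)]
            raise PedigreeError(
                "pedigree contains a cycle: " + " -> ".join(chain + [chain[0]])
            ) from None
        pos = {a: i for i, a in enumerate(self.animal_id)}
        return np.array([pos[a] for a in topo], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.animal_id)

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        i = self.animal_id.index(animal)
        s = self.sire_id[i] if self.sire_id[i] != self.unknown_code else None
        d = self.dam_id[i] if self.dam_id[i] != self.unknown_code else None
        return s, d

    def founders(self) -> list[str]:
        return [
            a
            for a, s, d in zip(self.animal_id, self.sire_id, self.dam_id)
            if s == self.unknown_code and d == self.unknown_code
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"animal_id": self.animal_id, "sire_id": self.sire_id, "dam_id": self.dam_id}
        )
        if self.sex is not None:
            df["sex"] = self.sex
        return df


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def _read_map(map_path) -> MarkerMap:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeFormatError(f"{map_path}: line {ln}: expected 4 columns")
            # chrom, id, cM (ignored), bp
            rows.append((parts[0], parts[1], int(parts[3])))
    if not rows:
        return MarkerMap(
            np.array([], dtype=object),
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=object),
            np.array([], dtype=object),
        )
    chrom, mid, pos = zip(*rows)
    m = len(rows)
    return MarkerMap(
        np.array(mid, dtype=object),
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(["?"] * m, dtype=object),
        np.array(["?"] * m, dtype=object),
    )


def read_plink_text(ped_path, map_path, recode_minor: bool = False) -> GenotypeDataset:
    """Read a PLINK text fileset into dosages of the A2 allele.

    The first allele observed at each marker becomes allele1; the second
    distinct allele becomes allele2, whose copies the dosage counts. "0 0"
    is a missing call. With ``recode_minor`` the dataset is re-oriented so
    allele2 is the minor allele.
    """
    mmap = _read_map(map_path)
    m = len(mmap)
    sample_ids: list[str] = []
    fam: list[list[str]] = []
    geno_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} markers), found {len(parts)}"
                )
            fam.append(parts[:6])
            sample_ids.append(parts[1])
            geno_rows.append(
                [(parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(m)]
            )

    n = len(sample_ids)
    allele1 = np.array(["?"] * m, dtype=object)
    allele2 = np.array(["?"] * m, dtype=object)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for k in range(m):
        seen = sorted({a for i in range(n) for a in geno_rows[i][k] if a != "0"})
        if len(seen) > 2:
            raise GenotypeFormatError(
                f"marker {mmap.marker_id[k]}: more than 2 distinct alleles {seen}"
            )
        # .map files carry no allele columns, so orientation is fixed by a
        # deterministic convention: alleles sorted, allele2 = the larger.
        a1 = seen[0] if seen else "?"
        a2 = seen[1] if len(seen) > 1 else a1
        allele1[k], allele2[k] = a1, a2
        for i in range(n):
            x, y = geno_rows[i][k]
            if x == "0" or y == "0":
                continue
            dosage[i, k] = (x == a2) + (y == a2) if a1 != a2 else 0
    markers = MarkerMap(mmap.marker_id, mmap.chromosome, mmap.position_bp, allele1, allele2)
    info = pd.DataFrame(
        fam, columns=["family_id", "sample_id", "sire_id", "dam_id", "sex", "phenotype"]
    ) if fam else None
    ds = GenotypeDataset(sample_ids, markers, dosage, info)
    return ds.recode_minor() if recode_minor else ds


# ---------------------------------------------------------------------------
# PLINK-1 binary (.bed / .bim / .fam), SNP-major
# ---------------------------------------------------------------------------

# 2-bit code -> dosage of allele2: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.full(4, MISSING, dtype=np.int8)
_BED_DECODE[0b00] = 0
_BED_DECODE[0b10] = 1
_BED_DECODE[0b11] = 2
_BED_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


def _read_bim(bim_path) -> MarkerMap:
    df = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele1", "allele2"],
        dtype=str,
    )
    if df.empty:
        return _read_map_empty()
    return MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chromosome"].to_numpy(dtype=object),
        df["position_bp"].astype(np.int64).to_numpy(),
        df["allele1"].to_numpy(dtype=object),
        df["allele2"].to_numpy(dtype=object),
    )


def _read_map_empty() -> MarkerMap:
    z = np.array([], dtype=object)
    return MarkerMap(z, z.copy(), np.array([], dtype=np.int64), z.copy(), z.copy())


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK-1 binary fileset (SNP-major ``.bed``)."""
    markers = _read_bim(bim_path)
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["family_id", "sample_id", "sire_id", "dam_id", "sex", "phenotype"],
        dtype=str,
    ) if _nonempty(fam_path) else pd.DataFrame(
        columns=["family_id", "sample_id", "sire_id", "dam_id", "sex", "phenotype"]
    )
    sample_ids = fam["sample_id"].tolist()
    n, m = len(sample_ids), len(markers)

    raw = open(bed_path, "rb").read()
    if raw[:2] != PLINK_MAGIC or raw[2:3] != SNP_MAJOR:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic/mode bytes {raw[:3]!r}; "
            "expected 6c 1b 01 (PLINK-1 SNP-major)"
        )
    bpm = (n + 3) // 4  # bytes per marker block
    if len(raw) != 3 + bpm * m:
        raise GenotypeFormatError(
            f"{bed_path}: {len(raw)} bytes, expected 3 + {bpm} x {m} = {3 + bpm * m} "
            "(truncated or wrong .fam/.bim?)"
        )
    if m == 0 or n == 0:
        dosage = np.zeros((n, m), dtype=np.int8)
    else:
        body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
        # expand each byte into 4 two-bit codes, low bits first
        codes = np.empty((m, bpm * 4), dtype=np.uint8)
        for shift in range(4):
            codes[:, shift::4] = (body >> (2 * shift)) & 0b11
        dosage = _BED_DECODE[codes[:, :n]].T.copy()
    return GenotypeDataset(sample_ids, markers, dosage, fam if len(fam) else None)


def _nonempty(path) -> bool:
    import os

    return os.path.exists(path) and os.path.getsize(path) > 0


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genotypes(dataset: GenotypeDataset, prefix, format: str = "text") -> list[str]:
    """Write ``dataset`` as PLINK text (.ped/.map) or binary (.bed/.bim/.fam).

    Returns the list of paths written. Round-trips through the matching
    reader reproduce the dataset exactly.
    """
    prefix = str(prefix)
    mk = dataset.markers
    a1 = np.where(mk.allele1 == "?", "A", mk.allele1)
    a2 = np.where(mk.allele2 == "?", "G", mk.allele2)
    # degenerate monomorphic markers: make the pair writable
    a2 = np.where(a1 == a2, np.where(a1 == "A", "G", "A"), a2)
    info = dataset.sample_info
    if info is None:
        info = pd.DataFrame(
            {
                "family_id": dataset.sample_ids,
                "sample_id": dataset.sample_ids,
                "sire_id": "0",
                "dam_id": "0",
                "sex": "0",
                "phenotype": "-9",
            }
        )
    if format == "text":
        map_path, ped_path = prefix + ".map", prefix + ".ped"
        with open(map_path, "w") as fh:
            for c, i, p in zip(mk.chromosome, mk.marker_id, mk.position_bp):
                fh.write(f"{c}\t{i}\t0\t{p}\n")
        pair = {0: None, 1: None, 2: None, MISSING: ("0", "0")}
        with open(ped_path, "w") as fh:
            for s in range(dataset.n_samples):
                fields = list(info.iloc[s][["family_id", "sample_id", "sire_id", "dam_id", "sex", "phenotype"]].astype(str))
                row = dataset.dosage[s]
                for k in range(dataset.n_markers):
                    x = row[k]
                    if x == MISSING:
                        fields += ["0", "0"]
                    elif x == 0:
                        fields += [a1[k], a1[k]]
                    elif x == 1:
                        fields += [a1[k], a2[k]]
                    else:
                        fields += [a2[k], a2[k]]
                fh.write(" ".join(fields) + "\n")
        return [ped_path, map_path]

    if format == "binary":
        bed_path, bim_path, fam_path = prefix + ".bed", prefix + ".bim", prefix + ".fam"
        with open(bim_path, "w") as fh:
            for c, i, p, x, y in zip(mk.chromosome, mk.marker_id, mk.position_bp, a1, a2):
                fh.write(f"{c}\t{i}\t0\t{p}\t{x}\t{y}\n")
        with open(fam_path, "w") as fh:
            for s in range(dataset.n_samples):
                fh.write(" ".join(info.iloc[s][["family_id", "sample_id", "sire_id", "dam_id", "sex", "phenotype"]].astype(str)) + "\n")
        n, m = dataset.n_samples, dataset.n_markers
        bpm = (n + 3) // 4
        with open(bed_path, "wb") as fh:
            fh.write(PLINK_MAGIC + SNP_MAJOR)
            for k in range(m):
                block = bytearray(bpm)
                col = dataset.dosage[:, k]
                for s in range(n):
                    block[s // 4] |= _BED_ENCODE[int(col[s])] << (2 * (s % 4))
                fh.write(bytes(block))
        return [bed_path, bim_path, fam_path]

    raise ValueError(f"unknown format {format!r}; use 'text' or 'binary'")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path, unknown_codes: tuple[str, ...] = ("0", "", ".", "NA")) -> PedigreeTable:
    """Read a delimited animal/sire/dam table (header optional).

    Any parent code in ``unknown_codes`` is normalized to "0". Rows may be
    in any order; the topological order is computed on load, and a cycle
    raises :class:`PedigreeError` naming one offending chain.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None)
    first = [str(v).lower() for v in df.iloc[0]]
    if any(h in first for h in ("animal", "animal_id", "id", "sire", "sire_id")):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: need at least 3 columns (animal, sire, dam)")
    norm = lambda v: "0" if (pd.isna(v) or str(v).strip() in unknown_codes) else str(v).strip()
    animal = [norm(v) for v in df.iloc[:, 0]]
    sire = [norm(v) for v in df.iloc[:, 1]]
    dam = [norm(v) for v in df.iloc[:, 2]]
    if "0" in animal:
        raise PedigreeError(f"{path}: animal id uses the unknown-parent code")
    for a, s, d in zip(animal, sire, dam):
        if a in (s, d):
            raise PedigreeError(f"pedigree contains a cycle: {a} -> {a}")
    sex = [str(v) for v in df.iloc[:, 3]] if df.shape[1] > 3 else None
    return PedigreeTable(animal, sire, dam, sex=sex)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)
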