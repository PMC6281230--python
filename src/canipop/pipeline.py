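"""End-to-end breed-characterization runs.

A single configuration drives the full analysis graph:

    io -> QC -> [pedigree A, F] -> GRM / IBS -> ROH / F_ROH
       -> LD decay -> Ne trajectory -> MDS / NJ / admixture

Per-breed statistics (mean F_ROH, recent Ne) are produced when the sample
metadata carries a breed label; breeds below ``min_breed_size`` (default
10) are excluded from per-breed tables. Every stage writes its table under
the output directory and the report records a checksum manifest, so each
reported number can be recomputed from the emitted files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grm, ldne, pedigree, qc, roh, structure
from .io import (
    GenotypeDataset,
    read_pedigree,
    read_plink_binary,
    read_plink_text,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_genotypes"]


@dataclass
class RunConfig:
    """Everything a run needs; file paths may be None for programmatic use."""

    genotype_prefix: str | None = None
    genotype_format: str = "text"  # or "binary"
    pedigree_path: str | None = None
    out_dir: str = "canipop_out"
    seed: int = 0
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    ne_params: ldne.NeParams = field(default_factory=ldne.NeParams)
    ld_max_distance_bp: int = 1_000_000
    ld_bin_step_bp: int = 20_000
    mds_k: int = 3
    K_list: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    cv_folds: int = 5
    breed_column: str = "family_id"
    min_breed_size: int = 10
    run_admixture: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("qc_thresholds", qc.QCThresholds),
            ("roh_params", roh.ROHParams),
            ("ne_params", ldne.NeParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


@dataclass
class RunReport:
    summary: dict
    manifest: dict  # path -> sha256

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary, "manifest": self.manifest}, fh, indent=2, sort_keys=True)


def load_genotypes(config: RunConfig) -> GenotypeDataset:
    p = config.genotype_prefix
    if p is None:
        raise ValueError("no genotype_prefix configured")
    if config.genotype_format == "binary":
        return read_plink_binary(p + ".bed", p + ".bim", p + ".fam")
    return read_plink_text(p + ".ped", p + ".map")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _breeds(ds: GenotypeDataset, column: str) -> pd.Series | None:
    if ds.sample_info is not None and column in ds.sample_info.columns:
        labels = ds.sample_info[column].astype(str)
        if labels.nunique() > 1:
            return labels.reset_index(drop=True)
    return None


def run_pipeline(
    config: RunConfig, dataset: GenotypeDataset | None = None
) -> RunReport:
    """Execute the full characterization run; returns the report.

    ``dataset`` bypasses genotype file loading (synthetic panels). A
    missing pedigree skips the pedigree stages with a notice rather than
    failing the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "notices": []}
    files: list[Path] = []

    ds = dataset if dataset is not None else load_genotypes(config)
    ds = ds.sort_markers()

    # --- QC ---
    ds, qc_report = qc.apply_qc(ds, config.qc_thresholds)
    qc_path = out / "qc_report.tsv"
    qc_report.to_frame().to_csv(qc_path, sep="\t", index=False)
    files.append(qc_path)
    summary["qc"] = {
        "markers_in": qc_report.n_markers_in,
        "markers_out": qc_report.n_markers_out,
        "samples_in": qc_report.n_samples_in,
        "samples_out": qc_report.n_samples_out,
    }
    if ds.n_markers == 0 or ds.n_samples == 0:
        summary["notices"].append("QC removed everything; downstream stages skipped")
        return _finish(summary, files, out)

    breeds = _breeds(ds, config.breed_column)

    # --- pedigree ---
    A = None
    if config.pedigree_path:
        ped = read_pedigree(config.pedigree_path)
        A = pedigree.additive_relationship_matrix(ped)
        A.write_tsv(out / "pedigree_A.tsv")
        f_tab = pedigree.pedigree_inbreeding(ped)
        f_tab.to_csv(out / "pedigree_F.tsv", sep="\t", index=False)
        pergen = pedigree.per_generation_inbreeding(ped)
        pergen.to_csv(out / "pedigree_F_per_generation.tsv", sep="\t", index=False)
        files += [out / "pedigree_A.tsv", out / "pedigree_F.tsv", out / "pedigree_F_per_generation.tsv"]
        genotyped = [a for a in ped.animal_id if a in set(ds.sample_ids)]
        summary["pedigree"] = {
            "n_animals": len(ped),
            "mean_F": f_tab.attrs["mean_F"],
            "sd_F": f_tab.attrs["sd_F"],
            "mean_depth_genotyped": pedigree.generation_number(ped).mean_depth(genotyped or None),
        }
    else:
        summary["notices"].append("no pedigree supplied; pedigree stages skipped")

    # --- GRM / IBS ---
    G = grm.genomic_relationship_matrix(ds)
    G.write_tsv(out / "grm.tsv")
    D = grm.ibs_distance_matrix(ds)
    D.write_tsv(out / "ibs_distance.tsv")
    files += [out / "grm.tsv", out / "ibs_distance.tsv"]
    if A is not None and len(set(A.labels) & set(G.labels)) >= 3:
        summary["r_g_a"] = {
            "off_diagonal": grm.matrix_correlation(G, A, mode="off_diagonal"),
            "all": grm.matrix_correlation(G, A, mode="all"),
        }

    # --- ROH / F_ROH ---
    rohset = roh.detect_roh(ds, config.roh_params)
    rohset.write_tsv(out / "roh_segments.tsv")
    genome_len = roh.autosomal_genome_length(ds)
    froh_tab = roh.froh(rohset, genome_len, list(ds.sample_ids))
    froh_tab.write_tsv(out / "froh.tsv")
    files += [out / "roh_segments.tsv", out / "froh.tsv"]
    fr = froh_tab.table["froh"]
    summary["froh"] = {"mean": float(fr.mean()), "sd": float(fr.std(ddof=1)) if len(fr) > 1 else None}
    if A is not None and config.pedigree_path:
        fped = pedigree.pedigree_inbreeding(read_pedigree(config.pedigree_path))
        joint = froh_tab.table.merge(fped, left_on="sample_id", right_on="animal_id")
        if len(joint) >= 3 and joint["F"].std() > 0 and joint["froh"].std() > 0:
            summary["froh"]["corr_with_pedigree_F"] = float(
                np.corrcoef(joint["F"], joint["froh"])[0, 1]
            )

    # --- LD / Ne (per breed when labels present, else whole panel) ---
    edges = np.arange(0, config.ld_max_distance_bp + config.ld_bin_step_bp, config.ld_bin_step_bp)
    groups: list[tuple[str, np.ndarray]] = [("ALL", np.arange(ds.n_samples))]
    if breeds is not None:
        counts = breeds.value_counts()
        groups += [
            (b, np.flatnonzero((breeds == b).to_numpy()))
            for b in sorted(counts.index[counts >= config.min_breed_size])
        ]
    ne_summary = []
    for name, idx in groups:
        sub = ds.subset(samples=idx)
        pairs = ldne.pairwise_r2(sub, config.ld_max_distance_bp)
        if pairs.empty:
            summary["notices"].append(f"no syntenic pairs for group {name}")
            continue
        decay = ldne.ld_decay(pairs, edges)
        decay.to_csv(out / f"ld_decay_{name}.tsv", sep="\t", index=False)
        files.append(out / f"ld_decay_{name}.tsv")
        ne = ldne.estimate_ne(decay, sub.n_samples, config.ne_params)
        ne.to_csv(out / f"ne_trajectory_{name}.tsv", sep="\t", index=False)
        files.append(out / f"ne_trajectory_{name}.tsv")
        if len(ne):
            recent = ne.iloc[0]  # smallest t = most recent
            ne_summary.append(
                {
                    "group": name,
                    "n": int(sub.n_samples),
                    "recent_t": int(recent["t"]),
                    "recent_ne": float(recent["ne"]),
                    "mean_froh": float(froh_tab.table.set_index("sample_id").loc[list(sub.sample_ids), "froh"].mean()),
                }
            )
    summary["ne"] = ne_summary

    # --- structure ---
    mds = structure.classical_mds(D, k=config.mds_k)
    mds.to_frame().to_csv(out / "mds_coordinates.tsv", sep="\t")
    files.append(out / "mds_coordinates.tsv")
    tree_dm, tree_labels = D, list(D.labels)
    if breeds is not None and breeds.nunique() >= 3:
        tree_dm = _breed_mean_distance(D, breeds)
        tree_labels = tree_dm.labels
    if len(tree_labels) >= 3:
        newick = structure.nj_tree(tree_dm, tree_labels)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        files.append(out / "nj_tree.nwk")
    if config.run_admixture:
        cv = structure.admixture_cv(ds, config.K_list, folds=config.cv_folds, seed=config.seed)
        cv.table.to_csv(out / "admixture_cv.tsv", sep="\t", index=False)
        files.append(out / "admixture_cv.tsv")
        fit = structure.admixture_fit(ds, cv.selected_K, seed=config.seed)
        fit.q_frame().to_csv(out / "admixture_Q.tsv", sep="\t")
        pd.DataFrame(fit.P).to_csv(out / "admixture_P.tsv", sep="\t", index=False)
        files += [out / "admixture_Q.tsv", out / "admixture_P.tsv"]
        summary["admixture"] = {"selected_K": cv.selected_K, "loglik": fit.loglik}

    return _finish(summary, files, out)


def _breed_mean_distance(D: grm.DistanceMatrix, breeds: pd.Series) -> grm.DistanceMatrix:
    """Breed-level distances: mean between-sample IBS distance per breed pair."""
    labels = sorted(breeds.unique())
    n = len(labels)
    M = np.zeros((n, n))
    idx = {b: np.flatnonzero((breeds == b).to_numpy()) for b in labels}
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            M[i, j] = M[j, i] = float(D.values[np.ix_(idx[a], idx[b])].mean())
    return grm.DistanceMatrix(labels, M)


def _finish(summary: dict, files: list[Path], out: Path) -> RunReport:
    manifest = {str(p.relative_to(out)): _sha256(p) for p in files}
    report = RunReport(summary, manifest)
    report.write(out / "run_report.json")
    return report
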