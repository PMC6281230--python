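"""ROH window scan, run filters, oracle agreement and F_ROH."""

import numpy as np
import pytest

from canipop.roh import (
    ROHParams,
    ROHSet,
    ROHSegment,
    autosomal_genome_length,
    detect_roh,
    detect_roh_oracle,
    froh,
    window_scan,
)
from canipop.simulate import plant_roh, sim_founders
from conftest import toy_dataset


class TestWindowScan:
    def test_three_hets_fail_a_window(self):
        x = np.zeros(50, dtype=np.int8)
        x[[10, 20, 30]] = 1
        # single window, 3 hets -> fails -> hit rate 0 everywhere
        assert not window_scan(x).any()

    def test_fully_homozygous_chromosome_all_eligible(self):
        x = np.full(120, 2, dtype=np.int8)
        assert window_scan(x).all()

    def test_single_het_tolerated_everywhere(self):
        x = np.zeros(200, dtype=np.int8)
        x[100] = 1
        assert window_scan(x).all()

    def test_two_missing_tolerated_three_not(self):
        x = np.zeros(50, dtype=np.int8)
        x[[5, 6]] = -1
        assert window_scan(x).all()
        x[7] = -1
        assert not window_scan(x).any()

    def test_short_chromosome_has_no_windows(self):
        assert not window_scan(np.zeros(49, dtype=np.int8)).any()


class TestDetect:
    def test_alternating_hets_give_zero_roh(self):
        dosage = np.tile([0, 1], 300)[None, :]
        assert len(detect_roh(toy_dataset(dosage))) == 0

    def test_short_run_rejected_on_length(self):
        # 60 homozygous SNPs spanning ~80 kb < 100 kb minimum
        background = np.tile([1, 1], 400)
        x = np.concatenate([background[:200], np.zeros(60, np.int8), background[:200]])
        ds = toy_dataset(x[None, :], spacing_bp=1350)
        assert len(detect_roh(ds)) == 0

    def test_planted_segment_recovered_with_exact_bounds(self):
        # 400-SNP homozygous stretch at 5 kb spacing (2 Mb) in het background
        ds, _ = sim_founders(1, 2000, chromosomes=1, seed=3, spacing_bp=5000)
        start, end = 500 * 5000 + 1, 900 * 5000 + 1
        planted, _ = plant_roh(ds, [("F1", "1", start, end)], background="het", seed=4)
        segs = detect_roh(planted).segments
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (start, end)
        assert segs[0].snp_count == 401

    def test_run_split_at_large_gap(self):
        # two homozygous blocks of 60 SNPs with a 150 kb gap between them
        import numpy as np
        from canipop.io import GenotypeDataset, MarkerMap

        pos = np.concatenate([np.arange(60) * 2000 + 1, np.arange(60) * 2000 + 270_001])
        mk = MarkerMap(
            np.array([f"m{i}" for i in range(120)], dtype=object),
            np.array(["1"] * 120, dtype=object),
            pos,
            np.array(["A"] * 120, dtype=object),
            np.array(["G"] * 120, dtype=object),
        )
        ds = GenotypeDataset(["s"], mk, np.zeros((1, 120), dtype=np.int8))
        params = ROHParams(min_snps=50, min_length_bp=100_000, max_gap_bp=100_000,
                           min_density=1 / 50_000)
        segs = detect_roh(ds, params).segments
        # each 118-kb block passes alone; the gap forbids one merged run
        assert len(segs) == 2
        assert all(s.snp_count == 60 for s in segs)


class TestOracle:
    def test_agrees_on_clean_planted_fixture(self):
        ds, _ = sim_founders(2, 2000, chromosomes=1, seed=9, spacing_bp=5000)
        segs = [("F1", "1", 300 * 5000 + 1, 700 * 5000 + 1),
                ("F2", "1", 900 * 5000 + 1, 1400 * 5000 + 1)]
        planted, _ = plant_roh(ds, segs, background="het", seed=10)
        w = detect_roh(planted).to_frame()
        o = detect_roh_oracle(planted).to_frame()
        assert w.equals(o)

    def test_interior_het_splits_oracle_but_not_window_scan(self):
        ds, _ = sim_founders(1, 2000, chromosomes=1, seed=11, spacing_bp=5000)
        planted, _ = plant_roh(ds, [("F1", "1", 300 * 5000 + 1, 1300 * 5000 + 1)],
                               background="het", seed=12)
        d = planted.dosage.copy()
        d[0, 800] = 1  # one genotyping error inside the run
        broken = toy_dataset(d, spacing_bp=5000)
        assert len(detect_roh_oracle(broken)) == 2
        assert len(detect_roh(broken)) == 1  # window allowance bridges it

    def test_empty_dataset_gives_empty_set(self):
        ds = toy_dataset(np.zeros((0, 0), dtype=np.int8))
        assert len(detect_roh_oracle(ds)) == 0


class TestFroh:
    def test_arithmetic(self):
        rs = ROHSet([ROHSegment("s", "1", 1, 100_000_000, 2000)])
        tab = froh(rs, 2_000_000_000, ["s"]).table
        assert tab["froh"][0] == pytest.approx(0.05)

    def test_zero_roh_zero_froh(self):
        tab = froh(ROHSet([]), 1_000_000, ["a", "b"]).table
        assert (tab["froh"] == 0).all()

    def test_total_exceeding_genome_raises(self):
        rs = ROHSet([ROHSegment("s", "1", 1, 2_000_000, 50)])
        with pytest.raises(ValueError, match="exceeds genome length"):
            froh(rs, 1_000_000, ["s"])

    def test_monotone_in_planted_length(self):
        ds, _ = sim_founders(1, 4000, chromosomes=2, seed=13, spacing_bp=5000)
        glen = autosomal_genome_length(ds)
        prev = -1.0
        for n_snps in (100, 400, 800):
            planted, _ = plant_roh(
                ds, [("F1", "1", 300 * 5000 + 1, (300 + n_snps) * 5000 + 1)],
                background="het", seed=14,
            )
            val = froh(detect_roh(planted), glen, ["F1"]).table["froh"][0]
            assert val > prev
            prev = val

    def test_genome_length_from_map(self):
        ds = toy_dataset(np.zeros((1, 10), dtype=np.int8), chromosomes=2, spacing_bp=1000)
        # two chromosomes of 5 SNPs spanning 4001 bp each
        assert autosomal_genome_length(ds) == 2 * 4001
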