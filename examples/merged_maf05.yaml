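# Merged multi-breed panel with the stricter MAF >= 5% marker set used for
# between-breed structure (MDS, NJ tree, admixture clustering).
genotype_prefix: data/merged_panel
genotype_format: binary
out_dir: out/merged_maf05
seed: 1
qc_thresholds:
  min_call_rate: 0.95
  min_maf: 0.05
  max_sample_missing: 0.10
min_breed_size: 1        # structure analyses keep every breed
mds_k: 3
K_list: [2, 4, 8, 16]
cv_folds: 5
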