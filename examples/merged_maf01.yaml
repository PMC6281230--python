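# Merged multi-breed panel: the permissive marker set used for ROH, LD and
# Ne estimation (MAF >= 1%; breeds under 10 animals excluded from per-breed
# statistics).
genotype_prefix: data/merged_panel      # .ped/.map or .bed/.bim/.fam prefix
genotype_format: binary
out_dir: out/merged_maf01
seed: 1
qc_thresholds:
  min_call_rate: 0.95
  min_maf: 0.01
  max_sample_missing: 0.10
min_breed_size: 10
K_list: [2, 4, 8, 16]
cv_folds: 5
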