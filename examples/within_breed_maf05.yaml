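# Single-breed analysis: pedigree vs genomic relationships, inbreeding and
# LD/Ne inside one breed (MAF >= 5% within the breed itself).
genotype_prefix: data/focal_breed
genotype_format: text
pedigree_path: data/focal_breed_pedigree.tsv
out_dir: out/within_breed
seed: 1
qc_thresholds:
  min_call_rate: 0.95
  min_maf: 0.05
  max_sample_missing: 0.10
run_admixture: false     # a single closed breed: clustering is uninformative
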