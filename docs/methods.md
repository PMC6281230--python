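# Methods

This note documents the models behind each stage, the defaults and why
they are set as they are, what the synthetic-data generators do and do not
emulate, and the numerical choices that were genuinely open.

## Genotype representation and I/O

Genotypes are dosages of the A2 allele (0/1/2, −1 missing) over a marker
map with 1-based physical positions; chromosomes 1–38 are canine
autosomes, everything else is flagged non-autosomal. PLINK-1 binary files
are decoded strictly by the 2-bit table (00 hom-A1, 01 missing, 10 het, 11
hom-A2, low bits first, SNP-major) and round-trip byte-exactly. PLINK
*text* files carry no allele columns, so the reader fixes orientation by a
deterministic convention (alleles sorted, A2 = the larger string); the
orientation of a marker at which only one allele is ever observed is not
recoverable from a `.ped` at all — such markers read back as dosage 0.
`GenotypeDataset.recode_minor()` restores the analysis-side convention
(A2 = minor) whenever orientation matters for reporting; none of the
estimators here depend on it, since every formula is symmetric under
p ↔ 1−p with dosage x ↔ 2−x.

## Quality control

Filters run in a fixed order — unmapped, non-autosomal, call rate, MAF,
then sample missingness — with strict inequalities at the printed
thresholds (call rate < 0.95 removed; MAF < 0.01 or 0.05 removed;
sample missingness > 0.10 removed). MAF is min(p, 1−p) over non-missing
calls, computed once after the marker filters; it is *not* recomputed
after sample removal (single pass). Raising the MAF cutoff can therefore
only shrink the marker set, and re-applying a filter set is a no-op — both
properties are tested.

## Pedigree relationships

**A** is built by the tabular method in topological order: founders
aᵢᵢ = 1, aᵢⱼ = ½(a_{j,sire} + a_{j,dam}), aᵢᵢ = 1 + ½·a_{sire,dam},
missing-parent terms zero. Ids referenced as parents but absent from the
table are treated as new founders. Generation number is the
maximum-generations-traced definition (founders 0, child = 1 + max over
known parents) — the common registry convention; mean depth is reported
over a caller-chosen focal subset (typically the genotyped animals).
A is positive semidefinite by construction (covariance of breeding
values); tests verify the smallest eigenvalue ≥ −1e−8 on random
pedigrees and agreement with Wright's path counting on hand-enumerable
ones.

## Genomic relationships and IBS distances

The GRM uses the locus-by-locus scaling with allele frequencies estimated
from the analyzed sample itself (no external reference panel exists for
these data). Missing genotypes are handled pairwise-complete — each pair
averages over the loci typed in both animals — rather than mean-imputed,
so sparse genotypes degrade variance, not bias. Monomorphic loci are
excluded. The IBS distance uses the shared-allele score 2 − |xᵢ − xⱼ|.
The G-vs-A correlation is reported for the off-diagonal entries by
default *and* for all entries including the diagonal: published values of
r₉,ₐ rarely state which was used, and the two can differ when inbreeding
varies.

## ROH detection

The windowed scan mirrors PLINK `--homozyg`: 50-SNP step-1 windows pass
with ≤ 2 heterozygous and ≤ 2 missing calls; a SNP's hit rate divides its
passing windows by the windows that actually contain it (edge SNPs sit in
fewer); eligibility requires hit rate strictly above 0.05. Candidate runs
of eligible SNPs are split at inter-marker gaps > 100 kb and kept at
≥ 50 SNPs, ≥ 100 kb and ≥ 1 SNP per 50 kb. Segment coordinates are the
first/last SNP positions — no extrapolation into flanking intervals.
There is no run-level heterozygote cap beyond the window mechanics, so an
isolated genotyping error inside a long run does not break it (the
exhaustive oracle, which demands strict homozygosity, splits there — a
deliberate, tested difference).

Two edge behaviors matter for validation fixtures. First, near chromosome
ends the shrinking hit-rate denominator can make a single flanking
heterozygous SNP eligible, extending a run by one position; detector ≡
oracle equality therefore holds for segments planted at least one window
from chromosome ends, which is how the equivalence fixtures are built.
Second, under a Hardy–Weinberg background chance runs of homozygous
background SNPs extend true segments in both detectors; exact
segment-for-segment equality is checked on fully heterozygous
backgrounds, and recall (≥ 95% under 0.5% heterozygote-error injection)
on Hardy–Weinberg backgrounds.

F_ROH divides total ROH length by the autosomal genome length; by default
that length is Σ over chromosomes of (last − first SNP position + 1) from
the analyzed map, with a fixed constant available when comparability
across marker sets matters.

**Array-density adaptation.** The default gap (100 kb) and density
(1/50 kb) values assume a dense array (~20 kb spacing). On sparser maps —
including the ~190 kb-spaced simulated panels used in the F_ROH recovery
runs — those run-level parameters must be scaled with the spacing
(400 kb gap, 1/250 kb density in the recovery harness), exactly as PLINK
users do on low-density panels; otherwise every run is rejected by
construction.

## LD and effective population size

r² is the squared Pearson correlation of dosage vectors
(composite/genotypic LD): the data are unphased, and dosage correlation
avoids haplotype-frequency estimation entirely; an EM haplotype-based r²
is out of scope. Pairs are formed within chromosomes up to 1 Mb by
default, binned at 20 kb. Physical distance maps to Morgans at 1 cM/Mb
(configurable) — no public fine-scale canine recombination map is assumed.

Sved's drift–recombination balance E[r²] ≈ 1/(α + 4Nc) is inverted per
bin with the bin midpoint as c (bins are narrow; the midpoint-vs-mean
distinction is negligible), the sample correction r²adj = r² − 1/(βn)
with β = 1 for genotypic correlations, and α = 2 by default (the
mutation-adjusted variant used by the common Ne-from-LD tools); α = 1 and
2.2 are selectable. Bins whose corrected r² or resulting Ne is
non-positive are dropped. The time interpretation t = 1/(2c) makes the
trajectory's t strictly decreasing in distance.

Validation: on constant-size Wright–Fisher panels (N = 100, 4N burn-in,
50 sampled diploids, 20 × 1000 SNPs) the recent-bin estimate lands within
a factor of two of truth, and binned mean r² agrees with
1/(1 + 4Nc) + 1/n within 15% at mid-range c (4Nc between 0.5 and 4) —
15% rather than a pure Monte-Carlo band because Sved's formula is itself
an approximation that is known to overshoot at large c.

**Bottleneck scenario.** A sustained 10× census collapse *inside* an
equilibrium simulation adds so much drift (≈ G/2N_b) that it inflates LD
at every distance and erases the ancestral signal — no LD-based method
can then show the ancestral size. The declining-Ne pattern characteristic
of breed histories is instead reproduced by its actual generating
process: founders at linkage equilibrium (an effectively infinite
ancestral population) followed by ~30 generations at breed size, which
yields low Ne at small t and large Ne at large t, as observed in real
breed panels.

## Population structure

Classical MDS is Torgerson scaling — eigendecomposition of
−½·J·D∘D·J — keeping the top-k positive eigenvalues (negative ones,
which arise for non-Euclidean IBS matrices, are reported but excluded;
fewer than k positive eigenvalues return fewer columns). It is exact on
Euclidean inputs to machine precision and cross-checked against
scikit-bio's PCoA.

Neighbor joining delegates to scikit-bio's Saitou–Nei implementation with
negative branch lengths clamped to zero; exactness on additive matrices
(path metric equals input) is the test oracle. Breed-level trees use the
mean between-sample IBS distance per breed pair.

The admixture model is the ADMIXTURE/frappe binomial likelihood,
maximized by plain EM — identical model and stationary points, without
the quasi-Newton acceleration; adequate at the panel sizes targeted here
(hundreds of samples, 10³–10⁵ markers) and monotone by construction,
which the tests assert iteration-by-iteration. π is clipped to
[1e−10, 1 − 1e−10]; missing genotypes contribute to no sum. Defaults: 3
seeded restarts keeping the best likelihood (ties to the lowest restart
index), absolute log-likelihood tolerance 1e−4, 2000 iterations.
Cross-validation masks random folds of observed genotype *entries*
(identical masks for every K), refits, and scores mean squared prediction
error (x − 2π̂)² on the held-out entries; the deviance-based error is a
possible alternative not implemented. CV fits use a coarser tolerance
(1e−2, 500 iterations): ranking K does not need fully polished optima,
and this keeps 5-fold × multi-K runs inside interactive time.

At the validation conditions (K = 2, Fst = 0.1, n = 100, m = 1000,
Dirichlet(0.5) ancestries) the EM reaches the maximum-likelihood estimate
(verified against longer runs and multiple restarts), whose Q-RMSE
against the simulated truth is dominated by statistical information, not
optimization: about 0.05 on average across panel realizations (0.042–0.059
over seeds). Recovery materially below that would require more markers or
stronger differentiation, not a better optimizer.

## Synthetic data

All generators are bit-reproducible from a seed and share one
recombination model: Haldane (no interference), switch probability
(1 − e^(−2d))/2 per marker interval, independent chromosomes at ½ — the
simplest defensible choice, and the one whose expectations (e.g. realized
F in gene dropping) are easy to state. Marker positions are evenly spaced
by default; spacing is configurable.

- `sim_founders`: i.i.d. haplotypes from a chosen frequency spectrum
  (uniform(0.05, 0.5) default; beta available for U-shaped spectra).
- `gene_drop`: transmits founder-allele *labels*, so autozygosity (both
  labels equal) and realized F are known exactly, not inferred; emitted
  genotypes are automatically homozygous inside IBD segments. Mean
  realized F of full-sib-mating offspring converges to the pedigree 0.25.
- `sim_wright_fisher`: discrete generations, random union of gametes, no
  mutation (array SNPs are pre-ascertained standing variation), default
  burn-in 4N; `size_history` phases express bottlenecks; markers fixed by
  drift are dropped and counted.
- `sim_breed_panel`: several breeds drifting independently from one
  ancestral frequency vector — the breed-formation scenario driving both
  between-breed differentiation and within-breed LD/ROH.
- `sim_admixture`: Balding–Nichols population frequencies around uniform
  ancestral frequencies, Dirichlet ancestries, binomial dosages; loci are
  independent (exactly the admixture model's assumption).
- `plant_roh`: homozygous segments (allele drawn by frequency) on a
  Hardy–Weinberg or fully heterozygous background, with optional per-SNP
  heterozygote-error injection; overlapping segments merge with a warning.

What these generators do *not* emulate: SNP ascertainment bias (real
array spectra are flattened toward common variants), crossover
interference, mutation, genotyping error outside planted segments,
sex chromosomes, and non-random mating within populations. Passing tests
therefore demonstrate correctness of the estimators under their own model
assumptions, not robustness to every artifact of real array data.

## Pipeline

Stages run in dependency order (I/O → QC → pedigree → GRM/IBS →
ROH/F_ROH → LD → Ne → MDS/NJ/admixture); a missing pedigree skips its
stages with a notice. Per-breed tables (recent Ne, mean F_ROH) appear
when sample metadata carries a breed label, excluding breeds under 10
animals by default. Every stage writes a TSV (trees as newick), the
report records a sha256 manifest, and all randomness flows from the
single configured seed, so a rerun is byte-identical and every summary
number is recomputable from the emitted files — both verified in tests.
Validation runs use scaled-down panel sizes (10³–10⁴ markers, tens of
samples) chosen so the whole suite exercises every stage at desk scale;
the estimators are O(n²m) or better and scale to array-sized data.

## Known limitations

- Ne point estimates are sensitive to binning, the cM/Mb constant, α and
  sample size; trajectory *shape* is robust, absolute values less so.
- The LD-based trajectory cannot see through strong sustained
  bottlenecks (see above) — a method property, not an implementation one.
- F_ROH depends on the genome-length denominator and on density-matched
  run parameters; defaults assume a dense array.
- Plain EM converges slowly near ridges of the admixture likelihood;
  for very large panels an accelerated optimizer would be preferable.
- Text-format PLINK I/O cannot preserve allele orientation at
  monomorphic markers (format limitation, documented above).
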