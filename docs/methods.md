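# Methods

## The problem and the model

Western European wild boar carry the Robertsonian fusion rob(15;17)
fixed (2n = 36); domestic pigs carry chromosomes 15 and 17 unfused
(2n = 38). A hybrid inherits one fused and one unfused complement
(2n = 37), and the fusion then segregates Mendelianly: a 2n = 36 parent
always transmits the fused centromere, a 2n = 38 parent never does, and
a 2n = 37 parent transmits it with probability 1/2. The offspring's
diploid number is 36 plus its count of unfused alleles, which yields the
classical expectations 25/50/25 (37×37), 50/50 (37×36 and 37×38) and
100% 2n = 37 (38×36). `simdata.transmit_karyotype` implements exactly
this two-allele model.

Because the fusion allele is physically the centromere of rob(15;17),
its state is locked to the *local ancestry* of the chromosomal segment
spanning the chr15/chr17 centromere junction: a wild-boar junction
haplotype is fused, a domestic one is not. That identity is what makes
an in-silico karyotype possible — infer the ancestry of the two
haplotypes at the junction and read off 2n — and it is built into the
simulator as an invariant.

## Synthetic data

`simdata` emulates the statistical structure the analysis assumes, not
pig genomes per se:

- **Panels.** Three source populations (wild boar, European domestic,
  Asian domestic) with per-SNP frequencies drawn Balding–Nichols:
  `f_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)` around ancestral
  frequencies `p ~ U(0.05, 0.95)`. `F` is a per-population Fst-like
  divergence; defaults (0.2, 0.2, 0.3) make the Asian panel the most
  diverged, mirroring the ordering seen in PC space on real pig data.
  The divergence values are calibration choices — no source states them —
  and they sit *below* realistic wild/domestic differentiation on
  ascertained chip SNPs, which is why tests pair them with chip-like
  marker densities (see below). Panel genotypes are binomial(2, f)
  draws; the reference panel itself carries the true frequencies clamped
  to [ε, 1−ε], ε = 1/(2n_k+2).
- **Meiosis.** Crossover counts are Poisson(r·L) with uniform placement
  and no interference — deliberately the same exponential-distance model
  the ancestry HMM assumes. Chromosomes 15 and 17 form a single linkage
  group on the fused coordinate system (chromosome 17 first; its true
  length 63,494,081 bp is the junction coordinate), with crossovers
  suppressed between the junction's two flanking SNPs. The suppression
  models pericentromeric recombination reduction and guarantees that the
  fusion allele, and the ancestry of both flanking markers, travel as one
  unit — which in turn makes karyotype prediction from exact tract
  dosages provably 100% accurate, a property the tests assert.
- **Genotypes.** Emitted per SNP as one Bernoulli draw per haplotype
  from the tract ancestry's panel frequency. Founder haplotypes carry no
  fixed alleles: the downstream methods consume unphased genotypes and
  panel frequencies only, so persistent founder haplotypes would add
  realism the estimators cannot see. This also means simulated data have
  no background LD within a source population — one reason synthetic
  benchmarks here say nothing about haplotype-model methods on real data.
- **Cohorts.** `simulate_admixed_cohort` defaults target the structure
  reported for French wild boar: ~40% unadmixed animals, the rest from
  hybridization events 2–8 generations back (expected domestic fraction
  2^-depth), ~10% of domestic contributions Asian, 2% missing genotypes
  (well under the 10% per-SNP filter cap). The genome-wide wild-boar
  fraction under these defaults is ≈95%. `simulate_karyotype_cohort`
  instead mimics a monitoring sample enriched for cytogenetic hybrids
  (30% pure, 10% F1, 25% F2, 35% backcrosses 2–12 generations deep), so
  all three karyotype classes are populated and the heterozygote is the
  genuinely hard class.
- Missingness is i.i.d.; real chips miss non-randomly. All randomness
  flows through one seeded generator per entry point; truth files record
  the seed in a `#` header line.

## Estimation components

**Supervised global ancestry.** For one individual with genotypes `g_m`
(alternate-allele counts, missing skipped) and fixed panel frequencies
`f_km`, the admixture log-likelihood
`Σ_m [g_m log Σ_k q_k f_km + (2−g_m) log Σ_k q_k (1−f_km)]` is concave
on the simplex and maximized by EM (allele-attribution update;
log-likelihood asserted non-decreasing every iteration; stop when the
gain falls below `tol` = 1e−7). Supervised estimation replaces an
unsupervised K-way clustering step on purpose: the downstream contrast
is exactly wild / European domestic / Asian domestic, and fixing the
panels removes the non-reproducible choice of K. Standard errors come
from resampling SNPs with replacement (200 replicates), expressed as
multinomial weights on the likelihood so all replicates share one panel
matrix and run as a single vectorized EM (replicate stopping rule 1e−4
on parameter change — replicates only feed a standard deviation). The
95% CI is q̂ ± 1.96·SE truncated to [0,1]; *unadmixed* means the WB
component's CI reaches 0.99 (a domestic fraction ≤1% cannot be
excluded), *recent-hybrid candidate* means q_WB < 0.60 (>40% domestic,
the level observed in PCA outliers). Whether the original analysis
bootstrapped SNPs or individuals is not stated; SNP resampling is the
natural choice for a per-individual estimate and is documented as such.

At 2,000 SNPs and divergence 0.1 the estimator's per-component SE is
≈0.03 — a Fisher-information floor, not an implementation artifact (the
EM optimum matches an independent derivative-free optimizer to <1e−5).
Recovery accuracy claims should therefore be read against that floor;
doubling SNPs or divergence shrinks it by √2.

**Local ancestry.** One diploid HMM serves both call sites. Hidden
state: the ordered pair of haplotype ancestries (K² = 9 states);
per-haplotype switch probability between adjacent SNPs at distance d of
`1 − exp(−g·r·d)`, new ancestry drawn from the mixture prior π; the two
haplotypes switch independently (no phasing needed), so the diploid
transition is a Kronecker square. Emissions multiply two Bernoulli
allele draws from panel frequencies and sum over orderings for the
unphased genotype; missing emits 1. Defaults are the standing
parameterization for detecting *modern* hybridization rather than
domestication-era gene flow: g = 25, r = 1e−8/bp,
π = (0.30, 0.66, 0.04). Decoding is scaled forward–backward per
chromosome (per-SNP normalization with a 1e−300 underflow guard;
correctness pinned by an exhaustive path-enumeration oracle at 1e−10)
or Viterbi for hard tracts. An individual with no genotype calls gets
the prior as its posterior, with a warning — the prior, not a uniform
distribution, is what zero data implies under this model.

Posterior dosages shrink toward the prior wherever data are sparse: at
~580 kb SNP spacing the shrinkage is substantial, at chip-like spacing
(~35–60 kb) it is a percent-level effect. Tests that quantify recovery
therefore fix marker density at chip scale; the sparse regime is a
property of the data, not a defect, and is visible in the dosage tracks.

**Karyotype prediction.** Chromosome maps are fused at their
centromeres (chromosome 15 position x ↦ 63,494,081 + x), and — the
detail that matters — the HMM for the junction is *decoded on the fused
chain*, so both flanking markers receive two-sided haplotype
information; decoded per chromosome they would sit at chain ends, where
one-sided posteriors systematically under-call homozygous wild boar.
The call takes the mean WB dosage of the `flank_window` = 1 nearest SNPs
per side (the first SNPs on both sides of the centromere; the window is
configurable for sensitivity analyses), averages the two flanks, and
rounds the implied fused-allele count, with exact .5 ties resolved to
2n = 37 — conservative, in that it flags the animal for follow-up
rather than clearing it. Concordance is reported as a 3×3 confusion
matrix (rows predicted, columns true) with column-normalized per-class
rates. The map fusion follows the operational transform (chr15 offset by
the chr17 length) without re-orienting acrocentric arms; if an assembly
placed these centromeres at low coordinates, a coordinate flip would be
needed first.

**Outlier detection.** PCA standardizes genotypes by 2p̂ and
√(2p̂(1−p̂)) (mean-imputed missing cells), takes the SVD, and fixes each
component's sign by its largest-magnitude score. Gaussian mixtures with
full covariance (5 restarts, fixed seed) are fitted on (PC1, PC2) for
k = 1..5 and selected by BIC; outliers are the individuals whose
maximum-posterior component is not the largest-weight component (ties to
the lower index). An optional density-quantile rule can additionally
flag low-density members of the majority component; it defaults to off,
since no source specifies how "not belonging to the cluster" was
thresholded. k = 1 selected ⇒ zero outliers, by construction. On
cohorts with a *continuum* of admixture (deep backcrosses), the mixture
split is a partition of a gradient and flags more than the recent
hybrids; the supervised q values are the arbiter in that situation.

**Scan.** Per-SNP mean WB proportion (dosage/2) across the cohort
(outliers excluded in the pipeline, as the cohort of interest is the
wild-boar cluster); μ and σ are the mean and SD of that per-SNP series;
intervals are maximal runs of SNPs below μ − kσ (k = 3 and 6), merged
across at most `max_gap` = 0 unflagged SNPs (conservative; configurable
for sparse maps) and reported at the bp of the first/last flagged SNP,
in BED (0-based half-open) and a 1-based TSV mirror. Averaging is per
SNP, since dosages exist only at SNPs. The SD rule is descriptive, not
a calibrated test; σ is inflated by any true signal in the series, which
makes the 6σ call conservative.

## Pipeline, determinism, problem sizes

`run_pipeline` spawns one child seed per stage from the config seed;
every output is TSV/BED/PED text with fixed float formatting, so
identical configs reproduce byte-identical outputs (asserted in tests).
The log records every parameter with its default (g = 25, r = 1e−8,
π = 0.30/0.66/0.04, MAF > 0.05, missing < 0.05, r² = 0.1,
n_boot = 200, chr17 length 63,494,081).

Problem sizes used by the test suite are desk-scale choices: the demo
config runs 150 animals and 3,000 SNPs on a ~194 Mb four-chromosome
genome (chip-like density; chromosome 17 always at its true length);
the karyotype benchmark uses 12,000 SNPs on a ~467 Mb genome (raw-chip
density) with 300-animal cohorts, pooling confusion matrices over three
seeds because per-seed class rates at the accuracy ceiling differ by
single animals; the scan benchmark uses 200 animals and 5,000 SNPs with
a 5.6 Mb injected interval on chromosome 13 at domestic dosage 0.8, and
a 20-seed null. The q-recovery suite uses 50 individuals at 2,000 SNPs.

## What passing tests do and do not show

The generator reproduces the *assumed* structure (frequency divergence,
recombinant mosaics, junction linkage) with no background LD, no
ascertainment bias, no genotyping error beyond i.i.d. missingness, and
founder-free panels. Passing benchmarks therefore validate the
estimators against their own model class at realistic marker densities;
they do not certify performance on real chips, where haplotype-based
local-ancestry methods exploit LD this HMM ignores, and where reference
panels are finite, related, and themselves partly admixed — the known
circularity of training "unadmixed" references selected by the very
admixture analysis being run. Known limitations, summarized: single
shared tie-break toward 2n = 37; per-SNP emission model (no
haplotype-cluster layer); prior-shrinkage of dosages on sparse maps;
mixture-model outlier calls on admixture continua; and the q-estimator
information floor at low divergence.
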