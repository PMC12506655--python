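# Methods

This note documents the statistical model, the simulation generator, and the
numerical and design decisions behind `biasgl`.

## 1. Mapping bias and its measurement

At a biallelic SNP with reference allele `R` and alternative allele `A`,
reads carrying `A` mismatch the linear reference and are lost during mapping
with some site-specific probability. The package measures this with a
flip-remap procedure:

1. Collect every mapped read overlapping a panel site (mapping quality and
   base quality at the site both ≥ 30 by default; duplicates optionally
   excluded; reads whose base at the site is neither panel allele are
   excluded from bias estimation but kept for genotype likelihoods).
2. For each read × overlapping-site pair, emit a modified copy of the read
   with the base at that one site flipped to the other allele. A read that
   spans k panel sites yields k copies, each modified at exactly one site.
3. Remap the modified copies with the same mapper as the original data.
   A copy is *retained* if it maps back to the same chromosome, still
   covers its origin site with mapping quality ≥ 30, and carries one of the
   two panel alleles there.
4. At each site, among the original reads plus retained modified copies,
   report the reference-carrying fraction

   `r = n_ref / n_total`.

Without bias the construction is symmetric and `r = 0.5` exactly; loss of
alternative-carrying copies pushes `r` above 0.5. Sites with `n_total = 0`
are flagged `low_evidence` and fall back to `r = 0.5` downstream: with no
retained reads there is no measurement to correct with.

Mappers are adapters (`map(flipped_reads) -> [AlignedRead | None]`):

- `BwaAlnMapper` shells out to `bwa aln -l 16500 -n 0.01 -o 2` + `samse`
  (seeding effectively disabled, as appropriate for short degraded
  fragments).
- `IdentityMapper` retains everything — the unbiased control.
- `BiasedMapper(beta)` retains every reference-carrying copy and drops each
  alternative-carrying copy independently with probability `beta` — a
  parametric stand-in used in simulation studies.

**Pooled invariant.** At homozygous-reference sites, every original read
carries `R` (so survives `BiasedMapper` unconditionally) and every flipped
copy carries `A` (so survives with probability `1 - beta`). The pooled ratio
`sum(n_ref) / sum(n_total)` then estimates

`E[r] = N / (N + (1 - beta) N) = 1 / (2 - beta)`,

e.g. 0.5556 at `beta = 0.2`. This identity is specific to
homozygous-reference pile-ups and the pooled (read-weighted) ratio; at
heterozygous sites the original reads are themselves subject to loss and the
expectation differs. The acceptance test evaluates the invariant where it
holds exactly.

## 2. Genotype likelihood model

Per read base `b` with phred quality `Q`, the error rate is
`e = 10^(-Q/10)` and

`P(b | allele a) = 1 - e` if `b = a`, else `e / 3`.

For a diploid genotype `(A1, A2)` the default per-site likelihood is the
product over reads of the equally weighted mixture:

`P(D | A1, A2) = prod_i [ P(b_i | A1) + P(b_i | A2) ] / 2`.

The bias-corrected model changes only the heterozygote, replacing the equal
weights with the site's measured reference-read proportion:

`P(D | R, A) = prod_i [ r * P(b_i | R) + (1 - r) * P(b_i | A) ]`.

Homozygote likelihoods are untouched. Both models share one implementation
of the log-mixture accumulation, so the corrected model at `r = 0.5` is the
default model bit for bit (asserted on 10^4 random fixtures).

Numerical choices:

- All products accumulate in log10; linear-scale values are exposed as
  properties and normalization works from the logs, so sites with thousands
  of reads do not underflow.
- `r` is clamped to `[0.001, 0.999]` before use. `r = 0` or `1` would
  assign zero heterozygote likelihood on the strength of a finite (possibly
  tiny) bias measurement; the clamp caps the per-read log-penalty instead
  of letting one extreme estimate veto a genotype. The clamp is a keyword
  and can be disabled.
- Beagle GL output normalizes each triplet to sum to 1, codes alleles
  0/1/2/3 = A/C/G/T, and writes `%.6g`; `.gz` suffixes are honored.

## 3. Estimators

**Allele frequency.** Per site, the reference-allele frequency `f`
maximizing `sum_i log sum_g GL_ig HWE_g(f)` is found by EM: the E-step
computes posterior genotype weights per individual, the M-step sets `f` to
half the mean expected reference dosage. Individuals whose likelihood
triplet is constant carry no information; they are dropped from the
iteration (they contribute exactly the current `f` to the M-step mean, so
the maximizer is unchanged). If no individual is informative the surface is
flat and the initialization (0.5) is returned flagged.

**f2.** Per site, `f2 = (f1 - f2)^2` in plain mode. The corrected mode
subtracts the unbiased finite-sample term `f(1-f)/(n-1)` for each
population (`n` in chromosomes), making the statistic unbiased under
binomial sampling; this is verified by a resampling test.

**Supervised admixture.** Given fixed per-site source frequencies `f_kl`
for K clusters, an individual's two allele copies at site `l` each descend
from cluster `k` with probability `q_k`, giving HWE genotypes at
`p_l = sum_k q_k f_kl`. The EM E-step combines posterior expected
reference/alternative dosages (from the GLs) with per-copy cluster
responsibilities; the M-step averages expected assignments over all `2L`
copies. Initialization is uniform, making the fit deterministic. Identical
sources make the surface flat; the result is then flagged. Both EM
estimators are tested against independent 1001-point grid-search oracles.

**Pseudohaploid calling.** One read (base quality ≥ 30, mapping quality
≥ 30, panel allele) is drawn uniformly per site; the haploid allele is
duplicated into a homozygous diploid genotype for tped output. Calls are
deterministic given the seed.

## 4. Simulation generator

The generator produces self-consistent bundles (panel, true frequencies,
genotypes, reads, admixture truth) from one scenario and one seed.

- **Sequence.** I.i.d. bases with P(G) = P(C) = gc/2 (default gc = 0.41).
- **Topology.** Four populations: an outgroup S1 splits from (S2, S3) at
  `t123` generations (default 20,000); S3 splits at `0.5 * t123`; the
  target T separates from S2 at `0.2 * t123`. Each branch applies one
  Balding–Nichols drift step: child frequency ~
  `Beta(p(1-F)/F, (1-p)(1-F)/F)` with `F = 1 - exp(-t / (2 Ne))`,
  `Ne = 10,000`. Ancestral frequencies are Beta(0.5, 0.5) truncated to
  (0.05, 0.95).
- **Pulse.** T receives an admixture pulse from S3:
  `p_T = f * p_S3 + (1 - f) * p_T,pre`. **Design decision:** the target's
  pre-pulse frequency follows the S2 lineage exactly (`p_T,pre = p_S2`)
  rather than drifting independently after the T–S2 split. With
  independent terminal drift, the supervised admixture model is
  misspecified (the true T frequencies are not an exact mixture of the
  present-day sources) and the estimator exhibits strong
  errors-in-variables attenuation — a mean estimate near 0.24 for a true
  pulse of 0.10 at these drift times. Collapsing the terminal branch makes
  the mixture exact, which isolates the quantity this package is about
  (mapping bias) from a separate, well-known model-misspecification effect.
  The limitation is documented here deliberately: the generator is a
  calibration instrument, not a full coalescent simulator.
- **Ascertainment.** Candidate sites (oversampled 4x by default) are kept
  if a binomial sample of `2 n_ind` S1 chromosomes shows minor-allele
  frequency ≥ 10%, then thinned to the requested panel size. Panels are
  transversions only.
- **Reads.** Site-centric: per site, Poisson(depth) reads; each read picks
  one of the individual's two chromosomes independently per covered site
  (sites are unlinked), with lognormal fragment lengths (location drawn per
  individual from U(3.3, 3.8), scale 0.2, minimum 30 bp) and uniform
  per-base errors at the scenario's phred rate. Mapping bias can act at
  generation time (alternative-carrying reads at the focal site dropped
  with probability `beta`) or at remap time through `BiasedMapper`.
- **Reference genome choice.** By default the mapping reference is the
  ancestral sequence, so reference alleles are symmetric with respect to
  the allele-frequency spectrum. With `reference_pop` set, the reference is
  a haplotype sampled from that population: at each site the ref/alt labels
  swap wherever the sampled haplotype carries the derived allele, making
  reference alleles predominantly the locally major allele. This matters
  for differentiation statistics: with a symmetric (ancestral) reference,
  bias shifts are a mid-frequency bump that inflates small frequency
  differences as much as it compresses large ones, and mean f2 is *not*
  reduced. The understatement of f2 seen in real data requires the
  reference-major configuration, and the package reproduces both regimes
  (the ancestral/outgroup reference acting as the control).
- **Reproducibility.** All randomness derives from
  `numpy.random.SeedSequence(seed)` child streams (frequencies,
  ascertainment, genotypes, one stream per individual's reads), so a
  scenario reproduces byte-identically, including written bundles.

## 5. Scope and limitations

- Single linear reference, biallelic transversion SNPs, unlinked sites.
  No indels, no linkage, no recombination, no post-mortem damage model.
- The flip-remap `r` is a per-site point estimate; no shrinkage across
  sites is applied beyond the low-evidence fallback.
- The supervised admixture estimator treats source frequencies as known
  constants; uncertainty in estimated source panels is not propagated.
- The drift generator collapses the target's terminal branch (see above)
  and models drift as one Balding–Nichols step per branch, which matches
  the first two moments but not the full trajectory of repeated binomial
  sampling.
- `BiasedMapper` applies a single global `beta`; real mapping bias varies
  by site context (fragment length, GC, flanking variation).
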