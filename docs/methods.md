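# Methods

## The problem

Summaries of the site frequency spectrum (SFS) — Watterson's θ_w, the
pairwise-difference θ_π, the derived-singleton count θ_FL, Fay & Wu's
θ_H — and the neutrality tests built from them (Tajima's D, Fu & Li's D
and F) assume the sample allele frequency at every site is known. With
low-depth sequencing (≲ 4×) genotypes are uncertain: hard genotype
calls systematically distort the spectrum (missed rare variants under
conservative SNP calling, error-driven false singletons under
permissive calling), and the distortion depends on depth, error rate
and on whether the region is neutral — exactly the situations a
selection scan is meant to distinguish.

This package estimates the spectrum, and the statistics, directly from
genotype likelihoods (GLs), never calling genotypes:

1. **Genotype likelihoods.** For a pileup of M bases with error
   probabilities e_i, Pr(D|G={A1,A2}) = ∏_i [½p(b_i|A1) + ½p(b_i|A2)],
   with p(b|A) = 1−e if b=A and e/3 otherwise (the simplified
   base-quality-only GATK model). Only base identity and quality enter;
   GLs are kept in log space, max-normalized per individual.
2. **Sample-allele-frequency (SAF) likelihoods.** For n diploids,
   Pr(D|x=j) for j = 0..2n derived alleles is computed by a band
   dynamic program over individuals (O(n²) per site), with the
   hypergeometric configuration weights C(2,g_i)·…/C(2n,j) included so
   the band is a genuine conditional likelihood. A brute-force
   enumerator over all 3ⁿ configurations serves as the test oracle for
   n ≤ 5.
3. **Full maximum likelihood.** The SFS probability vector p over
   0..2n is estimated by EM:
   p_j ← M⁻¹ Σ_s p_j·Pr(D_s|x=j) / Σ_k p_k·Pr(D_s|x=k).
   The total log-likelihood is non-decreasing; expected category counts
   are M·p. Defaults: uniform initialization (deliberately not the
   neutral 1/i shape, to avoid biasing toward neutrality; a start
   vector can be supplied), stopping at relative log-likelihood change
   below 1e-6 or 500 iterations. Categories that start at 0 stay 0 (EM
   fixed point).
4. **Empirical Bayes.** With a prior SFS (e.g. the genome- or
   region-wide ML estimate), per-site posteriors
   Pr(x=j|D) ∝ Pr(D|x=j)·Pr(x=j) are summed over the sites of a window
   into a fractional expected spectrum. Because every θ estimator is
   linear in the spectrum, the resulting estimates are exact posterior
   expectations E[θ̂|D]. This makes genome-wide sliding-window scans
   cheap: no per-window optimization.
5. **Statistics from fractional spectra.** S and η₁ enter the
   published variance chains unchanged; S(S−1) uses E[S]·(E[S]−1).
   Statistics are undefined (NaN, "NA" in files) when S = 0 or the
   variance expression is non-positive — never coerced to 0, and
   excluded from window summaries.

The genotype-calling comparators (highest-GL and HWE-prior callers, ML
allele frequency by EM, likelihood-ratio SNP inclusion against a
χ²(1 df) null) are included as the baseline whose biases the
likelihood-based routes avoid.

## Variance constants

The paper trail for the standardized tests leaves the constants to the
original publications; this package uses the classical chains — Tajima
(1989) for D (b₁,b₂,c₁,c₂,e₁,e₂), Fu & Li (1993) unfolded D, and the
corrected F variance (Simonsen et al. 1995) — all validated in the test
suite against an independently written oracle implementation, and
Tajima's D additionally against tskit on simulated tree sequences.

## The simulator

The synthetic-data engine defines the study conditions:

- **Genotypes.** Standard neutral coalescent via msprime with
  human-like parameters N = 10,000, μ = 2.35e-8 /bp/generation,
  r = 1e-8 /bp/generation (θ = 0.00094 per site), infinite-sites
  mutations mapped to integer bp by floor(pos·L)+1 with collision
  shifting; haplotypes paired into 25 diploids over 1 Mb regions by
  default. Externally simulated haplotypes (selective sweeps from
  msms and relatives) enter through the ms-format reader. Regions with
  prescribed spectra (e.g. for prior-mismatch experiments) are drawn
  site-wise from a given allele-frequency distribution with uniform
  assignment of derived copies to chromosomes.
- **Reads.** Every position 1..L, per individual: depth ~
  Poisson(mean depth) (default 2) or an empirical depth table; bases
  drawn uniformly from the two alleles; each base flipped to one of
  the three other nucleotides with probability e (default 0.005) or a
  phred-derived e from an empirical quality-score table. Sites are
  independent — no read-length, mapping or cycle structure, no depth
  autocorrelation between neighbouring sites, no ancestral-state
  misidentification. Ancestral and derived nucleotides are drawn
  uniformly and the ancestral state is treated as known.
- **Sweep-like spectra.** `sweep_like_prior` builds the simplest
  spectrum with a sweep's signature (reduced 1/i background, excess
  singletons, high-frequency derived mass) matching prescribed θ_w,
  θ_π, θ_FL moments exactly.

What passing tests on these simulations do **not** show: robustness to
mapping artefacts, indels, base-quality miscalibration, correlated
depth, or ancestral mispolarization in real data.

## Numerical design

- With a fixed error rate the GL at a site depends on the pileup only
  through the per-nucleotide read counts, so region-scale work draws
  Poisson counts per base class directly (multinomial thinning of a
  Poisson depth gives independent Poissons) and assembles linear-scale
  GLs from power lookup tables — no per-base loops, no large exp/log
  passes. A pileup-level simulator with per-base qualities exists for
  the empirical-table error model and for validating the fast path.
- The band DP runs category-major and chunked (100k sites/block); the
  region fast path keeps SAF rows in linear scale, float32, max 1 per
  site (relative magnitudes below ~1e-38 flush to 0, which cannot
  affect EM or posteriors at double-precision output). The public
  log-scale `saf_matrix` is float64 and exact; both paths are tested
  for agreement.
- Per-site renormalization bounds all DP intermediates; EM and
  posterior operations use BLAS matrix-vector products with float64
  accumulation of log-likelihoods.
- The per-site allele-frequency EM uses an active set (converged sites
  drop out; |Δf| < 1e-8, ≤ 200 iterations, init f = 0.05). Sites with
  no non-ancestral reads are counted monomorphic directly — their LRT
  statistic is exactly 0.
- Tie-breaks: hard calls break toward the smaller dosage; major/minor
  inference breaks lexicographically (A<C<G<T); the region-scale
  calling path picks the minor allele as the non-ancestral nucleotide
  with the most reads (ties prefer the true derived allele), a
  count-based stand-in for the per-site likelihood maximization of
  `infer_major_minor` at genome scale.
- Windows are half-open [start, start+size) on 1-based coordinates,
  fully contained in the region; centers are start + size//2. Sites
  with no reads in any individual are excluded from windows by default
  (their posterior is exactly the prior and would pull every window
  toward the prior's statistics); the exclusion is configurable and
  nSites counts used sites.
- Error probabilities are clamped to (1e-6, 0.75).

## Problem sizes in the shipped checks

The test suite uses 100 × 1 Mb regions for the true-genotype θ means,
and 20 × 250 kb regions (full study conditions otherwise) for the
low-depth EM/EB/calling comparisons — per-region bias of every method
is independent of region length; only Monte-Carlo noise grows, and the
corresponding assertions are Monte-Carlo-error aware (3 standard
errors of the replicate or paired-difference mean). Prior-mismatch
directions use 3 × 200 kb regions per condition.
`scripts/acceptance.py` recomputes the benchmark means at full scale:
100 × 1 Mb (true genotypes) and 20 × 1 Mb (EM from depth-2 reads).

## Known limitations

- Folded-spectrum analysis exists only at the spectrum level (`fold`);
  SAF bands are unfolded and require known ancestral states.
- No BAM/CRAM or VCF input; GLs enter via the Beagle text format or
  the internal simulator.
- The EM is plain (no acceleration); window-level full-ML scans over
  many windows are correspondingly slower than the EB scan, which is
  the intended genome-scale tool.
- Fixed-SNP-count windows and standardized Fay & Wu H are not
  implemented (θ_H is).
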