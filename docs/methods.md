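# Methods

## The association model

The scan treats genotype–methylation association non-parametrically: for a
variant genotype vector *g* (integer copy-number states 0–4, or SNP dosages
0–2) and a CpG β-vector *y* ∈ [0,1]ⁿ, the statistic is Spearman's ρ —
Pearson correlation of average-tie ranks — with the usual large-sample t
approximation for the nominal two-sided p.  Rank correlation is the right
default here because copy-number "genotypes" may arrive as integer states or
as array probe ratios; ρ is invariant to any monotone recoding, so the
choice of representation does not matter (and the package's permutation p is
tested for exactly this invariance).

**Proximal/distal windows.**  A variant is proximal to a CpG when its
interval shares ≥1 bp with the 2 Mb window centred on the CpG midpoint
(1 Mb each side), distal when it is on the same chromosome outside that
window, and untested otherwise.  Overlap — rather than a midpoint-in-window
rule — is used because CNVs are long; a variant straddling the window edge
would otherwise be misclassified.  All coordinates are 0-based half-open
(BED convention); midpoint = ⌊(start+end)/2⌋.

**Permutation correction.**  Correction is per phenotype and per mode
(proximal and distal families separately): the phenotype vector is shuffled
across samples *N* times, the maximum |ρ| over the family recorded per
shuffle, and each pair's permutation p is the add-one empirical tail
(1+k)/(N+1).  The max-null makes the per-phenotype best-pair p uniform under
the null regardless of family size and LD structure among variants; the
add-one estimator keeps p > 0.  Significance uses strict inequality at the
threshold (default 0.01).  Shuffles come from a counter-based per-phenotype
seed stream, so scan results are independent of phenotype order and safely
parallelizable.

**FDR.**  The genome-wide FDR of a scan is estimated in closed form as
min(1, n_tested × cutoff / n_called) over phenotypes: under the null each
tested phenotype has probability ≈ cutoff of producing a family-wise call,
so the numerator estimates the expected false discovery count.  At the
reference study scale (10,375 phenotypes, cutoff 0.01, 748 called) the
expression evaluates to ≈ 13.87%.

**eQTL / eQTM reuse.**  The same engine runs CNV→expression (eQTL) and
methylation→expression (eQTM) scans; for eQTM the "variant" role is played
by CpG β rows, restricted to CpGs already significant in the mQTL scan —
the scan is a follow-up on mQTL-associated methylation, not a genome-wide
methylation–expression screen.  Validation-cohort mode re-scans only
discovery-significant variants and reports replication at both 0.01 and
0.05.

## LD and conditional analysis

LD is squared Pearson correlation of genotype vectors, pairwise-complete;
the best tag SNP is the maximum-r² SNP whose position lies within 1 Mb of
the CNV interval's ends (ties break to the lower coordinate).  The
conditional test fits OLS of the rank-transformed β-vector on an intercept,
the nearby SNP covariates (strongest-r² first, capped at 10 to avoid
overfitting at small n) and the CNV term, and reads the CNV coefficient's
two-sided t-test p; p < 0.05 ⇒ the CNV has an independent effect.  The rank
transform keeps the conditional model aligned with the Spearman scan that
produced the candidates; with zero covariates it reduces exactly to the
marginal rank-regression test.  A CNV whose genotype adds no column-space
beyond the covariates (e.g. a perfect tag SNP present as covariate) is
flagged non-identifiable and called dependent rather than producing an
unstable fit.

## Enrichment tests

**Interval enrichment.**  The statistic is the number of query regions
(e.g. significant CNV-mQTLs) sharing ≥1 bp with a feature track — per
region, not per feature, so a region touching many peaks counts once.  The
null re-places each region uniformly on its own chromosome (preserving
per-chromosome counts and the exact length multiset; regions may overlap
each other) for 1,000 iterations; enrichment and depletion tails are both
reported with the add-one estimator, so p_enrich + p_deplete ≥ 1 and
neither can fall below 1/(iterations+1).  Placement preserves chromosome
to control chromosome-level feature density; no assembly-gap exclusion is
applied.

**Hi-C enrichment.**  Contacts are sparse KR-normalized bin pairs
(intra-chromosomal only); a CNV/CpG pair's signal is the maximum over all
(CNV bin, CpG bin) combinations after extending the CpG by a shore window
(2 or 5 kb), which preserves the zero/non-zero statistic exactly.  The test
statistic is the count of pairs with non-zero signal.  The null redraws,
per chromosome, random CNV-role and CpG-role regions with the observed
length multisets and re-pairs them at the observed midpoint distances
(anchor uniform, direction random, off-chromosome placements resampled), so
all three multisets are preserved exactly.  Log ratios
log((observed+1)/(null+1)) are reported alongside p; add-one smoothing
guards against zero null counts.

## The synthetic cohort

The generator emulates the study conditions this method is designed for: a
**77-sample** cohort on two desk-scale 5 Mb chromosomes (configurable
upward), with

- CNVs as diploid states 2 ± Binomial(2, p), deletion or duplication per
  variant, allele frequency uniform on (0.05, 0.5], sizes log-uniform
  500 bp–50 kb, every variant polymorphic;
- planted CNV→CpG effects β = logistic(a·z + σ·ε) with z the standardized
  state and ε standard normal; the scale *a* is calibrated empirically (a
  pilot-simulation bisection per planted pair) so the expected |ρ| hits the
  target; the target grid {0.3, 0.4, 0.5} covers the effect magnitudes
  typical of reported CNV-mQTLs; null CpGs are logistic pure noise;
- SNPs as biallelic dosages; a tagged SNP copies the CNV's non-reference
  dosage with per-allele error rate calibrated to the target r² (several
  candidate draws, closest kept — realized r² within ~0.1 at n ≥ 77);
- expression exp(±s·z + σ·ε), methylation- or CNV-driven or null
  (non-negative, monotone in the mediator with either sign);
- feature tracks placed uniformly with probability mass ×bias inside chosen
  regions (bias 1 = uniform; bias < 1 depletes, 0 excludes — the depletion
  side extends the generator so both enrichment tails can be exercised);
- Hi-C background entries appearing at bin distance d with probability
  min(1, 2/(1+d)) and log-normal signal around a power-law mean
  amp·(1+d)^−α (α = 1), planted anchor pairs boosted ×10 over the
  background mean at their distance.

Every generator is a pure function of (config, truth ledger, seed) via
per-generator seed streams, and the truth ledger records every planted
pair, null id, LD pair, mediation edge and contact anchor, so recovery is
scored exactly.

**What the generator does not emulate** — realistic human LD maps and
recombination structure, array probe noise and batch effects, cell-type
mixtures, bimodal genome-wide β distributions, CNV call uncertainty, and
genome-scale chromosome counts.  Passing tests therefore demonstrate the
statistical machinery (calibration, power at given effect sizes, estimator
correctness), not performance on any particular real cohort.

## Numerical choices and problem sizes

- Quantile normalization maps each sample column to the rank-wise mean of
  sorted columns, ties receiving the mean reference quantile (the limma
  convention); it is idempotent and Spearman-preserving per column.
- PCA for stratification QC centres features, uses a full SVD and fixes
  each component's sign by its largest-magnitude loading, so scores are
  deterministic.
- The permutation engine vectorizes rank correlation as a dot product of
  standardized ranks; rows with missing genotypes fall back to a
  per-subset re-ranking path (pairwise-complete).
- Test and acceptance runs use n = 77 samples, 50 CNVs, 200–500 CpGs and
  1,000 permutations/iterations — sizes chosen so the full suite exercises
  every statistical claim in a few minutes on one core; all counts scale
  up by configuration.
- Calibration checks use 200 repetitions and a KS test at α = 0.01; the
  Hi-C calibration uses 150 pairs per repetition because the non-zero-count
  statistic is discrete and small pair sets make its permutation p too
  lumpy for a meaningful uniformity check.
- Power bounds asserted in tests (≥80% recovery at |ρ| = 0.5, n = 77;
  ≥90% conditional-independence calls at n = 200) were fixed from
  independent pilot simulations before the tests were frozen (pilot
  estimates ≈90% and 100% respectively).

## Known limitations

- The conditional model is rank-OLS, not a mixed model; population
  structure is assumed absent (the PCA check is advisory).
- The FDR expression assumes phenotypes are exchangeable under the null;
  correlated CpGs make it conservative in expectation but noisy.
- Interval enrichment does not match GC content or mappability, and the
  Hi-C null does not preserve A/B compartment membership — only sizes and
  distances.
- Only same-chromosome (cis, in the wide sense) associations are tested;
  inter-chromosomal contacts and trans QTLs are out of scope.
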