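# Methods

This note documents the model and the numerical choices behind `hapclone`,
what the synthetic-data generator does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Model

A patient's tumor consists of `m` clones with integer haplotype-specific
copy numbers `(a_is, b_is)` per genomic segment `s`, mixed with diploid
normal cells (`(1,1)` everywhere) at proportions `u_ip` per sample `p`
(`sum_i u_ip = 1`). Two observables summarize each genomic bin:

* read-depth ratio (RDR) `r_sp = d_sp / d_s0`, library-size normalized so
  its mean over bins is exactly 1 per sample; its expectation is
  `F_sp / lambda_p` with `F_sp = sum_i u_ip (a_is + b_is)` and
  `lambda_p = sum_s w_s F_sp / sum_s w_s` (the same mean-1 convention);
* minor-haplotype B-allele frequency (mhBAF) `f_sp`, the frequency of the
  parental haplotype with the lower mean abundance across samples; its
  expectation is `G_sp / F_sp` with `G_sp = sum_i u_ip b_is`.

A bin's mhBAF above 0.5 in an individual sample — possible because the
orientation is chosen jointly across samples — indicates a
mirrored-subclonal CNA (clones amplifying opposite haplotypes).

## Stage-by-stage choices

### Switch-error guard and meta-SNPs

Reference phasing has appreciable switch-error rates, so adjacent-SNP counts
are combined only when their phased allele fractions are statistically
compatible. The test is a two-sided Fisher exact test per sample on
`[(x_i, y_i); (x_j, y_j)]`, with "significant in any sample blocks the
merge" (conservative: a switch error propagated into any sample corrupts
that sample's BAF). Default `alpha = 0.01`; no multiple-testing correction
across pairs, since each decision is local and correction would weaken the
guard. Candidate blocks never span more than 25 kb (phasing accuracy decays
with distance) and merging always compares the incoming SNP to the last
accepted one. Fisher's test is conservative at discrete counts: under the
null the realized split rate is below `alpha` (the calibration test asserts
`rate <= alpha + 3 SE` and `rate > alpha/10` at 100 reads per SNP); power to
catch a switch at haplotype frequency 0.2 with 30 reads per SNP exceeds 0.9
at `alpha = 0.01`. The p-values are computed by a vectorized hypergeometric
enumeration, unit-tested against `scipy.stats.fisher_exact`.

### Variable-width binning

The greedy walk accumulates SNP-covering and total reads per sample and cuts
a boundary at the midpoint after the first meta-SNP where *all* samples meet
both floors (`k_SNP`, `k_total`; defaults 1000 / 5000, always set explicitly
per study here). A trailing residual that violates a floor is merged into
the previous bin; if a whole arm cannot meet the floors it becomes a single
bin flagged `fallback`. Removal of the last boundary is conditional on the
residual actually violating a floor — unconditional removal would merge a
valid final bin for no reason. Bins are emitted 0-based half-open and tile
each arm exactly; the floors are checked in every sample including the
matched normal. Bins with zero normal reads are dropped before RDR.

### mhBAF estimation

Counts follow `x_jp ~ Bin(t_jp, f_p)` if meta-SNP `j`'s aggregated allele is
on the tracked haplotype, else `Bin(t_jp, 1 - f_p)`, independent across
meta-SNPs and samples. EM marginalizes the phases (responsibilities in log
space; 5 restarts, restart 0 initialized from the per-sample lower allele
fraction); restarts are ranked by the complete-data log-likelihood after
hardening and greedy single-flip polishing, which is also the quantity an
exhaustive maximization over all `2^l` phase vectors computes — the
acceptance suite checks agreement to 1e-6 on 100 random instances.

The *reported* frequency is the converged soft (phase-marginalized)
estimate, not the hard-phase value. The distinction matters near balance:
picking the minor count per site (the LAF) or hardening phases biases the
estimate below 0.5 by roughly `0.4 / sqrt(pooled reads per meta-SNP)`,
whereas the soft estimate removes most of it (the oriented value keeps a
smaller one-sided component from the minor-orientation rule itself — about
0.02 vs 0.073 for the LAF at the bias-test conditions) and coincides with
the hard one wherever the data are informative. With one tumor sample the
hard MLE collapses exactly onto the LAF, which is the baseline estimator
this stage is designed to improve on. Consequence: for a single site with
`x/t = 3/10` the reported value is the single-site mixture MLE (~0.318),
not 0.30.

Two residual biases of the per-bin orientation are handled downstream:

* In near-balanced regions the per-bin minor orientation cannot exceed 0.5
  on average, and the orientation of adjacent bins is phase noise. Maximal
  runs of at least 5 bins with switch rate >= 0.2 and mean `|f - 0.5| <
  0.1` are re-phased greedily toward the previous bin. The density
  threshold is deliberately below the naive 0.5: with 5-bin windows the
  rate quantizes to quarters and genuinely balanced runs show 25–50%
  switch rates; the balance guard alone protects imbalanced regions. This
  inter-bin repair is a reconstruction of the published intent; the original
  heuristic's exact statistic is not public.
* The residual one-sided bias of cluster-mean BAF for balanced clusters is
  added to the model-selection noise floor (below) rather than corrected in
  the estimate.

Samples with zero reads in a bin are imputed at 0.5 and flagged.

### Local-global clustering

The HMM has `K` states with diagonal-covariance Gaussian emissions in the
`2P`-dimensional `(RDR, mhBAF)` space (features z-scored before fitting;
centroids reported on the original scale), uniform start distribution, and
a single transition parameter: diagonal `1 - tau`, off-diagonal
`tau/(K-1)`, re-estimated as one pooled scalar. Arms are independent
sequences sharing one parameter set; transitions never cross arm
boundaries. `tau` is initialized at 0.1 and floored at 1e-6; emission means
are initialized from KMeans centers; empty states are re-seeded at the
worst-fit bin; variances are floored at 1e-6. Setting
`tau = (K-1)/K` makes every transition row uniform and the posteriors
reduce exactly to mixture responsibilities — the order-0 global baseline
used in the local-advantage benchmarks.

K is chosen by silhouette score of the MAP labels (Euclidean, standardized
features, subsampled to 10k bins). Among K within 0.03 of the best score
the *largest* K wins: the factorization can assign one state to two
clusters, but a merge of two genuine states is unrecoverable. After
selection, cluster pairs whose means coincide under the BAF complement
(within 4 SE) are merged — one copy-number state can surface as two
mirror-image clusters because the per-bin orientation is arbitrary near
balance.

### Integer factorization and model selection

The solver minimizes the weighted squared residual of RDR and mhBAF
(`kappa = 4 mean(R)^2` balances the two scales) over integer states with
`a + b <= c_max` (4 by default, 8 under WGD) and simplex-constrained
proportions, by block coordinate descent: exhaustive per-segment state
enumeration given `(U, lambda)`; per-sample simplex least squares
(active-set QP, iteratively re-linearized in the BAF denominator) given the
states; `lambda` updated to its definitional value or its least-squares
minimizer — every step guarded so the exact objective never increases. The
scale degeneracy (a doubled genome predicts identical observables) is
resolved by anchoring every tumor clone's weight-modal state at `(1,1)`
(`(2,2)` under WGD) — a model assumption: each clone's genome is
majority-baseline.  If the WGD branch wins with an all-even solution, its
halved version (with the matching proportion rescale, which leaves the
expected observables unchanged) is also offered to the diploid branch. Because the joint landscape is multimodal, each fit
multi-starts from Dirichlet proportions and per-sample `lambda` anchors
(20 restarts by default), then polishes the best fixed points with a
segment-reassignment local search and clone-level kicks (swapping clone
roles on random segment subsets, partial diploid resets, proportion jitter)
with re-descent. An optional parsimony term (`state_penalty` per unit of
proportion-weighted copy-number deviation from baseline) breaks ties among
near-equivalent fits toward the least-aberrant explanation; it never enters
the reported residual objective.

Model selection solves each clone number `m` in both WGD branches and picks
the smallest adequate model. When per-cluster dispersions are available,
"adequate" means the objective is within twice the sampling noise floor
(pooled within-cluster variance of bin RDR/BAF over cluster size, plus the
known one-sided orientation bias for clusters statistically consistent with
balance); otherwise an elbow rule applies (stop when the improvement toward
`m+1` falls below 5% of the smallest-m objective, or when the `m+1` fit
contains a clone below 5% proportion everywhere). Between branches the
score is objective plus a subclonal-genome-fraction penalty scaled by the
larger branch objective; branches tied within noise (or both exact) resolve
to no-WGD, and an adequate diploid branch skips the WGD solve entirely
(under these rules it cannot win). Clusters smaller than `max(2, 2%)` of
bins are excluded from the deconvolution and receive states post hoc at the
fitted proportions.

## The simulator, and what passing tests do not show

`hapclone.simulate` draws SNP positions by a Poisson process, assigns each
alternate allele to a parental haplotype uniformly, applies CNA events along
a clone tree (descendants inherit), and emits Poisson read totals (optional
gamma-Poisson overdispersion) with binomial allele counts whose success
probability is the haplotype-resolved allele fraction; depths are scaled by
`F/lambda` so simulated RDR follows the pipeline's mean-1 convention.
Reference phasing is emitted per phase set (exponential lengths, mean
40 kb) with independent per-SNP switch errors (default rate 0.02).

Not emulated: GC and mappability bias, correlated sequencing noise beyond
the overdispersion option, read-level artifacts, germline CNVs, and
subclonal SNVs. Passing the end-to-end benchmarks therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data artifacts.

Study conditions (fixed once, used by tests and the acceptance script):

* *Mirrored-subclonal study*: four 8-Mb arms, SNP density 0.2/kb, SNP
  coverage 50x, two samples, two clones at proportions `(0.5, 0.25)` and
  `(0.3, 0.55)` with 20% normal; a `(2,1)/(1,2)` mirrored pair on chr1q
  plus two private events per clone (each clone needs private events —
  a clone distinguishable from its sibling by no segment is unidentifiable
  by any method). Bins hold >= 2000 SNP-covering reads per sample.
* *Focal study*: one 40-Mb neutral arm, one clone at purity 0.25, a 3.3-Mb
  single-copy gain (~10 bins), SNP coverage 12x with depth overdispersion
  0.004 — chosen so the two states' marginal feature densities overlap and
  transition information is genuinely needed.
* *Factorization benchmark*: random star-tree mixtures, `m <= 3`, `P >= m`
  (at least 2 for multi-clone), 1–2 events per clone each including a loss,
  `c_max = 4`, <= 12 segments, clone proportion columns pairwise separated
  by >= 0.15.

## Identifiability of exact recovery

Exact integer recovery is only a meaningful benchmark on identifiable
instances. Three provable ambiguity classes are excluded from the benchmark
generator by construction:

1. a clone with only gains admits a halved-proportion / doubled-gain
   re-description (every benchmark clone carries a loss, which cannot
   double);
2. nested (chain-tree) clones are exactly re-expressible as a star
   decomposition with shifted proportions — bulk fractional copy numbers
   cannot distinguish the two (the benchmark uses star trees with private
   events);
3. compensating-state re-descriptions with equal event load can tie exactly
   (the parsimony penalty breaks ties, and a certificate screen redraws any
   instance for which a probe solve exhibits a *different* exact solution —
   a constructive proof of non-identifiability).

Even so, across independent seed batches roughly 2% of instances can fail
exact recovery, through a residual ambiguity the screen missed or a
multistart search miss; the acceptance script reports the measured recovery
rate rather than assuming it.

## Numerical conventions

Binomial log-likelihoods use the Bernoulli form with probabilities clipped
to `[1e-10, 1 - 1e-10]`; EM convergence is `|delta loglik| < 1e-6` (200
iterations max); Baum–Welch converges at `|delta loglik| < 1e-4` (200
iterations); coordinate descent at relative `1e-9` (60 iterations).
Orientation ties (mean frequency exactly 0.5) resolve by requiring the
first sample's value <= 0.5. MAP label ties resolve to the lower state
index. Clones are reported sorted by descending total proportion; segment
orientations are canonicalized so the mean expected mhBAF is <= 0.5. All
randomness flows through explicit seeds; pipelines derive per-stage seeds
from one master seed.

## Known limitations

* The mhBAF orientation is arbitrary for segments whose mean frequency
  across samples is exactly 0.5 (including perfectly symmetric mirrored
  events); downstream comparisons are orientation-invariant.
* Whole-genome duplication calls rely on the clonal-anchor assumption (the
  dominant clone's modal state is the baseline); genomes aberrant over more
  than half their length violate it.
* Problem sizes here are desk-scale (tens of Mb, hundreds of bins); the
  exhaustive state enumeration grows as `(c_max choose 2)^m` and is capped
  by an explicit budget.
* GC/mappability correction of RDR is out of scope.
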