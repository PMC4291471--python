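# Methods

## The decoding-time model

Ribosome-profiling footprint counts are treated as noisy readouts of
per-codon ribosome dwell times. For a gene that passes filtering, each
surviving codon position contributes a normalized footprint count (NFC):
its count divided by the gene's average count. Pooled per codon type, NFC
values are modeled as draws from an exponentially modified Gaussian (EMG):
the sum of a Gaussian N(μ, σ²), interpreted as the codon's typical,
pause-free decoding time, and an independent Exponential(λ) capturing rare
long dwells (pauses, ribosomal traffic jams). λ is parameterized as the
exponential *rate*, so the mean pause contribution is 1/λ; output tables
print `mean_pause = 1/lambda` alongside λ to keep the convention
unambiguous. The fitted μ is the typical decoding time; 1/μ the typical
decoding rate; and an ORF's MTDR index is the geometric mean of its
codons' rates.

Because NFC is a within-gene relative quantity, μ is in units of "fraction
of the gene's mean dwell" — it is meaningful relative to other codons
fitted from the same dataset, not across datasets. For the same reason the
whole pipeline is invariant under a joint rescaling of all dwell times
(μ, σ, 1/λ scaled together leave every NFC unchanged); only relative
decoding times are identifiable, which is all the MTDR index needs.

## Preprocessing

Order of operations: gene filter → end trimming → position filter →
normalization → pooling.

* **Gene filter**: keep genes whose untrimmed-profile statistic strictly
  exceeds a threshold. Default: median footprint count > 1 (the `mean`
  variant is exposed via `gene_stat` because both readings appear in the
  literature for this filter).
* **Trimming**: drop the first and last 20 codons (5′ ramp and terminal
  effects). The simulator plants a multiplicative 5′ ramp precisely so
  tests can verify trimming removes it.
* **Position filter**: drop positions with count < 1 (unreliable reads).
* **Normalization**: divide by the gene's mean count. The denominator is
  taken over exactly the trimmed positions that pass the position filter,
  so each gene's contributing NFC values average to 1 by construction; the
  `all_trimmed` variant (mean over every trimmed position) is selectable
  since the canonical choice between the two is not established. Stop
  codons never contribute samples.

The position filter truncates each gene's NFC sample at a gene-dependent
lower bound. The EMG is fitted to the surviving samples without a
truncated-likelihood correction, which biases low-μ codons upward
somewhat; a truncation-corrected likelihood is noted as future work. Rank
recovery of decoding times is robust to this bias (see the recovery
benchmarks).

## EMG fitting

The log-density is evaluated through the identity

    log f = log(λ/2) − (x−μ)²/(2σ²) + log erfcx(z),   z = (μ + λσ² − x)/(√2 σ),

which is exact for all z and free of the catastrophic cancellation the
textbook `exp(...)·erfc(...)` form suffers when λσ is large (near-Gaussian
regime); where erfcx overflows (z < −25, deep exponential tail) the
erfc → 2 asymptote is substituted. Maximum likelihood runs L-BFGS-B in
(μ, log σ, log λ) with an analytic gradient; log-space enforces positivity
without constraint machinery. Bounds: |μ| ≤ 5·max|x|, log σ and log λ in
[−20, 20]; tolerances ftol 1e-13, gtol 1e-8.

Initialization is method-of-moments: with sample mean m, variance s² and
skewness γ clamped to [0.02, 0.98·2] (2 is the EMG's maximal skewness),
1/λ = s·(γ/2)^{1/3}, μ = m − 1/λ, σ² = max(s²(1 − (γ/2)^{2/3}), 10⁻⁴ s²).
If the first start fails, 5 deterministically perturbed restarts are tried
and the best log-likelihood wins (ties broken toward smaller λ). A fit
counts as converged when the optimizer succeeds at a loose stationarity
check, or when a line-search stall still sits at a tight stationary point
(max |gradient| < 10⁻²) — L-BFGS-B frequently reports ABNORMAL at machine
precision with tight ftol while the solution is fully converged.

Codons with fewer than `min_samples = 200` NFC samples are reported as
unfit rather than fitted: below a few hundred samples the decomposition
into Gaussian and exponential components is unstable. Fits with μ̂ ≤ 0 are
flagged *atypical* and excluded from rate tables (a decoding time must be
positive; 1/μ̂ would be meaningless). Both kinds of exclusion are surfaced
in reports, and missing-codon handling at scoring time defaults to
skip-and-count rather than failure.

## Scoring

Whole input ORFs are scored (the 20-codon trim is an estimation-side
artifact filter, not a property of the index; `--trim-ends` reproduces the
trimmed variant). The terminal stop codon is never scored; internal stops
are an error under strict validation and are skipped with a warning
otherwise. MTDR is computed as exp(mean log rate), which is exactly
permutation-invariant and scales linearly with a global rescaling of the
rate table.

## Comparison indexes

CAI uses Sharp–Li relative-adaptiveness weights from a user-supplied
highly expressed reference set, with a pseudo-count floor (default 0.5) so
unobserved codons keep positive weight; single-codon families (ATG, TGG)
are excluded from scoring by default, per convention. tAI implements the
dos Reis wobble recursion: W_c = Σ (1−s)·tGCN over recognizing anticodons,
with default penalties s(G:U)=0.41, s(I:C)=0.28, s(I:A)=0.9999,
s(U:G)=0.68 and the lysidine special case for ATA (s=0.89); ATG is read by
its Watson–Crick anticodon only. Zero weights are replaced by the
geometric mean of the non-zero weights before normalization to max 1. The
decoding-time transforms DTCAI/DTtAI are defined as 1/w (or −log w via a
flag); the transform is monotone, and only rank agreement with fitted μ
values is ever asserted.

## Validation statistics

* **Spearman**: Pearson correlation of average ranks; two-sided p from the
  t approximation with n−2 df. Constant inputs yield a flagged undefined
  result.
* **Partial Spearman**: the first-order partial-Pearson formula on ranks,
  (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), n−3 df; degenerate when a
  control is collinear with an argument (flagged).
* **PA regression**: OLS of protein abundance on (MTDR, tAI, CAI) with
  intercept; 95% CIs from the t distribution with n−4 df; a coefficient
  "contributes" when its CI excludes zero. Rank-deficient designs raise
  with the condition number.
* **Held-out ribosomal load**: genes passing the gene filter (the
  operational definition of "highly expressed" — no separate threshold is
  established) are split 50/50 by a seeded permutation; decoding times are
  estimated on half A, MTDR of half B's ORFs is correlated (Spearman) with
  half B's mean footprint count. A `shuffle_loads` switch provides the
  permutation null.
* **Two-condition comparison**: Spearman of per-gene MTDR ratios vs load
  ratios on the shared positive genes, plus Welch's t and Wilcoxon
  rank-sum (normal approximation, continuity-corrected) comparing MTDR
  ratios of the top-q vs bottom-q genes by load ratio (q = 0.30 default;
  bottom group ⌊qn⌋, top group ⌈qn⌉, so q = 0.5 partitions all genes).
  Raw p-values are reported; a Benjamini–Hochberg helper exists but is off
  by default.

## Synthetic data

The generator emulates the statistical structure the estimator assumes,
per gene g: depth d_g ~ LogNormal(ln 10, 1.25); per-position dwell draws
from the codon's true EMG, truncated at 0 by rejection (counts cannot be
negative — this mildly biases low-μ codons and the recovery tolerances
were set with this generator); counts = d_g · dwell; a ×2 multiplicative
ramp on the first 20 codons; position dropout with probability
exp(−d_g/5), the simplest monotone model of low-coverage sparsity. True
decoding times default to 61 distinct μ spread evenly over [0.1, 1.0]
(σ = 0.25·μ, λ = 5).

Per-gene codon usage is tilted toward fast codons in proportion to the
gene's standardized log depth (`load_coupling`, default 0.8). This encodes
the selection-for-elongation-speed-in-highly-expressed-genes effect that
makes ribosomal load predictable from codon content in real data; without
it, simulated mean read count would be independent of codon composition
and the held-out load protocol would have nothing to detect. Held-out
target ORFs are drawn from the untilted base usage.

Defaults (200 genes of 200–400 codons) were chosen once so that roughly
three quarters of genes pass the median-count filter and per-codon NFC
buckets stay above `min_samples` even after a 50/50 split. Real Ribo-seq
data are sparser and noisier than this (most genes in published datasets
have mostly-zero profiles, and real footprints carry sequence-composition
and digestion biases the generator omits); passing recovery benchmarks
here demonstrates correctness of the estimator under its own model
assumptions, not performance on any particular organism's data. All
simulation outputs are pure functions of (config, seed), with independent
RNG streams per stage.

Benchmarks computed by the test suite and `scripts/acceptance.py` at these
defaults: Spearman(true μ, μ̂) > 0.9 across fitted codons,
Spearman(true-parameter MTDR, estimated MTDR) > 0.9 on 100 held-out ORFs,
median |μ̂ − μ| < 0.005 at n = 5000 draws, held-out load correlation
significantly positive with a shuffled null inside the 3/√n band.

## Numerical and design notes

* Counts are reals, not integers: upstream pipelines often emit
  multi-mapping-weighted or length-normalized coverage.
* Coordinates are 0-based half-open internally; reports print 1-based.
* Gene ids match across files by exact, case-sensitive string equality.
* Result tables print 12 significant digits and round-trip to better than
  1e-9 relative; outputs embed a config hash and the seed, never a
  timestamp, so reruns are byte-identical.
* The `--nt-input` flag sums non-overlapping nucleotide triplets into
  codon counts; how published pipelines aggregated nucleotide reads to
  codons (sum vs A-site only) is generally unstated, so the choice is
  documented rather than asserted.

## Known limitations

* No truncated-likelihood correction for the count ≥ 1 position filter.
* No mechanistic ribosome-traffic model (the exponential tail absorbs
  traffic jams statistically); no positional dependence of rates.
* μ values are dataset-relative (NFC units); absolute per-codon times
  from different datasets are not comparable without the original data.
* The simulator does not model sequencing biases (ligation, nuclease
  footprint-size effects) or isoform-aware read mapping.
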