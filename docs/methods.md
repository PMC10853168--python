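# Methods

This note documents the models, conventions, parameter choices and known
limitations of `hapscore`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external datasets.

## Grantham distance and HLA-I divergence

The amino-acid distance is
d(x, y) = ρ·[α(c_x−c_y)² + β(p_x−p_y)² + γ(v_x−v_y)²]^½ with the classical
property weights α = 1.833 (composition), β = 0.1018 (polarity),
γ = 0.000399 (molecular volume). ρ is not hard-coded: it is derived at
matrix-construction time from the normalization that defines the metric —
the mean of the 190 inter-residue distances equals 100 exactly. This
reproduces the standard anchor values (Leu–Ile = 5, the most conservative
exchange; Cys–Trp = 215, the maximum). A `rounded=True` mode rounds each
entry half-away-from-zero to the printed-table integers; internal
computation is always floating point. An explicit numeric `rho` can be
supplied to bypass the normalization.

HLA-I evolutionary divergence (HED) of one locus is the mean per-site
Grantham distance between the two aligned binding-domain sequences over
columns where neither sequence has a gap. Design choices:

- **Denominator.** Per-site normalization (sum ÷ compared columns) is the
  default, matching the divergence literature this score family comes
  from; the raw sum is available via `per_site=False`.
- **Gaps.** Columns with a gap in either sequence are dropped from both
  numerator and denominator, so alignment padding cannot inflate
  divergence. A pair with zero comparable columns is an error, not a 0.
- **Allele resolution.** Names are normalized to two-field resolution
  ("A*02:01:01" → "A*02:01"); unknown alleles are a hard error naming the
  allele — silent imputation would corrupt homozygosity calls.
- **Homozygosity.** A locus whose two allele names are equal scores
  exactly 0 without a sequence comparison (the names must still resolve).

The package ships no real HLA alignments; users supply their own aligned
FASTA (header = allele name, 181 columns expected for the exon 2–3
binding domain, any consistent width accepted). Test sequences are
synthetic.

## Neoantigen filtering, burden, quality, TMB

A binding record is a (patient, mutant peptide, allele) row with IC50 (nM)
and/or percentile rank. Filtering is a strict inequality — IC50 < 500 nM
by default, %rank < 1.0 in rank mode — following the wording of the
threshold definitions; records exactly at the threshold are excluded.

Per-locus tumor neoantigen burden counts **distinct mutant peptides** per
locus: a peptide presented by both alleles of a locus counts once, because
the burden is meant to measure the presentable peptide space, not
peptide–allele pairings. A `dedup="pairs"` mode counts pairs for
sensitivity analysis. The patient total is the number of distinct
peptides across loci (pair mode: the sum of per-locus pair counts).

Neoantigen quality is the self-discrimination score
D = (1−w)·log(K_d^WT/K_d^MT) + w·log(EC50^MT/EC50^WT); the EC50 terms are
consumed as inputs — the cross-reactivity model that produces them is not
reimplemented here. Natural log by default, configurable base; the
weight w defaults to 0.5 since no canonical value is fixed by the score's
definition.

TMB is nonsynonymous mutations ÷ sequenced coding megabases; the package
applies no mutation-calling logic of its own.

## HAPS

HAPS = mean over loci of HED_i × log10(TNB_i + 1). The log10 is part of
the score's definition (it is the only log base used in the score; the
quality score's log is independent of it). Classification is
**high iff HAPS ≥ cutoff**: the boundary is assigned to "high" for
consistency with the ≥-style decision threshold used by the response
model. Default cutoffs: 10 (whole-exome mode) and 1.31 (panel mode); any
numeric cutoff can be supplied, and `scan_cutoff` re-derives one from a
user's own cohort.

## Survival analysis and the cutoff scan

`cox_hr` fits a proportional-hazards model for a binary grouping. The
univariate path is an in-package Newton–Raphson on the Efron partial
likelihood, fully vectorized so the cutoff scan can afford thousands of
fits; the test suite holds it to 1e-6 agreement with R's `survival`
implementation (it typically agrees to ~1e-12). Adjusted fits delegate to
lifelines with covariates entering additively. The log-rank test is
lifelines'; KM medians use the convention *smallest time with survival
estimate ≤ 0.5* (evaluated with a 1e-12 tolerance because the product
limit can hit 0.5 exactly in even, uncensored groups), and a never-reached
median is reported as infinity.

The cutoff scan dichotomizes at every unique score value between the 10th
and 90th score percentiles, subject to each group keeping at least 10% of
the cohort (and ≥ 2 patients), and picks the cutoff minimizing the
high-vs-low HR. Ties within 1% relative HR resolve toward the cohort
median score. If no scanned cutoff has a 95% CI excluding HR = 1 the
result carries the tag `"no significant cutpoint"`.

Two statistical caveats are surfaced deliberately:

- **Resolution.** With a dense unique-value grid the argmin jitters over
  neighboring order statistics because one-patient reassignments barely
  move the partial likelihood. At n = 500 with a strong threshold effect
  (HR 0.4, 20% censoring) the scan localizes a generative threshold to
  about ±0.25 score units in ~94% of replicates (tested), i.e. to a few
  grid steps, not to one.
- **Multiplicity optimism.** The scan performs hundreds of correlated
  tests; on null cohorts the minimized HR is biased below 1 and its CI
  excludes 1 in roughly half of scans. The package reports this through
  the rationale tag and a dedicated test; it applies no multiplicity
  correction, because the scanned-cutoff methodology it mirrors applies
  none.

HLA-LOH: a locus is lost when minor-allele copy number < 0.5 **and**
allelic-imbalance p < 0.01; the conjunction is the package's reading of
the two stated conditions and can be relaxed to copy-number-only via
`rule="cn_only"`. A patient is LOH if any locus is. Joint stratification
yields the four HAPS × LOH cells, or two cells
(HAPShigh/HLAintact vs. other) in collapsed mode.

## TCR repertoire metrics

Clones are identified by CDR3 amino-acid sequence; nucleotide-distinct
clones with identical amino-acid CDR3s are merged (counts summed) before
any metric. Diversity is the Shannon index in nats; clonality is
1 − H/ln(n), defined as 1 at n = 1 (the monoclonal limit of 0/0).
Downsampling to a fixed read count is multivariate hypergeometric over
clone counts — exact sampling without replacement — and is seeded.

Two distances serve different purposes: **Levenshtein** edit distance
(via edlib) for top-clone summaries, because CDR3 lengths vary and a
substitution-only distance would be undefined across lengths; and
**Hamming with a ≤ 3 substitution bound** for similarity-network edges,
where the edge definition is explicitly substitution-based and
equal-length. Top-N selection (default 30) breaks count ties
lexicographically for reproducibility; the pairwise summary averages all
unordered pairs, with a nearest-neighbor mode as an option.

## Neural-network response model

Architecture: three standardized inputs (HAPS, TMB, TCR diversity), one
logistic hidden unit, one logistic output — six free parameters. The
single hidden unit is a deliberate capacity bound for cohorts of tens of
patients; the published coefficient set this package ships as a frozen
reference (hidden intercept 1.9214; input weights 1.54006, 1.4383,
2.46875; output parameters −0.42557 and −1.76532; threshold 0.436) has
exactly this parameter count, which is why the two output-layer numbers
are read as (output bias, hidden→output weight). That reading is this
package's documented interpretation; the reference model is used for
forward-pass regression checks and demonstrations, never as retrainable
truth, and its standardization is the identity because the original
preprocessing is unknown.

Training is full-batch RPROP (the variant without weight backtracking):
per-parameter step sizes start at 0.1, grow ×1.2 on gradient-sign
agreement and shrink ×0.5 on disagreement, bounded to [1e-6, 50]; the
loss is ½·Σ(ŷ−y)²; stopping at |ΔSSE| < 0.01 or 20 iterations (both
configurable); initialization is N(0, 0.5²) from the mandatory seed, so
equal seeds give byte-identical models. Inputs are z-scored with
parameters stored on the model; a constant feature is an error naming the
feature. The decision threshold maximizes Youden's J = sens + spec − 1
over observed scores (rule: score ≥ threshold is positive), resolving
float-level ties toward the lower threshold. Factor importance is
permutation-based mean AUC drop, seeded, ties lexicographic.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, at
desk scale. Defaults (the package's study conditions):

- 300 patients; 8 synthetic alleles per locus, 181 alignment columns,
  8 substituted sites per allele off a random consensus — giving per-site
  divergences of a few units, the realistic order of magnitude;
  per-locus homozygosity probability 0.15.
- Per-locus burden: log10(TNB+1) ~ N(1.8, 0.5) (whole-exome scale), plus
  30% non-binder background rows (IC50 0.5–30 µM, rank 1.5–50) so the
  binder filter has something to reject. The resulting cohort's median
  HAPS sits near 11 — on purpose in the neighborhood of the score's
  whole-exome cutoff of 10.
- Mutations ≈ 3 × total neoantigens with lognormal noise over a 30 Mb
  footprint; survival is exponential with a 12-month baseline median and
  hazard ×0.5 at/above HAPS 10; censoring is independent Uniform(0, c)
  with c solved (closed form + Brent) so the expected censoring fraction
  is 0.20; LOH prevalence 0.17; repertoires are rank-frequency power laws
  (exponent 1.0, 200 clones, 20k reads) with CASS…F-framed CDR3s of
  length 8–20; response is logistic on z-scored (HAPS, TMB, diversity)
  with coefficients (0.8, 0.5, 0.5) and intercept −0.4. Responders'
  on-treatment repertoires grow more clonal (exponent +0.3), progressors
  slightly less (−0.1).
- Reproducibility: a master seed fans out per stage as
  `SeedSequence([seed, stage_index])` with a fixed stage table, so any
  stage can be regenerated alone; bundle writing uses fixed float
  formatting, making same-seed bundles byte-identical.

Because response and survival are generated *from the scores the real
modules compute on the generated inputs*, effect directions downstream
are consistent by construction. What passing tests on these cohorts show
is that the estimators recover the generative structure they target; what
they cannot show is robustness to the things real data add — population
HLA frequencies and linkage, binding-predictor bias, panel/exome
discordance, informative censoring, batch effects in TCR sequencing.

Problem sizes used by the default test run and the acceptance script
(300-patient cohorts, 5k-read repertoires, 50-replicate scans at n = 500)
were chosen as the smallest sizes at which the measured properties are
stable; all are configurable upward.

## Numerical conventions and degenerate inputs

- Strict "<" at the binder thresholds; "≥" at the HAPS, NN and network
  classification boundaries.
- The Cox solver damps Newton steps to ±5 per iteration and stops on
  |β| > 40 (monotone likelihood); the Wald CI uses the 0.975 normal
  quantile.
- Empty repertoires, all-censored cohorts, constant scores, single-class
  labels, unresolvable alleles, missing loci and malformed table rows are
  hard errors with the offending item named — never silent defaults.
- TSV dialect: tab-separated, header row, UTF-8, "." for missing; readers
  reject rows with empty required cells, reporting line numbers.

## Known limitations

- The package consumes upstream outputs (HLA typing, binding predictions,
  LOH calls, clone tables); it implements none of those callers, so their
  error modes propagate.
- The divergence score treats all binding-domain positions equally; no
  weighting by peptide-contact residues.
- The HAPS cutoffs 10 / 1.31 and the NN threshold 0.436 are shipped as
  defaults from their source analyses, not re-derivable from package
  data; `scan_cutoff` and `youden_threshold` exist precisely so users can
  re-derive them on their own cohorts.
- The cutoff scan's optimism is reported, not corrected (see above).
- Class II divergence and HLA-II neoantigens are out of scope.
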