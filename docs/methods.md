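# Methods

This note records the models, numerical choices and known limitations of
`spelltract`, in the order the pipeline runs them.

## Spelling-error scoring

A response is *correct* only if, after whitespace trimming and
case-folding, it equals the target exactly; typing case is deliberately not
treated as a spelling error.  Per-participant accuracy is the proportion of
correct items (40 items by default); mean orthographic and phonological
error distances are computed over error responses only and are undefined
for a perfect speller.

**Edit distance.**  The optimal-string-alignment (restricted)
Damerau-Levenshtein recurrence is used: insertions, deletions,
substitutions and adjacent transpositions each cost 1, and a transposed
pair cannot be edited again afterwards.  Restricted vs unrestricted
variants differ only on contrived inputs (e.g. "ca" → "abc"); both agree on
every scoring example the package guarantees, and the restricted recurrence
is the one implemented in the common spelling-research tooling.  The
normalization denominator is the longer of the two sequences, making the
distance a [0, 1] measure; two empty sequences have no defined distance and
raise rather than returning 0.

**Phonological distance and tokenization.**  Both strings are transcribed
to IPA and compared with the same normalized distance over *phone symbols*:
stress marks (ˈ ˌ) are stripped — stress placement is not a spelling
phenomenon — and combining diacritics (including affricate tie bars with
the following base character) attach to their base phone, while diphthong
components and the length mark ː count as individual symbols.  This
symbol-level granularity, rather than one token per phoneme, is what
reproduces the reference worked example: dissuade (d ɪ s w e ɪ d, 7
symbols) vs dissaude (d ɪ s ɔ ː d, 6 symbols) gives 3 edits / 7 = 0.43.
Phoneme-level tokens (treating eɪ and ɔː as single units) would give
2/6 = 0.33 instead; the symbol-level convention is therefore frozen and
exercised by golden tests.

**G2P adapters.**  Transcription is pluggable.  `EspeakProcessG2P` shells
out to an `espeak-ng`/`espeak` binary (British English voice by default)
when one is installed.  `LexiconG2P` reads a word → IPA table; the package
ships a frozen British-English reference table covering its built-in
spelling-test lexicon (40 long, low-frequency words with one-to-many
phoneme-grapheme mappings) and the worked-example misspellings.  The table
is a calibration fixture: its entries are authored reference
transcriptions in eSpeak-style broad IPA, constrained by the worked-example
distances, not output exported from a G2P run.  Pipelines can bypass
adapters entirely via `target_ipa`/`response_ipa` columns; when no
transcription source is available the phonological stage is skipped with a
warning rather than failing the run.

## Synthetic cohort generator

The generator emulates the statistical structure the inference chain is
designed to detect, with every default chosen to mirror a realistic
73-participant adult cohort on a difficult 40-item spelling-to-dictation
test.

* **Scores** come from a two-component Gaussian mixture, truncated to
  [0, 1] and quantized to multiples of 1/40.  Defaults: means 0.22 and
  0.55 with variances 0.008 and 0.041 (the printed σ values of the
  reference distribution are interpreted as variances — √0.054 ≈ 0.23
  matches the full-sample SD ≈ 0.23, whereas reading them as SDs would
  not), and weight 41/73 on the low component, matching the observed group
  sizes; the weight is configurable because it is not separately reported.
* **Responses** realize exactly `round(score × n_items)` correct items per
  participant rather than independent Bernoulli draws.  Bernoulli
  realization would add binomial noise (SD ≈ 0.08 at 40 items) on top of
  the mixture and wash out the bimodality of realized accuracy that the
  GMM stage must detect; the stratified realization keeps realized
  accuracy equal to the mixture draw, which is what the mixture parameters
  describe.  Errors are phonologically plausible (homophonous respelling
  via grapheme substitutions; response IPA = target IPA by construction)
  with group-dependent probability (0.65 high / 0.30 low) or letter-level
  perturbations (1 edit high / 3 edits low) whose synthetic pronunciation
  deviates by about one phone symbol regardless of the letter-edit count —
  so groups diverge more orthographically than phonologically, the
  interaction the LME stage tests.
* **Profiles** are a smooth baseline FA curve (0.42-0.52) plus
  moving-average-correlated noise (SD 0.04 per node; adjacent-node FA is
  correlated in real tracts — white noise is available as a degenerate
  window).  Inside a planted contiguous node window, FA gains a slope
  b = σ·r/√(1−r²) on the standardized score, so the per-node score-FA
  correlation has expectation r in the affected (sub)sample.  Effects can
  be restricted to the high or low group (standardized within that group)
  and/or applied cohort-wide: the default study configuration plants
  r = +0.65 at nodes 55-79 of the left ILF among high performers and
  r = −0.65 at nodes 28-52 of the right SLF-III among low performers, each
  with a cohort-wide r = ±0.35 component in the same window so tract-FA
  also predicts scores in the full sample (as in the motivating design,
  where the group-specific clusters sit inside tracts that were selected
  on the full sample).  These sizes were calibrated once by simulation so
  the full pipeline recovers the planted structure in essentially all
  seeds at the study's n; they are configuration, not fit to any observed
  outcome.
* **Bundles** are smooth noisy curves threaded through the toy ROI
  geometry (lateral offset SD 1.5 mm, small smooth jitter), with the
  left/right count split satisfying the LI target exactly and optional
  injected outliers (8× lateral offset, ~double length) for the screening
  rules.  **Laterality** tables draw per-participant LI from normal
  distributions with tract-specific targets (SLF-III +0.24/0.14,
  ILF +0.46/0.22, arcuate −0.27/0.18, SLF-I −0.19/0.37, SLF-II 0.03/0.18).

What the generator does *not* emulate: registration error, FA measurement
noise correlated between tracts, partial-volume effects at bundle
crossings, keyboard typos as distinct from spelling errors, or
item-difficulty structure beyond random item intercepts.  Passing tests
therefore show that the machinery is correct and calibrated on data with
the assumed structure, not that real acquisitions satisfy that structure.

## Tractometry

ROIs are axis-aligned plane segments (finite extent, slab tolerance
0.5 mm) or boxes, with AND/NOT roles.  Intersection counts either a
sampled point inside the region or a segment crossing the plane within
bounds, so coarse step sizes cannot miss a crossing.  The toy frame puts
frontal AND planes on the anterior-commissure coronal plane (y = +15), the
shared parietal plane at y = −15, stacks the three SLF branches
dorsoventrally, and excludes arcuate fibres from the SLF with a temporal
NOT box below the Sylvian proxy.  Real template-space ROIs are inputs, not
part of the package.

Kept streamlines are reoriented first-ROI → last-ROI so node 1 is adjacent
to the frontal (or posterior, for the ILF) ROI in both hemispheres.
Screening iterates (cap 5) removing, simultaneously per iteration, (a)
streamlines *longer* than mean + k·SD of tract length — one-sided, because
probabilistic tracking's characteristic failure is wandering far past the
bundle, and short streamlines were already excluded at tracking — and (b)
streamlines whose maximum node-wise Mahalanobis distance from the core
(node-wise mean coordinate) exceeds 4, under the node-wise position
covariance (Euclidean over RMS spread behind a flag, and as automatic
fallback for degenerate covariances).  k = 3 by default; the SLF presets
use k = 1, the adjusted screening those branches need.  Simultaneous
removal makes cleaning order-independent.  Note that a one-sided 1-SD rule
iterated to a fixpoint necessarily keeps trimming the length tail; the
iteration cap is what bounds it.

Profiles clip each streamline between the first and last AND ROI, resample
to 100 arc-length-equidistant nodes, and weight each streamline at each
node by exp(−d²/2) of its Mahalanobis distance d to the core (kernel scale
1 covariance unit, configurable); weights are normalized to sum to 1 per
node, and the pre-normalization weight mass is kept as an effective-support
diagnostic.  FA samplers: trilinear interpolation in a NIfTI volume, a
per-point callable, or a constant field for fixtures.

## Inference chain

* **Spearman correlations**: Pearson on average ranks; exact permutation
  p (full enumeration, vectorized) for n ≤ 9, t approximation otherwise;
  missing values pairwise-complete.  Timed covariates with
  higher-is-worse polarity (RAN) are sign-flipped before the behavioral
  correlation matrix, which is FDR-controlled (Benjamini-Hochberg step-up)
  across all pairs at q = 0.05.
* **GMM split**: 1- and 2-component univariate mixtures by EM
  (scikit-learn backend; variance floor 10⁻⁶, tolerance 10⁻⁸, 20
  restarts), compared by AIC with 3k − 1 free parameters.  The split
  criterion is the density's local minimum between the two means (2001-
  point grid scan + bounded refinement; absent when the fitted density is
  unimodal between the means, in which case the split and the group
  analyses are skipped with a warning).  At n = 73 some genuinely bimodal
  configurations yield unimodal fitted densities — that is sampling
  variability, not an error state.
* **Stepwise selection**: forward partial-F entry (p < 0.05) of the best
  candidate, backward removal (p > 0.1) of the worst, looped to a
  fixpoint, ties broken by candidate order.  With 10 candidates and
  p-Enter 0.05 a spurious entry occurs in ≈ 1 − 0.95^8 of completed
  searches whatever the true effects; correctness is therefore asserted
  against a brute-force oracle's decisions rather than an absolute
  exact-recovery rate.
* **Along-tract clusters**: per-node rank correlations computed by one
  matrix product over standardized ranks, the same statistic applied to
  permuted scores (default 10,000 permutations in analysis, 1,000 in
  tests; seeded).  Clusters are maximal runs of p < α nodes.  The critical
  length is the smallest L with P(null max run ≥ L) ≤ 0.05.  Because run
  length is discrete, cutting at the 95th percentile *inclusively* admits
  the whole probability mass at that value and inflates the family-wise
  rate several-fold (measured 21% on white-noise profiles); the exceedance
  form restores control (measured 2-3%).  Per significant cluster,
  cluster-FA (per-participant mean over its nodes) is correlated with
  scores; tracts without a significant cluster contribute their tract-FA
  correlation, so every tract × group cell feeds one p-value into the
  FDR family (q = 0.05).
* **Specificity regression**: OLS of cluster-FA on spelling, vocabulary,
  spoonerisms and sight-word-efficiency scores, with standardized β
  (B·SD_x/SD_y) and VIF = 1/(1 − R²_j) per predictor.
* **Group profile comparison**: per-node Welch t with the same max-run
  permutation scheme over group labels (max-|t| thresholding behind a
  flag).
* **Lateralization battery**: per-tract one-sample t against 0 at a
  Bonferroni-adjusted α (0.05/n_tracts); LI-score Spearman correlations
  and pooled-variance two-sample group comparisons each FDR-controlled
  across tracts.
* **Error-type LME**: distance ~ Group × ErrorType with crossed random
  intercepts for subject and item (statsmodels MixedLM, variance
  components), fitted by ML — not REML — because the interaction is tested
  by a likelihood-ratio test of nested fixed-effect models (χ², df 1).
  Participants whose mean distance deviates > 2.5 SD from their
  group × error-type cell are excluded first.  Optimizers are tried in a
  small cascade (lbfgs, cg, powell) because boundary variance components
  defeat single optimizers on clean synthetic data; non-convergence under
  all of them raises.  Simple group effects per error type use two-sample
  t-tests on participant means, Bonferroni-corrected for the two tests.

## Pipeline and reproducibility

`run_full` derives every stage seed from the config seed through one
generator, stamps the SHA-256 config hash and seed into the report, records
warnings per stage, and on stage failure stores the error and continues
where inputs allow.  A rerun with the same config is bit-identical.
Missing tracts yield missing profiles handled pairwise per analysis.
Stage outputs (scored responses, profile TSV, report JSON) are written to
the output directory; the subcommands run stages standalone on those
files.

**Problem sizes.**  The test suite runs the permutation machinery at 300 —
1,000 permutations and cohorts of 32-73, the null-calibration check over
500 synthetic cohorts, and the LME checks at 20 subjects per group × 12
items; these sizes give stable rates while keeping the suite fast, and the
analysis-scale defaults (10,000 permutations, 73 participants) remain the
configuration defaults.

## Known limitations

* The reference transcription table covers the built-in lexicon only;
  scoring arbitrary corpora phonologically requires an eSpeak NG
  installation or precomputed IPA columns.
* The restricted edit distance is not a metric over all inputs (triangle
  inequality can fail in contrived cases); for scoring purposes only the
  pairwise distance matters.
* Toy ROI geometry validates the segmentation machinery, not anatomical
  plausibility; no registration or template warping is provided.
* MixedLM variance components are reported as fitted even when a
  component sits at zero; only convergence, not boundary diagnostics, is
  surfaced.
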