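# Methods

This note records the models, parameter choices and numerical conventions
behind `promfunc`, and what its synthetic-data tests do and do not
establish.

## Motif model and scanning

A motif of width *W* is a count matrix over A/C/G/T; frequencies are
`(count + pc) / (rowsum + 4·pc)` with pseudocount `pc ≥ 0`. A window scores
`Σⱼ log2(f_j(b_j) / q(b_j))` in bits. The background `q` is *local*: the
base composition of a window (default 100 bp) centered on the candidate
site and clipped at the sequence ends. Local conditioning makes scores
comparable between GC-rich promoters and AT-rich background, which matters
when ranking sites pooled across regions. Design choices:

- **Log base**: bits (log2) throughout.
- **Background floor**: local abundances are floored at 1e-3 and
  renormalized, so a composition with a missing base cannot produce an
  infinite score. With `bg_window ≥ 2·L` the scan reduces exactly to
  global-composition scoring (tested).
- **Ambiguity codes**: a window containing any non-ACGT character scores
  −∞ and can never be selected as a best site. Ambiguous bases are also
  ignored when tallying local composition.
- **Minus strand**: scored by scanning the reverse complement of the whole
  sequence, so the local background of a minus-strand site is the
  complemented composition and strand symmetry is exact (scanning the
  reverse complement of a sequence returns the same score multiset with
  strands flipped).
- **Ties** for the best site in a region: leftmost, then plus strand.
- **Information content**: `IC_j = 2 + Σ_b f log2 f` bits against a uniform
  background, the sequence-logo convention.

## Site prediction

One site per peak is assumed (the highest-scoring window over both
strands). PWMs are ranked by ROC AUC computed through the Mann-Whitney
identity with ties counted ½ — this makes small-sample oracles exact, at
the price of ignoring ROC interpolation subtleties that only matter for
plotting. Background sequence is sampled length-matched and uniform over
the unbound portion of the genome, without replacement across peaks
(re-draw on collision, 1000 attempts before a hard error naming the
unplaceable lengths).

The prediction filters follow the screen's rules: likelihood ratio vs
background ≥ 10, i.e. score ≥ log2 10 ≈ 3.32 bits (the "10-fold" phrasing
is read as a likelihood ratio), and peak FDR strictly below 0.05. A site
not contained in any supplied peak is an error, never silently dropped.

## Mutation design

Site-abolishing mutations are chosen greedily: each round evaluates every
single substitution at a not-yet-mutated position, scores the site against
the PWM with a *uniform* background (the designer has no ChIP context and
must be reproducible), and takes the admissible minimum. A substitution is
inadmissible when flanks + mutated site would match any library IUPAC
pattern on either strand — the factor's own consensus is excluded from the
library (`ConsensusLibrary.without`), otherwise the original site trivially
matches. Ties break toward the higher-information-content position, then
leftmost, then alphabetical base. The budget is five substitutions; the
loop stops early at the minimum achievable score, or returns the partial
plan flagged `exhausted` when no admissible substitution remains. Greedy
search is not guaranteed to equal the optimum over all ≤5-subsets; the test
suite keeps a per-round exhaustive argmin oracle for small widths.

## Reporter statistics

- **Normalization**: each well is divided by the median of all wells on its
  plate, controls included. The median is robust and scale-free; the exact
  statistic used by the original screen is not documented, and any
  per-plate scale factor cancels from fold changes either way.
- **Test**: two-sided Welch (unequal-variance) t-test on the 9 wild-type vs
  9 mutant normalized values per cell line. The prep/transfection nesting
  is ignored by default; `analyze(average_technical=True)` instead averages
  transfections within preps and tests 3 v 3. Degenerate case: both groups
  zero variance → p = 1 if the means are equal, else 0.
- **Multiplicity**: one global Benjamini-Hochberg family pooling all
  experiments — sites × cell lines plus negative-control and unbound-site
  experiments (455×4 + 12 + 23 = 1,855 in the reference screen's shape).
  `bh_adjust` is a hand-rolled four-line step-up (cross-checked against
  statsmodels in the tests); functional means q strictly below 0.025.
- **Direction**: functional and mutant dimmer than wild type ⇒ activating;
  brighter ⇒ repressing.
- **Summaries**: per-TF and overall counts; "ubiquitous" means functional
  in all four cell lines, and ubiquitously activating/repressing requires a
  consistent direction across them. Constructs missing a cell line are
  excluded from ubiquity counts with a warning. Percentages are reported
  rounded to the nearest integer (one decimal for control-class rates).

## Class comparisons

- **Conservation**: per-site mean of the per-base track over the motif
  span; per-position profiles are oriented to the motif strand and
  aggregated as mean ± SEM. The optional flank is clipped at fragment ends.
- **TSS distance**: signed site-midpoint − TSS distance in transcript
  orientation, downstream positive; class comparisons use |distance|, and
  the cumulative law ℙ_M is the ECDF of |distance|.
- **Two-sample tests**: KS (exact small-sample null where feasible) for
  distribution comparisons; Wilcoxon rank sum where a location test is
  wanted.
- **Per-position IC permutation test**: ΔIC between groups at one motif
  position, group PWMs built with pseudocount 0.5; one-sided p =
  (1 + #{ΔIC_perm ≥ ΔIC_obs}) / (n_perm + 1) with n_perm = 9,999 by
  default; exact enumeration replaces sampling for groups smaller than 5
  when the arrangement count is feasible.
- **Homotypic clusters**: non-overlapping hits at the prediction threshold,
  overlaps resolved best-first (the original analysis states no overlap
  rule; best-first is deterministic and conservative).
- **Secondary-motif enrichment**: presence/absence of ≥1 hit per promoter,
  one-sided Fisher exact for overrepresentation (p near 1 ⇒
  underrepresentation). The screen's own enrichment method was score-based;
  Fisher on presence/absence was chosen for exactness and zero
  dependencies, so published enrichment p-values are not exact targets.
- **Normalized CpG**: `(#CG/(L−1)) / ((#C/L)(#G/L))`, reverse-complement
  invariant, undefined without at least one C and one G.

## Synthetic screen: what it states and what it omits

Defaults are the screen's published shape: 455 constructs, ~1 kb promoters,
per-cell-line functional fractions (0.49, 0.38, 0.36, 0.39), repression in
one-third of functional sites, |log2 fold| effects uniform on [0.5, 2],
multiplicative lognormal noise with CV 0.2, 3 preps × 3 transfections per
allele per cell line, 96-well plates carrying 4 positive and 4 negative
control transfections, 12 negative-control constructs (never functional)
and 23 unbound PWM-match constructs (functional fraction 0.30), both
assayed in the first cell line only. Peaks span ±150 bp around planted
sites with summits jittered N(0, 20 bp); conservation is N(0, 0.5) baseline
plus a 1.5 elevation over functional sites. Activating sites sit near the
TSS (N(0, 30 bp)), repressing sites at the translational start
(N(0, 10 bp)), unverified sites scattered upstream — the class geometry the
screen reported. Where the original work states no value (noise CV, effect
range, peak geometry, conservation scale), values were chosen once as
field-realistic and are exposed as config fields.

Two deliberate generator conventions:

- **Exact class fractions.** The configured per-cell-line functional
  fractions are realized exactly by stratified assignment rather than
  i.i.d. Bernoulli draws. The config *is* the ground truth; removing
  binomial noise from the truth table means recovery tests measure the
  pipeline's detection loss, not generator sampling error.
- **Count-based emission.** Planted site sequences are drawn from the
  motif's raw count frequencies, not the pseudocount-smoothed scoring
  frequencies: the pseudocount regularizes scoring and is not part of the
  emission model.

A green synthetic run establishes that the pipeline recovers planted
functional structure (fractions within ±5 points, ≥95% direction accuracy,
false-positive control at the BH level) under multiplicative lognormal
noise with independent wells. It does not establish robustness to features
of real screens that the generator omits: plate-position effects, correlated
replicates within preps, cell-line-specific baselines, sequence-dependent
cloning artifacts, or ChIP peaks displaced from their sites.

## Numerical notes

- Scores are floats in bits; BED export rounds bits × 100 to integers.
- `compute_auc` uses midranks, so monotone transforms of scores leave it
  invariant (tested).
- All generator randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical FASTA.
- The reference-count expansion (`datasets.reference_calls`) assigns
  cell-line memberships of partially functional constructs greedily toward
  the largest remaining per-cell-line totals; the expansion reproduces every
  published marginal (per-TF tested/functional/ubiquitous, per-cell-line
  totals, the 63/75/77/105/135 distribution) but interior per-TF ×
  cell-line cells are not uniquely determined by the published tables.
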