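# Methods

This note records the model the scan implements, the defaults and why they
are set where they are, what the synthetic data generator does and does not
emulate, and the numerical conventions.

## Pipeline

1. **Masking.** For each sequence independently, windows of 10 of its real
   residues (gaps skipped) are slid along the alignment; a window
   *qualifies* when at least 4 of its residues agree with fewer than 30%
   of the other residues in their column. The union of residues covered by
   qualifying windows is grouped into maximal runs; each run is trimmed to
   its outermost sub-30%-identity residues (windows overhang into agreeing
   flanks, which are not part of the bad stretch), and trimmed runs of at
   least 10 residues are replaced by `X`. Identities are computed on the
   unmasked input, so masking one sequence never cascades into another.
   The rule targets mistranslated or misassembled stretches of a single
   sequence, hence the per-sequence formulation; whether windows should
   run in aligned or ungapped coordinates is a genuinely open choice, and
   the ungapped (real-residue) reading was picked because gaps carry no
   evidence of mistranslation.

2. **Column classification.** A column is *selected* when it holds ≥ 10
   real residues (`X` never counts), including one for the reference
   species and one for every required anchor species. The default anchor
   is the shortest-lived non-reference species in the trait table — the
   role the shrew plays in mammal panels, guaranteeing each selected
   column spans the lifespan range. (The anchor is a user choice; a
   taxonomy-aware choice such as "shortest-lived non-rodent" requires
   information a bare trait table does not carry.) Selected columns with
   ≥ 3 non-reference residues differing from the reference residue are
   *fit*; the rest are *conserved*.

3. **Scoring.** Fit-column responses are BLOSUM80 similarities (half-bit
   units) of each non-reference residue to the reference residue, shifted
   by `log10(m_s/m_ref)` where `m_s` is the species' root-to-tip path
   length on a substitution-scaled tree, and clamped to the score range
   attainable against that reference residue. "Tree length of a species"
   is read as root-to-tip path length: the quantity must be
   species-specific and comparable to the reference's value, which the
   sum of all branches is not. When no substitution tree is supplied, one
   is estimated on the fixed input topology by unweighted least squares to
   Poisson-corrected pairwise distances `d = −ln(1 − p)` (mismatch
   fraction over shared real-residue columns); negative fitted lengths are
   truncated to zero, and the branch pair meeting at the root — whose sum,
   not split, is identifiable — takes the minimum-norm split. A
   user-supplied substitution tree always takes precedence: the estimator
   is a desk-scale convenience, not a maximum-likelihood replacement.

4. **PGLS.** Per column, `B80mut ~ 1 + log10(MLS) + log10(mass)` with
   error covariance σ²V, `V_ij` the root-to-MRCA path length on the time
   tree restricted to the column's species (so pruning is exactly
   row/column deletion) and Pagel's λ (default 1) multiplying the
   off-diagonal. Both traits are log10-transformed by default: they span
   orders of magnitude, and the companion region-level analysis is
   explicitly a fit against log10 MLS; `--no-log-traits` switches this
   off. The solve whitens with the Cholesky factor of V and runs OLS on
   the whitened system; p-values are two-sided t-tests on n−3 degrees of
   freedom. The engine agrees with R's `nlme::gls` + `ape::corBrownian`
   to ~1e-9 on a frozen cross-check instance, and with explicit
   `V⁻¹`-normal-equation GLS to 1e-10 on random instances.

5. **Calls.** Longevity-selected: `b_MLS > 0` and `p_MLS < α` (default
   0.01). Because the p-value is two-sided and the sign is also required,
   the call is effectively one-sided at α/2 under the null. Conserved
   columns carry `(0, 1)` by convention. No multiple-testing correction is
   applied — the design instead pairs every scan with a randomized
   control: a uniformly random permutation of (MLS, mass, tip label)
   triples over the non-reference species (fixed points allowed; the text
   definition of swapping "without replacement" does not imply a
   derangement, and a uniform permutation is the simplest faithful
   reading). Alignments, scores and mutation-rate corrections are not
   permuted, so the identical column set is refit.

## Degenerate fits

Columns with < 4 usable species, a collinear design, or a constant
response return `(b=0, p=1)` flagged, mirroring the conserved convention
rather than aborting a scan. A zero-residual fit that is *not* constant
(exactly linear response) returns the exact coefficients with p = 0 for
nonzero terms: there is no residual variance to test against, but the
slope itself is perfectly determined.

## Synthetic data

The generator produces the three structures the method assumes:

- **Tree.** A Kingman coalescent topology rescaled so all tips sit at the
  requested depth, with 20% of the depth added to every terminal branch
  (the coalescent part squeezed into the rest). Mammal ortholog panels
  sample species spread across orders; their terminal branches are long
  fractions of total depth, unlike the near-zero cherry branches of a raw
  coalescent. This matters quantitatively: responses are integer BLOSUM
  scores, and on a near-zero terminal branch the quantization noise would
  dwarf the Brownian signal the GLS covariance expects, degrading both
  calibration and power in a way real panels do not exhibit.
- **Traits.** Correlated Brownian motion of (log10 MLS, log10 mass) along
  the tree; defaults (root lifespan 10 y, tip log-variance 0.12, mass
  log-variance 2.25, correlation 0.5) give tips spanning roughly 3–90
  years and shrew-to-whale masses, with the longest-lived tip as
  reference.
- **Columns.** *Conserved*: one residue everywhere. *Null* and *planted*:
  each species' target score is `base + effect·(log10 MLS − mean) +
  Brownian tree noise` (effect = 0 for null), with `base` centred on the
  off-diagonal scores of the reference residue's matrix row — a divergent
  column's residues sit below the self-score, which is typically far
  above the rest of the row. Residues are drawn by a Gaussian-kernel
  softmax over the row's scores centred at the target, so the realized
  response is the target quantized to the attainable score set and the
  planted slope is recoverable in score units. Non-conserved columns are
  spread evenly among conserved ones so that genuine divergence stays too
  sparse to trip the masking rule.

What the generator does **not** emulate: indels and alignment error,
site-rate heterogeneity beyond per-species multipliers, domain structure,
non-stationary amino-acid composition, and correlated selection across
columns. Passing tests therefore demonstrate that the statistical engine
is calibrated and powerful under its own assumptions — not that real
proteome scans are free of the artifacts the masking and filtering steps
exist to contain.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| window / min divergent / identity | 10 / 4 / 0.30 | masking rule |
| min run | 10 residues | smallest maskable stretch |
| min chars | 10 | residues needed for a selected column |
| min diff | 3 | non-reference mismatches for a fit column |
| α | 0.01 | significance threshold on `p_MLS`, `p_mass` |
| λ | 1 | Pagel's lambda (full phylogenetic signal) |
| matrix | BLOSUM80, half-bit | appropriate at 80–90% identity |
| min fit species | 4 | leaves ≥ 1 residual degree of freedom |

Simulation problem sizes used by the test suite and the acceptance script
— 2,000 null fit columns for calibration, 100 planted columns at effect
6 score-units per log10 year and tip noise 0.5 for power, 300 random toy
alignments (1,000 in the test suite) for the preprocessing oracle — are
the package's own choices, small enough to run everywhere while leaving
the binomial/KS tolerances meaningful.

## Numerical conventions

- Column indices are 0-based in memory, 1-based in every file written.
  Reference coordinates count every non-gap position, including masked
  `X`s, matching residue numbering of annotation databases.
- Ambiguity codes B/Z/U/O are masked to `X` on input with a warning;
  scoring is defined over the 20 standard residues only.
- Ultrametricity is enforced with relative tolerance 1e-6 on root-to-tip
  spread.
- Result tables store floats at full precision (`repr`), so write→read
  round-trips are exact.
- The composition χ² defaults to a goodness-of-fit reading (focal counts
  against fixed reference proportions, df = 2, n = focal total), which
  approximately — not exactly — reproduces published statistics of this
  design; a 2×3 contingency variant is available via `method=
  "contingency"`. The exact construction behind such published tables is
  typically unstated; both variants share df = 2.

## Known limitations

- The substitution-tree estimator is distance-based, not ML; with very
  sparse overlap between species pairs its distances are noisy, and it
  errors out (by design) on saturated pairs (`p ≥ 1`).
- Integer score responses are only approximately Gaussian; calibration
  degrades on trees with near-zero terminal branches (see above).
- The scan's p-values are screening scores, not hypothesis tests: the
  intended inference is the contrast against the randomized control, not
  any single column's p-value.
- One reference proteome anchors the similarity axis; a reference with
  poor sequence quality contaminates every column it appears in.
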