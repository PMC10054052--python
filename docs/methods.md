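# Methods

## Scope and data model

The package assesses mercury risk from paired measurements: one fruiting
body split into cap and stem, plus the soil/substrate directly beneath it,
all as total mercury in mg kg⁻¹ dry weight (DW).  The CSV schema is one row
per fruiting body (`locality, species, cap_hg_dw, stem_hg_dw, soil_hg_dw`):
every index pairs a cap and a stem with exactly one substrate value, so a
strictly 1:1 sample design is assumed.  Concentrations must be finite and
positive; values below the analytical limit of quantification (default
4.45 × 10⁻⁶ mg kg⁻¹ DW, the LOQ of cold-vapour AAS mercury analysers) are
excluded with a logged count rather than imputed or zeroed — a below-LOQ
reading carries no usable magnitude, and silently zeroing it would bias
every ratio index downward.  Decimal separator is `.` only; no locale
handling.

Summaries report the arithmetic mean, the sample standard deviation
(n − 1 denominator, the convention for field-sample summaries; 0 for a
single record), minimum and maximum per group.

## Indices

All indices are ratios, hence linear in their concentration argument.

- `Cfi = C_soil / C_background`, background 0.06 mg kg⁻¹ DW.  Classes are
  half-open (`[0,1)` low, `[1,3)` moderate, `[3,6)` considerable, `[6,∞)`
  very high), so a boundary value falls in the upper class.  The pipeline
  logs a warning when a factor lies within 1 % of a bin edge, because the
  class is then sensitive to rounding of the input mean.
- `BCF = C_tissue / C_soil`.  The conventional statement (> 1 accumulator,
  < 1 excluder) leaves BCF = 1 unassigned; it is classed as *excluder* here
  — the conservative choice, since "accumulator" is the actionable label.
- `Q_c/s = C_cap / C_stem`, no classes.  Per record it equals
  `BCF_cap / BCF_stem` exactly (an algebraic identity that the tests check
  to machine precision).
- `%PTWI = C_FW × W / L × 100` with weekly consumption
  `W = 0.18 kg FW` and tolerable weekly intake `L = 0.28 mg` per person;
  above 100 % is hazardous.  The FW concentration is obtained as
  `C_DW × dry-matter fraction` (default 0.10).
- `THQ = (Efr × ED × ADC × CE) / (RfDo × BW × ATn) × 10⁻³`, with ADC in
  g day⁻¹ and the 10⁻³ factor converting grams to kilograms.  Under the
  defaults `Efr × ED = ATn`, so THQ reduces to
  `ADC × CE × 10⁻³ / (RfDo × BW)`; the parameters are still kept separate
  because assessments with partial-year exposure need them.

**THQ concentration basis.**  The textbook definition takes CE on a fresh
weight basis, but the published per-locality THQ table this package
reproduces is arithmetically consistent only with CE on the dry-weight
basis (e.g. a cap mean of 0.97 mg kg⁻¹ DW yielding THQ 1.19).  Both modes
are implemented; `basis="DW"` is the reproduction default, the basis used
is recorded in every result, and `THQ_DW = THQ_FW / dry-matter fraction`
exactly.  Under default parameters `%PTWI / THQ_FW ≈ 52.53` for every
concentration — a useful cross-index consistency check.

**Aggregation.**  Per-species BCF and Q_c/s are aggregated as the mean of
per-sample ratios (not the ratio of group means): per-sample ratios are the
quantity on which the paired cap-vs-stem signed-rank test is defined, so
the table and the test stay coherent.  The ratio-of-means alternative is
available via a flag.  Per-locality %PTWI and THQ are computed from the
locality mean concentration, the convention under which published tables of
this kind are built; per-sample results can be had by calling the index
functions directly.

Report tables display 3 significant figures; full precision is kept
internally.

## Rank-based tests

Kruskal–Wallis (mid-ranks, tie correction, chi-square p with k − 1 degrees
of freedom), one-sample Wilcoxon signed-rank (exact null distribution for
n ≤ 25 without ties among |differences|, otherwise normal approximation
with tie and continuity correction; zero differences dropped), and Spearman
correlation (mid-rank Pearson formula, two-sided p from the t
approximation).  All p-values are two-sided; the locality comparison uses
the pooled all-locality median as the signed-rank reference, mirroring how
such surveys display a median reference line.  No multiple-testing
correction is applied by default, matching how such surveys report; a
Bonferroni helper is provided.  The computational kernels are scipy.stats;
this package fixes the branch policy, tie handling and error contracts, and
the test suite checks the results against independently coded exact
enumeration oracles (permutation and sign-flip distributions) at small n.

Numerical caveats worth knowing:

- The chi-square approximation to the Kruskal–Wallis p-value can be poor at
  very small n (differences above 0.2 for some 2-group instances with
  n = 4); the exact-enumeration comparisons in the tests use instances
  where the approximation is representative of its behaviour at realistic
  group sizes.
- The signed-rank test's null hypothesis is *symmetry about the reference*,
  not "median equals reference".  On right-skewed data (lognormal
  concentrations) referenced at the median it is anti-conservative
  (empirically ~9–10 % rejection at the nominal 5 % for n = 30).  The
  type-I calibration simulation therefore runs each test under its own
  null — identically distributed groups for Kruskal–Wallis, independent
  vectors for Spearman, and a symmetric sample (log scale) for the
  signed-rank — where all three hold the 5 % level within Monte-Carlo
  error.  Per-locality signed-rank stars on skewed raw concentrations
  should be read as descriptive, not as calibrated tests.
- Kruskal–Wallis and Spearman are invariant under strictly monotone
  transforms (they see only ranks); the signed-rank test is **not** (it
  ranks magnitudes of differences).

## Synthetic-data generator

Raw per-sample survey data were never published, so the generator emulates
the published summary structure: for each locality, soil is drawn from a
lognormal matching the published mean and SD, truncated by rejection
sampling (1000 retries per draw; an unreachable window is a configuration
error) to the published min–max range; then per sample
`stem = soil × B × ε₁` and `cap = stem × Q × ε₂`, where B and Q are
per-species lognormal draws centred on the published stem BCF and Q_c/s
means and ε is unit-mean multiplicative lognormal noise (log-SD 0.2 by
default).  Lognormal laws are used throughout because concentrations are
positive and right-skewed and the original survey rejected normality.

Design choices and what they buy:

- Conditioning tissue on soil builds in the positive soil–tissue rank
  correlation observed in the field; deriving cap from stem makes cap–stem
  the strongest correlation, reproducing the observed pattern, and keeps
  cap/stem ratios above 1 on average.
- The factor laws' coefficients of variation (0.3 for BCF, 0.15 for Q_c/s)
  are generator choices — the survey prints only factor means — set so that
  per-sample scatter is realistic while nearly all cap/stem ratios stay
  above 1, as reported in the field.
- Because noise has unit mean, the mean of per-sample ratios is an unbiased
  estimator of the configured law means: `recover_parameters` exploits this
  to verify generator ↔ index consistency, with Monte-Carlo error shrinking
  as 1/√n.
- The default configuration reproduces the published sampling design
  exactly: 249 records, 16 localities, 4 species with the published
  per-locality species counts.
- A fixed seed gives byte-identical CSV output.

What the generator does **not** emulate: the published cap BCF means are
not exactly the product of the stem BCF and Q_c/s means (real B and Q are
correlated within samples; the generator draws them independently), and
heavy truncation of a wide soil law (e.g. a locality with mean 0.53 and
range cut at 0.85) shifts the realized mean below the nominal one.  Tissue
concentration levels per locality follow soil × species factors and only
approximate the published per-locality tissue means.  There is no spatial
soil structure and no seasonal (June–October) effect.  Passing tests on
synthetic data therefore demonstrate correctness of the computational
chain and of distribution-level structure, not fidelity to any individual
locality's unpublished raw data.

## Pipeline and golden values

`run_pipeline` is deterministic and idempotent; flags (soil-limit
exceedances against 0.50 mg kg⁻¹ DW, THQ > 1, %PTWI > 100) are derived
from the same table cells they summarise, so flag/table consistency is an
invariant.  Golden tests compare recomputed health-table cells to the
published ones within 1 % **plus** the printed rounding resolution (the
published tables round both the input means and the index values to two
decimals; pure 1 % would misclassify ~10 legitimately consistent cells as
errors).  Six published cells are irreconcilable with the published means
and are excluded and documented in `docs/KNOWN_DEVIATIONS.md`.

Problem sizes used by the test suite: exact-enumeration oracles at n ≤ 9
(≤ 512 sign patterns, 210 group assignments, 120 rank permutations),
parameter recovery at n = 500, and 2000 replicates per test in the type-I
calibration — together a few seconds on one core.
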