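# Methods

## Model

The package treats GP coverage as pure accounting on administrative
counts. A scope (primary-care unit, region, nation) in year *t* is
described by enrolled patients *n(t)* (integer), unassigned patients
*m(t)* (integer) and GP workforce *GP(t)* (real, full-time equivalents).
The patient-to-GP ratio *L(t) = (n(t) − m(t))/GP(t)* — the average list
size per FTE physician — is never stored; it is recomputed from the three
stored quantities, so the identity *m = n − GP·L* holds exactly on every
record and the decomposition

*Δm = Δn − ΔGP·L(0) − ΔL·GP(1)*

is an arithmetic identity, not an estimator. There is consequently no
sampling uncertainty to quantify; the only numerical concern is floating
point, controlled by an identity check at 1e-9 relative tolerance inside
`decompose` (violations raise rather than warn, since they would indicate
a bug, not noise).

**Cross-term allocation.** Any exact three-way split must assign the
ΔGP·ΔL cross term somewhere. The default (`list`) evaluates supply at the
baseline list ratio and productivity at the final workforce; `gp` swaps
the evaluation points; `symmetric` averages the two (a Marshall–Edgeworth
style split). Totals are identical across conventions; individual effects
are not, which is why the convention is an explicit, recorded field of
every result.

**Signs.** Effects are contributions to the change in *unassigned*
patients: positive = worse coverage. Display layers may flip signs;
the data model never does.

**Shares.** Per-scope percentage shares are |effect|/Σ|effects|·100.
With mixed signs, signed shares would exceed 100, so magnitudes are
normalised and the signs carried as metadata; the productivity share is
set by complement so the three floats sum to exactly 100. Per-unit tables
are ordered by the change in the percent of patients without a GP
(each scope's own enrolled denominator per year).

**Aggregation.** Counts and FTE are additive, so unassigned totals and
Δm aggregate exactly from units to nation. Effects do **not** aggregate:
a decomposition of pooled records generally differs from the sum of
unit decompositions (the pooled list ratio is an FTE-weighted mean whose
composition shifts). The tests pin this non-identity on a constructed
counterexample rather than pretending it away.

**Chaining.** Yearly chains telescope exactly in the total and in the
demand effect (both are first differences). Chained supply and
productivity sums are path dependent and need not match the single-step
long-run split; this is documented, permitted behaviour.

## Workforce arithmetic

* FTE = weekly hours / 40, uncapped by default (overtime gives FTE > 1);
  an optional cap is available. Published workforce pairs (6 934 GPs
  ↔ 5 395 FTE in December 2023) imply an FTE share of 77.8%; the source
  report also prints 83.9%. Both constants are exposed
  (`COMPUTED_FTE_SHARE_2023`, `PRINTED_FTE_SHARE_2023`) so reports can
  show the discrepancy instead of silently choosing.
* Unit-level unassigned from a physician roster is enrolled − Σ list
  sizes. A literal FTE-weighted variant (enrolled − Σ FTE·list) is kept
  behind `literal_fte_weighting=True` for comparison; it undercounts
  assigned patients wherever part-timers hold lists, and with the default
  reading the unit identity m = n − GP·L holds exactly with
  L = Σ lists / Σ FTE.
* Age weights default to 1.5 (ages 0–6), 1.0 (7–64), 2.0 (65–74), 2.5
  (75+), on closed integer-age bands partitioning 0–∞; custom band maps
  load from YAML/JSON. Weighted units per patient moved from 1.24 (2009)
  to 1.32 (2023); the implied relative increase is 6.45% (the source
  rounds this to 5%; the computed value is used). The extra workforce a
  case-mix shift requires is gp_fte·(w1/w0 − 1), i.e. 5 395 × (1.32/1.24
  − 1) ≈ 348 FTE, consistent with the published "at least 200" bound.

## Synthetic panel generator

The generator emulates the *qualitative* structure of the Portuguese
2009–2023 series so the whole pipeline is testable without any download.
It does not attempt to match the real series beyond trend shapes and the
national anchor values.

* **Scale.** 55 units in 5 regions over 2009–2023; unit baseline sizes
  are log-normal (σ = 0.5) across units — administrative units are
  right-skewed — rescaled so national enrolment starts at 11.293 million.
* **Demand.** A piecewise-linear enrolment path (anchors 1.0 → 0.972 in
  2016 → 1.0 in 2023) times a one-off purge of 7% of enrolment spread
  over 2012–2013, modelling the administrative removal of non-users; the
  product ends 2023 at 0.93 (−7%, ≈ 793k at national scale).
* **Supply.** FTE path anchors 1.0 → 0.940 (2014) → 0.985 (2018) → 0.980
  (2019) → 0.985 (2020) → 0.947 (2022) → 0.9549 (2023), the last matching
  5 395/5 650.
* **Productivity.** Mean list size drifts −0.3%/yr multiplicatively; the
  baseline national ratio is 1 680 patients per FTE with σ = 0.08
  log-normal unit heterogeneity.
* **Unassigned is derived, never sampled**: m = n − round(GP·L_target),
  clipped into [0, n]; the implied list ratio absorbs the ±1 rounding
  residue, keeping the identity exact on integer data.
* **Noise** (default 2% relative SD) is mostly a *persistent* per-unit
  level offset, with a small transient i.i.d. component (default 10% of
  the SD). Purely transient noise would make yearly national first
  differences noisier than the smallest configured steps (±0.3–0.5%/yr),
  so the generated data could not exhibit the configured yearly sign
  pattern; persistent dispersion reproduces the realistic situation in
  which units differ in level but follow the common trend.
* **Covariates** (elderly share, diabetes prevalence, population
  density) are induced by a Gaussian copula on unit-level latents tied to
  the unit's list-ratio level. The copula residual is orthogonalised and
  re-standardised against the list-ratio latent, so the latent *sample*
  correlation equals its target exactly; what remains between target and
  achieved panel correlation is attenuation from within-unit temporal
  variation and the monotone marginal transforms, compensated by a fixed
  factor 0.95 derived from the default variance budget (unit σ = 0.08
  versus temporal path SD ≈ 0.012 and persistent noise 0.018). Default
  targets: −0.40 (elderly share), −0.40 (diabetes), −0.15 (density),
  achieved within ±0.1 at 55 units.
* **Age mix.** Band shares interpolate linearly between endpoints chosen
  to give 1.24 weighted units per patient in 2009 and 1.32 in 2023;
  elderly-band shares carry the unit's elderly latent as a multiplicative
  tilt, and the `elderly_share` covariate is literally the 65+ share of
  the generated age counts, keeping covariates and age structure
  mutually consistent. Integer band counts are apportioned by largest
  remainder so they sum exactly to enrolment.
* **Rosters.** Per-unit physician rosters draw hours around a 40 h mean,
  rescale them so total FTE matches the record exactly, and apportion
  assigned patients to lists by largest remainder, closing the
  micro (per-physician) ↔ macro (unit identity) loop exactly.
* **Single-driver scenarios** switch off noise, cross-unit
  unassigned-share dispersion and the other two trends. The supply
  scenario additionally snaps FTE and target list sizes to integers:
  integer·integer products and their quotients are exact in IEEE
  arithmetic, so the implied list ratio is bitwise constant across years
  and the off-driver effects are exactly 0 (not merely small). Demand and
  productivity scenarios are exact without snapping because their
  constant operands are bitwise stable.

What passing tests on this generator do *not* show: fidelity to real
within-region heterogeneity (no published parameters exist for it),
migration or mortality mechanisms behind the trends, or unit births and
mergers mid-series (the crosswalk handles the latter for real data).

## Data handling

* CSV is canonical (UTF-8, comma, dot decimal). Counts are written as
  integers; FTE and covariates with `repr` (shortest exact decimal) and
  read back with round-trip float parsing, so write → read is lossless.
* Validation fails loudly: unassigned > enrolled, negative counts,
  gp_fte = 0 with partially assigned patients, and age-band sums that
  miss enrolment are errors naming (unit_id, year), not warnings.
* The unit crosswalk renames a record when its year precedes the old
  id's effective year, then merges additively (covariates as
  enrolled-weighted means — they describe the served population). In any
  year before the latest effective year, an id that is neither an old nor
  a new id raises a mapping error.
* Aggregation is the same additive merge grouped by region or nation;
  the aggregate list ratio is total assigned over total FTE, never a mean
  of unit ratios.

## Reporting and reproducibility

Internal percentages are kept at full precision; presentation rounding is
half-away-from-zero, applied only when formatting headline figures (the
published tables round the same way, e.g. the 2023 pair 16.5%/83% against
computed 16.19%/83.81% from the printed aggregates — the unrounded
administrative values are not published, so headline percentages are
reproducible only as bounds). Pearson is the default correlation,
Spearman optional. Pipeline outputs contain no timestamps; identical
config and inputs give byte-identical files. All generator randomness
flows through one `numpy.random.default_rng(seed)` instance.

Problem sizes used by the test-suite and acceptance computations: the
two-record national worked example; the default 55-unit × 15-year
synthetic panel; 10 000 randomised record pairs for the identity
property; 200 randomised 15-year series for telescoping. All run in a few
seconds on one CPU.

## Known limitations

* Effects on aggregates are composition-dependent (see Aggregation);
  regional stories should be decomposed at the level they are told.
* The decomposition cannot separate mechanisms behind a falling
  patient-to-GP ratio (smaller lists vs exit of large-list physicians);
  it quantifies the contribution, not the cause.
* Zero-FTE endpoints abort a decomposition rather than imputing a list
  ratio; callers must handle units with no physicians explicitly.
* The published national contributions from unrounded sources (416k
  supply, "over 300k" productivity) are not exactly recoverable from the
  rounded printed aggregates, which give ≈428k and ≈265k; the identity
  and the published bounds are what the package reproduces.
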