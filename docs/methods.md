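# Methods

## Scope and model

`dustrisk` assesses human health risk from toxic metals (Cd, Ni, As, Pb,
Zn, Cu, Cr) in road dust for two receptor classes (adult, child) and three
exposure pathways (incidental ingestion, inhalation of resuspended dust,
dermal contact).  Two refinements distinguish it from the classical
deterministic assessment:

1. **Bioaccessibility adjustment.** The gastric-phase bioaccessible
   concentration CDBA (mg/kg), measured by a one-step in-vitro extraction
   (SBET), replaces the total concentration CT in the intake equations of
   *all three* pathways.  This is deliberate model fidelity to the
   assessment design being implemented, even though SBET simulates gastric
   conditions only; applying a gastric fraction to inhalation and dermal
   uptake is conservative for neither and is flagged as a known limitation
   below.  The bioaccessibility rate RD = CDBA / CT is a diagnostic output,
   not a model input.

2. **Fuzzy uncertainty propagation.** The concentration and the receptor
   parameters with the highest output sensitivity — ingestion rate IngR,
   inhalation rate InhR, body weight BW — are triangular fuzzy numbers
   (minimum, most-expected value, maximum); low-sensitivity parameters
   (ED, EF, AT, SA, SSAR, ABS, PEF) are crisp.  Computation proceeds on
   α-cuts: at confidence α each TFN becomes the interval
   [(a₂−a₁)α+a₁, −(a₃−a₂)α+a₃], and intervals combine by the endpoint
   formulas for sums, products and quotients of non-negative intervals.
   The default α = 0.9 follows the usual convention for this method; it is
   a config/CLI knob (`--alpha`), and a sweep over α can be performed by
   repeated calls.

The concentration TFN of each analysis group (season, site, season × site,
or pooled) is built from the group's per-sample CDBA values as
(min, centre, max).  The centre is the arithmetic mean by default
(`center_rule="median"` available): the "most-expected value" of a TFN is
not otherwise pinned down by the assessment design, and the mean is the
estimator whose recovery the synthetic calibration targets.

### Risk metrics

Per metal and pathway, intake (mg/(kg·d)), then:

* hazard quotient HQ = intake / RfD, summed over pathways with an RfD, and
  hazard index HI = Σ_metal HQ with the conventional threshold HI < 1;
* carcinogenic risk CR = intake · SF, summed over the three pathways into a
  per-metal total CR interval.

Reference doses (RfD) exist in the bundled set for Cd, Ni, As, Zn, Cu and
Cr; slope factors (SF) for Cd, Ni, As and Pb.  Metals without the relevant
toxicity datum are excluded from that endpoint with a log entry — never
zero-filled.  Whether CR should additionally be summed across metals is not
part of the assessment design; the package reports per-metal totals only.

The averaging time differs by endpoint, following HJ 25.3-2019 / USEPA
convention: AT_nc = ED · 365 d for non-carcinogenic quotients,
AT_ca = 70 yr · 365 d for carcinogenic risk.  Both are explicit config
fields.

### Risk-level classification

Total CR intervals are classified against an ordered, contiguous scheme of
half-open levels, by default I (−∞, 10⁻⁶), II [10⁻⁶, 10⁻⁵),
III [10⁻⁵, 5·10⁻⁵), IV [5·10⁻⁵, 10⁻⁴), V [10⁻⁴, 1).  Two membership
normalisations exist and genuinely disagree:

* `computed_interval` (default): membership = |CR ∩ level| / |CR|.
  Degrees sum to 1 for any positive-width interval inside the covered
  range; this is the normalisation whose output behaves like a partition of
  belief and the one used for level assignment.
* `level_interval` (`--normalization level`): membership =
  |CR ∩ level| / |level|.  Degrees need not sum to 1.  The lowest level is
  open below; because risk quantities are non-negative its width is
  measured from 0 (effectively [0, 10⁻⁶)), keeping the degree finite.

Both are first-class options rather than one being silently chosen,
because the assessment literature states both forms.  Degenerate cases:
a zero-width (point) interval takes membership 1 in the level containing
it; CR mass at or above the scheme's top bound (1) is clamped into the most
severe level with a logged warning.  Level assignment follows the maximum-
membership principle; ties break toward the more severe level, the
health-protective choice.

## Exposure and toxicity defaults

Bundled YAML defaults (`src/dustrisk/data/`) are standards-derived — HJ
25.3-2019 and USEPA values as conventionally used in Chinese urban
road-dust assessments — and every number is overridable per run.  Key
entries (adult / child): IngR TFN (50, 100, 150) / (100, 200, 300) mg/d;
InhR TFN (12, 14.5, 17) / (5, 7.5, 10) m³/d; BW TFN (54.4, 61.8, 70) /
(15, 19.2, 24) kg; ED 24 / 6 yr; EF 350 d/yr; SA 5373 / 2848 cm²; SSAR
0.07 / 0.2 mg/(cm²·d); ABS 0.001; PEF 1.36·10⁹ m³/kg.  The TFN spreads
bracket the standard point values with ranges typical of the surveyed
populations; they are modelling defaults, not measured quantiles.  ABS is a
single scenario-level scalar (no per-metal dermal fractions) and ABS = 0 is
legal, expressing no dermal uptake.  No dermal gastrointestinal-absorption
adjustment of RfD is applied.

GB 15618-2018 soil screening values are **not** bundled: they depend on
land use and soil pH, so exceedance screening requires a user-supplied
`{metal: value}` YAML with no silent default.

## Synthetic campaign generator

The generator emulates the study design the analysis assumes: 34 samples =
4 sites × 4 seasons × 2 replicates + 2 extra replicates at the S2 hotspot
(one winter, one summer; the true layout of the original campaign is not
recoverable, only its total).  Per metal:

* CT ~ log-normal (gamma available) with mean = pooled target ×
  season effect × site effect and coefficient of variation 0.3 — log-normal
  because it is the standard law for environmental concentration data, and
  CV 0.3 as a realistic within-cell spread for composite dust samples;
* season-effect templates: summer-high for Ni, As, Pb, Zn, Cr (the Ni and
  As summer multipliers are set to their reported summer/pooled mean
  ratios, 35.2/33.7 and 12.5/11.2; the rest use a generic 1.10),
  autumn-high/spring-low for Cd and the mirrored pattern for Cu; each
  template averages to 1 over seasons;
* a site effect (default 1.3 for Cd and As at S2) reproduces the hotspot
  qualitatively; its magnitude is a free config value;
* the joint season × site multiplier matrix is renormalised by its
  sample-count-weighted mean, so the expected pooled mean equals the
  calibration target exactly under any replicate layout;
* CDBA = CT · f with f ~ Beta(fκ, (1−f)κ), mean f at the metal's target
  bioaccessible fraction and concentration κ = 400.  κ sets the per-sample
  spread of bioaccessibility (standard deviation ≈ 1.2 percentage points at
  f ≈ 6.5%, ≈ 2.5 at f ≈ 42%) — a tight spread consistent with
  bioaccessibility rates showing no strong seasonal or spatial variation,
  and chosen so the campaign-level mean-RD ordering
  (Cd > Zn > Cu > Ni > Cr > As > Pb, tightest gap Cr 6.87% vs As 6.2%)
  is stable across seeds.

All draws come from one `numpy` generator seeded from the config, so a
fixed config + seed reproduces the table byte-for-byte.

**What the generator does not emulate:** spatial dispersion and wind
fields, temporal autocorrelation between seasons, measurement error and
detection limits, and between-metal correlation within a sample (metals are
drawn independently, whereas real dust shows strong co-contamination
structure).  Tests passing on synthetic data therefore demonstrate that the
pipeline's arithmetic, calibration recovery and qualitative orderings are
correct under the assumed laws — not that the assumed laws describe any
particular city's dust.

## Numerical choices

* Interval product/quotient use the non-negative endpoint formulas;
  operands are validated non-negative (quotients additionally require a
  strictly positive denominator), rather than generalising to signed
  interval arithmetic that no physical quantity here needs.
* α-cuts at α = 0 and α = 1 return the support [a₁, a₃] and mode [a₂, a₂]
  exactly; for intermediate α a sub-ulp endpoint crossing from rounding at
  near-degenerate cuts is collapsed to the midpoint.
* Binary interval operations require both operands cut at the same α
  (tolerance 10⁻¹²).
* Sample tables are written with `%.17g` and read with round-trip float
  parsing, so write-then-read is the identity on float64.
* Exceedance uses the strict inequality CT > screening value (equality does
  not count as exceedance).
* The dominant CR pathway per metal is the one with the largest CR interval
  midpoint — a reporting convention, since interval dominance is otherwise
  partial.

## Known limitations

* Gastric-phase (SBET) bioaccessibility applied to inhalation and dermal
  pathways, as discussed above.
* No Monte Carlo mode: the fuzzy-interval representation was chosen over
  probabilistic propagation by design, and the two are not mixed.
* No significance testing of RD across seasons or regions; the summary
  tables expose the inputs should a user test externally.
* Single-α propagation: the default reports one confidence level rather
  than a full membership function of the outputs; sweeping α reconstructs
  the latter at the cost of repeated runs.
* Risk levels above CR = 1 are not representable; such values are clamped
  into level V with a warning.
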