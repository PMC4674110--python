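# Methods

This note documents the models, parameter choices and numerical decisions
behind `songgaps`, and what the synthetic test bench does and does not show
about real song data.

## The measurement model

A corpus is a set of labelled renditions per bird (one condition, or two
paired conditions). Syllables are intervals separated by ≥5 ms of silence;
all times are seconds from rendition start, intervals half-open.

**Envelope.** The segmentation envelope is |waveform| smoothed with a
centered 5 ms square window (reflect padding at the edges, which affects at
most 5 ms per end) and resampled to the canonical 1 kHz with a polyphase
anti-aliasing filter, clipped at zero. Envelopes from 32 kHz and 44.1 kHz
recordings of the same signal agree to within 2% RMS, so both common
recording rates are interchangeable.

**Segmentation.** One amplitude threshold per corpus, default 10% of the
corpus median syllable peak — a fraction-of-peak rule keeps the measurement
invariant to global recording gain. Above-threshold runs separated by less
than 5 ms merge; merged candidates shorter than `min_syllable_ms`
(default 10 ms, an assumption — no published value exists) are discarded.
Threshold crossings are located by linear interpolation between the two
straddling envelope samples; this removes the 1 ms envelope-grid
quantization from boundary and gap estimates while still deriving
boundaries purely from the canonical 1 kHz envelope. A raw absolute
threshold mode is available for within-day paired recordings made under
identical conditions. When label files are present (the primary path),
labels are authoritative for syllable identity and segmentation only
refines their boundaries; label times win when no envelope segment overlaps
them.

**Gaps and amplitude.** Gap duration is (next onset − current offset) in
ms, attributed to the (resolved context, target) transition; negative gaps
signal corrupt labels and raise. Syllable amplitude is the RMS of the
baseline-subtracted waveform over the syllable extent, with the baseline
estimated as the median envelope value over inter-syllable regions;
per-syllable median RMS values are normalized by the recording platform's
maximum, giving values in (0, 1]. Recordings separated by long intervals
are compared via pointwise-median envelopes per transition (≥5 instances),
rescaled so the branch-point syllable's peak matches a common reference,
with one common threshold re-deriving a single gap per epoch.

## The syntax model

Transitions are counted per bird and condition up to context order 2.
A rendition-final syllable contributes a termination count, never an
outgoing transition; transition probabilities are counts divided by the
context's non-termination total, so they sum to one exactly. Occurrences
(for the ≥10-occurrence eligibility rule) include terminal occurrences.

History dependence is resolved per order-1 context by a likelihood-ratio
test across its order-2 predecessors: G = 2 Σ obs·ln(obs/exp) with
expectations from the pooled target distribution, df = (contexts−1) ×
(targets−1), and a χ² upper-tail p-value. Predecessor groups with fewer
than five transitions are pooled into a single sparse group before testing
(the test is unreliable on near-empty rows; this rule is a package
decision). A significant test (α = 0.05, no multiple-testing correction —
per-test α is the field convention here) splits the context per
predecessor; otherwise predecessors pool. Start-of-rendition positions form
their own pseudo-predecessor. Classification is strict: a context is
stereotyped only if its maximum target probability exceeds 0.95; a
probability of exactly 0.95 remains a branch point. Labels whose
maximal-run lengths vary across renditions are excluded wholesale:
transitions into, within and out of such runs never enter the analysis
(renditions are split into fragments around them, and fragment ends do not
count as terminations).

## The coupling models

All models are linear mixed models with random intercepts for bird and for
sequence (branch point or chain) nested within bird, fitted by REML.
Median gap durations enter as log₁₀ values; the Shapiro–Wilk screen is
reported but the log transform is applied unconditionally for consistency
across analyses. Only transitions with ≥5 gap instances contribute a
median; change analyses additionally require ≥5 instances in *both*
conditions and a context that is a branch point in at least one condition.

The fitter (`songgaps.lmm`) optimises the profiled REML criterion over
variance ratios with Nelder–Mead, *unconstrained* except for positive
definiteness of the marginal covariance — variance components may be
estimated negative, as in JMP-style unbounded REML. Wald t/F tests use
Satterthwaite denominator degrees of freedom computed from
finite-difference derivatives of the fixed-effect covariance and the
observed REML information; the implementation reproduces lmerTest's df to
four decimals on shared fixtures, and β, standard errors and variance
components match statsmodels' MixedLM to ~1e-5 on positive-variance
problems (statsmodels cannot represent negative components or fractional
df, which is why the fitter is in-house). Multi-df contrasts use the
eigenvalue-averaged Satterthwaite denominator; category least-squares means
are compared with the studentized range (Tukey–Kramer under imbalance).
Degenerate inputs are handled explicitly: a rank-deficient design (e.g. a
constant predictor) raises naming the offending column; an exactly
noise-free response returns the exact GLS solution with df clamped to the
residual df. With balanced data and zero random variation the fixed effects
equal the ordinary least-squares closed form to 1e-6.

Residualization: amplitude mediation is assessed by regressing log₁₀ gap
on log₁₀ amplitude (same random structure), taking *conditional* residuals
(observed minus fixed and BLUP random effects — the variation a
within-bird, within-sequence observer would see), and regressing those on
transition probability. Per-target change categorization uses a 2×2 table
(target vs. all other targets × condition A vs. B) tested by χ² without
continuity correction; a G-test variant is exposed because both statistics
are in circulation for this design. Percent gap change is computed from raw
(untransformed) medians.

## The synthetic generator

The generator is the package's oracle: it produces corpora whose every
transition has a known termination-excluded probability and a known
expected log₁₀ gap.

**Grammar.** Each bird sings a fixed cycle of units — stereotyped chains
(default `bcd`, `ghj`) interleaved with branch specs (default contexts
`ea`, `lm`, `rs`, `wx` with target distributions {0.85, 0.15}, {0.6, 0.4},
{0.5, 0.3, 0.2}, {0.75, 0.2, 0.05}). Branch targets are drawn
independently per visit. After each unit the song terminates with
probability 0.05, giving ~60-70 syllables per rendition — a realistic bout
length that also keeps per-context occurrence counts (~100 at the default
30 renditions) high enough that binomial error in estimated probabilities
barely attenuates recovered slopes. Per-bird Dirichlet jitter
(concentration 60 × template) individuates birds. Defaults of 22 birds ×
30 renditions reproduce the sampling scale of the study design this
package targets (~210-220 analyzed branch transitions).

**Gap model.** Per instance, gap = 10^(a + b·p + u_bird + v_seq + τ_trans
+ ε), floored at 6 ms. Defaults: a = 2.10 (≈110 ms mid-range gaps, matching
reported medians of ~14-490 ms with a ~112 ms mean), b = −0.240 (the
headline inverse coupling), u ~ N(0, 0.08²), v ~ N(0, 0.10²) per sequence,
τ ~ N(0, 0.17²) per transition, ε ~ N(0, 0.10²) per instance, all in log₁₀
ms. No variance components are published for this system; these are
assumptions chosen so that (i) per-instance gap variability is realistic
(CV ≈ 25%) and (ii) the slope standard error at study scale comes out near
the reported ±0.044. The transition-level effect τ exists precisely
because medians over ≥5 instances average ε away — without it the
simulated slope SE would be implausibly small and recovery tests would be
trivial.

**Amplitude model.** log₁₀ amplitude = log₁₀ base(bird, label) +
0.20·(p_in − 0.5) + N(0, 0.05²), with bases uniform on [0.25, 0.60]; louder
syllables for prevalent transitions, the direction reported for real song.

**Condition pairs.** Condition B shares all random effects with A
(repeated measures). Branch distributions drift per bird as
p_B = 0.5·p_A + 0.5·q, q ~ Dirichlet(2 × template) (sd(Δp) ≈ 0.14, the
scale of published example shifts), or take explicit per-target shifts.
Expected per-transition log-gap changes are: coupled mode
log₁₀(0.94) − 0.15·Δp + N(0, 0.03²) (gaps shorten overall, more so for
rising transitions); decoupled mode log₁₀(gap_factor) + noise regardless of
Δp; null mode exactly zero with no probability drift. The −6% overall
change matches the reported stereotyped/unchanged-category change. The
coupled coefficient 0.15 is deliberately stronger than the reported fitted
slope of −0.063: the validation suite requires ≥90% detection power at
study scale, which the published effect size (|z| ≈ 2.3) cannot supply;
the generator therefore represents a clearly-coupled world, not a
replication of the published estimate.

**Waveforms.** Syllables render as raised-cosine-edged envelopes
(4.5 ms edges) over per-label tonal carriers (2-6 kHz) or noise, with a
Gaussian noise floor (default SNR ≈ 30 dB); per-label durations are fixed
within bird (60-110 ms). Returned boundaries are exact nominal envelope
onsets/offsets, so true gap = next onset − current offset identically. The
4.5 ms edge was chosen by a crossing-bias analysis so that one absolute
corpus-level threshold recovers nominal boundaries to ≤1.5 ms across the
realized amplitude range; it is a renderer/measurement consistency
parameter, not a biological claim.

**Determinism.** One root seed; per-bird `SeedSequence` sub-streams for
parameters, condition-A sampling and condition-B sampling. Identical
configurations are byte-identical, including rendered audio.

**What the generator does not emulate.** Spectrally realistic syllables
(only amplitude structure matters downstream), variable syllable repeats
(excluded from the analyses by rule), bout-internal non-stationarity,
drift within a recording epoch, labelling errors, and higher-order history
dependence beyond order-2 contexts. Passing tests therefore demonstrate
that the pipeline measures what it claims under its stated assumptions —
not that those assumptions hold for any particular real corpus.

## Validation scale and seeds

The acceptance-style tests run at these sizes, chosen to finish comfortably
on a single CPU while keeping Monte Carlo error far from the pass bands:
segmentation oracle on 200 rendered renditions; probability consistency on
10,000 branch visits; G-test calibration on 2000 null replicates (±0.01
band around 0.05); slope recovery on 200 study-scale corpora; coupled
detection on 200 pairs and decoupled calibration on 400 pairs; category
ordering on 30 pairs. All seeds are fixed literals in the tests.

## Known limitations

* The Satterthwaite implementation uses finite differences; df can differ
  from lmerTest in the second decimal on ill-conditioned fits (estimates
  and SEs are unaffected).
* Cross-recording normalization assumes the branch syllable is the first
  above-threshold segment of the aligned median envelope.
* The change analyses match contexts across conditions by their resolved
  context string; a context that splits under one condition and pools under
  the other is skipped rather than partially matched.
* `categorize_changes` treats each target independently (2×2 vs. rest);
  within a branch point the categories are therefore not independent
  tests.
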