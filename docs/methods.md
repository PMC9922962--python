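# Methods

## The analysis model

The pipeline operates on *multispectral stacks*: co-registered 2-D images, one
per illumination wavelength, whose pixel values are proportional to local
optical absorption times the light fluence reaching that depth. Two instrument
presets are supported — a hand-held clinical geometry sampling 700–970 nm in
10 nm steps (28 planes) and a small-animal geometry sampling 680–960 nm
(29 planes). Row 0 is the probe side; the depth of a row is
`(row − skin_row) · pixel_pitch_cm`, with the rows above the skin line
occupied by the acoustic coupling medium (water), which carries no tissue
signal and therefore supplies the noise estimate.

The per-subject biomarker is the **normalized ratio spectrum**: the ROI mean
divided by the background (whole imaged tissue) mean at each wavelength,
normalized by the curve's own maximum. Two properties motivate it:

* multiplicative per-pulse energy fluctuations scale ROI and background
  means identically, so the raw ratio is exactly invariant to them (a unit
  test asserts this to 1e−12);
* the max normalization removes residual subject-level scale, so curves from
  different subjects, depths and instruments are comparable.

The score is the normalized ratio at 930 nm, where lipid absorption peaks in
the NIR. In a lipid-poor liver the ratio curve peaks in the hemoglobin band
(≤ 900 nm) and the 930 nm value is well below 1; lipid accumulation raises
it toward 1.

Normalization is **per ROI, per stack**: each ROI's curve is divided by its
own spectral maximum. The alternative — one shared maximum per stack pooled
over ROIs — would couple the liver score to the SAT curve; per-ROI
normalization is the only reading under which a SAT score near 0.9 and a
healthy-liver score near 0.2 can coexist, which is the regime the method is
designed for. Ties in the maximum resolve to the shortest wavelength. The
background region *contains* the ROIs (it is the entire imaged tissue, not
tissue-minus-ROI).

### Group inference

Two cohorts of per-subject scores are compared with an unpaired
pooled-variance Student t-test, df = n₁+n₂−2, after a per-group Shapiro–Wilk
normality check at α = 0.05. A failed gate is a warning, not a stop: the
t-test is still reported (that is how summary tables elsewhere are written)
and a Mann–Whitney U p-value is attached as a rank-based fallback. Effect
size is Cohen's d with the pooled sd. In **summary mode** the same test is
computed from (mean, SEM, n) triples via sdᵢ = semᵢ·√nᵢ; computing summaries
from raw values and running summary mode reproduces the raw-mode t, df and p
exactly (asserted numerically over 100 random pairs). A Welch variant is
available (`welch=True`) but pooling is the default: it is the convention
under which published group tables of this kind recompute correctly. Pooling
is also why the recomputation of printed tables can succeed at all — only
means, SEMs and n enter.

Degenerate inputs: a zero pooled sd with equal means yields t = 0, p = 1
(this actually occurs — see the SAT saturation note below); with unequal
means it is an error. Constant groups skip the Shapiro–Wilk gate with a
warning, as do groups of n < 3.

### SNR versus depth

The liver mask is tiled from its shallowest pixel downward into horizontal
slabs of 0.5 cm (the final slab may be thinner; the slab masks partition the
liver mask exactly — property-tested). Per slab, SNR = mean signal / noise
sd, where the noise sd is the population standard deviation (ddof = 0, so an
alternating ±1 pattern gives exactly 1) of all coupling-medium pixels above
the skin line at that wavelength. SNR is reported linear and in dB with the
amplitude convention 20·log₁₀, because reconstructed optoacoustic images are
amplitude-like; both are always emitted since "an SNR of 5" is ambiguous
otherwise. Percent-decrease summaries: per slab step,
100·(1 − SNR_{k+1}/SNR_k); per cm, the geometric interpolation
100·(1 − (SNR_{k+1}/SNR_k)^{1/Δdepth}), consistent with an exponential
attenuation model (for SNR ∝ e^{−μz} the per-cm figure is exactly
100·(1 − e^{−μ})). Steps with a zero numerator are flagged and excluded from
the means.

### Pixel-level threshold

Liver pixels at 930 nm are pooled per cohort. Densities are estimated by
Gaussian KDE with Silverman bandwidth on a common evaluation grid spanning
the pooled range ± 4 bandwidths (512 points); a histogram estimator with
configurable bins is available. The classification threshold is the point
where the two densities cross *between their global modes*, refined by linear
interpolation of the density difference between bracketing grid points; if
several crossings fall between the modes the one nearest the mode midpoint is
chosen and all candidates are reported; no crossing between the modes is an
error carrying diagnostics. On analytic Gaussian curves the threshold matches
the closed-form equal-density root to one grid step (tested).

The group test on above-threshold proportions defaults to a two-sample z-test
on the pooled pixel counts. Pooled pixels from the same subject are not
independent, so a cluster-aware alternative — an unpaired t-test on the
subject-level proportions — is implemented as `method="per_subject"` and is
the statistically safer choice; the pooled test is retained as the default
for comparability with pooled-pixel reporting. An all-above or all-below
threshold makes the pooled test degenerate: it reports p = 1 with a warning.

## The phantom generator

The generator exists so that every stage has realistic, fully controlled
inputs. It renders layered 2-D tissue with the forward model

    pixel(z, λ) = Γ · μa(λ) · exp(−μ_eff · z) · j(λ) + ε,  truncated at 0

where μa is the Beer–Lambert mixture of tabulated chromophore spectra
weighted by volume fractions, Γ the optoacoustic (Grueneisen) efficiency,
μ_eff a wavelength-independent effective attenuation rate, j(λ) a
per-wavelength pulse-energy factor (Normal, mean 1, CV = `pulse_jitter_cv`)
and ε additive Gaussian noise. Truncation at zero mirrors the non-negativity
constraint of tomographic reconstruction and is a deliberate distributional
distortion (it biases the standoff noise sd low; `generate_raw_noise_stack`
exposes the un-truncated field for calibration studies, and the noise
estimator recovers the generator's sd within 10% in ≥ 95/100 seeds there).

### Chromophore tables

`data/*.tsv` ship literature-shaped absorption compilations at 10 nm spacing
over 650–1000 nm: oxy- and deoxyhemoglobin as whole-blood μa (molar
extinction compilations converted at 150 g Hb/L, MW 64 500), water with its
970 nm rise (Hale–Querry-like), and lipid with the 930 nm peak
(van-Veen-like shape). They are accurate in *shape*, not absolute
calibration — the pipeline consumes only normalized ratios, and the one hard
requirement, that the lipid maximum over 680–970 nm falls in [920, 940] nm,
is asserted by tests. Linear interpolation resamples tables onto instrument
grids (resample-then-mix equals mix-then-resample; property-tested).

### Geometry and cohorts

Human preset: standoff 0.3 cm, skin 0.1 cm, SAT 0.8 cm (healthy) / 1.6 cm
(steatosis), an unanalysed muscle/fascia spacer of 1.3 cm, liver 1.5 cm to
the image bottom; pixel pitch 0.01 cm (reduced mode: 0.025 cm, 40 columns,
for replicate studies). The spacer places the first liver slab centroid near
2.5 cm depth — between SAT and liver there is real tissue that the analysis
never scores. Mouse preset: standoff 0.2, skin 0.05, SAT 0.15/0.40, spacer
0.2, liver 0.8 cm at 0.005 cm pitch on the 680–960 nm grid.

Cohorts differ in exactly two parameters: liver lipid volume fraction (0.02
healthy, 0.40 steatosis) and SAT thickness. SAT *composition* is identical
between cohorts, which makes the SAT contrast a true null. Inter-subject
variability multiplies each tissue layer's thickness and each chromophore
fraction by independent 1 + Uniform(−0.15, +0.15) factors; the deepest layer
then fills the remaining image depth, so a thicker SAT pushes the liver
deeper, as in real anatomy. Per-subject seeds derive from the base seed via
`numpy.random.SeedSequence.spawn`; the same seed gives bit-identical stacks.

### Calibration of the default presets, and what they do not emulate

The compositions are *effective*, not histological. Two physical effects that
the single-exponential, wavelength-independent attenuation model cannot
represent — spectral fluence filtering (deeper tissue sees light already
depleted at strongly absorbed wavelengths) and the reconstruction's dynamic
range compression — were folded into the volume fractions and μ_eff
(0.3 cm⁻¹). Concretely: a literal SAT lipid fraction of ~0.7 would make the
background spectrum so lipid-shaped that thickening the SAT layer (the
steatosis cohort's geometry) would depress the liver's normalized 930 nm
ratio more than liver lipid raises it, inverting the cohort contrast that
real data show. With SAT lipid at 0.15 and liver water at 0.20 the background
keeps a blood-dominated shape, and the defaults reproduce the intended
qualitative pattern robustly: the steatosis liver score exceeds the healthy
mean for every subject, the liver t-test detects the contrast and the SAT
t-test does not, and the pooled pixel distributions intersect between their
modes (all verified over seeded replicates in the acceptance suite).

One known artefact of the idealisation: the phantom's SAT ratio curve peaks
at 930 nm so cleanly that the SAT score saturates at exactly 1.0 for every
subject — the SAT null comparison is then the degenerate t = 0, p = 1 case
rather than a noisy non-significant one. Real SAT scores scatter slightly
below 1 because real spectra carry structured, spatially correlated artefacts
that the ratio does not cancel; the generator has no such artefact model.
Also not emulated: acoustic reconstruction and its artefacts, speckle,
motion, arc-shaped probe geometry, within-tissue heterogeneity (vessels), or
wavelength-dependent attenuation (a per-λ μ_eff table is accepted by the
forward model's `mu_eff_per_cm` being scalar-only by default design — left
out deliberately). Passing tests therefore demonstrate the correctness and
statistical behaviour of the *analysis*, not instrument-level realism of the
data.

### Noise-floor and depth figures

With the default noise sd (0.002 signal units) the deep liver slabs of the
human preset sit at comfortably detectable SNR; depth-dependent SNR decrease
figures (percent per 5 mm / per cm) are data-dependent outputs of whatever
geometry and μ_eff are simulated and are reported, not targeted. On
noise-free phantoms the regression of log slab mean on slab centroid depth
recovers −μ_eff to machine precision for equal-thickness slabs (within 1%
is the tested contract).

## Numerical conventions

* Wavelength lookups are exact (atol 1e−6 nm); off-grid requests are errors,
  never nearest-neighbour.
* Ratio-curve maxima tie-break to the shortest wavelength (`argmax`).
* Noise sd uses ddof = 0; group SEM uses ddof = 1 over subjects.
* Slab bands are half-open `[top, bottom)` with 1e−12 guards against float
  boundary misassignment.
* Density curves must integrate to 1 within 1e−3 (trapezoid) — guaranteed by
  the ± 4-bandwidth grid margin.
* p-values are kept at full precision internally; rounding (p to 3–4
  decimals, d to 2–3) happens only in reporting layers.
* HDF5 is the canonical stack container; TIFF + JSON sidecar round-trips
  bit-exactly and is validated against the same contracts (plane count,
  non-negativity, metadata presence). Readers reject inconsistent files
  rather than coercing.

## Problem sizes used by the test and acceptance runs

Replicate studies (cohort pattern, null calibration) use the reduced presets:
0.025 cm pitch, 40 columns, ~160–230 rows, 5 subjects per cohort, 100
replicates — chosen so the full suite and the acceptance script each complete
in well under a minute on one CPU while the per-replicate t-tests operate at
the study's n = 5. Oracle-equivalence and property tests use 16×16 toy
stacks where brute-force loops are feasible.

## Known limitations

* The pooled-pixel proportions test treats pixels as independent; use the
  per-subject variant for inference you intend to defend.
* Summary-mode recomputation inherits the rounding of published summaries;
  one published SAT comparison is not recoverable from its rounded values
  and is flagged in the reproduction table rather than silently matched.
* The phantom's effective compositions are calibrated for ratio-level
  realism; absolute pixel values are in arbitrary signal units and no
  absolute lipid quantification is attempted.
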