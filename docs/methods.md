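# Methods

## Optical model

Retinal images are formed under monochromatic scalar Fourier optics at the
photopic peak (555 nm) over a circular 5 mm artificial pupil. A focus state
of the tunable lens with residual defocus `Δ` diopters is represented as a
pure Zernike defocus wavefront with ANSI normalization,
`c = Δ (d/2)²/(4√3)` µm for pupil diameter `d` mm, and its PSF computed as
the squared modulus of the FFT of the complex pupil function. Two guards are
enforced at configuration time rather than at use: the PSF pixel pitch
(`λ / (pad_factor · d)` radians) must be finer than half the diffraction
cutoff period (`pad_factor ≥ 2` guarantees this), and the pupil-plane
defocus phase must advance less than half a wave per sample at the largest
supported defocus (3 D by default; 256 samples across a 5 mm pupil leave a
≈1.9× margin). The aperture edge is area-supersampled (8×8 within one pixel
of the rim); with that, the zero-defocus PSF matches the analytic Airy
pattern to ~2×10⁻⁵ of the peak, well inside the 10⁻³ tolerance the test
suite asserts.

The simulation is monochromatic and defocus-only: the simulated device is a
see-through system working over the wearer's natural optics, and chromatic
or higher-order effects are out of scope. `make_psf` accepts an arbitrary
extra pupil-phase map (waves) as a hook for higher-order aberrations, but
none are shipped. Strehl ratios are computed as peak-to-peak against the
zero-aberration PSF of the same grid. Note that pure-defocus Strehl is not
monotone in defocus — it rings like sinc² past the first zero — so
through-focus monotonicity holds only on coarse (≥0.5 D) grids.

## Corrections and energy accounting

Temporal multiplexing is modeled as an exact dwell-weighted intensity sum;
the device multiplexes at tens of hertz, above flicker fusion, so no
temporal dynamics are simulated. Profiles: F/I/N monofocals at adds 0, +1.5
and +3 D; 2SV bifocal 50% far / 50% near; 3SV trifocal 50/20/30. The
catalog pairs these into 17 labeled binocular corrections (dominant eye
first in the label); the preference protocol uses the 9 far-dominant
corrections and their 36 unordered pairs.

Dioptric demand at the three viewing distances (4 m, 66 cm, 33 cm) supports
two conventions: `nominal` (default) assigns 0 / 1.5 / 3 D — the adds the
device pairs with those distances, absorbing the 0.25 D far-plane vergence
into the subjective best focus — while `exact` uses `1/d − 1/4`. Whether the
far state encodes 0 D absolute or the 4 m vergence is genuinely ambiguous in
the source protocol, so both are provided; all printed energy percentages
are recovered under either mode because the matched-state residuals stay
below 0.25 D. Energy in focus counts dwell within ±0.35 D of the demand, a
typical ocular depth of focus; the window is exposed because no operational
definition exists for it, and any value in (0.25, 0.75) D reproduces the
dwell percentages exactly.

## Scene

The composite scene is generated procedurally: far and intermediate regions
fill the upper 60% of the field (split left/right), the near region the
lower 40%. The far region holds a 1/f-spectrum texture (a natural-image
surrogate with a landscape-like power spectrum) and a bright chart with
optotype-like glyphs; intermediate and near regions are bright display
panels (52 cd/m²) densely covered with text-like glyph rows over an indoor
background (30 cd/m²), dark ink at 1 cd/m² (Michelson contrast 0.96). Glyph
sizes default to 30 / 16 / 12 arcmin for far / intermediate / near. Every
plane is nonzero only inside its region mask, and generation is bit-exact
reproducible per seed. The surrogate deliberately omits color, luminance
adaptation gradients, and natural-scene semantics; conclusions about real
scenes therefore rest only on the blur-sensitivity of the content's spatial
spectrum, not on its appearance.

Scene pixels live on the PSF's angular grid (≈0.19 arcmin/px), so
convolution needs no resampling. Convolutions use mirror ("symmetric")
padding: with an axis-symmetric unit-sum kernel this conserves total flux
to machine precision and avoids the dark-border artifacts zero padding
would introduce into edge-heavy text metrics.

## Image quality and binocular combination

Quality is scored against the diffraction-limited image of the same plane,
within that plane's region mask (the task directs the observer's judgment
to the region showing that distance). The default metric is the regression
slope of the retinal image onto the reference (zero-mean covariance /
reference variance, clipped to [0, 1]). It equals correlation × relative
contrast, so the defocused veil a simultaneous-vision correction
superimposes lowers it roughly in proportion to the out-of-focus energy —
measured values track dwell fractions closely (2SV at near ≈ 0.50, 3SV at
intermediate ≈ 0.21). A scale-invariant normalized cross-correlation is
selectable (`ncc`, also `lowpass_ncc` with a 2 px Gaussian), but it is
nearly blind to that veil (2SV at far scores 0.92 under NCC) and was
therefore not made the default. A scene-free dwell-weighted Strehl mixture
is also provided. No neural transfer or retinal sampling is modeled; the
metric is an engineering correlate of perceived sharpness, validated only
against this package's own oracles.

Binocular combination defaults to `better_eye` (max of the two eyes),
reflecting sharpness dominance in binocular blur perception; `mean` and
`quadratic` summation are selectable. The better-eye rule is what makes
monovision inherit the better monofocal eye's quality at both far and near.

## Synthetic observers

A subject maps binocular quality `q ∈ [0, 1]` to a score
`clamp(g·q + b + ε, 0, 5)` with `ε ~ N(0, 0.45)` — the repetition SD the
protocol emulates. The default cohort of 8 draws gains from N(4.0, 0.25)
and biases from N(0.5, 0.1) (clipped), placing responses to the best and
worst stimuli about one noise SD inside the scale ends so that the clamped
noise realizes close to its nominal SD (pooled repetition SD ≈ 0.43 in
practice; an unbounded transducer at the rails would truncate it to ≈0.32).
Distance weights for "overall" judgments are Dirichlet(6, 4, 6) draws, one
fixed vector per subject. 2AFC choices compare distance-weighted utilities
with independent N(0, 0.09) interval noise (0.09 ≈ score noise divided by
the nominal gain), giving a cumulative-normal psychometric function with
comparison SD 0.09·√2. Each subject owns one seeded generator used for both
trial-order shuffling and response noise, so entire tables are reproducible
from the cohort specification.

The protocol sizes are fixed by the design: 17 corrections × 4 distances ×
3 repetitions of scoring and 36 pairs × 6 repetitions of preference per
subject. The observer does not model adaptation, learning, fatigue, or any
fit to a particular human cohort; human score means are not targets.

## Analyses

Score aggregation averages repetitions within subject first, then across
subjects; family aggregates report the mean |far − near| difference and the
mean (far + near)/2 score over each family's corrections. The energy-score
correlation is Pearson's r over per-subject mean scores against binocular
energy in focus at the corresponding distance, in all three binocular
energy modes. The ANOVA is a fixed-effects main-effects model
(type II sums of squares, via OLS) over the balanced subject × correction ×
distance factorial; degrees of freedom are therefore subjects−1,
corrections−1, distances−1. Zero-variance factors are reported as F = 0,
p = 1 rather than the 0/0 indeterminate form.

Preference cells classify on the operational count rule (≥5 of 6 preferred,
≤1 of 6 rejected), generalized to ⌈5n/6⌉ / ⌊n/6⌋ for pooled counts; the
exact one-sided binomial tail P(X ≥ k | n, ½) is attached to every cell.
The stated rule corresponds to a tail of 7/64 ≈ 0.109 at 5-of-6, so the
counts — not a nominal significance level — are authoritative, and the tails
let users apply any level they prefer. Pooled maps classify summed counts
across subjects (a majority-of-subjects pooling would be an alternative;
summed counts were chosen and are documented here). No multiple-testing
correction is applied across the 36 pairs, matching the protocol.

## Problem sizes and numerical choices

The package defaults to the device geometry (12° field, 5 mm pupil, 256
pupil samples, pad factor 2). The test suite and the acceptance script run
the same pipeline on 4° and 6° fields respectively — the scene scales with
the field while PSFs are field-independent, so this changes only the amount
of scene content, not the optics. PSF kernels are center-cropped to the
smallest window holding all but 10⁻¹² of the energy and renormalized, which
preserves flux conservation exactly. Convolution is FFT-based in float64;
multiplexing linearity holds to <10⁻⁹ per pixel by construction and is
asserted at that tolerance.

## Known limitations

Monochromatic, defocus-only optics; no straylight, prism magnification, or
anisometropic size differences; no stereo or 3-D targets (monovision's
known weakness is therefore invisible here); binocular combination is a
static pointwise rule with no rivalry or summation dynamics; the observer
is a linear transducer and cannot exhibit adaptation-dependent preference
reversals. The synthetic cohort demonstrates that the pipeline recovers
structure it is given — it cannot validate the perceptual model against
human data.
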