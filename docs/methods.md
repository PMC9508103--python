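# Methods

This note documents the models implemented in `phluorin`, the choices made
where the procedure left room, and what the synthetic benchmarks do and do
not establish.

## Imaging model and the synthetic generator

The generator (`phluorin.synthetic`) emulates widefield pHluorin imaging
of cultured oligodendrocytes:

```
stack(t) = background · cell_mask · exp(−t / bleach_tau)  +  Σ events  +  noise
```

with i.i.d. Gaussian read noise added last. Defaults
(`AcquisitionParams`): 250 ms/frame, 240 frames (1 min), 0.1 μm pixels,
background 200 AU, noise SD 10 AU, PSF σ 0.1 μm (≈ the diffraction limit
of a 63×/1.4 NA objective at 510 nm), no bleaching unless asked. The noise
model is additive Gaussian rather than Poisson because every detection
threshold is expressed in SD units, which makes the 4-SD criterion exactly
interpretable; at the background levels emulated the two regimes are
practically indistinguishable. Amplitudes are specified in multiples of
the noise SD for the same reason.

Event placement (`sample_events`) is a thinned Poisson process: count
~ Poisson(rate · duration), onsets uniform, positions uniform over the
cell mask, mode Bernoulli(full-fusion fraction). Rate defaults follow the
measured culture behaviour (23 events/min, 80% full fusion). The optional
minimum spatial/temporal separations exist to generate benchmark layouts;
they condition the uniform distributions rather than replacing them
(onsets use the exact sorted-uniform construction for gap-constrained
spacing) and truncate counts that cannot be packed.

**Event kinetics.** Kinetics are evaluated at frame midpoints with onsets
snapped to the nearest frame; sub-pixel positions are rendered by
evaluating the Gaussian analytically at pixel centres.

*Kiss-and-run*: a single diffraction-limited Gaussian whose amplitude
decays exponentially (default τ = 1.2 s, the slow end of reported
pHluorin re-acidification, with ±10% lognormal jitter) at fixed width —
no membrane is added, so nothing spreads and the 250–500 nm annulus stays
at the noise floor.

*Full fusion*: the reporter joins the plasma membrane. Rendered as two
components: a confined, diffraction-limited component (85% of the peak,
decay τ = 2.0 s) and a membrane-pool component (15% of the peak, σ ≈
0.33 μm ⊕ PSF) whose spatial variance grows as σ² + 2·D·Δt
(mass-conserving spreading, D = 0.01 μm²/s) while its total intensity
decays with its own half-life. The pool's half-life is drawn per event as
a multiple of the confined component's from N(0.89, 0.14²) — the observed
full-fusion border-decay-ratio population — truncated to [0.3, 1.5].

The two-component construction is deliberate. A single spreading Gaussian
cannot reproduce the observed ratio population: analytically, the
250–500 nm annulus of a spreading Gaussian always decays *more slowly*
than the 250 nm disk (the annulus is fed by the centre — writing the disk
content as `1 − exp(−a/s)` and the annulus as `exp(−a/s) − exp(−b/s)`
with `s = σ²(t)`, the annulus log-derivative in `s` is smaller for every
`s`), so deterministic ratios land well above 1 regardless of the
diffusion coefficient. The real sub-unity population arises from fit and
noise behaviour on real traces; the generator encodes it directly as the
pool's relative half-life, which keeps every physical invariant (mass
conservation when decay is off, strictly decreasing peak, border peaking
at or after the centre) while giving the downstream ratio distribution the
documented centre. The split (85/15) and pool width were set so the
annulus carries clearly resolvable signal while the centre disk remains
dominated by the confined component — with heavier cross-contamination the
fitted centre half-life blends toward the pool's and the measured ratios
drift toward 1. None of the kinetic constants (decay τ, D, pool width)
are measurements; they are emulation parameters.

Determinism: all sampling uses `numpy` Generators spawned from
`SeedSequence(seed)`; identical inputs give bit-identical stacks and truth
tables.

Sheath layouts place events along a 1-D sheath with a configurable
paranodal odds multiplier (1 = uniform); node line scans are sums of
Gaussian peaks (σ 0.3 μm) at class-defining arrangements with additive
noise; sheath cross-sections are two Gaussian tracks (σ 0.15 μm) at a
given separation.

## Detection

Pipeline (`phluorin.detection`): exponential bleach correction on the
frame-wise spatial mean (fits `A·exp(−t/τ) + C`; constant or
non-convergent cases return the stack unchanged with τ = ∞), ΔF/F against
the per-pixel all-time mean, then the event criteria.

Candidates are per-frame local maxima on ΔF/F inside the cell mask above
5 robust (MAD-based) SDs, linked across ≤ 2-frame gaps into tracks. For
each track the ⅓-of-max connected ROI is grown at the peak frame, and the
ROI-mean trace is scanned for the earliest onset whose preceding 4-frame
baseline (F0, SD) satisfies: rise ≥ 4 SD above F0, supra-threshold for
≥ 3 consecutive frames. Acceptance further requires a symmetric 2-D
Gaussian fit at the peak frame with R² ≥ 0.8, and total displacement
≤ 0.5 μm. Duplicates within 1 μm overlapping in time are merged keeping
the brighter.

Choices worth stating:

* **"Local background"** is the event's own ROI statistics over the
  4 frames preceding onset (the most explicit of the procedure's
  formulations and the one adopted).
* **Candidate pre-threshold (5 robust SD on peak ΔF/F).** The binding
  criterion is the 4-SD ROI-mean rule: an event at that limit has a
  peak-pixel amplitude around 6 SD, above the pre-filter. The pre-filter
  removes per-pixel noise maxima so the shape check cannot be reached by
  noise blobs. Measured consequence: zero false positives on eight
  pure-noise default stacks, recall 0.98–0.99 at amplitudes 8–14 SD.
* **Shape check.** "Gaussian-shaped" is operationalised as R² ≥ 0.8 of a
  symmetric 2-D Gaussian + offset on the peak frame, computed on a σ=1 px
  smoothed patch restricted to in-mask pixels. Smoothing keeps R²
  measuring shape rather than read noise (a Gaussian stays Gaussian);
  the mask restriction stops thin processes from truncating the fit.
* **Motion.** Displacement is the max of (a) the ΔF/F-weighted centroid's
  excursion from the peak over the supra-threshold run, and (b) the
  linked track's candidate-path excursion plus net first-to-last drift.
  (b) matters because a drifting punctum spends only a few frames at any
  one ROI and its track may split mid-drift. The 0.5 μm default (the
  border-annulus outer radius) is a choice; the procedure gives no number.
* ΔF/F is zeroed outside the cell mask before candidate search: outside
  pixels have near-zero temporal mean and the quotient is meaningless
  (real cameras add an offset; the synthetic background exists only
  inside the mask).
* Inputs are assumed registered; registration is out of scope.

## Fusion-mode classification

Traces (`phluorin.fusion`): centre = mean over pixels whose centres lie
within 250 nm of the event centroid; border = (sum within 500 nm − sum
within 250 nm) / annulus pixel count. Membership is by pixel-centre
distance with no partial-pixel weighting — reproducible bit-exactly, and
at 0.1 μm pixels the inner disk holds 21 pixels. Traces are aligned so the
centre maximum (earliest on ties) is t₀ and fitted on t ≥ 0 to
`A·exp(−t/τ) + C` (multi-start least squares; fits invalid when R² < 0.5,
A ≈ 0, or τ outside [dt/10, 100 × span]). The offset C is included
because pHluorin traces decay to a nonzero membrane baseline; half-lives
are reported analytically as τ·ln 2 for noise robustness.

The border decay ratio t½(border)/t½(center) is classified against the
population model (μ = 0.89, σ = 0.14): full fusion iff ratio ≥ μ − 3σ
= 0.47, boundary inclusive. The rule is one-sided — the minimal reading of
"within 3 standard deviations ... and less than" — with a strict
two-sided variant behind `RatioModel(two_sided=True)`.

**Noise-floor borders.** A kiss-and-run event's annulus holds ~4% of a
diffraction-limited punctum's light spread over ~59 pixels; its border
trace is statistically indistinguishable from noise and an offset
exponential fit on it is invalid-by-flatness. When the centre fit is valid
but the border carries no resolvable decaying signal (invalid fit, or
amplitude below 2× the border's pre-onset noise), the border half-life is
treated as below temporal resolution (half a frame interval), giving a
small ratio and a `border_noise_floor` flag — precisely the "rapid border
decay" phenotype that defines kiss-and-run. Invalid *centre* fits make an
event unclassifiable.

`fit_ratio_population` refits (μ, σ) with a two-component Gaussian
mixture (deterministic quantile initialisation, so the result is
seed-free); the component with the larger mean is the full-fusion
population. Fewer than 20 ratios, or a degenerate mixture, falls back to
the reference values. Batch classification defaults to the reference
population: on noisy batches the fitted component SD absorbs fit noise
and silently widens the 3-SD acceptance region, which is rarely wanted.

## Spatial statistics

A sheath is a 1-D coordinate system with 3 μm paranodal margins; events at
s ≤ 3 or s ≥ L − 3 are paranodal (boundary inclusive, mirroring the
fusion-rule convention). The uniform null per sheath is min(6/L, 1); the
summary averages the expectation per sheath (matching the sheath as the
unit of analysis; event-weighted pooling is available) and reports the
observed fraction as mean ± SEM across sheaths. No hypothesis test is
attached — the comparison is descriptive, as in the source analysis.

## Morphometry

* **Coverage**: `N·L·I` per genotype; the genotype comparison is the
  ratio, invariant under any common rescaling of units.
* **Membrane budget**: `n = rate · full_fraction · duration`; each fusion
  adds a sphere surface `π·d²` (diameters are the input unit to avoid
  radius/diameter confusion). Outputs are unrounded; a presentation
  helper reproduces conventional rounding (3-significant-figure areas,
  whole-percent truncation). At the default inputs the exact bounds are
  1664.8 / 6659.2 μm² and 27.75 / 110.99%, i.e. 27% and 110% after
  truncation.
* **Nodes**: maxima are counted on optionally smoothed line scans
  (default σ = 2 samples) with a prominence threshold of 20% of the
  profile range; both channels share one prominence scale (the larger
  channel's range) so a signal-free channel is not scored against its own
  noise. Rule: (Caspr, AnkG) maxima of (2, 1) → mature, (1, 1) →
  heminode, a maximum in exactly one channel → cluster, anything else →
  `none`, flagged. The exact smoothing used upstream of the original
  counts is unstated; these defaults are exposed in `MaximaParams`.
* **Diameter**: distance between the *two most prominent* maxima (robust
  to shoulder noise; more than two maxima flags the measurement
  ambiguous).

## Benchmarks: what they show

The test suite validates each stage against the generator's ground truth:
detector recall and precision ≥ 0.95 on 50 seeded stacks of well-separated
8–14 SD events (measured ≈ 0.98 / 1.0); zero detections on noiseless
static and pure-noise stacks; exponential-decay recovery exact (10⁻⁶
relative) on noiseless traces and median error ≈ 4% at SNR 10 on
well-sampled traces (20 Hz over 6τ, 240 samples — at 4 Hz over 4τ the
information floor of the 3-parameter fit is ~8–12% for any estimator, so
the sampling grid is part of the benchmark's definition); fusion-mode
recovery ≥ 95% on 500 labeled events per mode at SNR 10 with the fitted
full-fusion mixture mean inside [0.7, 1.1]; the spatial null calibrated
within 3 SE at L ∈ {6, 12, 30}; node classification 100% noiseless and
> 95% at moderate noise, with maxima counting equal to an exhaustive
brute-force oracle on all ternary profiles of length ≤ 8; and track
separations of 0.89 and 1.46 μm recovered within one sample spacing.

Passing these establishes internal consistency — the pipeline recovers
what the generator encodes under the stated conditions. It does not
establish performance on real microscopy: the generator omits Poisson
shot noise, camera gain and offset structure, focus drift, optical
aberration, sub-frame event kinetics, two-colour bleed-through and
registration error, and its kiss-and-run/full-fusion kinetics are
emulation parameters, not measurements. Problem sizes in the benchmarks
(stack dimensions, replicate counts) were chosen as the smallest that
make the statistical assertions well-powered.

## Known limitations

* Candidate generation (local maxima on ΔF/F) is validated only against
  the stated criteria, not against the original extraction software's
  internals, which are not described.
* The bleach model corrects a global exponential only; spatially
  heterogeneous bleaching is not modelled.
* Events whose 500 nm annulus clips the image edge are unclassifiable by
  construction.
* The coverage model treats N, L and I as independent means; it inherits
  that approximation from its source.
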