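# Methods

## Compartment model

Each tissue region (tumor or normal) is modeled independently. The targeted
agent occupies a free interstitial pool `Cf_T` and a receptor-bound pool
`Cb_T`:

    dCf_T/dt = K1·Cp(t) − (k2 + k3)·Cf_T + k4·Cb_T
    dCb_T/dt = k3·Cf_T − k4·Cb_T

with `k3 = kon·Bavail` and `k4 = koff`. The control agent sees no receptors
and reduces to the one-compartment Kety model, whose solution for a
biexponential input `Cp(t) = scale·(A·e^(−αt) + B·e^(−βt))` is closed-form:

    Cf_C(t) = K1·scale·[A/(k2−α)·(e^(−αt) − e^(−k2t)) + B/(k2−β)·(e^(−βt) − e^(−k2t))]

Units are fixed package-wide: minutes, min⁻¹, nM. All agents start at zero
tissue concentration at injection. Measured signals are
`ROI = η·[vp·Cp + (1−vp)·Ctissue]`; `vp` defaults to 0 (the vascular term is
negligible at imaging times, and published tissue-parameter tables list no
blood-volume fraction) but is implemented in full, and `η_T = η_C = 1` by
default (the analysis pipeline's early-time-point normalization realizes
this convention on data).

Assumptions inherited from the model class: first-order (trace-level)
binding — bound agent must stay well below the available receptor pool, and
the solver flags (rather than rejects) solutions whose bound pool reaches 5%
of `Bavail`; matched plasma kinetics and matched `K1`/`k2` between targeted
and control agents (the pipeline's plasma correction and normalization
stages exist to repair violations in data); no saturation, no
internalization compartment (first-order internalization is equivalent to a
larger effective `koff`), no spatial transport between regions.

### Numerics

ODE solves use `scipy.integrate.solve_ivp` with LSODA (automatic stiffness
switching; binding rate constants up to ~7 min⁻¹ combined with multi-day
antibody time grids make the system moderately stiff), `rtol 1e-8`,
`atol 1e-12`, evaluated on the requested grid by dense interpolation.
Closed-form Kety evaluation switches to the analytic `K1·A·t·e^(−k2t)` limit
when `k2` is within 1e-9 of a plasma decay constant. Concentrations are
clipped at zero to remove integrator round-off undershoot.

## Contrast metrics

CVR uses sample standard deviations (ddof = 1). AUROC is the nonparametric
Mann–Whitney estimate with ties counted one half; it is invariant under
monotone transforms of pixel intensities, and CVR under common affine
rescaling — both properties are enforced by tests. The time of maximum CVR
takes the first frame attaining the maximum (earliest time favors a shorter
injection-to-surgery delay); the ≥98%-of-maximum window edges are located by
linear interpolation between frames. Frames where a metric is undefined
(e.g. the all-zero injection frame) are reported as NaN rather than raising.
An optional centered moving average is available for noisy experimental
curves and is off by default.

## Analytical time-to-maximum-contrast rules

With the apparent tumor efflux rate `k2a = k2/(1+BP)`:

    Tmax_SA = ln(K1′/K1) / (k2′ − k2a)
    Tmax_PA = 10/(k2 − k2a) · ln[(1/k2² − 1/k2a²) / (2/k2² − 2/(k2·k2a))]

Primed symbols are normal-tissue rates. Negative SA values mean tumor
contrast is maximal immediately; they are clamped to zero with a
`contrast_immediate` flag. In the PA expression both log arguments are
individually negative whenever `k2a < k2`, so it is evaluated as the log of
the ratio, which is algebraically identical where both logs exist and
defined everywhere the ratio is positive (it simplifies to `ln((2+BP)/2)`).
The leading factor of 10 is an empirical proportionality correction carried
by the published form and kept verbatim. `Tmax_PA` requires `BP > 0`;
`BP = 0` makes `k2a = k2` and is reported as a singular input. Lookup grids
(`tmax_lookup_grid`) require explicit axis definitions — SA grids take the
`K1′/K1` ratio and `k2a` with an explicit `k2′` — and mark singular cells
NaN.

## Synthetic scenes

A scene is a tumor disc plus a background annulus on a pixel grid. Per
pixel, `K1` and `k2` are drawn from normal distributions truncated at zero
(region-specific mean/SD; truncation preserves rate positivity, at the cost
of shifting the sample mean slightly above the nominal mean — tests compare
against the truncated distribution's true moments). `BP` is constant per
region; `k3 = BP·koff` pixelwise. Pixel ensembles are integrated with a
vectorized fixed-step RK4 whose step is set well inside the accuracy region
of the fastest local rate (validated against the adaptive reference solver).

Detector: both channels are scaled by one joint factor so the brightest
expected pixel over the whole experiment reaches a configurable fraction
(default 20%) of a 16-bit detector's full scale (13107 expected counts);
counts are then Poisson-distributed per pixel per frame. A pre-injection
frame (optional constant autofluorescence, default 0) exercises the
pipeline's background-subtraction stage. Joint scaling preserves the
targeted/control ratio at every pixel; seeded generation is exactly
reproducible, and parameter maps and detector noise use separate seed
streams so changing the noise realization never changes the ground truth.

What the scenes do **not** emulate: optical blur, depth-dependent
attenuation, motion, autofluorescence structure, inter-animal variability.
Passing scene-level tests therefore demonstrates correctness of the
analysis chain under the stated noise model, not performance on real
instrument data.

## Analysis pipeline

Stages, in order: (1) pre-injection frame subtraction (negatives clamped to
zero for count data; an unclamped float mode exists for diagnostics);
(2) early-time-point pixel-by-pixel normalization — at the first frame ≥ 1
min the channels differ only by gain/labeling factors, so the per-pixel
ratio rescales the control channel (pixels with nonpositive early control
signal are excluded and reported); (3) optional plasma-kinetics correction:
the measured control series is deconvolved against the control plasma input
and reconvolved with the targeted plasma input, implemented as a causal
(lower-triangular Toeplitz, trapezoid-rule) Tikhonov-regularized linear
operator — identity when the plasma models coincide, and accurate to ~2e-4
relative against closed-form oracles at the default relative regularization
of 1e-10; (4) per-frame SA and PA metrics, a late-frame BPratio map, and
ROI-averaged BPratio (mean of pixel ratios by default; ratio of ROI means
available, since either reading of "ROI-averaged" is defensible).

Model fits minimize unweighted squared error (a Poisson-weighted option
exists): biexponential plasma fits post-sort phases so `α > β`; Kety fits
use bounded multi-start least squares (3 starts, bounds `[1e-6, 10]` min⁻¹)
with the closed form as forward model. An all-zero tissue curve carries no
kinetic information and returns the lower bound with zero residual.

## Monte-Carlo validation study

For each of four agent classes (peptides; low-MW antibody fragments; high-MW
fragments; antibodies) the five parameters (tumor/normal `K1`, `k2`, tumor
`BP`) are drawn uniformly and independently from packaged literature-derived
human-cancer ranges, 250–1000 draws per class. Per draw, noise-free tumor
and normal curves are simulated on a class-adaptive grid (0–600 min at
0.25 min for fast classes; 0–120 h at 2 min for slow classes, so the peak is
resolvable for every class), the "true" time of maximum contrast is located
on the CVR curve, and the analytical predictions are evaluated on the same
draw. Seeding derives one substream per class from the global seed and the
class name, so per-class results are independent of evaluation order and of
which classes are requested.

Three study conditions are underdetermined for hypothetical agent classes
and were fixed as follows:

- **Plasma input**: monoexponential decay at the class's elimination
  constant (the assumption under which the analytical rules were derived);
  the high-MW fragment class, which has no fitted plasma model of its own,
  uses the geometric mean of the neighboring classes' constants. A full
  biexponential mode is available (`plasma_mode="biexp"`).
- **BP split**: ranges specify `BP` only; it is realized with a fixed
  `k4 = 0.1` min⁻¹ (mid-range of physiological off-rates) and `k3 = BP·k4`.
  The numeric peak time depends only weakly on this split at fixed BP.
- **CVR construction**: region-mean signals are jointly scaled to the
  detector's 20%-of-16-bit peak and the pixel SD at each frame is the
  analytic Poisson SD of the expected counts (propagated through the
  pixelwise ratio for PA). This keeps per-draw curves deterministic while
  retaining the noise growth that terminates the contrast rise; without a
  noise term the PA ratio is monotone for a monoexponential input and the
  "time of maximum" would be censored at the end of every grid.

Dosing uses a trace-level plasma scale (0.001 nM reference) so bound agent
stays below 5% of the receptor pool for every packaged draw; the detector
rescaling makes the contrast curves independent of this choice.

### Known limitations

The numeric-vs-analytic agreement is sensitive to the unpublishable details
above. Under the constructions used here, the paired-agent comparison shows
strong correlation (Pearson r ≈ 0.91–0.94 pooled over classes, exceeding
the single-agent correlation) and the high-MW class lands on the expected
~10 h optimum, but the analytical PA rule runs ~1.5–2× from the numeric
optimum for some classes rather than within 10%, the single-agent numeric
optimum is dominated by slow bound-pool accumulation (large-BP draws) and
correlates poorly with the closed-form rule, and the PA-vs-SA
contrast-window ratios are near 1 rather than ≥ 2. The acceptance test
suite records these as failing expectations by design; the numbers the
package actually produces are written by `scripts/acceptance.py`. Users
applying the closed-form rules to their own agents should treat them as
order-of-magnitude scheduling estimates, which is also how the lookup grids
are intended.
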