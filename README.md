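# fgskinetics

Kinetic modeling and contrast-timing prediction for fluorescence-guided
surgery (FGS) with single-agent (SA) and paired-agent (PA) imaging
protocols.

In molecular FGS, a receptor-targeted fluorescent agent is injected before
surgery and the surgeon operates under an imaging system that displays
tumor-to-normal contrast. The central practical question is *when* after
injection the contrast is best — minutes for small peptides, many hours for
antibodies. This package provides the modeling layer for that question, for
imaging scientists and agent developers:

- **Compartment kinetics.** The targeted agent follows a linear
  two-compartment model per tissue region (extravasation `K1`, efflux `k2`,
  binding `k3 = kon·Bavail`, dissociation `k4 = koff`, all min⁻¹,
  concentrations in nM); a chemically matched untargeted "control" agent
  follows the one-compartment Kety model. The plasma input is a
  biexponential `Cp(t) = A·e^(−αt) + B·e^(−βt)`.
- **Paired-agent ratio.** The normalized channel difference
  `BPratio = (ROI_T − ROI_C)/ROI_C ≈ C_bound/C_free` converges at
  equilibrium to the binding potential `BP = kon·Bavail/koff`, a proxy for
  receptor density that cancels delivery variability.
- **Contrast metrics.** Tumor-vs-background discrimination over time via the
  contrast-to-variability ratio `CVR = |μ_T − μ_B| / √(σ_T² + σ_B²)` and the
  ideal-observer AUROC (Mann–Whitney), plus the time of maximum CVR and the
  window in which CVR stays ≥ 98% of its maximum.
- **Closed-form timing rules.** Analytical predictions of the time of
  maximum contrast: `Tmax_SA = ln(K1′/K1)/(k2′ − k2a)` with the apparent
  tumor efflux rate `k2a = k2/(1+BP)`, and a PA expression that depends only
  on the tumor `k2` and `BP`.
- **Synthetic scenes.** Dual-channel image time series with spatially
  heterogeneous kinetics and a shot-noise-limited 16-bit detector, so the
  full analysis pipeline is testable without any experimental data.
- **Monte-Carlo validation study.** Uniform sampling of literature-derived
  human-cancer parameter ranges for four agent classes (peptides, low- and
  high-molecular-weight antibody fragments, antibodies), comparing the
  numerically measured time of maximum CVR against the closed-form
  predictions.

## Worked example

Simulate an affibody-like agent pair in a tumor with binding potential 2 and
read off the paired-agent ratio:

```python
import numpy as np
from fgskinetics import (
    PlasmaInput, AgentKinetics, solve_targeted, solve_control,
    roi_signal, bp_ratio,
)

plasma = PlasmaInput(A=0.6, alpha=0.2, B=0.4, beta=5e-3)   # affibody plasma fit
k = AgentKinetics(K1=0.03, k2=0.3, kon=0.04, koff=0.1, Bavail=5.0)  # BP = 2
t = np.arange(0.0, 120.0 + 1e-9, 0.25)

curves = solve_targeted(k, plasma, t)          # free + bound targeted agent
curves.Cf_C = solve_control(k, plasma, t).Cf_C # control agent (Kety model)
roi_signal(curves, k, plasma)
ratio = bp_ratio(curves.roi_T, curves.roi_C)
for tm in (10, 30, 60, 120):
    print(f"BPratio at {tm:3d} min: {ratio[t == tm][0]:.3f}")
```

```
BPratio at  10 min: 0.656
BPratio at  30 min: 1.867
BPratio at  60 min: 2.150
BPratio at 120 min: 2.217
```

The ratio climbs toward the binding potential (2.0) as binding equilibrates,
then drifts slightly above it as the plasma input decays — quantifying
receptor density independent of how much agent was delivered.

Closed-form timing predictions (also available as the `predict-tmax` CLI
subcommand):

```python
from fgskinetics import tmax_sa, tmax_pa, SAInputs, PAInputs

tmax_sa(SAInputs(K1_tumor=0.2, K1_normal=0.4, k2_tumor=0.66,
                 k2_normal=0.5, BP=40.0)).tmax   # -> 1.43 min
tmax_pa(PAInputs(k2_tumor=0.66, BP=40.0))        # -> 47.28 min
```

For a fast peptide agent, single-agent contrast peaks within ~1.4 min, while
the paired-agent readout peaks near 47 min — the kind of scheduling
information the package exists to provide.

## Command line

```sh
fgskinetics simulate --preset peptide --bp 10 --out curves.csv
fgskinetics render-scene --preset affibody --bp 2 --seed 1 --outdir scene/
fgskinetics analyze --scene-dir scene/ --out analysis.json
fgskinetics predict-tmax --k2-tumor 0.66 --bp 40
fgskinetics run-study --classes peptide,lowmw,highmw,antibody --n 250 --seed 1 --outdir study/
fgskinetics make-grid --protocol PA --axis1 1,100,25 --axis2 0.001,1,25 --out grid.csv
```

Every output embeds the package version, the resolved configuration, and the
seed; all randomness flows from a single seed.

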