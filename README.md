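# epifold

A 3D vertex model of epithelial folding, with the analysis stages used to
study fold formation in columnar epithelia such as the *Drosophila* wing
imaginal disc: quasistatic tension-ramp simulations, in-silico laser
ablation recoil velocimetry, fold-shape quantification from cross sections,
and cross-correlation analysis of pulsatile actomyosin intensity and cell
height. Synthetic-data generators emulate the tracked-data structure of the
corresponding experiments, so every analysis stage is testable end to end
without any external data.

## The model

The tissue is a laterally periodic sheet of prismatic cells described by
paired apical and basal vertices x_i^a, x_i^b. Mechanics is governed by the
work function

```
W = Σ_c T_a A_a(c) + Σ_c T_b A_b(c) + Σ_f T̄_l A(f)
  + Σ_e∈apical Λ̄_a L(e) + Σ_e∈basal Λ̄_b L(e)
  + Σ_i∈basal (k/2) |x_i^b − X_i^ref|²
  + Σ_c (K_V/2) (V_c − V_0)² / V_0
```

with apical/basal/lateral surface tensions T_a, T_b, T_l, apical/basal edge
(junctional) tensions Λ_a, Λ_b, elastic springs of stiffness k anchoring
basal vertices to the extracellular matrix (ECM), and a stiff volume
penalty standing in for cell volume conservation. Shared lateral faces and
edges carry the mean tension of their 1–2 adjacent cells, counted once.
Units: the reference apical surface tension and the cell target volume are
1. Basal edge and surface tensions default to four times the apical ones
(the asymmetry measured by laser ablation in vivo); the two remaining free
parameters, Λ̂ = Λ_a/(T_a V_0^{1/3}) and k̂ = k V_0^{1/3}/T_a, default to 1.

Folds form by quasistatic ramping: in a stripe of pre-fold cells, either
the basal tensions are decreased (T_b, Λ_b → (1+δ_b)·, δ_b ≤ 0; the
ECM-depletion mechanism) or the lateral tension is increased (T_l →
(1+δ_l)·; the lateral actomyosin mechanism), re-relaxing to mechanical
equilibrium at each step. Both mechanisms produce folds with a pronounced
apical indentation; the basal-decrease fold shows the stronger basal
expansion, and increased apical tension (the classical apical-constriction
picture) produces almost no fold.

## Worked example

```python
from epifold import build_hex_tissue, assign_stripe, run_ramp, RampProtocol

mesh, params = build_hex_tissue(6, 6)          # relaxed periodic packing
assign_stripe(mesh, width=2)                   # pre-fold stripe
steps = run_ramp(mesh, params,
                 RampProtocol.default("basal_decrease", n_steps=6, magnitude=0.6))
for s in steps:
    g = s.geometry
    print(f"-delta={-s.delta:.2f}  d_a/h={g.d_a_norm:.4f}  l_b/h={g.l_b_norm:.4f}")
```

prints the quasistatic fold-growth curve

```
-delta=0.10  d_a/h=0.0580  l_b/h=0.2430
-delta=0.20  d_a/h=0.1039  l_b/h=0.2905
-delta=0.30  d_a/h=0.1477  l_b/h=0.3081
-delta=0.40  d_a/h=0.2098  l_b/h=0.3324
-delta=0.50  d_a/h=0.2907  l_b/h=0.3668
-delta=0.60  d_a/h=0.3235  l_b/h=0.3815
```

where d_a/h is the apical indentation depth and l_b/h the basal
cross-sectional length of the fold cells, both normalized by the height of
cells outside the fold: as basal tension drops, the fold deepens and its
cells widen basally into wedges. The `examples/` directory contains one
short script per capability (build/relax, fold ramps, ablation recoil,
fold-shape readout, intensity/height cross-correlation, intensity ratios);
each prints the numbers it computes and what they mean. A thin CLI mirrors
the pipeline stages: `epifold build | simulate | ablate | quantify | xcorr
| synth | run-scenario`.

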