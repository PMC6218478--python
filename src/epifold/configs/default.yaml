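# Default run configuration.  All numeric defaults of the simulation live
# here; tensions are in units of the reference apical surface tension and
# lengths in units of the cell target volume^(1/3).
scenario: basal_decrease      # basal_decrease | lateral_increase | apical_increase
seed: 0
n_replicates: 1
perturb_amplitude: 0.0        # seeded vertex perturbation for replicates
relax_tol: 1.0e-06             # max vertex force norm at equilibrium

tissue:
  nx: 10
  ny: 10
  aspect_ratio: 5.0           # cell height / in-plane diameter before folding
  stripe_width: 2             # pre-fold stripe width in cell rows (4 = the
                              # observed ECM-reduction stripe width)

params:
  basal_apical_ratio: 4.0     # basal edge+surface tensions over apical ones
  lambda_hat: 1.0             # edge tension / (T_a V0^(1/3)) -- free parameter
  k_hat: 1.0                  # ECM spring constant V0^(1/3) / T_a -- free parameter
  K_V: 2.0e+4                  # volume-penalty stiffness (keeps violation < 0.1%)

ramp:
  n_steps: 40
  magnitude: 0.8              # |delta| at the end of the ramp (1.0 for lateral)

ablation:
  drag: 1.0                   # overdamped drag per vertex (cancels in ratios)
  dt: 2.0e-05                  # recoil integration step, reduced time
  n_frames: 4
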