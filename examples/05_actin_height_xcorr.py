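"""Cross-correlation of lateral F-actin intensity and cell height.

Twelve synthetic fold cells are generated in which a relative increase of
lateral intensity drives a relative decrease of cell height 22 s later
(pulsatile mean-reverting fluctuations, sampled every 10 s).  The analysis
computes the relative rates of change by central differences and their
cross-correlation C(tau); the minimum of C at a positive lag near 22 s,
with a negative value, is the signature that intensity pulses precede
height drops.  A zero-coupling control stays inside the independence null
bound.
"""

import numpy as np

from epifold import (
    cross_correlation,
    gen_coupled_timeseries,
    min_lag,
    null_bound,
    relative_rate,
)


def analyze(series):
    dt = series[0].dt
    g1 = [relative_rate(s.a_l, dt) for s in series]
    g2 = [relative_rate(s.h, dt) for s in series]
    return g1, g2, cross_correlation(g1, g2, max_lag=100.0, dt=dt)


fold = gen_coupled_timeseries(n_cells=12, duration=600, dt_sample=10.0,
                              delay=22.0, coupling=1.0, seed=42)
g1, g2, res = analyze(fold)
tau, c = min_lag(res)
print(f"fold cells:    C minimum {c:+.2e} at lag {tau:+.0f} s "
      f"(generator delay 22 s, grid step 10 s)")

control = gen_coupled_timeseries(n_cells=12, duration=600, dt_sample=10.0,
                                 delay=22.0, coupling=0.0, seed=43)
g1c, g2c, res_c = analyze(control)
bound = null_bound(g1c, g2c, max_lag=100.0, dt=10.0)
print(f"zero coupling: max |C| = {np.nanmax(np.abs(res_c.C)):.2e} "
      f"< null bound {bound:.2e}")
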