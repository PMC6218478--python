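"""Quasistatic fold formation by basal tension decrease.

The basal edge and surface tensions of a 2-row stripe of pre-fold cells are
reduced in steps (delta from 0 to -0.6); after each step the tissue is
re-relaxed to mechanical equilibrium and the fold geometry is measured on a
cross section: apical indentation d_a, signed basal deformation d_b
(positive = outward bulge), apical/basal cross-sectional lengths l_a / l_b
of fold cells, all normalized by the neighbor cell height h_tissue.  d_a
and l_b grow monotonically while l_a shrinks: the fold cells become wedges
that widen basally, with a pronounced apical indentation.
"""

from epifold import RampProtocol, assign_stripe, build_hex_tissue, run_ramp

mesh, params = build_hex_tissue(6, 6)
assign_stripe(mesh, width=2)

protocol = RampProtocol.default("basal_decrease", n_steps=6, magnitude=0.6)
steps = run_ramp(mesh, params, protocol, keep_meshes=False)

print("  -delta    d_a/h    d_b/h    l_a/h    l_b/h")
for s in steps:
    g = s.geometry
    print(
        f"  {-s.delta:6.2f} {g.d_a_norm:8.4f} {g.d_b_norm:+8.4f}"
        f" {g.l_a_norm:8.4f} {g.l_b_norm:8.4f}"
    )
print(f"\nmax volume violation along the ramp: "
      f"{max(s.max_volume_violation for s in steps):.2e}")
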