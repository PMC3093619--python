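"""Render the plaid and chevron-contour adaptor stimuli to PNG.

The plaid is the sum of two 0.49-contrast gratings at +/-45 deg from
vertical (0.8 c/deg) under an isotropic Gaussian envelope (sigma 1.33 deg,
8-deg diameter at the 1% cutoff).  The contour abuts two oblique gratings
(1.1 c/deg, 0.98 contrast) along a vertical hard edge to form a 140-deg
chevron, under an anisotropic envelope (10 x 5 deg at the 1% cutoff).
"""

from compadapt import (
    GaussianEnvelope,
    GratingSpec,
    envelope_extent,
    make_contour,
    make_plaid,
    save_png,
)

a = GratingSpec(orientation=45.0, spatial_frequency=0.8, contrast=0.49)
b = GratingSpec(orientation=-45.0, spatial_frequency=0.8, contrast=0.49)
plaid_env = GaussianEnvelope(sigma_x=1.33, sigma_y=1.33)
plaid = make_plaid(a, b, plaid_env)
save_png(plaid, "plaid.png")
print(f"plaid.png: peak contrast {abs(plaid.values).max():.3f} "
      f"(sum of the two 0.49-contrast components)")
print(f"plaid diameter at 1% cutoff: {envelope_extent(1.33, 0.01):.2f} deg "
      f"(~8 deg)")

g = GratingSpec(orientation=0.0, spatial_frequency=1.1, contrast=0.98)
contour_env = GaussianEnvelope(sigma_x=1.67, sigma_y=0.83)
contour = make_contour(g, g, contour_env, apex_angle=140.0)
save_png(contour, "contour.png")
print(f"contour.png: {contour.extent_deg[0]:.0f} x {contour.extent_deg[1]:.0f} deg "
      f"raster, extents at 1% cutoff "
      f"{envelope_extent(1.67):.1f} x {envelope_extent(0.83):.1f} deg (~10 x 5)")
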