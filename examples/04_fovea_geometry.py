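"""Foveal extent at viewing distances and eccentricity-driven field sizes.

The 5-degree fovea (half-angle 2.5 deg) subtends d * tan(2.5 deg) at
distance d: 43.7 mm at 1 m. Receptive fields grow with eccentricity;
the default profile is 3 + 0.5 * ecc pixels, snapped up to odd.
"""

from retipath import LinearRFProfile, RetinalGeometry, fovea_extent, fovea_mask, rf_size_at

for d in (500, 1000, 1300, 2000):
    print(f"at {d:5d} mm the fovea subtends {fovea_extent(d):5.1f} mm")

geometry = RetinalGeometry(
    fixation=(31.5, 31.5), pixels_per_degree=10,
    rf_size_profile=LinearRFProfile(intercept=3, slope=0.5),
)
mask = fovea_mask(geometry, (64, 64))
print(f"\nfovea mask on a 64x64 image at 10 px/deg: {mask.sum()} foveal pixels "
      f"(disc of radius 25 px)")
for ecc in (0.0, 1.0, 2.5, 4.0, 6.0):
    print(f"eccentricity {ecc:3.1f} deg -> receptive field {rf_size_at(ecc, geometry)}x"
          f"{rf_size_at(ecc, geometry)}")
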