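"""Instrument readings to physical quantities.

Converts a capillary nectar column to volume, a refractometer Brix
reading to sugar mass, and haemocytometer corner counts to a per-anther
pollen estimate.
"""

from floralwastage import (
    CapillarySpec,
    HaemocytometerSpec,
    brix_to_sugar_per_uL,
    capillary_volume,
    nectar_sugar_mass,
    pollen_per_anther,
    pollen_suspension_count,
    vpd,
)

# 12 mm of nectar in a 1 uL / 32 mm capillary
vol = capillary_volume(12.0, CapillarySpec(volume_uL=1.0, length_mm=32.0))
print(f"nectar volume: {vol:.3f} uL")

# that volume at 42% Brix (sucrose-equivalent, % m/m)
print(f"sugar content at 42% Brix: {brix_to_sugar_per_uL(42.0):.1f} ug/uL")
print(f"sugar in the sample: {nectar_sugar_mass(vol, 42.0):.1f} ug")

# four haemocytometer corner squares from one anther's 15 uL suspension
counts = [40, 45, 38, 44]
print(f"summed corner count: {pollen_suspension_count(counts)}")
print(f"estimated grains per anther: {pollen_per_anther(counts, HaemocytometerSpec()):.0f}")

# weather context: vapour pressure deficit at 15 C, 70% RH
print(f"VPD: {vpd(15.0, 70.0):.3f} kPa")

# The sugar figures chain a published sucrose-density table through linear
# interpolation; the per-anther estimate scales the mean corner count by
# chamber geometry and suspension volume.
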