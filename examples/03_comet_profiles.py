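"""Bin, align and average comet intensity profiles; high/low condition ratio.

Synthetic per-microtubule profiles share one comet shape (shallow rise at
the seed, flat lattice, bright exponential end peak) plus noise.  Profiles
are length-binned (±0.64 µm), aligned by integer-pixel shifts that minimize
the s.d. of the difference to a seeded reference, averaged, and the
high-motor condition is normalized by the low-motor condition per region.
"""

import numpy as np

from tiptraffic import (IntensityProfile, average_profiles, bin_and_align,
                        condition_ratio, parametric_comet_profile)

rng = np.random.default_rng(0)


def condition(lattice_level, end_amplitude, n=30):
    profiles = []
    for _ in range(n):
        p, _ = parametric_comet_profile(
            8.0 + rng.uniform(-0.4, 0.4), lattice_level=lattice_level,
            end_amplitude=end_amplitude)
        noisy = np.clip(p.values + rng.normal(0, 5, p.values.size), 0, None)
        profiles.append(IntensityProfile(noisy, p.pixel_size_um))
    return profiles


low = condition(100.0, 300.0)     # low motor concentration
high = condition(200.0, 1200.0)   # lattice signal x2, end peak x4

pset = bin_and_align(low, seed=0)
means = average_profiles(pset)
print(f"{len(low)} low-condition profiles in {pset.n_bins} length bin(s); "
      f"offsets span {pset.offsets_px.min()}..{pset.offsets_px.max()} px")
b0 = min(means)
print(f"bin 0 average: lattice ~{means[b0].values[30:60].mean():.0f} counts, "
      f"tip {means[b0].values[-1]:.0f} counts")

comet_ratio = condition_ratio(high, low, (0.0, 0.5)).mean()
lattice_ratio = condition_ratio(high, low, (2.0, 6.0)).mean()
print(f"high/low intensity ratio: comet {comet_ratio:.2f}, "
      f"lattice {lattice_ratio:.2f}")
print("The comet brightens ~2x more than the lattice: cargo at the end does "
      "not scale stoichiometrically with the motor signal.")
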