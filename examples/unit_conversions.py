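"""Worked unit conversions for the static-water assay.

Converts between water concentrations, mass release rates and molarities
using the assay geometry (3 l bucket, 30 min baseline window, 10 min
post-exposure window).
"""

from countersignal import (mass_for_molarity, molarity_from_rate,
                           post_exposure_rate, rate_from_molarity,
                           release_rate)

# A male whose 30 min of accumulation left 0.5 ng/ml in 3 l of water
rate = release_rate(0.5, volume_l=3.0, duration_min=30.0)
print(f"baseline release rate: {rate:.4f} mg/h")

# Post-exposure: concentration rose to 0.7 ng/ml after the 50 ml sample
# withdrawal and 1 ml treatment addition (volume 3.000 -> 2.951 l)
post = post_exposure_rate(0.5, 0.7, 3.0, 2.951, post_duration_min=10.0)
print(f"post-exposure release rate: {post.rate_mg_per_h:.5f} mg/h "
      f"(mass increased: {post.increased})")

# The average male reaches 7e-8 M in the bucket by the end of the baseline
# window -- expressed as a mass release rate in ng/s:
ngs = rate_from_molarity(7e-8, duration_s=1800, volume_l=3.0,
                         molar_mass_g_per_mol=472.64)
print(f"7e-8 M over 30 min in 3 l = {ngs:.1f} ng/s (~60 ng/s at 1 s.f.)")
print(f"round trip: {molarity_from_rate(ngs, 1800, 3.0, 472.64):.3g} M")

# Mass of labelled pheromone (sodium salt) needed for the weakest
# above-threshold treatment: males respond to under a nanogram.
mass = mass_for_molarity(5e-13, 3.0, 494.62)
print(f"mass for 5e-13 M in 3 l: {mass:.3f} ng")
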