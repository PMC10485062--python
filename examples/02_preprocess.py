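"""Record-level preprocessing: VPD, LE-to-WF conversion, QC filtering and
gap-limited interpolation.

Shows the arithmetic of each step on small inputs: the Magnus vapour
pressure deficit, the 0.408e-6 latent-heat conversion, the inclusive 0.8
quality threshold, and why a 7-day gap is filled but an 8-day gap is not.
"""

import numpy as np

from fluxbridge import compute_vpd, interpolate_series, le_to_wf

print("Vapour pressure deficit (kPa):")
for ta, td in ((25.0, 15.0), (15.0, 15.0), (10.0, 12.0)):
    print(f"  Ta={ta:5.1f} C, Td={td:5.1f} C -> VPD={compute_vpd(ta, td):.3f}")
print("  (saturated air gives zero; a dew point above Ta clamps to zero)")

print("\nLatent heat to water flux (mm per day):")
for le in (0.0, 100.0, -10.0):
    print(f"  LE={le:6.1f} W m-2 -> WF={le_to_wf(le):+.5f}")
print("  (100 W m-2 sustained for a day evaporates ~3.5 mm of water)")

print("\nGap-limited linear interpolation (fill only gaps of < 8 days):")
seven = np.array([1.0] + [np.nan] * 7 + [9.0])
eight = np.array([1.0] + [np.nan] * 8 + [10.0])
print("  7-day gap:", np.round(interpolate_series(seven, max_gap=7), 1))
print("  8-day gap:", interpolate_series(eight, max_gap=7))
print("  (the 8-day run stays missing: too long to trust a straight line)")
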