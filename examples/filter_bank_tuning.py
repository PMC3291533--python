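"""Build the oriented filter bank and report its calibrated tuning.

The bank holds 72 receptive fields: 4 orientations x 2 phases at the center,
and the same 8 filters replicated at 8 surround positions on a radius-6
circle.  Kernel parameters are calibrated at build time so that, measured
with full-field gratings, the peak spatial frequency is 1/6 cycles/pixel and
the orientation half-width at 70% of peak energy is 23.5 degrees (the median
V1 bandwidth the model emulates).
"""
from mgsm import build_filterbank, tuning_curves

bank = build_filterbank()
table, summary = tuning_curves(bank)

print(f"filters: {bank.n_filters} "
      f"({bank.n_center} center + {bank.n_groups} surround groups "
      f"of {bank.group_size})")
print(f"measured peak spatial frequency : {summary['peak_sf']:.4f} cyc/px")
print(f"orientation half-width @70%     : "
      f"{summary['orientation_halfwidth']:.2f} deg")
print(f"calibrated carrier / sigmas     : {bank.carrier_sf:.4f}, "
      f"{bank.sigma_u:.2f}, {bank.sigma_v:.2f} px")
# The half-width matches the design target because the envelope width along
# the bar axis is solved for it; the carrier is solved for the peak SF.
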