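"""Fit the energy-channel calibration from the line table's printed pairs.

A least-squares line channel = a*energy + b over the five reference
(energy keV, channel) pairs; the leave-one-out predictions show the map
is accurate to the nearest channel.
"""

from xrfdwt import LineTable, band_channels, fit_energy_calibration
from xrfdwt.spectra import REFERENCE_CHANNEL_PAIRS

lines = LineTable.default()
cal = fit_energy_calibration(REFERENCE_CHANNEL_PAIRS)
print(f"gain = {1000 * cal.gain:.4f} eV/channel, "
      f"offset = {cal.offset * 1000:.2f} eV at channel 0")

for held_out in ("Cu", "Zn"):
    pairs = [(e, c) for (e, c), ln in zip(REFERENCE_CHANNEL_PAIRS, lines)
             if ln.element != held_out]
    loo = fit_energy_calibration(pairs)
    print(f"leave-one-out {held_out}: predicted channel "
          f"{loo.channel_index(lines[held_out].energy)}")

print("quantification bands (inclusive channel intervals):")
for line in lines:
    lo, hi = band_channels(line, cal, 4096)
    print(f"  {line.element} {line.line} {line.energy} keV -> {lo}-{hi}")
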