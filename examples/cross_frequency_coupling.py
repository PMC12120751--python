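"""Measure phase-amplitude coupling between two estimated networks.

Simulates a 2.4 Hz modulator network whose phase modulates the amplitude of a
~40 Hz carrier network (depth 0.6), estimates both networks by scanning a
small grid, and quantifies the coupling as the amplitude of a one-cycle sine
fitted to the carrier's mean power over 36 modulator-phase bins.
"""

import numpy as np

import freqness as fn
from freqness.datamodel import FrequencyGrid

spec = fn.default_pac_spec(seed=11, depth=0.6)
dataset, _ = fn.simulate_dataset(spec)

centers = np.array([2.4, 20.4, 30.0, 40.8, 50.4, 60.0])
grid = FrequencyGrid(
    centers=centers,
    fwhms=np.array([fn.fwhm_schedule(c) for c in centers]),
    stimulation_frequency=2.4,
)
landscape = fn.scan_frequencies(dataset, grid, n_keep=2)
profiles = fn.cfc_scan(dataset, landscape, grid, modulator_frequency=2.4)

print("carrier    modulation strength   relative (strength / mean power)")
for prof in profiles:
    flag = "  <- planted carrier" if prof.carrier_frequency == 40.8 else ""
    print(
        f"{prof.carrier_frequency:6.1f} Hz   {prof.modulation_strength:12.4f}   "
        f"{prof.relative_strength:10.3f}{flag}"
    )
print(
    "\nOnly the planted carrier's power follows the 2.4 Hz network's phase:\n"
    "its fitted sine amplitude stands far above the background carriers,\n"
    "whose residual 'modulation' is just envelope noise."
)
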