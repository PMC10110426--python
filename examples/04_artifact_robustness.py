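"""How do real-world artifacts degrade the detection?

Superimposes synthetic EMG and cardiac (ECG) artifact waveforms on clean
CSD epochs at increasing gain and re-runs the detection on each cell of
the kind x gain grid.
"""

import numpy as np

import ckcnet as ck
from ckcnet.robustness import robustness_sweep

epoch_sets = []
for seed in (1, 2, 3):
    rec = ck.generate_scalp_recording(ck.SynthScalpConfig(duration=125.0, seed=seed))
    ep = ck.csd(ck.epoch(ck.filter_and_resample(rec)))
    ep.data = ep.data[:100]
    ep.kept_trigger_indices = ep.kept_trigger_indices[:100]
    epoch_sets.append(ep)

rms = float(np.sqrt(np.mean(epoch_sets[0].data**2)))
gains = [0.0, 2 * rms, 4 * rms, 8 * rms]
table = robustness_sweep(epoch_sets, ["emg", "ecg"], gains, seed=0)
print(table.to_string(index=False))
print(
    "\ngains are the injected artifact RMS in CSD units (multiples of the "
    "clean-data RMS here).  EMG (5-70 Hz) barely touches the 3.56 Hz "
    "response band, so detection survives; the spiky cardiac artifact "
    "overlaps it and eventually destroys both the mean peak CKC and the "
    "detection rate."
)
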