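"""Detect a movement-locked cortical response in a synthetic recording.

Generates two minutes of 21-channel EEG with a 3.56 Hz response embedded
on C3/C4 (phase-locked to 1.78 Hz stimulation triggers), then runs the
full detection chain: 0.5-30 Hz filtering, trigger-locked epoching, the
current-source-density transform, wavelet inter-trial phase coherence and
the Rayleigh/FDR channel statistics.
"""

import numpy as np

import ckcnet as ck
from ckcnet.pipeline import PipelineConfig, run_detection_pipeline

recording = ck.generate_scalp_recording(
    ck.SynthScalpConfig(duration=125.0, seed=1)
)
print(f"{len(recording.trigger_times)} stimulation triggers, "
      f"{recording.duration:.0f} s of EEG")

result = run_detection_pipeline(recording, PipelineConfig(max_epochs=100))

table = result.to_frame().sort_values("ckc", ascending=False)
print(table.head(6).to_string(index=False))
print(
    f"\npeak CKC {result.peak_ckc:.3f} at "
    f"{result.channel_labels[int(np.argmax(result.ckc))]} "
    f"over {result.n_epochs} epochs"
)
print(
    "CKC is the mean inter-trial phase coherence at 3.56 Hz: 1 = perfectly "
    "stimulus-locked, 0 = no locking.  'significant' marks channels whose "
    "aggregated Rayleigh P survives FDR (q = 0.01) - expected on the "
    "rolandic channels C3/C4 where the response was planted."
)
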