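"""Write a synthetic recording as a BrainVision triplet and read it back.

Demonstrates the minimal .vhdr/.vmrk/.eeg dialect: float-32 multiplexed
binary with the sampling rate and channel table carried in the header.
"""

import os
import tempfile

import numpy as np

from restalpha.brainvision import read_brainvision, write_brainvision
from restalpha.geometry import build_default_layout
from restalpha.simulate import GenerativeParams, generate_cohort, generate_recording

layout = build_default_layout()
params = GenerativeParams(seed=6, duration_s=10.0)
profile = generate_cohort(1, 1, params)[0]
recording = generate_recording(profile, "open", layout, params)

with tempfile.TemporaryDirectory() as tmp:
    header = os.path.join(tmp, f"{profile.id}.vhdr")
    write_brainvision(recording, header)
    sizes = {
        ext: os.path.getsize(os.path.join(tmp, f"{profile.id}{ext}"))
        for ext in (".vhdr", ".vmrk", ".eeg")
    }
    print("triplet sizes (bytes):", sizes)
    again = read_brainvision(header)

print(f"channels: {len(again.channel_labels)}, sampling rate: {again.sampling_rate} Hz")
stored = recording.samples.astype(np.float32).astype(float)  # what float-32 holds
print("bit-exact round trip at float-32:", bool(np.array_equal(again.samples, stored)))
print(
    f"binary size check: 64 channels x {recording.samples.shape[1]} samples "
    f"x 4 bytes = {64 * recording.samples.shape[1] * 4}"
)
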