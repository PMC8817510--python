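"""Generate a synthetic ICP recording and remove its spike artifacts.

Builds a one-hour, 100 Hz recording carrying macro-patterns, cardiac
and respiratory oscillations, noise, and two large sub-second spikes;
then runs the EMD-based artifact removal and reports what was flagged.
"""

import numpy as np

from icpshape import SyntheticSpec, generate_recording, remove_spikes

spec = SyntheticSpec(spike_amp_mmHg=50.0, seed=7)
recording, truth = generate_recording(spec)
print(f"recording: {recording.n_samples} samples at {recording.fs:g} Hz, "
      f"{len(truth.labels)} macro-pattern segments, "
      f"{len(truth.spike_indices)} injected spikes")

cleaned, mask = remove_spikes(recording)
print(f"universal threshold eta_s = {mask.eta_s:.2f} mmHg")
print(f"{mask.n_flagged} samples flagged "
      f"({100 * mask.flagged_fraction:.4f}% of monitoring time)")

hit = sum(mask.flags[a: a + w].any() for a, w in truth.spike_spans)
print(f"{hit}/{len(truth.spike_spans)} injected spikes detected")
print(f"max |cleaned - raw| at spike sites: "
      f"{np.max(np.abs(cleaned.samples - recording.samples)):.1f} mmHg removed")
# Every injected spike episode is caught while the flagged time stays
# around a tenth of a percent -- spikes are rare and sub-second, so the
# artifact-removed signal is essentially the raw signal minus spikes.
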