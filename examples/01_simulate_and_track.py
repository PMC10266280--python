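"""Simulate a two-mouse session and re-identify the animals across frames.

The simulator emits noisy, identity-stripped detections plus the ground
truth that produced them; the tracker must re-link identities using only
box/part-box geometry (the hierarchical IOU descriptor).
"""

import motiftrack as mt
from motiftrack.pipeline import track_session

session = mt.standard_benchmark(seed=7)
print(f"simulated {session.n_frames} frames, "
      f"{len(session.schedule)} motif segments")

tracked = track_session(session)
accuracy = mt.identity_accuracy(tracked, session.ground_truth)
print(f"frame-wise identity accuracy: {100 * accuracy:.2f}%")
# 100% means the tracker kept both identities through every crossing;
# each percent lost corresponds to ~10 frames of swapped labels.
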