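"""Trim a clip so motion starts at frame 2, then verify by re-detection.

Event-related designs need every stimulus to begin moving at the same frame;
trimming to the frame preceding the detected onset makes frame 1 a still
reference and frame 2 the first moving frame of every clip.
"""

from stimchar import (
    SyntheticVideoSpec,
    detect_motion_onset,
    make_motion_video,
    trim_to_onset,
)

seq, truth = make_motion_video(SyntheticVideoSpec(onset_frame=14, seed=3))
onset = detect_motion_onset(seq).onset_frame
trimmed = trim_to_onset(seq, onset)

print(f"original: {seq.n_frames} frames, onset at {onset}")
print(f"trimmed:  {trimmed.n_frames} frames (= {seq.n_frames} - {onset} + 2)")
print(f"re-detected onset on trimmed clip: {detect_motion_onset(trimmed).onset_frame}")
# The re-detected onset is 2: the edit removed exactly the still prefix.
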