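"""Clap-based synchronization of the two camera audio tracks.

The simulator staggers the right track's clap impulse by 600 audio samples
(12.5 ms at 48 kHz); detection recovers the stagger exactly and converts it
to a video-frame offset at 60 Hz, leaving the sub-frame remainder for the
later RMSE-based fine alignment.
"""

from lipstereo import compute_offset, render_audio

left, right = render_audio(2.0, stagger_samples=600, noise_sd=0.01, seed=3)
res = compute_offset(left, right, threshold=0.5, frame_rate=60.0)

print(f"clap indices: left {res.left_clap_index}, right {res.right_clap_index}")
print(f"offset: {res.offset_samples} samples = "
      f"{res.offset_samples / res.audio_rate * 1e3:.2f} ms")
print(f"frame offset at 60 Hz: {res.offset_frames} frames "
      f"(residual {res.residual_frames:+.2f} frames, corrected later by the "
      f"RMSE alignment stage)")
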