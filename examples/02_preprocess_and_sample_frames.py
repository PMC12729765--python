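"""Annotation removal and keyframe-window frame sampling.

Binarizing the keyframe at intensity 50 and taking the largest 8-connected
component's bounding rectangle isolates the imaging region, discarding the
device-text band and black margins; 10 frames are then sampled uniformly
from the +/-5-frame window around the reader keyframe.
"""

from ceusalnm import SyntheticConfig, generate_dataset, preprocess_clip, sample_frames

config = SyntheticConfig(n_patients=2, seed=1)
sample = generate_dataset(config)[0]

clip, indices, region = preprocess_clip(sample.frames, sample.keyframe_index,
                                        threshold=50, out_size=(64, 64))
print(f"frame size: {sample.frames.shape[1:]}, crop region (x0,y0,x1,y1): {region.as_tuple()}")
print(f"ground-truth imaging region:            {config.imaging_region()}")
print(f"annotation band occupies rows 0..{config.band_height - 1}; crop starts at row {region.y0}")
print(f"keyframe {sample.keyframe_index} -> sampled indices {indices}")
print(f"model input: {clip.shape} float in [{clip.min():.2f}, {clip.max():.2f}]")

print("window shifts at clip boundaries:", sample_frames(120, 2), "for keyframe 2")
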