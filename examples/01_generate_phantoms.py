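"""Generate a small phantom dataset and inspect its labels and quality.

The generator emulates B-mode echocardiography geometry: a sector fan
containing bright-walled elliptical "chambers" that pulsate over a cardiac
cycle, with multiplicative speckle.  Known view classes are distinct
chamber layouts; the three unknown subcategories (novel category, poor
quality, multiple views) appear only in the validation/test splits.
"""

from collections import Counter

from echoviews import DatasetConfig, GeneratorConfig, generate_dataset

cfg = DatasetConfig(n_classes=4, train_per_class=5, val_per_class=3,
                    test_per_class=3, frames_per_clip=8,
                    generator=GeneratorConfig(frame_size=128))
ds = generate_dataset(cfg, seed=0)

for split in ("train", "val", "test"):
    clips = ds.split(split)
    counts = Counter(str(c.label) for c in clips)
    print(f"{split:5s}: {dict(sorted(counts.items()))}")

clip = ds.test[0]
print(f"\nexample clip {clip.clip_id!r}: label={clip.label}, "
      f"{clip.n_frames} frames of {clip.frames.shape[1:]} in "
      f"[{clip.frames.min():.2f}, {clip.frames.max():.2f}], "
      f"ground-truth quality {clip.true_quality:.2f}")
print("Training holds known views only; val/test mix in all three unknown "
      "subcategories, each clip carrying a ground-truth quality in [0, 1].")
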