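"""Train three single-feature models and fuse them.

A desk-scale end-to-end run: three synthetic species (distinct chirp slopes,
imbalanced 30/20/10 syllables), 300 ms windows rendered as spe/mel/ch images,
one width-0.25 residual model per spectrogram kind at 32 px input, then
result-mode fusion of the frozen backbones. Takes about a minute on one CPU.
"""

from chirpid import (ModelSpec, TrainConfig, build_fusion_model, build_sfim,
                     default_recipe, generate_dataset, split_dataset,
                     train_fusion, train_sfim)
from chirpid.fusion import self_omega
from chirpid.pipeline import build_sample_images, make_sample_sets

SEED = 0
recipe = default_recipe(3, counts=[30, 20, 10], snr_db=20.0, seed=SEED)
dataset = generate_dataset(recipe)
sets, triple = make_sample_sets(build_sample_images(dataset.recordings,
                                                    duration_ms=300.0))
print(f"{len(sets['ch'])} windows per spectrogram kind, "
      f"class counts {sets['ch'].class_counts.tolist()}")

cfg = TrainConfig(batch_size=16, learning_rate=0.001, max_epochs=15,
                  patience=5, seed=SEED)
backbones = {}
for kind in ("spe", "mel", "ch"):
    train, test = split_dataset(sets[kind], 0.7, seed=SEED)
    model = build_sfim(ModelSpec(n_classes=3, width_multiplier=0.25,
                                 input_size=32), seed=SEED)
    history = train_sfim(model, train, test, cfg)
    backbones[kind] = model
    print(f"SFIM({kind}): {len(history)} epochs, "
          f"best test MAP {max(h['map'] for h in history):.3f}")

train3, test3 = split_dataset(triple, 0.7, seed=SEED)
fusion_cfg = TrainConfig(batch_size=16, learning_rate=0.001, max_epochs=100,
                         patience=10, seed=SEED)
fused = build_fusion_model([backbones[k] for k in ("spe", "mel", "ch")],
                           "result", n_classes=3, seed=SEED)
history = train_fusion(fused, train3, test3, fusion_cfg)
print(f"Re-fuse: {len(history)} epochs, "
      f"best test MAP {max(h['map'] for h in history):.3f}, "
      f"omega = {[round(w, 3) for w in self_omega(fused)]}")
print("\nMAP here is the mean over species of per-species accuracy. The"
      "\nfused model sits at or near the best single channel (at this tiny"
      "\nscale a strong channel can win outright), and omega shows how much"
      "\neach spectrogram kind contributes to the fused decision.")
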