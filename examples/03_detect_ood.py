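"""Classify held-out frontal vs lateral phantoms with the full decision rule.

Small-scale version of the detection experiment: train on frontal
phantoms only, then run inversion + Kolmogorov-Smirnov on unseen images
of both views and print each decision with its evidence (reconstruction
loss, K-S p-value, which rule fired).
"""

from ganscreen import (GanConfig, InversionConfig, PhantomSpec, ViewLabel,
                       build_models, detect, generate_dataset, train_gan)

cfg = GanConfig(latent_dim=16, resolution=16, base_feature_maps=8,
                batch_size=8, train_steps=300, seed=0)
train_set = generate_dataset(64, 0, PhantomSpec(ViewLabel.FRONTAL, 16), seed=1)
models, _ = train_gan(build_models(cfg), train_set, cfg)

test_set = generate_dataset(4, 4, PhantomSpec(ViewLabel.FRONTAL, 16), seed=99)
inv = InversionConfig(loss_threshold=0.05, extra_steps=30, max_steps=300,
                      z_seed=2, ks_stride=2)

correct = 0
for sample in test_set:
    d = detect(models, sample, inv)
    truth = "OOD" if sample.label is ViewLabel.LATERAL else "ID"
    call = "OOD" if d.is_ood else "ID"
    correct += truth == call
    print(f"true {truth:3s} -> called {call:3s}  loss {d.reconstruction_loss:.3f}  "
          f"p {d.ks.p_value:.3f}  rule {d.failure_mode.value}")
print(f"\naccuracy {correct}/{len(test_set)}")
# ID frontals reconstruct below the threshold and pass the K-S test;
# laterals either fail to reach the threshold (rule threshold_not_reached)
# or reconstruct with a wrong intensity distribution (p < 0.05).
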