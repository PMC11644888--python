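"""Train the 3-5-1 fatigue regressor and measure its hold-out accuracy.

Blink features of a 40 s window (mean closing, opening and idle time) are
mapped to a 10-50 fatigue self-assessment scale. The synthetic dataset uses
a monotone feature-to-scale mapping (slower, longer blinks = more fatigued)
plus Gaussian label noise; accuracy is 100% minus the mean absolute
relative error on the held-out 20%.
"""

import numpy as np

import capblink as cb
from capblink import fatigue as fg

samples = cb.generate_feature_dataset(8343, noise_sd=1.5, seed=7)
train_set, test_set = fg.train_test_split(samples, 0.8, seed=7)
print(f"dataset: {len(samples)} windows -> {len(train_set)} train / {len(test_set)} test")

net = fg.train(train_set, fg.TrainConfig(iterations=2000, learning_rate=0.5, seed=7))
print(f"training loss (normalized MSE): start {net.loss_history[0]:.4f}, "
      f"iter 100 {net.loss_history[99]:.4f}, final {net.loss_history[-1]:.5f}")

preds = fg.predict_many(net, np.array([s.features for s in test_set]))
acc = fg.accuracy(preds, [s.scale for s in test_set])
print(f"hold-out accuracy: {acc:.2f}%")

print("\nsample predictions (closing/opening/idle in s -> scale):")
for s, p in list(zip(test_set, preds))[:5]:
    print(f"  ({s.closing:.2f}, {s.opening:.2f}, {s.idle:.2f}) "
          f"-> predicted {p:.1f}, true {s.scale:.1f}")

net.to_json("fatigue_model.json")
print("\nmodel saved to fatigue_model.json")
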