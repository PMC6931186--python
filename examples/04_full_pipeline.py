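"""Train the full nine-path system and compare fusion strategies.

Uses a miniature configuration (small grid, narrow networks, few steps) so
the whole script finishes in a few minutes on one CPU; the desk-scale
profile used for the package's headline numbers is
multipath25d.desk_scale_pipeline().
"""

import numpy as np

from multipath25d import GridSpec, TrainConfig, generate_dataset
from multipath25d.phantom import PhantomSpec
from multipath25d.pipeline import MultiPathPipeline, as_cases
from multipath25d.training import evaluate_cases, summarize

spec = PhantomSpec(shape=(32, 32, 32))
train = as_cases(generate_dataset(8, base_spec=spec, size_mix=1.0, seed=1))
test = as_cases(generate_dataset(3, base_spec=spec, size_mix=1.0, seed=2))

pipe = MultiPathPipeline(
    GridSpec(target_shape=(32, 32, 32)), base_filters=4,
    path_train=TrainConfig(batch_size=8, epochs=3, steps_per_epoch=30, seed=0),
    fuser_train=TrainConfig(batch_size=8, epochs=4, steps_per_epoch=20,
                            lr0=0.01, seed=0),
    strategy="cnn3d", seed=3)
pipe.fit(train)

for strategy in ("union", "majority", "cnn3d"):
    table = evaluate_cases(test, lambda c: pipe.predict(c, strategy))
    s = summarize(table)
    print(f"{strategy:9s} mean Dice {s['mean_dice']:.3f}  "
          f"median {s['median_dice']:.3f}  (n={s['n']})")

# Union over-segments (any path's false positive survives); the learned 3D
# fuser and the majority vote clean those up, matching the ordering the
# full-scale system shows.
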