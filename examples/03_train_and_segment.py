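"""Train a small network on phantom patches and segment a held-out stack.

This is the full pipeline at desk scale: phantoms -> CLAHE -> balanced
64x64 patches -> weighted-BCE training with F-score checkpoint selection
-> tile-and-stitch inference -> pixel metrics.  A few minutes on one CPU.
"""

import numpy as np

from isletseg import (AANetSpec, PhantomSpec, RunConfig, apply_clahe,
                      evaluate_probabilities, generate_phantom,
                      make_training_set, predict_stack, train_model)

phantoms = PhantomSpec(stack_shape=(12, 128, 128), n_islets=4,
                       radius_range_px=(4, 9), z_radius_range_px=(2.5, 4),
                       seed=11)
data = make_training_set(phantoms, n_stacks=6, split_fracs=(4/6, 1/6, 1/6),
                         patch_size=64, stride=32, balance_fg=True)
print(f"training patches: {len(data['train']['images'])}, "
      f"foreground fraction {data['train']['masks'].mean():.3f}")

cfg = RunConfig(patch_size=64, learning_rate=1e-3, weight_decay=1e-5,
                batch_size=8, max_epochs=12, seed=0)
model, state = train_model((data["train"]["images"], data["train"]["masks"]),
                           (data["val"]["images"], data["val"]["masks"]),
                           cfg, AANetSpec(base_channels=8))
print(f"best validation F-score {state.best_fscore:.3f} "
      f"at epoch {state.best_epoch}")

stack, truth, _ = generate_phantom(PhantomSpec(
    stack_shape=(12, 128, 128), n_islets=4, radius_range_px=(4, 9),
    z_radius_range_px=(2.5, 4), seed=99))
enhanced = np.stack([apply_clahe(s) for s in stack.voxels])
probs = predict_stack(model, enhanced, patch_size=64)
report = evaluate_probabilities(probs, truth, threshold=0.5)
print(f"held-out stack: SE {report.SE:.3f}  PPV {report.PPV:.3f}  "
      f"IOU {report.IOU:.3f}  F {report.F_score:.3f}  AUPR {report.AUPR:.3f}")
# SE = fraction of true islet pixels found; PPV = fraction of predicted
# islet pixels that are real; IOU/F summarise the overlap; AUPR is
# threshold-free ranking quality.
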