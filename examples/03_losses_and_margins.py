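"""The reconstructive-contrastive loss and its margin schedule.

L_RC = [L_R - alpha]+ + [L_R - L_C + gamma]+ keeps the same-subject error
within the alpha margin while pushing predictions away from other subjects'
targets by at least gamma.  During phase-2 training alpha halves and gamma
doubles every 20 epochs.
"""

import numpy as np

from surftask import LossConfig, rc_loss
from surftask.train import margin_schedule

rng = np.random.default_rng(0)
targets = [rng.standard_normal((100, 4)) for _ in range(4)]

# predictions close to own target, far from others
preds = [t + 0.1 * rng.standard_normal(t.shape) for t in targets]
rep = rc_loss(preds, targets, LossConfig(alpha=0.05, gamma=1.0))
print(f"good predictions: L_R={rep.L_R:.4f}  L_C={rep.L_C:.4f}  L_RC={rep.L_RC:.4f}")
print("  (L_R below alpha and the contrast gap above gamma -> both hinges ~0)")

# predictions collapsed onto the group mean: small L_C - L_R gap
mean_map = np.mean(targets, axis=0)
collapsed = [mean_map.copy() for _ in targets]
rep = rc_loss(collapsed, targets, LossConfig(alpha=0.05, gamma=1.0))
print(f"collapsed predictions: L_R={rep.L_R:.4f}  L_C={rep.L_C:.4f}  L_RC={rep.L_RC:.4f}")
print("  (indistinguishable across subjects -> the contrastive hinge fires)")

print("\nmargin schedule (alpha0=1, gamma0=2):")
for epoch in (0, 19, 20, 40, 45):
    a, g = margin_schedule(1.0, 2.0, epoch)
    print(f"  epoch {epoch:3d}: alpha={a:.3f}  gamma={g:.1f}")
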