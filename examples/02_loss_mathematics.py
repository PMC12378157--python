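"""The distillation loss, piece by piece.

The student minimizes  L = alpha * L_hard + (1-alpha) * t^2 * KL(P_T || P_S)
where P_T and P_S are the teacher's and student's temperature-t softmax
distributions. Higher temperature flattens the targets, exposing how the
teacher ranks the wrong classes — the "dark knowledge" the student learns.
"""

import numpy as np

from meddistill import (DistillConfig, hard_label_loss, soft_target_kl_loss,
                        temperature_softmax, total_loss, TaskSpec)

teacher_z = np.array([2.0, 0.0, -1.0])
student_z = np.array([0.5, 0.2, 0.0])

for t in (1.0, 2.0, 8.0):
    p = temperature_softmax(teacher_z, t).probs
    print(f"t={t:>4}: teacher soft targets {np.round(p, 4)}")
# As t grows the targets approach uniform (1/3, 1/3, 1/3).

cfg = DistillConfig(temperature=2.0, alpha=0.2)
hard = hard_label_loss(student_z, [0], TaskSpec("multiclass", 3))
soft = soft_target_kl_loss(teacher_z, student_z, cfg.temperature)
breakdown = total_loss(hard, soft, cfg)
print(f"hard {breakdown.hard:.4f}  distill {breakdown.distill:.4f}  "
      f"total {breakdown.total:.4f} (alpha={cfg.alpha}, beta={cfg.beta})")
# total is the convex mixture 0.2*hard + 0.8*distill, in nats per sample.
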