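"""The two-phase pipeline on one seed: probe a frozen teacher, distill it
into a student, and compare against hard-label-only training.

Runs the full reference protocol (up to 100 epochs per stage with early
stopping) — a few minutes on one CPU. Expect the distilled and baseline
students to land within a few points of each other, with the distilled one
usually at or above the baseline at these moderate-noise conditions.
"""

from meddistill import Preprocessor, build_student, evaluate, distill, train_student
from meddistill.experiments import (make_reference_teacher, reference_config,
                                    reference_spec)
from meddistill.synthetic import generate_dataset

seed = 0
bundle = generate_dataset(reference_spec(seed))
pre = Preprocessor(bundle, 28, "dataset")

teacher = make_reference_teacher(bundle, pre, seed)
print("teacher test ACC:", round(evaluate(teacher, bundle, "test", pre).acc, 3))

student, history = distill(teacher, build_student("tiny", bundle.task, seed=seed),
                           bundle, reference_config(seed), pre)
rep = evaluate(student, bundle, "test", pre)
print(f"distilled student (t=2.0, alpha=0.2): AUC {rep.auc:.3f} ACC {rep.acc:.3f}")

baseline, _ = train_student(build_student("tiny", bundle.task, seed=seed),
                            bundle, reference_config(seed, alpha=1.0),
                            preprocess=pre)
rep_b = evaluate(baseline, bundle, "test", pre)
print(f"hard-label baseline (alpha=1.0):      AUC {rep_b.auc:.3f} ACC {rep_b.acc:.3f}")
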