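"""Construct each architecture (no weights needed) and count parameters.

The ResNet-50 student with a MedMNIST-sized head and the three
DINOv2-dimension ViT teachers land at 23M / 22M / 86M / 304M (floored
millions), which is why the compact student is worth distilling into.
"""

from meddistill import (TaskSpec, build_student, build_vit_backbone,
                        count_parameters, millions_floor)

task = TaskSpec("multiclass", 9)
for name, model in [("resnet50 student", build_student("resnet50", task)),
                    ("tiny student", build_student("tiny", task))]:
    n = count_parameters(model)
    print(f"{name:>18}: {n:>11,} ({millions_floor(n)}M)")
for variant in ("s14", "b14", "l14"):
    n = count_parameters(build_vit_backbone(variant))
    print(f"{'vit-' + variant + ' teacher':>18}: {n:>11,} ({millions_floor(n)}M)")
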