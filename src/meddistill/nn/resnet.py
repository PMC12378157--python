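"""ResNet-50 in NumPy: bottleneck stages [3,4,6,3], bias-free convolutions
with affine batch norm, global average pooling, and a task-sized linear head.

The construction matches the standard ImageNet ResNet-50 layer-for-layer, so
the backbone parameter count is the canonical 23,508,032; only the head size
depends on the task (m classes instead of the stock 1000-way classifier).
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear,
                     MaxPool2d, ReLU, Sequential)


class Bottleneck(Layer):
    expansion = 4

    def __init__(self, inplanes, planes, stride, rng):
        out = planes * self.expansion
        self.conv1 = Conv2d(inplanes, planes, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        if stride != 1 or inplanes != out:
            self.down_conv = Conv2d(inplanes, out, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x, train=True):
        identity = x
        y = self.relu1(self.bn1(self.conv1(x, train), train), train)
        y = self.relu2(self.bn2(self.conv2(y, train), train), train)
        y = self.bn3(self.conv3(y, train), train)
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x, train), train)
        return self.relu3(y + identity, train)

    def backward(self, dy):
        dy = self.relu3.backward(dy)
        d_identity = dy
        d_main = self.conv3.backward(self.bn3.backward(dy))
        d_main = self.conv2.backward(self.bn2.backward(self.relu2.backward(d_main)))
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(d_main)))
        if self.down_conv is not None:
            d_identity = self.down_conv.backward(self.down_bn.backward(d_identity))
        return d_main + d_identity


class ResNet50Backbone(Layer):
    feature_dim = 2048

    def __init__(self, rng: np.random.Generator):
        self.stem = Sequential(
            Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng, grad_input=False),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, stride=2, pad=1),
        )
        inplanes = 64
        stages = []
        for planes, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
            blocks_list = [Bottleneck(inplanes, planes, stride, rng)]
            inplanes = planes * Bottleneck.expansion
            for _ in range(blocks - 1):
                blocks_list.append(Bottleneck(inplanes, planes, 1, rng))
            stages.append(Sequential(*blocks_list))
        self.stages = stages
        self.pool = GlobalAvgPool()

    def feature_map(self, x, train=False):
        """Output of the last bottleneck stage, before pooling (for CAM)."""
        y = self.stem(x, train)
        for stage in self.stages:
            y = stage(y, train)
        return y

    def forward(self, x, train=True):
        return self.pool(self.feature_map(x, train), train)

    def backward(self, dy):
        dy = self.pool.backward(dy)
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        return self.stem.backward(dy)


def resnet50(num_classes: int, rng: np.random.Generator):
    """Backbone + head pair for a task with ``num_classes`` logits."""
    backbone = ResNet50Backbone(rng)
    head = Linear(ResNet50Backbone.feature_dim, num_classes, rng=rng)
    return backbone, head
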