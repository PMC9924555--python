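"""Shallow CNN classifier for HER2 membrane-staining intensity.

A small convolutional network (two stride-2 convolution blocks, global
average pooling, one dense softmax layer) that takes a downscaled HER2
slide and labels its membrane staining as faint or intense. The
optical-density fallback in :mod:`ihcsubtype.scoring` needs no training and
is the default in the pipeline; this classifier is the learned alternative.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from . import nn

CLASSES = ("faint", "intense")
INPUT_SIZE = 64


def _prepare(image: np.ndarray) -> np.ndarray:
    im = Image.fromarray(np.asarray(image, dtype=np.uint8))
    im = im.resize((INPUT_SIZE, INPUT_SIZE), Image.BILINEAR)
    return np.asarray(im, dtype=np.float32) / 255.0


class IntensityClassifier(nn.Module):
    def __init__(self, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, 8, 3, stride=2, rng=rng, name="i.c1")
        self.bn1 = nn.BatchNorm(8, name="i.bn1")
        self.conv2 = nn.Conv2d(8, 16, 3, stride=2, rng=rng, name="i.c2")
        self.bn2 = nn.BatchNorm(16, name="i.bn2")
        self.fc = nn.Dense(16, len(CLASSES), rng=rng, name="i.fc")

    def _forward(self, batch: np.ndarray) -> nn.Tensor:
        h = self.bn1(nn.relu(self.conv1(nn.Tensor(batch))))
        h = self.bn2(nn.relu(self.conv2(h)))
        return nn.softmax(self.fc(nn.global_avg_pool(h)), axis=-1)

    def predict(self, image: np.ndarray) -> str:
        self.eval()
        probs = self._forward(_prepare(image)[None]).data[0]
        return CLASSES[int(np.argmax(probs))]


def train_intensity_classifier(
    images: list[np.ndarray],
    labels: list[str],
    epochs: int = 20,
    lr: float = 0.01,
    seed: int = 0,
) -> IntensityClassifier:
    """Fit the classifier on (image, faint/intense) pairs."""
    clf = IntensityClassifier(seed=seed)
    x = np.stack([_prepare(im) for im in images])
    y = np.array([CLASSES.index(l) for l in labels])
    onehot = np.eye(len(CLASSES), dtype=np.float32)[y]
    opt = nn.Adam(clf.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), 8):
            idx = order[start : start + 8]
            clf.train(True)
            probs = clf._forward(x[idx])
            p = np.clip(probs.data, 1e-7, 1.0)
            grad = (-onehot[idx] / p / len(idx)).astype(np.float32)
            opt.zero_grad()
            probs.backward(grad)
            opt.step()
    # population batch-norm statistics for stable inference
    nn.collect_batchnorm_stats(
        clf, clf._forward, [x[i : i + 8] for i in range(0, len(x), 8)]
    )
    clf.eval()
    return clf
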