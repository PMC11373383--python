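"""Classifier architectures.

The primary model family is a compact 1-D CNN over the 2 x W feature
matrix (DAF row + distance row): ``n_layers`` repetitions of
[Conv1d -> ReLU -> MaxPool(2, 2)] followed by a single dense layer to
two class logits.  The family is parameterized by a :class:`ModelSpec`
drawn from a small hyperparameter grid (layers x channels x kernel
width x stride) that an exhaustive architecture search enumerates; the
grid of 4 x 5 x 3 x 3 choices yields 180 candidates.

For controlled comparison, 2-D reference classifiers over the raw
N x W allele image are also provided, in three position-fusion
flavours: no positions, distances through a dense side branch
concatenated before the head ("late" fusion), and distances broadcast
as a second image channel ("early" fusion).
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn

#: default hyperparameter grid for the architecture search
DEFAULT_GRID: Dict[str, Sequence[int]] = {
    "n_layers": (2, 3, 4, 5),
    "channels": (8, 16, 32, 64, 80),
    "kernel_width": (2, 3, 4),
    "stride": (1, 2, 3),
}

#: the architecture the grid search selects on the old-migration data
BEST_SPEC_KWARGS = dict(n_layers=3, channels=80, kernel_width=2, stride=1)


class InfeasibleModelError(ValueError):
    """A spec whose conv/pool stages collapse the width below one SNP."""


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one 1-D conv/pool classifier."""

    n_layers: int
    channels: int
    kernel_width: int
    stride: int = 1
    input_channels: int = 2
    input_width: int = 128
    n_classes: int = 2

    def to_dict(self) -> Dict[str, int]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict[str, int]) -> "ModelSpec":
        return cls(**d)


def stage_widths(spec: ModelSpec) -> List[Tuple[int, int]]:
    """Width bookkeeping oracle: (post-conv, post-pool) width per stage.

    Convolutions use "same"-style padding (output ``ceil(w / stride)``);
    each pooling stage floors the width to half.  Raises
    :class:`InfeasibleModelError` at the first stage whose pooled width
    would fall below one.
    """
    w = spec.input_width
    out: List[Tuple[int, int]] = []
    for stage in range(spec.n_layers):
        w_conv = -(-w // spec.stride)
        w_pool = w_conv // 2
        if w_pool < 1:
            raise InfeasibleModelError(
                f"stage {stage}: width {w} -> conv {w_conv} -> pool {w_pool} < 1"
            )
        out.append((w_conv, w_pool))
        w = w_pool
    return out


def is_feasible(spec: ModelSpec) -> bool:
    try:
        stage_widths(spec)
        return True
    except InfeasibleModelError:
        return False


def flat_features(spec: ModelSpec) -> int:
    return spec.channels * stage_widths(spec)[-1][1]


def parameter_count(spec: ModelSpec) -> int:
    n = 0
    cin = spec.input_channels
    for _ in range(spec.n_layers):
        n += spec.channels * cin * spec.kernel_width + spec.channels
        cin = spec.channels
    n += spec.n_classes * flat_features(spec) + spec.n_classes
    return n


def enumerate_grid(
    space: Optional[Dict[str, Sequence[int]]] = None,
    input_width: int = 128,
) -> List[ModelSpec]:
    """Cartesian product of the grid in deterministic lexicographic order."""
    space = dict(DEFAULT_GRID if space is None else space)
    keys = ("n_layers", "channels", "kernel_width", "stride")
    for k in keys:
        if not space.get(k):
            raise ValueError(f"empty range for {k}")
    return [
        ModelSpec(
            n_layers=a, channels=b, kernel_width=c, stride=d, input_width=input_width
        )
        for a, b, c, d in itertools.product(*(space[k] for k in keys))
    ]


class Conv1dClassifier:
    """The 1-D conv/pool sweep classifier built from a :class:`ModelSpec`.

    Consumes ``(batch, 2, W)`` feature arrays; the input never depends
    on the sample size N, so neither does the model's cost or output.
    """

    kind = "conv1d"

    def __init__(self, spec: ModelSpec, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        stage_widths(spec)  # raises if infeasible
        self.spec = spec
        layers: List[nn.Layer] = []
        cin = spec.input_channels
        for _ in range(spec.n_layers):
            layers += [
                nn.Conv1d(cin, spec.channels, spec.kernel_width, spec.stride, rng=rng),
                nn.ReLU(),
                nn.MaxPool1d(),
            ]
            cin = spec.channels
        layers += [nn.Flatten(), nn.Linear(flat_features(spec), spec.n_classes, rng=rng)]
        self.net = nn.Sequential(layers)

    def parameters(self) -> List[nn.Parameter]:
        return self.net.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float64))

    def backward(self, grad: np.ndarray) -> None:
        self.net.backward(grad)

    def layer_output_widths(self, x: np.ndarray) -> List[Tuple[int, int]]:
        """Actual (post-conv, post-pool) widths observed on a forward pass."""
        widths: List[Tuple[int, int]] = []
        h = np.asarray(x, dtype=np.float64)
        it = iter(self.net.layers)
        for _ in range(self.spec.n_layers):
            conv, relu, pool = next(it), next(it), next(it)
            h = conv.forward(h)
            w_conv = h.shape[2]
            h = pool.forward(relu.forward(h))
            widths.append((w_conv, h.shape[2]))
        return widths

    # -- state round-tripping -------------------------------------------------
    def get_state(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
            p.value[...] = v

    def meta(self) -> Dict:
        return {"kind": self.kind, "spec": self.spec.to_dict()}


@dataclass(frozen=True)
class Fusion2DSpec:
    """Descriptor of a 2-D reference classifier over the raw allele image.

    ``fusion`` selects how inter-SNP distances enter the model:
    ``"none"`` (alleles only), ``"late_fc"`` (distances through a dense
    branch appended before the final layer) or ``"early_conv"``
    (distances broadcast across rows as a second input channel).  The
    convolutional trunk is shared across all three flavours; only the
    first convolution's input-channel count differs for early fusion.
    """

    fusion: str = "none"
    n_layers: int = 3
    channels: int = 32
    kernel: int = 3
    dist_hidden: int = 32
    n_classes: int = 2

    def __post_init__(self):
        if self.fusion not in ("none", "late_fc", "early_conv"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "Fusion2DSpec":
        return cls(**d)


class Fusion2DClassifier:
    """2-D conv/pool classifier over N x W allele images.

    Input is ``(batch, C, N, W)`` images (C = 2 for early fusion, else
    1) plus, for late fusion, the per-window ``(batch, W)`` distance
    vectors consumed by a dense side branch.
    """

    kind = "fusion2d"

    def __init__(
        self,
        spec: Fusion2DSpec,
        n_samples: int,
        width: int,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.n_samples = n_samples
        self.width = width
        cin = 2 if spec.fusion == "early_conv" else 1
        layers: List[nn.Layer] = []
        h, w = n_samples, width
        for _ in range(spec.n_layers):
            layers += [nn.Conv2d(cin, spec.channels, spec.kernel, rng=rng), nn.ReLU(), nn.MaxPool2d()]
            cin = spec.channels
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise InfeasibleModelError("image collapses below 1x1")
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(layers)
        trunk_features = spec.channels * h * w
        head_in = trunk_features
        if spec.fusion == "late_fc":
            self.dist_fc = nn.Linear(width, spec.dist_hidden, rng=rng)
            self.dist_relu = nn.ReLU()
            head_in += spec.dist_hidden
        else:
            self.dist_fc = None
            self.dist_relu = None
        self._trunk_features = trunk_features
        self.head = nn.Linear(head_in, spec.n_classes, rng=rng)

    def parameters(self) -> List[nn.Parameter]:
        out = self.trunk.parameters()
        if self.dist_fc is not None:
            out += self.dist_fc.parameters()
        out += self.head.parameters()
        return out

    def forward(self, x) -> np.ndarray:
        img, dist = x if isinstance(x, tuple) else (x, None)
        feats = self.trunk.forward(np.asarray(img, dtype=np.float64))
        if self.dist_fc is not None:
            if dist is None:
                raise ValueError("late fusion model needs the distance vectors")
            side = self.dist_relu.forward(
                self.dist_fc.forward(np.asarray(dist, dtype=np.float64))
            )
            feats = np.concatenate([feats, side], axis=1)
        return self.head.forward(feats)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        if self.dist_fc is not None:
            g_trunk = g[:, : self._trunk_features]
            g_side = g[:, self._trunk_features :]
            self.dist_fc.backward(self.dist_relu.backward(g_side))
        else:
            g_trunk = g
        self.trunk.backward(g_trunk)

    def get_state(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            p.value[...] = v

    def meta(self) -> Dict:
        return {
            "kind": self.kind,
            "spec": self.spec.to_dict(),
            "n_samples": self.n_samples,
            "width": self.width,
        }


def build_1d_model(
    spec: ModelSpec, seed: Optional[int] = None
) -> Conv1dClassifier:
    """Instantiate the 1-D classifier for a spec with seeded init."""
    return Conv1dClassifier(spec, rng=np.random.default_rng(seed))


def build_reference_2d(
    spec: Fusion2DSpec, n_samples: int, width: int, seed: Optional[int] = None
) -> Fusion2DClassifier:
    """Instantiate a 2-D reference classifier with seeded init."""
    return Fusion2DClassifier(spec, n_samples, width, rng=np.random.default_rng(seed))


def best_1d_spec(input_width: int = 128) -> ModelSpec:
    """The grid-search winner: 3 layers, 80 channels, kernel width 2."""
    return ModelSpec(input_width=input_width, **BEST_SPEC_KWARGS)


def model_from_meta(meta: Dict, seed: Optional[int] = None):
    """Rebuild an untrained model from checkpoint metadata."""
    if meta["kind"] == Conv1dClassifier.kind:
        return build_1d_model(ModelSpec.from_dict(meta["spec"]), seed=seed)
    if meta["kind"] == Fusion2DClassifier.kind:
        return build_reference_2d(
            Fusion2DSpec.from_dict(meta["spec"]),
            meta["n_samples"],
            meta["width"],
            seed=seed,
        )
    raise ValueError(f"unknown model kind {meta['kind']!r}")
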