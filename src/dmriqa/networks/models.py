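"""SQA-Net and VQA-Net: the slice and volume quality assessment networks."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..data_model import ProbTriple
from .blocks import CLFBlock, DSRBlock, NLDRBlock, NLRBlock
from .layers import BatchNorm, Layer, PointwiseConv

__all__ = ["NetSpec", "SQANet", "VQANet", "save_model", "load_model"]


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyper-parameters shared by both networks.

    ``channels`` are the output widths of the four down-sampling blocks
    (DSR, DSR, NLDR, NLDR); the NLR block preserves the last width and the
    classifier maps to 3 classes.  ``reduce_to`` is the per-slice channel
    width after the shared 1x1 reduction feeding VQA-Net.
    """

    input_size: int = 144
    channels: tuple = (32, 64, 128, 256)
    reduce_to: int = 16
    seed: int = 0

    @classmethod
    def full_scale(cls, seed: int = 0) -> "NetSpec":
        """Full-scale geometry: 144x144 inputs, widths 32/64/128/256/256/3."""
        return cls(input_size=144, channels=(32, 64, 128, 256), reduce_to=16, seed=seed)

    @classmethod
    def toy(cls, seed: int = 0) -> "NetSpec":
        """Desk-scale geometry for CPU runs: 64x64 inputs, widths / 4."""
        return cls(input_size=64, channels=(8, 16, 32, 64), reduce_to=8, seed=seed)

    @property
    def feature_size(self) -> int:
        """Spatial size of the NLR feature map (four 2x down-samplings)."""
        return self.input_size // 16


class SQANet(Layer):
    """Slice quality assessment network.

    DSR(c1) -> DSR(c2) -> NLDR(c3) -> NLDR(c4) -> NLR(c4) -> CLF(3).
    ``forward`` returns (class probabilities, NLR feature map); the feature
    map is the slice representation that VQA-Net agglomerates.
    """

    def __init__(self, spec: NetSpec) -> None:
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        c1, c2, c3, c4 = spec.channels
        self.blocks = [
            DSRBlock(1, c1, rng),
            DSRBlock(c1, c2, rng),
            NLDRBlock(c2, c3, rng),
            NLDRBlock(c3, c4, rng),
            NLRBlock(c4, rng),
        ]
        self.clf = CLFBlock(c4, rng)
        self.children = [*self.blocks, self.clf]

    def forward(self, x: np.ndarray, training: bool = False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        n, h, w, c = x.shape
        if (h, w, c) != (self.spec.input_size, self.spec.input_size, 1):
            raise ValueError(
                f"expected {self.spec.input_size}x{self.spec.input_size}x1 slices, got {h}x{w}x{c}"
            )
        for block in self.blocks:
            x = block.forward(x, training)
        probs = self.clf.forward(x, training)
        return probs, x

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.clf.backward_from_logits(dlogits)
        for block in reversed(self.blocks):
            dy = block.backward(dy)
        return dy

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = [self.forward(x[i : i + batch_size], training=False)[0]
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> list[ProbTriple]:
        return [ProbTriple(p) for p in self.predict_proba(x, batch_size)]


class VQANet(Layer):
    """Volume quality assessment network over agglomerated slice features.

    A shared 1x1 convolution reduces each slice's NLR feature map from c4 to
    ``reduce_to`` channels; the per-slice maps are concatenated along the
    channel axis (slice order preserved — the volume classifier is *not*
    slice-permutation invariant), then passed through an NLR block and a
    classifier head.  During training only VQA parameters receive gradients;
    the slice network stays frozen.
    """

    def __init__(self, spec: NetSpec, n_slices: int) -> None:
        super().__init__()
        if n_slices < 1:
            raise ValueError("a volume needs at least one slice")
        self.spec = spec
        self.n_slices = n_slices
        rng = np.random.default_rng(spec.seed + 1)
        c4 = spec.channels[-1]
        cc = spec.reduce_to * n_slices
        self.reduce = PointwiseConv(c4, spec.reduce_to, rng=rng)
        self.nlr = NLRBlock(cc, rng)
        self.clf = CLFBlock(cc, rng)
        self.children = [self.reduce, self.nlr, self.clf]

    def forward(self, feats: np.ndarray, training: bool = False) -> np.ndarray:
        """feats: (N, n_slices, h, w, c4) stacked slice feature maps."""
        feats = np.asarray(feats, dtype=np.float32)
        if feats.ndim != 5 or feats.shape[1] != self.n_slices:
            raise ValueError(
                f"expected (N, {self.n_slices}, h, w, c) feature stacks, got {feats.shape}"
            )
        n, ns, h, w, c4 = feats.shape
        red = self.reduce.forward(feats.reshape(n * ns, h, w, c4), training)
        self._red_shape = (n, ns, h, w, red.shape[-1])
        # concatenate slices along channels, slice-major order
        x = red.reshape(n, ns, h, w, -1).transpose(0, 2, 3, 1, 4).reshape(n, h, w, -1)
        x = self.nlr.forward(x, training)
        return self.clf.forward(x, training)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dy = self.clf.backward_from_logits(dlogits)
        dy = self.nlr.backward(dy)
        n, ns, h, w, r = self._red_shape
        dred = dy.reshape(n, h, w, ns, r).transpose(0, 3, 1, 2, 4).reshape(n * ns, h, w, r)
        self.reduce.backward(dred)  # slice features upstream stay frozen

    def predict_proba(self, feats: np.ndarray, batch_size: int = 8) -> np.ndarray:
        feats = np.asarray(feats, dtype=np.float32)
        out = [self.forward(feats[i : i + batch_size], training=False)
               for i in range(0, len(feats), batch_size)]
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz weight container + a JSON sidecar with the NetSpec
# ---------------------------------------------------------------------------

def _state_dict(model: Layer) -> dict[str, np.ndarray]:
    state = {}
    for i, layer in enumerate(model.walk()):
        for name, arr in layer.params.items():
            state[f"L{i}.{name}"] = arr
        if isinstance(layer, BatchNorm):
            state[f"L{i}.running_mean"] = layer.running_mean
            state[f"L{i}.running_var"] = layer.running_var
            state[f"L{i}.n_updates"] = np.array(layer.n_updates)
    return state


def save_model(model: "SQANet | VQANet", path: str | Path, extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **_state_dict(model))
    meta = {
        "kind": type(model).__name__,
        "spec": asdict(model.spec),
        "n_slices": getattr(model, "n_slices", None),
    }
    if extra:
        meta["provenance"] = extra
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=list))


def load_model(path: str | Path) -> "SQANet | VQANet":
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    spec = NetSpec(
        input_size=spec_d["input_size"],
        channels=tuple(spec_d["channels"]),
        reduce_to=spec_d["reduce_to"],
        seed=spec_d["seed"],
    )
    if meta["kind"] == "SQANet":
        model: SQANet | VQANet = SQANet(spec)
    elif meta["kind"] == "VQANet":
        model = VQANet(spec, n_slices=meta["n_slices"])
    else:
        raise ValueError(f"unknown model kind {meta['kind']!r}")
    with np.load(path.with_suffix(".npz")) as state:
        for i, layer in enumerate(model.walk()):
            for name in layer.params:
                layer.params[name] = state[f"L{i}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"L{i}.running_mean"].copy()
                layer.running_var = state[f"L{i}.running_var"].copy()
                layer.n_updates = int(state[f"L{i}.n_updates"])
    return model
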