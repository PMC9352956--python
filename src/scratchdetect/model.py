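"""Convolutional-recurrent scratching classifier.

The network maps a segment — a stack of ``seq_len`` binarized motion images —
to a single score in [0, 1].  A shared convolutional feature extractor (three
convolution + max-pool stages) is applied to every image of the stack; the
per-frame features feed two stacked LSTM layers; the recurrent readout feeds
five fully connected layers ending in a sigmoid scalar.  The 3/2/5 stage
skeleton is enforced; all widths are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = ["CRNNSpec", "CRNNModel", "build", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class CRNNSpec:
    """Architecture hyperparameters; defaults are the full-size network."""

    conv_channels: tuple[int, int, int] = (16, 32, 64)
    conv_kernel: int = 3
    pool: int = 2
    lstm_units: tuple[int, int] = (64, 64)
    fc_units: tuple[int, ...] = (256, 128, 64, 32, 1)
    input_size: int = 200
    seq_len: int = 21
    readout: str = "last"  # "last" hidden state or "mean" over time

    def __post_init__(self):
        if len(self.conv_channels) != 3:
            raise ValueError("exactly 3 convolution stages are required")
        if len(self.lstm_units) != 2:
            raise ValueError("exactly 2 recurrent stages are required")
        if len(self.fc_units) != 5 or self.fc_units[-1] != 1:
            raise ValueError("exactly 5 fully connected stages ending in width 1")
        if self.input_size <= 0 or self.input_size % self.pool ** 3:
            raise ValueError(
                f"input_size must be a positive multiple of {self.pool ** 3}")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.readout not in ("last", "mean"):
            raise ValueError("readout must be 'last' or 'mean'")

    @property
    def feature_dim(self) -> int:
        side = self.input_size // self.pool ** 3
        return self.conv_channels[-1] * side * side

    @classmethod
    def small(cls, seq_len: int = 21) -> "CRNNSpec":
        """CPU-speed preset used by tests and the packaged demo."""
        return cls(conv_channels=(8, 16, 32), lstm_units=(32, 32),
                   fc_units=(64, 32, 16, 8, 1), input_size=64, seq_len=seq_len)


class CRNNModel:
    """A built network: spec, parameters, epoch tag, and the init seed."""

    def __init__(self, spec: CRNNSpec, seed: int, dtype=np.float32,
                 epoch: int = 0):
        self.spec = spec
        self.rng_seed = int(seed)
        self.epoch = int(epoch)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.convs = []
        c_in = 1
        for idx, c_out in enumerate(spec.conv_channels):
            self.convs.append(nn.Conv2dSame(c_in, c_out, spec.conv_kernel,
                                            rng, dtype=dtype,
                                            need_dx=idx > 0))
            c_in = c_out
        self.pools = [nn.MaxPool2d(spec.pool) for _ in range(3)]
        self.relus = [nn.ReLU() for _ in range(3)]
        self.lstms = [
            nn.LSTM(spec.feature_dim, spec.lstm_units[0], rng, dtype=dtype),
            nn.LSTM(spec.lstm_units[0], spec.lstm_units[1], rng, dtype=dtype),
        ]
        self.fcs = []
        d_in = spec.lstm_units[1]
        for j, d_out in enumerate(spec.fc_units):
            last = j == len(spec.fc_units) - 1
            self.fcs.append(nn.Linear(d_in, d_out, rng, dtype=dtype,
                                      relu_gain=not last))
            d_in = d_out
        self.fc_relus = [nn.ReLU() for _ in range(len(spec.fc_units) - 1)]

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        out = []
        for j, c in enumerate(self.convs):
            out.append((f"conv{j}", c))
        for j, l in enumerate(self.lstms):
            out.append((f"lstm{j}", l))
        for j, f in enumerate(self.fcs):
            out.append((f"fc{j}", f))
        return out

    @property
    def params(self) -> dict[str, np.ndarray]:
        flat = {}
        for name, layer in self._layers():
            for pname, arr in layer.params().items():
                flat[f"{name}.{pname}"] = arr
        return flat

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        for name, layer in self._layers():
            for pname, arr in layer.params().items():
                arr[...] = flat[f"{name}.{pname}"]

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    # -- forward / backward ------------------------------------------------
    def _features(self, x: np.ndarray) -> np.ndarray:
        b, t, s, _ = x.shape
        h = x.reshape(b * t, s, s, 1).astype(self.dtype)  # NHWC
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        return h.reshape(b, t, -1)

    def logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass; x is (batch, seq_len, S, S) with values in {0, 1}."""
        spec = self.spec
        if x.ndim != 4 or x.shape[1] != spec.seq_len or \
                x.shape[2] != spec.input_size or x.shape[3] != spec.input_size:
            raise ValueError(
                f"expected (B, {spec.seq_len}, {spec.input_size}, "
                f"{spec.input_size}) stacks, got {x.shape}")
        feat = self._features(x)
        h = self.lstms[1].forward(self.lstms[0].forward(feat))
        self._t = h.shape[1]
        r = h[:, -1] if spec.readout == "last" else h.mean(axis=1)
        for fc, relu in zip(self.fcs[:-1], self.fc_relus):
            r = relu.forward(fc.forward(r))
        return self.fcs[-1].forward(r)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean BCE loss and the gradient dict for one batch."""
        with nn.single_thread_blas():
            return self._loss_and_grads(x, y)

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        z = self.logits(x)
        loss, dz = nn.bce_with_logits(z, y)
        grads = {}

        def collect(name, layer, d):
            dx, g = layer.backward(d)
            for pname, arr in g.items():
                grads[f"{name}.{pname}"] = arr
            return dx

        d = dz.reshape(-1, 1).astype(self.dtype)
        d = collect("fc4", self.fcs[-1], d)
        for j in range(len(self.fcs) - 2, -1, -1):
            d = self.fc_relus[j].backward(d)[0]
            d = collect(f"fc{j}", self.fcs[j], d)
        b, t = d.shape[0], self._t
        dh = np.zeros((b, t, self.spec.lstm_units[1]), dtype=self.dtype)
        if self.spec.readout == "last":
            dh[:, -1] = d
        else:
            dh[:] = d[:, None, :] / t
        d = collect("lstm1", self.lstms[1], dh)
        d = collect("lstm0", self.lstms[0], d)
        s = self.spec.input_size // self.spec.pool ** 3
        d = d.reshape(b * t, s, s, self.spec.conv_channels[-1])
        for j in range(2, -1, -1):
            d, _ = self.pools[j].backward(d)
            d, _ = self.relus[j].backward(d)
            d = collect(f"conv{j}", self.convs[j], d)
        return loss, grads

    # -- inference ---------------------------------------------------------
    def score(self, stacks: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid scores in [0, 1], one per segment stack."""
        stacks = np.asarray(stacks)
        if stacks.ndim == 3:
            stacks = stacks[None]
        out = np.empty(stacks.shape[0], dtype=np.float64)
        with nn.single_thread_blas():
            for i in range(0, stacks.shape[0], batch_size):
                z = self.logits(stacks[i:i + batch_size])
                out[i:i + batch_size] = nn.sigmoid(z.astype(np.float64)).ravel()
        return out


def build(spec: CRNNSpec, seed: int, dtype=np.float32) -> CRNNModel:
    """Construct a model with seed-reproducible initial parameters."""
    return CRNNModel(spec, seed, dtype=dtype)


def save_checkpoint(model: CRNNModel, path) -> None:
    meta = {"spec": asdict(model.spec), "epoch": model.epoch,
            "rng_seed": model.rng_seed}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path) -> CRNNModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        spec_d = meta["spec"]
        for k in ("conv_channels", "lstm_units", "fc_units"):
            spec_d[k] = tuple(spec_d[k])
        spec = CRNNSpec(**spec_d)
        model = CRNNModel(spec, meta["rng_seed"], epoch=meta["epoch"])
        model.set_params({k: z[k] for k in z.files if k != "__meta__"})
    return model
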