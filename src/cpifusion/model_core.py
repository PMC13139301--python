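"""The four-head local+global fusion regression network.

Architecture
------------
Two *local* heads read the label-encoded SMILES (length 100) and protein
sequence (length 1,000) through an embedding followed by a stack of 1-D
convolutions and a global max pool over sequence positions.  Two *global*
heads read the fingerprint+descriptor vectors through fully connected
layers.  The four head outputs are concatenated — 1,216 dimensions under
the default widths 96/96/512/512 — and passed through a fully connected
fusion stack with dropout to a single scalar affinity prediction.

The network, backpropagation and the Adam optimizer are implemented
directly on NumPy (float32).  Padding positions are masked out of the
convolutions and the max pool, which makes the local heads exactly
invariant to trailing zero padding and lets batches be trimmed to their
longest real sequence without changing any output.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

FUSION_WIDTH = 1216  # printed architecture constant: sum of the four head widths


class ConfigError(ValueError):
    pass


class ShapeError(ValueError):
    pass


class ModelLoadError(Exception):
    pass


@dataclass
class ModelConfig:
    """Full architecture hyper-parameterization.

    The four head output widths must sum to 1,216 (the concatenated
    representation width) unless ``nonstandard=True`` explicitly waives the
    constraint.  The last convolution filter count of each local head must
    equal that head's output width (the global max pool preserves channel
    count).
    """

    compound_vocab_size: int = 64
    protein_vocab_size: int = 21
    embedding_dim: int = 128
    compound_conv_filters: tuple = (32, 64, 96)
    compound_kernel_sizes: tuple = (4, 6, 8)
    protein_conv_filters: tuple = (32, 64, 96)
    protein_kernel_sizes: tuple = (4, 8, 12)
    compound_local_out: int = 96
    protein_local_out: int = 96
    compound_global_out: int = 512
    protein_global_out: int = 512
    compound_global_in: int = 1024 + 20
    protein_global_in: int = 567
    fusion_hidden: tuple = (1024, 512)
    dropout: float = 0.1
    random_seed: int = 0
    nonstandard: bool = False

    def __post_init__(self):
        self.compound_conv_filters = tuple(self.compound_conv_filters)
        self.compound_kernel_sizes = tuple(self.compound_kernel_sizes)
        self.protein_conv_filters = tuple(self.protein_conv_filters)
        self.protein_kernel_sizes = tuple(self.protein_kernel_sizes)
        self.fusion_hidden = tuple(self.fusion_hidden)
        self.validate()

    @property
    def concat_width(self) -> int:
        return (
            self.compound_local_out
            + self.protein_local_out
            + self.compound_global_out
            + self.protein_global_out
        )

    def validate(self) -> None:
        widths = (
            self.compound_local_out,
            self.protein_local_out,
            self.compound_global_out,
            self.protein_global_out,
            self.compound_global_in,
            self.protein_global_in,
            self.embedding_dim,
            *self.compound_conv_filters,
            *self.protein_conv_filters,
            *self.fusion_hidden,
        )
        if any(w <= 0 for w in widths):
            raise ConfigError("all layer widths must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if len(self.compound_conv_filters) != len(self.compound_kernel_sizes):
            raise ConfigError("compound filters and kernel sizes differ in length")
        if len(self.protein_conv_filters) != len(self.protein_kernel_sizes):
            raise ConfigError("protein filters and kernel sizes differ in length")
        if self.compound_conv_filters[-1] != self.compound_local_out:
            raise ConfigError(
                "last compound conv filter count must equal compound_local_out"
            )
        if self.protein_conv_filters[-1] != self.protein_local_out:
            raise ConfigError(
                "last protein conv filter count must equal protein_local_out"
            )
        if not self.nonstandard and self.concat_width != FUSION_WIDTH:
            raise ConfigError(
                f"head widths sum to {self.concat_width}, expected {FUSION_WIDTH}; "
                "pass nonstandard=True to override"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class FeatureBatch:
    """One prediction batch: aligned rows across the four feature blocks."""

    compound_tokens: np.ndarray  # (B, 100) int
    compound_global: np.ndarray  # (B, Gc) float
    protein_tokens: np.ndarray  # (B, 1000) int
    protein_global: np.ndarray  # (B, Gp) float

    def __post_init__(self):
        n = {a.shape[0] for a in (
            self.compound_tokens, self.compound_global,
            self.protein_tokens, self.protein_global)}
        if len(n) != 1:
            raise ShapeError(f"feature blocks disagree on batch size: {sorted(n)}")

    def __len__(self) -> int:
        return self.compound_tokens.shape[0]

    def take(self, idx) -> "FeatureBatch":
        return FeatureBatch(
            self.compound_tokens[idx],
            self.compound_global[idx],
            self.protein_tokens[idx],
            self.protein_global[idx],
        )


# --------------------------------------------------------------------------
# layers (float32, explicit forward/backward)
# --------------------------------------------------------------------------

def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _Embedding:
    """Token embedding with the padding row (index 0) frozen at zero."""

    def __init__(self, rng, n_tokens: int, dim: int, name: str):
        self.name = name
        scale = 1.0 / np.sqrt(dim)
        self.W = rng.uniform(-scale, scale, size=(n_tokens + 1, dim)).astype(np.float32)
        self.W[0] = 0.0

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.W[ids]

    def backward(self, dout: np.ndarray) -> None:
        self.dW = np.zeros_like(self.W)
        np.add.at(self.dW, self._ids.ravel(), dout.reshape(-1, dout.shape[-1]))
        self.dW[0] = 0.0  # padding embedding stays zero

    def params(self):
        yield f"{self.name}.W", self

    def get(self):
        return self.W

    def set(self, v):
        self.W = v.astype(np.float32)
        self.W[0] = 0.0

    def grad(self):
        return self.dW


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int, name: str):
        self.name = name
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        yield f"{self.name}.W", _P(self, "W", "dW")
        yield f"{self.name}.b", _P(self, "b", "db")


class _P:
    """Adapter exposing one named array of a layer as a parameter slot."""

    def __init__(self, layer, attr, gattr):
        self.layer, self.attr, self.gattr = layer, attr, gattr

    def get(self):
        return getattr(self.layer, self.attr)

    def set(self, v):
        setattr(self.layer, self.attr, v.astype(np.float32))

    def grad(self):
        return getattr(self.layer, self.gattr)


class _Conv1D:
    """Valid 1-D convolution after right zero-padding by (kernel-1).

    Output length equals input length; positions at or beyond a row's valid
    length are zeroed by the caller, so padded and trimmed batches produce
    identical activations at every valid position.
    """

    def __init__(self, rng, n_in: int, n_out: int, kernel: int, name: str):
        self.name = name
        self.kernel = kernel
        self.W = _glorot(rng, (kernel * n_in, n_out), kernel * n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        xp = np.concatenate(
            [x, np.zeros((B, k - 1, C), dtype=x.dtype)], axis=1
        )
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(B * L, k * C)
        self._cols = cols
        self._in_shape = (B, L, C)
        return (cols @ self.W + self.b).reshape(B, L, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        k = self.kernel
        d2 = dout.reshape(B * L, -1)
        self.dW = self._cols.T @ d2
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + k - 1, C), dtype=np.float32)
        for j in range(k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, :L, :]

    def params(self):
        yield f"{self.name}.W", _P(self, "W", "dW")
        yield f"{self.name}.b", _P(self, "b", "db")


class _LocalHead:
    """Embedding -> stacked masked convolutions (ReLU) -> masked global max pool."""

    def __init__(self, rng, vocab_size, cfg_filters, cfg_kernels, embedding_dim, name):
        self.name = name
        self.embedding = _Embedding(rng, vocab_size, embedding_dim, f"{name}.embedding")
        self.convs = []
        n_in = embedding_dim
        for i, (n_out, k) in enumerate(zip(cfg_filters, cfg_kernels)):
            self.convs.append(_Conv1D(rng, n_in, n_out, k, f"{name}.conv{i}"))
            n_in = n_out
        self.out_width = n_in

    def forward(self, ids: np.ndarray) -> np.ndarray:
        nz = ids != 0
        last = ids.shape[1] - np.argmax(nz[:, ::-1], axis=1)  # index after last real token
        lengths = np.where(nz.any(axis=1), last, 1)
        trim = int(lengths.max())
        ids = ids[:, :trim]
        B, L = ids.shape
        mask = (np.arange(L)[None, :] < lengths[:, None]).astype(np.float32)[:, :, None]
        self._mask = mask
        x = self.embedding.forward(ids)
        self._relu_masks = []
        for conv in self.convs:
            x = conv.forward(x)
            rm = (x > 0).astype(np.float32) * mask
            self._relu_masks.append(rm)
            x = x * rm
        neg = np.where(mask > 0, 0.0, -np.inf).astype(np.float32)
        self._argmax = np.argmax(x + neg, axis=1)  # (B, C)
        self._L = L
        out = np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]
        return out

    def backward(self, dout: np.ndarray) -> None:
        B, C = dout.shape
        dx = np.zeros((B, self._L, C), dtype=np.float32)
        np.put_along_axis(dx, self._argmax[:, None, :], dout[:, None, :], axis=1)
        for conv, rm in zip(reversed(self.convs), reversed(self._relu_masks)):
            dx = conv.backward(dx * rm)
        self.embedding.backward(dx * self._mask)

    def params(self):
        yield from self.embedding.params()
        for conv in self.convs:
            yield from conv.params()


class _GlobalHead:
    """Fully connected stack with ReLU producing the head's output width."""

    def __init__(self, rng, n_in: int, n_out: int, name: str):
        self.name = name
        self.n_in = n_in
        self.dense = _Dense(rng, n_in, n_out, f"{name}.dense")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.n_in:
            raise ShapeError(
                f"{self.name}: expected input width {self.n_in}, got {x.shape[1]}"
            )
        h = self.dense.forward(x.astype(np.float32))
        self._rm = (h > 0).astype(np.float32)
        return h * self._rm

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.dense.backward(dout * self._rm)

    def params(self):
        yield from self.dense.params()


class _FusionNet:
    """Concatenated representation -> hidden dense stack with dropout -> scalar."""

    def __init__(self, rng, n_in: int, hidden: tuple, dropout: float, name: str):
        self.name = name
        self.dropout = dropout
        self.layers = []
        for i, h in enumerate(hidden):
            self.layers.append(_Dense(rng, n_in, h, f"{name}.dense{i}"))
            n_in = h
        self.out = _Dense(rng, n_in, 1, f"{name}.out")

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        self._rms, self._dms = [], []
        for layer in self.layers:
            x = layer.forward(x)
            rm = (x > 0).astype(np.float32)
            x = x * rm
            self._rms.append(rm)
            if train and self.dropout > 0:
                dm = (rng.random(x.shape) >= self.dropout).astype(np.float32) / (
                    1.0 - self.dropout
                )
                x = x * dm
                self._dms.append(dm)
            else:
                self._dms.append(None)
        return self.out.forward(x)[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.out.backward(dout[:, None])
        for layer, rm, dm in zip(
            reversed(self.layers), reversed(self._rms), reversed(self._dms)
        ):
            if dm is not None:
                dx = dx * dm
            dx = layer.backward(dx * rm)
        return dx

    def params(self):
        for layer in self.layers:
            yield from layer.params()
        yield from self.out.params()


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class FusionRegressor:
    """Learnable state of the four-head network (weights + config).

    Feature preparation (vocabulary, postprocessors) lives in the training
    pipeline; a :class:`~cpifusion.train_eval.CPIFeaturizer` can be attached
    as ``featurizer`` and is serialized with the model.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.featurizer = None  # optional, attached by the pipeline
        rng = np.random.default_rng(config.random_seed)
        self.compound_local = _LocalHead(
            rng, config.compound_vocab_size, config.compound_conv_filters,
            config.compound_kernel_sizes, config.embedding_dim, "compound_local",
        )
        self.protein_local = _LocalHead(
            rng, config.protein_vocab_size, config.protein_conv_filters,
            config.protein_kernel_sizes, config.embedding_dim, "protein_local",
        )
        self.compound_global = _GlobalHead(
            rng, config.compound_global_in, config.compound_global_out, "compound_global"
        )
        self.protein_global = _GlobalHead(
            rng, config.protein_global_in, config.protein_global_out, "protein_global"
        )
        concat = self.config.concat_width
        assert concat == (
            self.compound_local.out_width + self.protein_local.out_width
            + config.compound_global_out + config.protein_global_out
        )
        self.fusion = _FusionNet(rng, concat, config.fusion_hidden, config.dropout, "fusion")
        self._splits = np.cumsum([
            config.compound_local_out, config.protein_local_out, config.compound_global_out,
        ])

    # -- parameter access ------------------------------------------------
    def named_parameters(self):
        for part in (
            self.compound_local, self.protein_local,
            self.compound_global, self.protein_global, self.fusion,
        ):
            yield from part.params()

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: slot.get().copy() for name, slot in self.named_parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, slot in self.named_parameters():
            if name not in weights:
                raise ModelLoadError(f"missing weight {name!r}")
            if weights[name].shape != slot.get().shape:
                raise ModelLoadError(
                    f"shape mismatch for {name!r}: checkpoint {weights[name].shape}, "
                    f"model {slot.get().shape}"
                )
            slot.set(weights[name])

    # -- forward / backward ---------------------------------------------
    def forward(self, batch: FeatureBatch, train: bool = False, rng=None) -> np.ndarray:
        h = np.concatenate(
            [
                self.compound_local.forward(batch.compound_tokens),
                self.protein_local.forward(batch.protein_tokens),
                self.compound_global.forward(batch.compound_global),
                self.protein_global.forward(batch.protein_global),
            ],
            axis=1,
        )
        assert h.shape[1] == self.config.concat_width
        self._concat = h
        return self.fusion.forward(h, train=train, rng=rng)

    def backward(self, dout: np.ndarray) -> None:
        dh = self.fusion.backward(dout)
        d_cl, d_pl, d_cg, d_pg = np.split(dh, self._splits, axis=1)
        self.compound_local.backward(d_cl)
        self.protein_local.backward(d_pl)
        self.compound_global.backward(d_cg)
        self.protein_global.backward(d_pg)

    def predict(self, batch: FeatureBatch, batch_size: int = 512) -> np.ndarray:
        """Inference forward pass (dropout off), in mini-batches."""
        outs = []
        for start in range(0, len(batch), batch_size):
            outs.append(self.forward(batch.take(slice(start, start + batch_size))))
        return np.concatenate(outs) if outs else np.empty(0, dtype=np.float32)

    def copy(self) -> "FusionRegressor":
        clone = FusionRegressor(self.config)
        clone.set_weights(self.get_weights())
        clone.featurizer = self.featurizer
        return clone


def build_model(config: ModelConfig) -> FusionRegressor:
    """Construct the four-head network with seeded weight initialization."""
    return FusionRegressor(config)


# --------------------------------------------------------------------------
# serialization: a zip of .npy arrays plus a JSON header (config, featurizer)
# --------------------------------------------------------------------------

def save_model(model: FusionRegressor, path) -> None:
    header = {"format": "cpifusion-checkpoint-v1", "config": model.config.to_dict()}
    if model.featurizer is not None:
        header["featurizer"] = model.featurizer.to_dict()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header))
        for name, slot in model.named_parameters():
            buf = io.BytesIO()
            np.save(buf, slot.get())
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_model(path) -> FusionRegressor:
    from .train_eval import CPIFeaturizer

    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("format") != "cpifusion-checkpoint-v1":
                raise ModelLoadError(f"unrecognized checkpoint format in {path}")
            config = ModelConfig.from_dict(header["config"])
            model = FusionRegressor(config)
            weights = {}
            for name, _ in model.named_parameters():
                arc = f"weights/{name}.npy"
                if arc not in zf.namelist():
                    raise ModelLoadError(f"checkpoint missing weight {name!r}")
                weights[name] = np.load(io.BytesIO(zf.read(arc)))
            model.set_weights(weights)
            if "featurizer" in header:
                model.featurizer = CPIFeaturizer.from_dict(header["featurizer"])
            return model
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"cannot read checkpoint {path}: {exc}") from exc
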