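"""Compact residual U-net reconstruction generator built from conv banks.

The generator maps a 2-channel (real/imaginary) zero-filled image to a
2-channel de-aliased image through a chainable encoder–decoder with
additive skip connections and a global residual skip (output = input +
correction). Every learnable layer is a plain :class:`ConvFilterBank`,
so scale-and-shift (SS) blocks can be inserted plug-and-play into any
layer and folded back out for deployment.

The network, its forward pass, and its gradients are implemented
directly in NumPy: at the problem sizes this package targets the layers
are small, and a self-contained implementation gives bitwise CPU
reproducibility of training runs, which the transfer-strategy contracts
rely on.

Architecture (per chain, depth ``d``, base channels ``C``):
head conv (in -> C); ``d`` encoder levels of [conv, strided conv x2
channels]; bottleneck conv; ``d`` decoder levels of [nearest upsample,
conv halving channels, add encoder skip, conv]; zero-initialized tail
conv (C -> out) feeding the global residual sum. All hidden
activations are leaky ReLU (slope 0.2); the tail is linear.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ShapeError, StateError
from .ssconv import (
    ConvFilterBank,
    RowFactors,
    SSFactors,
    Strategy,
    conv2d,
    conv2d_backward,
    count_trainable,
    fold_row,
    fold_ss,
)

__all__ = [
    "NetworkSpec",
    "ConvUnit",
    "ReconNetwork",
    "build_generator",
    "insert_ss",
    "fold_network",
    "save_checkpoint",
    "load_checkpoint",
]

_LRELU_SLOPE = 0.2


@dataclass
class NetworkSpec:
    """Hyperparameters of the reconstruction generator."""

    depth: int = 2
    base_channels: int = 8
    chain_length: int = 1
    in_channels: int = 2
    use_adversarial: bool = False

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if self.chain_length not in (1, 2):
            raise ConfigurationError("chain_length must be 1 or 2")
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        if self.use_adversarial:
            raise NotImplementedError(
                "adversarial training is not provided; the generator is "
                "trained with pixelwise losses"
            )


class ConvUnit:
    """One conv layer: bank, optional SS factors, stride, activation."""

    def __init__(self, bank: ConvFilterBank, stride: int = 1, activation: str = "lrelu"):
        if stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        if activation not in ("lrelu", "linear"):
            raise ConfigurationError("activation must be 'lrelu' or 'linear'")
        self.bank = bank
        self.factors: SSFactors | RowFactors | None = None
        self.stride = stride
        self.activation = activation
        self._cache = None
        self.grads: dict[str, np.ndarray] = {}

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.bank.weights.shape

    @property
    def last_preactivation(self) -> np.ndarray:
        """Pre-activation output of the last recorded forward pass."""
        if self._cache is None:
            raise StateError("no recorded forward pass")
        return self._cache[1]

    def effective(self) -> ConvFilterBank:
        """Bank with any SS factors folded in (identity if none)."""
        if self.factors is None:
            return self.bank
        if isinstance(self.factors, SSFactors):
            return fold_ss(self.bank, self.factors)
        return fold_row(self.bank, self.factors)

    def forward(self, x: np.ndarray, record: bool = False) -> np.ndarray:
        eff = self.effective()
        pre = conv2d(x, eff.weights, eff.bias, stride=self.stride)
        if self.activation == "lrelu":
            out = np.where(pre >= 0, pre, _LRELU_SLOPE * pre)
        else:
            out = pre
        if record:
            self._cache = (x, pre, eff.weights)
        return out

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        """Backprop through activation and conv; populates ``self.grads``.

        Gradients are taken w.r.t. the *effective* weights/bias and then
        chained into whichever parameters own them: the bank itself, or
        the SS factors when present (the frozen-backbone path).
        """
        if self._cache is None:
            raise StateError("backward called without a recorded forward pass")
        x, pre, eff_w = self._cache
        if self.activation == "lrelu":
            d_pre = d_out * np.where(pre >= 0, 1.0, _LRELU_SLOPE)
        else:
            d_pre = d_out
        d_weff, d_beff, d_x = conv2d_backward(d_pre, x, eff_w, stride=self.stride)
        g: dict[str, np.ndarray] = {}
        if self.factors is None:
            g["weights"] = d_weff
            g["bias"] = d_beff
        elif isinstance(self.factors, SSFactors):
            # d eff_w[n,m] = scale[n,m] * W[n,m]; d eff_b[n] = b[n] + sum_m shift
            g["scale"] = np.einsum("nmij,nmij->nm", d_weff, self.bank.weights)
            g["shift"] = np.repeat(d_beff[:, None], self.bank.n_channels, axis=1)
        else:
            g["row_scale"] = np.einsum("nmij,nmij->nmi", d_weff, self.bank.weights)
            g["shift"] = np.repeat(d_beff[:, None], self.bank.n_channels, axis=1)
        self.grads = g
        self._cache = None
        return d_x


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=-2).repeat(2, axis=-1)


def _upsample2_backward(d: np.ndarray) -> np.ndarray:
    h, w = d.shape[-2], d.shape[-1]
    return d.reshape(*d.shape[:-2], h // 2, 2, w // 2, 2).sum(axis=(-3, -1))


@dataclass
class _Chain:
    head: ConvUnit
    enc: list  # [(conv, down), ...] shallow -> deep
    bottleneck: ConvUnit
    dec: list  # [(upconv, conv), ...] deep -> shallow
    tail: ConvUnit

    def units(self) -> list[ConvUnit]:
        out = [self.head]
        for conv, down in self.enc:
            out += [conv, down]
        out.append(self.bottleneck)
        for upconv, conv in self.dec:
            out += [upconv, conv]
        out.append(self.tail)
        return out


class ReconNetwork:
    """Residual U-net generator composed of :class:`ConvUnit` layers."""

    def __init__(self, spec: NetworkSpec, chains: list[_Chain]):
        self.spec = spec
        self.chains = chains

    # -- structure ---------------------------------------------------------

    @property
    def layers(self) -> list[ConvUnit]:
        out: list[ConvUnit] = []
        for chain in self.chains:
            out.extend(chain.units())
        return out

    @property
    def has_ss(self) -> bool:
        return any(u.factors is not None for u in self.layers)

    def layer_shapes(self) -> list[tuple[int, int, int, int]]:
        return [u.shape for u in self.layers]

    def trainable_count(self, strategy: Strategy | str) -> int:
        return count_trainable(strategy, self.layer_shapes())

    # -- forward / backward ------------------------------------------------

    @property
    def dtype(self) -> np.dtype:
        return self.layers[0].bank.weights.dtype

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim not in (3, 4) or x.shape[-3] != self.spec.in_channels:
            raise ShapeError(
                f"expected ({self.spec.in_channels}, H, W) input "
                f"(optionally batched), got {x.shape}"
            )
        div = 2**self.spec.depth
        if x.shape[-2] % div or x.shape[-1] % div:
            raise ShapeError(
                f"spatial dims {x.shape[-2:]} must be divisible by {div}; "
                f"pad to the next multiple of {div}"
            )
        return x

    def forward(self, x: np.ndarray, record: bool = False) -> np.ndarray:
        x = self._check_input(x)
        h = x
        for chain in self.chains:
            h = self._chain_forward(chain, h, record)
        if record and not np.all(np.isfinite(h)):
            raise FloatingPointError("non-finite activations in forward pass")
        return h

    def _chain_forward(self, chain: _Chain, x: np.ndarray, record: bool) -> np.ndarray:
        h = chain.head.forward(x, record)
        skips = []
        for conv, down in chain.enc:
            h = conv.forward(h, record)
            skips.append(h)
            h = down.forward(h, record)
        h = chain.bottleneck.forward(h, record)
        for (upconv, conv), skip in zip(chain.dec, reversed(skips)):
            h = _upsample2(h)
            h = upconv.forward(h, record)
            h = h + skip
            h = conv.forward(h, record)
        corr = chain.tail.forward(h, record)
        return x + corr

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        """Backprop a recorded forward pass; returns gradient w.r.t. input.

        Per-layer parameter gradients land in each unit's ``grads``.
        """
        d = np.asarray(d_out, dtype=np.float64)
        for chain in reversed(self.chains):
            d = self._chain_backward(chain, d)
        return d

    def _chain_backward(self, chain: _Chain, d_out: np.ndarray) -> np.ndarray:
        d_input_residual = d_out  # global skip
        d = chain.tail.backward(d_out)
        d_skips = []  # gradients for encoder skip tensors, deep -> shallow
        for upconv, conv in reversed(chain.dec):
            d = conv.backward(d)
            d_skips.append(d)  # the additive skip passes d through unchanged
            d = upconv.backward(d)
            d = _upsample2_backward(d)
        d = chain.bottleneck.backward(d)
        d_skips.reverse()  # collected shallow->deep; reversed(enc) is deep->shallow
        for (conv, down), d_skip in zip(reversed(chain.enc), d_skips):
            d = down.backward(d)
            d = d + d_skip
            d = conv.backward(d)
        d = chain.head.backward(d)
        return d_input_residual + d

    # -- state -------------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        """Flat copy of all backbone weights/biases (and factors if present)."""
        state = {}
        for i, u in enumerate(self.layers):
            state[f"layer{i:02d}/weights"] = u.bank.weights.copy()
            state[f"layer{i:02d}/bias"] = u.bank.bias.copy()
            if isinstance(u.factors, SSFactors):
                state[f"layer{i:02d}/ss/scale"] = u.factors.scale.copy()
                state[f"layer{i:02d}/ss/shift"] = u.factors.shift.copy()
            elif isinstance(u.factors, RowFactors):
                state[f"layer{i:02d}/ss/row_scale"] = u.factors.row_scale.copy()
                state[f"layer{i:02d}/ss/shift"] = u.factors.shift.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray], backbone_only: bool = False) -> None:
        """Load a state dict; factor entries are applied when present.

        With ``backbone_only`` the factor entries in ``state`` are
        ignored (used when warm-starting an SS net from a plain
        pretrained checkpoint).
        """
        for i, u in enumerate(self.layers):
            w = state[f"layer{i:02d}/weights"]
            b = state[f"layer{i:02d}/bias"]
            if w.shape != u.bank.weights.shape:
                raise ShapeError(
                    f"checkpoint layer {i} shape {w.shape} does not match "
                    f"network {u.bank.weights.shape}"
                )
            u.bank.weights[...] = w
            u.bank.bias[...] = b
            if backbone_only:
                continue
            if f"layer{i:02d}/ss/scale" in state and isinstance(u.factors, SSFactors):
                u.factors.scale[...] = state[f"layer{i:02d}/ss/scale"]
                u.factors.shift[...] = state[f"layer{i:02d}/ss/shift"]
            if f"layer{i:02d}/ss/row_scale" in state and isinstance(u.factors, RowFactors):
                u.factors.row_scale[...] = state[f"layer{i:02d}/ss/row_scale"]
                u.factors.shift[...] = state[f"layer{i:02d}/ss/shift"]

    def backbone_hashes(self) -> list[str]:
        """SHA-256 of every backbone tensor, for frozen-weight audits."""
        out = []
        for u in self.layers:
            out.append(hashlib.sha256(u.bank.weights.tobytes()).hexdigest())
            out.append(hashlib.sha256(u.bank.bias.tobytes()).hexdigest())
        return out


def _he_bank(rng, n, m, k, dtype, zero: bool = False) -> ConvFilterBank:
    if zero:
        w = np.zeros((n, m, k, k))
    else:
        std = np.sqrt(2.0 / (m * k * k))
        w = rng.normal(0.0, std, size=(n, m, k, k))
    return ConvFilterBank(w.astype(dtype), np.zeros(n, dtype=dtype))


def build_generator(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> ReconNetwork:
    """Construct and deterministically initialize a generator.

    He-normal weight init, zero biases, and a zero-initialized tail so
    the fresh network is the identity on its input (pure residual
    start): the untrained reconstruction equals the zero-filled input.
    Single precision by default; pass ``dtype=np.float64`` for the
    tight-tolerance double path.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x55C0]))
    dtype = np.dtype(dtype)
    k = 3
    chains = []
    for _ in range(spec.chain_length):
        c = spec.base_channels
        head = ConvUnit(_he_bank(rng, c, spec.in_channels, k, dtype))
        enc = []
        for _level in range(spec.depth):
            conv = ConvUnit(_he_bank(rng, c, c, k, dtype))
            down = ConvUnit(_he_bank(rng, 2 * c, c, k, dtype), stride=2)
            enc.append((conv, down))
            c *= 2
        bottleneck = ConvUnit(_he_bank(rng, c, c, k, dtype))
        dec = []
        for _level in range(spec.depth):
            upconv = ConvUnit(_he_bank(rng, c // 2, c, k, dtype))
            conv = ConvUnit(_he_bank(rng, c // 2, c // 2, k, dtype))
            dec.append((upconv, conv))
            c //= 2
        tail = ConvUnit(_he_bank(rng, spec.in_channels, c, k, dtype, zero=True),
                        activation="linear")
        chains.append(_Chain(head, enc, bottleneck, dec, tail))
    return ReconNetwork(spec, chains)


def insert_ss(net: ReconNetwork, granularity: str = "kernel") -> ReconNetwork:
    """Attach identity-initialized SS factors to every conv layer in place.

    Identity initialization (scale 1, shift 0) guarantees the network
    output is unchanged, so transfer training starts exactly from the
    pretrained model's behavior.
    """
    if granularity not in ("kernel", "row"):
        raise ConfigurationError("granularity must be 'kernel' or 'row'")
    if net.has_ss:
        raise StateError("SS blocks already inserted")
    for u in net.layers:
        n, m, kh, _ = u.shape
        dt = u.bank.weights.dtype
        if granularity == "kernel":
            u.factors = SSFactors(np.ones((n, m), dt), np.zeros((n, m), dt))
        else:
            u.factors = RowFactors(
                np.ones((n, m, kh), dt), np.zeros((n, m), dt)
            )
    return net


def fold_network(net: ReconNetwork) -> ReconNetwork:
    """Equivalent plain network with every layer's SS factors folded in."""
    folded = build_generator(net.spec, seed=0, dtype=net.dtype)
    for src, dst in zip(net.layers, folded.layers):
        eff = src.effective()
        dst.bank.weights[...] = eff.weights
        dst.bank.bias[...] = eff.bias
    return folded


def save_checkpoint(path, net: ReconNetwork) -> None:
    """HDF5 checkpoint (bank layout of :mod:`ssmri.ssconv`) + JSON descriptor."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["architecture"] = json.dumps(
            {
                "depth": net.spec.depth,
                "base_channels": net.spec.base_channels,
                "chain_length": net.spec.chain_length,
                "in_channels": net.spec.in_channels,
            }
        )
        for key, arr in net.get_state().items():
            fh.create_dataset(key, data=arr)
        fh.attrs["layout"] = "NMHW"


def load_checkpoint(path) -> ReconNetwork:
    import h5py

    with h5py.File(path, "r") as fh:
        arch = json.loads(fh.attrs["architecture"])
        state = {}

        def _collect(name, obj):
            if isinstance(obj, h5py.Dataset):
                state[name] = obj[...]

        fh.visititems(_collect)
    net = build_generator(NetworkSpec(**arch), seed=0)
    if any("/ss/" in k for k in state):
        granularity = "row" if any(k.endswith("row_scale") for k in state) else "kernel"
        insert_ss(net, granularity)
    net.set_state(state)
    return net
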