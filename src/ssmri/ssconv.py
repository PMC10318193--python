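"""Scale-and-shift convolution primitives.

A convolution layer applies ``N`` filters to an ``M``-channel input. Each
filter holds ``M`` kernels; the per-kernel responses are the *basic
features*, and their per-filter sum is the *advanced feature* map. Linear
fine-tuning (LFT) freezes the pretrained kernel weights ``W`` and bias
``b`` and trains one multiplicative scale and one additive shift per
(filter, input-channel) kernel. Because a scalar commutes with
convolution, the factors can be *folded* back into the weights to obtain
an equivalent plain bank, so a trained SS network deploys with zero
overhead.

Conventions: convolution is cross-correlation (no kernel flip) with zero
"same" padding and stride 1 unless stated; kernels must be odd-sized.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidKernelError,
    ShapeError,
)

__all__ = [
    "Strategy",
    "ConvFilterBank",
    "SSFactors",
    "RowFactors",
    "conv2d",
    "conv2d_backward",
    "basic_features",
    "advanced_features",
    "ss_forward",
    "rft_forward",
    "fold_ss",
    "fold_row",
    "count_trainable",
    "save_bank",
    "load_bank",
]


class Strategy(str, enum.Enum):
    """The five training regimes compared in transfer experiments.

    PT  -- pretrained model applied directly to the target domain.
    DT  -- trained from scratch on the target data only.
    FT  -- classic fine-tuning: all weights update.
    RFT -- row fine-tuning: one scale per kernel row.
    LFT -- linear fine-tuning: one scale and one shift per kernel.
    """

    PT = "pt"
    DT = "dt"
    FT = "ft"
    RFT = "rft"
    LFT = "lft"


def _as_float(arr) -> np.ndarray:
    """Coerce to a floating array, preserving float32; float64 otherwise."""
    arr = np.asarray(arr)
    if arr.dtype == np.float32:
        return arr
    return arr.astype(np.float64, copy=False)


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")


def _check_feature_tensor(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ShapeError(
            f"feature tensor must be 3D (channels, height, width), got shape {x.shape}"
        )
    if min(x.shape) < 1:
        raise ShapeError("feature tensor dimensions must all be >= 1")
    _check_finite(x, "feature tensor")
    return x


@dataclass
class ConvFilterBank:
    """Weights and biases of one convolution layer.

    Parameters
    ----------
    weights
        Real array of shape ``(N, M, k_h, k_w)``: N filters, each with M
        odd-sized kernels.
    bias
        Real vector of length ``N``, one bias per filter. Per-kernel
        shifts are aggregated additively into this per-filter bias when
        SS factors are folded.
    """

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _as_float(self.weights)
        self.bias = np.asarray(self.bias, dtype=self.weights.dtype)
        if self.weights.ndim != 4:
            raise ShapeError(
                f"weights must be 4D (N, M, k_h, k_w), got shape {self.weights.shape}"
            )
        n, _, kh, kw = self.weights.shape
        if kh % 2 == 0 or kw % 2 == 0 or kh < 1 or kw < 1:
            raise InvalidKernelError(
                f"kernel size ({kh}, {kw}) must be odd and >= 1"
            )
        if self.bias.shape != (n,):
            raise ShapeError(
                f"bias must have shape ({n},), got {self.bias.shape}"
            )
        _check_finite(self.weights, "weights")
        _check_finite(self.bias, "bias")

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel_size(self) -> tuple[int, int]:
        return self.weights.shape[2], self.weights.shape[3]

    def copy(self) -> "ConvFilterBank":
        return ConvFilterBank(self.weights.copy(), self.bias.copy())


@dataclass
class SSFactors:
    """Per-kernel scale and shift factors, the only trainable state under LFT.

    Identity state (``scale == 1``, ``shift == 0``) leaves the owning
    bank's output unchanged.
    """

    scale: np.ndarray  # (N, M)
    shift: np.ndarray  # (N, M)

    def __post_init__(self) -> None:
        self.scale = _as_float(self.scale)
        self.shift = np.asarray(self.shift, dtype=self.scale.dtype)
        if self.scale.ndim != 2 or self.shift.shape != self.scale.shape:
            raise ShapeError(
                "scale and shift must be 2D arrays of identical (N, M) shape"
            )
        _check_finite(self.scale, "scale")
        _check_finite(self.shift, "shift")

    @classmethod
    def identity(cls, n_filters: int, n_channels: int) -> "SSFactors":
        return cls(
            np.ones((n_filters, n_channels)), np.zeros((n_filters, n_channels))
        )

    def copy(self) -> "SSFactors":
        return SSFactors(self.scale.copy(), self.shift.copy())


@dataclass
class RowFactors:
    """Row-granular factors: one scale per kernel row, one shift per kernel.

    The row variant interpolates between full fine-tuning (one factor per
    weight) and LFT (one factor per kernel). Whether the shift belongs in
    the row regime is an open choice; it is included by default so RFT
    strictly generalizes LFT, and can be disabled at the trainer level.
    """

    row_scale: np.ndarray  # (N, M, k_h)
    shift: np.ndarray  # (N, M)

    def __post_init__(self) -> None:
        self.row_scale = _as_float(self.row_scale)
        self.shift = np.asarray(self.shift, dtype=self.row_scale.dtype)
        if self.row_scale.ndim != 3:
            raise ShapeError("row_scale must be 3D (N, M, k_h)")
        if self.shift.shape != self.row_scale.shape[:2]:
            raise ShapeError("shift shape must match row_scale's leading (N, M)")
        _check_finite(self.row_scale, "row_scale")
        _check_finite(self.shift, "shift")

    @classmethod
    def identity(cls, n_filters: int, n_channels: int, k_h: int) -> "RowFactors":
        return cls(
            np.ones((n_filters, n_channels, k_h)),
            np.zeros((n_filters, n_channels)),
        )

    def copy(self) -> "RowFactors":
        return RowFactors(self.row_scale.copy(), self.shift.copy())


def _check_factors(bank: ConvFilterBank, factors) -> None:
    n, m = bank.n_filters, bank.n_channels
    if isinstance(factors, SSFactors):
        if factors.scale.shape != (n, m):
            raise ConfigurationError(
                f"factor shape {factors.scale.shape} does not match bank ({n}, {m})"
            )
    elif isinstance(factors, RowFactors):
        kh = bank.kernel_size[0]
        if factors.row_scale.shape != (n, m, kh):
            raise ConfigurationError(
                f"row factor shape {factors.row_scale.shape} does not match "
                f"bank ({n}, {m}, {kh})"
            )
    else:
        raise ConfigurationError(f"unsupported factor type {type(factors)!r}")


# ---------------------------------------------------------------------------
# Convolution core (cross-correlation, zero "same" padding)
# ---------------------------------------------------------------------------

def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Multi-channel 2D cross-correlation with zero "same" padding.

    Parameters
    ----------
    x
        Input of shape ``(M, H, W)``, or ``(B, M, H, W)`` for a batch.
    weights
        Kernel stack of shape ``(N, M, k_h, k_w)``, odd kernel dims.
    bias
        Optional per-filter bias, shape ``(N,)``.
    stride
        Output subsampling step (1 or 2).

    Returns
    -------
    Output of shape ``(N, ceil(H/stride), ceil(W/stride))`` (a leading
    batch axis is preserved when present).
    """
    x = np.asarray(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ShapeError(
            f"input must be (M, H, W) or (B, M, H, W), got shape {x.shape}"
        )
    if min(x.shape) < 1:
        raise ShapeError("input dimensions must all be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite entries")
    weights = np.asarray(weights)
    if weights.ndim != 4:
        raise ShapeError("weights must be 4D (N, M, k_h, k_w)")
    n, m, kh, kw = weights.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise InvalidKernelError(f"kernel size ({kh}, {kw}) must be odd")
    if x.shape[1] != m:
        raise ShapeError(
            f"input has {x.shape[1]} channels but weights expect {m}"
        )
    h, w = x.shape[2], x.shape[3]
    xp = _pad_same(x, kh, kw)
    out_h = -(-h // stride)
    out_w = -(-w // stride)
    b = x.shape[0]
    y = np.zeros((b, n, out_h * out_w), dtype=np.result_type(x, weights))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + h : stride, j : j + w : stride]
            y += weights[:, :, i, j] @ patch.reshape(b, m, -1)
    y = y.reshape(b, n, out_h, out_w)
    if bias is not None:
        y += np.asarray(bias)[:, None, None]
    return y[0] if squeeze else y


def conv2d_backward(
    d_out: np.ndarray,
    x: np.ndarray,
    weights: np.ndarray,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv2d` w.r.t. weights, bias, and input.

    ``d_out`` is the upstream gradient with the output's shape. Returns
    ``(d_weights, d_bias, d_x)``; weight/bias gradients are summed over
    any leading batch axis, ``d_x`` matches the input's shape.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
        d_out = d_out[None]
    n, m, kh, kw = weights.shape
    b = x.shape[0]
    h, w = x.shape[2], x.shape[3]
    xp = _pad_same(x, kh, kw)
    oh, ow = d_out.shape[2], d_out.shape[3]
    d_flat = np.ascontiguousarray(d_out.reshape(b, n, -1))
    d_xp = np.zeros_like(xp)
    d_w = np.zeros_like(weights)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + h : stride, j : j + w : stride]
            d_w[:, :, i, j] = (
                d_flat @ patch.reshape(b, m, -1).transpose(0, 2, 1)
            ).sum(axis=0)
            d_xp[:, :, i : i + h : stride, j : j + w : stride] += (
                weights[:, :, i, j].T @ d_flat
            ).reshape(b, m, oh, ow)
    d_b = d_out.sum(axis=(0, 2, 3))
    ph, pw = kh // 2, kw // 2
    d_x = d_xp[:, :, ph : ph + h, pw : pw + w]
    if squeeze:
        d_x = d_x[0]
    return d_w, d_b, d_x


# ---------------------------------------------------------------------------
# Basic / advanced feature decomposition
# ---------------------------------------------------------------------------

def basic_features(
    input_channel: np.ndarray,
    kernel_weights: np.ndarray,
    kernel_bias: float,
) -> np.ndarray:
    """Response of a single kernel on a single input channel.

    Cross-correlates one 2D channel with one odd-sized kernel (zero
    "same" padding, stride 1) and adds the scalar kernel bias.
    """
    input_channel = np.asarray(input_channel)
    kernel_weights = np.asarray(kernel_weights)
    if input_channel.ndim != 2:
        raise ShapeError("input channel must be 2D")
    if kernel_weights.ndim != 2:
        raise InvalidKernelError("kernel must be a 2D array")
    if not np.isfinite(kernel_bias):
        raise ValueError("kernel bias must be finite")
    out = conv2d(
        input_channel[None],
        kernel_weights[None, None],
        np.asarray([float(kernel_bias)]),
    )
    return out[0]


def advanced_features(
    x: np.ndarray, bank: ConvFilterBank, filter_index: int
) -> np.ndarray:
    """Feature map of one filter: the sum of its per-kernel basic features.

    The per-filter bias is distributed equally over the filter's M
    kernels so that the decomposition holds exactly, term by term, in
    the same summation order as an explicit per-kernel loop.
    """
    x = _check_feature_tensor(x)
    if x.shape[0] != bank.n_channels:
        raise ShapeError(
            f"input has {x.shape[0]} channels, bank expects {bank.n_channels}"
        )
    if not 0 <= filter_index < bank.n_filters:
        raise IndexError(f"filter index {filter_index} out of range")
    m = bank.n_channels
    per_kernel_bias = bank.bias[filter_index] / m
    out = basic_features(x[0], bank.weights[filter_index, 0], per_kernel_bias)
    for ch in range(1, m):
        out = out + basic_features(
            x[ch], bank.weights[filter_index, ch], per_kernel_bias
        )
    return out


# ---------------------------------------------------------------------------
# SS forward paths and folding
# ---------------------------------------------------------------------------

def _per_kernel_maps(x: np.ndarray, bank: ConvFilterBank) -> np.ndarray:
    """All (filter, kernel) response maps, shape (N, M, H, W), no bias."""
    n, m, kh, kw = bank.weights.shape
    h, w = x.shape[1], x.shape[2]
    xp = _pad_same(x[None], kh, kw)[0]
    maps = np.zeros((n, m, h, w))
    for i in range(kh):
        for j in range(kw):
            maps += (
                bank.weights[:, :, i, j, None, None]
                * xp[None, :, i : i + h, j : j + w]
            )
    return maps


def ss_forward(
    x: np.ndarray, bank: ConvFilterBank, factors: SSFactors
) -> np.ndarray:
    """SSConv forward pass: scaled per-kernel responses plus shifted bias.

    Channel ``n`` of the output is
    ``sum_m scale[n,m] * (x[m] (*) W[n,m]) + b[n] + sum_m shift[n,m]``.
    Computed by scaling the per-kernel response maps directly — a
    different arithmetic route from folding the factors into the weights,
    with which it agrees to numerical tolerance.
    """
    x = _check_feature_tensor(x)
    _check_factors(bank, factors)
    if not isinstance(factors, SSFactors):
        raise ConfigurationError("ss_forward requires SSFactors")
    if x.shape[0] != bank.n_channels:
        raise ShapeError(
            f"input has {x.shape[0]} channels, bank expects {bank.n_channels}"
        )
    maps = _per_kernel_maps(x, bank)
    y = np.einsum("nm,nmhw->nhw", factors.scale, maps)
    y += (bank.bias + factors.shift.sum(axis=1))[:, None, None]
    return y


def rft_forward(
    x: np.ndarray, bank: ConvFilterBank, factors: RowFactors
) -> np.ndarray:
    """Row-granular SS forward: each kernel row r scaled by its own factor."""
    x = _check_feature_tensor(x)
    _check_factors(bank, factors)
    if not isinstance(factors, RowFactors):
        raise ConfigurationError("rft_forward requires RowFactors")
    folded = fold_row(bank, factors)
    return conv2d(x, folded.weights, folded.bias)


def fold_ss(bank: ConvFilterBank, factors: SSFactors) -> ConvFilterBank:
    """Absorb per-kernel scale/shift factors into an equivalent plain bank.

    Returned weights are ``scale[n,m] * W[n,m]`` elementwise; the
    returned bias is ``b[n] + sum_m shift[n,m]``. Inputs are unmodified.
    """
    _check_factors(bank, factors)
    if not isinstance(factors, SSFactors):
        raise ConfigurationError("fold_ss requires SSFactors")
    weights = factors.scale[:, :, None, None] * bank.weights
    bias = bank.bias + factors.shift.sum(axis=1)
    return ConvFilterBank(weights, bias)


def fold_row(bank: ConvFilterBank, factors: RowFactors) -> ConvFilterBank:
    """Absorb row-granular factors into an equivalent plain bank."""
    _check_factors(bank, factors)
    if not isinstance(factors, RowFactors):
        raise ConfigurationError("fold_row requires RowFactors")
    weights = factors.row_scale[:, :, :, None] * bank.weights
    bias = bank.bias + factors.shift.sum(axis=1)
    return ConvFilterBank(weights, bias)


def count_trainable(
    strategy: Strategy | str,
    layer_shapes: Sequence[tuple[int, int, int, int]],
) -> int:
    """Number of trainable parameters per strategy over a stack of layers.

    ``layer_shapes`` is a list of ``(N, M, k_h, k_w)`` tuples. PT trains
    nothing; DT and FT train every weight and bias; LFT trains two
    factors per kernel; RFT trains ``k_h`` row scales plus one shift per
    kernel.
    """
    try:
        strategy = Strategy(strategy)
    except ValueError as exc:
        raise ConfigurationError(f"unknown strategy {strategy!r}") from exc
    total = 0
    for n, m, kh, kw in layer_shapes:
        if min(n, m, kh, kw) < 1:
            raise ConfigurationError(f"invalid layer shape {(n, m, kh, kw)}")
        if strategy is Strategy.PT:
            total += 0
        elif strategy in (Strategy.DT, Strategy.FT):
            total += n * (m * kh * kw + 1)
        elif strategy is Strategy.LFT:
            total += 2 * n * m
        elif strategy is Strategy.RFT:
            total += n * m * (kh + 1)
    return total


# ---------------------------------------------------------------------------
# Serialization (portable HDF5 layout)
# ---------------------------------------------------------------------------

def save_bank(group, bank: ConvFilterBank, factors=None) -> None:
    """Write a bank (and optional factors) into an h5py group or file.

    Layout: datasets ``weights`` and ``bias``; factors under ``ss/scale``
    and ``ss/shift`` (plus ``ss/row_scale`` for row factors); attribute
    ``layout="NMHW"``.
    """
    group.attrs["layout"] = "NMHW"
    group.create_dataset("weights", data=bank.weights)
    group.create_dataset("bias", data=bank.bias)
    if factors is not None:
        ss = group.create_group("ss")
        if isinstance(factors, SSFactors):
            ss.create_dataset("scale", data=factors.scale)
        elif isinstance(factors, RowFactors):
            ss.create_dataset("row_scale", data=factors.row_scale)
        else:
            raise ConfigurationError(f"unsupported factor type {type(factors)!r}")
        ss.create_dataset("shift", data=factors.shift)


def load_bank(group):
    """Inverse of :func:`save_bank`. Returns ``(bank, factors_or_None)``."""
    bank = ConvFilterBank(group["weights"][...], group["bias"][...])
    factors = None
    if "ss" in group:
        ss = group["ss"]
        if "scale" in ss:
            factors = SSFactors(ss["scale"][...], ss["shift"][...])
        else:
            factors = RowFactors(ss["row_scale"][...], ss["shift"][...])
    return bank, factors
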