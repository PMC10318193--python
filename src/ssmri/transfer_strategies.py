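"""The five transfer regimes and their training protocol.

Strategies
----------
PT   evaluate the pretrained source model on target data, no training.
DT   train from random initialization on the target data only.
FT   warm-start from the pretrained checkpoint; every weight updates.
RFT  warm-start; only per-row scale factors (and per-kernel shifts)
     update, the backbone is bitwise frozen.
LFT  warm-start; only per-kernel scale/shift factors update, the
     backbone is bitwise frozen.

Protocol: Adam (initial learning rate 1e-4 for pretraining, strategy-
dependent for transfer), early stopping when validation PSNR has not
strictly improved for ``patience`` epochs (default 15), best-checkpoint
selection by validation PSNR, and a deterministic 16:5:4
train/val/test split. All randomness flows from one seed, and training
is bitwise reproducible on CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ShapeError, StateError
from .kspace_sim import SamplingMask, from_kspace, to_kspace, undersample
from .metrics import psnr
from .recon_net import ReconNetwork, build_generator
from .ssconv import RowFactors, SSFactors, Strategy

__all__ = [
    "Strategy",
    "StrategyConfig",
    "SplitSpec",
    "EpochRecord",
    "TrainingHistory",
    "Sample",
    "make_samples",
    "split_dataset",
    "early_stop_check",
    "evaluate_psnr",
    "pretrain",
    "transfer",
]

_DEFAULT_TRANSFER_LR = {
    Strategy.FT: 1e-5,
    Strategy.DT: 1e-4,
    Strategy.LFT: 1e-4,
    Strategy.RFT: 1e-4,
}


@dataclass
class StrategyConfig:
    strategy: Strategy | str = Strategy.FT
    learning_rate: float | None = None  # None -> per-strategy default
    max_epochs: int = 50
    patience: int = 15
    batch_size: int = 4
    seed: int = 0
    loss: str = "l1"  # l1 | l2 | l1+dc
    dc_weight: float = 0.1

    def __post_init__(self) -> None:
        self.strategy = Strategy(self.strategy)
        if self.learning_rate is None:
            self.learning_rate = _DEFAULT_TRANSFER_LR.get(self.strategy, 1e-4)
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.max_epochs < 0:
            raise ConfigurationError("max_epochs must be >= 0")
        if self.loss not in ("l1", "l2", "l1+dc"):
            raise ConfigurationError("loss must be 'l1', 'l2' or 'l1+dc'")


@dataclass
class SplitSpec:
    ratio: tuple[int, int, int] = (16, 5, 4)
    train_subset_size: int | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratio):
            raise ConfigurationError("ratio parts must be positive")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_psnr: float


@dataclass
class TrainingHistory:
    """Per-epoch log of one training run.

    ``initial_val_psnr`` is measured before the first optimization step
    (epoch 0); ``best_epoch`` tracks the strictly best validation PSNR
    over trained epochs (>= 1), with ties resolved to the earlier epoch.
    """

    records: list[EpochRecord] = field(default_factory=list)
    initial_val_psnr: float = float("nan")
    best_epoch: int = 0
    best_val_psnr: float = -np.inf
    stopped_epoch: int = 0

    def val_psnrs(self) -> list[float]:
        return [r.val_psnr for r in self.records]

    def log_lines(self) -> list[str]:
        """Per-epoch 'epoch, loss, val_psnr, best_epoch' lines."""
        out = []
        best = -np.inf
        best_epoch = 0
        for r in self.records:
            if r.val_psnr > best:
                best, best_epoch = r.val_psnr, r.epoch
            out.append(
                f"epoch {r.epoch}, loss {r.train_loss:.6f}, "
                f"val_psnr {r.val_psnr:.4f}, best_epoch {best_epoch}"
            )
        return out

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_psnr,best_epoch\n")
            best = -np.inf
            best_epoch = 0
            for r in self.records:
                if r.val_psnr > best:
                    best, best_epoch = r.val_psnr, r.epoch
                fh.write(f"{r.epoch},{r.train_loss},{r.val_psnr},{best_epoch}\n")


def split_dataset(images: list, spec: SplitSpec, seed: int):
    """Deterministic disjoint train/val/test partition in ratio proportions.

    Sizes follow largest-remainder rounding of the ratio; the optional
    training subset is drawn from the train portion only.
    """
    n = len(images)
    total = sum(spec.ratio)
    if n < total:
        raise ValueError(
            f"need at least {total} images for ratio {spec.ratio}, got {n}"
        )
    exact = [n * r / total for r in spec.ratio]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n - sum(sizes)]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = order[: sizes[0]]
    val_idx = order[sizes[0] : sizes[0] + sizes[1]]
    test_idx = order[sizes[0] + sizes[1] :]
    train = [images[i] for i in train_idx]
    if spec.train_subset_size is not None:
        if spec.train_subset_size > len(train):
            raise ValueError(
                f"subset size {spec.train_subset_size} exceeds train size {len(train)}"
            )
        train = train[: spec.train_subset_size]
    return train, [images[i] for i in val_idx], [images[i] for i in test_idx]


def early_stop_check(history: TrainingHistory, patience: int) -> bool:
    """True when validation PSNR has not strictly improved for ``patience`` epochs."""
    if not history.records:
        raise ValueError("history is empty")
    current = history.records[-1].epoch
    return (current - history.best_epoch) >= patience


# ---------------------------------------------------------------------------
# Samples and losses
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    """One training example: ZF network input and its ground-truth slice."""

    zf: np.ndarray  # (2, H, W) real/imag zero-filled image
    target: np.ndarray  # (H, W) magnitude ground truth in [0, 1]
    k_under: np.ndarray  # (H, W) complex undersampled k-space
    mask_rows: np.ndarray  # (H,) binary


def make_samples(images, mask: SamplingMask) -> list[Sample]:
    """Apply the undersampling forward model to ground-truth slices.

    ``images`` may be 2D arrays or objects with an ``image`` attribute
    (e.g. :class:`~ssmri.phantom_gen.LabeledSlice`).
    """
    samples = []
    for im in images:
        arr = np.asarray(getattr(im, "image", im), dtype=np.float64)
        if arr.ndim != 2:
            raise ShapeError("each image must be 2D")
        k = to_kspace(arr)
        ku = undersample(k, mask)
        zf_complex = from_kspace(ku)
        zf = np.stack([zf_complex.real, zf_complex.imag]).astype(np.float32)
        samples.append(
            Sample(
                zf=zf,
                target=arr.astype(np.float32),
                k_under=ku,
                mask_rows=mask.rows.copy(),
            )
        )
    return samples


_MAG_EPS = 1e-12
_FFT_AXES = (-2, -1)


def _magnitude(pred: np.ndarray) -> np.ndarray:
    """Magnitude of a 2-channel complex-as-real image; batched or not."""
    re = pred[..., 0, :, :]
    im = pred[..., 1, :, :]
    return np.sqrt(re**2 + im**2 + _MAG_EPS)


def _loss_and_grad(pred: np.ndarray, samples: list[Sample], kind: str, dc_weight: float):
    """Mean pixelwise loss on magnitude images and its gradient w.r.t. pred.

    ``pred`` is a batch ``(B, 2, H, W)`` aligned with ``samples``.
    'l1+dc' adds a k-space data-consistency penalty: the mean squared
    deviation of the prediction's k-space from the measured values on
    the sampled rows (the FFT is unitary, so the gradient maps back by
    the inverse transform).
    """
    target = np.stack([s.target for s in samples])
    mag = _magnitude(pred)
    diff = mag - target
    n = diff.size
    if kind.startswith("l1"):
        loss = float(np.abs(diff).mean())
        d_mag = np.sign(diff) / n
    else:
        loss = float((diff**2).mean())
        d_mag = 2.0 * diff / n
    d_pred = d_mag[:, None] * pred / mag[:, None]
    if kind == "l1+dc":
        pred_complex = pred[:, 0] + 1j * pred[:, 1]
        k_pred = to_kspace_complex(pred_complex)
        k_meas = np.stack([s.k_under for s in samples])
        rows = np.stack([s.mask_rows for s in samples])[:, :, None]
        resid = (k_pred - k_meas) * rows
        loss += dc_weight * float(np.mean(np.abs(resid) ** 2))
        g_complex = from_kspace_complex(resid) * (
            2.0 * dc_weight / resid[0].size / len(samples)
        )
        d_pred = d_pred + np.stack([g_complex.real, g_complex.imag], axis=1)
    return loss, d_pred


def to_kspace_complex(image: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(image, axes=_FFT_AXES), norm="ortho"),
        axes=_FFT_AXES,
    )


def from_kspace_complex(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=_FFT_AXES), norm="ortho"),
        axes=_FFT_AXES,
    )


# ---------------------------------------------------------------------------
# Parameter selection and optimizer
# ---------------------------------------------------------------------------

def _select_params(net: ReconNetwork, strategy: Strategy):
    """(array, grad_key, unit) triples the strategy is allowed to update."""
    params = []
    for u in net.layers:
        if strategy in (Strategy.DT, Strategy.FT):
            if u.factors is not None:
                raise StateError(f"{strategy.value} expects a plain network")
            params.append((u.bank.weights, "weights", u))
            params.append((u.bank.bias, "bias", u))
        elif strategy is Strategy.LFT:
            if not isinstance(u.factors, SSFactors):
                raise StateError("LFT requires kernel-granular SS blocks")
            params.append((u.factors.scale, "scale", u))
            params.append((u.factors.shift, "shift", u))
        elif strategy is Strategy.RFT:
            if not isinstance(u.factors, RowFactors):
                raise StateError("RFT requires row-granular SS blocks")
            params.append((u.factors.row_scale, "row_scale", u))
            params.append((u.factors.shift, "shift", u))
    return params


class Adam:
    """Plain Adam with bias correction; updates parameter arrays in place."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _, _ in params]
        self.v = [np.zeros_like(p) for p, _, _ in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, ((p, _, _), g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def evaluate_psnr(net: ReconNetwork, samples: list[Sample]) -> float:
    """Mean PSNR of the network's magnitude reconstructions over a set."""
    if not samples:
        raise ValueError("empty evaluation set")
    recon = _magnitude(net.forward(np.stack([s.zf for s in samples])))
    vals = [
        psnr(s.target, r, data_range=1.0) for s, r in zip(samples, recon)
    ]
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("inf")


def _train(
    net: ReconNetwork,
    strategy: Strategy,
    train_samples: list[Sample],
    val_samples: list[Sample],
    config: StrategyConfig,
) -> TrainingHistory:
    """Shared epoch loop with early stopping and best-checkpoint restore."""
    if not train_samples:
        raise ValueError("empty training set")
    params = _select_params(net, strategy)
    opt = Adam(params, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7A41]))

    history = TrainingHistory()
    history.initial_val_psnr = evaluate_psnr(net, val_samples)
    best_state = net.get_state()

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            pred = net.forward(np.stack([s.zf for s in batch]), record=True)
            loss, d_pred = _loss_and_grad(pred, batch, config.loss, config.dc_weight)
            net.backward(d_pred)
            epoch_loss += loss
            n_batches += 1
            opt.step([unit.grads[key] for _, key, unit in params])
        epoch_loss /= n_batches
        val = evaluate_psnr(net, val_samples)
        history.records.append(EpochRecord(epoch, epoch_loss, val))
        if val > history.best_val_psnr:  # strict improvement only
            history.best_val_psnr = val
            history.best_epoch = epoch
            best_state = net.get_state()
        history.stopped_epoch = epoch
        if early_stop_check(history, config.patience):
            break

    if history.records:
        net.set_state(best_state)
    else:
        history.best_val_psnr = history.initial_val_psnr
    return history


def pretrain(
    net: ReconNetwork,
    source_samples: list[Sample],
    val_samples: list[Sample],
    config: StrategyConfig,
) -> tuple[ReconNetwork, TrainingHistory]:
    """Train all weights from random init on the source domain.

    Returns the network restored to its best-validation-PSNR state,
    together with the full epoch history.
    """
    if net.has_ss:
        raise StateError("pretraining expects a plain network without SS blocks")
    if not source_samples:
        raise ValueError("empty source dataset")
    cfg = dataclasses.replace(config, strategy=Strategy.DT)
    history = _train(net, Strategy.DT, source_samples, val_samples, cfg)
    return net, history


def transfer(
    net: ReconNetwork,
    checkpoint: dict[str, np.ndarray],
    train_samples: list[Sample],
    val_samples: list[Sample],
    config: StrategyConfig,
) -> tuple[ReconNetwork, TrainingHistory]:
    """Run one transfer strategy against a pretrained checkpoint.

    Contracts: PT performs zero steps; DT re-initializes from
    ``config.seed`` and ignores the checkpoint weights; FT warm-starts
    and trains everything; LFT/RFT warm-start and update only their SS
    factors, leaving the backbone bitwise identical to the checkpoint.
    For LFT/RFT the caller must have inserted identity-initialized SS
    blocks (:func:`ssmri.recon_net.insert_ss`).
    """
    strategy = Strategy(config.strategy)
    if strategy in (Strategy.LFT, Strategy.RFT) and not net.has_ss:
        raise StateError(f"{strategy.value} requires SS blocks; call insert_ss first")
    if strategy in (Strategy.PT, Strategy.FT, Strategy.LFT, Strategy.RFT):
        net.set_state(checkpoint, backbone_only=True)
    if strategy is Strategy.PT:
        history = TrainingHistory()
        history.initial_val_psnr = evaluate_psnr(net, val_samples)
        history.best_val_psnr = history.initial_val_psnr
        return net, history
    if strategy is Strategy.DT:
        fresh = build_generator(net.spec, seed=config.seed)
        history = _train(fresh, Strategy.DT, train_samples, val_samples, config)
        return fresh, history
    history = _train(net, strategy, train_samples, val_samples, config)
    return net, history
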