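"""Retrospective Cartesian k-space undersampling.

The forward model of accelerated 2D MRI at desk scale: a magnitude
image is mapped to k-space by a centered orthonormal 2D DFT, a binary
row mask keeps a fraction of phase-encode lines (denser near the
center, where most image energy lives), and the zero-filled (ZF)
reconstruction is the magnitude of the inverse transform with the
missing rows left at zero. ZF is the aliased baseline every learned
reconstruction is compared against.

Masks are variable-density: a contiguous low-frequency band around the
DC row is always kept, and the remaining rows are drawn without
replacement with probability proportional to a Gaussian profile
centered on DC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "SamplingMask",
    "generate_cartesian_mask",
    "to_kspace",
    "from_kspace",
    "undersample",
    "zero_filled_recon",
]


@dataclass
class SamplingMask:
    """Binary phase-encode row selection pattern.

    ``rows[i] == 1`` means k-space row ``i`` is acquired. The number of
    ones equals ``round(rate * height)`` and the center band is always
    fully sampled.
    """

    rows: np.ndarray
    rate: float
    center_fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.uint8)
        if self.rows.ndim != 1:
            raise ShapeError("mask rows must be a 1D vector")
        if not 0 < self.rate <= 1:
            raise ConfigurationError("rate must be in (0, 1]")

    @property
    def height(self) -> int:
        return self.rows.shape[0]

    @property
    def n_sampled(self) -> int:
        return int(self.rows.sum())

    def to_text(self) -> str:
        return "".join(str(int(v)) for v in self.rows)

    @classmethod
    def from_text(cls, text: str, rate: float, center_fraction: float, seed: int):
        rows = np.array([int(c) for c in text.strip()], dtype=np.uint8)
        return cls(rows, rate, center_fraction, seed)

    def save(self, path) -> None:
        """Write the mask to an HDF5 container with its parameters."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("rows", data=self.rows)
            fh.attrs["rate"] = self.rate
            fh.attrs["center_fraction"] = self.center_fraction
            fh.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "SamplingMask":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                fh["rows"][...],
                float(fh.attrs["rate"]),
                float(fh.attrs["center_fraction"]),
                int(fh.attrs["seed"]),
            )


def _center_band(height: int, center_fraction: float) -> tuple[int, int]:
    """Inclusive-exclusive row range of the always-sampled center band.

    The band holds ``round(center_fraction * height)`` rows centered on
    the DC row ``height // 2`` (extra row placed above DC when odd).
    """
    n_center = int(round(center_fraction * height))
    dc = height // 2
    lo = dc - n_center // 2
    return lo, lo + n_center


def generate_cartesian_mask(
    height: int,
    rate: float,
    center_fraction: float = 0.08,
    sigma_fraction: float = 1.0 / 6.0,
    seed: int = 0,
) -> SamplingMask:
    """Draw a variable-density 1D Cartesian row mask.

    Exactly ``round(rate * height)`` rows are selected: the center band
    deterministically, the rest at random without replacement with
    probability proportional to a Gaussian of standard deviation
    ``sigma_fraction * height`` centered on the DC row. Deterministic
    given ``seed``.
    """
    if not 0 < rate <= 1:
        raise ConfigurationError("rate must be in (0, 1]")
    if not 0 <= center_fraction < 1:
        raise ConfigurationError("center_fraction must be in [0, 1)")
    n_keep = int(round(rate * height))
    lo, hi = _center_band(height, center_fraction)
    n_center = hi - lo
    if n_center > n_keep:
        raise ConfigurationError(
            f"rate {rate} keeps {n_keep} rows, fewer than the {n_center}-row "
            "center band; raise the rate or shrink center_fraction"
        )
    rows = np.zeros(height, dtype=np.uint8)
    rows[lo:hi] = 1
    n_random = n_keep - n_center
    if n_random > 0:
        candidates = np.flatnonzero(rows == 0)
        dc = height // 2
        sigma = sigma_fraction * height
        weights = np.exp(-0.5 * ((candidates - dc) / sigma) ** 2)
        total = weights.sum()
        rng = np.random.default_rng(seed)
        if total <= 0 or not np.isfinite(total):
            chosen = rng.choice(candidates, size=n_random, replace=False)
        else:
            chosen = rng.choice(
                candidates, size=n_random, replace=False, p=weights / total
            )
        rows[chosen] = 1
    return SamplingMask(rows, rate, center_fraction, seed)


def to_kspace(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT of a real image.

    The DC component lands at index ``(h//2, w//2)``. Orthonormal
    scaling makes the transform unitary, so image and k-space energies
    agree (Parseval).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def from_kspace(k: np.ndarray) -> np.ndarray:
    """Centered orthonormal inverse 2D DFT; returns the complex image."""
    k = np.asarray(k)
    if k.ndim != 2:
        raise ShapeError(f"expected 2D k-space, got shape {k.shape}")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


def undersample(k: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero out the k-space rows the mask did not acquire."""
    k = np.asarray(k)
    if k.ndim != 2:
        raise ShapeError(f"expected 2D k-space, got shape {k.shape}")
    if k.shape[0] != mask.height:
        raise ShapeError(
            f"mask length {mask.height} does not match k-space height {k.shape[0]}"
        )
    return k * mask.rows[:, None]


def zero_filled_recon(k_under: np.ndarray) -> np.ndarray:
    """Magnitude of the centered inverse FFT of (under)sampled k-space."""
    return np.abs(from_kspace(k_under))
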