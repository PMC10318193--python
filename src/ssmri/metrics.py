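"""Image-quality metrics: PSNR, SSIM, and a weighted PSNR variant.

All metrics operate on 2D magnitude images, conventionally normalized
to [0, 1] (``data_range`` defaults to 1.0). SSIM follows the Wang et
al. convention: an 11x11 Gaussian window with sigma = 1.5, stability
constants C1 = (k1*L)^2 and C2 = (k2*L)^2 with k1 = 0.01, k2 = 0.03,
Gaussian-weighted (not sample-corrected) local statistics, and the
border cropped so every retained window lies fully inside the image.

WPSNR replaces the uniform mean-squared-error average with a weighted
one. The default weight map is a contrast-sensitivity-inspired
high-frequency attenuation map derived from the reference image
(errors in busy regions are down-weighted, as the eye masks them); it
is a documented in-house approximation, not a published standard, and
a user-supplied map takes precedence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ShapeError

__all__ = [
    "psnr",
    "ssim",
    "wpsnr",
    "default_weight_map",
    "MetricsReport",
    "aggregate_report",
]

#: Sentinel for zero-error comparisons (identical images).
INF_PSNR = math.inf


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.ndim != 2 or test.ndim != 2:
        raise ShapeError("metrics expect 2D images")
    if reference.shape != test.shape:
        raise ShapeError(
            f"shape mismatch: {reference.shape} vs {test.shape}"
        )
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB.

    ``10 * log10(data_range**2 / MSE)``. Identical images return
    ``math.inf`` as a distinct sentinel.
    """
    reference, test = _check_pair(reference, test)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return INF_PSNR
    return 10.0 * math.log10(data_range**2 / mse)


def _gaussian_window_stats(img: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return gaussian_filter(img, sigma=sigma, truncate=truncate, mode="reflect")


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity index over the image.

    Local means, variances and covariance are computed under an 11x11
    Gaussian window (sigma = 1.5); the map is averaged after cropping a
    5-pixel border so only fully supported windows count. Returns a
    value in [-1, 1]; exactly 1.0 for identical images.
    """
    reference, test = _check_pair(reference, test)
    radius = 5  # 11x11 window
    truncate = radius / sigma
    if min(reference.shape) < 2 * radius + 1:
        raise ShapeError(
            f"images must be at least {2 * radius + 1} pixels per side for SSIM"
        )
    if np.array_equal(reference, test):
        return 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_x = _gaussian_window_stats(reference, sigma, truncate)
    mu_y = _gaussian_window_stats(test, sigma, truncate)
    var_x = _gaussian_window_stats(reference * reference, sigma, truncate) - mu_x**2
    var_y = _gaussian_window_stats(test * test, sigma, truncate) - mu_y**2
    cov_xy = _gaussian_window_stats(reference * test, sigma, truncate) - mu_x * mu_y
    s = ((2 * mu_x * mu_y + c1) * (2 * cov_xy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    interior = s[radius:-radius, radius:-radius]
    return float(interior.mean())


def default_weight_map(reference: np.ndarray, smoothing: float = 1.5) -> np.ndarray:
    """Contrast-sensitivity-style weight map from local high-frequency energy.

    Pixels in smooth regions (where errors are most visible) receive
    larger weights than pixels in high-detail regions. The map is
    normalized to mean 1, so uniform images yield uniform weights and
    WPSNR degenerates to PSNR.
    """
    reference = np.asarray(reference, dtype=np.float64)
    low = gaussian_filter(reference, smoothing, mode="reflect")
    energy = gaussian_filter((reference - low) ** 2, 2 * smoothing, mode="reflect")
    w = 1.0 / (1.0 + energy / (energy.mean() + 1e-12))
    return w / w.mean()


def wpsnr(
    reference: np.ndarray,
    test: np.ndarray,
    data_range: float = 1.0,
    weight_map: np.ndarray | None = None,
) -> float:
    """Weighted PSNR: MSE averaged under a nonnegative, mean-1 weight map.

    A uniform map reproduces :func:`psnr` exactly. The default map is
    the high-frequency attenuation map of :func:`default_weight_map`.
    """
    reference, test = _check_pair(reference, test)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if weight_map is None:
        w = default_weight_map(reference)
    else:
        w = np.asarray(weight_map, dtype=np.float64)
        if w.shape != reference.shape:
            raise ShapeError("weight map shape must match the images")
        if np.any(w < 0):
            raise ValueError("weight map must be nonnegative")
        w = w / w.mean()
    wmse = float(np.sum(w * (reference - test) ** 2) / np.sum(w))
    if wmse == 0.0:
        return INF_PSNR
    return 10.0 * math.log10(data_range**2 / wmse)


# ---------------------------------------------------------------------------
# Aggregation (mean ± sample std over a test set, one row per model)
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-model mean ± std table over a test set.

    ``table`` is indexed by model name with two-level columns
    (metric, {"mean", "std", "n_finite", "n_inf"}). Infinite PSNR
    sentinels are excluded from mean/std and counted separately.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        flat = self.table.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        flat.to_csv(path)

    def render_markdown(self) -> str:
        """Markdown table, best per-metric mean in bold."""
        metrics_names = sorted({c[0] for c in self.table.columns})
        lines = ["| model | " + " | ".join(metrics_names) + " |"]
        lines.append("|" + "---|" * (len(metrics_names) + 1))
        best = {
            m: self.table[(m, "mean")].max() for m in metrics_names
        }
        for model in self.table.index:
            cells = []
            for m in metrics_names:
                mean = self.table.loc[model, (m, "mean")]
                std = self.table.loc[model, (m, "std")]
                n_inf = int(self.table.loc[model, (m, "n_inf")])
                cell = f"{mean:.2f} ± {std:.2f}"
                if n_inf:
                    cell += f" ({n_inf} inf)"
                if mean == best[m]:
                    cell = f"**{cell}**"
                cells.append(cell)
            lines.append(f"| {model} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def aggregate_report(
    per_image_metrics: dict[str, dict[str, list[float]]],
    roster: list[str] | None = None,
    metadata: dict | None = None,
) -> MetricsReport:
    """Aggregate per-image metric values into a mean ± std report.

    Parameters
    ----------
    per_image_metrics
        ``{model: {metric: [values...]}}``. Each cell needs at least two
        finite values (sample standard deviation, ddof=1).
    roster
        Optional explicit row order; defaults to the dict's key order.
    """
    roster = list(per_image_metrics) if roster is None else list(roster)
    if not roster:
        raise ValueError("empty model roster")
    rows = {}
    for model in roster:
        if model not in per_image_metrics:
            raise ValueError(f"missing metrics for model {model!r}")
        row = {}
        for metric, values in per_image_metrics[model].items():
            values = np.asarray(values, dtype=np.float64)
            finite = values[np.isfinite(values)]
            if finite.size < 2:
                raise ValueError(
                    f"cell ({model}, {metric}) needs >= 2 finite values for std"
                )
            row[(metric, "mean")] = float(finite.mean())
            row[(metric, "std")] = float(finite.std(ddof=1))
            row[(metric, "n_finite")] = int(finite.size)
            row[(metric, "n_inf")] = int(values.size - finite.size)
        rows[model] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return MetricsReport(table=table, metadata=dict(metadata or {}))
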