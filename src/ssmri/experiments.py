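"""End-to-end transfer-scenario runner at desk scale.

Reproduces the comparison protocol — ZF / PT / DT / FT / RFT / LFT
evaluated on a common target test set across sampling rates and
training-set sizes — on synthetic phantom domains, plus two
diagnostics: feature-map extraction (to inspect how scale/shift
factors recombine shared basic features) and a catastrophic-forgetting
probe that scores transferred models on held-out source-domain data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ShapeError
from .kspace_sim import generate_cartesian_mask, zero_filled_recon
from .metrics import aggregate_report, psnr, ssim, wpsnr, MetricsReport
from .phantom_gen import generate_domain_pair, scenario_specs
from .recon_net import NetworkSpec, ReconNetwork, build_generator, insert_ss
from .ssconv import Strategy
from .transfer_strategies import (
    Sample,
    SplitSpec,
    StrategyConfig,
    evaluate_psnr,
    make_samples,
    pretrain,
    split_dataset,
    transfer,
)

__all__ = [
    "ScenarioConfig",
    "run_scenario",
    "extract_feature_maps",
    "compare_forgetting",
    "save_reconstruction_panel",
]

_FULL_ROSTER = ("ZF", "PT", "DT", "FT", "RFT", "LFT")


@dataclass
class ScenarioConfig:
    """Configuration of one scenario grid run."""

    scenario: str = "contrast"
    rates: tuple[float, ...] = (0.3,)
    train_sizes: tuple[int, ...] = (16,)
    roster: tuple[str, ...] = _FULL_ROSTER
    seeds: tuple[int, ...] = (0,)
    size: int = 64
    n_source: int = 160
    n_target: int = 32
    net_spec: NetworkSpec = field(default_factory=NetworkSpec)
    pretrain_seed: int = 0
    pretrain_epochs: int = 200
    transfer_epochs: int = 150
    patience: int = 15
    # desk-scale step sizes: an epoch here is a handful of optimizer steps,
    # so the library's per-strategy defaults are scaled up tenfold
    pretrain_lr: float = 1e-3
    transfer_lrs: dict = field(
        default_factory=lambda: {"DT": 1e-3, "FT": 1e-4, "LFT": 1e-3, "RFT": 1e-3}
    )
    batch_size: int = 4
    pretrain_batch_size: int = 8
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.rates or not self.train_sizes or not self.seeds:
            raise ConfigurationError("rates, train_sizes and seeds must be nonempty")
        if any(not 0 < r <= 1 for r in self.rates):
            raise ConfigurationError("rates must lie in (0, 1]")
        unknown = set(self.roster) - set(_FULL_ROSTER)
        if unknown:
            raise ConfigurationError(f"unknown roster entries {unknown}")


def _score(recon: np.ndarray, target: np.ndarray) -> dict[str, float]:
    return {
        "psnr": psnr(target, recon),
        "ssim": ssim(target, recon),
        "wpsnr": wpsnr(target, recon),
    }


def _evaluate_model(model, test_samples) -> dict[str, list[float]]:
    from .transfer_strategies import _magnitude  # shared magnitude convention

    out: dict[str, list[float]] = {"psnr": [], "ssim": [], "wpsnr": []}
    for s in test_samples:
        if model == "ZF":
            recon = zero_filled_recon(s.k_under)
        else:
            recon = _magnitude(model.forward(s.zf))
        for k, v in _score(recon, s.target).items():
            out[k].append(v)
    return out


def run_scenario(config: ScenarioConfig):
    """Run the full model roster over the (rate, train_size, seed) grid.

    For each sampling rate the source model is pretrained once per seed
    and shared across training-set sizes. Every model in a cell is
    scored on the identical target test set under the identical mask.
    Returns ``(reports, long_df)``: a dict of per-cell
    :class:`~ssmri.metrics.MetricsReport` and one long-format DataFrame.
    """
    reports: dict[tuple, MetricsReport] = {}
    rows = []
    src_spec, tgt_spec = scenario_specs(config.scenario, config.size, seed=17)
    source, target = generate_domain_pair(
        src_spec, tgt_spec, config.n_source, config.n_target, seed=0
    )
    src_train, src_val, _ = split_dataset(
        source, SplitSpec(), seed=config.pretrain_seed
    )
    tgt_train_all, tgt_val, tgt_test = split_dataset(
        target, SplitSpec(), seed=config.pretrain_seed
    )
    for rate in config.rates:
        mask = generate_cartesian_mask(
            config.size, rate, seed=1000 + int(round(rate * 100))
        )
        t_val = make_samples(tgt_val, mask)
        t_test = make_samples(tgt_test, mask)

        # one source model per sampling rate, shared by every transfer seed
        checkpoint = None
        if set(config.roster) - {"ZF"}:
            s_train = make_samples(src_train, mask)
            s_val = make_samples(src_val, mask)
            net = build_generator(config.net_spec, seed=config.pretrain_seed)
            cfg = StrategyConfig(
                strategy=Strategy.DT,
                learning_rate=config.pretrain_lr,
                max_epochs=config.pretrain_epochs,
                patience=config.patience,
                batch_size=config.pretrain_batch_size,
                seed=config.pretrain_seed,
            )
            net, _hist = pretrain(net, s_train, s_val, cfg)
            checkpoint = net.get_state()

        for seed in config.seeds:
            for train_size in config.train_sizes:
                if train_size > len(tgt_train_all):
                    raise ConfigurationError(
                        f"train_size {train_size} exceeds target train pool "
                        f"{len(tgt_train_all)}"
                    )
                t_train = make_samples(tgt_train_all[:train_size], mask)
                cell_metrics = {}
                for model_name in config.roster:
                    model = _fit_model(
                        model_name, config, checkpoint, t_train, t_val, seed
                    )
                    cell_metrics[model_name] = _evaluate_model(model, t_test)
                meta = {"scenario": config.scenario, "rate": rate,
                        "train_size": train_size, "seed": seed}
                report = aggregate_report(cell_metrics, list(config.roster), meta)
                reports[(rate, train_size, seed)] = report
                for model_name, metric_lists in cell_metrics.items():
                    for metric, values in metric_lists.items():
                        for i, v in enumerate(values):
                            rows.append({**meta, "model": model_name,
                                         "metric": metric, "image": i, "value": v})
    long_df = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        long_df.to_csv(out / "results_long.csv", index=False)
        for (rate, train_size, seed), report in reports.items():
            stem = f"{config.scenario}_r{int(rate*100)}_n{train_size}_s{seed}"
            report.to_csv(out / f"{stem}.csv")
            (out / f"{stem}.md").write_text(report.render_markdown() + "\n")
    return reports, long_df


def _fit_model(model_name, config, checkpoint, t_train, t_val, seed):
    """Train (or set up) one roster entry for a cell."""
    if model_name == "ZF":
        return "ZF"
    net = build_generator(config.net_spec, seed=seed)
    if model_name in ("LFT", "RFT"):
        insert_ss(net, "kernel" if model_name == "LFT" else "row")
    cfg = StrategyConfig(
        strategy=Strategy(model_name.lower()),
        learning_rate=config.transfer_lrs.get(model_name),
        max_epochs=config.transfer_epochs,
        patience=config.patience,
        batch_size=config.batch_size,
        seed=seed,
    )
    net, _ = transfer(net, checkpoint, t_train, t_val, cfg)
    return net


def save_reconstruction_panel(
    out_path,
    target: np.ndarray,
    reconstructions: dict[str, np.ndarray],
    error_scale: float = 10.0,
) -> None:
    """Render ground truth, reconstructions, and amplified error maps.

    Top row: ground truth followed by each model's magnitude
    reconstruction; bottom row: the corresponding absolute error maps
    multiplied by ``error_scale`` (errors are small relative to the
    [0, 1] intensity range, so a fixed amplification makes residual
    aliasing visible).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(reconstructions)
    n_cols = len(names) + 1
    fig, axes = plt.subplots(2, n_cols, figsize=(2.2 * n_cols, 4.6))
    axes[0, 0].imshow(target, cmap="gray", vmin=0, vmax=1)
    axes[0, 0].set_title("reference")
    axes[1, 0].axis("off")
    for j, name in enumerate(names, start=1):
        recon = reconstructions[name]
        axes[0, j].imshow(recon, cmap="gray", vmin=0, vmax=1)
        axes[0, j].set_title(name)
        err = np.abs(recon - target) * error_scale
        axes[1, j].imshow(np.clip(err, 0, 1), cmap="viridis", vmin=0, vmax=1)
        axes[1, j].set_title(f"|err| x{error_scale:g}")
    for ax in axes.ravel():
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def extract_feature_maps(
    net: ReconNetwork, image: np.ndarray, layer_index: int, channel_index: int
) -> np.ndarray:
    """Advanced-feature map of one filter: post-linear-combination,
    pre-activation, with SS factors applied when present."""
    layers = net.layers
    if not 0 <= layer_index < len(layers):
        raise IndexError(f"layer index {layer_index} out of range [0, {len(layers)})")
    net.forward(np.asarray(image), record=True)
    pre = layers[layer_index].last_preactivation
    if not 0 <= channel_index < pre.shape[0]:
        raise IndexError(
            f"channel index {channel_index} out of range [0, {pre.shape[0]})"
        )
    fmap = pre[channel_index].copy()
    for u in layers:  # release caches
        u._cache = None
    return fmap


def compare_forgetting(
    pretrained: ReconNetwork,
    transferred: ReconNetwork,
    source_val_samples: list[Sample],
) -> tuple[float, float]:
    """Source-domain PSNR of the pretrained vs. the transferred model.

    The difference quantifies catastrophic forgetting: a frozen-backbone
    strategy with identity factors forgets nothing by construction,
    while full fine-tuning may trade source competence for target fit.
    """
    if pretrained.layer_shapes() != transferred.layer_shapes():
        raise ShapeError("models have incompatible layer shapes")
    return (
        evaluate_psnr(pretrained, source_val_samples),
        evaluate_psnr(transferred, source_val_samples),
    )
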