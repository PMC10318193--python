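"""Training regimes: splits, early stopping, freezing contracts."""

import numpy as np
import pytest

from ssmri.exceptions import ConfigurationError, StateError
from ssmri.kspace_sim import generate_cartesian_mask
from ssmri.phantom_gen import generate_domain_pair, scenario_specs
from ssmri.recon_net import NetworkSpec, build_generator, insert_ss
from ssmri.transfer_strategies import (
    EpochRecord,
    SplitSpec,
    Strategy,
    StrategyConfig,
    TrainingHistory,
    early_stop_check,
    make_samples,
    pretrain,
    split_dataset,
    transfer,
)

SPEC = NetworkSpec(depth=2, base_channels=4)


@pytest.fixture(scope="module")
def toy_data():
    """Small 32x32 contrast-scenario source/target sample sets."""
    src_spec, tgt_spec = scenario_specs("contrast", size=32, seed=17)
    source, target = generate_domain_pair(src_spec, tgt_spec, 25, 25, seed=0)
    mask = generate_cartesian_mask(32, 0.3, seed=5)
    s_tr, s_va, _ = split_dataset(source, SplitSpec(), seed=0)
    t_tr, t_va, _ = split_dataset(target, SplitSpec(), seed=0)
    return {
        "src_train": make_samples(s_tr, mask),
        "src_val": make_samples(s_va, mask),
        "tgt_train": make_samples(t_tr, mask),
        "tgt_val": make_samples(t_va, mask),
    }


@pytest.fixture(scope="module")
def pretrained(toy_data):
    net = build_generator(SPEC, seed=0)
    cfg = StrategyConfig(strategy="dt", learning_rate=1e-4, max_epochs=8,
                         patience=15, seed=0)
    net, history = pretrain(net, toy_data["src_train"], toy_data["src_val"], cfg)
    return net.get_state(), history


class TestSplitDataset:
    def test_default_ratio_at_minimal_size(self):
        train, val, test = split_dataset(list(range(25)), SplitSpec(), seed=0)
        assert (len(train), len(val), len(test)) == (16, 5, 4)

    def test_proportional_scaling(self):
        train, val, test = split_dataset(list(range(100)), SplitSpec(), seed=0)
        assert (len(train), len(val), len(test)) == (64, 20, 16)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = list(range(50))
        train, val, test = split_dataset(items, SplitSpec(), seed=3)
        assert sorted(train + val + test) == items

    def test_subset_drawn_from_train_only(self):
        items = list(range(100))
        full_train, val, test = split_dataset(items, SplitSpec(), seed=1)
        sub_train, sub_val, sub_test = split_dataset(
            items, SplitSpec(train_subset_size=20), seed=1
        )
        assert len(sub_train) == 20
        assert set(sub_train) <= set(full_train)
        assert sub_val == val and sub_test == test

    def test_deterministic_given_seed(self):
        a = split_dataset(list(range(30)), SplitSpec(), seed=9)
        b = split_dataset(list(range(30)), SplitSpec(), seed=9)
        assert a == b

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), SplitSpec(), seed=0)


class TestEarlyStop:
    @staticmethod
    def _history(psnrs):
        h = TrainingHistory()
        for i, v in enumerate(psnrs, start=1):
            h.records.append(EpochRecord(i, 0.0, v))
            if v > h.best_val_psnr:
                h.best_val_psnr = v
                h.best_epoch = i
        return h

    def test_strictly_increasing_never_stops(self):
        h = self._history(np.linspace(20, 30, 40))
        assert not early_stop_check(h, 15)

    def test_constant_psnr_stops_at_epoch_16(self):
        h = self._history([25.0] * 16)
        assert h.best_epoch == 1
        assert early_stop_check(h, 15)
        assert not early_stop_check(self._history([25.0] * 15), 15)

    def test_improvement_resets_window(self):
        vals = [25.0] + [24.0] * 13 + [26.0]
        h = self._history(vals)
        assert h.best_epoch == 15
        assert not early_stop_check(h, 15)


class TestPretrain:
    def test_zero_learning_rate_changes_nothing(self, toy_data):
        net = build_generator(SPEC, seed=4)
        before = net.get_state()
        cfg = StrategyConfig(strategy="dt", learning_rate=0.0, max_epochs=1,
                             patience=15, seed=0)
        net, history = pretrain(net, toy_data["src_train"], toy_data["src_val"], cfg)
        for key, arr in net.get_state().items():
            np.testing.assert_array_equal(arr, before[key])
        assert history.records[0].val_psnr == pytest.approx(
            history.initial_val_psnr, abs=1e-6
        )

    def test_history_is_bitwise_reproducible(self, toy_data):
        def run():
            net = build_generator(SPEC, seed=2)
            cfg = StrategyConfig(strategy="dt", learning_rate=1e-4, max_epochs=4,
                                 patience=15, seed=2)
            _, h = pretrain(net, toy_data["src_train"], toy_data["src_val"], cfg)
            return [(r.train_loss, r.val_psnr) for r in h.records]

        assert run() == run()

    def test_best_checkpoint_has_max_val_psnr(self, pretrained):
        _, history = pretrained
        assert history.best_val_psnr == max(history.val_psnrs())

    def test_ss_network_rejected(self, toy_data):
        net = insert_ss(build_generator(SPEC, seed=0), "kernel")
        with pytest.raises(StateError):
            pretrain(net, toy_data["src_train"], toy_data["src_val"],
                     StrategyConfig(strategy="dt"))


class TestTransferContracts:
    def test_pt_performs_no_training(self, toy_data, pretrained):
        ckpt, _ = pretrained
        net = build_generator(SPEC, seed=0)
        net, history = transfer(net, ckpt, toy_data["tgt_train"],
                                toy_data["tgt_val"],
                                StrategyConfig(strategy="pt", seed=0))
        assert history.records == []
        for key in ckpt:
            if "/ss/" not in key:
                np.testing.assert_array_equal(net.get_state()[key], ckpt[key])

    @pytest.mark.parametrize("strategy,granularity", [("lft", "kernel"), ("rft", "row")])
    def test_frozen_backbone_is_bitwise_identical(
        self, toy_data, pretrained, strategy, granularity
    ):
        """An epoch of factor training must not flip a single backbone bit."""
        ckpt, _ = pretrained
        net = insert_ss(build_generator(SPEC, seed=0), granularity)
        before = None
        net.set_state(ckpt, backbone_only=True)
        before = net.backbone_hashes()
        cfg = StrategyConfig(strategy=strategy, max_epochs=2, patience=15, seed=0)
        net, history = transfer(net, ckpt, toy_data["tgt_train"],
                                toy_data["tgt_val"], cfg)
        assert net.backbone_hashes() == before
        # ...while the factors did move
        moved = any(
            not np.allclose(
                u.factors.scale if strategy == "lft" else u.factors.row_scale, 1.0
            )
            for u in net.layers
        )
        assert moved

    def test_lft_without_ss_blocks_is_state_error(self, toy_data, pretrained):
        ckpt, _ = pretrained
        net = build_generator(SPEC, seed=0)
        with pytest.raises(StateError):
            transfer(net, ckpt, toy_data["tgt_train"], toy_data["tgt_val"],
                     StrategyConfig(strategy="lft"))

    def test_ft_with_zero_lr_equals_pt(self, toy_data, pretrained):
        ckpt, _ = pretrained
        pt_net, pt_h = transfer(build_generator(SPEC, seed=0), ckpt,
                                toy_data["tgt_train"], toy_data["tgt_val"],
                                StrategyConfig(strategy="pt", seed=0))
        ft_net, ft_h = transfer(build_generator(SPEC, seed=0), ckpt,
                                toy_data["tgt_train"], toy_data["tgt_val"],
                                StrategyConfig(strategy="ft", learning_rate=0.0,
                                               max_epochs=1, seed=0))
        assert ft_h.records[0].val_psnr == pytest.approx(
            pt_h.initial_val_psnr, abs=1e-6
        )

    def test_lft_epoch0_equals_pt(self, toy_data, pretrained):
        """Identity-initialized factors start exactly from the PT model."""
        ckpt, _ = pretrained
        _, pt_h = transfer(build_generator(SPEC, seed=0), ckpt,
                           toy_data["tgt_train"], toy_data["tgt_val"],
                           StrategyConfig(strategy="pt", seed=0))
        lft_net = insert_ss(build_generator(SPEC, seed=0), "kernel")
        _, lft_h = transfer(lft_net, ckpt, toy_data["tgt_train"],
                            toy_data["tgt_val"],
                            StrategyConfig(strategy="lft", max_epochs=1, seed=0))
        assert lft_h.initial_val_psnr == pytest.approx(
            pt_h.initial_val_psnr, abs=1e-6
        )

    def test_dt_ignores_checkpoint(self, toy_data, pretrained):
        ckpt, _ = pretrained
        net, _ = transfer(build_generator(SPEC, seed=3), ckpt,
                          toy_data["tgt_train"], toy_data["tgt_val"],
                          StrategyConfig(strategy="dt", learning_rate=0.0,
                                         max_epochs=1, seed=3))
        fresh = build_generator(SPEC, seed=3)
        for key, arr in net.get_state().items():
            np.testing.assert_array_equal(arr, fresh.get_state()[key])

    def test_identical_lft_runs_are_identical(self, toy_data, pretrained):
        ckpt, _ = pretrained

        def run():
            net = insert_ss(build_generator(SPEC, seed=0), "kernel")
            net, h = transfer(net, ckpt, toy_data["tgt_train"],
                              toy_data["tgt_val"],
                              StrategyConfig(strategy="lft", max_epochs=3, seed=1))
            return h.val_psnrs(), net.get_state()

        h1, s1 = run()
        h2, s2 = run()
        assert h1 == h2
        for key in s1:
            np.testing.assert_array_equal(s1[key], s2[key])


class TestConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ConfigurationError):
            StrategyConfig(patience=0)
        with pytest.raises(ConfigurationError):
            StrategyConfig(loss="perceptual")
        with pytest.raises(ValueError):
            Strategy("adapter")

    def test_default_transfer_learning_rates(self):
        assert StrategyConfig(strategy="ft").learning_rate == pytest.approx(1e-5)
        assert StrategyConfig(strategy="lft").learning_rate == pytest.approx(1e-4)
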