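"""Schedules, splits, early stopping, and loop determinism."""

import numpy as np
import pytest

import slidemae.training as tr
from slidemae.model import RegionEncoder, encode_region
from slidemae.store import SlideFeatureSet
from slidemae.training import (
    EarlyStopper,
    FinetuneConfig,
    PretrainConfig,
    evaluate,
    finetune,
    lr_at,
    pretrain,
)


class TestLearningRateSchedule:
    CFG = PretrainConfig()  # full-scale schedule

    def test_peak_at_end_of_warmup(self):
        assert lr_at(8000, self.CFG) == pytest.approx(4e-5)

    def test_zero_at_final_step(self):
        assert lr_at(400_000, self.CFG) == pytest.approx(0.0, abs=1e-20)

    def test_half_peak_at_warmup_midpoint(self):
        assert lr_at(4000, self.CFG) == pytest.approx(2e-5)

    def test_cosine_midpoint(self):
        mid = 8000 + (400_000 - 8000) // 2
        assert lr_at(mid, self.CFG) == pytest.approx(2e-5, rel=1e-3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            lr_at(-1, self.CFG)
        with pytest.raises(ValueError):
            lr_at(400_001, self.CFG)


class TestEarlyStopper:
    def test_flat_series_stops_after_patience_plus_one_epochs(self):
        stopper = EarlyStopper(patience=5)
        stops = [stopper.update(1.0) for _ in range(10)]
        # first epoch improves over -inf; the next 5 are stagnant
        assert stops.index(True) + 1 == 6  # stops at epoch patience + 1
        assert stopper.best_epoch == 1

    def test_strictly_improving_series_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(float(v)) for v in range(50))

    def test_recovery_resets_the_counter(self):
        stopper = EarlyStopper(patience=2)
        values = [1.0, 1.0, 2.0, 2.0, 2.0]
        stops = [stopper.update(v) for v in values]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 3


class TestSplits:
    def test_disjoint_and_seed_deterministic(self):
        ids = [f"s{i}" for i in range(10)]
        rng1 = np.random.Generator(np.random.PCG64(3))
        rng2 = np.random.Generator(np.random.PCG64(3))
        a_train, a_mon = tr._split_slides(ids, 0.8, rng1)
        b_train, b_mon = tr._split_slides(ids, 0.8, rng2)
        assert a_train == b_train and a_mon == b_mon
        assert set(a_train) & set(a_mon) == set()
        assert sorted(a_train + a_mon) == sorted(ids)
        assert len(a_train) == 8

    def test_different_seeds_give_different_splits(self):
        ids = [f"s{i}" for i in range(20)]
        a, _ = tr._split_slides(ids, 0.8, np.random.Generator(np.random.PCG64(0)))
        b, _ = tr._split_slides(ids, 0.8, np.random.Generator(np.random.PCG64(1)))
        assert a != b


@pytest.fixture(scope="module")
def toy_setup(request):
    from slidemae.fixtures import FixtureSpec, gen_outcomes, gen_store

    spec = FixtureSpec(n_slides=16, outcome="classification", seed=3)
    cohort = gen_store(spec)
    labels = gen_outcomes(spec, cohort)
    return cohort, labels


def _toy_model(seed=0):
    return RegionEncoder(d=32, L=2, H=4, n_max=8, dropout=0.1, seed=seed)


class TestPretrainLoop:
    def test_same_seed_gives_identical_loss_history(self, toy_setup):
        cohort, _ = toy_setup
        cfg = PretrainConfig.toy(total_steps=12, warmup_steps=4, seed=5)
        h1 = pretrain(cohort.slides, _toy_model(1), cfg).history
        h2 = pretrain(cohort.slides, _toy_model(1), cfg).history
        assert h1["train_loss"].tolist() == h2["train_loss"].tolist()

    def test_monitor_slides_never_trained_on(self, toy_setup):
        cohort, _ = toy_setup
        cfg = PretrainConfig.toy(total_steps=6, warmup_steps=2, seed=0)
        res = pretrain(cohort.slides, _toy_model(), cfg)
        assert set(res.train_slides) & set(res.monitor_slides) == set()
        assert len(res.train_slides) == round(0.8 * 16)

    def test_empty_store_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain([], _toy_model(), PretrainConfig.toy(total_steps=2, warmup_steps=1))


class TestFinetuneLoop:
    def test_parameter_groups_cover_backbone_and_head_exactly(self, toy_setup, monkeypatch):
        cohort, labels = toy_setup
        captured = {}
        real_adamw = tr.AdamW

        class SpyAdamW(real_adamw):
            def __init__(self, groups, **kw):
                captured.update(groups)
                super().__init__(groups, **kw)

        monkeypatch.setattr(tr, "AdamW", SpyAdamW)
        model = _toy_model()
        cfg = FinetuneConfig(task="classification", region_n=8, max_epochs=1, seed=0)
        result = finetune(cohort.slides, labels, model, cfg)

        def union(prefix):
            names, lrs = set(), set()
            for g in (prefix, f"{prefix}_no_decay"):
                params, lr = captured[g][0], captured[g][1]
                names |= set(params)
                lrs.add(lr)
            assert len(lrs) == 1  # same rate across the decay split
            return names, lrs.pop()

        head_params, head_lr = union("head")
        backbone_params, backbone_lr = union("backbone")
        assert head_lr == pytest.approx(3e-3)  # classification head rate
        assert backbone_lr == pytest.approx(1e-5)
        assert backbone_params == set(model.named_parameters())
        assert head_params == set(result.head.named_parameters())
        assert not (backbone_params & head_params)
        # norm gains / biases / tokens sit in the no-decay groups
        for g in ("head_no_decay", "backbone_no_decay"):
            assert all(
                any(m in k for m in tr._NO_DECAY_MARKERS) for k in captured[g][0]
            )

    def test_single_region_slide_representation_is_its_class_token(self):
        rng = np.random.default_rng(0)
        n = 4
        coords = np.array([(x, y) for y in range(n) for x in range(n)])
        fset = SlideFeatureSet(
            slide_id="one",
            magnification_tag="10x",
            patch_size_px=224,
            grid_shape=(n, n),
            features=rng.standard_normal((n * n, 8)).astype(np.float32),
            coords=coords,
        )
        model = RegionEncoder(d=8, L=1, H=2, n_max=4, dropout=0.0, seed=2)
        reps, kept = tr._slide_representations(
            model, {"one": fset}, ["one"], n=4, regions_per_slide=1,
            coverage=1.0, max_overlap=0.5,
            rng=np.random.Generator(np.random.PCG64(0)),
        )
        assert kept == ["one"]
        from slidemae.store import load_grid

        grid = load_grid(fset, (0, 0), 4)
        enc = encode_region(grid.features, grid.foreground, model)
        np.testing.assert_allclose(reps.data[0], enc.class_out, atol=1e-12)

    def test_survival_without_events_errors(self, toy_setup):
        cohort, _ = toy_setup
        import pandas as pd

        labels = pd.DataFrame(
            {
                "slide_id": [s.slide_id for s in cohort.slides],
                "time_years": np.arange(1.0, len(cohort.slides) + 1),
                "event": 0,
            }
        )
        with pytest.raises(ValueError, match="[Nn]o events"):
            finetune(
                cohort.slides,
                labels,
                _toy_model(),
                FinetuneConfig(task="survival", region_n=8, max_epochs=1),
            )

    def test_coverage_keeps_requested_fraction(self):
        from slidemae.sampling import RegionSample
        from slidemae.store import PatchGrid

        fg = np.ones((8, 8), dtype=bool)
        grid = PatchGrid((0, 0), 8, np.random.default_rng(0).standard_normal((8, 8, 4)), fg)
        region = RegionSample("s", (0, 0), 8, grid)
        feats, kept_fg = tr._apply_coverage(
            region, 0.25, np.random.Generator(np.random.PCG64(0))
        )
        assert kept_fg.sum() == 16  # 25% of 64
        assert (feats[~kept_fg] == 0).all()
        np.testing.assert_array_equal(feats[kept_fg], grid.features[kept_fg])


@pytest.fixture(scope="module")
def fitted(toy_setup):
    cohort, labels = toy_setup
    model = _toy_model()
    cfg = FinetuneConfig(task="classification", region_n=8, max_epochs=2, seed=0)
    result = finetune(cohort.slides, labels, model, cfg)
    return cohort, labels, result


class TestEvaluate:
    def test_same_seed_gives_identical_metric(self, fitted):
        cohort, labels, result = fitted
        kw = dict(task="classification", region_n=8, seed=4, label_order=result.label_order)
        a = evaluate(result.model, result.head, cohort.slides, labels, (2, 1.0), **kw)
        b = evaluate(result.model, result.head, cohort.slides, labels, (2, 1.0), **kw)
        assert a == b

    def test_schemas_reported_separately(self, fitted):
        cohort, labels, result = fitted
        kw = dict(task="classification", region_n=8, seed=4, label_order=result.label_order)
        full = evaluate(result.model, result.head, cohort.slides, labels, (4, 1.0), **kw)
        quarter = evaluate(result.model, result.head, cohort.slides, labels, (4, 0.25), **kw)
        assert full["schema"] == "4x100%"
        assert quarter["schema"] == "4x25%"
        assert 0.0 <= full["macro_auc"] <= 1.0 and 0.0 <= quarter["macro_auc"] <= 1.0


def test_pretrain_config_validation():
    with pytest.raises(ValueError):
        PretrainConfig(warmup_steps=10, total_steps=10)
    with pytest.raises(ValueError):
        PretrainConfig(mask_p=1.5)
    with pytest.raises(ValueError):
        FinetuneConfig(task="regression")
    with pytest.raises(ValueError):
        FinetuneConfig(patience=0)
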