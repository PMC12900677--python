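"""Schedule, augmentation, patch sampling, curriculum and the training loop."""

import math

import numpy as np
import pytest

import vesselsr.training as tr
from vesselsr.errors import ContractError
from vesselsr.losses import LossWeights
from vesselsr.model import ModelConfig
from vesselsr.synthetic import VesselTreeParams, make_dataset


def quick_cfg(**kw):
    base = dict(epochs=2, steps_per_epoch=8, batch=2, patch=12,
                eta_max=2e-3, seed=0, weights=LossWeights(1.0, 0.0, 0.0))
    base.update(kw)
    return tr.TrainConfig(**base)


@pytest.fixture(scope="module")
def small_data():
    return make_dataset(5, VesselTreeParams(image_size=64), scale=2, seed=3)


class TestCosineSchedule:
    def test_closed_form_at_landmarks(self):
        cfg = tr.TrainConfig(eta_max=2e-4, eta_min=1e-6, epochs=300)
        assert tr.cosine_lr(0, cfg) == pytest.approx(2e-4)
        assert tr.cosine_lr(300, cfg) == pytest.approx(1e-6)
        assert tr.cosine_lr(150, cfg) == pytest.approx((2e-4 + 1e-6) / 2)

    def test_matches_formula_everywhere(self):
        cfg = tr.TrainConfig(eta_max=1e-3, eta_min=1e-5, epochs=40)
        for t in range(41):
            want = 1e-5 + 0.5 * (1e-3 - 1e-5) * (1 + math.cos(t * math.pi / 40))
            assert tr.cosine_lr(t, cfg) == pytest.approx(want)

    def test_out_of_range_rejected(self):
        cfg = tr.TrainConfig(epochs=10)
        with pytest.raises(ContractError):
            tr.cosine_lr(11, cfg)
        with pytest.raises(ContractError):
            tr.cosine_lr(-1, cfg)


class TestAugment:
    def test_all_toggles_off_is_identity(self, rng):
        lr = rng.uniform(0, 1, (8, 8, 3))
        hr = rng.uniform(0, 1, (16, 16, 3))
        a, b = tr.augment(lr, hr, seed=0, flips=False, rotation=False,
                          jitter=False)
        assert np.array_equal(a, lr) and np.array_equal(b, hr)

    def test_seeded_determinism(self, rng):
        lr = rng.uniform(0, 1, (8, 8, 3))
        hr = rng.uniform(0, 1, (16, 16, 3))
        a1, b1 = tr.augment(lr, hr, seed=9)
        a2, b2 = tr.augment(lr, hr, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_geometric_ops_preserve_pixel_multiset(self, rng):
        lr = rng.uniform(0, 1, (8, 8, 3))
        hr = rng.uniform(0, 1, (16, 16, 3))
        a, b = tr.augment(lr, hr, seed=4, jitter=False)
        assert np.array_equal(np.sort(a.ravel()), np.sort(lr.ravel()))
        assert np.array_equal(np.sort(b.ravel()), np.sort(hr.ravel()))


class TestSamplePatches:
    def test_alignment_rule(self, rng):
        lr = rng.uniform(0, 1, (32, 32, 3))
        hr = rng.uniform(0, 1, (64, 64, 3))
        # embed a recognisable coordinate pattern
        lr[..., 0] = np.arange(32)[:, None] / 32
        hr[..., 0] = np.repeat(np.arange(32), 2)[:, None] / 32
        for lp, hp in tr.sample_patches(lr, hr, 5, patch=8, scale=2, seed=0):
            assert lp.shape[:2] == (8, 8) and hp.shape[:2] == (16, 16)
            # HR crop covers the same rows: row-pattern must match
            assert np.allclose(np.unique(lp[..., 0]), np.unique(hp[..., 0]))

    def test_seeded_determinism(self, rng):
        lr = rng.uniform(0, 1, (20, 20))
        hr = rng.uniform(0, 1, (40, 40))
        a = tr.sample_patches(lr, hr, 3, 8, 2, seed=1)
        b = tr.sample_patches(lr, hr, 3, 8, 2, seed=1)
        for (l1, h1), (l2, h2) in zip(a, b):
            assert np.array_equal(l1, l2) and np.array_equal(h1, h2)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ContractError):
            tr.sample_patches(np.zeros((8, 8)), np.zeros((16, 16)), 1, 16, 2, 0)


class TestCurriculum:
    def test_two_phase_structure(self):
        cfg = tr.TrainConfig(epochs=10, curriculum_switch=0.3)
        early = tr.curriculum_stage(0, cfg)
        late = tr.curriculum_stage(9, cfg)
        assert len(early) == 1 and early[0].kind == "bicubic_down"
        assert any(s.kind == "gaussian_noise" for s in late)
        # piecewise constant: same stage within a phase
        assert tr.curriculum_stage(1, cfg) == tr.curriculum_stage(2, cfg)

    def test_phase2_severities_at_or_below_protocol(self):
        cfg = tr.TrainConfig(epochs=10)
        for s in tr.curriculum_stage(9, cfg):
            if s.kind == "gaussian_blur":
                assert s.sigma <= 1.2
            if s.kind == "gaussian_noise":
                assert s.sigma <= 25
            if s.kind == "jpeg":
                assert s.quality >= 20


class TestTrainLoop:
    def test_loss_descends_and_history_is_complete(self, small_data):
        cfg = quick_cfg(epochs=3, steps_per_epoch=10)
        net, hist = tr.train(ModelConfig.tiny(), small_data, cfg)
        assert len(hist) == 3
        assert hist[-1].loss < hist[0].loss
        for rec in hist:
            assert cfg.eta_min <= rec.lr <= cfg.eta_max
        epochs = [r.epoch for r in hist]
        assert epochs == sorted(epochs)

    def test_equal_seeds_give_bitwise_identical_histories(self, small_data):
        cfg = quick_cfg()
        _, h1 = tr.train(ModelConfig.tiny(), small_data, cfg)
        _, h2 = tr.train(ModelConfig.tiny(), small_data, cfg)
        for a, b in zip(h1, h2):
            assert a.loss == b.loss
            assert a.val_psnr == b.val_psnr

    def test_resume_matches_uninterrupted_run(self, small_data, tmp_path):
        cfg = quick_cfg(epochs=4)
        _, full = tr.train(ModelConfig.tiny(), small_data, cfg)
        out = tmp_path / "ck"
        net, _ = tr.train(ModelConfig.tiny(), small_data, cfg, out_dir=out,
                          end_epoch=2)
        opt_state = tr.load_opt_state(out / "last.npz")
        _, tail = tr.train(ModelConfig.tiny(), small_data, cfg, net=net,
                           start_epoch=opt_state["epoch"] + 1,
                           opt_state=opt_state)
        assert [r.loss for r in tail] == [r.loss for r in full[2:]]
        assert [r.val_psnr for r in tail] == [r.val_psnr for r in full[2:]]

    def test_logged_lr_trace_equals_closed_form(self, small_data):
        cfg = quick_cfg(epochs=3)
        _, hist = tr.train(ModelConfig.tiny(), small_data, cfg)
        for rec in hist:
            assert rec.lr == tr.cosine_lr(rec.epoch, cfg)

    def test_empty_split_rejected(self, small_data):
        train_only = [it for it in small_data if it.split == "train"]
        with pytest.raises(ContractError):
            tr.train(ModelConfig.tiny(), train_only, quick_cfg())

    def test_history_jsonl_round_trip(self, small_data, tmp_path):
        import json
        cfg = quick_cfg()
        _, hist = tr.train(ModelConfig.tiny(), small_data, cfg)
        path = tmp_path / "h.jsonl"
        hist.write_jsonl(path)
        rows = [json.loads(line) for line in open(path)]
        assert len(rows) == len(hist)
        assert rows[0]["epoch"] == 0
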