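import numpy as np
import pytest

from longimpute import training as tr
from longimpute.errors import ConfigError, DataError, InputError
from longimpute.losses import LossWeights
from longimpute.synthetic import generate_cohort, generate_subject
from longimpute.volume_io import Volume

TINY = dict(width_scale=8)


def _tiny_cfg(**kw):
    kw.setdefault("variant", "pgan")
    kw.setdefault("train_epochs", 1)
    kw.setdefault("seed", 3)
    kw.update(TINY)
    return tr.TrainConfig(**kw)


@pytest.fixture(scope="module")
def tiny_cohort():
    from longimpute.synthetic import PhantomSpec

    return generate_cohort(PhantomSpec(shape=(16, 16, 16), seed=5), 4, 0.0,
                           (0.5, 0.25, 0.25))


class TestSchedule:
    def test_published_values(self):
        cfg = tr.TrainConfig()
        assert tr.learning_rate(0, cfg) == 2e-4
        assert tr.learning_rate(43, cfg) == 2e-4
        assert tr.learning_rate(44, cfg) == pytest.approx(1e-4)
        assert tr.learning_rate(219, cfg) == pytest.approx(2e-4 * 0.5 ** 8)

    def test_breakpoints_and_monotonicity(self):
        cfg = tr.TrainConfig()
        seq = [tr.learning_rate(e, cfg) for e in range(220)]
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        changes = [e for e in range(1, 220) if seq[e] != seq[e - 1]]
        assert changes == list(range(44, 199, 22))  # 44, 66, ..., 198
        assert len(changes) == 8

    def test_out_of_range_epoch_rejected(self):
        cfg = tr.TrainConfig()
        with pytest.raises(InputError):
            tr.learning_rate(220, cfg)
        with pytest.raises(InputError):
            tr.learning_rate(-1, cfg)

    def test_total_epoch_accounting(self):
        assert tr.TrainConfig().total_epochs == 220


class TestConfig:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            tr.TrainConfig(variant="wgan")

    def test_batch_size_fixed_at_one(self):
        with pytest.raises(ConfigError):
            tr.TrainConfig(batch_size=2)

    def test_variant_term_activation(self):
        assert tr.TrainConfig(variant="unet_lvr").active_terms == {
            "adv": False, "vr": True, "perceptual": False}
        assert tr.TrainConfig(variant="gan").active_terms == {
            "adv": True, "vr": False, "perceptual": False}
        assert tr.TrainConfig(variant="mpgan").active_terms == {
            "adv": True, "vr": True, "perceptual": True}


class TestTrainStep:
    def test_unet_lvr_leaves_discriminator_untouched(self, tiny_cohort):
        cfg = _tiny_cfg(variant="unet_lvr")
        bundle = tr.build_bundle_for_config(cfg)
        before = [p.value.copy() for p in bundle.discriminator_params()]
        ex = tr.example_from_record(tiny_cohort.subjects("train")[0], cfg)
        tr.train_step(bundle, ex, cfg)
        after = bundle.discriminator_params()
        assert all(np.array_equal(a, b.value) for a, b in zip(before, after))

    def test_feature_extractor_frozen_across_step(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan")
        bundle = tr.build_bundle_for_config(cfg)
        before = [p.value.copy() for p in bundle.feature_extractor.params()]
        ex = tr.example_from_record(tiny_cohort.subjects("train")[0], cfg)
        tr.train_step(bundle, ex, cfg)
        after = bundle.feature_extractor.params()
        assert all(np.array_equal(a, b.value) for a, b in zip(before, after))

    def test_two_fresh_runs_are_bit_identical(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan")
        params = []
        for _ in range(2):
            bundle = tr.build_bundle_for_config(cfg)
            ex = tr.example_from_record(tiny_cohort.subjects("train")[0], cfg)
            tr.train_step(bundle, ex, cfg)
            params.append([p.value.copy() for p in bundle.generator_params()])
        assert all(np.array_equal(a, b) for a, b in zip(*params))

    def test_breakdown_satisfies_weighted_sum_invariant(self, tiny_cohort):
        cfg = _tiny_cfg(variant="mpgan")
        bundle = tr.build_bundle_for_config(cfg)
        ex = tr.example_from_record(tiny_cohort.subjects("train")[0], cfg)
        bd = tr.train_step(bundle, ex, cfg)
        w = cfg.weights
        assert bd.total_G == pytest.approx(
            bd.adv_G + w.alpha * bd.vr + w.beta * bd.perceptual, rel=1e-6)
        assert all(np.isfinite(v) for v in bd.as_dict().values())

    def test_pgan_with_zero_beta_matches_gan_lvr_discriminator_update(self, tiny_cohort):
        """With beta=0 the pgan generator objective reduces to gan_lvr's, so
        the first discriminator update must coincide bit-for-bit."""
        ex_params = []
        for variant, beta in (("gan_lvr", 25.0), ("pgan", 0.0)):
            cfg = _tiny_cfg(variant=variant,
                            weights=LossWeights(alpha=25.0, beta=beta))
            bundle = tr.build_bundle_for_config(cfg)
            ex = tr.example_from_record(tiny_cohort.subjects("train")[0], cfg)
            tr.train_step(bundle, ex, cfg)
            ex_params.append([p.value.copy() for p in bundle.discriminator_params()])
        assert all(np.array_equal(a, b) for a, b in zip(*ex_params))


class TestFit:
    def test_history_bookkeeping(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan", train_epochs=3)
        bundle, hist = tr.fit(tiny_cohort, cfg)
        assert len(hist.epochs) == 3
        for e in hist.epochs:
            assert np.isfinite(e["total_G"])
            assert e["val_vr"] is not None and np.isfinite(e["val_vr"])
        assert hist.best_epoch in range(3)

    def test_empty_training_split_rejected(self, tiny_cohort):
        import copy

        empty = copy.deepcopy(tiny_cohort)
        empty.split = {k: "test" for k in empty.split}
        with pytest.raises(ConfigError):
            tr.fit(empty, _tiny_cfg())

    def test_fit_is_deterministic(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan", train_epochs=2)
        _, h1 = tr.fit(tiny_cohort, cfg)
        _, h2 = tr.fit(tiny_cohort, cfg)
        assert h1.epochs == h2.epochs

    def test_smoke_convergence_unet_variant(self, tiny_cohort):
        """A pure-L1 U-Net should reduce its training loss within 25 epochs."""
        cfg = _tiny_cfg(variant="unet_lvr", train_epochs=25, lr0=1e-2)
        _, hist = tr.fit(tiny_cohort, cfg)
        assert hist.epochs[-1]["vr"] < hist.epochs[0]["vr"]


class TestPredictAndImpute:
    def test_predict_dual_arity_and_range(self, tiny_cohort):
        cfg = _tiny_cfg(variant="mpgan")
        bundle = tr.build_bundle_for_config(cfg)
        rec = tiny_cohort.subjects("train")[0]
        out = tr.predict(bundle, rec.scans["6m"])
        assert isinstance(out, tuple) and len(out) == 2
        for v in out:
            assert v.age_tag == "12m"
            assert v.normalized
            assert -1.0 < v.data.min() and v.data.max() < 1.0

    def test_single_contrast_bundle_rejects_pair(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan")
        bundle = tr.build_bundle_for_config(cfg)
        rec = tiny_cohort.subjects("train")[0]
        with pytest.raises(InputError):
            tr.predict(bundle, rec.scans["6m"])  # two contrasts to a 1-input model

    def test_unnormalized_input_rejected(self, tiny_cohort):
        cfg = _tiny_cfg(variant="pgan")
        bundle = tr.build_bundle_for_config(cfg)
        raw = Volume(np.zeros((16, 16, 16)) + 5.0, contrast="T1w")
        with pytest.raises(InputError):
            tr.predict(bundle, raw)

    def _bundles(self, seed=3):
        b612 = tr.build_bundle_for_config(
            _tiny_cfg(variant="mpgan", direction="6to12", seed=seed))
        b126 = tr.build_bundle_for_config(
            _tiny_cfg(variant="mpgan", direction="12to6", seed=seed))
        return b612, b126

    def test_impute_completes_cohort_without_touching_real_data(self):
        from longimpute.synthetic import PhantomSpec

        cohort = generate_cohort(PhantomSpec(shape=(16, 16, 16), seed=6), 6, 0.5,
                                 (0.7, 0.15, 0.15))
        real = {
            (r.subject_id, age, c): r.scans[age][c].data.copy()
            for r in cohort.records for age in r.present_ages
            for c in r.scans[age]
        }
        b612, b126 = self._bundles()
        cohort, manifest = tr.impute_cohort(cohort, b612, b126)
        assert all(r.is_complete() for r in cohort.records)
        pairs = set(zip(manifest["subject_id"], manifest["age_tag"]))
        assert len(pairs) == 3
        assert set(manifest["direction"]) == {"6to12", "12to6"}
        for (sid, age, c), data in real.items():
            rec = next(r for r in cohort.records if r.subject_id == sid)
            assert np.array_equal(rec.scans[age][c].data, data)

    def test_no_missing_is_a_no_op(self, tiny_cohort):
        import copy

        b612, b126 = self._bundles()
        cohort, manifest = tr.impute_cohort(copy.deepcopy(tiny_cohort), b612, b126)
        assert manifest.empty

    def test_imputing_a_test_subject_is_refused(self):
        from longimpute.synthetic import PhantomSpec

        cohort = generate_cohort(PhantomSpec(shape=(16, 16, 16), seed=6), 6, 0.5,
                                 (0.7, 0.15, 0.15))
        victim = next(r for r in cohort.records if r.missing_tag is not None)
        cohort.split[victim.subject_id] = "test"
        b612, b126 = self._bundles()
        with pytest.raises(DataError):
            tr.impute_cohort(cohort, b612, b126)
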