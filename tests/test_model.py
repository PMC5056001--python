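import json

import numpy as np
import pytest

from gaborvessel.metrics import roc_curve
from gaborvessel.model import (
    AzObjective,
    Dataset,
    GaborVesselModel,
    fitness_az,
    load_dataset,
    preprocess,
    run_pipeline,
)
from gaborvessel.phantom import PhantomConfig, generate_dataset, save_dataset


@pytest.fixture(scope="module")
def clean_single_vessel_train():
    cfg = PhantomConfig(
        width=96,
        height=96,
        n_vessels=1,
        branch_probability=0.0,
        noise_sigma=0.0,
        illumination_amplitude=0.0,
        vessel_fwhm=7.0,
        seed=42,
    )
    return Dataset.from_phantoms(generate_dataset(cfg, 3))


@pytest.fixture(scope="module")
def saved_dirs(tmp_path_factory):
    root = tmp_path_factory.mktemp("data")
    cfg = PhantomConfig(width=96, height=96, seed=500)
    save_dataset(generate_dataset(cfg, 3), root / "train")
    cfg2 = PhantomConfig(width=96, height=96, seed=600)
    save_dataset(generate_dataset(cfg2, 2), root / "test")
    return root / "train", root / "test"


class TestLoadDataset:
    def test_roundtrip(self, saved_dirs):
        train_dir, _ = saved_dirs
        ds = load_dataset(train_dir)
        assert len(ds) == 3
        for im, m in zip(ds.images, ds.masks):
            assert im.min() >= 0 and im.max() <= 1
            assert m.dtype == bool

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path)

    def test_missing_mask_named(self, tmp_path, saved_dirs):
        import shutil

        train_dir, _ = saved_dirs
        shutil.copy(train_dir / "img_000.png", tmp_path / "img_000.png")
        with pytest.raises(FileNotFoundError, match="mask_000"):
            load_dataset(tmp_path)

    def test_mask_binarized_at_128(self, saved_dirs):
        import imageio.v3 as iio

        train_dir, _ = saved_dirs
        stored = iio.imread(train_dir / "mask_000.png")
        assert set(np.unique(stored)) <= {0, 255}
        ds = load_dataset(train_dir)
        assert np.array_equal(ds.masks[0], stored >= 128)


class TestPreprocess:
    def test_involution_and_inversion(self, rng):
        img = rng.uniform(size=(16, 16))
        assert np.allclose(preprocess(preprocess(img)), img)
        assert np.allclose(preprocess(np.zeros((4, 4))), 1.0)


class TestFitnessAz:
    def test_matched_thickness_wins(self, clean_single_vessel_train):
        good = fitness_az(7, 2.9, clean_single_vessel_train, kappa=36)
        bad = fitness_az(1, 2.9, clean_single_vessel_train, kappa=36)
        assert good > bad

    def test_duplicated_training_set_identical(self, clean_single_vessel_train):
        ds = clean_single_vessel_train
        doubled = Dataset(
            images=ds.images * 2, masks=ds.masks * 2, names=[f"i{k}" for k in range(6)]
        )
        a = AzObjective(ds, kappa=12)(5, 2.0)
        b = AzObjective(doubled, kappa=12)(5, 2.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_memoization(self, clean_single_vessel_train):
        obj = AzObjective(clean_single_vessel_train, kappa=12)
        obj(5, 2.0)
        assert obj.n_evaluations == 1
        obj(5, 2.0)
        obj(5, 2.00004)  # same key after rounding to 4 decimals
        assert obj.n_evaluations == 1
        obj(6, 2.0)
        assert obj.n_evaluations == 2

    def test_out_of_box_clamped_with_warning(self, clean_single_vessel_train, caplog):
        obj = AzObjective(clean_single_vessel_train, kappa=12)
        with caplog.at_level("WARNING"):
            val = obj(40, 0.1)
        assert "clamped" in caplog.text
        assert val == obj(16, 1.3)


class TestFit:
    def test_huge_vmin_stops_after_one_generation(self, clean_single_vessel_train):
        model = GaborVesselModel(clean_single_vessel_train, kappa=12)
        res = model.fit(method="bumda", seed=0, v_min=1e9)
        assert len(res.history) == 1
        assert res.n_evaluations <= 20
        assert 1 <= res.params.tau <= 16
        assert "training Az" in res.summary()

    def test_grid_fit_small(self, clean_single_vessel_train):
        model = GaborVesselModel(clean_single_vessel_train, kappa=12)
        res = model.fit(method="grid", tau_values=[1, 7], ell_values=[2.9])
        assert res.params.tau == 7  # matched thickness beats tau=1
        assert res.method == "grid"

    def test_unknown_method_rejected(self, clean_single_vessel_train):
        with pytest.raises(ValueError, match="bumda.*grid|grid.*bumda"):
            GaborVesselModel(clean_single_vessel_train).fit(method="anneal")

    def test_training_az_at_least_initial_population_best(
        self, clean_single_vessel_train
    ):
        model = GaborVesselModel(clean_single_vessel_train, kappa=12)
        res = model.fit(method="bumda", seed=2, max_generations=5)
        first_gen_best = res.history[0].best_fitness
        assert res.best_az >= first_gen_best

    def test_evaluate_on_training_set_matches_training_az(
        self, clean_single_vessel_train
    ):
        model = GaborVesselModel(clean_single_vessel_train, kappa=12)
        res = model.fit(method="grid", tau_values=[5, 7], ell_values=[2.0, 2.9])
        report = res.evaluate(clean_single_vessel_train)
        assert report["test_az"] == pytest.approx(res.best_az, abs=1e-12)


class TestRunPipeline:
    def test_report_deterministic_and_files_written(self, saved_dirs, tmp_path):
        train_dir, test_dir = saved_dirs
        kwargs = dict(kappa=12, method="bumda", seed=3, max_generations=3)
        r1 = run_pipeline(train_dir, test_dir, tmp_path / "out", **kwargs)
        r2 = run_pipeline(train_dir, test_dir, **kwargs)
        assert r1 == r2
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "roc_test.csv").exists()
        assert (tmp_path / "out" / "bumda_trace.csv").exists()
        on_disk = json.loads((tmp_path / "out" / "report.json").read_text())
        assert on_disk == r1
        assert 0 <= r1["test_az"] <= 1
        assert 0 <= r1["mean_accuracy"] <= 1

    def test_empty_test_dir_fails_before_training(self, saved_dirs, tmp_path):
        train_dir, _ = saved_dirs
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            run_pipeline(train_dir, empty, kappa=12, max_generations=1)


class TestCli:
    def test_simulate_train_segment_evaluate(self, tmp_path):
        from click.testing import CliRunner

        from gaborvessel.cli import main

        runner = CliRunner()
        cfg = tmp_path / "phantom.yaml"
        cfg.write_text("width: 96\nheight: 96\n")
        data = tmp_path / "data"
        r = runner.invoke(
            main,
            ["simulate", "--out", str(data), "--n-images", "2", "--seed", "5",
             "--config", str(cfg)],
        )
        assert r.exit_code == 0, r.output
        assert (data / "img_001.png").exists()

        out_json = tmp_path / "train.json"
        r = runner.invoke(
            main,
            ["train", str(data), "--kappa", "12", "--max-gen", "2", "--out",
             str(out_json)],
        )
        assert r.exit_code == 0, r.output
        payload = json.loads(out_json.read_text())
        assert 1 <= payload["tau"] <= 16

        mask_png = tmp_path / "mask.png"
        r = runner.invoke(
            main,
            ["segment", str(data / "img_000.png"), "--tau", "7", "--ell", "2.9",
             "--kappa", "12", "--out", str(mask_png)],
        )
        assert r.exit_code == 0, r.output
        assert mask_png.exists()

        r = runner.invoke(
            main, ["evaluate", str(data), "--tau", "7", "--ell", "2.9", "--kappa", "12"]
        )
        assert r.exit_code == 0, r.output
        assert "Az" in r.output
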