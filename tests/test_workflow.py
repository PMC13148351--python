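import json

import numpy as np
import pytest
from click.testing import CliRunner
from oracles import gamma_brute

import filmdose as fd
from filmdose.cli import main as cli_main


def _write_calibration_set(tmp_path, models, doses, replicates=3, noise=0.0, seed=0):
    levels = []
    for i, d in enumerate(doses):
        films, pres = [], []
        for r in range(replicates):
            s = seed + 1000 * i + r
            plan = fd.DoseMap(np.full((20, 20), d), (0.254, 0.254))
            post = fd.film_from_dose(plan, models,
                                     fd.ScannerNoiseSpec(gaussian_sigma_fraction=noise, seed=s))
            zero = fd.DoseMap(np.zeros((20, 20)), (0.254, 0.254))
            pre = fd.film_from_dose(zero, models,
                                    fd.ScannerNoiseSpec(gaussian_sigma_fraction=noise,
                                                        seed=s + 500000))
            post_path = tmp_path / f"d{i}_r{r}_post.tif"
            pre_path = tmp_path / f"d{i}_r{r}_pre.tif"
            fd.write_tiff_film(post, post_path)
            fd.write_tiff_film(pre, pre_path)
            films.append(str(post_path))
            pres.append(str(pre_path))
        levels.append({"dose_gy": float(d), "films": films, "pre_films": pres})
    return levels


def _calibrate_config(tmp_path, levels):
    return fd.RunConfig(
        paths={"output_dir": str(tmp_path / "out")},
        calibration={
            "model_kind": "rational",
            "roi": [5, 5, 10, 10],
            "dose_range_gy": [0.0, 10.0],
            "levels": levels,
        },
    )


class TestRunCalibrate:
    def test_noise_free_recovery_is_quantization_limited(self, tmp_path, models):
        doses = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0]
        levels = _write_calibration_set(tmp_path, models, doses)
        fitted, report = fd.run_calibrate(_calibrate_config(tmp_path, levels))
        for ch in "RGB":
            np.testing.assert_allclose(fitted[ch].params, models[ch].params, rtol=5e-3)
            assert fitted[ch].r_squared > 0.99999
        assert (tmp_path / "out" / "models.json").exists()
        assert (tmp_path / "out" / "calibration_report.json").exists()

    def test_noisy_recovery_within_uncertainty(self, tmp_path, models):
        doses = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0]
        levels = _write_calibration_set(tmp_path, models, doses, noise=0.01, seed=7)
        fitted, _ = fd.run_calibrate(_calibrate_config(tmp_path, levels))
        for ch in "RGB":
            for p, p_true, s in zip(fitted[ch].params, models[ch].params,
                                    fitted[ch].param_sigma):
                assert abs(p - p_true) < 5 * max(s, 1e-6)

    def test_too_few_levels_rejected(self, tmp_path, models):
        levels = _write_calibration_set(tmp_path, models, [0.0, 2.0, 5.0], replicates=1)
        with pytest.raises(ValueError, match="4 dose levels"):
            fd.run_calibrate(_calibrate_config(tmp_path, levels))

    def test_missing_films_listed_in_error(self, tmp_path, models):
        levels = _write_calibration_set(tmp_path, models, [0.0, 2.0, 5.0, 8.0],
                                        replicates=1)
        levels[1]["films"] = [str(tmp_path / "ghost.tif")]
        with pytest.raises(FileNotFoundError, match="ghost.tif"):
            fd.run_calibrate(_calibrate_config(tmp_path, levels))


def _compare_setup(tmp_path, models, dose_scale=1.0, offset=(15, 20)):
    plan = fd.make_dose_phantom(
        fd.PhantomSpec("uniform_square", 5.0, 60.0, penumbra_sigma_mm=2.0,
                       grid_spacing_mm=2.0, margin_mm=10.0)
    )
    scaled = fd.DoseMap(plan.dose_gy * dose_scale, plan.pixel_spacing_mm)
    film, _ = fd.make_registration_case(
        scaled, offset, 0.0, fd.ScannerNoiseSpec(seed=0), models=models
    )
    plan_path = tmp_path / "plan.dcm"
    film_path = tmp_path / "film.tif"
    models_path = tmp_path / "models.json"
    fd.write_rtdose(plan, plan_path)
    fd.write_tiff_film(film, film_path)
    fd.save_models(models, models_path)
    return fd.RunConfig(
        paths={
            "film": str(film_path),
            "plan": str(plan_path),
            "models": str(models_path),
            "output_dir": str(tmp_path / "out"),
        },
        reconstruction={
            "method": "single",
            "channel": "R",
            "reference_transmittance": fd.reference_transmittance(),
            "median_size": 1,
            "wiener_window": 1,
        },
        registration={"flip_vertical": False, "rotate_180": False},
        gamma={"dd_percent": 3.0, "dta_mm": 3.0, "threshold_percent": 5.0,
               "normalization": "global"},
    )


class TestRunCompare:
    def test_zero_noise_end_to_end_passes_everywhere(self, tmp_path, models):
        config = _compare_setup(tmp_path, models)
        result, report = fd.run_compare(config)
        assert result.pass_rate == 1.0
        assert report["registration"]["offset_px"] == [15, 20]
        assert report["registration"]["angle_deg"] == 0.0
        saved = json.loads((tmp_path / "out" / "gamma_report.json").read_text())
        assert saved["gamma"]["pass_rate"] == 1.0
        assert (tmp_path / "out" / "measured_dose.dcm").exists()

    def test_ten_percent_dose_error_fails_on_plateau(self, tmp_path, models):
        config = _compare_setup(tmp_path, models, dose_scale=1.10)
        result, _ = fd.run_compare(config)
        assert result.pass_rate < 1.0
        # plateau pixels (5.5 vs 5.0 Gy) are > 3% of global max: they must fail
        assert result.pass_rate < 0.9

    def test_scaled_dose_gamma_matches_brute_force_oracle(self, models, ref_t):
        plan = fd.make_dose_phantom(
            fd.PhantomSpec("uniform_square", 5.0, 60.0, penumbra_sigma_mm=2.0,
                           grid_spacing_mm=4.0, margin_mm=8.0)
        )
        hot = fd.DoseMap(plan.dose_gy * 1.10, plan.pixel_spacing_mm)
        film = fd.film_from_dose(hot, models, fd.ScannerNoiseSpec(seed=0))
        measured = fd.single_channel_dose(film, models["R"], "R", ref_t)
        crit = fd.GammaCriteria(3.0, 3.0, 5.0, "global", search_radius_factor=20.0)
        res = fd.gamma_matrix(plan, measured, crit)
        oracle = gamma_brute(plan.dose_gy, measured.dose_gy,
                             plan.pixel_spacing_mm, 3.0, 3.0)
        m = res.evaluated_mask
        np.testing.assert_allclose(res.gamma[m], oracle[m], atol=1e-10)
        assert 0.0 < res.pass_rate < 1.0

    def test_missing_models_file_named_in_error(self, tmp_path, models):
        config = _compare_setup(tmp_path, models)
        config.paths["models"] = str(tmp_path / "nonexistent.json")
        with pytest.raises(FileNotFoundError, match="nonexistent.json"):
            fd.run_compare(config)

    def test_registration_floor_advises_manual_override(self, tmp_path, models):
        config = _compare_setup(tmp_path, models)
        config.registration["min_score"] = 1.1  # unreachable on purpose
        with pytest.raises(RuntimeError, match="manual"):
            fd.run_compare(config)

    def test_manual_override_bypasses_matching(self, tmp_path, models):
        config = _compare_setup(tmp_path, models)
        config.registration["manual_offset"] = [15, 20]
        config.registration["manual_angle"] = 0.0
        result, _ = fd.run_compare(config)
        assert result.pass_rate == 1.0

    def test_rerun_is_bit_identical(self, tmp_path, models):
        config = _compare_setup(tmp_path, models)
        fd.run_compare(config)
        first = (tmp_path / "out" / "gamma_report.json").read_text()
        fd.run_compare(config)
        assert (tmp_path / "out" / "gamma_report.json").read_text() == first


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            "paths:\n  film: f.tif\ngamma:\n  dd_percent: 2.0\n"
        )
        config = fd.RunConfig.from_file(path)
        assert config.paths["film"] == "f.tif"
        assert config.gamma["dd_percent"] == 2.0

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("nonsense:\n  a: 1\n")
        with pytest.raises(ValueError, match="unknown"):
            fd.RunConfig.from_file(path)


class TestCli:
    def test_synth_square_then_gamma_self_comparison(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "case")
        out = runner.invoke(cli_main, ["synth", "square", "--dose", "5", "--field-size",
                                       "60", "--spacing", "2", "--out-prefix", prefix])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, ["gamma", "--ref", f"{prefix}_plan.dcm",
                                       "--meas", f"{prefix}_plan.dcm"])
        assert out.exit_code == 0, out.output
        assert "100.00%" in out.output

    def test_dose_subcommand_writes_rtdose(self, tmp_path, models, ref_t):
        plan = fd.DoseMap(np.full((12, 12), 4.0), (1.0, 1.0))
        film = fd.film_from_dose(plan, models, fd.ScannerNoiseSpec(seed=0))
        film_path = tmp_path / "film.tif"
        models_path = tmp_path / "models.json"
        out_path = tmp_path / "dose.dcm"
        fd.write_tiff_film(film, film_path)
        fd.save_models(models, models_path)
        runner = CliRunner()
        out = runner.invoke(cli_main, ["dose", "--film", str(film_path),
                                       "--models", str(models_path),
                                       "--reference-t", str(ref_t),
                                       "--out", str(out_path)])
        assert out.exit_code == 0, out.output
        back = fd.read_rtdose(out_path)
        assert back.dose_gy.mean() == pytest.approx(4.0, rel=1e-3)
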