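"""Cohort model, pipeline orchestration, ingestion and CLI tests."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from eegfd.cli import main as cli_main
from eegfd.model import HFDCohortModel
from eegfd.pipeline import PipelineConfig, ingest_s1, run_cohort, run_subject
from eegfd.preprocessing import MONTAGE_19, PreprocessConfig, save_recording_text
from eegfd.simulate import CohortSpec, make_cohort, make_recording


@pytest.fixture(scope="module")
def cohort():
    return make_cohort(CohortSpec(seed=17))


@pytest.fixture(scope="module")
def results(cohort):
    return HFDCohortModel(cohort.covariates, cohort.channel_hfd).fit()


def synthetic_s1_frame(n_yc=24, n_ec=17, n_ad=67, seed=0):
    """S1-style per-subject sheet (synthetic stand-in for deposited data)."""
    c = make_cohort(
        CohortSpec(seed=seed, group_sizes={"YC": n_yc, "EC": n_ec, "AD": n_ad})
    )
    chan = c.channel_hfd.rename(columns={"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"})
    cov = c.covariates
    ncc = cov["serum_copper_umol_l"] - cov["ceruloplasmin_mg_dl"] * 10 * 0.0472
    frame = pd.DataFrame({"Age": cov["age"], "MMSE": cov["mmse"], "NCC": ncc})
    frame.loc[cov["group"] == "YC", "NCC"] = np.nan
    out = pd.concat([frame, chan], axis=1).reset_index(names="Subject")
    return out, c


class TestModel:
    def test_frame_carries_all_derived_columns(self, results):
        frame = results.frame
        for col in ("whole_brain_hfd", "hfd_parietal_left", "hars_parietal",
                    "ncc_umol_l"):
            assert col in frame.columns

    def test_descriptives_match_manual_means(self, cohort, results):
        desc = results.descriptives
        wb = cohort.channel_hfd.mean(axis=1)
        for g in ("YC", "EC", "AD"):
            manual = wb[cohort.covariates["group"] == g].mean()
            assert desc.loc[g, "hfd_mean"] == pytest.approx(manual, abs=1e-12)

    def test_ncc_computed_from_copper_panel(self, cohort, results):
        row = cohort.covariates[cohort.covariates["group"] == "AD"].iloc[0]
        expected = row["serum_copper_umol_l"] - row["ceruloplasmin_mg_dl"] * 0.472
        sid = cohort.covariates[cohort.covariates["group"] == "AD"].index[0]
        assert results.frame.loc[sid, "ncc_umol_l"] == pytest.approx(expected, abs=1e-9)

    def test_precomputed_ncc_overrides_panel(self, cohort):
        cov = cohort.covariates.copy()
        cov["ncc_umol_l"] = 9.99
        model = HFDCohortModel(cov, cohort.channel_hfd)
        assert (model.covariates["ncc_umol_l"] == 9.99).all()

    def test_from_dataframe_splits_channels(self, cohort):
        joined = cohort.covariates.join(cohort.channel_hfd)
        model = HFDCohortModel.from_dataframe(joined)
        assert set(model.channel_hfd.columns) == set(MONTAGE_19)
        assert "group" in model.covariates.columns

    def test_summary_mentions_key_sections(self, results):
        text = results.summary()
        for token in ("Descriptives", "parabola", "Full mixed ANOVA",
                      "Reduced models", "HArS"):
            assert token in text

    def test_mismatched_subjects_rejected(self, cohort):
        with pytest.raises(ValueError, match="covariates"):
            HFDCohortModel(cohort.covariates.iloc[:5], cohort.channel_hfd)

    def test_plots_render(self, results):
        ax = results.plot_age_curve()
        assert ax.get_xlabel() == "age (years)"
        ax2 = results.plot_hars()
        assert ax2.get_ylabel() == "HFD HArS"


class TestRunSubject:
    @pytest.fixture(scope="class")
    def flat_recording(self):
        return make_recording({ch: 1.5 for ch in MONTAGE_19}, duration_s=20,
                              fs=128, seed=23)

    def test_nineteen_channel_table(self, flat_recording):
        res = run_subject(flat_recording, PipelineConfig())
        assert len(res.channel_hfd) == 19
        assert res.n_windows == 10

    def test_flat_fd_profile_is_flat_within_tolerance(self, flat_recording):
        res = run_subject(flat_recording, PipelineConfig())
        cells = res.regional["hfd"]
        assert cells.max() - cells.min() < 0.2
        assert res.whole_brain == pytest.approx(1.5, abs=0.15)

    def test_unreadable_file_names_subject(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            run_subject(tmp_path / "missing.tsv")

    def test_artifact_threshold_drops_windows(self, flat_recording):
        rec = flat_recording
        spiked = rec.data.copy()
        spiked[0, 300] += 1e4
        from eegfd.preprocessing import EEGRecording

        noisy = EEGRecording(spiked, rec.fs, list(rec.channel_labels), "spiky")
        cfg = PipelineConfig(
            preprocessing=PreprocessConfig(artifact_abs_threshold_uv=1e3)
        )
        res = run_subject(noisy, cfg)
        assert res.n_rejected >= 1


class TestRunCohort:
    def test_fast_path_bundle_written_with_stamp(self, cohort, tmp_path):
        res = run_cohort(
            cohort.covariates, channel_hfd=cohort.channel_hfd,
            out_dir=tmp_path / "out",
        )
        report = (tmp_path / "out" / "report.txt").read_text()
        assert report.startswith("# eegfd")
        frame_head = (tmp_path / "out" / "cohort_frame.tsv").read_text().splitlines()[0]
        assert "config=" in frame_head
        assert res.full_anova is not None

    def test_rerun_is_deterministic(self, cohort):
        a = run_cohort(cohort.covariates, channel_hfd=cohort.channel_hfd)
        b = run_cohort(cohort.covariates, channel_hfd=cohort.channel_hfd)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.summary() == b.summary()

    def test_recordings_path(self, tmp_path):
        sizes = {"YC": 2, "EC": 2, "AD": 2}
        c = make_cohort(CohortSpec(seed=31, group_sizes=sizes),
                        emit_recordings=True, duration_s=10)
        res = run_cohort(c.covariates, recordings=c.recordings)
        assert len(res.frame) == 6
        assert res.frame["whole_brain_hfd"].between(1.0, 2.1).all()

    def test_both_inputs_rejected(self, cohort):
        with pytest.raises(ValueError, match="exactly one"):
            run_cohort(cohort.covariates, recordings={}, channel_hfd=cohort.channel_hfd)

    def test_unmatched_recordings_listed(self, cohort):
        rec = make_recording({ch: 1.5 for ch in MONTAGE_19}, 4, seed=0,
                             subject_id="ghost")
        with pytest.raises(ValueError, match="ghost"):
            run_cohort(cohort.covariates, recordings={"ghost": rec})


class TestIngestS1:
    def test_row_count_and_group_inference(self, tmp_path):
        frame, truth = synthetic_s1_frame()
        path = tmp_path / "s1.xlsx"
        frame.to_excel(path, index=False)
        cov, chan = ingest_s1(path)
        assert len(cov) == 108 and len(chan) == 108
        # MMSE-based rule recovers the generating groups
        assert (cov["group"].values == truth.covariates["group"].values).all()
        assert set(chan.columns) == set(MONTAGE_19)

    def test_missing_ncc_left_as_nan(self, tmp_path):
        frame, _ = synthetic_s1_frame(n_yc=4, n_ec=3, n_ad=5)
        path = tmp_path / "s1.csv"
        frame.to_csv(path, index=False)
        cov, _ = ingest_s1(path)
        assert cov.loc[cov["group"] == "YC", "ncc_umol_l"].isna().all()
        assert cov.loc[cov["group"] == "AD", "ncc_umol_l"].notna().all()

    def test_ingested_table_feeds_the_model(self, tmp_path):
        frame, _ = synthetic_s1_frame(n_yc=8, n_ec=8, n_ad=12, seed=4)
        path = tmp_path / "s1.xlsx"
        frame.to_excel(path, index=False)
        cov, chan = ingest_s1(path)
        res = HFDCohortModel(cov, chan).fit()
        assert res.descriptives.loc["AD", "n"] == 12

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="no channel columns"):
            ingest_s1(path)


class TestCLI:
    def test_simulate_then_cohort(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r1 = runner.invoke(cli_main, ["simulate", "--seed", "5", "--out", str(sim_dir)])
        assert r1.exit_code == 0, r1.output
        assert (sim_dir / "covariates.tsv").exists()
        r2 = runner.invoke(
            cli_main,
            ["cohort", "--covariates", str(sim_dir / "covariates.tsv"),
             "--channel-hfd", str(sim_dir / "channel_hfd.tsv"),
             "--out", str(tmp_path / "res")],
        )
        assert r2.exit_code == 0, r2.output
        assert "parabola" in r2.output

    def test_compute_on_text_recording(self, tmp_path):
        rec = make_recording({ch: 1.4 for ch in MONTAGE_19}, duration_s=6,
                             fs=128, seed=2)
        path = save_recording_text(rec, tmp_path / "rec.tsv")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["compute", str(path), "--kmax", "30"])
        assert res.exit_code == 0, res.output
        assert "whole-brain HFD" in res.output

    def test_sweep_command(self, tmp_path):
        rec = make_recording({"Cz": 1.5, "Pz": 1.5}, duration_s=6, fs=128, seed=3)
        path = save_recording_text(rec, tmp_path / "rec.tsv")
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["sweep", str(path), "--kmax-min", "2", "--kmax-max", "16"],
        )
        assert res.exit_code == 0, res.output
        assert "selected k_max" in res.output

    def test_compute_error_exit(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["compute", str(tmp_path)])
        assert res.exit_code != 0
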