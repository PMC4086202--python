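import numpy as np
import pandas as pd
import pytest

from costnet.connectivity import correlation_matrix
from costnet.preprocess import (
    mean_rt,
    normalize_run,
    segment_and_concatenate,
    SubjectTimeSeries,
)
from costnet.simulate import (
    RTModel,
    SimConfig,
    build_schedule,
    generate_cohort,
    generate_volume_fixture,
    planted_truth_report,
)

from conftest import tiny_roi_frame, tiny_sim_config, TINY_ASSIGNMENT


class TestSchedule:
    def test_default_tiling_covers_run(self):
        sched = build_schedule(146)
        assert len(sched) == 146
        assert (sched[:2] == "rest").all()
        counts = pd.Series(sched).value_counts()
        assert counts["SI"] == 48 and counts["ET"] == 48 and counts["CTL"] == 48

    def test_truncated_final_block(self):
        sched = build_schedule(10, block_len_frames=4, rest_frames=0)
        assert list(sched) == ["SI"] * 4 + ["ET"] * 4 + ["CTL"] * 2


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self):
        cfg = tiny_sim_config(seed=42)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(tiny_sim_config(seed=42))
        s = c1.subjects[0]
        np.testing.assert_array_equal(
            c1.timeseries[s].runs[0], c2.timeseries[s].runs[0]
        )
        pd.testing.assert_frame_equal(t1.couplings, t2.couplings)
        pd.testing.assert_frame_equal(c1.events, c2.events)

    def test_distinct_seeds_differ(self):
        c1, _ = generate_cohort(tiny_sim_config(seed=1))
        c2, _ = generate_cohort(tiny_sim_config(seed=2))
        s = c1.subjects[0]
        assert not np.allclose(c1.timeseries[s].runs[0], c2.timeseries[s].runs[0])

    def test_group_sizes_and_run_geometry(self):
        cohort, _ = generate_cohort(tiny_sim_config())
        assert len(cohort.group_subjects("HV")) == 6
        assert len(cohort.group_subjects("PD")) == 6
        for s in cohort.subjects:
            ts = cohort.timeseries[s]
            assert len(ts.runs) == 1
            assert ts.runs[0].shape == (50, 8)

    def test_noise_free_shared_factor_gives_unit_correlation(self):
        """With base coupling 1 and a single community, sigma = 0 and any
        two ROIs correlate perfectly."""
        table = tiny_roi_frame().iloc[:2].reset_index(drop=True)
        cfg = SimConfig(
            n_subjects_group1=1,
            n_subjects_group2=1,
            n_runs=1,
            frames_per_run=30,
            roi_table=table,
            module_assignment={"CtxA1": "a", "CtxA2": "a"},
            base_coupling=1.0,
            attenuated_edges=(),
            rt_model=RTModel(dlpfc_edge=None, vlpfc_edge=None),
            seed=3,
        )
        cohort, _ = generate_cohort(cfg)
        run = cohort.timeseries[cohort.subjects[0]].runs[0]
        r = np.corrcoef(run[:, 0], run[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_sample_correlation_approaches_closed_form(self):
        """The factor model implies corr = base.[same community] + coupling;
        with long series and no subject variability the sample correlation
        converges to it."""
        cfg = tiny_sim_config(
            n_subjects_group1=1,
            n_subjects_group2=1,
            frames_per_run=20_000,
            subject_coupling_sd=0.0,
            edge_noise_sd=0.0,
            rt_edge_coupling_sd=0.0,
            activity_coupling_gain=0.0,
            seed=11,
        )
        cohort, truth = generate_cohort(cfg)
        run = cohort.timeseries["HV01"].runs[0]
        names = cohort.timeseries["HV01"].roi_names
        r = np.corrcoef(run, rowvar=False)
        expect = truth.expected_correlations.set_index(["node_a", "node_b"])
        # planted cross-community edge (group 1: full coupling)
        i, j = names.index("CtxA1"), names.index("CtxB1")
        assert r[i, j] == pytest.approx(
            expect.loc[("CtxA1", "CtxB1"), "r_group1"], abs=0.03
        )
        # same-community pair without planted edge
        i, j = names.index("CtxA2"), names.index("CtxA3")
        assert r[i, j] == pytest.approx(cfg.base_coupling, abs=0.03)
        # cross-community pair without planted edge
        i, j = names.index("CtxA3"), names.index("CtxB2")
        assert r[i, j] == pytest.approx(0.0, abs=0.03)

    def test_group_difference_only_on_attenuated_edges(self):
        truth = generate_cohort(tiny_sim_config())[1]
        tbl = truth.expected_correlations
        att = tbl[tbl["attenuated"]]
        rest = tbl[~tbl["attenuated"]]
        assert (att["r_group1"] > att["r_group2"]).all()
        assert (rest["r_group1"] == rest["r_group2"]).all()

    def test_measured_rt_tracks_model_rt(self):
        cohort, truth = generate_cohort(tiny_sim_config(seed=5))
        measured = pd.Series(
            {
                s: mean_rt(cohort.events[cohort.events["subject"] == s], "SI")
                for s in cohort.subjects
            }
        )
        # press-interval noise (40 ms model + 30 ms timing) averages out
        err = (measured - truth.rt_true_ms).abs()
        assert err.median() < 60.0
        assert measured.corr(truth.rt_true_ms) > 0.8

    def test_activity_index_correlates_with_subject_factor(self):
        cfg = tiny_sim_config(
            n_subjects_group1=12, n_subjects_group2=1, frames_per_run=100, seed=9
        )
        cohort, truth = generate_cohort(cfg)
        idx = {}
        for s in cohort.group_subjects("HV"):
            ts = cohort.timeseries[s]
            normed = SubjectTimeSeries(
                [normalize_run(r) for r in ts.runs],
                ts.roi_names,
                ts.tr_seconds,
                ts.schedule,
            )
            cond = segment_and_concatenate(normed, "SI", 0.0)
            from costnet.preprocess import subcortical_activity_index

            idx[s] = subcortical_activity_index(cond, cohort.roi_table)
        idx = pd.DataFrame(idx).T
        factor = truth.subject_factor[idx.index]
        assert idx["PutL"].corr(factor) > 0.5
        assert idx["ThalL"].corr(factor) < -0.5

    def test_variance_budget_violation_names_node(self):
        with pytest.raises(ValueError, match="CtxA1"):
            tiny_sim_config(
                attenuated_edges=(("CtxA1", "CtxB1"), ("CtxA1", "CtxB2")),
                rt_model=RTModel(dlpfc_edge=None, vlpfc_edge=None),
            )

    @pytest.mark.parametrize(
        "overrides, message",
        [
            (dict(attenuation_multiplier=1.5), "multiplier"),
            (dict(n_runs=0), "n_runs"),
            (dict(tr_seconds=0.0), "tr_seconds"),
            (
                dict(attenuated_edges=(("CtxA1", "NoSuch"),)),
                "unknown ROI",
            ),
        ],
    )
    def test_invalid_configs_rejected(self, overrides, message):
        with pytest.raises(ValueError, match=message):
            tiny_sim_config(**overrides)


class TestTruthReport:
    def test_attenuated_rows_flagged(self):
        truth = generate_cohort(SimConfig(seed=0))[1]
        report = planted_truth_report(truth)
        assert int(report["attenuated"].sum()) == 5
        assert len(report) == 7  # 5 attenuated + 2 RT edges

    def test_zero_effect_config_has_zero_effects(self):
        cfg = tiny_sim_config(
            attenuation_multiplier=1.0,
            rt_model=RTModel(
                dlpfc_edge=("CtxA2", "PutL"),
                dlpfc_slope_ms=0.0,
                vlpfc_edge=("CtxB2", "CaudL"),
                vlpfc_slope_ms=0.0,
            ),
        )
        report = planted_truth_report(generate_cohort(cfg)[1])
        assert np.allclose(report["effect_z_diff"], 0.0)
        assert np.allclose(report["rt_slope_ms"], 0.0)

    def test_rt_slope_signs_echo_config(self):
        report = planted_truth_report(generate_cohort(SimConfig(seed=0))[1])
        slopes = report.set_index("edge")["rt_slope_ms"]
        assert slopes["Caudate1|DLPFC1"] < 0
        assert slopes["VLPFC2|VS2"] > 0


class TestVolumeFixture:
    def test_constant_signal_recovered(self, tiny_roi_table):
        from costnet.preprocess import extract_roi_timeseries

        signals = np.zeros((5, len(tiny_roi_table)))
        signals[:, 2] = 5.0
        fix = generate_volume_fixture(
            tiny_roi_table, frames=5, seed=0, noise_sd=0.0, signals=signals
        )
        out = extract_roi_timeseries(fix.data, fix.affine, fix.peak_table)
        assert np.allclose(out[:, 2], 5.0)
        assert np.allclose(out[:, 0], 0.0)

    def test_deterministic_volume(self, tiny_roi_table):
        a = generate_volume_fixture(tiny_roi_table, frames=10, seed=4, noise_sd=1.0)
        b = generate_volume_fixture(tiny_roi_table, frames=10, seed=4, noise_sd=1.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_colliding_peaks_listed(self):
        table = tiny_roi_frame().iloc[:2].reset_index(drop=True)
        table.loc[1, ["x", "y", "z"]] = table.loc[0, ["x", "y", "z"]] + 1.0
        with pytest.raises(ValueError, match="overlapping"):
            generate_volume_fixture(table, frames=2, seed=0)
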