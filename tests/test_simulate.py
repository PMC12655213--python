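"""Forward simulation: schedules, sampling windows, residual error."""

import math

import numpy as np
import pytest
from scipy import stats

from mcubed.cohort import generate_cohort
from mcubed.simulate import (
    apply_residual_error, build_dose_schedule, draw_n_samples,
    draw_sampling_times, individual_parameters, resolve_windows,
    simulate_pooled, simulate_study, dataset_summary,
)
from mcubed.studies import (DesignSpec, RenalBand, ResidualSpec,
                            SamplingWindow, SourceModel,
                            typical_cl_at_reference)
from mcubed.cohort import generate_cohorts


def make_model(bsv=None, sigma2=0.04):
    return SourceModel(n_compartments=1, cl_formula_kind="linear",
                       cl_coefficients=(0.75, 0.045),
                       volume_params={"V1": 40.0}, bsv=bsv or {},
                       residual=ResidualSpec("proportional", sigma2))


PATIENT = {"ID": 1, "AGE": 60.0, "BW": 80.0, "CLCR": 50.0, "SEX": 1}


class TestDoseSchedule:
    def test_plain_maintenance_schedule(self):
        design = DesignSpec(dose_mg=1000.0, interval_h=12.0, infusion_h=1.0,
                            steady_state_only=False)
        events = build_dose_schedule(PATIENT, design)
        assert [ev.time for ev in events] == [0.0, 12.0, 24.0, 36.0, 48.0,
                                              60.0]
        assert all(ev.rate == 1000.0 for ev in events)

    def test_renal_band_lookup(self):
        design = DesignSpec(
            dose_mg=1000.0, interval_h=12.0, infusion_h=1.0,
            steady_state_only=False,
            renal_table=[RenalBand(0.0, 30.0, 1000.0, 24.0),
                         RenalBand(30.0, 1000.0, 1000.0, 12.0)])
        low = dict(PATIENT, CLCR=25.0)
        events = build_dose_schedule(low, design)
        assert events[1].time - events[0].time == 24.0

    def test_weight_based_loading_dose(self):
        design = DesignSpec(dose_mg=1000.0, interval_h=12.0, infusion_h=1.0,
                            loading_dose_mg_per_kg=25.0,
                            steady_state_only=False)
        events = build_dose_schedule(PATIENT, design)
        assert events[0].amount == pytest.approx(25.0 * 80.0)
        assert events[1].amount == 1000.0

    def test_steady_state_schedule_long_enough(self):
        design = DesignSpec(dose_mg=1000.0, interval_h=12.0, infusion_h=1.0,
                            steady_state_only=True)
        events = build_dose_schedule(PATIENT, design, make_model())
        # at least 7 intervals or 5 terminal half-lives
        assert len(events) >= 8


class TestIndividualParameters:
    def test_zero_bsv_reproduces_typical(self):
        model = make_model(bsv={"CL": 0.0})
        p = individual_parameters(PATIENT, model, 0)
        assert p["CL"] == pytest.approx(
            typical_cl_at_reference(model, 50.0))

    def test_lognormal_variance_recovered(self):
        model = make_model(bsv={"CL": 0.09})
        rng = np.random.default_rng(5)
        logs = [math.log(individual_parameters(PATIENT, model, rng)["CL"])
                for _ in range(20_000)]
        assert np.var(logs, ddof=1) == pytest.approx(0.09, abs=0.004)


class TestSamplingTimes:
    def _design(self, windows):
        return DesignSpec(dose_mg=1000.0, interval_h=12.0, infusion_h=1.0,
                          sampling_windows=windows, steady_state_only=False)

    def test_trough_draws_within_window(self):
        design = self._design([SamplingWindow("trough")])
        schedule = build_dose_schedule(PATIENT, design)
        last = schedule[-1].time
        times = draw_sampling_times(schedule, design, 200,
                                    np.random.default_rng(0))
        for t, tag in times:
            assert tag == "trough"
            assert last + 11.5 <= t <= last + 12.0

    def test_uniformity_within_window(self):
        design = self._design([SamplingWindow("peak", 1.0, 2.0)])
        schedule = build_dose_schedule(PATIENT, design)
        last = schedule[-1].time
        times = np.array([t for t, _ in draw_sampling_times(
            schedule, design, 10_000, np.random.default_rng(1))])
        u = (times - last - 1.0)
        assert stats.kstest(u, stats.uniform(0, 1).cdf).pvalue > 0.01

    def test_no_windows_defaults_to_trough(self):
        design = self._design([])
        windows = resolve_windows(design, 12.0, 1.0)
        assert [w.tag for w in windows] == ["trough"]

    def test_truncated_poisson_sample_counts(self):
        rng = np.random.default_rng(2)
        counts = [draw_n_samples(1.8, rng) for _ in range(20_000)]
        assert min(counts) >= 1
        assert np.mean(counts) == pytest.approx(1.8, abs=0.03)
        assert all(draw_n_samples(1.0, rng) == 1 for _ in range(50))


class TestResidualError:
    def test_zero_variance_identity(self):
        spec = ResidualSpec("proportional", 0.0)
        assert apply_residual_error(12.3, spec, 0) == 12.3

    def test_additive_censoring_fraction(self):
        # c = 0.1 with additive sigma = 1: P(censored) = Phi(-0.1)
        spec = ResidualSpec("additive", 0.0)
        spec.kind, spec.sigma2 = "additive", 1.0
        rng = np.random.default_rng(3)
        n = 20_000
        censored = sum(math.isnan(apply_residual_error(0.1, spec, rng))
                       for _ in range(n))
        expected = stats.norm.cdf(-0.1)
        assert censored / n == pytest.approx(expected, abs=0.01)

    def test_proportional_cv(self):
        spec = ResidualSpec("proportional", 0.04)
        rng = np.random.default_rng(4)
        ys = np.array([apply_residual_error(20.0, spec, rng)
                       for _ in range(50_000)])
        ys = ys[~np.isnan(ys)]
        assert ys.std() / ys.mean() == pytest.approx(0.2, abs=0.005)


class TestStudySimulation:
    def test_noise_free_observations_match_solver(self, vanco_studies):
        import copy
        study = copy.deepcopy(vanco_studies[5])       # trough-only study
        study.source_model.bsv = {}
        study.source_model.residual = ResidualSpec("proportional", 0.0)
        cohort = generate_cohort(study, 9)
        frame = simulate_study(cohort, study, 9)
        obs = frame[frame["EVID"] == 0]
        from mcubed.compartmental import DoseEvent, concentration
        for pid, grp in obs.groupby("ID"):
            doses = frame[(frame["ID"] == pid) & (frame["EVID"] == 1)]
            events = [DoseEvent(r.TIME, r.AMT, r.AMT / r.RATE)
                      for r in doses.itertuples()]
            params = {"CL": study.source_model.typical_cl(grp["CLCR"]
                                                          .iloc[0]),
                      **study.source_model.volume_params}
            expected = concentration(params, events,
                                     grp["TIME"].to_numpy())
            assert np.allclose(grp["DV"].to_numpy(), expected, rtol=1e-10)

    def test_observation_count_without_censoring(self, vanco_studies):
        import copy
        study = copy.deepcopy(vanco_studies[9])       # 14-patient study
        study.design.samples_per_patient = 1.0        # degenerate: always 1
        study.source_model.residual = ResidualSpec("proportional", 0.0)
        cohort = generate_cohort(study, 1)
        frame = simulate_study(cohort, study, 1)
        assert (frame["EVID"] == 0).sum() == 14
        assert frame.attrs["n_censored"] == 0

    def test_pooled_dataset_structure(self, vanco_studies):
        studies = vanco_studies[:3]
        cohorts = generate_cohorts(studies, 4)
        frame = simulate_pooled(studies, cohorts, 4)
        # every observation row has a preceding dose row for its ID
        for pid, grp in frame.groupby("ID"):
            first_obs = grp[grp["EVID"] == 0]["TIME"].min()
            first_dose = grp[grp["EVID"] == 1]["TIME"].min()
            assert first_dose <= first_obs
        # EVID/MDV consistency
        assert (frame.loc[frame["EVID"] == 1, "MDV"] == 1).all()
        assert (frame.loc[frame["EVID"] == 0, "MDV"] == 0).all()
        assert frame.loc[frame["EVID"] == 0, "DV"].gt(0).all()
        summary = dataset_summary(frame)
        assert summary["n_patients"] == sum(s.n_patients for s in studies)

    def test_label_columns_union(self, vanco_studies):
        studies = [vanco_studies[1], vanco_studies[4]]   # labelled+plain
        cohorts = generate_cohorts(studies, 8)
        frame = simulate_pooled(studies, cohorts, 8)
        col = "LABEL_hematologic malignancy"
        assert col in frame.columns
        flagged = frame.loc[frame[col] == 1, "STUDY"].unique()
        assert list(flagged) == ["buelga_2005"]
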