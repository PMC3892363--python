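"""Chamber trace fitting, flux conversion, QC and closure pairing."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from mesoflux.chamber import (ChamberTrace, PairingError, TraceFitError,
                              concentration_slope_to_flux, default_deadband,
                              fit_record, fit_trace_slope, fit_traces,
                              flux_to_concentration_slope, has_flag,
                              pair_cycle, qc_filter)
from mesoflux.config import RunConfig, SimConfig
from mesoflux.simulate import synthesize_trace


def make_trace(co2, chamber_type="transparent", **kw):
    t = np.arange(len(co2), dtype=float)
    defaults = dict(closure_id="x", collar_id="C01", chamber_type=chamber_type,
                    timestamp=dt.datetime(2006, 11, 10, 12),
                    volume_m3=0.004823, area_m2=0.0278, t_air_c=10.0,
                    pressure_pa=101325.0)
    defaults.update(kw)
    return ChamberTrace(t=t, co2=np.asarray(co2, dtype=float), **defaults)


def ols_oracle(x, y):
    """Independent closed-form OLS on fsum-accumulated normal equations."""
    n = len(x)
    sx = math.fsum(x)
    sy = math.fsum(y)
    sxx = math.fsum(xi * xi for xi in x)
    sxy = math.fsum(xi * yi for xi, yi in zip(x, y))
    syy = math.fsum(yi * yi for yi in y)
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / n
    ss_res = math.fsum((yi - slope * xi - intercept) ** 2
                       for xi, yi in zip(x, y))
    ss_tot = syy - sy * sy / n
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    se = math.sqrt(ss_res / (n - 2) / (sxx - sx * sx / n))
    return slope, r2, se


class TestFitTraceSlope:
    def test_exact_line_recovers_slope_and_unit_r2(self):
        t = np.arange(145.0)
        trace = make_trace(400.0 + 0.05 * t)
        slope, r2, se = fit_trace_slope(trace, deadband_s=20, window_s=90)
        assert slope == pytest.approx(0.05, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_trace_gives_zero_slope(self):
        trace = make_trace(np.full(145, 400.0))
        slope, r2, _ = fit_trace_slope(trace, 20, 90)
        assert slope == 0.0
        assert r2 == 0.0

    def test_matches_independent_ols_oracle_on_noisy_traces(self, rng):
        for _ in range(100):
            n = int(rng.integers(120, 160))
            slope_true = rng.normal(0, 0.3)
            co2 = 400 + slope_true * np.arange(n) + rng.normal(0, 0.5, n)
            trace = make_trace(np.maximum(co2, 1.0))
            deadband = float(rng.choice([20.0, 50.0]))
            window = 60.0
            slope, r2, se = fit_trace_slope(trace, deadband, window)
            mask = (trace.t >= deadband) & (trace.t < deadband + window)
            o_slope, o_r2, o_se = ols_oracle(trace.t[mask], trace.co2[mask])
            assert slope == pytest.approx(o_slope, rel=1e-12)
            assert r2 == pytest.approx(o_r2, rel=1e-9, abs=1e-12)
            assert se == pytest.approx(o_se, rel=1e-9, abs=1e-12)

    def test_window_is_half_open(self):
        trace = make_trace(400 + 0.1 * np.arange(145.0))
        # [20, 110) at 1 Hz holds exactly 90 samples
        mask = (trace.t >= 20) & (trace.t < 110)
        assert mask.sum() == 90

    def test_short_trace_is_explicit_failure_not_zero(self):
        trace = make_trace(400 + 0.05 * np.arange(60.0), chamber_type="opaque")
        with pytest.raises(TraceFitError):
            fit_trace_slope(trace, 50, 90)


class TestDeadbands:
    def test_paper_rule_values(self):
        assert default_deadband("opaque") == 50.0
        assert default_deadband("transparent") == 20.0
        assert RunConfig().window_s == 90.0

    def test_unknown_chamber_type_rejected(self):
        with pytest.raises(ValueError):
            default_deadband("mirrored")


class TestSlopeToFlux:
    def test_worked_ideal_gas_example(self):
        # n = PV/RT = 101325*0.00482/(8.314*283.15) = 0.2075 mol
        flux = concentration_slope_to_flux(0.05, 0.00482, 0.0314, 283.15, 101325)
        assert flux == pytest.approx(0.330, abs=5e-4)

    def test_zero_slope_zero_flux(self):
        assert concentration_slope_to_flux(0.0, 0.01, 0.03, 280.0, 1e5) == 0.0

    def test_linearity_in_volume(self):
        f1 = concentration_slope_to_flux(0.05, 0.005, 0.03, 283.0, 101325)
        f2 = concentration_slope_to_flux(0.05, 0.010, 0.03, 283.0, 101325)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_rejects_nonfinite_and_nonpositive(self):
        with pytest.raises(ValueError):
            concentration_slope_to_flux(np.nan, 0.005, 0.03, 283.0, 101325)
        with pytest.raises(ValueError):
            concentration_slope_to_flux(0.05, -1.0, 0.03, 283.0, 101325)

    def test_inverse_conversion_round_trips(self):
        m = flux_to_concentration_slope(1.7, 0.0048, 0.0278, 283.15, 101325)
        back = concentration_slope_to_flux(m, 0.0048, 0.0278, 283.15, 101325)
        assert back == pytest.approx(1.7, rel=1e-14)


class TestObservationRoundTrip:
    """synthesize -> fit -> convert recovers the generating flux."""

    @pytest.mark.parametrize("chamber_type,flux", [
        ("transparent", -2.4), ("transparent", 0.0), ("opaque", 1.3)])
    def test_noise_free_recovery_is_exact(self, chamber_type, flux, rng):
        config = SimConfig(trace_noise_sd_ppm=0.0)
        trace = synthesize_trace(flux, config, chamber_type, rng,
                                 temperature_c=8.0, drawdown_flux=2.0,
                                 par_out=300.0)
        record = fit_record(trace)
        assert record.flux == pytest.approx(flux, abs=1e-10)
        if flux == 0.0:
            # constant trace apart from the (frozen) mixing transient
            window = trace.co2[trace.t >= 20]
            assert np.ptp(window) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_three_se(self, rng):
        config = SimConfig()
        misses = 0
        for flux in rng.normal(0, 2, size=50):
            trace = synthesize_trace(float(flux), config, "opaque", rng,
                                     temperature_c=5.0)
            record = fit_record(trace)
            se_flux = record.slope_se * abs(record.flux / record.slope) \
                if record.slope != 0 else np.inf
            if abs(record.flux - flux) > 3 * se_flux:
                misses += 1
        assert misses <= 2  # ~0.3% expected rate; allow a couple at n=50

    def test_sign_convention(self, rng):
        config = SimConfig(trace_noise_sd_ppm=0.0)
        resp = fit_record(synthesize_trace(0.8, config, "opaque", rng,
                                           temperature_c=5.0))
        photo = fit_record(synthesize_trace(-3.0, config, "transparent", rng,
                                            temperature_c=5.0, par_out=500.0))
        assert resp.flux > 0
        assert photo.flux < 0

    def test_opaque_daytime_drawdown_biases_early_window_low(self, rng):
        config = SimConfig(trace_noise_sd_ppm=0.0, transient_amp_ppm=0.0)
        trace = synthesize_trace(1.0, config, "opaque", rng,
                                 temperature_c=5.0, drawdown_flux=3.0)
        early, _, _ = fit_trace_slope(trace, 0, 50)
        late, _, _ = fit_trace_slope(trace, 50, 90)
        assert early < late

    def test_batch_fit_matches_per_trace_fit(self, short_sim, short_runconfig):
        sub_meta = short_sim.traces.meta.iloc[:40]
        from mesoflux.chamber import TraceSet
        ts = TraceSet(meta=sub_meta.reset_index(drop=True),
                      t=short_sim.traces.t, co2=short_sim.traces.co2[:40])
        batch = fit_traces(ts, short_runconfig)
        for i, trace in enumerate(ts.iter_traces()):
            rec = fit_record(trace, short_runconfig)
            assert batch["flux"].iloc[i] == pytest.approx(rec.flux, rel=1e-12)
            assert batch["r2"].iloc[i] == pytest.approx(rec.r2, rel=1e-9)


class TestQcFilter:
    def make_records(self):
        return pd.DataFrame({
            "closure_id": ["a", "b", "c"],
            "collar_id": ["C01"] * 3,
            "chamber_type": ["transparent"] * 3,
            "timestamp": pd.to_datetime(["2006-11-10 02:00",
                                         "2006-11-10 12:00",
                                         "2006-11-10 13:00"]),
            "flux": [0.5, -2.0, -1.0],
            "slope": [0.07, -0.3, -0.15],
            "r2": [0.5, 0.99, 0.5],
            "slope_se": [0.01] * 3,
            "deadband_s": [20.0] * 3, "window_s": [90.0] * 3,
            "par_in": [0.0, 300.0, 200.0],
            "par_out": [0.0, 500.0, 300.0],
            "temperature_c": [5.0] * 3,
            "qc_flags": ["", "", ""],
        })

    def test_night_rain_poor_fit_flags(self):
        records = self.make_records()
        env = pd.DataFrame({
            "timestamp": pd.to_datetime(["2006-11-10 02:00",
                                         "2006-11-10 12:00",
                                         "2006-11-10 13:00"]),
            "rain": [False, True, False]})
        out = qc_filter(records, env)
        assert has_flag(out, "night").tolist() == [True, False, False]
        assert has_flag(out, "rain").tolist() == [False, True, False]
        # row 0: r2 low AND |slope| above floor -> poor_fit; row 1 clean fit
        assert has_flag(out, "poor_fit").tolist() == [True, False, True]

    def test_clean_daytime_record_unflagged(self):
        records = self.make_records().iloc[[1]]
        out = qc_filter(records)
        assert out["qc_flags"].iloc[0] == ""

    def test_low_slope_low_r2_is_not_poor_fit(self):
        records = self.make_records()
        records.loc[0, "slope"] = 0.001  # below noise floor
        out = qc_filter(records)
        assert not has_flag(out, "poor_fit").iloc[0]

    def test_unknown_rule_key_rejected(self):
        with pytest.raises(ValueError, match="unknown QC rule"):
            qc_filter(self.make_records(), nighttime_cutoff=3.0)

    def test_flag_counts_match_brute_force_recount(self, short_sim,
                                                   short_runconfig):
        from mesoflux.pipeline import stage_flux
        records = stage_flux(short_sim.traces, short_sim.env, short_runconfig)
        day_tr = records[(records["chamber_type"] == "transparent")
                         & ~has_flag(records, "night")
                         & ~has_flag(records, "rain")
                         & ~has_flag(records, "poor_fit")]
        # independent recount from raw columns
        env = short_sim.env.set_index("timestamp")
        n_expected = 0
        for row in records.itertuples(index=False):
            if row.chamber_type != "transparent":
                continue
            if row.par_out < short_runconfig.night_par_threshold:
                continue
            hour = pd.Timestamp(row.timestamp).floor("h")
            if bool(env.loc[hour, "rain"]):
                continue
            if (row.r2 < short_runconfig.r2_threshold
                    and abs(row.slope) > short_runconfig.slope_noise_floor_ppm_s):
                continue
            n_expected += 1
        assert len(day_tr) == n_expected


class TestPairCycle:
    def rec(self, ctype, hour, collar="C01", minute=0):
        return {
            "closure_id": f"{collar}-{hour}-{ctype[0]}",
            "collar_id": collar, "chamber_type": ctype,
            "timestamp": pd.Timestamp(2006, 11, 10, hour, minute),
            "flux": -1.0 if ctype == "transparent" else 0.5,
            "slope": 0.0, "r2": 1.0, "slope_se": 0.0, "deadband_s": 20.0,
            "window_s": 90.0, "par_in": 100.0, "par_out": 200.0,
            "temperature_c": 5.0, "qc_flags": "",
        }

    def test_one_transparent_one_opaque_pairs(self):
        records = pd.DataFrame([self.rec("transparent", 12, minute=0),
                                self.rec("opaque", 12, minute=5)])
        pairs, unpaired = pair_cycle(records)
        assert len(pairs) == 1 and len(unpaired) == 0
        assert pairs["nee"].iloc[0] == -1.0
        assert pairs["reco"].iloc[0] == 0.5

    def test_opaque_only_hour_reports_reco_only(self):
        pairs, unpaired = pair_cycle(pd.DataFrame([self.rec("opaque", 3)]))
        assert len(pairs) == 1
        assert np.isnan(pairs["nee"].iloc[0])
        assert len(unpaired) == 1

    def test_duplicate_same_type_closure_is_ambiguity_error(self):
        records = pd.DataFrame([self.rec("opaque", 12, minute=5),
                                self.rec("opaque", 12, minute=40)])
        records.loc[1, "closure_id"] = "dup"
        with pytest.raises(PairingError, match="dup"):
            pair_cycle(records)

    def test_pair_count_matches_counting_oracle(self, short_sim,
                                                short_runconfig):
        records = fit_traces(short_sim.traces, short_runconfig)
        pairs, _ = pair_cycle(records)
        both = pairs.dropna(subset=["nee", "reco"])
        meta = short_sim.traces.meta.copy()
        meta["hour"] = pd.to_datetime(meta["timestamp"]).dt.floor("h")
        counts = meta.groupby(["collar_id", "hour"])["chamber_type"].nunique()
        assert len(both) == int((counts == 2).sum())
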