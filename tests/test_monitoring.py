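"""Phase I estimation and Phase II chart execution."""

import json
import math

import numpy as np
import pytest

from vsiewma import (
    ChartDesign,
    estimate_eta0,
    run_chart,
    transform_observation,
    uti_phases,
    zone_of,
)
from vsiewma.core import MU0, TRANSFORM_POWER
from vsiewma.errors import DataError, DomainError, InsufficientDataError
from vsiewma.monitoring import read_observations


class TestEstimateEta0:
    def test_constant_series(self):
        assert estimate_eta0([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_uti_phase1_mean_matches_compensated_sum(self):
        p1, _ = uti_phases()
        want = math.fsum(p1) / len(p1)
        assert estimate_eta0(p1) == pytest.approx(want, rel=1e-14)

    def test_empty_and_invalid(self):
        with pytest.raises(InsufficientDataError):
            estimate_eta0([])
        with pytest.raises(DataError):
            estimate_eta0([0.2, -0.1])


class TestRunChart:
    def test_fixed_point_stream_never_alarms(self, ref_design):
        """Feeding the observation whose transform equals the process mean
        keeps the statistic pinned at the center line."""
        eta = 0.4
        x_fix = eta * MU0**3.6
        session = run_chart([x_fix] * 50, ref_design, eta_hat=eta)
        assert session.alarms == []
        target = MU0 * eta**TRANSFORM_POWER
        assert all(r.z == pytest.approx(target, rel=1e-12)
                   for r in session.records)
        assert all(r.zone == "CR" for r in session.records)

    def test_recursion_replay_identity(self, ref_design):
        rng = np.random.default_rng(3)
        xs = rng.exponential(0.5, size=200)
        session = run_chart(xs, ref_design, eta_hat=0.5)
        z = session.z0
        for r, x in zip(session.records, xs):
            z = ref_design.lam * transform_observation(x) \
                + (1 - ref_design.lam) * z
            assert r.z == z  # bit-identical replay

    def test_scale_equivariance(self, ref_design):
        """Doubling both the data and the estimate leaves the normalized
        trajectory, the zones and the alarms unchanged."""
        rng = np.random.default_rng(4)
        xs = rng.exponential(1.0, size=300)
        a = run_chart(xs, ref_design, eta_hat=1.0)
        b = run_chart(2.0 * xs, ref_design, eta_hat=2.0)
        sf = 2.0**TRANSFORM_POWER
        assert [r.zone for r in a.records] == [r.zone for r in b.records]
        assert a.alarms == b.alarms
        for ra, rb in zip(a.records, b.records):
            assert rb.z == pytest.approx(sf * ra.z, rel=1e-12)

    def test_zone_matches_shared_classifier(self, ref_design):
        rng = np.random.default_rng(5)
        xs = rng.exponential(0.8, size=200)
        session = run_chart(xs, ref_design, eta_hat=0.8)
        sf = session.scale_factor
        for r in session.records:
            assert r.zone == zone_of(r.z / sf, ref_design.limits)

    def test_interval_follows_previous_zone(self, ref_design):
        rng = np.random.default_rng(6)
        xs = rng.exponential(0.8, size=200)
        session = run_chart(xs, ref_design, eta_hat=0.8)
        assert session.records[0].interval_used == ref_design.h1
        for prev, cur in zip(session.records, session.records[1:]):
            expected = ref_design.h1 if prev.zone == "CR" else ref_design.h2
            assert cur.interval_used == expected
        clocks = [r.clock for r in session.records]
        assert all(b > a for a, b in zip(clocks, clocks[1:]))

    def test_halt_mode_stops_at_first_alarm(self, ref_design):
        # a burst of long waiting times drives the statistic upward
        xs = [5.0] * 100
        halt = run_chart(xs, ref_design, eta_hat=0.2, mode="halt")
        cont = run_chart(xs, ref_design, eta_hat=0.2, mode="continue")
        assert halt.records[-1].zone == "AR"
        assert len(halt.records) < len(cont.records) == 100

    def test_signal_rate_matches_chain(self, ref_design):
        """Mean samples-to-signal over repeated synthetic streams at a
        large shift agrees with the chain's conditional ARL."""
        from vsiewma import build_transition_model, conditional_ats

        delta = 5.0
        perf = conditional_ats(build_transition_model(ref_design, delta))
        rng = np.random.default_rng(8)
        counts = []
        for _ in range(400):
            xs = rng.exponential(delta, size=200)  # eta_hat = 1
            s = run_chart(xs, ref_design, eta_hat=1.0, mode="halt")
            assert s.records[-1].zone == "AR"  # shift large, cap generous
            counts.append(len(s.records))
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - perf.carl) < 3 * se

    def test_nonpositive_observation_rejected(self, ref_design):
        with pytest.raises(DataError, match="sample 2"):
            run_chart([0.5, -0.2], ref_design, eta_hat=0.5)

    def test_bad_mode(self, ref_design):
        with pytest.raises(DomainError):
            run_chart([0.5], ref_design, eta_hat=0.5, mode="oops")

    def test_time_varying_limits_tighter_early(self, ref_design):
        """With exact early-sample limits a moderately deviant first point
        can alarm even though the asymptotic limits would not flag it."""
        eta = 1.0
        x = (MU0 + 0.8) ** 3.6  # ~2.9 sigma above center on the Y scale
        asym = run_chart([x], ref_design, eta, time_varying=False)
        tv = run_chart([x], ref_design, eta, time_varying=True)
        assert asym.records[0].zone == "WR"
        assert tv.records[0].zone == "AR"


@pytest.fixture(scope="module")
def fitted(ref_design):
    p1, p2 = uti_phases()
    return p1, p2, estimate_eta0(p1), ref_design


class TestUtiExample:
    """Retrospective surveillance of the urinary-tract-infection data."""

    def test_phase1_in_control(self, fitted):
        p1, _, eta_hat, design = fitted
        assert run_chart(p1, design, eta_hat).alarms == []

    def test_phase2_signals_shift(self, fitted):
        """The prospective stream drifts to longer gaps between cases; the
        chart must flag it, mostly through warning-region points followed by
        action-region signals late in the stream."""
        _, p2, eta_hat, design = fitted
        session = run_chart(p2, design, eta_hat)
        assert len(session.alarms) >= 1
        assert min(session.alarms) > 10  # shift emerges late in the stream

    def test_summary_and_export(self, fitted, tmp_path):
        _, p2, eta_hat, design = fitted
        session = run_chart(p2, design, eta_hat)
        text = session.summary()
        assert "alarms" in text and f"{eta_hat:.6f}" in text
        csv, js = tmp_path / "s.csv", tmp_path / "s.json"
        session.save(csv, js)
        back = json.loads(js.read_text())
        assert back["n_alarms"] == len(session.alarms)
        assert back["n_samples"] == len(p2)


class TestIO:
    def test_read_combined_and_plain(self, tmp_path):
        comb = tmp_path / "comb.csv"
        comb.write_text("phase,index,days\nI,1,0.5\nI,2,0.7\nII,1,0.9\n")
        assert read_observations(comb, phase="I").tolist() == [0.5, 0.7]
        assert read_observations(comb, phase="II").tolist() == [0.9]
        plain = tmp_path / "plain.csv"
        plain.write_text("value\n0.1\n0.2\n")
        assert read_observations(plain).tolist() == [0.1, 0.2]

    def test_missing_column(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("name\nalpha\n")
        with pytest.raises(DataError):
            read_observations(bad)
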