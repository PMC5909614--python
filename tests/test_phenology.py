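import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoscan import (
    ANTHESIS_FAILED,
    CultivarParams,
    PhenologyConfig,
    simulate_anthesis,
    simulate_anthesis_batch,
    stage2_daily_increment,
    total_leaf_number,
)

from conftest import constant_weather_siteyear
from _oracles import simulate_anthesis_dayloop


class TestStage2Increment:
    @pytest.mark.parametrize(
        "daylength,p2,p2o,expected",
        [
            (13.0, 2.0, 14.0, 0.25),  # below critical day length: 4-day minimum
            (15.0, 2.0, 14.0, 1 / 6),
            (16.0, 0.5, 14.0, 0.2),
            (14.0, 2.0, 14.0, 0.25),  # exactly at the critical day length
        ],
    )
    def test_values(self, daylength, p2, p2o, expected):
        assert stage2_daily_increment(daylength, p2, p2o) == pytest.approx(expected)

    @given(
        p2=st.floats(0.01, 6),
        p2o=st.floats(8, 16),
        dl=st.floats(0, 24),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_decreasing(self, p2, p2o, dl):
        inc = stage2_daily_increment(dl, p2, p2o)
        assert 0 < inc <= 0.25
        if dl > p2o:
            assert inc < stage2_daily_increment(p2o, p2, p2o)


class TestTotalLeafNumber:
    @pytest.mark.parametrize(
        "sumdtt,phint,expected",
        [
            (0, 44, 5.0),  # five embryonic leaves, nothing accumulated
            (220, 44, 15.0),
            (100, 50, 9.0),
        ],
    )
    def test_values(self, sumdtt, phint, expected):
        assert total_leaf_number(sumdtt, phint) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            total_leaf_number(100, 0)
        with pytest.raises(ValueError):
            total_leaf_number(-1, 40)


class TestCultivarParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(p1=0, p2=1, p2o=12, phint=40),
            dict(p1=200, p2=-0.1, p2o=12, phint=40),
            dict(p1=200, p2=1, p2o=0, phint=40),
            dict(p1=200, p2=1, p2o=25, phint=40),
            dict(p1=200, p2=1, p2o=12, phint=0),
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            CultivarParams(**kw)


class TestSimulateAnthesis:
    def test_hand_trace_constant_weather(self, const_siteyear):
        """17 GDD/day, short days: the full stage trace is computable by hand.

        Emergence after ceil(45/17)=3 d; Stage 1: 170/17=10 d; Stage 2:
        4 d (day length below P2O); SUMDTT = 14x17 = 238 GDD; TOLN =
        238/21.5+5; Stage 3 threshold = (TOLN+.5)*43-238 = 474.5 GDD ->
        28 d.
        """
        r = simulate_anthesis(
            const_siteyear, CultivarParams(p1=170, p2=2.0, p2o=14.0, phint=43)
        )
        assert r.emergence_dap == 3
        assert r.end_juvenile_dap == 13
        assert r.tassel_initiation_dap == 17
        assert r.sumdtt_at_ti == pytest.approx(238.0)
        assert r.toln == pytest.approx(238 / 21.5 + 5)
        assert r.anthesis_dap == 45
        assert not r.failed

    def test_four_day_stage2_below_critical_daylength(self, const_siteyear):
        """Whenever day length stays below P2O, Stage 2 is 4 days, any P2."""
        for p2 in (0.0, 0.5, 2.0, 6.0):
            r = simulate_anthesis(
                const_siteyear,
                CultivarParams(p1=170, p2=p2, p2o=14.0, phint=43),
            )
            assert r.tassel_initiation_dap == r.end_juvenile_dap + 4

    def test_matches_dayloop_oracle_on_panel(self, siteyears):
        """Fast implementation vs an independent day-by-day trace."""
        rng = np.random.default_rng(42)
        cfg = PhenologyConfig()
        for _ in range(25):
            sy = siteyears[rng.integers(len(siteyears))]
            params = CultivarParams(
                p1=rng.uniform(150, 450),
                p2=rng.uniform(0, 2),
                p2o=rng.uniform(10, 14),
                phint=rng.uniform(25, 70),
            )
            season = sy.season(cfg.max_horizon_days)
            expected = simulate_anthesis_dayloop(
                season["tmax"].to_numpy(),
                season["tmin"].to_numpy(),
                season["daylength"].to_numpy(),
                params.p1,
                params.p2,
                params.p2o,
                params.phint,
            )
            r = simulate_anthesis(sy, params, cfg)
            got = (
                r.emergence_dap,
                r.end_juvenile_dap,
                r.tassel_initiation_dap,
                r.anthesis_dap,
            )
            assert got == expected

    def test_determinism(self, siteyears):
        p = CultivarParams(p1=300, p2=0.7, p2o=12.5, phint=50)
        a = simulate_anthesis(siteyears[0], p)
        b = simulate_anthesis(siteyears[0], p)
        assert a == b

    def test_failure_sentinel_when_horizon_too_short(self, const_siteyear):
        r = simulate_anthesis(
            const_siteyear, CultivarParams(p1=4000, p2=0, p2o=12, phint=40)
        )
        assert r.failed and r.anthesis_dap == ANTHESIS_FAILED

    def test_p2_zero_makes_p2o_irrelevant(self, siteyears):
        for p2o in (10.0, 12.0, 14.0):
            r = simulate_anthesis(
                siteyears[0], CultivarParams(p1=250, p2=0.0, p2o=p2o, phint=45)
            )
            assert r.anthesis_dap == simulate_anthesis(
                siteyears[0], CultivarParams(p1=250, p2=0.0, p2o=10.0, phint=45)
            ).anthesis_dap


class TestMonotonicity:
    """Directional effects of the GSPs on anthesis day, random draws."""

    def _draw(self, rng):
        return dict(
            p1=rng.uniform(150, 450),
            p2=rng.uniform(0, 2),
            p2o=rng.uniform(10, 14),
            phint=rng.uniform(25, 70),
        )

    def _anth(self, sy, kw):
        return simulate_anthesis(sy, CultivarParams(**kw)).anthesis_dap

    def test_p1_never_hastens(self, siteyears):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sy = siteyears[rng.integers(len(siteyears))]
            kw = self._draw(rng)
            lo = self._anth(sy, kw)
            kw2 = {**kw, "p1": kw["p1"] + rng.uniform(5, 100)}
            hi = self._anth(sy, kw2)
            if lo != ANTHESIS_FAILED and hi != ANTHESIS_FAILED:
                assert hi >= lo

    def test_raising_p2o_never_delays(self, siteyears):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sy = siteyears[rng.integers(len(siteyears))]
            kw = self._draw(rng)
            base = self._anth(sy, kw)
            later = self._anth(sy, {**kw, "p2o": min(kw["p2o"] + 1.5, 24)})
            if base != ANTHESIS_FAILED and later != ANTHESIS_FAILED:
                assert later <= base

    def test_raising_p2_never_hastens(self, siteyears):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sy = siteyears[rng.integers(len(siteyears))]
            kw = self._draw(rng)
            base = self._anth(sy, kw)
            later = self._anth(sy, {**kw, "p2": kw["p2"] + rng.uniform(0.2, 2)})
            if base != ANTHESIS_FAILED and later != ANTHESIS_FAILED:
                assert later >= base


class TestBatchKernel:
    def test_batch_equals_scalar_random_cells(self, siteyears):
        rng = np.random.default_rng(7)
        n = 64
        p1 = rng.uniform(150, 450, n)
        p2 = rng.uniform(0, 2, n)
        p2o = rng.uniform(10, 14, n)
        phint = rng.uniform(25, 70, n)
        for sy in siteyears[::3]:
            batch = simulate_anthesis_batch(sy, p1, p2, p2o, phint, chunk=17)
            for i in rng.choice(n, 10, replace=False):
                r = simulate_anthesis(
                    sy,
                    CultivarParams(
                        p1=p1[i], p2=p2[i], p2o=p2o[i], phint=phint[i]
                    ),
                )
                assert batch[i] == r.anthesis_dap

    def test_batch_varying_cardinal_temperatures(self, siteyears):
        """Six-parameter path: per-set tbase/topt agrees with scalar runs."""
        from phenoscan import TemperatureResponse

        rng = np.random.default_rng(8)
        n = 16
        p1 = rng.uniform(150, 450, n)
        p2 = rng.uniform(0, 2, n)
        p2o = rng.uniform(10, 14, n)
        phint = rng.uniform(25, 70, n)
        tbase = rng.uniform(4, 12, n)
        topt = tbase + rng.uniform(15, 30, n)
        sy = siteyears[0]
        batch = simulate_anthesis_batch(
            sy, p1, p2, p2o, phint, tbase=tbase, topt=topt
        )
        for i in range(0, n, 3):
            r = simulate_anthesis(
                sy,
                CultivarParams(
                    p1=p1[i],
                    p2=p2[i],
                    p2o=p2o[i],
                    phint=phint[i],
                    resp=TemperatureResponse(tbase[i], topt[i]),
                ),
            )
            assert batch[i] == r.anthesis_dap


class TestConfigVariants:
    def test_fixed_stage2_mode_matches_rate_mode_when_daylength_constant(self):
        """With a flat photoperiod the two Stage-2 readings agree."""
        sy = constant_weather_siteyear()
        p = CultivarParams(p1=200, p2=1.5, p2o=11.0, phint=45)
        r_rate = simulate_anthesis(sy, p, PhenologyConfig(stage2_mode="rate"))
        r_fixed = simulate_anthesis(sy, p, PhenologyConfig(stage2_mode="fixed"))
        assert r_rate.tassel_initiation_dap == r_fixed.tassel_initiation_dap
        assert r_rate.anthesis_dap == r_fixed.anthesis_dap

    def test_sumdtt_origin_variants_ordered(self, const_siteyear):
        p = CultivarParams(p1=170, p2=2.0, p2o=14.0, phint=43)
        r_em = simulate_anthesis(
            const_siteyear, p, PhenologyConfig(sumdtt_origin="emergence")
        )
        r_juv = simulate_anthesis(
            const_siteyear, p, PhenologyConfig(sumdtt_origin="juvenile_end")
        )
        # resetting at the end of the juvenile phase discards P1 worth of GDD
        assert r_juv.sumdtt_at_ti == pytest.approx(r_em.sumdtt_at_ti - 170.0)
        assert r_juv.anthesis_dap <= r_em.anthesis_dap
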