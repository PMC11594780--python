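import dataclasses
import math

import numpy as np
import pytest

from czeis import (
    SimConfig,
    SpikeSpec,
    UndefinedIndex,
    ZoneMap,
    compute_panel,
    immunoglobulin_index,
    light_chain_index,
    locate_peak,
    sharpness_index,
    simulate_trace,
)
from czeis.graphic_indexes import (
    ReportingPolicy,
    ZoneEvaluationError,
    panels_to_frame,
)

from conftest import impulse, make_traceset


class TestLocatePeak:
    def test_unique_maximum(self, default_zones):
        ref = np.zeros(300)
        ref[240] = 5.0
        loc = locate_peak(make_traceset(ref), default_zones, "gamma")
        assert loc.apex_index == 240
        assert loc.apex_absorbance == 5.0
        assert loc.prominence == 5.0

    def test_tie_breaks_to_smallest_index(self, default_zones):
        ref = np.zeros(300)
        ref[240] = ref[241] = 5.0
        assert locate_peak(make_traceset(ref), default_zones, "gamma").apex_index == 240

    def test_flat_zone_returns_start_with_zero_prominence(self, default_zones):
        loc = locate_peak(make_traceset(np.ones(300)), default_zones, "gamma")
        assert loc.apex_index == default_zones["gamma"][0]
        assert loc.prominence == 0.0

    def test_narrow_or_missing_zone_raises(self):
        zm = ZoneMap(zones={"beta2": (0, 2), "gamma": (2, 10)}, n_points=10)
        ts = make_traceset(np.arange(10.0))
        with pytest.raises(ZoneEvaluationError, match="beta2"):
            locate_peak(ts, zm, "beta2")
        with pytest.raises(KeyError, match="albumin"):
            locate_peak(ts, zm, "albumin")


class TestSharpnessIndex:
    def test_unit_impulse_gives_two(self, small_zones):
        ts = make_traceset(impulse(1.0))
        assert sharpness_index(ts, small_zones, "gamma") == 2.0

    def test_linear_ramp_gives_zero(self):
        zm = ZoneMap(zones={"beta2": (0, 1), "gamma": (1, 5)}, n_points=6)
        ts = make_traceset([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert sharpness_index(ts, zm, "gamma") == 0.0

    def test_discrete_gaussian_matches_closed_form(self):
        # P(x) = 100 exp(-(x-mu)^2/8) at integer offsets; at the apex the
        # second difference is 2*100*(1 - e^{-1/8}) = 23.500619483...
        mu = 10
        x = np.arange(21, dtype=float)
        ts = make_traceset(100.0 * np.exp(-((x - mu) ** 2) / 8.0))
        zm = ZoneMap(zones={"beta2": (0, 5), "gamma": (5, 16)}, n_points=21)
        expected = 2.0 * (100.0 - 100.0 * math.exp(-1.0 / 8.0))
        assert sharpness_index(ts, zm, "gamma") == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(23.500619483, abs=1e-8)

    def test_apex_on_axis_boundary_raises_naming_zone(self):
        zm = ZoneMap(zones={"beta2": (0, 3), "gamma": (3, 6)}, n_points=6)
        ts = make_traceset([9.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ZoneEvaluationError, match="beta2"):
            sharpness_index(ts, zm, "beta2")

    def test_max_mode_equals_brute_force_over_interior_points(self):
        rng = np.random.default_rng(8)
        zm = ZoneMap(zones={"beta2": (3, 20), "gamma": (25, 58)}, n_points=60)
        for _ in range(25):
            p = rng.normal(10.0, 3.0, 60)
            ts = make_traceset(p)
            for zone in ("beta2", "gamma"):
                start, end = zm[zone]
                brute = max(
                    -(p[x + 1] + p[x - 1] - 2 * p[x]) for x in range(start, end)
                )
                assert sharpness_index(ts, zm, zone, mode="max") == pytest.approx(brute)

    def test_sharpness_decreases_with_gaussian_width(self):
        zm = ZoneMap(zones={"beta2": (0, 10), "gamma": (10, 90)}, n_points=100)
        x = np.arange(100, dtype=float)
        values = []
        for sigma in (1.5, 2.5, 4.0, 8.0, 16.0):
            ts = make_traceset(50.0 * np.exp(-((x - 50.0) ** 2) / (2 * sigma**2)))
            values.append(sharpness_index(ts, zm, "gamma"))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_smoothing_window_must_be_odd(self, small_zones):
        ts = make_traceset(impulse(1.0))
        with pytest.raises(ValueError, match="odd"):
            sharpness_index(ts, small_zones, "gamma", smooth_window=4)


class TestLightChainIndex:
    def test_basic_ratio(self, small_zones):
        ts = make_traceset(impulse(10.0), K=4.0, L=7.0)
        assert light_chain_index(ts, small_zones, "gamma") == 2.0

    def test_identical_antisera_channels_give_one(self, small_zones):
        ts = make_traceset(impulse(10.0), K=6.0, L=6.0)
        assert light_chain_index(ts, small_zones, "gamma") == 1.0

    def test_vanishing_denominator_returns_undefined_marker(self, small_zones):
        ts = make_traceset(impulse(10.0), K=4.0)  # L == REF
        q = light_chain_index(ts, small_zones, "gamma")
        assert isinstance(q, UndefinedIndex)
        assert "denominator" in q.reason
        assert not q


class TestImmunoglobulinIndex:
    def test_basic_difference(self, small_zones):
        ts = make_traceset(impulse(10.0), IgG=3.0)
        assert immunoglobulin_index(ts, small_zones, "gamma", "IgG") == 7.0

    def test_channel_equal_to_ref_gives_zero(self, small_zones):
        ts = make_traceset(impulse(10.0))
        assert immunoglobulin_index(ts, small_zones, "gamma", "IgA") == 0.0

    def test_negative_value_returned_unclamped(self, small_zones):
        ts = make_traceset(impulse(5.0), IgG=7.0)
        assert immunoglobulin_index(ts, small_zones, "gamma", "IgG") == -2.0

    def test_unknown_isotype_rejected(self, small_zones):
        with pytest.raises(ValueError, match="isotype"):
            immunoglobulin_index(
                make_traceset(np.ones(8)), small_zones, "gamma", "IgE"
            )


NOISE_FREE = SimConfig(noise_sd=0.0)


class TestComputePanel:
    def test_balanced_light_chains_give_exactly_one(self):
        cfg = dataclasses.replace(NOISE_FREE, kappa_fraction=0.5)
        panel = compute_panel(simulate_trace(cfg, seed=4).traceset)
        assert panel.value("light_chain", "gamma") == 1.0
        assert panel.value("light_chain", "beta2") == 1.0

    def test_zero_epsilon_gives_zero_deltas_and_undefined_q(self):
        cfg = dataclasses.replace(NOISE_FREE, epsilon=0.0)
        panel = compute_panel(simulate_trace(cfg, seed=4).traceset)
        for zone in ("gamma", "beta2"):
            assert panel.value("igg", zone) == 0.0
            assert panel.value("iga", zone) == 0.0
            assert panel.value("igm", zone) == 0.0
            assert isinstance(panel.value("light_chain", zone), UndefinedIndex)
            assert panel.value("sharpness", zone) != 0.0

    def test_monoclonal_spike_raises_gamma_sharpness_and_igg(self):
        spike = SpikeSpec(
            zone="gamma", isotype="IgG", light_chain="kappa",
            amplitude=6.0, width_pts=2.0, center_frac=0.84, relative=True,
        )
        cfg = dataclasses.replace(NOISE_FREE, case_type="monoclonal", spike=spike)
        base = compute_panel(simulate_trace(NOISE_FREE, seed=6).traceset)
        spiked = compute_panel(simulate_trace(cfg, seed=6).traceset)
        assert spiked.value("sharpness", "gamma") > base.value("sharpness", "gamma")
        assert spiked.value("igg", "gamma") > base.value("igg", "gamma")

    def test_shift_invariance_and_scale_equivariance(self):
        ts = simulate_trace(SimConfig(), seed=12).traceset
        panel = compute_panel(ts)
        shifted = make_traceset(
            ts.ref + 100.0, **{c: ts[c] + 100.0 for c in ("IgG", "IgA", "IgM", "K", "L")}
        )
        scaled = make_traceset(
            ts.ref * 3.0, **{c: ts[c] * 3.0 for c in ("IgG", "IgA", "IgM", "K", "L")}
        )
        p_shift = compute_panel(shifted)
        p_scale = compute_panel(scaled)
        for zone in ("gamma", "beta2"):
            for idx in ("sharpness", "igg", "iga", "igm"):
                assert p_shift.value(idx, zone) == pytest.approx(
                    panel.value(idx, zone), abs=1e-9
                )
                assert p_scale.value(idx, zone) == pytest.approx(
                    3.0 * panel.value(idx, zone), rel=1e-12
                )
            assert p_shift.value("light_chain", zone) == pytest.approx(
                panel.value("light_chain", zone), rel=1e-12
            )
            assert p_scale.value("light_chain", zone) == pytest.approx(
                panel.value("light_chain", zone), rel=1e-12
            )

    def test_delta_conservation_at_shared_apex(self):
        panel = compute_panel(simulate_trace(NOISE_FREE, seed=13).traceset)
        ts = simulate_trace(NOISE_FREE, seed=13).traceset
        for zone in ("gamma", "beta2"):
            x = panel.zones[zone].peak.apex_index
            lc_sum = (ts.ref[x] - ts["K"][x]) + (ts.ref[x] - ts["L"][x])
            iso_sum = (
                panel.value("igg", zone)
                + panel.value("iga", zone)
                + panel.value("igm", zone)
            )
            assert iso_sum == pytest.approx(lc_sum, abs=1e-9)

    def test_rounding_policy_for_reports(self):
        panel = compute_panel(
            simulate_trace(SimConfig(), seed=2).traceset,
            reporting=ReportingPolicy(),
        )
        rounded = panel.rounded()
        for zone in ("gamma", "beta2"):
            assert isinstance(rounded[zone]["sharpness"], int)
            lc = rounded[zone]["light_chain"]
            if not isinstance(lc, UndefinedIndex):
                assert lc == round(float(panel.value("light_chain", zone)), 2)

    def test_panels_to_frame_layout(self):
        panels = [
            compute_panel(simulate_trace(SimConfig(), seed=s).traceset)
            for s in (1, 2)
        ]
        df = panels_to_frame(panels)
        assert len(df) == 4  # 2 cases x 2 zones
        assert list(df.columns[:7]) == [
            "case_id", "zone", "sharpness", "light_chain", "igg", "iga", "igm",
        ]
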