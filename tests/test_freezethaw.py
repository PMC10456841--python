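"""Freeze-thaw protocol: durations, boosts, cycle-resolved conversion."""

import numpy as np
import pytest

from cryodsd import (
    DEFAULT_ANIONS,
    AnionParams,
    CycleSchedule,
    basic_reaction_crn,
    cycles_to_fraction,
    freeze_boost,
    per_cycle_table,
    protocol_duration,
    simulate_freeze_thaw,
    simulate_isothermal,
)
from cryodsd.freezethaw import FTResult
from conftest import K_C0


class TestProtocolDuration:
    def test_eight_cycles_is_0p8_hours(self):
        assert protocol_duration(8) / 3600.0 == pytest.approx(0.8)

    def test_three_cycles_is_18_minutes(self):
        assert protocol_duration(3) / 60.0 == pytest.approx(18.0)

    def test_zero_cycles(self):
        assert protocol_duration(0) == 0.0

    def test_linear_in_cycle_count(self):
        d = [protocol_duration(n) for n in range(6)]
        assert np.allclose(np.diff(d), d[1])

    def test_negative_cycles_rejected(self):
        with pytest.raises(ValueError):
            protocol_duration(-1)

    def test_schedule_validates_durations(self):
        with pytest.raises(ValueError):
            CycleSchedule(t_freeze=0)
        with pytest.raises(ValueError):
            CycleSchedule(eutectic_window=120.0)  # longer than freeze episode


class TestFreezeBoost:
    def test_sulfate_boost_matches_dose_arithmetic(self):
        # boost = (dose - kC0*t_thaw) / (kC0*window), independent arithmetic
        expected = (1.0 - K_C0 * 300.0) / (K_C0 * 60.0)
        assert freeze_boost(DEFAULT_ANIONS["SO4"]) == pytest.approx(expected)
        assert expected == pytest.approx(57.89, rel=1e-3)

    def test_one_cycle_delivers_the_dose(self):
        for anion in DEFAULT_ANIONS.values():
            boost = freeze_boost(anion)
            delivered = boost * K_C0 * 60.0 + K_C0 * 300.0
            assert delivered == pytest.approx(anion.dose)

    def test_hofmeister_ordering_of_boosts(self):
        boosts = [freeze_boost(DEFAULT_ANIONS[a]) for a in ("SO4", "Ac", "Cl", "NO3")]
        assert boosts == sorted(boosts, reverse=True)
        veins = [DEFAULT_ANIONS[a].vein_thickness_um for a in ("SO4", "Ac", "Cl", "NO3")]
        assert veins == sorted(veins)  # boost decreasing in vein thickness

    def test_unachievable_dose_rejected(self):
        tiny = AnionParams("SO4", 0.04, dose=K_C0 * 300.0 / 2)
        with pytest.raises(ValueError, match="not achievable"):
            freeze_boost(tiny)

    def test_pinned_boost_passes_through(self):
        assert freeze_boost(AnionParams("SO4", 0.04, 1.0, boost=5.0)) == 5.0


class TestCyclesToFraction:
    def _result(self, conv):
        return FTResult(np.asarray(conv), None, None, None,
                        CycleSchedule(), DEFAULT_ANIONS["SO4"], 1.0)

    def test_first_cycle_reaching_fraction(self):
        assert cycles_to_fraction(self._result([0.5, 0.67, 0.75]), 0.5) == 1

    def test_dose_accumulation_half_at_eight(self):
        # closed form n*delta/(1+n*delta) with delta = 1/8
        conv = [n / 8 / (1 + n / 8) for n in range(1, 11)]
        assert cycles_to_fraction(self._result(conv), 0.5) == 8

    def test_unreached_fraction_is_none(self):
        conv = [n / 8 / (1 + n / 8) for n in range(1, 11)]
        assert cycles_to_fraction(self._result(conv), 0.99) is None

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cycles_to_fraction(self._result([]), 0.5)


class TestFreezeThawSimulation:
    @pytest.mark.parametrize(
        "anion,half", [("SO4", 1), ("Ac", 3), ("Cl", 6), ("NO3", 8)]
    )
    def test_half_completion_cycles_follow_hofmeister_series(self, anion, half):
        crn = basic_reaction_crn(4, 50.0)
        result = simulate_freeze_thaw(crn, anion=DEFAULT_ANIONS[anion], n_cycles=10)
        assert result.cycles_to_half == half

    def test_per_cycle_conversion_matches_dose_additivity(self):
        """Cycle-end conversion equals n*delta/(1+n*delta) within 1e-3."""
        crn = basic_reaction_crn(4, 50.0, with_reporter=False)
        for name in ("SO4", "NO3"):
            anion = DEFAULT_ANIONS[name]
            result = simulate_freeze_thaw(crn, anion=anion, n_cycles=10)
            n = np.arange(1, 11)
            expected = n * anion.dose / (1 + n * anion.dose)
            assert np.abs(result.per_cycle_conversion - expected).max() < 1e-3

    def test_conversion_is_nondecreasing(self):
        crn = basic_reaction_crn(4, 50.0)
        result = simulate_freeze_thaw(crn, anion=DEFAULT_ANIONS["Cl"], n_cycles=8)
        assert (np.diff(result.per_cycle_conversion) >= -1e-12).all()
        assert result.cycles_to_half <= (result.cycles_to_completion or 10**9)

    def test_shorter_toehold_needs_at_least_as_many_cycles(self):
        anion = DEFAULT_ANIONS["SO4"]
        halves = []
        for m in (3, 4):
            crn = basic_reaction_crn(m, 50.0)
            result = simulate_freeze_thaw(crn, anion=anion, n_cycles=10)
            halves.append(result.cycles_to_half or 11)
        assert halves[0] >= halves[1]

    def test_unit_boost_degenerates_to_isothermal(self):
        """boost = 1 for all phases reproduces the isothermal trace."""
        crn = basic_reaction_crn(4, 50.0, with_reporter=False)
        anion = AnionParams("SO4", 0.04, 1.0, boost=1.0)
        n = 5
        result = simulate_freeze_thaw(crn, anion=anion, n_cycles=n)
        total = protocol_duration(n)
        iso = simulate_isothermal(crn, total)
        ft_final = result.per_cycle_conversion[-1]
        iso_final = iso.conversion(crn.outputs, crn.output_ref_nM)[-1]
        assert ft_final == pytest.approx(iso_final, abs=1e-6)

    def test_reporter_added_after_last_cycle_by_default(self):
        crn = basic_reaction_crn(4, 50.0, with_reporter=True)
        result = simulate_freeze_thaw(crn, anion=DEFAULT_ANIONS["SO4"], n_cycles=2)
        f = result.trace.series("F")
        cycling_end = 2 * CycleSchedule().cycle_duration
        during = f[result.trace.times <= cycling_end]
        assert during.max() == 0.0
        assert f[-1] > 25.0  # reporting tail converts released output

    def test_per_cycle_table_layout(self):
        crn = basic_reaction_crn(4, 50.0)
        result = simulate_freeze_thaw(crn, anion=DEFAULT_ANIONS["SO4"], n_cycles=3)
        df = per_cycle_table(result)
        assert list(df.columns) == ["cycle", "time_h", "conversion"]
        assert df["time_h"].iloc[-1] == pytest.approx(0.3)

    def test_invalid_cycle_count_rejected(self):
        crn = basic_reaction_crn(4, 50.0)
        with pytest.raises(ValueError):
            simulate_freeze_thaw(crn, n_cycles=0)
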