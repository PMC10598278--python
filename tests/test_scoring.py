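"""Decision-tree potency scoring: individual checks and the full tree."""


import numpy as np
import pytest

from isletchip.config import BiphasicConfig
from isletchip.profiles import BiphasicKinetics
from isletchip.scoring import (
    ResponseFlags,
    ScoringError,
    assign_chip_score,
    check_biphasic,
    check_dose_dependence,
    check_epi_disambiguation,
    check_g1_activity,
    check_response,
    subgroup_of,
)

from _helpers import make_stats, profile_from_rate


class TestG1Activity:
    @pytest.mark.parametrize("mean,expected", [(0.1, False), (0.6, True), (0.5, False)])
    def test_strict_threshold(self, mean, expected):
        stats = make_stats("G1", [mean] * 6)
        assert check_g1_activity(stats, threshold_hz=0.5) is expected

    def test_missing_segment_aborts(self):
        with pytest.raises(ScoringError, match="G1"):
            check_g1_activity(None)


class TestEpiDisambiguation:
    def test_silencing(self):
        g1 = make_stats("G1", [0.8] * 6)
        epi = make_stats("G1+EPI", [0.1] * 6)
        assert check_epi_disambiguation(g1, epi) == "silences"

    def test_enhancement(self):
        g1 = make_stats("G1", [0.8] * 6)
        epi = make_stats("G1+EPI", [1.6] * 6)
        assert check_epi_disambiguation(g1, epi) == "enhances"

    def test_unchanged_is_neither(self):
        g1 = make_stats("G1", [0.8] * 6)
        epi = make_stats("G1+EPI", [0.8] * 6)
        assert check_epi_disambiguation(g1, epi) == "neither"

    def test_missing_epi_segment_aborts(self):
        with pytest.raises(ScoringError, match="epinephrine"):
            check_epi_disambiguation(make_stats("G1", [0.8] * 6), None)


class TestResponse:
    def test_clear_rise_detected(self):
        # 0.05 -> 0.40 Hz on all 10 electrodes: even the conservative sign
        # test gives p = 2^-10 < 0.05, and both effect floors are cleared
        base = make_stats("G1", [0.05] * 10)
        stim = make_stats("G15", [0.40] * 10)
        r = check_response(base, stim)
        assert r.passed and r.p_value < 0.05

    def test_identical_values_are_no_response(self):
        vals = [0.2, 0.25, 0.18, 0.22, 0.21, 0.24]
        r = check_response(make_stats("a", vals), make_stats("b", vals))
        assert not r.passed

    def test_micro_effect_blocked_by_floor(self):
        # 1.5-fold rise of 0.02 Hz absolute: below both floors
        base = make_stats("a", [0.04] * 10)
        stim = make_stats("b", [0.06] * 10)
        r = check_response(base, stim)
        assert not r.passed

    def test_few_electrodes_fall_back_to_effect_floor(self):
        base = make_stats("a", [0.05] * 3)
        stim = make_stats("b", [0.40] * 3)
        r = check_response(base, stim)
        assert r.passed and r.low_confidence and r.p_value is None

    def test_decrease_is_not_a_response(self):
        base = make_stats("a", [0.4] * 10)
        stim = make_stats("b", [0.05] * 10)
        assert not check_response(base, stim).passed


class TestDoseDependence:
    CONCS = (1.0, 3.0, 5.5, 8.2, 11.0)

    def stats_for(self, means, jitter=0.01, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for c, m in zip(self.CONCS, means):
            vals = np.clip(m + rng.normal(0, jitter, 10), 0, None)
            out[c] = make_stats(f"G{c:g}", vals)
        return out

    def test_graded_monotone_response(self):
        d = check_dose_dependence(self.stats_for([0.02, 0.05, 0.12, 0.25, 0.40]))
        assert d.passed and d.p_value < 0.05

    def test_flat_response_rejected(self):
        d = check_dose_dependence(self.stats_for([0.2] * 5))
        assert not d.passed

    def test_decreasing_response_rejected(self):
        d = check_dose_dependence(self.stats_for([0.40, 0.25, 0.12, 0.05, 0.02]))
        assert not d.passed

    def test_missing_concentration_aborts(self):
        stats = self.stats_for([0.02, 0.05, 0.12, 0.25, 0.40])
        del stats[5.5]
        with pytest.raises(ScoringError, match="missing"):
            check_dose_dependence(stats)

    def test_weak_absolute_rise_blocked(self):
        # monotone in rank but trivially small in absolute terms
        d = check_dose_dependence(self.stats_for([0.010, 0.015, 0.020, 0.025, 0.030],
                                                 jitter=0.001))
        assert not d.passed


class TestBiphasicCheck:
    def test_generator_kinetics_accepted_with_correct_latency(self):
        kin = BiphasicKinetics()
        prof = profile_from_rate(lambda t: kin.rate(np.maximum(t - 120, 0), 0.02)
                                 * (np.asarray(t) >= 120) + 0.02 * (np.asarray(t) < 120),
                                 duration_s=120 + 1380)
        b = check_biphasic(prof, stimulus_onset_s=120.0)
        assert b.passed
        assert b.first_peak_min == pytest.approx(5.0, abs=1.0)

    def test_monotone_rise_rejected(self):
        prof = profile_from_rate(lambda t: 0.4 * np.asarray(t) / 1500.0, duration_s=1500)
        assert not check_biphasic(prof, stimulus_onset_s=0.0).passed

    def test_flat_zero_rejected(self):
        prof = profile_from_rate(lambda t: np.zeros_like(np.asarray(t, dtype=float)),
                                 duration_s=1500)
        assert not check_biphasic(prof, stimulus_onset_s=0.0).passed

    def test_step_to_constant_rate_rejected(self):
        # sustained response without a first-phase peak and decline
        prof = profile_from_rate(lambda t: np.full_like(np.asarray(t, dtype=float), 0.4),
                                 duration_s=1500)
        assert not check_biphasic(prof, stimulus_onset_s=0.0, baseline_hz=0.0).passed

    def test_short_span_aborts(self):
        prof = profile_from_rate(lambda t: np.zeros_like(np.asarray(t, dtype=float)),
                                 duration_s=600)
        with pytest.raises(ScoringError, match="span"):
            check_biphasic(prof, stimulus_onset_s=0.0)

    def test_transient_without_second_phase_rejected(self):
        # first-phase peak that decays to baseline: no sustained second phase
        def rate(t):
            t = np.asarray(t, dtype=float) / 60.0
            return 0.4 * np.exp(-0.5 * (t - 5.0) ** 2 / 1.5**2)

        prof = profile_from_rate(rate, duration_s=1500)
        b = check_biphasic(prof, stimulus_onset_s=0.0, baseline_hz=0.0,
                           config=BiphasicConfig())
        assert not b.passed and b.first_peak_min == pytest.approx(5.0, abs=1.0)


# --- full tree --------------------------------------------------------------


def oracle_tree(active, epi, g15, dose, biph, glp1, inhib, gli):
    """Independent hand-coding of the published ranking algorithm."""
    if active and epi == "enhances":
        return "disqualified"
    if g15:
        if dose:
            return 6 if biph else 5
        return 4
    if glp1:
        return 3 if inhib else 2
    return 2 if gli else 1


def reachable_flag_vectors():
    """Every flag assignment reachable by walking the decision tree."""
    prefixes = [(False, None)] + [(True, e) for e in ("silences", "enhances", "neither")]
    for active, epi in prefixes:
        if active and epi == "enhances":
            yield active, epi, None, None, None, None, None, None
            continue
        # glucose-responsive branch
        yield active, epi, True, False, None, None, None, None
        yield active, epi, True, True, False, None, None, None
        yield active, epi, True, True, True, None, None, None
        # unresponsive branch
        for inhib in (False, True):
            yield active, epi, False, None, None, True, inhib, None
        for gli in (False, True):
            yield active, epi, False, None, None, False, None, gli


def flags_from_vector(vec):
    active, epi, g15, dose, biph, glp1, inhib, gli = vec
    return ResponseFlags(
        active_at_g1=active,
        epi_silences=None if epi is None else epi == "silences",
        epi_enhances=None if epi is None else epi == "enhances",
        g15_response=g15, dose_dependent=dose, biphasic=biph,
        glp1_response=glp1, epi_inhibits_glp1=inhib, gli_response=gli,
    )


class TestAssignChipScore:
    def test_exhaustive_enumeration_matches_hand_coded_tree(self):
        seen = set()
        for vec in reachable_flag_vectors():
            result = assign_chip_score(flags_from_vector(vec))
            expected = oracle_tree(*vec)
            got = "disqualified" if result.disqualified else result.score
            assert got == expected, f"flags {vec}: got {got}, expected {expected}"
            seen.add(got)
        assert seen == {1, 2, 3, 4, 5, 6, "disqualified"}

    def test_monotonicity_passing_more_points_never_lowers_score(self):
        # flipping any single evaluated False flag to True (where the result
        # is still tree-reachable) must not lower the score
        bool_fields = ["g15_response", "dose_dependent", "biphasic",
                       "glp1_response", "epi_inhibits_glp1", "gli_response"]
        for vec in reachable_flag_vectors():
            base = flags_from_vector(vec)
            res = assign_chip_score(base)
            if res.disqualified:
                continue
            for name in bool_fields:
                if getattr(base, name) is not False:
                    continue
                upgraded = flags_from_vector(vec)
                setattr(upgraded, name, True)
                try:
                    up = assign_chip_score(upgraded)
                except ScoringError:
                    continue  # flip made the vector unreachable
                assert up.score >= res.score

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # no glucose, GLP-1 or glibenclamide response -> lowest rank
            (dict(active_at_g1=False, g15_response=False, glp1_response=False,
                  gli_response=False), 1),
            # full phenotype -> highest rank
            (dict(active_at_g1=False, g15_response=True, dose_dependent=True,
                  biphasic=True), 6),
            # GLP-1 response inhibited by epinephrine -> 3
            (dict(active_at_g1=False, g15_response=False, glp1_response=True,
                  epi_inhibits_glp1=True), 3),
            # high-glucose response without dose dependence -> 4
            (dict(active_at_g1=False, g15_response=True, dose_dependent=False), 4),
            # glibenclamide-only response -> 2
            (dict(active_at_g1=False, g15_response=False, glp1_response=False,
                  gli_response=True), 2),
            # dose dependence without biphasic activation -> 5
            (dict(active_at_g1=False, g15_response=True, dose_dependent=True,
                  biphasic=False), 5),
        ],
    )
    def test_published_score_examples(self, kwargs, expected):
        result = assign_chip_score(ResponseFlags(**kwargs))
        assert result.score == expected

    def test_enhancement_disqualifies(self):
        flags = ResponseFlags(active_at_g1=True, epi_silences=False, epi_enhances=True)
        result = assign_chip_score(flags)
        assert result.disqualified and result.score is None and result.subgroup is None
        assert result.decision_path == [1, 2]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(active_at_g1=True, epi_silences=True, epi_enhances=True),
            dict(active_at_g1=False, epi_silences=True),
            dict(active_at_g1=False, g15_response=False, dose_dependent=True),
            dict(active_at_g1=False, g15_response=True, dose_dependent=False,
                 biphasic=True),
            dict(active_at_g1=False, g15_response=True, glp1_response=True),
            dict(active_at_g1=False, g15_response=False, glp1_response=False,
                 epi_inhibits_glp1=True),
            dict(active_at_g1=False, g15_response=False, glp1_response=True,
                 gli_response=True),
        ],
    )
    def test_contradictory_flags_rejected(self, kwargs):
        with pytest.raises(ScoringError):
            assign_chip_score(ResponseFlags(**kwargs))

    def test_decision_path_follows_branch(self):
        r = assign_chip_score(ResponseFlags(active_at_g1=False, g15_response=True,
                                            dose_dependent=True, biphasic=True))
        assert r.decision_path == [1, 3, 4, 5]
        r = assign_chip_score(ResponseFlags(active_at_g1=False, g15_response=False,
                                            glp1_response=False, gli_response=True))
        assert r.decision_path == [1, 3, 6, 8]


@pytest.mark.parametrize("score,band", [(1, "low"), (2, "low"), (3, "moderate"),
                                        (4, "moderate"), (5, "excellent"), (6, "excellent"),
                                        (None, None)])
def test_subgroup_banding(score, band):
    assert subgroup_of(score) == band
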