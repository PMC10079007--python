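"""Line-of-therapy engine: establishment, addition, switch, segmentation,
naming, post-SCT labelling, and equivalence with a day-stepping oracle."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimlines import (GraceConfig, canonical_name, classify_post_sct,
                        derive_lines, detect_switch, establish_regimen,
                        segment_lines)

from _reference import reference_lines
from conftest import day

GRACE = GraceConfig()


def ev(*pairs):
    """[(offset, drug), ...] -> drug events."""
    return [(day(o), d) for o, d in pairs]


class TestEstablishment:
    def test_addition_within_window_forms_one_episode(self):
        events = ev((0, "bortezomib"), (4, "bortezomib"), (8, "bortezomib"),
                    (11, "bortezomib"), (0, "dexamethasone"), (8, "dexamethasone"))
        episodes = establish_regimen(events, GRACE)
        assert len(episodes) == 1
        assert episodes[0].drugs == {"bortezomib", "dexamethasone"}
        assert episodes[0].start == day(0)

    def test_single_administration_never_founds_a_regimen(self):
        assert establish_regimen(ev((0, "lenalidomide")), GRACE) == []

    def test_late_drug_outside_addition_window_is_a_switch_not_addition(self):
        events = ev((0, "bortezomib"), (4, "bortezomib"),
                    (35, "lenalidomide"), (45, "lenalidomide"))
        episodes = establish_regimen(events, GRACE)
        assert [e.drugs for e in episodes] == [{"bortezomib"}, {"lenalidomide"}]
        assert episodes[1].start == day(35)

    def test_administration_beyond_grace_does_not_persist(self):
        # second bortezomib 40 days later: outside its 28-day grace
        assert establish_regimen(ev((0, "bortezomib"), (40, "bortezomib")),
                                 GRACE) == []

    def test_steroid_alone_never_anchors(self):
        events = ev((0, "dexamethasone"), (7, "dexamethasone"),
                    (14, "dexamethasone"))
        assert establish_regimen(events, GRACE) == []

    def test_unknown_drug_ignored_with_warning(self):
        events = ev((0, "bortezomib"), (7, "bortezomib"), (3, "aspirin"))
        with pytest.warns(UserWarning, match="aspirin"):
            episodes = establish_regimen(events, GRACE)
        assert episodes[0].drugs == {"bortezomib"}


class TestSwitch:
    def _vd(self):
        return ([(o, "bortezomib") for o in range(0, 211, 7)]
                + [(o, "dexamethasone") for o in range(0, 211, 7)])

    def test_new_persisting_drug_switches(self):
        events = ev(*self._vd(), (200, "daratumumab"), (214, "daratumumab"))
        current = establish_regimen(events, GRACE)[0]
        switch_date, new_ep = detect_switch(current, events, GRACE)
        assert switch_date == day(200)
        assert "daratumumab" in new_ep.drugs

    def test_single_dose_of_new_drug_does_not_switch(self):
        events = ev(*self._vd(), (200, "carfilzomib"))
        current = establish_regimen(events, GRACE)[0]
        assert detect_switch(current, events, GRACE) == (None, None)

    def test_member_steroid_pattern_change_does_not_switch(self):
        events = ev(*self._vd(), (203, "dexamethasone"), (205, "dexamethasone"))
        current = establish_regimen(events, GRACE)[0]
        assert detect_switch(current, events, GRACE) == (None, None)


class TestSegmentation:
    def test_long_silence_splits_into_two_lines(self):
        # Vd for 8 weeks, silence of grace+20 past the slack, Vd again
        block1 = [(o, "bortezomib") for o in range(0, 57, 7)]
        block2 = [(o, "bortezomib") for o in range(56 + 28 + 20 + 14, 200, 7)]
        lines = derive_lines(ev(*block1, *block2), data_end=day(400))
        assert [l.line_number for l in lines] == [1, 2]
        assert lines[0].end_reason == "discontinuation-gap"
        assert lines[0].end == day(56)
        assert lines[1].regimen == lines[0].regimen  # same-set restart, new line

    def test_death_during_line_ends_it_at_death_date(self):
        events = [(o, "bortezomib") for o in range(0, 100, 7)]
        lines = derive_lines(ev(*events), death_date=day(60), data_end=day(60))
        assert len(lines) == 1
        assert lines[0].end_reason == "death"
        assert lines[0].end == day(60)

    def test_switch_day_boundary_is_closed_interval(self):
        events = (
            [(o, "bortezomib") for o in range(0, 98, 7)]
            + [(o, "dexamethasone") for o in range(0, 98, 7)]
            + [(o, "lenalidomide") for o in range(100, 160, 28)]
            + [(o, "dexamethasone") for o in range(100, 160, 14)]
        )
        lines = derive_lines(ev(*events), data_end=day(400))
        assert lines[0].end == day(99)
        assert lines[0].end_reason == "switch"
        assert lines[1].start == day(100)
        assert lines[1].regimen == "Rd"

    def test_data_end_inside_alive_window_censors_line(self):
        events = [(o, "bortezomib") for o in range(0, 60, 7)]
        lines = derive_lines(ev(*events), data_end=day(70))
        assert lines[0].end_reason == "data-end"
        assert lines[0].end == day(70)
        assert lines[0].duration_days == 71

    def test_death_in_post_line_silence_still_counts_as_death(self):
        events = [(o, "bortezomib") for o in range(0, 60, 7)]
        # death 30 days after last dose: inside grace+slack, line not yet over
        lines = derive_lines(ev(*events), death_date=day(86), data_end=day(86))
        assert lines[0].end_reason == "death"
        # death past the alive window: the line had already discontinued
        lines = derive_lines(ev(*events), death_date=day(200), data_end=day(200))
        assert lines[0].end_reason == "discontinuation-gap"
        assert lines[0].end == day(56)


class TestNaming:
    @pytest.mark.parametrize("drugs,name", [
        ({"bortezomib", "dexamethasone"}, "Vd"),
        ({"bortezomib", "lenalidomide", "dexamethasone"}, "VRd"),
        ({"lenalidomide", "dexamethasone"}, "Rd"),
        ({"melphalan", "prednisolone"}, "MP"),
        ({"bortezomib", "melphalan", "prednisolone"}, "VMP"),
        ({"daratumumab", "lenalidomide", "dexamethasone"}, "DRd"),
        ({"carfilzomib", "lenalidomide", "dexamethasone"}, "KRd"),
        ({"cyclophosphamide", "dexamethasone"}, "Cy+Dex"),
        ({"bortezomib"}, "V"),  # fallback
        ({"carfilzomib", "daratumumab"}, "D+K"),  # fallback, sorted
    ])
    def test_canonical_names(self, drugs, name):
        assert canonical_name(drugs) == name

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            canonical_name(set())


class TestPostSct:
    def test_phase_boundaries(self):
        from claimlines.lot import TherapyLine
        starts = [-30, 0, 60, 122, 123, 200]
        lines = [TherapyLine(i + 1, "Vd", frozenset({"bortezomib"}),
                             day(s), day(s + 14), "discontinuation-gap")
                 for i, s in enumerate(starts)]
        labels = classify_post_sct(lines, day(0))
        assert labels == ["induction", "post-SCT", "post-SCT", "post-SCT",
                          "other", "other"]


class TestProperties:
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["bortezomib", "lenalidomide", "daratumumab",
                                 "melphalan", "dexamethasone"]),
                st.integers(min_value=0, max_value=160),
            ),
            min_size=1, max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_day_stepping_oracle(self, raw):
        events = [(day(o), d) for d, o in raw]
        got = derive_lines(events)
        expected = reference_lines(events, GRACE)
        assert [(l.drugs, l.start, l.end, l.end_reason) for l in got] == expected

    @given(st.integers(min_value=-300, max_value=300))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        base = ev((0, "bortezomib"), (7, "bortezomib"), (14, "bortezomib"),
                  (0, "dexamethasone"), (14, "dexamethasone"),
                  (120, "lenalidomide"), (140, "lenalidomide"))
        delta = dt.timedelta(days=shift)
        shifted = [(d + delta, drug) for d, drug in base]
        a = derive_lines(base)
        b = derive_lines(shifted)
        assert [(l.start + delta, l.end + delta, l.drugs, l.end_reason)
                for l in a] == [(l.start, l.end, l.drugs, l.end_reason)
                                for l in b]

    @given(st.integers(min_value=0, max_value=120))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_lengthening_a_gap_never_merges_lines(self, extra):
        first = [(o, "bortezomib") for o in range(0, 36, 7)]
        second_start = 36 + 70  # already a clean discontinuation gap
        second = [(second_start + extra + o, "bortezomib") for o in (0, 7, 14)]
        events = ev(*first) + [(day(o), d) for o, d in second]
        lines = derive_lines(events)
        assert len(lines) == 2
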