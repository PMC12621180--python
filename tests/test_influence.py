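"""Neighbor-influence case-control construction and temporal permutation."""

import numpy as np
import pandas as pd
import pytest

from vasonet.communities import CommunityPartition
from vasonet.influence import (
    build_cases,
    characteristics_by_k,
    compute_window,
    permute_event_times,
    probability_by_k,
    temporal_permutation,
)

from conftest import event_table, toy_graph


def star_tissue():
    """Target 0 with neighbors 1..4; 5 is disconnected from 0."""
    return toy_graph([(0, 1), (0, 2), (0, 3), (0, 4), (4, 5)])


class TestWindow:
    def test_three_times_median(self):
        ev = event_table([(1, 1.0, 1.0, 0.5, 1.0, 1.0, True),
                          (1, 5.0, 1.0, 0.5, 1.0, 2.0, True),
                          (2, 9.0, 1.0, 0.5, 1.0, 3.0, True)])
        assert compute_window(ev) == pytest.approx(6.0)

    def test_single_event(self):
        ev = event_table([(1, 1.0, 1.0, 0.5, 1.0, 2.0, True)])
        assert compute_window(ev) == pytest.approx(6.0)

    def test_unfit_events_excluded_from_median(self):
        ev = event_table([(1, 1.0, 1.0, 0.5, 1.0, 2.0, True),
                          (2, 3.0, 1.0, 0.5, 1.0, 99.0, False)])
        assert compute_window(ev) == pytest.approx(6.0)

    def test_no_events_fails(self):
        with pytest.raises(ValueError):
            compute_window(event_table([]))


class TestCases:
    def test_single_preceding_neighbor_positive(self):
        tg = star_tissue()
        t_w = 6.0
        ev = event_table([(1, 10.0), (0, 13.0)])
        cases = [c for c in build_cases(ev, tg, t_w) if c.target == 0]
        pos = [c for c in cases if c.positive]
        assert len(pos) == 1 and pos[0].k == 1

    def test_same_neighbor_counted_once(self):
        tg = star_tissue()
        ev = event_table([(1, 10.0), (1, 12.0), (0, 14.0)])
        pos = [c for c in build_cases(ev, tg, 6.0) if c.target == 0 and c.positive]
        assert len(pos) == 1 and pos[0].k == 1

    def test_negative_window_grouping_matches_hand_count(self):
        # neighbors 1,2,3 fire at 10, 12, 20; target 0 stays silent.
        # window 1: [10,16] covers {1@10, 2@12} -> k=2; window 2: [20,26] -> k=1
        tg = star_tissue()
        ev = event_table([(1, 10.0), (2, 12.0), (3, 20.0)])
        neg = [c for c in build_cases(ev, tg, 6.0) if c.target == 0 and not c.positive]
        assert sorted(c.k for c in neg) == [1, 2]
        assert {c.reference_time for c in neg} == {10.0, 20.0}

    def test_window_after_target_event_is_not_a_control(self):
        # target fired at 9; neighbor activity at 10 opens inside the target's
        # own transient, so it is neither positive (wrong order) nor negative
        tg = star_tissue()
        ev = event_table([(0, 9.0), (1, 10.0)])
        cases = [c for c in build_cases(ev, tg, 6.0) if c.target == 0]
        pos = [c for c in cases if c.positive]
        neg = [c for c in cases if not c.positive]
        assert len(pos) == 0  # neighbor at 10 is after the event at 9
        assert len(neg) == 0

    def test_cluster_category_assignment(self):
        tg = star_tissue()
        part = CommunityPartition(communities=[{0, 1, 2}], isolated=set())
        ev = event_table([(1, 10.0), (0, 13.0), (3, 30.0), (0, 33.0),
                          (2, 50.0), (3, 51.0), (0, 53.0)])
        pos = [c for c in build_cases(ev, tg, 6.0, part) if c.target == 0 and c.positive]
        cats = {c.reference_time: c.category for c in pos}
        assert cats[13.0] == "cluster"       # neighbor 1 shares the community
        assert cats[33.0] == "non-cluster"   # neighbor 3 does not
        assert cats[53.0] == "mixed"         # neighbors 2 (in) and 3 (out)


class TestProbability:
    def test_all_positive_at_k1(self):
        tg = star_tissue()
        ev = event_table([(1, 10.0), (0, 12.0), (2, 30.0), (0, 32.0)])
        curve = probability_by_k([c for c in build_cases(ev, tg, 6.0) if c.target == 0])
        assert curve.table.at[1, "p"] == pytest.approx(1.0)

    def test_exact_line(self):
        from vasonet.influence import InfluenceCase

        cases = []
        for k, p, n in ((1, 2, 8), (2, 4, 6), (3, 6, 4)):
            cases += [InfluenceCase(0, k, True, "cluster", 0.0)] * p
            cases += [InfluenceCase(0, k, False, "cluster", 0.0)] * n
        curve = probability_by_k(cases)
        assert curve.slope == pytest.approx(0.2)
        assert curve.r2 == pytest.approx(1.0)

    def test_category_restriction(self):
        from vasonet.influence import InfluenceCase

        cases = [
            InfluenceCase(0, 1, True, "cluster", 0.0),
            InfluenceCase(0, 1, False, "non-cluster", 0.0),
        ]
        curve = probability_by_k(cases, categories=("cluster",))
        assert curve.table.at[1, "p"] == pytest.approx(1.0)


class TestCharacteristics:
    def test_single_case_means_equal_event(self):
        tg = star_tissue()
        ev = event_table([(1, 10.0), (0, 13.0, 0.8, 0.4, 1.1, 1.9, True)])
        ev = event_table([(1, 10.0), (0, 13.0)])
        ev.loc[1, ["amplitude", "rise_time", "fall_time", "fdhm"]] = [0.8, 0.4, 1.1, 1.9]
        cases = build_cases(ev, tg, 6.0)
        out = characteristics_by_k(cases, ev)
        assert out.loc[1, "amplitude"] == pytest.approx(0.8)
        assert out.loc[1, "fdhm"] == pytest.approx(1.9)


class TestPermutation:
    def test_counts_preserved(self):
        ev = event_table([(1, 1.0), (1, 2.0), (2, 5.0), (3, 9.0)])
        rng = np.random.default_rng(0)
        perm = permute_event_times(ev, rng)
        assert perm.groupby("cell_id").size().equals(ev.groupby("cell_id").size())
        assert sorted(perm.peak_time) == sorted(ev.peak_time)

    def test_single_active_cell_identity(self):
        tg = star_tissue()
        ev = event_table([(0, 5.0), (0, 9.0)])
        null = temporal_permutation(ev, tg, 6.0, n_perm=5, seed=0)
        # with one active cell every permutation reproduces the observed curve
        for pn in null.values():
            if pn.values.size:
                assert np.allclose(pn.values, pn.observed, equal_nan=True)

    def test_seeded_reproducibility(self):
        tg = star_tissue()
        ev = event_table([(0, 15.0), (1, 12.0), (2, 30.0), (3, 33.0), (4, 50.0)])
        n1 = temporal_permutation(ev, tg, 6.0, n_perm=10, seed=7)
        n2 = temporal_permutation(ev, tg, 6.0, n_perm=10, seed=7)
        for key in n1:
            assert np.array_equal(n1[key].values, n2[key].values, equal_nan=True)
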