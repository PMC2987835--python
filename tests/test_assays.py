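"""Fecundity statistic, screen rule, blocked ANOVA, ROS summaries."""

import math

import pytest
from scipy import stats

from aphidmine.assays import (
    ConstructSummary,
    RosSeries,
    WellCounts,
    blocked_anova,
    initial_screen,
    production_rate,
    read_plate_tsv,
    read_ros_tsv,
    ros_summary,
    summarize_construct,
    write_plate_tsv,
    write_ros_tsv,
)


def well(construct="c", rep="r1", A=(4, 4, 4), N=(4, 4, 4), wid="w"):
    return WellCounts(construct=construct, replicate=rep, well=wid,
                      A6=A[0], A12=A[1], A14=A[2],
                      N12=N[0], N14=N[1], N17=N[2])


class TestProductionRate:
    def test_all_alive_unit_rates(self):
        assert production_rate(well(A=(4, 4, 4), N=(4, 4, 4))) == 3.0

    def test_hand_worked_mixed_counts(self):
        # 4/4 + 2/2 + 1/2 = 2.5
        assert production_rate(well(A=(4, 2, 2), N=(4, 2, 1))) == 2.5

    def test_all_dead_by_day6_excluded(self):
        assert production_rate(well(A=(0, 0, 0), N=(0, 0, 0))) is None

    def test_later_death_excludes_too(self):
        assert production_rate(well(A=(4, 0, 0), N=(5, 0, 0))) is None

    def test_linear_in_nymph_counts(self):
        base = production_rate(well(A=(4, 3, 2), N=(4, 3, 2)))
        scaled = production_rate(well(A=(4, 3, 2), N=(12, 9, 6)))
        assert scaled == pytest.approx(3 * base)

    def test_independent_of_initial_n(self):
        a = well(A=(4, 4, 4), N=(6, 6, 6))
        b = WellCounts(construct="c", replicate="r1", A6=4, A12=4, A14=4,
                       N12=6, N14=6, N17=6, initial_n=6)
        assert production_rate(a) == production_rate(b)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            well(N=(-1, 0, 0))

    def test_adults_must_not_increase(self):
        with pytest.raises(ValueError, match="non-increasing"):
            well(A=(2, 3, 3))


class TestSummarize:
    def wells_with_rates(self, rates, construct="c"):
        # A=(4,4,4): R = (N12+N14+N17)/4, so rate r needs counts summing 4r
        out = []
        for i, r in enumerate(rates):
            total = int(round(4 * r))
            n12, rem = min(total, 8), max(total - 8, 0)
            out.append(well(construct=construct, wid=f"w{i}",
                            N=(n12, min(rem, 8), max(rem - 8, 0))))
        return out

    def test_hand_computed_mean_and_se(self):
        summary = summarize_construct(self.wells_with_rates([2, 3, 4]), "c")
        assert summary.mean_rate == pytest.approx(3.0)
        assert summary.se == pytest.approx(1.0 / math.sqrt(3))  # sd 1, n 3

    def test_single_well_flagged(self):
        summary = summarize_construct(self.wells_with_rates([2.5]), "c")
        assert summary.se == 0.0 and summary.single_well

    def test_order_invariant(self):
        wells = self.wells_with_rates([1, 2, 3, 4])
        a = summarize_construct(wells, "c")
        b = summarize_construct(wells[::-1], "c")
        assert (a.mean_rate, a.se, a.n_wells) == (b.mean_rate, b.se, b.n_wells)

    def test_excluded_wells_dropped(self):
        wells = self.wells_with_rates([2, 4]) + [well(A=(0, 0, 0), N=(0, 0, 0))]
        summary = summarize_construct(wells, "c")
        assert summary.n_wells == 2 and summary.mean_rate == 3.0

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError, match="no data"):
            summarize_construct([well(A=(0, 0, 0), N=(0, 0, 0))], "c")


class TestInitialScreen:
    def s(self, name, mean, se):
        return ConstructSummary(construct=name, n_wells=18, mean_rate=mean, se=se)

    def test_hit_at_one_se(self):
        # EV SE set to 0 so every basis reduces to the candidate's SE
        ev = self.s("EV", 2.5, 0.0)
        (hit,) = initial_screen([self.s("c", 3.0, 0.4)], ev)
        assert hit.direction == "enhanced"

    def test_miss_below_one_se(self):
        ev = self.s("EV", 2.5, 0.0)
        assert initial_screen([self.s("c", 2.6, 0.4)], ev) == []

    def test_reduced_direction(self):
        ev = self.s("EV", 2.5, 0.0)
        (hit,) = initial_screen([self.s("c", 1.9, 0.4)], ev)
        assert hit.direction == "reduced"

    def test_se_bases(self):
        ev = self.s("EV", 2.5, 0.3)
        cand = self.s("c", 2.95, 0.4)
        assert initial_screen([cand], ev, "difference") == []  # 0.45 < hypot(.3,.4)
        assert initial_screen([cand], ev, "candidate")
        assert initial_screen([cand], ev, "control")
        with pytest.raises(ValueError, match="se_basis"):
            initial_screen([cand], ev, "bogus")


class TestBlockedAnova:
    def make_design(self, table):
        """table[construct][block] = list of rates (quarters of integers)."""
        wells = []
        for construct, blocks in table.items():
            for block, rates in blocks.items():
                for i, r in enumerate(rates):
                    total = int(round(4 * r))
                    wells.append(well(construct=construct, rep=block,
                                      wid=f"{construct}{block}{i}",
                                      N=(min(total, 8),
                                         min(max(total - 8, 0), 8),
                                         max(total - 16, 0))))
        return wells

    def test_textbook_two_by_three_table(self):
        # hand-worked RCBD: SS_T=1.5, SS_B=3.0, SS_E=1.0 -> F(1,2)=3.0
        wells = self.make_design({
            "T1": {"b1": [2.0], "b2": [3.0], "b3": [4.0]},
            "T2": {"b1": [3.0], "b2": [5.0], "b3": [4.0]},
        })
        res = blocked_anova(wells)
        assert res.F == pytest.approx(3.0, abs=1e-4)
        assert (res.df_treatment, res.df_residual) == (1, 2)
        assert res.p == pytest.approx(float(stats.f.sf(3.0, 1, 2)), abs=1e-4)

    def test_all_equal_values_give_f_zero(self):
        wells = self.make_design({
            "T1": {"b1": [2.0, 2.0], "b2": [2.0, 2.0]},
            "T2": {"b1": [2.0, 2.0], "b2": [2.0, 2.0]},
        })
        assert blocked_anova(wells).F == 0.0

    def test_shift_and_block_relabel_invariance(self):
        table = {
            "T1": {"b1": [1.0, 2.0], "b2": [2.0, 3.0]},
            "T2": {"b1": [2.0, 2.5], "b2": [3.0, 4.0]},
        }
        base = blocked_anova(self.make_design(table))
        shifted = {c: {b: [r + 2.0 for r in rs] for b, rs in bl.items()}
                   for c, bl in table.items()}
        relabelled = {c: {"x" + b: rs for b, rs in bl.items()}
                      for c, bl in table.items()}
        assert blocked_anova(self.make_design(shifted)).F == pytest.approx(
            base.F, rel=1e-9)
        assert blocked_anova(self.make_design(relabelled)).F == pytest.approx(
            base.F, rel=1e-9)

    def test_missing_cell_is_singular(self):
        wells = self.make_design({
            "T1": {"b1": [2.0], "b2": [3.0]},
            "T2": {"b1": [3.0]},
        })
        with pytest.raises(ValueError, match="singular design.*'T2'.*'b2'"):
            blocked_anova(wells)

    def test_needs_two_blocks(self):
        wells = self.make_design({"T1": {"b1": [2.0]}, "T2": {"b1": [3.0]}})
        with pytest.raises(ValueError, match=">= 2"):
            blocked_anova(wells)


def series(construct, disc, counts):
    return RosSeries(disc_id=disc, construct=construct,
                     times=tuple(range(len(counts))), counts=tuple(counts))


class TestRosSummary:
    def test_flat_identical_groups_p_one(self):
        data = {"EV": [series("EV", f"e{i}", [10, 10, 10]) for i in range(8)],
                "cand": [series("cand", f"c{i}", [10, 10, 10]) for i in range(8)]}
        summaries, tests = ros_summary(data)
        assert summaries["cand"].mean_max == 10.0
        assert tests["cand"].p == 1.0 and tests["cand"].undefined

    def test_hand_worked_welch(self):
        # maxima 5..12 vs 1..8: t = 4/sqrt(1.5), df = 14
        data = {"EV": [series("EV", f"e{i}", [0, v]) for i, v in
                       enumerate(range(1, 9))],
                "cand": [series("cand", f"c{i}", [0, v]) for i, v in
                         enumerate(range(5, 13))]}
        _, tests = ros_summary(data)
        t = tests["cand"]
        assert t.t == pytest.approx(4.0 / math.sqrt(1.5), abs=1e-4)
        assert t.df == pytest.approx(14.0, abs=1e-6)
        assert t.p == pytest.approx(
            2 * stats.t.sf(4.0 / math.sqrt(1.5), 14.0), abs=1e-6)

    def test_max_over_time_is_used(self):
        data = {"EV": [series("EV", f"e{i}", [1, 9, 2]) for i in range(2)],
                "cand": [series("cand", f"c{i}", [4, 3, 1]) for i in range(2)]}
        summaries, _ = ros_summary(data)
        assert summaries["EV"].mean_max == 9.0
        assert summaries["cand"].mean_max == 4.0

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            ros_summary({"cand": [series("cand", "c", [1])] * 2}, control="EV")


def test_plate_and_ros_tsv_round_trip(tmp_path):
    wells = [well(construct="EV", rep="r1", wid="w1", N=(5, 3, 2)),
             well(construct="c1", rep="r2", wid="w2", A=(4, 3, 3), N=(2, 2, 2))]
    path = tmp_path / "plate.tsv"
    write_plate_tsv(wells, path)
    assert read_plate_tsv(path) == wells

    data = {"EV": [series("EV", "d1", [1.0, 5.0, 2.0])],
            "cand": [series("cand", "d2", [0.5, 2.5, 1.0])]}
    rpath = tmp_path / "ros.tsv"
    write_ros_tsv(data, rpath)
    back = read_ros_tsv(rpath)
    assert back["EV"][0].counts == data["EV"][0].counts
    assert back["cand"][0].disc_id == "d2"
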