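import numpy as np
import pandas as pd
import pytest

from rcctriad.outcome_and_markers import (
    IhcThresholds,
    assign_cohort,
    assign_group_by_markers,
    call_marker_status,
    classification_table,
    kaplan_meier,
    logrank_test,
    survival_by_group,
)
from rcctriad.synthetic_cohort import CohortSpec, generate_clinical, generate_expression


def records(times, events, index=None):
    index = index or [f"T{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events},
                        index=pd.Index(index, name="sample_id"))


class TestMarkerRule:
    @pytest.mark.parametrize(
        "mvd,dek,msh6,expected",
        [
            (150, 20.0, 20.0, "A"),    # high MVD, DEK+, MSH6+
            (30, 20.0, 20.0, "C"),     # low MVD, DEK+, MSH6+
            (150, 20.0, 0.5, "B"),     # MSH6- trumps everything
            (30, 0.0, 0.0, "B"),       # MSH6- at any MVD / DEK
            (70, 20.0, 20.0, "unassigned"),   # indeterminate MVD
            (150, 0.5, 20.0, "unassigned"),   # DEK- with MSH6+
            (30, 0.5, 20.0, "unassigned"),
        ],
    )
    def test_rule_truth_table(self, mvd, dek, msh6, expected):
        status = call_marker_status(mvd, dek, msh6)
        assert assign_group_by_markers(status) == expected

    def test_mvd_cutoffs_are_strict(self):
        # exactly 100 is not high; exactly 50 is not low
        assert call_marker_status(100, 20, 20)[0] == "indeterminate"
        assert call_marker_status(101, 20, 20)[0] == "high"
        assert call_marker_status(50, 20, 20)[0] == "indeterminate"
        assert call_marker_status(49, 20, 20)[0] == "low"

    def test_positivity_strictly_above_one_percent(self):
        assert call_marker_status(150, 1.0, 20)[1] == "neg"
        assert call_marker_status(150, 1.01, 20)[1] == "pos"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            call_marker_status(-1, 10, 10)
        with pytest.raises(ValueError):
            call_marker_status(10, 150, 10)
        with pytest.raises(ValueError):
            IhcThresholds(mvd_low_max=120)

    def test_cohort_assignment_matches_truth_when_assignable(self, default_study):
        clin = default_study["clinical"]
        groups = assign_cohort(clin)
        assignable = groups != "unassigned"
        # assignable tumors are assigned to their true group
        agree = (groups[assignable] == clin.loc[assignable, "true_group"]).mean()
        assert agree == pytest.approx(1.0)
        # roughly three quarters of the cohort is assignable by design
        assert 0.6 <= assignable.mean() <= 0.9


class TestClassificationTable:
    def test_printed_percentages(self):
        # 48/74 ccRCC in A -> 65%; 12/19 pRCC in C -> 63%;
        # 23/46 sarcomatoid in C -> 50%
        rows = (
            [("ccRCC", "no", "A")] * 48 + [("ccRCC", "no", "B")] * 16
            + [("ccRCC", "no", "C")] * 10
            + [("pRCC", "no", "A")] * 1 + [("pRCC", "no", "B")] * 6
            + [("pRCC", "no", "C")] * 12
        )
        rows += [("ccRCC", "yes", "C")] * 23 + [("ccRCC", "yes", "A")] * 23
        idx = [f"S{i}" for i in range(len(rows))]
        ann = pd.DataFrame(
            [(r[0], r[1]) for r in rows], columns=["subtype", "sarcomatoid"],
            index=idx,
        )
        groups = pd.Series([r[2] for r in rows], index=idx)
        # restrict subtype rows to the non-sarcomatoid cohort
        table = classification_table(
            ann[ann["sarcomatoid"] == "no"], groups.loc[ann.index[ann["sarcomatoid"] == "no"]],
            fields=("subtype",),
        )
        cc = table[table["level"] == "ccRCC"].iloc[0]
        assert cc["total"] == 74 and cc["A_n"] == 48 and cc["A_pct"] == 65
        p = table[table["level"] == "pRCC"].iloc[0]
        assert p["total"] == 19 and p["C_n"] == 12 and p["C_pct"] == 63
        sarc = classification_table(ann, groups, fields=("sarcomatoid",))
        yes = sarc[sarc["level"] == "yes"].iloc[0]
        assert yes["total"] == 46 and yes["C_n"] == 23 and yes["C_pct"] == 50

    def test_rounding_half_away_from_zero(self):
        idx = [f"S{i}" for i in range(8)]
        ann = pd.DataFrame({"subtype": ["x"] * 8}, index=idx)
        groups = pd.Series(["A"] * 1 + ["B"] * 7, index=idx)
        table = classification_table(ann, groups, fields=("subtype",))
        # 1/8 = 12.5% -> 13 with half-away rounding (not banker's 12)
        assert table.iloc[0]["A_pct"] == 13


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 2, 4, 6, 7; censored at 3 and 5
        # S(2)=5/6, S(4)=5/6*3/4=0.625, S(6)=0.625*1/2=0.3125, S(7)=0
        recs = records([2, 3, 4, 5, 6, 7], [1, 0, 1, 0, 1, 1])
        km = kaplan_meier(recs).set_index("time")["survival"]
        assert km.loc[0.0] == pytest.approx(1.0)
        assert km.loc[2.0] == pytest.approx(5 / 6)
        assert km.loc[4.0] == pytest.approx(0.625)
        assert km.loc[6.0] == pytest.approx(0.3125)
        assert km.loc[7.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        recs = records([5, 10, 15], [0, 0, 0])
        km = kaplan_meier(recs)
        assert (km["survival"] == 1.0).all()

    def test_nonpositive_time_errors(self):
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier(records([0, 5], [1, 1]))


def hand_logrank_two_groups(times, events, groups):
    """Brute-force two-group log-rank chi-square over distinct event times."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    stat_num, var_sum = 0.0, 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        n1 = (at_risk["g"] == "x").sum()
        d = int(((df["t"] == t) & (df["e"] == 1)).sum())
        d1 = int(((df["t"] == t) & (df["e"] == 1) & (df["g"] == "x")).sum())
        e1 = d * n1 / n
        stat_num += d1 - e1
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return stat_num**2 / var_sum


class TestLogrank:
    def test_matches_brute_force_two_groups(self):
        rng = np.random.default_rng(0)
        times = np.concatenate([rng.exponential(20, 15), rng.exponential(60, 15)])
        events = rng.random(30) < 0.8
        groups = ["x"] * 15 + ["y"] * 15
        recs = records(times, events.astype(int))
        grp = pd.Series(groups, index=recs.index)
        stat, dof, p = logrank_test(recs, grp)
        ref = hand_logrank_two_groups(times, events.astype(int), groups)
        assert dof == 1
        assert stat == pytest.approx(ref, rel=1e-9)

    def test_three_group_separation_on_planted_cohort(self):
        spec = CohortSpec(n_primary=600, group_sizes=(200, 200, 200), seed=2)
        _, _, truth = generate_expression(spec)
        clin = generate_clinical(spec, truth)
        clin = clin[clin.index.str.startswith("P")]
        stat, dof, p = logrank_test(clin, clin["true_group"])
        assert dof == 2
        assert p < 1e-4

    def test_validations(self):
        recs = records([5, 10], [1, 1])
        with pytest.raises(ValueError, match=">= 2 groups"):
            logrank_test(recs, pd.Series(["x", "x"], index=recs.index))
        recs0 = records([5, 10], [0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(recs0, pd.Series(["x", "y"], index=recs0.index))


def test_survival_by_group_drops_unassigned(default_study):
    clin = default_study["clinical"]
    groups = assign_cohort(clin)
    curves = survival_by_group(clin, groups)
    assert "unassigned" not in curves
    assert set(curves) == {"A", "B", "C"}
    for sf in curves.values():
        assert sf["survival"].iloc[0] == pytest.approx(1.0)
        assert (sf["survival"].diff().dropna() <= 1e-12).all()
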