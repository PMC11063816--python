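"""The retrieval-dependency statistic against exact and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from loopmem.dependency import (
    PER_EVENT,
    ContingencyTable,
    DataCompletenessError,
    DependencyError,
    TableSpec,
    build_independent_table,
    build_observed_table,
    condition_summary,
    dependency_summary,
    enumerate_tables,
    joint_retrieval_proportion,
)
from loopmem.design import ROLES

# ---------------------------------------------------------------------------
# helpers


def outcomes_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "event_id", "loop", "delay",
                 "cue_role", "target_role", "correct"],
    )


def closed_event_rows(eid, corrects, subject=0, delay="delay"):
    """All six directed tests of a closed event; ``corrects`` maps
    (cue, target) -> 0/1 or is a constant."""
    rows = []
    for cue, tgt in itertools.permutations(ROLES, 2):
        c = corrects if isinstance(corrects, int) else corrects[(cue, tgt)]
        rows.append([subject, eid, "closed", delay, cue, tgt, c])
    return rows


def open_event_rows(eid, common, corrects, subject=0, delay="delay"):
    """The four directed tests of an open event through its common element."""
    rows = []
    others = [r for r in ROLES if r != common]
    for other in others:
        for cue, tgt in ((common, other), (other, common)):
            c = corrects if isinstance(corrects, int) else corrects[(cue, tgt)]
            rows.append([subject, eid, "open", delay, cue, tgt, c])
    return rows


def random_outcomes(rng, n_closed, n_open, subject=0, delay="delay"):
    rows = []
    eid = 0
    for _ in range(n_closed):
        corrects = {
            (c, t): int(rng.integers(2))
            for c, t in itertools.permutations(ROLES, 2)
        }
        rows += closed_event_rows(eid, corrects, subject, delay)
        eid += 1
    for _ in range(n_open):
        common = ROLES[rng.integers(3)]
        others = [r for r in ROLES if r != common]
        corrects = {}
        for other in others:
            corrects[(common, other)] = int(rng.integers(2))
            corrects[(other, common)] = int(rng.integers(2))
        rows += open_event_rows(eid, common, corrects, subject, delay)
        eid += 1
    return outcomes_frame(rows)


# ---------------------------------------------------------------------------
# brute-force reference implementation (explicit loops, no pandas pivots)

_KINDS = {
    "common_cue": (("A", "B"), ("A", "C")),
    "common_target": (("B", "A"), ("C", "A")),
    "mixed_ab_ca": (("A", "B"), ("C", "A")),
    "mixed_ba_ac": (("B", "A"), ("A", "C")),
}


def brute_condition(df, loop):
    lookup = {}
    for r in df.itertuples():
        lookup[(r.event_id, r.cue_role, r.target_role)] = int(r.correct)
    events = sorted(df["event_id"].unique())

    def common_of(eid):
        roles = []
        for r in df[df["event_id"] == eid].itertuples():
            roles += [r.cue_role, r.target_role]
        return max(set(roles), key=roles.count)

    if loop == "closed":
        table_defs = []
        for a in ROLES:
            for kind in ("common_cue", "common_target"):
                table_defs.append((kind, a))
    else:
        table_defs = [(kind, None) for kind in _KINDS]

    joint_data, joint_ind = [], []
    for kind, fixed_a in table_defs:
        xs, ys = [], []
        for eid in events:
            a = fixed_a if fixed_a is not None else common_of(eid)
            b, c = [r for r in ROLES if r != a]
            m = {"A": a, "B": b, "C": c}
            (c1, t1), (c2, t2) = _KINDS[kind]
            xs.append(lookup[(eid, m[c1], m[t1])])
            ys.append(lookup[(eid, m[c2], m[t2])])
        n = len(events)
        both = sum(1 for x, y in zip(xs, ys) if x == 1 and y == 1)
        neither = sum(1 for x, y in zip(xs, ys) if x == 0 and y == 0)
        joint_data.append((both + neither) / n)
        pab = sum(xs) / n
        pac = sum(ys) / n
        joint_ind.append(pab * pac + (1 - pab) * (1 - pac))
    k = len(table_defs)
    return sum(joint_data) / k, sum(joint_ind) / k


# ---------------------------------------------------------------------------


class TestEnumerateTables:
    def test_closed_has_six_specs_over_all_roles(self):
        specs = enumerate_tables("closed")
        assert len(specs) == 6
        assert {s.common_role for s in specs} == set(ROLES)
        assert all(not s.kind.startswith("mixed") for s in specs)

    def test_open_has_four_specs_sharing_common(self):
        specs = enumerate_tables("open", "location")
        assert len(specs) == 4
        assert all(s.common_role == "location" for s in specs)
        assert {s.kind for s in specs} == {
            "common_cue", "common_target", "mixed_ab_ca", "mixed_ba_ac"}

    def test_specification_errors(self):
        with pytest.raises(DependencyError):
            enumerate_tables("open")  # missing common role
        with pytest.raises(DependencyError):
            enumerate_tables("closed", "location")
        with pytest.raises(DependencyError):
            TableSpec(kind="mixed_ab_ca", loop="closed", common_role="person")


class TestObservedTable:
    spec = TableSpec(kind="common_cue", loop="closed", common_role="location")

    def frame(self, ab, ac):
        rows = []
        for eid, (x, y) in enumerate(zip(ab, ac)):
            rows.append([0, eid, "closed", "delay", "location", "person", x])
            rows.append([0, eid, "closed", "delay", "location", "object", y])
        return outcomes_frame(rows)

    def test_hand_enumerated_counts(self):
        t = build_observed_table(self.frame([1, 1, 0, 0], [1, 0, 1, 0]), self.spec)
        assert (t.c11, t.c10, t.c01, t.c00) == (1, 1, 1, 1)
        assert joint_retrieval_proportion(t) == 0.5

    def test_degenerate_corners(self):
        t = build_observed_table(self.frame([1] * 5, [1] * 5), self.spec)
        assert (t.c11, t.c10, t.c01, t.c00) == (5, 0, 0, 0)
        assert joint_retrieval_proportion(t) == 1.0
        t = build_observed_table(self.frame([1] * 5, [0] * 5), self.spec)
        assert (t.c11, t.c10, t.c01, t.c00) == (0, 5, 0, 0)
        assert joint_retrieval_proportion(t) == 0.0

    def test_absent_test_named_in_error(self):
        df = self.frame([1, 0], [1, 0])
        df = df[~((df.event_id == 1) & (df.target_role == "object"))]
        with pytest.raises(DataCompletenessError, match="event 1"):
            build_observed_table(df, self.spec)


class TestIndependentTable:
    spec = TestObservedTable.spec

    def test_expected_cells_from_marginals(self):
        frame = TestObservedTable().frame([1, 1, 0, 0], [1, 0, 1, 0])
        t = build_independent_table(frame, self.spec)
        assert t.c11 == t.c10 == t.c01 == t.c00 == pytest.approx(1.0)
        assert joint_retrieval_proportion(t) == pytest.approx(0.5)

    def test_boundary_p_ab_one(self):
        frame = TestObservedTable().frame([1] * 4, [1, 1, 0, 0])
        t = build_independent_table(frame, self.spec)
        assert t.c01 == t.c00 == 0
        assert t.c11 == pytest.approx(4 * 0.5)

    def test_symmetric_half(self):
        frame = TestObservedTable().frame([1, 0] * 8, [1, 1, 0, 0] * 4)
        t = build_independent_table(frame, self.spec)
        assert all(c == pytest.approx(4.0) for c in (t.c11, t.c10, t.c01, t.c00))

    def test_cells_conserve_event_count(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            df = random_outcomes(rng, n_closed=5, n_open=0)
            for spec in enumerate_tables("closed"):
                t = build_independent_table(df, spec)
                assert t.c11 + t.c10 + t.c01 + t.c00 == pytest.approx(5.0)


class TestContingencyTable:
    def test_cells_must_sum_to_n(self):
        with pytest.raises(DependencyError):
            ContingencyTable(c11=1, c10=1, c01=1, c00=1, n_events=5)
        with pytest.raises(DependencyError):
            joint_retrieval_proportion(
                ContingencyTable(c11=0, c10=0, c01=0, c00=0, n_events=0))


class TestDependencySummary:
    @pytest.mark.parametrize("p", [0.25, 0.5, 0.75])
    def test_all_or_none_tied_data_equals_2p_1mp(self, p):
        """Perfectly holistic outcomes: dependency is exactly 2p(1-p)."""
        n = 8
        k = int(p * n)
        rows = []
        for eid in range(n):
            rows += closed_event_rows(eid, 1 if eid < k else 0)
        for eid in range(n, 2 * n):
            common = ROLES[eid % 3]
            rows += open_event_rows(eid, common, 1 if eid - n < k else 0)
        dep = dependency_summary(outcomes_frame(rows))
        assert (dep["p_joint_data"] == 1.0).all()
        expected = 2 * p * (1 - p)
        assert dep["dependency"].to_numpy() == pytest.approx(
            [expected] * len(dep), abs=1e-12)

    def test_ceiling_gives_zero_dependency(self):
        rows = []
        for eid in range(4):
            rows += closed_event_rows(eid, 1)
        dep = dependency_summary(outcomes_frame(rows))
        assert dep["dependency"].to_numpy() == pytest.approx([0.0])

    def test_matches_brute_force_on_small_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            df = random_outcomes(
                rng, n_closed=int(rng.integers(2, 7)),
                n_open=int(rng.integers(2, 7)))
            dep = dependency_summary(df)
            for loop in ("closed", "open"):
                sub = df[df["loop"] == loop]
                jd, ji = brute_condition(sub, loop)
                row = dep[dep["loop"] == loop].iloc[0]
                assert row["p_joint_data"] == pytest.approx(jd, abs=1e-12)
                assert row["p_joint_independent"] == pytest.approx(ji, abs=1e-12)

    def test_matches_per_table_builders_on_cohort(self, cohort_outcomes):
        """The vectorized summary agrees with the explicit per-table path."""
        sub = cohort_outcomes[cohort_outcomes["subject_id"] == 7]
        dep = dependency_summary(sub)
        for loop, specs in (("closed", enumerate_tables("closed")),
                            ("open", enumerate_tables("open", PER_EVENT))):
            for delay in ("delay", "no_delay"):
                props_d, props_i = [], []
                for spec in specs:
                    obs = build_observed_table(sub, spec, loop=loop, delay=delay)
                    ind = build_independent_table(sub, spec, loop=loop, delay=delay)
                    props_d.append(joint_retrieval_proportion(obs))
                    props_i.append(joint_retrieval_proportion(ind))
                row = dep[(dep["loop"] == loop) & (dep["delay"] == delay)].iloc[0]
                assert row["p_joint_data"] == pytest.approx(np.mean(props_d), abs=1e-12)
                assert row["p_joint_independent"] == pytest.approx(np.mean(props_i), abs=1e-12)

    def test_condition_summary_layout(self, cohort_outcomes):
        table = condition_summary(cohort_outcomes)
        assert len(table) == 4
        assert {"accuracy_mean", "joint_data_mean",
                "joint_independent_mean", "dependency_mean"} <= set(table.columns)
        # joint retrieval exceeds the independent model for closed loops
        closed = table[table["loop"] == "closed"]
        assert (closed["dependency_mean"] > 0).all()
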