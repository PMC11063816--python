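"""Retrieval dependency: observed vs independent-model contingency tables.

For each subject and loop x delay condition, every pair of directed tests
that shares an element ``A`` defines a 2x2 contingency table over the
condition's events (both correct / first only / second only / both
incorrect).  The *independent model* predicts the same table from the
subject's marginal accuracies: with ``P_AB`` the mean accuracy of the
A→B test across events, its expected cells are ``N·P_AB·P_AC``,
``N·P_AC(1−P_AB)``, ``N·P_AB(1−P_AC)`` and ``N·(1−P_AB)(1−P_AC)``.

The *proportion of joint retrieval* of a table is the leading diagonal
(both correct + both incorrect) divided by the number of events; averaged
over a condition's tables (six for closed loops, four for open loops) it
yields one number per subject x condition for the data and for the
independent model.  *Retrieval dependency* is their difference — positive
when events are retrieved or forgotten holistically.

Closed loops contribute, for each of the three choices of the shared
element A, a common-cue table (A→B with A→C) and a common-target table
(B→A with C→A).  Open loops only encode the two pairs through their
common element, so A is fixed; their four tables are the common-cue and
common-target tables plus the two mixed pairings (A→B with C→A, and
B→A with A→C).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .design import DELAYS, LOOPS, ROLES

__all__ = [
    "PER_EVENT",
    "TABLE_KINDS",
    "TableSpec",
    "ContingencyTable",
    "DependencyError",
    "DataCompletenessError",
    "enumerate_tables",
    "build_observed_table",
    "build_independent_table",
    "joint_retrieval_proportion",
    "dependency_summary",
    "condition_summary",
]

#: Sentinel: resolve the shared element A from each event's own common
#: element (the role appearing in all of an open-loop event's tests).
PER_EVENT = "per_event"

TABLE_KINDS = ("common_cue", "common_target", "mixed_ab_ca", "mixed_ba_ac")

#: kind -> (first, second) directed tests in relational labels, where
#: "AB" means cue A / target B etc.
_KIND_TESTS = {
    "common_cue": ("AB", "AC"),
    "common_target": ("BA", "CA"),
    "mixed_ab_ca": ("AB", "CA"),
    "mixed_ba_ac": ("BA", "AC"),
}


class DependencyError(ValueError):
    """Invalid table specification or empty condition."""


class DataCompletenessError(DependencyError):
    """An event lacks an outcome for a directed test a table requires."""


@dataclasses.dataclass(frozen=True)
class TableSpec:
    """One 2x2 table: which pair of directed tests it crosses.

    ``common_role`` names the shared element A (a concrete role for closed
    loops; a concrete role or :data:`PER_EVENT` for open loops).  The two
    non-common roles B and C follow the canonical role order.
    """

    kind: str
    loop: str
    common_role: str

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise DependencyError(f"unknown table kind {self.kind!r}")
        if self.loop not in LOOPS:
            raise DependencyError(f"unknown loop {self.loop!r}")
        if self.loop == "closed":
            if self.common_role not in ROLES:
                raise DependencyError(
                    "closed-loop tables need a concrete common role"
                )
            if self.kind.startswith("mixed"):
                raise DependencyError(
                    "mixed tables are defined only for open loops"
                )
        else:
            if self.common_role not in ROLES and self.common_role != PER_EVENT:
                raise DependencyError(
                    f"open-loop common_role must be a role or PER_EVENT, "
                    f"got {self.common_role!r}"
                )

    def tests(self, common: str) -> tuple[tuple[str, str], tuple[str, str]]:
        """The two (cue, target) role pairs, given the resolved common role."""
        b, c = [r for r in ROLES if r != common]
        roles = {"A": common, "B": b, "C": c}
        first, second = _KIND_TESTS[self.kind]
        return (
            (roles[first[0]], roles[first[1]]),
            (roles[second[0]], roles[second[1]]),
        )


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Counts (observed) or expected counts (independent model).

    Cell order: c11 both correct, c10 first-test-only correct, c01
    second-test-only correct, c00 both incorrect.
    """

    c11: float
    c10: float
    c01: float
    c00: float
    n_events: int

    def __post_init__(self) -> None:
        cells = (self.c11, self.c10, self.c01, self.c00)
        if any(c < -1e-9 for c in cells):
            raise DependencyError("negative contingency cell")
        if abs(sum(cells) - self.n_events) > 1e-9:
            raise DependencyError(
                f"cells sum to {sum(cells)}, expected n_events={self.n_events}"
            )


def enumerate_tables(loop: str, common_role: str | None = None) -> list[TableSpec]:
    """The condition's table specs: 6 for closed loops, 4 for open loops.

    Closed loops take no ``common_role`` (A iterates over all three roles);
    open loops require one (a concrete role, or :data:`PER_EVENT` to
    resolve each event's own common element).
    """
    if loop == "closed":
        if common_role is not None:
            raise DependencyError(
                "closed loops iterate A over all roles; do not pass common_role"
            )
        return [
            TableSpec(kind=k, loop="closed", common_role=a)
            for a in ROLES
            for k in ("common_cue", "common_target")
        ]
    if loop == "open":
        if common_role is None:
            raise DependencyError("open-loop tables require common_role")
        return [
            TableSpec(kind=k, loop="open", common_role=common_role)
            for k in TABLE_KINDS
        ]
    raise DependencyError(f"unknown loop {loop!r}")


# ---------------------------------------------------------------------------
# per-table construction (single subject x condition)

def _single_condition(outcomes: pd.DataFrame, loop: str | None,
                      delay: str | None, subject_id=None) -> pd.DataFrame:
    df = outcomes
    if subject_id is not None:
        df = df[df["subject_id"] == subject_id]
    if loop is not None:
        df = df[df["loop"] == loop]
    if delay is not None:
        df = df[df["delay"] == delay]
    if df.empty:
        raise DependencyError("no outcomes in the requested condition")
    for col in ("subject_id", "loop", "delay"):
        if col in df.columns and df[col].nunique() > 1:
            raise DependencyError(
                f"outcomes span multiple values of {col!r}; filter first"
            )
    return df


def infer_common_roles(open_outcomes: pd.DataFrame) -> pd.Series:
    """Per open-loop event, the role present in every directed test."""
    melted = pd.concat(
        [
            open_outcomes[["event_id", "cue_role"]].rename(columns={"cue_role": "role"}),
            open_outcomes[["event_id", "target_role"]].rename(columns={"target_role": "role"}),
        ]
    )
    counts = melted.groupby(["event_id", "role"]).size().unstack(fill_value=0)
    n_tests = open_outcomes.groupby("event_id").size()
    common = counts.idxmax(axis=1)
    full = counts.max(axis=1) == n_tests.reindex(counts.index)
    if not full.all():
        bad = counts.index[~full].tolist()
        raise DependencyError(
            f"cannot infer a common element for open-loop events {bad}"
        )
    return common


def _correct_lookup(df: pd.DataFrame) -> dict[tuple[int, str, str], int]:
    return {
        (r.event_id, r.cue_role, r.target_role): int(r.correct)
        for r in df.itertuples()
    }


def _resolve_commons(df: pd.DataFrame, spec: TableSpec) -> pd.Series:
    events = df["event_id"].unique()
    if spec.common_role == PER_EVENT:
        return infer_common_roles(df)
    return pd.Series(spec.common_role, index=pd.Index(events, name="event_id"))


def _test_outcomes(df: pd.DataFrame, spec: TableSpec) -> tuple[np.ndarray, np.ndarray]:
    """Arrays of correctness for the spec's two directed tests, one entry
    per event of the (single subject x condition) frame."""
    lookup = _correct_lookup(df)
    commons = _resolve_commons(df, spec)
    x, y = [], []
    for eid, common in commons.items():
        (cue1, tgt1), (cue2, tgt2) = spec.tests(common)
        for cue, tgt, acc in (((cue1), (tgt1), x), ((cue2), (tgt2), y)):
            key = (eid, cue, tgt)
            if key not in lookup:
                raise DataCompletenessError(
                    f"event {eid}: no outcome for directed test "
                    f"{cue}->{tgt} required by table {spec.kind}"
                )
            acc.append(lookup[key])
    return np.asarray(x), np.asarray(y)


def build_observed_table(
    outcomes: pd.DataFrame,
    spec: TableSpec,
    loop: str | None = None,
    delay: str | None = None,
    subject_id=None,
) -> ContingencyTable:
    """Observed 2x2 counts for one subject x condition.

    ``outcomes`` must reduce (after the optional filters) to a single
    subject and condition; missing responses must already be coded
    ``correct=0``.
    """
    df = _single_condition(outcomes, loop, delay, subject_id)
    x, y = _test_outcomes(df, spec)
    return ContingencyTable(
        c11=int(np.sum((x == 1) & (y == 1))),
        c10=int(np.sum((x == 1) & (y == 0))),
        c01=int(np.sum((x == 0) & (y == 1))),
        c00=int(np.sum((x == 0) & (y == 0))),
        n_events=len(x),
    )


def build_independent_table(
    outcomes: pd.DataFrame,
    spec: TableSpec,
    loop: str | None = None,
    delay: str | None = None,
    subject_id=None,
) -> ContingencyTable:
    """Independent-model expected 2x2 cells from marginal accuracies."""
    df = _single_condition(outcomes, loop, delay, subject_id)
    x, y = _test_outcomes(df, spec)
    n = len(x)
    if n == 0:
        raise DependencyError("empty condition")
    p_ab = float(np.mean(x))
    p_ac = float(np.mean(y))
    return ContingencyTable(
        c11=n * p_ab * p_ac,
        c10=n * p_ab * (1 - p_ac),
        c01=n * p_ac * (1 - p_ab),
        c00=n * (1 - p_ab) * (1 - p_ac),
        n_events=n,
    )


def joint_retrieval_proportion(table: ContingencyTable) -> float:
    """Leading diagonal (both correct + both incorrect) over event count."""
    if table.n_events <= 0:
        raise DependencyError("table has no events")
    return (table.c11 + table.c00) / table.n_events


# ---------------------------------------------------------------------------
# cohort-level summary (vectorized)

def _closed_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per subject x delay joint proportions for closed loops (6 tables)."""
    wide = df.pivot_table(
        index=["subject_id", "delay", "event_id"],
        columns=["cue_role", "target_role"],
        values="correct",
        aggfunc="first",
    )
    expected_cols = [
        (a, b) for a, b in itertools.permutations(ROLES, 2)
    ]
    missing = [c for c in expected_cols if c not in wide.columns]
    if missing or wide.isna().any().any():
        _raise_incomplete(wide, expected_cols)
    specs = enumerate_tables("closed")
    return _tables_to_summary(wide, [
        (s.tests(s.common_role)) for s in specs
    ])


def _open_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per subject x delay joint proportions for open loops (4 tables),
    with each event's tests mapped to relational A/B/C labels."""
    commons = infer_common_roles(df)
    df = df.copy()
    df["common"] = df["event_id"].map(commons)
    cue, tgt, com = df["cue_role"], df["target_role"], df["common"]
    b_role = df["common"].map(
        {r: next(s for s in ROLES if s != r) for r in ROLES}
    )
    # relational label: A = common; B = first non-common role canonically
    label = np.where(
        cue == com,
        np.where(tgt == b_role, "AB", "AC"),
        np.where(cue == b_role, "BA", "CA"),
    )
    df["test"] = label
    wide = df.pivot_table(
        index=["subject_id", "delay", "event_id"],
        columns="test",
        values="correct",
        aggfunc="first",
    )
    expected_cols = ["AB", "AC", "BA", "CA"]
    if (
        any(c not in wide.columns for c in expected_cols)
        or wide.isna().any().any()
    ):
        _raise_incomplete(wide, expected_cols)
    return _tables_to_summary(
        wide, [_KIND_TESTS[k] for k in TABLE_KINDS]
    )


def _raise_incomplete(wide: pd.DataFrame, expected_cols) -> None:
    for col in expected_cols:
        if col not in wide.columns:
            raise DataCompletenessError(f"no outcomes at all for test {col}")
        nas = wide.index[wide[col].isna()]
        if len(nas):
            raise DataCompletenessError(
                f"missing outcome for test {col} at {tuple(nas[0])}"
            )


def _tables_to_summary(wide: pd.DataFrame, table_tests: list) -> pd.DataFrame:
    """Average per-table joint proportions over tables, per subject x delay."""
    p_data_tables = []
    p_ind_tables = []
    for first, second in table_tests:
        x = wide[first]
        y = wide[second]
        tie = (x == y).astype(float)
        p_data_tables.append(
            tie.groupby(level=["subject_id", "delay"]).mean()
        )
        p_ab = x.groupby(level=["subject_id", "delay"]).mean()
        p_ac = y.groupby(level=["subject_id", "delay"]).mean()
        p_ind_tables.append(p_ab * p_ac + (1 - p_ab) * (1 - p_ac))
    p_data = pd.concat(p_data_tables, axis=1).mean(axis=1)
    p_ind = pd.concat(p_ind_tables, axis=1).mean(axis=1)
    out = pd.DataFrame(
        {"p_joint_data": p_data, "p_joint_independent": p_ind}
    )
    out["dependency"] = out["p_joint_data"] - out["p_joint_independent"]
    return out.reset_index()


def dependency_summary(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per subject x loop x delay dependency summary.

    Returns a tidy frame with columns subject_id, loop, delay,
    p_joint_data, p_joint_independent, dependency (data − independent).
    Closed loops average six tables; open loops average four, resolving
    each event's own common element.
    """
    required = {"subject_id", "event_id", "loop", "delay",
                "cue_role", "target_role", "correct"}
    missing = required - set(outcomes.columns)
    if missing:
        raise DependencyError(f"outcomes missing columns {sorted(missing)}")
    parts = []
    for loop in LOOPS:
        sub = outcomes[outcomes["loop"] == loop]
        if sub.empty:
            continue
        summary = _closed_summary(sub) if loop == "closed" else _open_summary(sub)
        summary.insert(1, "loop", loop)
        parts.append(summary)
    if not parts:
        raise DependencyError("no outcomes to summarize")
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["subject_id", "loop", "delay"]).reset_index(drop=True)


def condition_summary(outcomes: pd.DataFrame,
                      summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Condition-level table: mean (SD) proportion correct and joint
    retrieval for data and independent model, per loop x delay."""
    if summary is None:
        summary = dependency_summary(outcomes)
    acc = (
        outcomes.groupby(["subject_id", "loop", "delay"])["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    merged = summary.merge(acc, on=["subject_id", "loop", "delay"])
    agg = merged.groupby(["loop", "delay"]).agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        joint_data_mean=("p_joint_data", "mean"),
        joint_data_sd=("p_joint_data", "std"),
        joint_independent_mean=("p_joint_independent", "mean"),
        joint_independent_sd=("p_joint_independent", "std"),
        dependency_mean=("dependency", "mean"),
        dependency_sd=("dependency", "std"),
    )
    return agg.reset_index()
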