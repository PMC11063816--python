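"""Factorial closed-/open-loop experimental designs.

Each *event* is a triad of elements (a location, a famous person, and a
common object) bound by pairwise associations.  Closed-loop events encode
all three pairs, so any element can reach any other; open-loop events
encode only the two pairs that share one *common element*, leaving the
third pair never shown.  Events are crossed with a delay factor (encoded
~24 h before retrieval vs immediately before), giving a 2x2 within-subject
design with ``n_per_cell`` events per cell.

This module generates the event assignment, the block-structured encoding
schedules with counterbalanced pair orders, and the constrained retrieval
schedules (every encoded pair tested in both directions, never two trials
from the same event in succession).
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "LOOPS",
    "DELAYS",
    "CLOSED_PAIR_ORDERS",
    "OPEN_PAIR_ORDERS",
    "DesignConfig",
    "EventStructure",
    "EncodingTrial",
    "RetrievalTrial",
    "DesignError",
    "SchedulingError",
    "generate_events",
    "default_pools",
    "build_encoding_schedule",
    "build_retrieval_schedule",
    "classify_trial_roles",
]

#: Canonical element-role order used everywhere roles need a stable ordering.
ROLES: tuple[str, str, str] = ("location", "person", "object")
LOOPS: tuple[str, str] = ("closed", "open")
DELAYS: tuple[str, str] = ("delay", "no_delay")

#: The three rotated pair orders for closed loops (one pair per block).
CLOSED_PAIR_ORDERS: tuple[tuple[tuple[str, str], ...], ...] = (
    (("person", "location"), ("location", "object"), ("object", "person")),
    (("location", "object"), ("object", "person"), ("person", "location")),
    (("object", "person"), ("person", "location"), ("location", "object")),
)

#: The three two-pair orders for open loops (blocks 2 and 3).  Each order
#: determines the common element: the role present in both pairs.
OPEN_PAIR_ORDERS: tuple[tuple[tuple[str, str], ...], ...] = (
    (("person", "location"), ("location", "object")),
    (("location", "object"), ("object", "person")),
    (("object", "person"), ("person", "location")),
)


def _common_role_of_order(order: tuple[tuple[str, str], ...]) -> str:
    (a1, b1), (a2, b2) = order
    common = {a1, b1} & {a2, b2}
    assert len(common) == 1
    return common.pop()


#: common element role -> open-loop order index
_OPEN_ORDER_BY_COMMON: dict[str, int] = {
    _common_role_of_order(o): i for i, o in enumerate(OPEN_PAIR_ORDERS)
}


class DesignError(ValueError):
    """Configuration or input violates the design's structural contract."""


class SchedulingError(RuntimeError):
    """An ordering constraint could not be satisfied within the retry budget."""


@dataclasses.dataclass(frozen=True)
class DesignConfig:
    """Sizing of the factorial design.

    Parameters
    ----------
    n_events
        Total number of events; must equal ``4 * n_per_cell``.
    n_per_cell
        Events per loop x delay cell; must be divisible by 3 so that
        open-loop common elements can be balanced across roles.
    nulls_per_run
        Null (fixation-only) trials inserted per retrieval run.
    seed
        Master seed for all randomization in design generation.
    """

    n_events: int = 72
    n_per_cell: int = 18
    nulls_per_run: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0 or self.n_per_cell <= 0 or self.nulls_per_run <= 0:
            raise DesignError("all design counts must be positive")
        if self.n_events != 4 * self.n_per_cell:
            raise DesignError(
                f"n_events ({self.n_events}) must equal 4 * n_per_cell "
                f"({4 * self.n_per_cell})"
            )
        if self.n_per_cell % 3 != 0:
            raise DesignError(
                f"n_per_cell ({self.n_per_cell}) must be divisible by 3 to "
                "balance open-loop common elements across roles"
            )


@dataclasses.dataclass(frozen=True)
class EventStructure:
    """One three-element event with its loop/delay assignment.

    ``order_index`` selects which of the three counterbalanced pair orders
    the event follows at encoding.  For open loops it is determined by the
    common element; for closed loops it is assigned (balanced) at
    generation time.
    """

    event_id: int
    elements: Mapping[str, str]
    loop: str
    delay: str
    common_element: str | None
    order_index: int

    def __post_init__(self) -> None:
        if set(self.elements) != set(ROLES):
            raise DesignError(f"event {self.event_id}: needs one element per role")
        if self.loop not in LOOPS or self.delay not in DELAYS:
            raise DesignError(f"event {self.event_id}: bad loop/delay labels")
        if (self.common_element is None) != (self.loop == "closed"):
            raise DesignError(
                f"event {self.event_id}: common_element must be set iff open loop"
            )

    @property
    def encoded_pairs(self) -> list[frozenset[str]]:
        """Unordered role pairs encoded for this event (3 closed, 2 open)."""
        if self.loop == "closed":
            return [frozenset(p) for p in itertools.combinations(ROLES, 2)]
        return [
            frozenset({self.common_element, r})
            for r in ROLES
            if r != self.common_element
        ]

    @property
    def pair_order(self) -> tuple[tuple[str, str], ...]:
        """The event's counterbalanced encoding pair order."""
        if self.loop == "closed":
            return CLOSED_PAIR_ORDERS[self.order_index]
        return OPEN_PAIR_ORDERS[self.order_index]


@dataclasses.dataclass(frozen=True)
class EncodingTrial:
    session: int
    block: int
    position: int  # 0-based within session
    event_id: int
    pair: tuple[str, str]  # (left role, right role) as shown on screen
    duration_s: float = 6.0
    fixation_s: float = 0.5
    blank_s: float = 0.5

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise DesignError("encoding pair roles must be distinct")


@dataclasses.dataclass(frozen=True)
class RetrievalTrial:
    run: int
    position: int  # 0-based within run, nulls included
    event_id: int | None
    cue_role: str | None
    target_role: str | None
    nontarget_role: str | None
    is_null: bool = False
    max_duration_s: float = 6.0
    fixation_s: float = 1.0
    blank_s: float = 1.0

    def __post_init__(self) -> None:
        if self.is_null:
            if self.event_id is not None or self.cue_role is not None:
                raise DesignError("null trials carry no event or roles")
        else:
            roles = {self.cue_role, self.target_role, self.nontarget_role}
            if roles != set(ROLES):
                raise DesignError(
                    "non-null trial roles must be a permutation of the three roles"
                )


def default_pools(n: int = 72) -> dict[str, list[str]]:
    """Synthetic label pools (``location_00`` ...), one list per role."""
    return {role: [f"{role}_{i:02d}" for i in range(n)] for role in ROLES}


def generate_events(
    config: DesignConfig,
    element_pools: Mapping[str, Sequence[str]] | None = None,
) -> list[EventStructure]:
    """Randomly assign elements and conditions to ``config.n_events`` events.

    Each pool label is used at most once.  Exactly ``n_per_cell`` events
    land in each loop x delay cell, and within each session (delay level)
    the open-loop common elements are balanced ``n_per_cell/3`` per role.
    Deterministic given ``config.seed``.
    """
    if element_pools is None:
        element_pools = default_pools(config.n_events)
    for role in ROLES:
        pool = element_pools.get(role) if isinstance(element_pools, Mapping) else None
        if pool is None:
            raise DesignError(f"element_pools missing role {role!r}")
        if len(set(pool)) < config.n_events:
            raise DesignError(
                f"pool for {role!r} has {len(set(pool))} distinct labels; "
                f"need at least {config.n_events}"
            )

    rng = np.random.default_rng(config.seed)
    chosen = {
        role: [
            element_pools[role][i]
            for i in rng.permutation(len(element_pools[role]))[: config.n_events]
        ]
        for role in ROLES
    }

    # cell assignment: shuffle event indices into the four cells
    cells = [(lo, de) for de in DELAYS for lo in LOOPS]
    order = rng.permutation(config.n_events)
    per_third = config.n_per_cell // 3
    events: list[EventStructure] = []
    pos = 0
    for loop, delay in cells:
        ids = order[pos : pos + config.n_per_cell]
        pos += config.n_per_cell
        # balanced order/common assignment within the cell
        thirds = np.repeat(np.arange(3), per_third)
        rng.shuffle(thirds)
        for eid, third in zip(ids, thirds):
            common = None
            if loop == "open":
                order_index = int(third)
                common = _common_role_of_order(OPEN_PAIR_ORDERS[order_index])
            else:
                order_index = int(third)
            events.append(
                EventStructure(
                    event_id=int(eid),
                    elements={role: chosen[role][eid] for role in ROLES},
                    loop=loop,
                    delay=delay,
                    common_element=common,
                    order_index=order_index,
                )
            )
    events.sort(key=lambda e: e.event_id)
    return events


def _session_events(events: Sequence[EventStructure], session: int) -> list[EventStructure]:
    if session not in (1, 2):
        raise DesignError(f"session must be 1 or 2, got {session}")
    delay = "delay" if session == 1 else "no_delay"
    return [e for e in events if e.delay == delay]


def build_encoding_schedule(
    events: Sequence[EventStructure],
    session: int,
    rng: np.random.Generator | None = None,
) -> list[EncodingTrial]:
    """Block-structured encoding schedule for one session.

    Session 1 encodes the delay events (~24 h before retrieval), session 2
    the no-delay events.  Block 1 holds only the first pair of every
    closed loop; blocks 2 and 3 interleave the remaining closed pairs with
    the open-loop pairs in randomized order.  Left/right screen order is
    randomized per trial.
    """
    if rng is None:
        rng = np.random.default_rng()
    sess = _session_events(events, session)
    closed = [e for e in sess if e.loop == "closed"]
    open_ = [e for e in sess if e.loop == "open"]
    if len(closed) != len(open_) or not closed:
        raise DesignError(
            f"session {session}: need equal nonzero closed/open event counts, "
            f"got {len(closed)}/{len(open_)}"
        )

    trials: list[EncodingTrial] = []
    position = 0

    def emit(block: int, entries: list[tuple[EventStructure, tuple[str, str]]]) -> None:
        nonlocal position
        idx = rng.permutation(len(entries))
        for i in idx:
            event, pair = entries[i]
            if rng.random() < 0.5:
                pair = (pair[1], pair[0])
            trials.append(
                EncodingTrial(
                    session=session, block=block, position=position,
                    event_id=event.event_id, pair=pair,
                )
            )
            position += 1

    # block 1: closed loops only (their first counterbalanced pair)
    emit(1, [(e, e.pair_order[0]) for e in closed])
    # blocks 2-3: closed pair k, open pair k-1, intermixed
    for block in (2, 3):
        entries = [(e, e.pair_order[block - 1]) for e in closed]
        entries += [(e, e.pair_order[block - 2]) for e in open_]
        emit(block, entries)
    return trials


def _clash_free_at(idx: list[int], keys: list[int], positions: tuple[int, ...]) -> bool:
    n = len(idx)
    for p in positions:
        if 1 <= p < n and keys[idx[p]] == keys[idx[p - 1]]:
            return False
    return True


def _repair_adjacencies(
    idx: list[int], keys: list[int], rng: np.random.Generator, max_passes: int = 60
) -> bool:
    """Swap clashing items to random positions until no adjacent pair shares
    a key; returns False if a clash could not be placed anywhere."""
    n = len(idx)
    for _ in range(max_passes):
        bad = [j for j in range(1, n) if keys[idx[j]] == keys[idx[j - 1]]]
        if not bad:
            return True
        j = bad[0]
        for m in rng.permutation(n):
            m = int(m)
            if m == j:
                continue
            idx[j], idx[m] = idx[m], idx[j]
            if _clash_free_at(idx, keys, (j, j + 1, m, m + 1)):
                break
            idx[j], idx[m] = idx[m], idx[j]
        else:
            return False
    return False


def _order_without_adjacent_repeats(
    keys: list[int], rng: np.random.Generator, max_retries: int = 10_000
) -> list[int]:
    """Permutation of ``range(len(keys))`` with no two consecutive equal keys.

    Uniform shuffle followed by local repair swaps; bounded reshuffles.
    """
    n = len(keys)
    for _ in range(max_retries):
        idx = [int(i) for i in rng.permutation(n)]
        if _repair_adjacencies(idx, keys, rng):
            return idx
    raise SchedulingError(
        f"could not order {n} trials without same-event adjacency "
        f"after {max_retries} attempts"
    )


def build_retrieval_schedule(
    events: Sequence[EventStructure],
    config: DesignConfig,
    rng: np.random.Generator | None = None,
) -> list[RetrievalTrial]:
    """Two-run retrieval schedule testing every encoded pair in both directions.

    Closed loops yield 6 directed tests, open loops 4 (the never-encoded
    pair is never tested).  Each run tests half of each cell's events
    (events are nested within run), contains ``nulls_per_run`` null trials,
    and never presents two trials from the same event in succession.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if len(events) != config.n_events:
        raise DesignError(
            f"expected {config.n_events} events, got {len(events)}"
        )
    half = config.n_per_cell // 2
    if config.n_per_cell % 2 != 0:
        raise DesignError("n_per_cell must be even to split events across 2 runs")

    run_of_event: dict[int, int] = {}
    for loop in LOOPS:
        for delay in DELAYS:
            cell = [e.event_id for e in events if e.loop == loop and e.delay == delay]
            if len(cell) != config.n_per_cell:
                raise DesignError(
                    f"cell ({loop}, {delay}) has {len(cell)} events, "
                    f"expected {config.n_per_cell}"
                )
            perm = rng.permutation(len(cell))
            for k, i in enumerate(perm):
                run_of_event[cell[i]] = 1 if k < half else 2

    by_id = {e.event_id: e for e in events}
    trials: list[RetrievalTrial] = []
    for run in (1, 2):
        directed: list[tuple[int, str, str]] = []
        for e in events:
            if run_of_event[e.event_id] != run:
                continue
            for pair in e.encoded_pairs:
                r1, r2 = sorted(pair, key=ROLES.index)
                directed.append((e.event_id, r1, r2))
                directed.append((e.event_id, r2, r1))
        keys = [d[0] for d in directed]
        order = _order_without_adjacent_repeats(keys, rng)
        seq = [directed[i] for i in order]

        # interleave nulls: draw insertion slots uniformly over the final grid
        n_total = len(seq) + config.nulls_per_run
        null_slots = set(
            int(s)
            for s in rng.choice(n_total, size=config.nulls_per_run, replace=False)
        )
        it = iter(seq)
        for position in range(n_total):
            if position in null_slots:
                trials.append(
                    RetrievalTrial(
                        run=run, position=position, event_id=None,
                        cue_role=None, target_role=None, nontarget_role=None,
                        is_null=True, max_duration_s=6.0,
                        fixation_s=0.0, blank_s=0.0,
                    )
                )
            else:
                eid, cue, target = next(it)
                nontarget = next(r for r in ROLES if r not in (cue, target))
                trials.append(
                    RetrievalTrial(
                        run=run, position=position, event_id=eid,
                        cue_role=cue, target_role=target,
                        nontarget_role=nontarget,
                    )
                )
        assert by_id  # events retained for future extensions
    return trials


def classify_trial_roles(trial: RetrievalTrial) -> dict[str, str]:
    """Map each element role of a non-null trial to cue/target/nontarget."""
    if trial.is_null:
        raise DesignError("null trials have no cue/target/nontarget roles")
    return {
        trial.cue_role: "cue",
        trial.target_role: "target",
        trial.nontarget_role: "nontarget",
    }
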