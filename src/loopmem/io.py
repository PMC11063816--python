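"""File formats and configuration.

Schedules are written as BIDS-style events TSV (onset, duration,
trial_type plus design columns); analysis tables are plain CSV with
validated schemas.  Configuration loads from YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from collections.abc import Sequence

import pandas as pd
import yaml

from .behavior_sim import CellParams, GenerativeParams
from .design import DesignConfig, EncodingTrial, EventStructure, RetrievalTrial
from .roi_sim import CouplingParams

__all__ = [
    "SchemaError",
    "events_to_frame",
    "encoding_events_frame",
    "retrieval_events_frame",
    "write_events_tsv",
    "read_events_tsv",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "write_contrasts_csv",
    "read_contrasts_csv",
    "load_config",
    "PipelineConfig",
    "config_hash",
]

OUTCOMES_COLUMNS = [
    "subject_id", "event_id", "loop", "delay",
    "cue_role", "target_role", "correct", "missing", "rt_s",
]
CONTRASTS_COLUMNS = [
    "subject_id", "delay", "hipp_contrast", "nontarget_contrast",
    "cue_contrast", "target_contrast",
]


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def events_to_frame(events: Sequence[EventStructure]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "loop": e.loop,
                "delay": e.delay,
                "common_element": e.common_element or "",
                "order_index": e.order_index,
                **{f"element_{r}": e.elements[r] for r in e.elements},
            }
            for e in events
        ]
    )


_BREAK_EVERY = 18  # encoding trials per mini-block before a 10 s break
_BREAK_S = 10.0


def encoding_events_frame(trials: Sequence[EncodingTrial]) -> pd.DataFrame:
    """BIDS-style frame with onsets from the stated trial timing
    (0.5 s fixation + 6 s stimulus + 0.5 s blank; 10 s break per 18 trials)."""
    rows = []
    clock = 0.0
    for i, t in enumerate(sorted(trials, key=lambda t: t.position)):
        if i > 0 and i % _BREAK_EVERY == 0:
            clock += _BREAK_S
        onset = clock + t.fixation_s
        rows.append(
            {
                "onset": onset,
                "duration": t.duration_s,
                "trial_type": "encoding",
                "session": t.session,
                "block": t.block,
                "position": t.position,
                "event_id": t.event_id,
                "left_role": t.pair[0],
                "right_role": t.pair[1],
            }
        )
        clock = onset + t.duration_s + t.blank_s
    return pd.DataFrame(rows)


def retrieval_events_frame(trials: Sequence[RetrievalTrial]) -> pd.DataFrame:
    """BIDS-style frame for the retrieval runs (1 s fixation, up to 6 s
    stimulus, 1 s blank; null trials are flat 6 s)."""
    rows = []
    for run in sorted({t.run for t in trials}):
        clock = 0.0
        for t in sorted([x for x in trials if x.run == run],
                        key=lambda t: t.position):
            onset = clock + t.fixation_s
            rows.append(
                {
                    "onset": onset,
                    "duration": t.max_duration_s,
                    "trial_type": "null" if t.is_null else "retrieval",
                    "run": t.run,
                    "position": t.position,
                    "event_id": -1 if t.event_id is None else t.event_id,
                    "cue_role": t.cue_role or "n/a",
                    "target_role": t.target_role or "n/a",
                    "nontarget_role": t.nontarget_role or "n/a",
                    "is_null": int(t.is_null),
                }
            )
            clock = onset + t.max_duration_s + t.blank_s
    return pd.DataFrame(rows)


def write_events_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False: 'null' is a trial_type and 'n/a' marks
    # inapplicable fields (BIDS convention), not pandas missing values
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ["onset", "duration", "trial_type"], str(path))
    return df


def write_outcomes_csv(outcomes: pd.DataFrame, path: str | Path) -> Path:
    _require_columns(outcomes, OUTCOMES_COLUMNS[:-1], "outcomes")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(path, index=False)
    return path


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, OUTCOMES_COLUMNS[:-1], str(path))
    for col in ("correct", "missing"):
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            row = df.index[~df[col].isin((0, 1))][0]
            raise SchemaError(
                f"{path}: column {col!r} must be 0/1 (row {row})"
            )
    bad = df[(df["missing"] == 1) & (df["correct"] == 1)]
    if len(bad):
        raise SchemaError(
            f"{path}: missing responses must be incorrect "
            f"(row {bad.index[0]})"
        )
    return df


def write_contrasts_csv(contrasts: pd.DataFrame, path: str | Path) -> Path:
    _require_columns(contrasts, CONTRASTS_COLUMNS[:2], "contrasts")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    contrasts.to_csv(path, index=False)
    return path


def read_contrasts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["subject_id", "delay", "hipp_contrast", "nontarget_contrast"],
        str(path),
    )
    return df


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (design, simulators, analysis)."""

    design: DesignConfig
    behavior: GenerativeParams
    coupling_sim: CouplingParams
    n_subjects: int = 50
    baseline: str = "within_condition"
    alpha: float = 0.05
    robustness_k_max: int = 20
    robustness_iters: int = 50
    robustness_alpha: float = 0.05 / 6
    seed: int = 0


def _build_behavior(block: dict, seed: int) -> GenerativeParams:
    cells = {}
    for key, cp in block.get("cells", {}).items():
        loop, delay = key.split(".") if isinstance(key, str) else key
        cells[(loop, delay)] = CellParams(**cp)
    kwargs = {k: v for k, v in block.items() if k != "cells"}
    if cells:
        return GenerativeParams(cells=cells, seed=seed, **kwargs)
    from .behavior_sim import default_params

    base = default_params(seed)
    return dataclasses.replace(base, **kwargs) if kwargs else base


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    seed = int(raw.get("seed", 0))
    design = DesignConfig(**{**{"seed": seed}, **raw.get("design", {})})
    behavior = _build_behavior(raw.get("behavior", {}), seed + 1)
    coupling = CouplingParams(**{**{"seed": seed + 2}, **raw.get("coupling_sim", {})})
    extra = {
        k: raw[k]
        for k in (
            "n_subjects", "baseline", "alpha",
            "robustness_k_max", "robustness_iters", "robustness_alpha",
        )
        if k in raw
    }
    return PipelineConfig(design=design, behavior=behavior,
                          coupling_sim=coupling, seed=seed, **extra)


def _jsonable(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        o = dataclasses.asdict(o)
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    return o


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
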