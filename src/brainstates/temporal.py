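"""Per-subject temporal statistics of hard state paths.

Three global statistics summarize each subject's state dynamics:
fractional occupancy (fraction of timepoints spent in a state), lifetimes
(lengths of maximal contiguous runs of a state), and interval times (gaps
between consecutive visits to a state). All are computed on hard
maximum-probability paths, in units of timepoints; an optional TR converts
to seconds for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateMetrics",
    "fractional_occupancy",
    "lifetimes",
    "intervals",
    "cohort_metrics",
]


def _validate_path(path: np.ndarray, n_states: int) -> np.ndarray:
    path = np.asarray(path)
    if path.ndim != 1 or path.size < 1:
        raise ValueError("path must be a non-empty 1-D array of state ids")
    if not np.issubdtype(path.dtype, np.integer):
        raise ValueError("path must contain integer state ids")
    if path.min() < 0 or path.max() >= n_states:
        raise ValueError(
            f"state id out of range: path uses {path.min()}..{path.max()}, K={n_states}"
        )
    return path


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs as (state, start, length) arrays."""
    change = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    return path[starts], starts, ends - starts


def fractional_occupancy(path: np.ndarray, n_states: int) -> np.ndarray:
    """Fraction of timepoints spent in each state; sums to 1 exactly."""
    path = _validate_path(path, n_states)
    return np.bincount(path, minlength=n_states) / path.size


def lifetimes(path: np.ndarray, n_states: int, censor_boundaries: bool = False) -> list[list[int]]:
    """Run lengths per state, in order of occurrence.

    Runs truncated by the start or end of the sequence are included by
    default (preserving the identity that lifetimes sum to T); set
    ``censor_boundaries`` to drop them.
    """
    path = _validate_path(path, n_states)
    states, starts, lengths = _runs(path)
    if censor_boundaries:
        keep = np.ones(states.size, dtype=bool)
        keep[0] = False
        keep[-1] = False
        states, lengths = states[keep], lengths[keep]
    out: list[list[int]] = [[] for _ in range(n_states)]
    for s, ln in zip(states, lengths):
        out[s].append(int(ln))
    return out


def intervals(path: np.ndarray, n_states: int) -> list[list[int]]:
    """Gaps (in timepoints) between consecutive visits to each state.

    A state visited at most once has an empty list.
    """
    path = _validate_path(path, n_states)
    states, starts, lengths = _runs(path)
    ends = starts + lengths  # exclusive
    out: list[list[int]] = [[] for _ in range(n_states)]
    last_end: dict[int, int] = {}
    for s, st, en in zip(states, starts, ends):
        if s in last_end:
            out[s].append(int(st - last_end[s]))
        last_end[int(s)] = int(en)
    return out


@dataclass
class StateMetrics:
    """One subject's per-state temporal statistics."""

    subject_id: str
    fractional_occupancy: np.ndarray  # length K
    lifetimes: list[list[int]]
    intervals: list[list[int]]

    @property
    def mean_lifetime(self) -> np.ndarray:
        return np.array([np.mean(v) if v else np.nan for v in self.lifetimes])

    @property
    def mean_interval(self) -> np.ndarray:
        return np.array([np.mean(v) if v else np.nan for v in self.intervals])


def subject_metrics(subject_id: str, path: np.ndarray, n_states: int,
                    censor_boundaries: bool = False) -> StateMetrics:
    return StateMetrics(
        subject_id=subject_id,
        fractional_occupancy=fractional_occupancy(path, n_states),
        lifetimes=lifetimes(path, n_states, censor_boundaries=censor_boundaries),
        intervals=intervals(path, n_states),
    )


def cohort_metrics(paths: dict[str, np.ndarray], n_states: int,
                   manifest: pd.DataFrame | None = None,
                   censor_boundaries: bool = False,
                   tr_seconds: float | None = None) -> pd.DataFrame:
    """Tidy per-(subject, state) table of temporal statistics.

    Columns: subject_id, group (if a manifest is given), state,
    fractional_occupancy, mean_lifetime, n_visits, mean_interval. Means of
    empty lists are reported as NaN. ``tr_seconds`` rescales lifetime and
    interval columns to seconds.
    """
    group_of = {}
    if manifest is not None:
        group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    rows = []
    for sid, path in paths.items():
        m = subject_metrics(sid, path, n_states, censor_boundaries=censor_boundaries)
        mlt, mit = m.mean_lifetime, m.mean_interval
        for k in range(n_states):
            rows.append({
                "subject_id": sid,
                **({"group": group_of.get(sid)} if group_of else {}),
                "state": k,
                "fractional_occupancy": m.fractional_occupancy[k],
                "mean_lifetime": mlt[k],
                "n_visits": len(m.lifetimes[k]),
                "mean_interval": mit[k],
            })
    df = pd.DataFrame(rows)
    if tr_seconds is not None:
        df["mean_lifetime"] *= tr_seconds
        df["mean_interval"] *= tr_seconds
    return df
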