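"""Per-run dynamics of brain-state sequences.

Three measures summarize how a run moves through its k states:

* fractional occupancy — fraction of the run's timepoints assigned to
  each state (sums to 1);
* dwell time — mean visit duration of each state in TRs: total
  timepoints in the state divided by its number of maximal consecutive
  episodes (e.g. for 11122112221, state 1 has 6 timepoints in 3
  episodes, dwell time 2); undefined (missing) for an absent state;
* transition probability — row-stochastic k x k matrix of moving from
  state i (row) to state j (column) between consecutive timepoints,
  self-transitions included.

Transitions are never counted across run boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ConcatMatrix


@dataclass
class StateSequence:
    """A run's per-TR state labels (1-based) plus provenance."""

    labels: np.ndarray
    subject: str
    session: str
    run: int
    condition: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.size < 2:
            raise ValidationError("a state sequence needs at least 2 timepoints")
        if self.labels.min() < 1:
            raise ValidationError("state labels are 1-based; found a label < 1")

    @property
    def n_timepoints(self) -> int:
        return self.labels.size

    @property
    def provenance(self) -> tuple[str, str, int, str]:
        return (self.subject, self.session, self.run, self.condition)


def sequences_from_model(labels: np.ndarray, concat: ConcatMatrix) -> list[StateSequence]:
    """Restrict a concatenated label vector back to per-run sequences,
    using the concatenation index (run boundaries stay intact)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != concat.n_rows:
        raise ValidationError("label vector length does not match the concatenated matrix")
    out = []
    for (subject, session, run, condition), sl in concat.run_slices():
        out.append(StateSequence(labels[sl].copy(), subject, session, run, condition))
    return out


def _check_k(labels: np.ndarray, k: int) -> None:
    if labels.max() > k:
        raise ValidationError(f"label {labels.max()} exceeds k={k}")


def fractional_occupancy(seq: StateSequence | Sequence[int], k: int) -> np.ndarray:
    """fo_i = (# timepoints in state i) / T; entries sum to 1."""
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    _check_k(labels, k)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    return counts / labels.size


def episode_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label vector: (episode state, episode length)."""
    labels = np.asarray(labels, dtype=int)
    change = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def dwell_time(seq: StateSequence | Sequence[int], k: int) -> np.ndarray:
    """Mean visit duration per state in TRs; NaN where the state is
    absent from the run."""
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    _check_k(labels, k)
    states, lengths = episode_lengths(labels)
    total = np.bincount(states, weights=lengths, minlength=k + 1)[1:]
    episodes = np.bincount(states, minlength=k + 1)[1:]
    dt = np.full(k, np.nan)
    visited = episodes > 0
    dt[visited] = total[visited] / episodes[visited]
    return dt


def transition_counts(labels: np.ndarray, k: int) -> np.ndarray:
    """k x k counts over the T - 1 consecutive label pairs of one run."""
    labels = np.asarray(labels, dtype=int)
    _check_k(labels, k)
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    return counts


def transition_matrix(
    seq: StateSequence | Sequence[int],
    k: int,
    *,
    off_diagonal_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition probabilities (row = from, column = to).

    Returns ``(tp, undefined)`` where ``undefined[i]`` marks rows with
    no outgoing transitions (absent states, or a state occupied only at
    the final timepoint); those rows are all-zero rather than silently
    imputed.  With ``off_diagonal_only`` the diagonal is dropped and
    each defined row renormalized over departures to other states.
    """
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    counts = transition_counts(labels, k)
    if off_diagonal_only:
        counts = counts.copy()
        np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1)
    undefined = row_sums == 0
    tp = np.zeros((k, k))
    tp[~undefined] = counts[~undefined] / row_sums[~undefined, None]
    return tp, undefined


@dataclass
class DynamicsRecord:
    """All three dynamics measures for one (subject, session, run)."""

    subject: str
    session: str
    run: int
    condition: str
    fo: np.ndarray
    dt: np.ndarray
    tp: np.ndarray
    tp_undefined: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.fo.size

    @property
    def absent(self) -> np.ndarray:
        """States never visited in this run (fo = 0, dt missing)."""
        return self.fo == 0


def compute_dynamics(sequences: Sequence[StateSequence], k: int) -> list[DynamicsRecord]:
    """One :class:`DynamicsRecord` per run; duplicate (subject, session,
    run) provenance is an error."""
    seen: set[tuple[str, str, int]] = set()
    records = []
    for seq in sequences:
        key = (seq.subject, seq.session, seq.run)
        if key in seen:
            raise ValidationError(f"duplicate run provenance {key}")
        seen.add(key)
        tp, undef = transition_matrix(seq, k)
        records.append(
            DynamicsRecord(
                subject=seq.subject,
                session=seq.session,
                run=seq.run,
                condition=seq.condition,
                fo=fractional_occupancy(seq, k),
                dt=dwell_time(seq, k),
                tp=tp,
                tp_undefined=undef,
            )
        )
    return records


def fo_dt_table(records: Sequence[DynamicsRecord]) -> pd.DataFrame:
    """Tidy long table: subject, session, run, condition, measure in
    {fo, dt}, state, value (dt of an absent state is NaN)."""
    rows = []
    for rec in records:
        for measure, vec in (("fo", rec.fo), ("dt", rec.dt)):
            for state in range(1, rec.k + 1):
                rows.append({
                    "subject": rec.subject, "session": rec.session,
                    "run": rec.run, "condition": rec.condition,
                    "measure": measure, "state": state,
                    "value": float(vec[state - 1]),
                })
    return pd.DataFrame(rows)


def tp_table(records: Sequence[DynamicsRecord]) -> pd.DataFrame:
    """Tidy long table of transition probabilities: one row per
    (subject, session, run, from_state, to_state); rows of states with
    no departures carry NaN and undefined=True."""
    rows = []
    for rec in records:
        for i in range(rec.k):
            for j in range(rec.k):
                undef = bool(rec.tp_undefined[i])
                rows.append({
                    "subject": rec.subject, "session": rec.session,
                    "run": rec.run, "condition": rec.condition,
                    "from_state": i + 1, "to_state": j + 1,
                    "p": np.nan if undef else float(rec.tp[i, j]),
                    "undefined": undef,
                })
    return pd.DataFrame(rows)
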