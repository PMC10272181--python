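"""K-Means identification of brain states and cluster-number selection.

Brain states are recurring whole-brain activity patterns: each timepoint
of the concatenated (subjects x sessions x runs) timeseries is assigned
to the nearest of k centroids under Euclidean distance.  The number of
states is chosen from the gain in variance explained — the increase of
BSS/TSS per unit increase of k — with the scan capped by the feasibility
bound k^2 < T needed to populate a k x k transition matrix from a single
run of T timepoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import FitError, ValidationError
from .io import ConcatMatrix

#: Rows used at most for the silhouette diagnostic (uniform subsample).
SILHOUETTE_MAX_ROWS = 5000


def max_feasible_k(T: int) -> int:
    """Largest cluster count k with k^2 < T.

    Estimating a k x k transition matrix from one run of T timepoints
    requires more transition observations (T - 1) than matrix cells, so
    the scan range is capped at the largest k whose square is strictly
    below the per-run length.  T = 217 gives k = 14.
    """
    T = int(T)
    if T < 5:
        raise ValidationError(f"no feasible k >= 2 for run length T={T} (need T >= 5)")
    k = int(np.floor(np.sqrt(T - 1)))
    # guard against floating point at perfect squares
    while (k + 1) ** 2 < T:
        k += 1
    while k ** 2 >= T:
        k -= 1
    return k


@dataclass
class StateModel:
    """A fitted k-state clustering of the concatenated timeseries.

    ``labels`` are 1-based state ids aligned to the concatenated rows.
    ``wss``/``bss`` are within- and between-cluster sums of squares;
    ``variance_explained`` = bss / (wss + bss).  ``silhouette`` is a
    diagnostic computed on a fixed-seed subsample; it never drives the
    choice of k.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    wss: float
    bss: float
    variance_explained: float
    silhouette: float
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValidationError("state labels must lie in 1..k")
        if self.centroids.shape[0] != self.k:
            raise ValidationError("centroid count does not match k")

    @property
    def tss(self) -> float:
        return self.wss + self.bss


def _total_ss(x: np.ndarray) -> float:
    mu = x.mean(axis=0)
    return float(((x - mu) ** 2).sum())


def fit_states(
    concat: ConcatMatrix | np.ndarray,
    k: int,
    n_init: int = 100,
    seed: int = 42,
    *,
    compute_silhouette: bool = True,
) -> StateModel:
    """Fit k-means with Euclidean distance; keep the restart with
    minimal within-cluster sum of squares.

    Deterministic for fixed (data, k, n_init, seed).  Raises
    :class:`FitError` when k exceeds the number of rows or all rows are
    identical (no cluster structure to estimate).
    """
    x = concat.data if isinstance(concat, ConcatMatrix) else np.asarray(concat, dtype=float)
    n = x.shape[0]
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > n:
        raise FitError(f"cannot fit k={k} states to N={n} rows")
    if np.allclose(x, x[0]):
        raise FitError("degenerate data: all rows identical")
    tss = _total_ss(x)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd").fit(x)
    wss = float(km.inertia_)
    bss = max(tss - wss, 0.0)
    labels = km.labels_.astype(int) + 1
    sil = np.nan
    if compute_silhouette:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=min(SILHOUETTE_MAX_ROWS, n), replace=False) if n > SILHOUETTE_MAX_ROWS else np.arange(n)
        sub_labels = labels[idx]
        if np.unique(sub_labels).size >= 2:
            sil = float(silhouette_score(x[idx], sub_labels))
    return StateModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        wss=wss,
        bss=bss,
        variance_explained=bss / tss if tss > 0 else 0.0,
        silhouette=sil,
        seed=seed,
        n_init=n_init,
    )


def choose_k(ks: Sequence[int], variance_explained: Sequence[float],
             threshold: float = 0.01) -> tuple[int, bool]:
    """Apply the gain-in-variance-explained rule to a VE-by-k profile.

    The chosen k is the largest k whose gain VE(k) - VE(k-1) is at least
    ``threshold`` (absolute scale; "1%" means 0.01).  When every gain is
    below threshold the smallest scanned k is returned with a warning
    flag set.
    """
    ks = list(ks)
    ve = list(variance_explained)
    if sorted(ks) != ks or len(ks) < 2 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValidationError("k range must be contiguous ascending integers, length >= 2")
    gains = {ks[i]: ve[i] - ve[i - 1] for i in range(1, len(ks))}
    passing = [k for k, g in gains.items() if g >= threshold]
    if not passing:
        return ks[0], True
    return max(passing), False


@dataclass
class KSelectionReport:
    """Diagnostics of a k scan: one row per k (VE, gain, silhouette,
    WSS, BSS), the chosen k, and the gain threshold used."""

    table: pd.DataFrame
    chosen_k: int
    threshold: float
    warning: bool = False

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chosen_k": int(self.chosen_k),
            "threshold": float(self.threshold),
            "warning": bool(self.warning),
            "per_k": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def k_selection_scan(
    concat: ConcatMatrix | np.ndarray,
    k_range: Iterable[int],
    threshold: float = 0.01,
    n_init: int = 100,
    seed: int = 42,
    *,
    compute_silhouette: bool = True,
) -> KSelectionReport:
    """Fit k-means over a contiguous k range and pick k by VE gain.

    The feasibility of ``k_range`` against the run length is the
    caller's responsibility (see :func:`max_feasible_k`); the scan
    itself only needs k <= N.
    """
    ks = sorted(int(k) for k in k_range)
    rows = []
    for k in ks:
        m = fit_states(concat, k, n_init=n_init, seed=seed, compute_silhouette=compute_silhouette)
        rows.append({"k": k, "wss": m.wss, "bss": m.bss,
                     "variance_explained": m.variance_explained, "silhouette": m.silhouette})
    table = pd.DataFrame(rows)
    table["gain"] = table["variance_explained"].diff()
    chosen, warn = choose_k(ks, table["variance_explained"].tolist(), threshold)
    if warn:
        warnings.warn(
            f"all VE gains below threshold {threshold}; defaulting to k={chosen}",
            stacklevel=2,
        )
    return KSelectionReport(table=table, chosen_k=chosen, threshold=threshold, warning=warn)


def canonical_order(model: StateModel) -> StateModel:
    """Relabel states 1..k by descending overall fractional occupancy.

    Ties keep the original index order; centroid rows and the label
    vector are permuted consistently.  Idempotent.
    """
    counts = np.bincount(model.labels, minlength=model.k + 1)[1:]
    # stable argsort on negated counts: ties resolved by original index
    order = np.argsort(-counts, kind="stable")
    mapping = np.empty(model.k + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        mapping[old + 1] = new
    return replace(
        model,
        centroids=model.centroids[order].copy(),
        labels=mapping[model.labels],
    )


@dataclass
class AbsenceAudit:
    """Counts of states never visited, per run and aggregated.

    A subject may simply never express some state in a given run; the
    audit quantifies how often that happens so that the correspondence
    of state labels across participants can be judged for each k.
    """

    k: int
    per_run: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.per_run["n_absent"].sum())

    def by_session(self) -> pd.Series:
        return self.per_run.groupby("session")["n_absent"].sum()

    def by_run(self) -> pd.Series:
        return self.per_run.groupby("run")["n_absent"].sum()


def absence_audit(sequences: Sequence, k: int) -> AbsenceAudit:
    """Count, for each run's state sequence, how many of the k states
    never occur.  Raises on labels outside 1..k."""
    rows = []
    for seq in sequences:
        labels = np.asarray(seq.labels, dtype=int)
        if labels.min() < 1 or labels.max() > k:
            raise ValidationError(
                f"sequence {seq.provenance} has labels outside 1..{k}"
            )
        present = np.unique(labels)
        rows.append({
            "subject": seq.subject,
            "session": seq.session,
            "run": seq.run,
            "condition": seq.condition,
            "n_absent": int(k - present.size),
        })
    return AbsenceAudit(k=k, per_run=pd.DataFrame(rows))


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label vector as one integer per line."""
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).ravel()
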