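"""Markov-switching synthetic studies with planted ground truth.

The generator emulates the study design the analysis targets: 15
subjects scanned in two sessions (placebo, drug), three runs per
session of T = 217 timepoints where run 2 is the music run (available
for 12 of the 15 subjects).  Each run's activity is a first-order
Markov chain over k planted states with isotropic Gaussian emissions
around well-separated centroids; per-(session, run) transition matrices
plant the detectable session, run, and interaction effects.  Every
random draw derives from a single seed, so (spec, seed) reproduces a
dataset bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ParcellatedRun, save_run

DEFAULT_T = 217
DEFAULT_P = 400
DEFAULT_K = 4
#: Pairwise centroid distance and emission noise of the default study;
#: separation/noise = 16 keeps states well-identified after z-scoring.
DEFAULT_SEPARATION = 8.0
DEFAULT_NOISE_SD = 0.5
#: Baseline self-transition probability of the planted chains.
DEFAULT_P_STAY = 0.7
#: Default planted effects: the drug session lowers state-2 persistence
#: (a session effect on dwell time) and raises the 3 -> 4 transition in
#: its final rest run (a session x run effect on transition probability).
DEFAULT_DT_EFFECT = 0.10
DEFAULT_TP_SHIFT = 0.06


def _check_stochastic(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("transition matrix must be square")
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError("transition matrix rows must be non-negative and sum to 1")
    return m


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible chain (left
    eigenvector of eigenvalue 1, normalized)."""
    m = _check_stochastic(matrix)
    vals, vecs = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def uniform_offdiagonal_matrix(k: int, p_stay: float) -> np.ndarray:
    """k x k matrix with constant self-transition probability and the
    remainder spread evenly over the other states."""
    if not 0 <= p_stay < 1 or k < 2:
        raise ValidationError("need 0 <= p_stay < 1 and k >= 2")
    m = np.full((k, k), (1 - p_stay) / (k - 1))
    np.fill_diagonal(m, p_stay)
    return m


def shift_transition(matrix: np.ndarray, from_state: int, to_state: int,
                     shift: float) -> np.ndarray:
    """Move probability mass ``shift`` from the (from, from) diagonal to
    (from, to), keeping the row stochastic.  States are 1-based."""
    m = _check_stochastic(matrix).copy()
    i, j = from_state - 1, to_state - 1
    if i == j:
        raise ValidationError("shift target must differ from the source state")
    if m[i, i] < shift:
        raise ValidationError("not enough diagonal mass to shift")
    m[i, i] -= shift
    m[i, j] += shift
    return m


@dataclass
class SyntheticSpec:
    """All knobs of a synthetic study; defaults emulate the target
    design (15 subjects, 12 with the music run, 2 sessions x 3 runs of
    T = 217, k = 4 planted states)."""

    n_subjects: int = 15
    n_music_subjects: int = 12
    P: int = DEFAULT_P
    T: int = DEFAULT_T
    k_true: int = DEFAULT_K
    centroid_separation: float = DEFAULT_SEPARATION
    noise_sd: float = DEFAULT_NOISE_SD
    transition_matrices: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    seed: int = 0
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.n_music_subjects > self.n_subjects:
            raise ValidationError("n_music_subjects cannot exceed n_subjects")
        if self.centroid_separation <= 0 or self.noise_sd < 0:
            raise ValidationError("centroid_separation must be > 0 and noise_sd >= 0")
        if not self.transition_matrices:
            self.transition_matrices = default_transition_matrices(self.k_true)
        for key, m in self.transition_matrices.items():
            mat = _check_stochastic(m)
            if mat.shape[0] != self.k_true:
                raise ValidationError(f"transition matrix for {key} is not {self.k_true} x {self.k_true}")
            self.transition_matrices[key] = mat

    def matrix_for(self, session: str, run: int) -> np.ndarray:
        return self.transition_matrices[(session, run)]


def default_transition_matrices(
    k: int = DEFAULT_K,
    p_stay: float = DEFAULT_P_STAY,
    dt_effect: float = DEFAULT_DT_EFFECT,
    tp_shift: float = DEFAULT_TP_SHIFT,
) -> dict[tuple[str, int], np.ndarray]:
    """Per-(session, run) chains of the default study.

    Placebo runs share a uniform-off-diagonal baseline.  The drug
    session lowers state 2's self-transition probability by
    ``dt_effect`` in every run (shorter state-2 dwell times under the
    drug) and additionally moves ``tp_shift`` of state 3's diagonal
    mass onto the 3 -> 4 transition in run 3 only (a session x run
    effect confined to the post-music rest run).  Both effects vanish
    when their sizes are 0, giving a null study.
    """
    base = uniform_offdiagonal_matrix(k, p_stay)
    drug = base.copy()
    if dt_effect:
        if k < 2:
            raise ValidationError("need k >= 2 for the dwell-time effect")
        drug[1, 1] -= dt_effect
        off = [j for j in range(k) if j != 1]
        drug[1, off] += dt_effect / len(off)
    matrices: dict[tuple[str, int], np.ndarray] = {}
    for run in (1, 2, 3):
        matrices[("placebo", run)] = base.copy()
        matrices[("drug", run)] = drug.copy()
    if tp_shift and k >= 4:
        matrices[("drug", 3)] = shift_transition(matrices[("drug", 3)], 3, 4, tp_shift)
    return matrices


def null_transition_matrices(k: int = DEFAULT_K, p_stay: float = DEFAULT_P_STAY) -> dict[tuple[str, int], np.ndarray]:
    """Identical chains everywhere: no session, run or interaction
    effect (for calibration studies)."""
    return default_transition_matrices(k, p_stay, dt_effect=0.0, tp_shift=0.0)


def make_centroids(k_true: int, P: int, separation: float, seed: int,
                   *, orthogonal: bool = False) -> np.ndarray:
    """Random unit directions scaled so every pairwise Euclidean
    distance is at least ``separation``; deterministic per seed."""
    if k_true < 2:
        raise ValidationError("need at least 2 centroids")
    if orthogonal and k_true > P:
        raise ValidationError(f"cannot draw {k_true} orthogonal directions in {P} dimensions")
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((k_true, P))
    if orthogonal:
        directions, _ = np.linalg.qr(directions.T)
        directions = directions.T[:k_true]
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    dists = np.linalg.norm(directions[:, None] - directions[None, :], axis=-1)
    min_dist = dists[np.triu_indices(k_true, k=1)].min()
    if min_dist == 0:
        raise ValidationError("degenerate draw: coincident directions")
    return directions * (separation / min_dist)


def simulate_labels(transition_matrix: np.ndarray, T: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample a length-T chain (1-based labels), initial state from the
    stationary distribution."""
    m = _check_stochastic(transition_matrix)
    pi = stationary_distribution(m)
    # inverse-CDF sampling: one uniform per step against the cumulative rows
    cum = m.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random(T)
    labels = np.empty(T, dtype=int)
    state = int(np.searchsorted(np.cumsum(pi), u[0]))
    state = min(state, m.shape[0] - 1)
    labels[0] = state + 1
    for t in range(1, T):
        state = int(np.searchsorted(cum[state], u[t]))
        labels[t] = state + 1
    return labels


def simulate_run(
    centroids: np.ndarray,
    transition_matrix: np.ndarray,
    T: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "sim",
    session: str = "placebo",
    run_index: int = 1,
    condition: str = "rest",
    tr_seconds: float = 2.0,
) -> tuple[ParcellatedRun, np.ndarray]:
    """One run: Markov label chain plus isotropic Gaussian emissions
    around the labelled centroid.  Returns (run, true labels)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centroids = np.asarray(centroids, dtype=float)
    labels = simulate_labels(transition_matrix, T, rng)
    data = centroids[labels - 1] + rng.normal(0.0, noise_sd, size=(T, centroids.shape[1]))
    run = ParcellatedRun(subject_id, session, run_index, condition, data, tr_seconds)
    return run, labels


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study: planted centroids, true
    per-run label sequences (keyed by subject/session/run), and the
    generating spec."""

    spec: SyntheticSpec
    centroids: np.ndarray
    labels: dict[tuple[str, str, int], np.ndarray]


@dataclass
class StudyData:
    """A simulated study: the run list, its manifest, and the truth."""

    runs: list[ParcellatedRun]
    manifest: pd.DataFrame
    truth: SyntheticTruth


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def simulate_study(spec: SyntheticSpec, out_dir: str | Path | None = None) -> StudyData:
    """Simulate the full multi-subject study; optionally write it out.

    Every subject contributes 2 sessions x runs {1, 3}; the first
    ``n_music_subjects`` subjects also contribute the music run 2.  The
    default spec yields 15*2*2 + 12*2*1 = 84 runs and 18,228
    concatenated timepoints.  When ``out_dir`` is given, run matrices
    are written as TSV with a driving manifest, plus the truth bundle
    (spec JSON, centroid TSV, per-run label files).
    """
    root = np.random.SeedSequence(spec.seed)
    centroid_seed, run_entropy = root.spawn(2)
    centroids = make_centroids(
        spec.k_true, spec.P, spec.centroid_separation,
        seed=np.random.default_rng(centroid_seed).integers(2**31),
    )
    subjects = _subject_ids(spec.n_subjects)
    plan: list[tuple[str, str, int, str]] = []
    for subject in subjects:
        has_music = subjects.index(subject) < spec.n_music_subjects
        for session in ("placebo", "drug"):
            for run in (1, 2, 3):
                if run == 2 and not has_music:
                    continue
                plan.append((subject, session, run, "music" if run == 2 else "rest"))
    runs: list[ParcellatedRun] = []
    labels: dict[tuple[str, str, int], np.ndarray] = {}
    for child, (subject, session, run, condition) in zip(run_entropy.spawn(len(plan)), plan):
        rng = np.random.default_rng(child)
        parc, true = simulate_run(
            centroids, spec.matrix_for(session, run), spec.T, spec.noise_sd, rng,
            subject_id=subject, session=session, run_index=run, condition=condition,
            tr_seconds=spec.tr_seconds,
        )
        runs.append(parc)
        labels[(subject, session, run)] = true
    manifest = pd.DataFrame(
        {
            "path": [f"{r.subject_id}_{r.session}_run-{r.run_index}.tsv" for r in runs],
            "subject": [r.subject_id for r in runs],
            "session": [r.session for r in runs],
            "run": [r.run_index for r in runs],
            "condition": [r.condition for r in runs],
        }
    )
    truth = SyntheticTruth(spec=spec, centroids=centroids, labels=labels)
    study = StudyData(runs=runs, manifest=manifest, truth=truth)
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: StudyData, out_dir: str | Path) -> Path:
    """Write runs, manifest and truth bundle as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run, rel in zip(study.runs, study.manifest["path"]):
        save_run(run, out / rel)
    study.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    np.savetxt(truth_dir / "centroids.tsv", study.truth.centroids, delimiter="\t", fmt="%.10g")
    spec = study.truth.spec
    payload = {
        "n_subjects": spec.n_subjects,
        "n_music_subjects": spec.n_music_subjects,
        "P": spec.P,
        "T": spec.T,
        "k_true": spec.k_true,
        "centroid_separation": spec.centroid_separation,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "tr_seconds": spec.tr_seconds,
        "transition_matrices": {
            f"{session}/run-{run}": m.tolist()
            for (session, run), m in spec.transition_matrices.items()
        },
    }
    (truth_dir / "spec.json").write_text(json.dumps(payload, indent=2))
    for (subject, session, run), true in study.truth.labels.items():
        np.savetxt(truth_dir / f"{subject}_{session}_run-{run}_labels.txt", true, fmt="%d")
    return out
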