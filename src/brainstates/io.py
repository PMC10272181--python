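"""Readers, writers and containers for parcellated fMRI runs.

A *run* is one scan's T x P matrix of parcel-averaged BOLD activity
(T timepoints sampled every TR, P parcels), carried together with its
subject / session / run / condition metadata.  Files are plain delimited
text (tab by default, comma accepted), rows = timepoints, columns =
parcels, no header unless requested.  Batch loading is driven by a
manifest table with one row per run.

The study design emulated throughout the package is two sessions
(placebo vs. drug) of three runs each, where the middle run involves
music listening and the outer runs are eyes-closed rest.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, NormalizationError, ValidationError

SESSIONS = ("placebo", "drug")
CONDITIONS = ("rest", "music")

#: Columns a run manifest must provide, in no particular order.
MANIFEST_COLUMNS = ("path", "subject", "session", "run", "condition")


@dataclass
class ParcellatedRun:
    """One run's parcellated timeseries plus its design metadata.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier.
    session:
        ``"placebo"`` or ``"drug"``.
    run_index:
        1-based run number within the session (1..3 in the emulated design).
    condition:
        ``"rest"`` or ``"music"``.
    data:
        T x P float array, T >= 2 timepoints, P >= 1 parcels, no NaN/inf.
    tr_seconds:
        Sampling interval; metadata only (durations elsewhere are in TRs).
    """

    subject_id: str
    session: str
    run_index: int
    condition: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r}; expected one of {SESSIONS}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not isinstance(self.run_index, (int, np.integer)) or not 1 <= int(self.run_index) <= 3:
            raise ValidationError(f"run_index must be an integer in 1..3, got {self.run_index!r}")
        self.run_index = int(self.run_index)
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError(f"data must be 2-D (T x P), got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValidationError(f"a run needs at least 2 timepoints, got T={data.shape[0]}")
        if data.shape[1] < 1:
            raise ValidationError("a run needs at least 1 parcel")
        if not np.all(np.isfinite(data)):
            raise ValidationError("run data contains NaN or infinite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        self.data = data

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def provenance(self) -> tuple[str, str, int, str]:
        return (self.subject_id, self.session, self.run_index, self.condition)


def validate_design(run: ParcellatedRun) -> None:
    """Check the emulated-design constraint: run 2 <=> music condition."""
    is_music = run.condition == "music"
    if (run.run_index == 2) != is_music:
        raise ValidationError(
            f"run {run.run_index} of subject {run.subject_id} has condition "
            f"{run.condition!r}; in this design run 2 and only run 2 is the music run"
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def _read_matrix(path: str | Path, delimiter: str | None, header: bool) -> np.ndarray:
    """Read a delimited numeric matrix, failing loudly on ragged or
    non-numeric input with row/column coordinates."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"file not found: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str,
                         engine="python", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: file is empty")
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"{path}: ragged rows ({exc})") from exc
    if df.isna().any().any():
        r, c = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise DataFormatError(f"{path}: ragged or missing cell at row {r + 1}, column {c + 1}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = next(zip(*np.nonzero(bad)))
        raise DataFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {r + 1}, column {c + 1}"
        )
    return numeric.to_numpy(dtype=float)


def load_run(
    path: str | Path,
    subject_id: str,
    session: str,
    run_index: int,
    condition: str,
    *,
    delimiter: str | None = None,
    header: bool = False,
    tr_seconds: float = 2.0,
) -> ParcellatedRun:
    """Load one run's T x P timeseries from delimited text.

    The delimiter is sniffed from the first line when not given (tab,
    then comma, then whitespace).  Raises :class:`DataFormatError` for
    ragged rows or non-numeric cells, :class:`ValidationError` when the
    matrix violates the run invariants (e.g. a single row).
    """
    data = _read_matrix(path, delimiter, header)
    return ParcellatedRun(subject_id, session, run_index, condition, data, tr_seconds)


def save_run(run: ParcellatedRun, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a run's data matrix as headerless delimited text."""
    np.savetxt(path, run.data, delimiter=delimiter, fmt="%.10g")


def zscore_run(run: ParcellatedRun, ddof: int = 1) -> ParcellatedRun:
    """Z-score every parcel column (sample sd by default); metadata kept.

    Raises :class:`NormalizationError` naming the first constant parcel.
    """
    data = run.data
    sd = data.std(axis=0, ddof=ddof)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise NormalizationError(
            f"parcel column {zero[0]} of run {run.provenance} is constant; z-scoring undefined"
        )
    z = (data - data.mean(axis=0)) / sd
    return replace(run, data=z)


@dataclass
class ConcatMatrix:
    """Runs stacked into one N x P matrix with full row provenance.

    ``index`` has one row per data row with columns subject, session,
    run, condition, timepoint (0-based within the run); ``run_meta``
    keeps per-run metadata so :meth:`split` can reconstruct the inputs
    bit-exactly.
    """

    data: np.ndarray
    index: pd.DataFrame
    run_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.index):
            raise ValidationError("index length does not match the number of rows")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def run_slices(self) -> list[tuple[tuple[str, str, int, str], slice]]:
        """Row slice of each run, in input order."""
        out = []
        start = 0
        for row in self.run_meta.itertuples(index=False):
            stop = start + int(row.n_timepoints)
            out.append(((row.subject, row.session, int(row.run), row.condition), slice(start, stop)))
            start = stop
        return out

    def split(self) -> list[ParcellatedRun]:
        """Invert concatenation: reproduce the input run list exactly."""
        runs = []
        for (subject, session, run, condition), sl in self.run_slices():
            tr = float(self.run_meta.iloc[len(runs)].tr_seconds)
            runs.append(ParcellatedRun(subject, session, run, condition,
                                       self.data[sl].copy(), tr))
        return runs


def concatenate_runs(runs: Sequence[ParcellatedRun]) -> ConcatMatrix:
    """Stack runs row-wise into an N x P matrix, N = sum of run lengths.

    Row order follows the input run order with timepoints kept in
    temporal order; the index records each row's provenance so the
    operation is invertible.  All runs must share P.
    """
    if not runs:
        raise ValidationError("cannot concatenate an empty run list")
    p = runs[0].n_parcels
    for r in runs:
        if r.n_parcels != p:
            raise ValidationError(
                f"parcel count mismatch: run {r.provenance} has P={r.n_parcels}, expected {p}"
            )
    data = np.vstack([r.data for r in runs])
    index = pd.DataFrame(
        {
            "subject": np.repeat([r.subject_id for r in runs], [r.n_timepoints for r in runs]),
            "session": np.repeat([r.session for r in runs], [r.n_timepoints for r in runs]),
            "run": np.repeat([r.run_index for r in runs], [r.n_timepoints for r in runs]),
            "condition": np.repeat([r.condition for r in runs], [r.n_timepoints for r in runs]),
            "timepoint": np.concatenate([np.arange(r.n_timepoints) for r in runs]),
        }
    )
    run_meta = pd.DataFrame(
        {
            "subject": [r.subject_id for r in runs],
            "session": [r.session for r in runs],
            "run": [r.run_index for r in runs],
            "condition": [r.condition for r in runs],
            "n_timepoints": [r.n_timepoints for r in runs],
            "tr_seconds": [r.tr_seconds for r in runs],
        }
    )
    return ConcatMatrix(data, index, run_meta)


@dataclass
class NetworkPartition:
    """Assignment of each parcel to exactly one large-scale network."""

    parcel_ids: list[str]
    network_of: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [p for p in self.parcel_ids if p not in self.network_of]
        if missing:
            raise ValidationError(f"parcels without a network assignment: {missing[:5]}")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValidationError("duplicate parcel ids in partition")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> list[str]:
        """Distinct network names in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.parcel_ids:
            seen.setdefault(self.network_of[p], None)
        return list(seen)

    def indicator(self, network: str) -> np.ndarray:
        """0/1 membership vector over parcels, in ``parcel_ids`` order."""
        if network not in self.networks:
            raise ValidationError(f"unknown network {network!r}")
        return np.array([1.0 if self.network_of[p] == network else 0.0 for p in self.parcel_ids])


def load_network_partition(path: str | Path, *, delimiter: str | None = None) -> NetworkPartition:
    """Read a two-column parcel_id, network_name table.

    Raises :class:`DataFormatError` on an empty file or a duplicated
    parcel id.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"file not found: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, engine="python")
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty network table")
    if df.shape[1] != 2:
        raise DataFormatError(f"{path}: expected 2 columns (parcel_id, network), got {df.shape[1]}")
    parcels = df.iloc[:, 0].tolist()
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
    if dupes:
        raise DataFormatError(f"{path}: parcel listed twice: {dupes[0]!r}")
    return NetworkPartition(parcels, dict(zip(parcels, df.iloc[:, 1].tolist())))


@dataclass
class ReferenceMap:
    """A named parcel-level reference vector (e.g. a meta-analytic topic
    map resampled to the parcellation)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"reference map {self.name!r} has non-finite values")


def load_reference_map(path: str | Path, name: str | None = None) -> ReferenceMap:
    """Read a one-value-per-line parcel vector; name defaults to the
    file stem."""
    path = Path(path)
    values = _read_matrix(path, delimiter=None, header=False)
    if values.shape[1] != 1:
        raise DataFormatError(f"{path}: a reference map must be a single column, got {values.shape[1]}")
    return ReferenceMap(name or path.stem, values.ravel())


def load_manifest(path: str | Path, *, delimiter: str | None = None) -> pd.DataFrame:
    """Read a run manifest (one row per run: path, subject, session,
    run, condition) with paths resolved relative to the manifest."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"manifest not found: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: manifest missing columns {missing}")
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df


def load_study(manifest_path: str | Path, *, zscore: bool = True,
               tr_seconds: float = 2.0, strict_design: bool = True) -> list[ParcellatedRun]:
    """Load every run listed in a manifest, optionally z-scoring each.

    With ``strict_design`` the emulated-design rule (run 2 <=> music) is
    enforced on every run.
    """
    manifest = load_manifest(manifest_path)
    runs = []
    for row in manifest.itertuples(index=False):
        run = load_run(row.path, str(row.subject), row.session, int(row.run),
                       row.condition, tr_seconds=tr_seconds)
        if strict_design:
            validate_design(run)
        if zscore:
            run = zscore_run(run)
        runs.append(run)
    return runs
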