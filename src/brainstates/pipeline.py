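"""Config-driven end-to-end orchestration.

The pipeline reproduces the analysis order: load -> (z-score) ->
concatenate -> k scan -> fit at the chosen k -> canonical ordering ->
state characterization -> per-run dynamics -> group statistics.  Every
stage writes its tables under the configured output directory, the
summary is a single JSON file, and all seeds are recorded, so a re-run
with the same config reproduces all outputs bit-identically.

Stages can also be run individually (the CLI exposes them); later
stages read the text artifacts earlier stages wrote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import dynamics as _dynamics
from . import profiles as _profiles
from . import stats as _stats
from .errors import ConfigError
from .io import (
    concatenate_runs,
    load_network_partition,
    load_reference_map,
    load_study,
)

#: The two run comparisons of the analysis: rest vs. music (runs 1, 2)
#: and rest before vs. after music (runs 1, 3).
RUN_COMPARISONS = ((1, 2), (1, 3))


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, loadable from YAML."""

    manifest: str
    out_dir: str
    network_labels: str | None = None
    reference_maps: list[str] = field(default_factory=list)
    k_min: int = 2
    k_max: int | None = None  # defaults to the feasibility bound
    threshold: float = 0.01
    n_init: int = 100
    seed_clustering: int = 42
    seed_permutation: int = 0
    n_perm: int = 10000
    alpha: float = 0.05
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ConfigError("n_perm must be at least 100")
        if self.k_min < 2:
            raise ConfigError("k_min must be at least 2")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ConfigError("k_max must be >= k_min")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log(out: Path, message: str) -> None:
    with open(out / "pipeline.log", "a") as fh:
        fh.write(message + "\n")


def _load_concat(config: PipelineConfig):
    runs = load_study(config.manifest, zscore=config.zscore)
    concat = concatenate_runs(runs)
    min_t = int(concat.run_meta["n_timepoints"].min())
    bound = _cluster.max_feasible_k(min_t)
    k_max = config.k_max if config.k_max is not None else bound
    if k_max > bound:
        raise ConfigError(
            f"k_max={k_max} exceeds the feasibility bound {bound} for the shortest run (T={min_t})"
        )
    return concat, k_max


def stage_cluster(config: PipelineConfig) -> dict:
    """k scan, fit at the chosen k, canonical ordering, absence audit."""
    out = _out(config)
    concat, k_max = _load_concat(config)
    _log(out, f"cluster: N={concat.n_rows} P={concat.n_parcels} "
              f"k_range={config.k_min}..{k_max} n_init={config.n_init} seed={config.seed_clustering}")
    report = _cluster.k_selection_scan(
        concat, range(config.k_min, k_max + 1), threshold=config.threshold,
        n_init=config.n_init, seed=config.seed_clustering,
    )
    report.to_tsv(out / "k_scan.tsv")
    report.to_json(out / "k_scan.json")
    model = _cluster.fit_states(concat, report.chosen_k, n_init=config.n_init,
                                seed=config.seed_clustering)
    model = _cluster.canonical_order(model)
    np.savetxt(out / "centroids.tsv", model.centroids, delimiter="\t", fmt="%.10g")
    _cluster.write_labels(model.labels, out / "labels.txt")
    sequences = _dynamics.sequences_from_model(model.labels, concat)
    audit = _cluster.absence_audit(sequences, model.k)
    audit.per_run.to_csv(out / "absence_audit.tsv", sep="\t", index=False)
    concat.index.to_csv(out / "row_index.tsv", sep="\t", index=False)
    return {
        "chosen_k": int(report.chosen_k),
        "k_scan_warning": bool(report.warning),
        "variance_explained": float(model.variance_explained),
        "silhouette": float(model.silhouette),
        "n_rows": int(concat.n_rows),
        "n_parcels": int(concat.n_parcels),
        "absent_state_total": audit.total,
    }


def _read_model(out: Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    centroids = np.loadtxt(out / "centroids.tsv", delimiter="\t", ndmin=2)
    labels = _cluster.read_labels(out / "labels.txt")
    index = pd.read_csv(out / "row_index.tsv", sep="\t", dtype={"subject": str})
    return centroids, labels, index


def stage_characterize(config: PipelineConfig) -> dict:
    """Correlate centroids with networks and reference maps."""
    out = _out(config)
    centroids, _, _ = _read_model(out)
    summary: dict = {"n_states": int(centroids.shape[0])}
    if config.network_labels:
        partition = load_network_partition(config.network_labels)
        rows = [
            _profiles.network_profile(centroids[i], partition, state_id=i + 1)
            for i in range(centroids.shape[0])
        ]
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "network_profiles.tsv", sep="\t", index=False)
        summary["n_networks"] = len(partition.networks)
    if config.reference_maps:
        maps = [load_reference_map(p) for p in config.reference_maps]
        rows = [
            _profiles.functional_profile(centroids[i], maps, state_id=i + 1)
            for i in range(centroids.shape[0])
        ]
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "functional_profiles.tsv", sep="\t", index=False)
        summary["n_reference_maps"] = len(maps)
    _log(out, f"characterize: {summary}")
    return summary


def _sequences_from_artifacts(out: Path) -> list[_dynamics.StateSequence]:
    _, labels, index = _read_model(out)
    sequences = []
    for (subject, session, run, condition), group in index.groupby(
        ["subject", "session", "run", "condition"], sort=False
    ):
        sequences.append(_dynamics.StateSequence(
            labels[group.index.to_numpy()], str(subject), session, int(run), condition
        ))
    return sequences


def stage_dynamics(config: PipelineConfig) -> dict:
    """Per-run fractional occupancy, dwell time, transition matrices."""
    out = _out(config)
    centroids, _, _ = _read_model(out)
    k = centroids.shape[0]
    sequences = _sequences_from_artifacts(out)
    records = _dynamics.compute_dynamics(sequences, k)
    _dynamics.fo_dt_table(records).to_csv(out / "dynamics_fo_dt.tsv", sep="\t", index=False)
    _dynamics.tp_table(records).to_csv(out / "dynamics_tp.tsv", sep="\t", index=False)
    _log(out, f"dynamics: {len(records)} records, k={k}")
    return {"n_records": len(records), "k": k}


def _tp_series(tpt: pd.DataFrame, session: str, run: int, i: int, j: int) -> pd.Series:
    sub = tpt[(tpt["session"] == session) & (tpt["run"] == run)
              & (tpt["from_state"] == i) & (tpt["to_state"] == j)]
    return sub.set_index("subject")["p"]


def stage_stats(config: PipelineConfig) -> dict:
    """Normality screen, mixed models for FO/DT, permutation tests for
    transition probabilities, for both run comparisons."""
    out = _out(config)
    fo_dt = pd.read_csv(out / "dynamics_fo_dt.tsv", sep="\t", dtype={"subject": str})
    tpt = pd.read_csv(out / "dynamics_tp.tsv", sep="\t", dtype={"subject": str})
    k = int(fo_dt["state"].max())
    seed = config.seed_permutation

    ks_rows, mlm_results, perm_rows = [], [], []
    for run_a, run_b in RUN_COMPARISONS:
        pair = fo_dt[fo_dt["run"].isin([run_a, run_b])]
        comparison = f"run{run_a}_vs_run{run_b}"
        for measure in ("fo", "dt"):
            for state in range(1, k + 1):
                values = pair[(pair["measure"] == measure) & (pair["state"] == state)]["value"].dropna()
                try:
                    stat, p = _stats.ks_normality(values)
                    ks_rows.append({"comparison": comparison, "measure": measure,
                                    "state": state, "ks_stat": stat, "ks_p": p})
                except _stats.StatsError:
                    pass
                try:
                    res = _stats.fit_mlm(pair, measure, state)
                except _stats.StatsError:
                    continue
                res_tbl = _stats.mlm_results_table([res])
                res_tbl.insert(0, "comparison", comparison)
                mlm_results.append(res_tbl)
        # permutation comparisons on every transition cell:
        # later-vs-earlier run within each session, drug-vs-placebo at
        # the later run, and the session contrast of run differences
        for i in range(1, k + 1):
            for j in range(1, k + 1):
                named = {}
                for session in ("placebo", "drug"):
                    named[f"{session}_run{run_b}_vs_run{run_a}"] = (
                        _tp_series(tpt, session, run_b, i, j),
                        _tp_series(tpt, session, run_a, i, j),
                    )
                named[f"drug_vs_placebo_run{run_b}"] = (
                    _tp_series(tpt, "drug", run_b, i, j),
                    _tp_series(tpt, "placebo", run_b, i, j),
                )
                for test_name, (a, b) in named.items():
                    subjects = a.index.intersection(b.index)
                    try:
                        res = _stats.permutation_paired(
                            a.loc[subjects].to_numpy(), b.loc[subjects].to_numpy(),
                            n_perm=config.n_perm, seed=seed, from_state=i, to_state=j,
                        )
                    except _stats.StatsError:
                        continue
                    row = _stats.permutation_results_table([res])
                    row.insert(0, "test", test_name)
                    row.insert(0, "comparison", comparison)
                    perm_rows.append(row)
                # difference of run differences between sessions
                d = {}
                for session in ("placebo", "drug"):
                    hi = _tp_series(tpt, session, run_b, i, j)
                    lo = _tp_series(tpt, session, run_a, i, j)
                    subjects = hi.index.intersection(lo.index)
                    d[session] = hi.loc[subjects] - lo.loc[subjects]
                subjects = d["drug"].index.intersection(d["placebo"].index)
                try:
                    res = _stats.permutation_diff_of_diffs(
                        d["drug"].loc[subjects].to_numpy(),
                        d["placebo"].loc[subjects].to_numpy(),
                        n_perm=config.n_perm, seed=seed, from_state=i, to_state=j,
                    )
                except _stats.StatsError:
                    continue
                row = _stats.permutation_results_table([res])
                row.insert(0, "test", "session_diff_of_run_diffs")
                row.insert(0, "comparison", comparison)
                perm_rows.append(row)

    pd.DataFrame(ks_rows).to_csv(out / "ks_normality.tsv", sep="\t", index=False)
    mlm_table = pd.concat(mlm_results, ignore_index=True)
    mlm_table.to_csv(out / "mlm_results.tsv", sep="\t", index=False)
    perm_table = pd.concat(perm_rows, ignore_index=True)
    perm_table.to_csv(out / "permutation_results.tsv", sep="\t", index=False)
    _log(out, f"stats: {len(mlm_table)} MLM effects, {len(perm_table)} permutation tests, "
              f"n_perm={config.n_perm} seed={seed} alpha={config.alpha}")
    return {
        "n_mlm_effects": int(len(mlm_table)),
        "n_mlm_significant": int((mlm_table["p"] < config.alpha).sum()),
        "n_permutation_tests": int(len(perm_table)),
        "n_permutation_significant": int((perm_table["p"] < config.alpha).sum()),
        "alpha": config.alpha,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write ``summary.json``."""
    out = _out(config)
    (out / "pipeline.log").write_text("")
    summary = {
        "config": {
            "manifest": str(config.manifest),
            "k_min": config.k_min,
            "k_max": config.k_max,
            "threshold": config.threshold,
            "n_init": config.n_init,
            "seed_clustering": config.seed_clustering,
            "seed_permutation": config.seed_permutation,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "zscore": config.zscore,
        },
        "cluster": stage_cluster(config),
        "characterize": stage_characterize(config),
        "dynamics": stage_dynamics(config),
        "stats": stage_stats(config),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
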