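"""Group-level inference on the dynamics measures.

Fractional occupancy and dwell time are compared with a two-level mixed
model (fixed effects: session, run, session x run; random effects by
subject), after Kolmogorov-Smirnov normality screening.  Transition
probabilities, which are not normally distributed at these sample
sizes, are compared with within-subject permutation tests: condition
labels are exchanged within each subject, which for paired data is
sign-flipping the per-subject difference.

Alpha defaults to 0.05 and p-values are reported uncorrected (the
designs targeted here are small); a Benjamini-Hochberg adjustment is
available as an explicit step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import StatsError

DEFAULT_ALPHA = 0.05


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the
    sample's mean and sd.  Returns (statistic, p)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise StatsError(f"KS normality screen needs n >= 5 finite values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("KS normality screen undefined for a zero-variance sample")
    stat, p = scipy.stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired t-test on per-subject differences, two-sided.

    Pairs with a missing value in either member are dropped; identical
    vectors (zero-variance differences) are an error rather than t = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired_t requires equal-length paired samples")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise StatsError(f"paired_t needs at least 3 complete pairs, got {x.size}")
    d = x - y
    if d.std(ddof=1) == 0:
        raise StatsError("paired_t undefined: all per-subject differences are identical")
    res = scipy.stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PermutationResult:
    """Outcome of a within-subject permutation test."""

    observed: float
    p_value: float
    n_perm: int
    seed: int
    n_pairs: int
    n_dropped: int
    statistic: str
    from_state: int | None = None
    to_state: int | None = None


def _perm_stat(diffs: np.ndarray, statistic: str) -> np.ndarray:
    """Row-wise statistic over a (draws x subjects) matrix of signed
    differences."""
    if statistic == "mean_diff":
        return diffs.mean(axis=-1)
    if statistic == "t":
        n = diffs.shape[-1]
        sd = diffs.std(axis=-1, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return diffs.mean(axis=-1) / (sd / np.sqrt(n))
    raise StatsError(f"unknown permutation statistic {statistic!r}")


def permutation_paired(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    *,
    statistic: Literal["mean_diff", "t"] = "mean_diff",
    from_state: int | None = None,
    to_state: int | None = None,
) -> PermutationResult:
    """Paired two-condition permutation test by within-subject label
    exchange.

    Swapping a subject's condition labels negates that subject's paired
    difference, so the null is built by sign-flipping each difference
    independently, ``n_perm`` Monte-Carlo draws with a fixed seed.  The
    two-sided p-value uses the add-one rule
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1), so p >= 1/(n_perm+1)
    and p is never exactly zero.  Incomplete pairs are dropped and
    counted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    n_dropped = int(a.size - keep.sum())
    d = (a - b)[keep]
    if d.size < 3:
        raise StatsError(f"permutation test needs at least 3 complete pairs, got {d.size}")
    observed = float(_perm_stat(d, statistic))
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = _perm_stat(signs * d, statistic)
    tol = 1e-12 * max(1.0, abs(observed))
    exceed = int(np.count_nonzero(np.abs(null) >= abs(observed) - tol))
    return PermutationResult(
        observed=observed,
        p_value=(1 + exceed) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        n_pairs=int(d.size),
        n_dropped=n_dropped,
        statistic=statistic,
        from_state=from_state,
        to_state=to_state,
    )


def permutation_diff_of_diffs(
    d_drug: Sequence[float],
    d_placebo: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    **kwargs,
) -> PermutationResult:
    """Permutation test on per-subject (later run - earlier run)
    differences contrasted between sessions: statistic
    mean(d_drug - d_placebo), same sign-flip null as
    :func:`permutation_paired` (flipping = exchanging session labels
    within a subject)."""
    return permutation_paired(d_drug, d_placebo, n_perm=n_perm, seed=seed, **kwargs)


@dataclass
class EffectTest:
    name: str
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class MlmResult:
    """Fixed-effect tests of the two-level mixed model for one
    (measure, state) cell.

    ``structure`` records which random-effects structure produced the
    reported tests: ``"slopes"`` (random intercept plus random session
    and run slopes by subject), ``"intercept"`` (fallback when the
    slopes model does not converge), or ``"degenerate"`` (zero-residual
    data; fixed effects from an exact least-squares fit).
    """

    dependent: str
    state: int
    effects: dict[str, EffectTest]
    structure: str
    converged: bool
    n_obs: int
    n_subjects: int
    n_dropped: int
    params: dict[str, float] = field(default_factory=dict)
    marginal_means: pd.DataFrame | None = None

    def effect_difference(self, factor: Literal["session", "run"]) -> float:
        """Marginal difference between the two levels of a factor
        (second level minus first in sorted order, e.g. placebo - drug
        for session), averaged over the other factor."""
        mm = self.marginal_means
        if mm is None:
            raise StatsError("marginal means unavailable")
        by = mm.groupby(factor)["mean"].mean().sort_index()
        return float(by.iloc[1] - by.iloc[0])


_FORMULA = "value ~ C(session, Sum) * C(run, Sum)"


def _containment_df(n_obs: int, n_subjects: int, rank_fe: int) -> float:
    """Containment-style denominator df for within-subject fixed
    effects: observations minus subjects minus fixed-effect rank,
    plus one for the grand mean absorbed by both."""
    return float(max(n_obs - n_subjects - rank_fe + 1, 1))


def _effect_columns(names: Sequence[str]) -> dict[str, str]:
    out = {}
    for name in names:
        if name == "Intercept":
            continue
        if ":" in name:
            out["session:run"] = name
        elif "session" in name:
            out["session"] = name
        elif "run" in name:
            out["run"] = name
    return out


def fit_mlm(
    table: pd.DataFrame,
    dependent: Literal["fo", "dt"],
    state: int,
) -> MlmResult:
    """Fit the two-level mixed model for one measure and state.

    ``table`` is the tidy fo/dt long table (columns subject, session,
    run, measure, state, value) restricted to the two runs under
    comparison.  Fixed effects are session, run and their interaction
    (sum-to-zero coding, so each single-df Wald F is the main effect);
    random effects are an intercept plus session and run slopes by
    subject, downgraded automatically to intercept-only when the slopes
    model fails to converge.  Missing values (absent-state dwell times)
    are dropped and counted.
    """
    sub = table[(table["measure"] == dependent) & (table["state"] == state)].copy()
    n_before = len(sub)
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise StatsError(f"no non-missing {dependent} values for state {state}")
    n_dropped = n_before - len(sub)
    sub["session"] = sub["session"].astype(str)
    sub["run"] = sub["run"].astype(str)
    subjects = sub["subject"].unique()
    if subjects.size < 2:
        raise StatsError("mixed model needs at least 2 subjects")
    if sub["session"].nunique() != 2 or sub["run"].nunique() != 2:
        raise StatsError("mixed model expects exactly 2 sessions and 2 runs in the table")

    ols = smf.ols(_FORMULA, data=sub).fit()
    rank_fe = int(np.linalg.matrix_rank(ols.model.exog))
    design_info = ols.model.data.design_info
    total_ss = float(((sub["value"] - sub["value"].mean()) ** 2).sum())
    cols = _effect_columns(list(ols.params.index))

    if float(ols.ssr) <= 1e-12 * max(total_ss, 1.0):
        # perfect-fit limit: variance components are unidentifiable,
        # report the exact least-squares coefficients
        effects = {eff: EffectTest(eff, np.inf, 1.0, np.nan, 0.0) for eff in cols}
        return MlmResult(
            dependent=dependent, state=state, effects=effects,
            structure="degenerate", converged=True,
            n_obs=len(sub), n_subjects=int(subjects.size), n_dropped=n_dropped,
            params=dict(ols.params),
            marginal_means=_marginal_means(design_info, ols.params, sub),
        )

    result, structure, converged = None, "slopes", False
    for re_formula, label in (("~ C(session, Sum) + C(run, Sum)", "slopes"), ("~ 1", "intercept")):
        for method in (None, "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    md = smf.mixedlm(_FORMULA, data=sub, groups=sub["subject"], re_formula=re_formula)
                    fit = (md.fit(reml=True, maxiter=200) if method is None
                           else md.fit(reml=True, method=method, maxiter=500))
                ok = bool(fit.converged) and np.all(np.isfinite(fit.bse.iloc[: len(ols.params)]))
            except Exception:
                ok = False
                fit = None
            if ok:
                result, structure, converged = fit, label, True
                break
        if converged:
            break
    if result is None:
        # last resort: report OLS-based tests, flagged as non-converged
        result, structure, converged = ols, "intercept", False

    params = result.params[: len(ols.params)] if hasattr(result, "fe_params") else result.params
    if hasattr(result, "fe_params"):
        params = result.fe_params
        bse = result.bse[: len(params)]
    else:
        bse = result.bse
    df2 = _containment_df(len(sub), int(subjects.size), rank_fe)
    effects = {}
    for eff, col in cols.items():
        coef = float(params[col])
        se = float(bse[col])
        F = (coef / se) ** 2 if se > 0 else np.inf
        effects[eff] = EffectTest(eff, F, 1.0, df2, float(scipy.stats.f.sf(F, 1, df2)))
    return MlmResult(
        dependent=dependent, state=state, effects=effects,
        structure=structure, converged=converged,
        n_obs=len(sub), n_subjects=int(subjects.size), n_dropped=n_dropped,
        params={k: float(params[k]) for k in params.index},
        marginal_means=_marginal_means(design_info, params, sub),
    )


def _marginal_means(design_info, params: pd.Series, sub: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect predicted means for every (session, run) cell."""
    grid = pd.DataFrame(
        [(s, r) for s in sorted(sub["session"].unique()) for r in sorted(sub["run"].unique())],
        columns=["session", "run"],
    )
    (exog,) = build_design_matrices([design_info], grid)
    grid["mean"] = np.asarray(exog) @ np.asarray(params)
    return grid


def mlm_results_table(results: Sequence[MlmResult]) -> pd.DataFrame:
    """Flatten mixed-model results into a tidy effects table."""
    rows = []
    for res in results:
        for eff in res.effects.values():
            rows.append({
                "dependent": res.dependent, "state": res.state, "effect": eff.name,
                "F": eff.F, "df1": eff.df1, "df2": eff.df2, "p": eff.p,
                "structure": res.structure, "converged": res.converged,
            })
    return pd.DataFrame(rows)


def permutation_results_table(results: Sequence[PermutationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.append({
            "from_state": res.from_state, "to_state": res.to_state,
            "observed": res.observed, "p": res.p_value,
            "n_perm": res.n_perm, "seed": res.seed,
            "n_pairs": res.n_pairs, "n_dropped": res.n_dropped,
            "statistic": res.statistic,
        })
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Optional Benjamini-Hochberg adjustment (off by default in the
    pipeline, matching the uncorrected reporting convention)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]
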