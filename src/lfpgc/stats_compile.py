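"""Trial compilation and between-state inference.

The analysis layer works on a tidy *trial metrics table* — a DataFrame
with one row per (trial, metric):

    state | session | segment | metric | value

``segment`` is the trial id (unique within the study); ``metric`` is a
string id such as ``gc/L-STN->L-PMC/peakB`` or ``power/L-M1/peakA``.

Stages
------
1. Outlier filtering: a trial is dropped, all metrics at once, when a
   designated per-trial summary statistic falls outside
   median +- k * MAD within its state (k = 3 by default).  With MAD
   ~ 0 (degenerate spread) nothing is excluded.
2. State summaries: mean, SEM = sd/sqrt(n) and 95% CI (1.96 x SEM) per
   metric and state.
3. Between-state tests: a linear mixed-effects model with a fixed state
   effect and a session random intercept (the compound-symmetry
   covariance structure), fitted by REML with Wald z p-values — used
   for GC metrics; or a two-sided Mann-Whitney U-test — used for power
   and coherence metrics.  Raw p-values are Benjamini-Hochberg adjusted
   across all metric x transition cells of the table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .synthgen import TRANSITIONS, transition_name

__all__ = [
    "gc_metric",
    "power_metric",
    "coh_metric",
    "filter_outliers",
    "compile_state",
    "lmm_compare",
    "mwu_compare",
    "bh_adjust",
    "build_delta_report",
    "reml_random_intercept",
]

TRIAL_COLUMNS = ("state", "session", "segment", "metric", "value")

#: per-trial summary metric used by the outlier filter for the GC table
GC_SUMMARY_METRIC = "summary/gc_overall_mean"
#: pre-normalization 5-50 Hz power summary (catches gain artifacts,
#: which per-segment normalization would otherwise hide from GC)
POWER_SUMMARY_METRIC = "summary/band_power"


def gc_metric(source: str, target: str, band: str) -> str:
    return f"gc/{source}->{target}/{band}"


def power_metric(channel: str, band: str) -> str:
    return f"power/{channel}/{band}"


def coh_metric(ch1: str, ch2: str, band: str) -> str:
    return f"coh/{ch1}&{ch2}/{band}"


def parse_metric(metric: str) -> dict:
    kind, mid, band = metric.split("/")
    out = {"kind": kind, "band": band}
    if kind == "gc":
        out["source"], out["target"] = mid.split("->")
    elif kind == "coh":
        out["ch1"], out["ch2"] = mid.split("&")
    else:
        out["channel"] = mid
    return out


# ---------------------------------------------------------------------------
# outlier filtering


def filter_outliers(table: pd.DataFrame, k: float = 3.0,
                    summary_metrics=(GC_SUMMARY_METRIC,),
                    mad_floor: float = 1e-12):
    """Median +- k*MAD trial filter, all-or-nothing per trial.

    For each summary metric and each state, trials whose summary value
    deviates from the state median by more than ``k`` times the median
    absolute deviation are excluded (union over summary metrics).  A
    near-zero MAD disables exclusion for that (metric, state).

    Returns (kept_table, excluded_trial_ids).
    """
    trials = table[["state", "session", "segment"]].drop_duplicates()
    counts = trials.groupby("state").size()
    if (counts < 5).any():
        warnings.warn(
            "fewer than 5 trials in some state; outlier thresholds will "
            "be unreliable"
        )
    excluded: set[str] = set()
    for sm in summary_metrics:
        rows = table[table["metric"] == sm]
        if rows.empty:
            warnings.warn(f"summary metric {sm!r} absent; skipped by filter")
            continue
        for state, grp in rows.groupby("state"):
            v = grp["value"].to_numpy(dtype=float)
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad < mad_floor * max(1.0, abs(med)):
                continue
            bad = np.abs(v - med) > k * mad
            excluded.update(grp["segment"].to_numpy()[bad])
    kept = table[~table["segment"].isin(excluded)]
    if kept.empty:
        raise ValueError("outlier filter excluded every trial")
    return kept, sorted(excluded)


def compile_state(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and 95% CI per (metric, state) across trials."""
    def _agg(g: pd.Series):
        n = g.size
        mean = g.mean()
        if n < 2:
            warnings.warn("single trial for a (metric, state); SEM undefined")
            sem = np.nan
        else:
            sem = g.std(ddof=1) / np.sqrt(n)
        return pd.Series({"mean": mean, "sem": sem, "n_trials": n,
                          "ci95": 1.96 * sem})

    out = (table.groupby(["metric", "state"])["value"]
           .apply(_agg).unstack().reset_index())
    out["n_trials"] = out["n_trials"].astype(int)
    return out


# ---------------------------------------------------------------------------
# linear mixed model (random intercept == compound symmetry), REML


def reml_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Profiled REML fit of  y = X b + u_group + e.

    The marginal covariance is sigma2_e (I + lambda Z Z') with
    lambda = sigma2_b / sigma2_e — a compound-symmetry (exchangeable)
    within-group structure.  Block structure makes every quantity
    closed-form given lambda, which is then optimized on a log grid.

    Returns dict with beta, cov_beta, sigma2_e, sigma2_b, loglambda.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, kdim = X.shape
    uniq, inv = np.unique(groups, return_inverse=True)
    G = uniq.size
    n_i = np.bincount(inv).astype(float)
    # per-group sufficient statistics
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((G, kdim))
    Sy = np.zeros(G)
    np.add.at(Sx, inv, X)
    np.add.at(Sy, inv, y)

    def components(lam: float):
        c = lam / (1.0 + lam * n_i)  # shrinkage per group
        XtWX = XtX - (Sx * c[:, None]).T @ Sx
        XtWy = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        # r'Wr = y'Wy - 2 b'X'Wy + b'X'WX b
        ytWy = yty - float(c @ Sy**2)
        rss = ytWy - 2.0 * float(beta @ XtWy) + float(beta @ XtWX @ beta)
        rss = max(rss, 1e-300)
        return beta, XtWX, rss

    def neg2_reml(lam: float) -> float:
        beta, XtWX, rss = components(lam)
        sigma2 = rss / (N - kdim)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        return ((N - kdim) * np.log(sigma2)
                + float(np.sum(np.log1p(lam * n_i)))
                + logdet_x)

    res = scipy.optimize.minimize_scalar(
        lambda u: neg2_reml(np.exp(u)), bounds=(-16.0, 16.0),
        method="bounded", options={"xatol": 1e-8},
    )
    lam_hat = float(np.exp(res.x))
    if neg2_reml(0.0) <= res.fun:  # boundary: no between-group variance
        lam_hat = 0.0
    beta, XtWX, rss = components(lam_hat)
    sigma2 = rss / (N - kdim)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma2_e": sigma2,
        "sigma2_b": lam_hat * sigma2,
        "lambda": lam_hat,
    }


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 1.0 if est == 0 else 0.0
    z = est / se
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def lmm_compare(table: pd.DataFrame, transitions=TRANSITIONS,
                adjust: bool = True) -> pd.DataFrame:
    """Between-state contrasts via the random-intercept REML model.

    For each metric and transition (a -> b), the model value ~ state
    with a session random intercept is fitted on the two states'
    trials; the state fixed effect is the mean difference (b minus a)
    after adjusting for session clustering, tested with a Wald z-test.
    Cells whose fit fails are flagged and excluded from the BH family.
    """
    rows = []
    for metric, mgrp in table.groupby("metric", sort=True):
        if metric.startswith("summary/"):
            continue
        for a, b in transitions:
            sub = mgrp[mgrp["state"].isin([a, b])]
            if sub["state"].nunique() < 2:
                continue
            n_sessions = sub.groupby("state")["session"].nunique()
            if (n_sessions < 2).any():
                warnings.warn(
                    f"{metric} {a}->{b}: fewer than 2 sessions in a state; "
                    "session variance weakly identified"
                )
            y = sub["value"].to_numpy(dtype=float)
            X = np.column_stack([
                np.ones(len(sub)),
                (sub["state"] == b).to_numpy(dtype=float),
            ])
            try:
                fit = reml_random_intercept(y, X, sub["session"].to_numpy())
                est = float(fit["beta"][1])
                se = float(np.sqrt(fit["cov_beta"][1, 1]))
                p = _wald_p(est, se)
                ok = np.isfinite(p)
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(f"{metric} {a}->{b}: LMM failed ({exc})")
                est, se, p, ok = np.nan, np.nan, np.nan, False
            rows.append({
                "metric": metric,
                "transition": transition_name(a, b),
                "estimate": est,
                "se": se,
                "p_raw": p,
                "direction": "increase" if est > 0 else "decrease",
                "test": "lmm",
                "converged": ok,
            })
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out = _attach_adjusted(out)
    return out


def mwu_compare(table: pd.DataFrame, transitions=TRANSITIONS,
                cap: int | None = None, seed: int = 0,
                adjust: bool = True) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparisons per metric and transition.

    Exact p-values when both groups have <= 8 untied values; otherwise
    the normal approximation with tie correction.  When ``cap`` is set,
    larger groups are randomly subsampled to ``cap`` values with a
    seeded generator (a fidelity option mirroring tooling limits; off
    by default).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for metric, mgrp in table.groupby("metric", sort=True):
        if metric.startswith("summary/"):
            continue
        for a, b in transitions:
            x = mgrp.loc[mgrp["state"] == a, "value"].to_numpy(dtype=float)
            y = mgrp.loc[mgrp["state"] == b, "value"].to_numpy(dtype=float)
            if min(x.size, y.size) < 3:
                continue
            if cap is not None:
                if x.size > cap:
                    x = rng.choice(x, size=cap, replace=False)
                if y.size > cap:
                    y = rng.choice(y, size=cap, replace=False)
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):
                warnings.warn(f"{metric} {a}->{b}: all values tied; p = 1")
                p, est = 1.0, 0.0
            else:
                no_ties = np.unique(pooled).size == pooled.size
                method = ("exact" if (x.size <= 8 and y.size <= 8 and no_ties)
                          else "asymptotic")
                p = float(scipy.stats.mannwhitneyu(
                    x, y, alternative="two-sided", method=method).pvalue)
                est = float(np.median(y) - np.median(x))
            rows.append({
                "metric": metric,
                "transition": transition_name(a, b),
                "estimate": est,
                "p_raw": p,
                "direction": "increase" if est > 0 else "decrease",
                "test": "mwu",
                "converged": True,
                "subsampled": cap is not None,
            })
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out = _attach_adjusted(out)
    return out


# ---------------------------------------------------------------------------
# multiple comparisons and reporting


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _attach_adjusted(out: pd.DataFrame) -> pd.DataFrame:
    out = out.copy()
    out["p_adj"] = np.nan
    ok = out["converged"] & out["p_raw"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


def build_delta_report(comparisons: pd.DataFrame, channels,
                       alpha: float = 0.05):
    """Significance-gated state-transition report.

    Returns (table, deltas): ``table`` adds a ``significant`` flag
    (adjusted p < alpha); ``deltas`` maps (transition, band) to an
    n x n integer matrix over ``channels`` with +1 / -1 at
    [target, source] for significant increases / decreases of directed
    GC cells and 0 elsewhere (non-significant entries suppressed).
    """
    table = comparisons.copy()
    table["significant"] = (table["p_adj"] < alpha).fillna(False)
    idx = {ch: i for i, ch in enumerate(channels)}
    n = len(channels)
    deltas: dict[tuple[str, str], np.ndarray] = {}
    for _, row in table[table["significant"]].iterrows():
        info = parse_metric(row["metric"])
        if info["kind"] != "gc":
            continue
        key = (row["transition"], info["band"])
        mat = deltas.setdefault(key, np.zeros((n, n), dtype=int))
        sgn = 1 if row["direction"] == "increase" else -1
        mat[idx[info["target"]], idx[info["source"]]] = sgn
    return table, deltas
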