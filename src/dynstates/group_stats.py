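"""Covariate-residualized group comparisons of connectivity and dynamics.

Edgewise differences use a two-sample comparison on OLS residuals
(equivalently a one-way ANOVA, F = t^2) with Benjamini-Hochberg FDR across
all edges within a state.  Network-level tests compare subject-level
within-network mean z values with Bonferroni correction; dwell-time tests
and a cross-state coefficient-of-variance ANOVA round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "EdgewiseResult",
    "residualize_covariates",
    "edgewise_group_differences",
    "bh_fdr",
    "network_level_tests",
    "network_summary",
    "percent_deviation",
    "dwell_group_tests",
    "cross_state_variability",
]


@dataclass
class EdgewiseResult:
    state: str
    estimate: np.ndarray  # control - patient mean residual, per edge
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    mask: np.ndarray  # significant at q <= fdr_level
    fdr_level: float
    n_control: int
    n_patient: int


def _design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"covariate_{i}" for i in range(C.shape[1])]
    X = np.column_stack([np.ones(len(C)), C])
    return X, ["intercept"] + names


def residualize_covariates(values, covariates):
    """OLS residuals of each column of ``values`` on covariates + intercept.

    Residuals are centered (the intercept is regressed out along with the
    covariates).  A rank-deficient design fails, naming the collinear
    columns.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    X, names = _design(covariates, values.shape[0])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        r = 0
        for j in range(X.shape[1]):
            new_r = np.linalg.matrix_rank(X[:, : j + 1])
            if new_r == r:
                bad.append(names[j])
            r = new_r
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return resid[:, 0] if squeeze else resid


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection mask and monotone q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    qvals = np.empty(m)
    qvals[order] = qvals_sorted
    mask = qvals <= q
    return mask, qvals


def _two_sample_t(resid: np.ndarray, is_control: np.ndarray):
    """Vectorized pooled-variance two-sample t per column (control - patient)."""
    a = resid[is_control]
    b = resid[~is_control]
    na, nb = len(a), len(b)
    est = a.mean(axis=0) - b.mean(axis=0)
    sp2 = (a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = est / np.sqrt(sp2 * (1 / na + 1 / nb))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=na + nb - 2)
    return est, t, p


def _group_mask(group_labels) -> np.ndarray:
    g = np.asarray(group_labels)
    if g.dtype.kind in "biu":
        return g == 0  # 0 = control
    return g == "control"


def edgewise_group_differences(
    profiles: np.ndarray,
    group_labels,
    covariates=None,
    state: str = "",
    fdr_level: float = 0.05,
) -> EdgewiseResult:
    """Per-edge control-vs-patient comparison on covariate residuals.

    ``profiles`` is (n_subjects, n_edges) of per-state mean z values for
    subjects who expressed the state.  FDR is controlled across all edges of
    this state.
    """
    profiles = np.asarray(profiles, dtype=float)
    is_control = _group_mask(group_labels)
    if is_control.sum() == 0 or (~is_control).sum() == 0:
        raise ValueError("both groups must be non-empty")
    resid = residualize_covariates(profiles, covariates)
    est, t, p = _two_sample_t(resid, is_control)
    mask, qvals = bh_fdr(p, fdr_level)
    return EdgewiseResult(
        state=state,
        estimate=est,
        t_stat=t,
        p_value=p,
        q_value=qvals,
        mask=mask,
        fdr_level=fdr_level,
        n_control=int(is_control.sum()),
        n_patient=int((~is_control).sum()),
    )


def network_level_tests(
    profiles_by_state: Mapping[str, np.ndarray],
    group_labels_by_state: Mapping[str, Sequence],
    covariates_by_state: Mapping | None,
    network_edges: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group tests on subject-level within-network mean z, per (state, network).

    Bonferroni correction spans the whole tested family (all state x network
    cells).  Networks with no within-network edges fail loudly.
    """
    rows = []
    for state, profiles in profiles_by_state.items():
        profiles = np.asarray(profiles, dtype=float)
        is_control = _group_mask(group_labels_by_state[state])
        cov = covariates_by_state[state] if covariates_by_state else None
        for net, edges in network_edges.items():
            if len(edges) == 0:
                raise ValueError(f"network {net!r} has no within-network edges")
            means = profiles[:, edges].mean(axis=1)
            resid = residualize_covariates(means, cov)
            est, t, p = _two_sample_t(resid[:, None], is_control)
            rows.append(
                {
                    "state": state,
                    "network": net,
                    "estimate": float(est[0]),
                    "t": float(t[0]),
                    "p": float(p[0]),
                }
            )
    df = pd.DataFrame(rows)
    n_tests = len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * n_tests, 1.0)
    df["significant"] = df["p_bonferroni"] <= alpha
    return df


def percent_deviation(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value is zero")
    return 100.0 * (value - reference) / reference


def network_summary(
    profiles_by_state: Mapping[str, np.ndarray],
    network_edges: Mapping[str, np.ndarray],
    reference_state: str,
) -> pd.DataFrame:
    """Mean within-network z per state plus percent deviation from a reference."""
    rows = []
    ref_means = {}
    for net, edges in network_edges.items():
        ref_means[net] = float(
            np.asarray(profiles_by_state[reference_state])[:, edges].mean()
        )
    for state, profiles in profiles_by_state.items():
        profiles = np.asarray(profiles, dtype=float)
        for net, edges in network_edges.items():
            mean_z = float(profiles[:, edges].mean())
            rows.append(
                {
                    "state": state,
                    "network": net,
                    "mean_z": mean_z,
                    "pct_deviation_from_reference": (
                        percent_deviation(mean_z, ref_means[net])
                        if state != reference_state and ref_means[net] != 0
                        else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def dwell_group_tests(
    dwell: pd.DataFrame,
    group_labels,
    covariates=None,
) -> pd.DataFrame:
    """Two-sample t on covariate-residualized dwell fractions, per state.

    ``dwell`` is subjects x states.
    """
    is_control = _group_mask(group_labels)
    resid = residualize_covariates(dwell.to_numpy(dtype=float), covariates)
    est, t, p = _two_sample_t(resid, is_control)
    return pd.DataFrame(
        {"state": list(dwell.columns), "estimate": est, "t": t, "p": p}
    )


def cross_state_variability(
    network_means: pd.DataFrame,
    cv_eps: float = 1e-8,
):
    """Coefficient of variance of network connectivity across states.

    ``network_means`` has columns (solution, state, network, mean_z): the
    mean within-network z per state, for each clustering solution.  CV per
    (solution, network) is sample SD across states / mean across states;
    near-zero-mean networks are flagged undefined (NaN).  A repeated-measures
    ANOVA treats solutions as repeated measures of the network factor, with
    Bonferroni-corrected pairwise post-hocs.

    Returns (cv table, anova table or None, post-hoc table or None).
    """
    rows = []
    for (sol, net), sub in network_means.groupby(["solution", "network"]):
        vals = sub["mean_z"].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        cv = float("nan") if abs(mean) < cv_eps else sd / mean
        rows.append({"solution": sol, "network": net, "cv": cv})
    cv_df = pd.DataFrame(rows)

    complete = cv_df.dropna()
    nets = sorted(complete["network"].unique())
    sols = sorted(complete["solution"].unique())
    usable = [
        n for n in nets if set(complete.loc[complete["network"] == n, "solution"]) >= set(sols)
    ]
    anova = posthoc = None
    if len(usable) >= 2 and len(sols) >= 2:
        sub = complete[complete["network"].isin(usable)]
        anova = AnovaRM(sub, depvar="cv", subject="solution", within=["network"]).fit()
        wide = sub.pivot(index="solution", columns="network", values="cv")
        ph_rows = []
        pairs = list(combinations(usable, 2))
        for a, b in pairs:
            t, p = stats.ttest_rel(wide[a], wide[b])
            ph_rows.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "t": float(t),
                    "p": float(p),
                    "p_bonferroni": min(float(p) * len(pairs), 1.0),
                }
            )
        posthoc = pd.DataFrame(ph_rows)
    return cv_df, anova, posthoc
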