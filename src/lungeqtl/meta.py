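"""Cross-cohort combination of eQTL association results.

Inverse-variance fixed-effect pooling, Cochran's Q heterogeneity statistic
with its chi-square P value, the DerSimonian-Laird moment estimator of the
between-study variance tau^2, random-effects pooling with weights
1/(se^2 + tau^2), and the replication rule (same SNP-transcript association
with the same effect sign at P <= 1e-4 in more than one cohort).

Pairs missing from some cohorts are combined over the k cohorts that carry
them; with k = 1 the meta estimate equals the single cohort's estimate and
Q is undefined (reported missing).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fixed_effect",
    "cochran_q",
    "tau_squared",
    "random_effect",
    "combine",
    "meta_scan",
    "assess_replication",
]

DEFAULT_ALPHA_REP = 1e-4


def _check(betas: np.ndarray, ses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("empty input")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have the same length")
    if np.any(s <= 0) or np.any(np.isnan(s)) or np.any(np.isnan(b)):
        raise ValueError("standard errors must be positive and finite")
    return b, s


def fixed_effect(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, float, float]:
    """Inverse-variance fixed-effect estimate: (beta, se, z, two-sided P)."""
    b, s = _check(betas, ses)
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, float(z), max(p, np.finfo(float).tiny)


def cochran_q(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, int, float]:
    """Cochran's Q = sum w_i (beta_i - beta_FE)^2 with w_i = 1/se_i^2.

    Under homogeneity Q is chi-square with k-1 degrees of freedom, which
    calibrates the returned P value.
    """
    b, s = _check(betas, ses)
    if b.size < 2:
        raise ValueError("Cochran's Q requires at least two studies")
    w = 1.0 / s**2
    beta_fe = (w * b).sum() / w.sum()
    q = float((w * (b - beta_fe) ** 2).sum())
    df = b.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def tau_squared(q: float, df: int, weights: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimator tau^2 = max(0, (Q-df)/(S1 - S2/S1))."""
    if df < 1:
        raise ValueError("df must be >= 1")
    w = np.asarray(weights, dtype=float)
    s1 = w.sum()
    denom = s1 - (w**2).sum() / s1
    if denom <= 0:
        warnings.warn("degenerate weights in DerSimonian-Laird estimator; tau^2 set to 0")
        return 0.0
    return float(max(0.0, (q - df) / denom))


def random_effect(
    betas: Sequence[float], ses: Sequence[float], tau2: float
) -> tuple[float, float, float, float]:
    """Random-effects estimate with weights 1/(se_i^2 + tau^2)."""
    b, s = _check(betas, ses)
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    widened = np.sqrt(s**2 + tau2)
    return fixed_effect(b, widened)


def combine(betas: Sequence[float], ses: Sequence[float]) -> dict:
    """Full meta record for one SNP x probeset pair (any k >= 1)."""
    b, s = _check(betas, ses)
    k = b.size
    beta_fe, se_fe, z, p_fe = fixed_effect(b, s)
    if k >= 2:
        q, df, q_pvalue = cochran_q(b, s)
        tau2 = tau_squared(q, df, 1.0 / s**2)
    else:
        q = df = q_pvalue = np.nan
        tau2 = 0.0
    beta_re, se_re, _, p_re = random_effect(b, s, tau2)
    return {
        "k": k,
        "beta_fe": beta_fe,
        "se_fe": se_fe,
        "p_fe": p_fe,
        "beta_re": beta_re,
        "se_re": se_re,
        "p_re": p_re,
        "q": q,
        "q_df": df,
        "q_pvalue": q_pvalue,
        "tau2": tau2,
        "tau": float(np.sqrt(tau2)),
    }


def _combine_stacks(beta: np.ndarray, se: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized meta-analysis over stacked cohort arrays.

    ``beta`` and ``se`` have shape (k_cohorts, ...); NaN marks a missing
    cohort. Returns arrays of the trailing shape. Entries with k = 0 are NaN.
    """
    ok = ~(np.isnan(beta) | np.isnan(se))
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(ok, 1.0 / se**2, 0.0)
        k = ok.sum(axis=0)
        sw = w.sum(axis=0)
        beta_fe = np.where(sw > 0, np.nansum(np.where(ok, w * beta, 0.0), axis=0) / sw, np.nan)
        se_fe = np.where(sw > 0, 1.0 / np.sqrt(sw), np.nan)
        z = beta_fe / se_fe
        p_fe = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
        q = np.nansum(np.where(ok, w * (beta - beta_fe) ** 2, 0.0), axis=0)
        df = k - 1
        q_pvalue = np.where(df >= 1, stats.chi2.sf(q, np.maximum(df, 1)), np.nan)
        sw2 = (w**2).sum(axis=0)
        denom = sw - np.where(sw > 0, sw2 / sw, 0.0)
        tau2 = np.where((df >= 1) & (denom > 0), np.maximum(0.0, (q - df) / denom), 0.0)
        w_re = np.where(ok, 1.0 / (se**2 + tau2[None]), 0.0)
        sw_re = w_re.sum(axis=0)
        beta_re = np.where(sw_re > 0, (w_re * np.where(ok, beta, 0.0)).sum(axis=0) / sw_re, np.nan)
        se_re = np.where(sw_re > 0, 1.0 / np.sqrt(sw_re), np.nan)
        z_re = beta_re / se_re
        p_re = np.minimum(2.0 * stats.norm.sf(np.abs(z_re)), 1.0)
    q = np.where(df >= 1, q, np.nan)
    tiny = np.finfo(float).tiny
    return {
        "k": k,
        "beta_fe": beta_fe,
        "se_fe": se_fe,
        "p_fe": np.where(np.isnan(p_fe), np.nan, np.maximum(p_fe, tiny)),
        "beta_re": beta_re,
        "se_re": se_re,
        "p_re": np.where(np.isnan(p_re), np.nan, np.maximum(p_re, tiny)),
        "q": q,
        "q_pvalue": q_pvalue,
        "tau2": tau2,
        "tau": np.sqrt(tau2),
    }


def meta_scan(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyze per-cohort scan tables pair by pair.

    Each table needs columns snp_id, probeset_id, beta, se (plus optionally
    cis and effect_allele). One record is returned for every pair observed in
    at least one cohort; k counts the contributing cohorts. Cohorts sharing a
    SNP must agree on its effect allele.
    """
    if not tables:
        raise ValueError("no cohort tables supplied")
    names = list(tables)
    if any("effect_allele" in t.columns for t in tables.values()):
        allele: dict[str, tuple[str, str]] = {}
        for name, t in tables.items():
            if "effect_allele" not in t.columns:
                continue
            for snp, a in zip(t["snp_id"], t["effect_allele"]):
                prev = allele.get(snp)
                if prev is not None and prev[1] != a:
                    raise ValueError(
                        f"effect allele mismatch for {snp}: {prev[1]} in {prev[0]} vs {a} in {name}"
                    )
                allele.setdefault(snp, (name, a))
    frames = []
    for name in names:
        t = tables[name][["snp_id", "probeset_id", "beta", "se"]].copy()
        t["cohort"] = name
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot(index=["snp_id", "probeset_id"], columns="cohort", values=["beta", "se"])
    wide_b = wide["beta"].reindex(columns=names)
    wide_s = wide["se"].reindex(columns=names)
    stats_ = _combine_stacks(wide_b.to_numpy().T, wide_s.to_numpy().T)
    out = wide_b.index.to_frame(index=False)
    for key, arr in stats_.items():
        out[key] = arr
    cis_cols = [t[["snp_id", "probeset_id", "cis"]] for t in tables.values() if "cis" in t.columns]
    if cis_cols:
        cis = pd.concat(cis_cols, ignore_index=True).drop_duplicates(["snp_id", "probeset_id"])
        out = out.merge(cis, on=["snp_id", "probeset_id"], how="left")
    return out


def assess_replication(
    tables: Mapping[str, pd.DataFrame],
    calls: pd.DataFrame | None = None,
    alpha_rep: float = DEFAULT_ALPHA_REP,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Apply the replication rule and per-cohort replication rates.

    A pair is replicated when at least two cohorts show the association with
    the same beta sign at P <= ``alpha_rep``. The per-cohort rate is the
    fraction of that cohort's declared eQTLs (rows of ``calls`` when given,
    else its pairs at P <= alpha_rep) supported by at least one other cohort
    with the same sign at P <= alpha_rep.
    """
    if len(tables) < 2:
        raise ValueError("replication requires at least two cohorts")
    names = list(tables)
    frames = []
    for name in names:
        t = tables[name][["snp_id", "probeset_id", "beta", "p"]].copy()
        t["cohort"] = name
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    sig = long[long["p"] <= alpha_rep].copy()
    sig["sign"] = np.sign(sig["beta"]).astype(int)
    support = (
        sig.groupby(["snp_id", "probeset_id", "sign"])["cohort"]
        .agg(list)
        .reset_index()
        .rename(columns={"cohort": "cohorts_significant"})
    )
    support["n_support"] = support["cohorts_significant"].str.len()
    best = (
        support.sort_values("n_support", ascending=False, kind="mergesort")
        .drop_duplicates(["snp_id", "probeset_id"])
    )
    if calls is not None and len(calls):
        pairs = calls[["snp_id", "probeset_id", "cohort"]].drop_duplicates()
    else:
        pairs = sig[["snp_id", "probeset_id", "cohort"]].drop_duplicates()
    records = pairs.merge(best, on=["snp_id", "probeset_id"], how="left")
    records["cohorts_significant"] = records["cohorts_significant"].apply(
        lambda v: v if isinstance(v, list) else []
    )
    records["n_support"] = records["n_support"].fillna(0).astype(int)
    records["replicated"] = records["n_support"] >= 2
    # supported elsewhere: another cohort (not the declaring one) agrees
    records["supported_elsewhere"] = [
        any(c != row.cohort for c in row.cohorts_significant)
        for row in records.itertuples(index=False)
    ]
    rates = {}
    for name in names:
        mine = records[records["cohort"] == name]
        rates[name] = float(mine["supported_elsewhere"].mean()) if len(mine) else float("nan")
    out = records[
        ["snp_id", "probeset_id", "cohort", "cohorts_significant", "replicated"]
    ].reset_index(drop=True)
    return out, rates
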