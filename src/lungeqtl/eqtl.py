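"""Per-cohort eQTL mapping.

Genotype QC (call rate and exact Hardy-Weinberg test), robust covariate
adjustment of expression (Huber M-estimation on age, sex and two smoking
indicators), single-SNP additive association by OLS on the adjusted
residuals, cis/trans classification by a 1 Mb window around the probeset,
permutation-based FDR thresholds estimated separately for the cis and trans
strata, and best-eSNP calls (at most one cis-eQTL per transcript).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "FdrThreshold",
    "hwe_exact_test",
    "qc_genotypes",
    "adjust_expression",
    "classify_pair",
    "cis_mask",
    "test_association",
    "scan",
    "estimate_fdr_threshold",
    "call_eqtls",
]

DEFAULT_WINDOW = 1_000_000
DEFAULT_MIN_SAMPLES = 30


@dataclass
class QcReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_hwe: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_call_rate - self.n_removed_hwe


@dataclass
class FdrThreshold:
    eqtl_class: str
    cohort: str
    p_cutoff: float
    n_discoveries: int
    n_permutations: int
    target_fdr: float


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test P value for one biallelic SNP.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more likely than the observed one (the standard exact SNP-HWE test).
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        return 1.0
    n_rare = 2 * min(counts[0], counts[2]) + counts[1]
    obs_het = counts[1]
    # P(het = h | allele counts) via the stable recurrence over h
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(het_values.size, dtype=float)
    probs[0] = 1.0
    for i in range(1, het_values.size):
        h = het_values[i]
        # ratio p(h)/p(h-2) = (n_rare-h+2)(2n-n_rare-h+2) / (h(h-1))
        probs[i] = probs[i - 1] * (n_rare - h + 2) * (2 * n - n_rare - h + 2) / (h * (h - 1))
    probs /= probs.sum()
    obs_p = probs[het_values == obs_het][0]
    return float(min(1.0, probs[probs <= obs_p * (1 + 1e-12)].sum()))


def qc_genotypes(
    genotypes: pd.DataFrame,
    call_rate_min: float = 0.9,
    hwe_alpha: float = 1e-6,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop SNPs with call rate < ``call_rate_min`` or exact HWE P < ``hwe_alpha``."""
    G = genotypes.to_numpy(dtype=float)
    n_input = G.shape[0]
    called = ~np.isnan(G)
    call_rate = called.mean(axis=1)
    pass_cr = call_rate >= call_rate_min
    pass_hwe = np.ones(n_input, dtype=bool)
    for i in np.flatnonzero(pass_cr):
        g = G[i, called[i]]
        n0, n1, n2 = int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        pass_hwe[i] = hwe_exact_test(n0, n1, n2) >= hwe_alpha
    keep = pass_cr & pass_hwe
    report = QcReport(
        n_input=n_input,
        n_removed_call_rate=int((~pass_cr).sum()),
        n_removed_hwe=int((pass_cr & ~pass_hwe).sum()),
    )
    if not keep.any():
        raise ValueError("no SNPs left after genotype QC")
    return genotypes.loc[keep], report


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    required = {"age", "sex", "smoking"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    age = pd.to_numeric(covariates["age"], errors="raise").to_numpy(dtype=float)
    sex = pd.to_numeric(covariates["sex"], errors="raise").to_numpy(dtype=float)
    smoking = covariates["smoking"].astype(str)
    bad = ~smoking.isin(["never", "ex", "current"])
    if bad.any():
        raise ValueError(f"unknown smoking levels: {sorted(smoking[bad].unique())}")
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            age,
            sex,
            (smoking == "ex").to_numpy(dtype=float),
            (smoking == "current").to_numpy(dtype=float),
        ]
    )
    return X


def adjust_expression(expression: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize each probeset on age, sex and smoking with a Huber robust fit.

    Uses M-estimation with the Huber loss (tuning constant 1.345, IRLS,
    convergence tolerance 1e-8, at most 50 iterations) so outlying expression
    values do not drag the covariate fit. Residuals are mean-centered.
    """
    if list(expression.columns) != list(covariates.index):
        if set(expression.columns) != set(covariates.index):
            raise ValueError("expression samples do not match covariate samples")
        covariates = covariates.loc[expression.columns]
    X = _covariate_design(covariates)
    Y = expression.to_numpy(dtype=float)
    resid = np.empty_like(Y)
    norm = sm.robust.norms.HuberT(t=1.345)
    n_constant = 0
    for i in range(Y.shape[0]):
        y = Y[i]
        if np.ptp(y) == 0.0:
            resid[i] = 0.0
            n_constant += 1
            continue
        fit = sm.RLM(y, X, M=norm).fit(maxiter=50, tol=1e-8)
        r = fit.resid
        resid[i] = r - r.mean()
    if n_constant:
        warnings.warn(f"{n_constant} constant expression rows produced all-zero residuals")
    return pd.DataFrame(resid, index=expression.index, columns=expression.columns)


def classify_pair(
    snp_chrom: str,
    snp_pos: int,
    probe_chrom: str,
    probe_start: int,
    probe_end: int,
    window: int = DEFAULT_WINDOW,
) -> str:
    """cis iff the SNP lies within ``window`` bp of the probeset interval
    (inclusive boundaries) on the same chromosome; otherwise trans."""
    if pd.isna(snp_pos) or pd.isna(probe_start) or pd.isna(probe_end):
        raise ValueError("missing position in annotation")
    if snp_chrom == probe_chrom and probe_start - window <= snp_pos <= probe_end + window:
        return "cis"
    return "trans"


def cis_mask(
    snps: pd.DataFrame,
    probesets: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Boolean matrix (probesets x SNPs): True where the pair is cis."""
    s_chrom = snps["chrom"].to_numpy()
    s_pos = snps["pos"].to_numpy()
    p_chrom = probesets["chrom"].to_numpy()
    p_start = probesets["start"].to_numpy()
    p_end = probesets["end"].to_numpy()
    same = p_chrom[:, None] == s_chrom[None, :]
    within = (s_pos[None, :] >= (p_start - window)[:, None]) & (
        s_pos[None, :] <= (p_end + window)[:, None]
    )
    return same & within


def test_association(
    dosage: np.ndarray,
    residual: np.ndarray,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> dict:
    """Additive OLS association of one adjusted expression trait on one dosage.

    Returns beta, its SE, the two-sided t-test P value, the squared Pearson
    correlation r2 and the number of samples used (pairwise-complete).
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(residual, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    n = g.size
    if n < min_samples:
        raise ValueError(f"only {n} complete pairs (< {min_samples})")
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise ValueError("monomorphic dosage")
    sxy = float(gc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    df = n - 2
    rss = syy - beta * sxy
    se = float(np.sqrt(max(rss, 0.0) / df / sxx))
    if se > 0.0:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        p = 0.0 if beta != 0 else 1.0
    r2 = float(sxy * sxy / (sxx * syy)) if syy > 0 else 0.0
    return {"beta": beta, "se": se, "p": max(p, np.finfo(float).tiny), "r2": r2, "n": n}


def _assoc_matrices(
    G: np.ndarray, Y: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES
) -> dict[str, np.ndarray]:
    """Vectorized OLS of every probeset row of Y on every SNP row of G.

    Returns (probesets x SNPs) matrices beta/se/p/r2 plus per-SNP n. Pairs
    whose SNP is monomorphic or under-sampled are NaN. Missing dosages are
    handled pairwise per SNP; expression rows must be complete.
    """
    n_snps, n = G.shape
    n_probes = Y.shape[0]
    beta = np.full((n_probes, n_snps), np.nan)
    se = np.full_like(beta, np.nan)
    p = np.full_like(beta, np.nan)
    r2 = np.full_like(beta, np.nan)
    n_used = np.zeros(n_snps, dtype=int)

    snp_missing = np.isnan(G).any(axis=1)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy_full = np.einsum("ij,ij->i", Yc, Yc)

    def fill(cols: np.ndarray, Gsub: np.ndarray, Ycs: np.ndarray, syy: np.ndarray, nn: int) -> None:
        if nn < min_samples:
            return
        Gc = Gsub - Gsub.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", Gc, Gc)
        poly = sxx > 0
        if not poly.any():
            return
        cols = cols[poly]
        Gc = Gc[poly]
        sxx = sxx[poly]
        sxy = Ycs @ Gc.T  # probes x snps_sub
        b = sxy / sxx
        rss = syy[:, None] - b * sxy
        df = nn - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
            tstat = np.where(s > 0, b / s, np.inf * np.sign(b))
            pv = 2.0 * stats.t.sf(np.abs(tstat), df)
            r2v = np.where(syy[:, None] > 0, sxy * sxy / (sxx * syy[:, None]), 0.0)
        beta[:, cols] = b
        se[:, cols] = s
        p[:, cols] = np.maximum(pv, np.finfo(float).tiny)
        r2[:, cols] = r2v
        n_used[cols] = nn

    complete = np.flatnonzero(~snp_missing)
    if complete.size:
        fill(complete, G[complete], Yc, syy_full, n)
    for j in np.flatnonzero(snp_missing):
        ok = ~np.isnan(G[j])
        nn = int(ok.sum())
        if nn < min_samples:
            continue
        Ys = Y[:, ok]
        Ycs = Ys - Ys.mean(axis=1, keepdims=True)
        syy = np.einsum("ij,ij->i", Ycs, Ycs)
        fill(np.array([j]), G[j : j + 1, ok], Ycs, syy, nn)
    return {"beta": beta, "se": se, "p": p, "r2": r2, "n": n_used}


def scan(
    genotypes: pd.DataFrame,
    residuals: pd.DataFrame,
    snps: pd.DataFrame,
    probesets: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Test every SNP x probeset pair; tag each with its cis/trans class.

    Returns a long table (snp_id, probeset_id, cohort, beta, se, p, r2, n,
    cis). Monomorphic or under-sampled SNPs are skipped (and logged).
    """
    snps = snps.set_index("snp_id").loc[genotypes.index].rename_axis("snp_id").reset_index()
    probesets = (
        probesets.set_index("probeset_id")
        .loc[residuals.index]
        .rename_axis("probeset_id")
        .reset_index()
    )
    mats = _assoc_matrices(
        genotypes.to_numpy(dtype=float), residuals.to_numpy(dtype=float), min_samples
    )
    mask = cis_mask(snps, probesets, window)
    ok = ~np.isnan(mats["p"])
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("scan skipped %d pairs (monomorphic or under-sampled SNPs)", n_skipped)
    pi, si = np.nonzero(ok)
    out = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy()[si],
            "probeset_id": probesets["probeset_id"].to_numpy()[pi],
            "cohort": cohort,
            "beta": mats["beta"][pi, si],
            "se": mats["se"][pi, si],
            "p": mats["p"][pi, si],
            "r2": mats["r2"][pi, si],
            "n": mats["n"][si],
            "cis": mask[pi, si],
        }
    )
    out["class"] = np.where(out["cis"], "cis", "trans")
    return out


def estimate_fdr_threshold(
    observed: np.ndarray,
    permuted: list[np.ndarray],
    target_fdr: float = 0.10,
    eqtl_class: str = "cis",
    cohort: str = "cohort",
) -> FdrThreshold:
    """Largest observed P value t with estimated FDR(t) <= target.

    FDR(t) = (mean number of permutation-null P values <= t) / (number of
    observed P values <= t). If no candidate satisfies the target the cutoff
    is 0 with zero discoveries.
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        raise ValueError("no observed P values")
    if not permuted:
        raise ValueError("at least one permutation list is required")
    perm = [np.sort(np.asarray(x, dtype=float)) for x in permuted]
    n_obs = 1 + np.arange(obs.size)  # observed count <= each candidate t
    mean_null = np.zeros(obs.size)
    for x in perm:
        mean_null += np.searchsorted(x, obs, side="right")
    mean_null /= len(perm)
    fdr = mean_null / n_obs
    ok = np.flatnonzero(fdr <= target_fdr)
    if ok.size == 0:
        warnings.warn(
            f"no P value cutoff achieves FDR <= {target_fdr} for {eqtl_class}/{cohort}"
        )
        return FdrThreshold(eqtl_class, cohort, 0.0, 0, len(perm), target_fdr)
    i = int(ok[-1])
    return FdrThreshold(
        eqtl_class=eqtl_class,
        cohort=cohort,
        p_cutoff=float(obs[i]),
        n_discoveries=int(n_obs[i]),
        n_permutations=len(perm),
        target_fdr=target_fdr,
    )


def call_eqtls(
    results: pd.DataFrame,
    thresholds: dict[str, float],
    snps: pd.DataFrame,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Declare eQTLs from a scan table given per-class P cutoffs.

    cis: per probeset, the lowest-P cis SNP is the eSNP, declared if its P is
    at or below the cis cutoff (at most one cis-eQTL per transcript). trans:
    per probeset x SNP-chromosome, the lowest-P distal SNP. Ties in P are
    broken by (position, snp_id).
    """
    pos = snps.set_index("snp_id")[["chrom", "pos"]]
    res = results.merge(pos, left_on="snp_id", right_index=True, how="left")
    calls = []
    for eqtl_class, grouper in (("cis", ["probeset_id"]), ("trans", ["probeset_id", "chrom"])):
        cutoff = thresholds.get(eqtl_class, 0.0)
        sub = res[res["cis"]] if eqtl_class == "cis" else res[~res["cis"]]
        if sub.empty or cutoff <= 0.0:
            continue
        sub = sub.sort_values(["p", "pos", "snp_id"], kind="mergesort")
        best = sub.groupby(grouper, sort=True, as_index=False).first()
        best = best[best["p"] <= cutoff]
        for row in best.itertuples(index=False):
            calls.append(
                {
                    "probeset_id": row.probeset_id,
                    "snp_id": row.snp_id,
                    "class": eqtl_class,
                    "p": row.p,
                    "beta": row.beta,
                    "r2": row.r2,
                    "fdr_level": fdr_level,
                    "cohort": row.cohort,
                }
            )
    cols = ["probeset_id", "snp_id", "class", "p", "beta", "r2", "fdr_level", "cohort"]
    return pd.DataFrame(calls, columns=cols)
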