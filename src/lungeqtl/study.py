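"""Model/Results interface for the multi-cohort eQTL study.

:class:`LungEqtlStudy` holds the per-cohort genotype, expression and
covariate data plus the shared SNP/probeset annotations; :meth:`fit` runs
genotype QC, robust covariate adjustment, the full cis/trans association
scan in every cohort, permutation FDR thresholds (per cohort and at the
meta-analysis level, sharing permutation replicates across cohorts),
fixed/random-effects meta-analysis with Cochran's Q and DerSimonian-Laird
tau^2, best-eSNP calls and the cross-cohort replication rule, returning a
:class:`LungEqtlResults` with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import eqtl, meta
from .integrate import EsnpSet, build_esnp_set
from .simulate import CohortData, Dataset, SimConfig, load_dataset, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["LungEqtlStudy", "LungEqtlResults"]


def _strata_minima(
    P: np.ndarray, cis: np.ndarray, chrom_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probeset min cis P and per-(probeset, chromosome) min trans P."""
    with np.errstate(all="ignore"):
        Pc = np.where(cis, P, np.nan)
        cis_min = np.nanmin(Pc, axis=1, initial=np.inf)
    cis_min = cis_min[np.isfinite(cis_min)]
    trans_mins = []
    for code in np.unique(chrom_codes):
        cols = chrom_codes == code
        with np.errstate(all="ignore"):
            Pt = np.where(~cis[:, cols], P[:, cols], np.nan)
            tmin = np.nanmin(Pt, axis=1, initial=np.inf)
        trans_mins.append(tmin[np.isfinite(tmin)])
    trans_min = np.concatenate(trans_mins) if trans_mins else np.array([])
    return cis_min, trans_min


@dataclass
class LungEqtlResults:
    """Fitted study: thresholds, eQTL calls, meta-analysis and replication."""

    cohort_names: list[str]
    qc_reports: dict[str, eqtl.QcReport]
    thresholds: pd.DataFrame  # cohort (incl. "meta") x class cutoffs and counts
    calls: pd.DataFrame  # declared eQTLs, per cohort and meta
    replication: pd.DataFrame
    replication_rates: dict[str, float]
    fdr_target: float
    alpha_rep: float
    n_permutations: int
    seed: int
    window: int
    heterogeneity: dict[str, float]
    model: "LungEqtlStudy" = field(repr=False)
    _assoc: dict[str, np.ndarray] = field(repr=False)
    _meta: dict[str, np.ndarray] = field(repr=False)
    _snp_ids: np.ndarray = field(repr=False)
    _probe_ids: np.ndarray = field(repr=False)
    _cis: np.ndarray = field(repr=False)

    # ------------------------------------------------------------- accessors
    def calls_for(self, cohort: str, eqtl_class: str | None = None) -> pd.DataFrame:
        out = self.calls[self.calls["cohort"] == cohort]
        if eqtl_class is not None:
            out = out[out["class"] == eqtl_class]
        return out.reset_index(drop=True)

    def n_calls(self, cohort: str, eqtl_class: str) -> int:
        return int(len(self.calls_for(cohort, eqtl_class)))

    def cutoff(self, cohort: str, eqtl_class: str) -> float:
        row = self.thresholds[
            (self.thresholds["cohort"] == cohort) & (self.thresholds["class"] == eqtl_class)
        ]
        return float(row["p_cutoff"].iloc[0]) if len(row) else 0.0

    def assoc_records(self, cohort: str, max_p: float | None = None) -> pd.DataFrame:
        """Per-cohort association records (snp_id, probeset_id, beta, se, p, r2, n, cis)."""
        ci = self.cohort_names.index(cohort)
        P = self._assoc["p"][ci]
        valid = ~np.isnan(P)
        if max_p is not None:
            valid &= P <= max_p
        pi, si = np.nonzero(valid)
        out = pd.DataFrame(
            {
                "snp_id": self._snp_ids[si],
                "probeset_id": self._probe_ids[pi],
                "cohort": cohort,
                "beta": self._assoc["beta"][ci][pi, si],
                "se": self._assoc["se"][ci][pi, si],
                "p": P[pi, si],
                "r2": self._assoc["r2"][ci][pi, si],
                "cis": self._cis[pi, si],
            }
        )
        return out

    def meta_records(self, pairs: list[tuple[str, str]] | None = None,
                     max_p: float | None = None) -> pd.DataFrame:
        """Meta-analysis records as a table (optionally restricted).

        ``pairs`` is a list of (snp_id, probeset_id); ``max_p`` keeps records
        with fixed-effect P at or below the bound.
        """
        snp_pos = {s: j for j, s in enumerate(self._snp_ids)}
        probe_pos = {p: i for i, p in enumerate(self._probe_ids)}
        if pairs is not None:
            si = np.array([snp_pos[s] for s, _ in pairs])
            pi = np.array([probe_pos[p] for _, p in pairs])
        else:
            valid = self._meta["k"] > 0
            if max_p is not None:
                valid &= self._meta["p_fe"] <= max_p
            pi, si = np.nonzero(valid)
        out = pd.DataFrame(
            {
                "snp_id": self._snp_ids[si],
                "probeset_id": self._probe_ids[pi],
                "cis": self._cis[pi, si],
            }
        )
        for key in ("k", "beta_fe", "se_fe", "p_fe", "beta_re", "se_re", "p_re",
                    "q", "q_pvalue", "tau2", "tau"):
            out[key] = self._meta[key][pi, si]
        return out

    def esnp_set(self) -> EsnpSet:
        """All cis SNP x probeset pairs passing the meta-level cis FDR cutoff."""
        cutoff = self.cutoff("meta", "cis")
        hits = self.meta_records(max_p=max(cutoff, 0.0))
        tab = hits.rename(columns={"p_fe": "p"})[["snp_id", "probeset_id", "p", "cis"]]
        return build_esnp_set(tab, cutoff, self.model.probesets)

    # ------------------------------------------------------------- reporting
    def summary(self) -> str:
        """Cohort x class cutoff/count table plus replication and heterogeneity."""
        cols = self.cohort_names + ["meta"]
        lines = [
            "Lung eQTL study summary",
            f"  {self.fdr_target:.0%} FDR ({self.n_permutations} permutations, seed {self.seed}, "
            f"window {self.window/1e6:g} Mb)",
            "",
            "  " + "".join(f"{c:>14}" for c in [""] + cols),
        ]
        def row(label: str, values: list[str]) -> str:
            return "  " + f"{label:>14}" + "".join(f"{v:>14}" for v in values)

        for cls in ("cis", "trans"):
            lines.append(row(f"{cls} cutoff", [f"{self.cutoff(c, cls):.1e}" for c in cols]))
        for cls in ("cis", "trans"):
            lines.append(row(f"n {cls}-eQTL", [str(self.n_calls(c, cls)) for c in cols]))
        lines.append("")
        lines.append("  Replication (same sign, P <= %g in another cohort):" % self.alpha_rep)
        for c in self.cohort_names:
            r = self.replication_rates.get(c, float("nan"))
            lines.append(f"    {c}: {r:.1%}" if np.isfinite(r) else f"    {c}: n/a")
        lines.append(
            "  Heterogeneity: %.1f%% of pairs with Q P<0.05, %.1f%% with Q P<0.001"
            % (100 * self.heterogeneity["frac_q_lt_05"], 100 * self.heterogeneity["frac_q_lt_001"])
        )
        return "\n".join(lines)


class LungEqtlStudy:
    """Multi-cohort lung eQTL mapping model.

    Parameters
    ----------
    cohorts : mapping of cohort name to :class:`~lungeqtl.simulate.CohortData`
    snps, probesets : shared annotation tables
    window : cis window in bp around the probeset interval (default 1 Mb)
    """

    def __init__(
        self,
        cohorts: Mapping[str, CohortData],
        snps: pd.DataFrame,
        probesets: pd.DataFrame,
        window: int = eqtl.DEFAULT_WINDOW,
        min_samples: int = eqtl.DEFAULT_MIN_SAMPLES,
        call_rate_min: float = 0.9,
        hwe_alpha: float = 1e-6,
    ):
        if not cohorts:
            raise ValueError("at least one cohort is required")
        self.cohorts = dict(cohorts)
        self.snps = snps.reset_index(drop=True)
        self.probesets = probesets.reset_index(drop=True)
        self.window = int(window)
        self.min_samples = min_samples
        self.call_rate_min = call_rate_min
        self.hwe_alpha = hwe_alpha

    @classmethod
    def from_dataset(cls, dataset: Dataset, **kwargs) -> "LungEqtlStudy":
        return cls(dataset.cohorts, dataset.snps, dataset.probesets, **kwargs)

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "LungEqtlStudy":
        return cls.from_dataset(load_dataset(path), **kwargs)

    @classmethod
    def from_simulation(cls, config: SimConfig, **kwargs) -> "LungEqtlStudy":
        return cls.from_dataset(simulate_dataset(config), **kwargs)

    # ----------------------------------------------------------------- fitting
    def fit(
        self,
        fdr_target: float = 0.10,
        n_permutations: int = 5,
        alpha_rep: float = meta.DEFAULT_ALPHA_REP,
        seed: int = 0,
    ) -> LungEqtlResults:
        names = list(self.cohorts)
        snp_ids = self.snps["snp_id"].to_numpy()
        probe_ids = self.probesets["probeset_id"].to_numpy()
        n_snps, n_probes = len(snp_ids), len(probe_ids)
        chrom_codes = pd.factorize(self.snps["chrom"])[0]
        cis = eqtl.cis_mask(self.snps, self.probesets, self.window)
        snp_index = pd.Index(snp_ids)

        k = len(names)
        beta = np.full((k, n_probes, n_snps), np.nan)
        se = np.full_like(beta, np.nan)
        p = np.full_like(beta, np.nan)
        r2 = np.full_like(beta, np.nan)
        qc_reports: dict[str, eqtl.QcReport] = {}
        kept_G: list[np.ndarray] = []
        kept_cols: list[np.ndarray] = []
        resid_arr: list[np.ndarray] = []

        for ci, name in enumerate(names):
            cohort = self.cohorts[name]
            Gq, report = eqtl.qc_genotypes(cohort.genotypes, self.call_rate_min, self.hwe_alpha)
            qc_reports[name] = report
            logger.info(
                "%s: %d/%d SNPs kept after QC", name, report.n_kept, report.n_input
            )
            resid = eqtl.adjust_expression(cohort.expression, cohort.covariates)
            resid = resid.loc[probe_ids]
            cols = snp_index.get_indexer(Gq.index)
            mats = eqtl._assoc_matrices(
                Gq.to_numpy(dtype=float), resid.to_numpy(dtype=float), self.min_samples
            )
            beta[ci][:, cols] = mats["beta"]
            se[ci][:, cols] = mats["se"]
            p[ci][:, cols] = mats["p"]
            r2[ci][:, cols] = mats["r2"]
            kept_G.append(Gq.to_numpy(dtype=float))
            kept_cols.append(cols)
            resid_arr.append(resid.to_numpy(dtype=float))

        meta_obs = meta._combine_stacks(beta, se)

        # observed strata minima
        observed: dict[tuple[str, str], np.ndarray] = {}
        for ci, name in enumerate(names):
            cmin, tmin = _strata_minima(p[ci], cis, chrom_codes)
            observed[(name, "cis")], observed[(name, "trans")] = cmin, tmin
        cmin, tmin = _strata_minima(meta_obs["p_fe"], cis, chrom_codes)
        observed[("meta", "cis")], observed[("meta", "trans")] = cmin, tmin

        # permutation null strata minima (same replicate index across cohorts)
        null: dict[tuple[str, str], list[np.ndarray]] = {key: [] for key in observed}
        for r in range(n_permutations):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7001, r]))
            pb = np.full_like(beta, np.nan)
            ps = np.full_like(beta, np.nan)
            for ci, name in enumerate(names):
                perm = rng.permutation(resid_arr[ci].shape[1])
                mats = eqtl._assoc_matrices(
                    kept_G[ci], resid_arr[ci][:, perm], self.min_samples
                )
                pb[ci][:, kept_cols[ci]] = mats["beta"]
                ps[ci][:, kept_cols[ci]] = mats["se"]
                cmin, tmin = _strata_minima(
                    np.where(np.isnan(mats["p"]), np.nan, mats["p"]), cis[:, kept_cols[ci]],
                    chrom_codes[kept_cols[ci]],
                )
                null[(name, "cis")].append(cmin)
                null[(name, "trans")].append(tmin)
            meta_perm = meta._combine_stacks(pb, ps)
            cmin, tmin = _strata_minima(meta_perm["p_fe"], cis, chrom_codes)
            null[("meta", "cis")].append(cmin)
            null[("meta", "trans")].append(tmin)

        thr_rows = []
        cutoffs: dict[tuple[str, str], float] = {}
        for (who, cls), obs in observed.items():
            if obs.size == 0:
                cutoffs[(who, cls)] = 0.0
                continue
            thr = eqtl.estimate_fdr_threshold(
                obs, null[(who, cls)], fdr_target, eqtl_class=cls, cohort=who
            )
            cutoffs[(who, cls)] = thr.p_cutoff
            thr_rows.append(
                {
                    "cohort": who,
                    "class": cls,
                    "p_cutoff": thr.p_cutoff,
                    "n_discoveries": thr.n_discoveries,
                    "n_permutations": thr.n_permutations,
                    "target_fdr": fdr_target,
                }
            )
        thresholds = pd.DataFrame(
            thr_rows, columns=["cohort", "class", "p_cutoff", "n_discoveries",
                               "n_permutations", "target_fdr"]
        )

        # eQTL calls per cohort and for the meta-analysis
        pos = self.snps["pos"].to_numpy()
        call_frames = []
        for ci, name in enumerate(names):
            call_frames.append(
                self._matrix_calls(p[ci], beta[ci], r2[ci], cis, chrom_codes, pos,
                                   snp_ids, probe_ids, cutoffs, name, fdr_target)
            )
        call_frames.append(
            self._matrix_calls(meta_obs["p_fe"], meta_obs["beta_fe"], None, cis,
                               chrom_codes, pos, snp_ids, probe_ids, cutoffs, "meta",
                               fdr_target)
        )
        nonempty = [f for f in call_frames if len(f)]
        calls = pd.concat(nonempty, ignore_index=True) if nonempty else call_frames[0]

        # replication across cohorts
        sig_tables = {}
        for ci, name in enumerate(names):
            pi, si = np.nonzero(p[ci] <= alpha_rep)
            sig_tables[name] = pd.DataFrame(
                {
                    "snp_id": snp_ids[si],
                    "probeset_id": probe_ids[pi],
                    "beta": beta[ci][pi, si],
                    "p": p[ci][pi, si],
                }
            )
        cohort_calls = calls[calls["cohort"] != "meta"]
        if len(names) >= 2:
            replication, rates = meta.assess_replication(
                sig_tables, cohort_calls, alpha_rep
            )
        else:
            replication, rates = pd.DataFrame(), {}

        with np.errstate(invalid="ignore"):
            qp = meta_obs["q_pvalue"]
            qp = qp[~np.isnan(qp)]
        heterogeneity = {
            "frac_q_lt_05": float((qp < 0.05).mean()) if qp.size else float("nan"),
            "frac_q_lt_001": float((qp < 0.001).mean()) if qp.size else float("nan"),
        }

        return LungEqtlResults(
            cohort_names=names,
            qc_reports=qc_reports,
            thresholds=thresholds,
            calls=calls,
            replication=replication,
            replication_rates=rates,
            fdr_target=fdr_target,
            alpha_rep=alpha_rep,
            n_permutations=n_permutations,
            seed=seed,
            window=self.window,
            heterogeneity=heterogeneity,
            model=self,
            _assoc={"beta": beta, "se": se, "p": p, "r2": r2},
            _meta=meta_obs,
            _snp_ids=snp_ids,
            _probe_ids=probe_ids,
            _cis=cis,
        )

    @staticmethod
    def _matrix_calls(
        P: np.ndarray,
        B: np.ndarray,
        R2: np.ndarray | None,
        cis: np.ndarray,
        chrom_codes: np.ndarray,
        pos: np.ndarray,
        snp_ids: np.ndarray,
        probe_ids: np.ndarray,
        cutoffs: dict[tuple[str, str], float],
        who: str,
        fdr_target: float,
    ) -> pd.DataFrame:
        """Best-eSNP calls from a P matrix; ties broken by (position, snp_id)."""
        rows = []

        def emit(pi: int, cols: np.ndarray, cls: str, cutoff: float) -> None:
            sub = P[pi, cols]
            if np.all(np.isnan(sub)):
                return
            pmin = np.nanmin(sub)
            if not (pmin <= cutoff):
                return
            tied = cols[np.flatnonzero(sub == pmin)]
            j = int(tied[np.lexsort((snp_ids[tied], pos[tied]))[0]])
            rows.append(
                {
                    "probeset_id": probe_ids[pi],
                    "snp_id": snp_ids[j],
                    "class": cls,
                    "p": P[pi, j],
                    "beta": B[pi, j],
                    "r2": R2[pi, j] if R2 is not None else np.nan,
                    "fdr_level": fdr_target,
                    "cohort": who,
                }
            )

        cis_cut = cutoffs.get((who, "cis"), 0.0)
        trans_cut = cutoffs.get((who, "trans"), 0.0)
        # cheap pre-screen: only probesets whose stratum minimum passes
        if cis_cut > 0:
            with np.errstate(all="ignore"):
                Pc = np.where(cis, P, np.nan)
                hit = np.flatnonzero(np.nanmin(Pc, axis=1, initial=np.inf) <= cis_cut)
            for pi in hit:
                emit(int(pi), np.flatnonzero(cis[pi]), "cis", cis_cut)
        if trans_cut > 0:
            for code in np.unique(chrom_codes):
                chrom_cols = chrom_codes == code
                with np.errstate(all="ignore"):
                    Pt = np.where(~cis & chrom_cols[None, :], P, np.nan)
                    hit = np.flatnonzero(np.nanmin(Pt, axis=1, initial=np.inf) <= trans_cut)
                for pi in hit:
                    cols = np.flatnonzero(~cis[pi] & chrom_cols)
                    emit(int(pi), cols, "trans", trans_cut)
        cols_ = ["probeset_id", "snp_id", "class", "p", "beta", "r2", "fdr_level", "cohort"]
        return pd.DataFrame(rows, columns=cols_)
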