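"""GWAS - eSNP integration.

Builds the eSNP set (every SNP passing the cis FDR cutoff for at least one
probeset, not just best-per-transcript), tests whether eSNPs are enriched
for small GWAS P values (Q-Q coordinates plus a one-sided Mann-Whitney
enrichment P), and translates sub-threshold GWAS SNPs into genes through the
eSNP list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EsnpSet", "QqResult", "build_esnp_set", "enrichment_qq", "link_gwas_genes"]

DEFAULT_GWAS_THRESHOLD = 0.01


@dataclass
class EsnpSet:
    """snp_id -> probesets (and gene symbols) it controls at the FDR cutoff."""

    snp_to_probesets: dict[str, set[str]] = field(default_factory=dict)
    snp_to_genes: dict[str, set[str]] = field(default_factory=dict)
    p_cutoff: float = 0.0

    @property
    def snps(self) -> set[str]:
        return set(self.snp_to_probesets)

    def __len__(self) -> int:
        return len(self.snp_to_probesets)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_to_probesets

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": snp,
                "probesets": ",".join(sorted(ps)),
                "genes": ",".join(sorted(self.snp_to_genes.get(snp, set()))),
            }
            for snp, ps in sorted(self.snp_to_probesets.items())
        ]
        return pd.DataFrame(rows, columns=["snp_id", "probesets", "genes"])


@dataclass
class QqResult:
    expected: np.ndarray  # -log10 expected uniform quantiles for the eSNP subset
    observed: np.ndarray  # -log10 observed GWAS P, ascending
    enrichment_p: float
    n_esnps: int
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"expected": self.expected, "observed": self.observed})

    def plot(self, ax=None):
        """Q-Q plot of eSNP GWAS P values against the uniform expectation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.expected, self.observed, s=6, alpha=0.6)
        lim = max(self.expected.max(), self.observed.max())
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel(r"expected $-\log_{10} P$")
        ax.set_ylabel(r"observed $-\log_{10} P$")
        ax.set_title(f"eSNP enrichment (P = {self.enrichment_p:.3g})")
        return ax


def build_esnp_set(
    results: pd.DataFrame,
    p_cutoff: float,
    probesets: pd.DataFrame | None = None,
) -> EsnpSet:
    """Collect all cis SNP x probeset pairs at or below the cis P cutoff.

    ``results`` needs snp_id, probeset_id, p and a boolean cis column (scan
    or meta output with p renamed accordingly). Gene symbols are attached
    through the probeset annotation when given.
    """
    need = {"snp_id", "probeset_id", "p", "cis"}
    missing = need - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    hits = results[results["cis"] & (results["p"] <= p_cutoff)]
    snp_to_ps: dict[str, set[str]] = {}
    for snp, ps in zip(hits["snp_id"], hits["probeset_id"]):
        snp_to_ps.setdefault(snp, set()).add(ps)
    snp_to_genes: dict[str, set[str]] = {}
    if probesets is not None:
        gene_of = dict(zip(probesets["probeset_id"], probesets["gene_symbol"]))
        snp_to_genes = {
            snp: {str(gene_of[p]).upper() for p in ps if p in gene_of and pd.notna(gene_of[p])}
            for snp, ps in snp_to_ps.items()
        }
    return EsnpSet(snp_to_probesets=snp_to_ps, snp_to_genes=snp_to_genes, p_cutoff=p_cutoff)


def enrichment_qq(gwas: pd.DataFrame, esnps: EsnpSet | set[str], min_esnps: int = 10) -> QqResult:
    """Q-Q coordinates and one-sided enrichment P for the eSNP subset.

    The enrichment P is a one-sided Mann-Whitney U test of the GWAS P values
    of eSNPs against those of the remaining SNPs (alternative: eSNP P values
    are stochastically smaller).
    """
    members = esnps.snps if isinstance(esnps, EsnpSet) else set(esnps)
    is_esnp = gwas["snp_id"].isin(members).to_numpy()
    p = gwas["p"].to_numpy(dtype=float)
    n_in = int(is_esnp.sum())
    if n_in == 0:
        raise ValueError("no eSNPs found in the GWAS table")
    if n_in < min_esnps:
        raise ValueError(f"only {n_in} eSNPs with GWAS P values (< {min_esnps})")
    if n_in == len(gwas):
        raise ValueError("all GWAS SNPs are eSNPs; no comparison group")
    p_in = np.sort(p[is_esnp])
    p_out = p[~is_esnp]
    expected = -np.log10((np.arange(1, n_in + 1) - 0.5) / n_in)[::-1]
    observed = -np.log10(p_in)[::-1]
    mwu = stats.mannwhitneyu(p_in, p_out, alternative="less")
    return QqResult(
        expected=expected,
        observed=observed,
        enrichment_p=float(mwu.pvalue),
        n_esnps=n_in,
        n_background=int(len(gwas) - n_in),
    )


def link_gwas_genes(
    gwas: pd.DataFrame,
    esnps: EsnpSet,
    gwas_threshold: float = DEFAULT_GWAS_THRESHOLD,
) -> tuple[pd.DataFrame, set[str]]:
    """Translate GWAS SNPs at P < threshold into genes via the eSNP list.

    Returns the per-SNP link table and the union of linked gene symbols.
    """
    hits = gwas[(gwas["p"] < gwas_threshold) & gwas["snp_id"].isin(esnps.snps)]
    rows = []
    union: set[str] = set()
    for snp, pval in zip(hits["snp_id"], hits["p"]):
        genes = esnps.snp_to_genes.get(snp, set())
        union |= genes
        rows.append({"snp_id": snp, "gwas_p": pval, "genes": ",".join(sorted(genes))})
    links = pd.DataFrame(rows, columns=["snp_id", "gwas_p", "genes"])
    return links, union
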