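"""End-to-end driver: simulate/load -> eQTL study -> integration -> network.

:func:`run_all` executes every stage in order, writes the declared output
files under one directory and returns a summary dictionary with the counts
at each stage. :func:`report` renders the summary as human-readable tables
(cohort x class cutoffs/counts, and the locus-candidate ranking).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import integrate, network as net
from .simulate import Dataset, SimConfig, load_dataset, simulate_dataset
from .study import LungEqtlStudy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "report"]


@dataclass
class RunConfig:
    """All pipeline constants in one serializable record."""

    data_dir: str | None = None  # existing dataset; None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    window: int = 1_000_000
    fdr_target: float = 0.10
    alpha_rep: float = 1e-4
    gwas_threshold: float = 0.01
    h: int = 3
    kda_alpha: float = 0.05
    permutations: int = 5
    seed: int = 0
    assoc_p_max: float = 1e-3  # row filter for the (large) assoc.tsv files
    meta_p_max: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        for name in ("fdr_target", "alpha_rep", "gwas_threshold", "kda_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.permutations < 1:
            raise ValueError("at least one permutation is required")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = config.to_json() + "\n"
    (out / "run_config.json").write_text(config_text)
    import hashlib

    import networkx
    import numpy
    import pandas
    import scipy
    import statsmodels

    from . import __version__

    logger.info(
        "run config sha256=%s seed=%d | lungeqtl %s numpy %s scipy %s pandas %s "
        "statsmodels %s networkx %s",
        hashlib.sha256(config_text.encode()).hexdigest()[:12],
        config.seed,
        __version__,
        numpy.__version__,
        scipy.__version__,
        pandas.__version__,
        statsmodels.__version__,
        networkx.__version__,
    )

    # ---- stage: data ----------------------------------------------------
    stage = "simulate/load"
    try:
        if config.data_dir is None:
            dataset = simulate_dataset(config.sim)
            dataset.write(out / "data")
        else:
            dataset = load_dataset(config.data_dir)
    except Exception as exc:  # noqa: BLE001 - report failing stage by name
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    summary: dict = {"seed": config.seed, "cohorts": list(dataset.cohorts)}

    # ---- stage: eQTL study ----------------------------------------------
    stage = "eqtl+meta"
    try:
        study = LungEqtlStudy.from_dataset(dataset, window=config.window)
        results = study.fit(
            fdr_target=config.fdr_target,
            n_permutations=config.permutations,
            alpha_rep=config.alpha_rep,
            seed=config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for name in results.cohort_names:
        results.assoc_records(name, max_p=config.assoc_p_max).to_csv(
            out / f"assoc_{name}.tsv", sep="\t", index=False
        )
    results.thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    results.calls.to_csv(out / "eqtl_calls.tsv", sep="\t", index=False)
    results.meta_records(max_p=config.meta_p_max).to_csv(out / "meta.tsv", sep="\t", index=False)
    rep = results.replication.copy()
    if len(rep):
        rep["cohorts_significant"] = rep["cohorts_significant"].apply(",".join)
    rep.to_csv(out / "replication.tsv", sep="\t", index=False)

    summary["qc"] = {
        name: dataclasses.asdict(r) for name, r in results.qc_reports.items()
    }
    summary["thresholds"] = results.thresholds.to_dict(orient="records")
    summary["n_eqtls"] = {
        who: {cls: results.n_calls(who, cls) for cls in ("cis", "trans")}
        for who in results.cohort_names + ["meta"]
    }
    summary["replication_rates"] = results.replication_rates
    summary["heterogeneity"] = results.heterogeneity

    # ---- stage: GWAS integration ----------------------------------------
    stage = "integrate"
    try:
        esnps = results.esnp_set()
        esnps.to_frame().to_csv(out / "esnp_set.tsv", sep="\t", index=False)
        qq = integrate.enrichment_qq(dataset.gwas, esnps)
        qq.to_frame().to_csv(out / "qq.tsv", sep="\t", index=False)
        (out / "enrichment.json").write_text(
            json.dumps(
                {
                    "enrichment_p": qq.enrichment_p,
                    "n_esnps": qq.n_esnps,
                    "n_background": qq.n_background,
                },
                indent=1,
            )
            + "\n"
        )
        links, genes = integrate.link_gwas_genes(dataset.gwas, esnps, config.gwas_threshold)
        links.to_csv(out / "gwas_links.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    summary["integration"] = {
        "n_esnps": len(esnps),
        "enrichment_p": qq.enrichment_p,
        "n_linked_snps": int(len(links)),
        "n_linked_genes": len(genes),
    }

    # ---- stage: network -------------------------------------------------
    stage = "network"
    try:
        graph = dataset.network
        net.validate_network(graph)
        seeds = sorted(g for g in genes if g in graph)
        if seeds:
            sub, sub_report = net.extract_subnetwork(graph, seeds, config.h)
            pd.DataFrame(sorted(sub.edges()), columns=["parent_gene", "child_gene"]).to_csv(
                out / "subnetwork.tsv", sep="\t", index=False
            )
            kda = net.key_driver_analysis(sub, seeds, config.h, config.kda_alpha)
        else:
            sub, sub_report = None, {"n_nodes": 0, "n_seeds": 0, "seed_proportion": 0.0}
            kda = pd.DataFrame(
                columns=["gene", "x", "k_draw", "m", "n", "p", "p_adjusted", "driver"]
            )
        kda.to_csv(out / "kda.tsv", sep="\t", index=False)
        locus = net.rank_locus_candidates(graph, seeds, dataset.canonical, config.h)
        locus.to_csv(out / "locus_rank.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    summary["network"] = {
        "subnetwork": sub_report,
        "n_drivers": int(kda["driver"].sum()) if len(kda) else 0,
        "top_drivers": kda.head(6)["gene"].tolist() if len(kda) else [],
        "n_locus_candidates": int(len(locus)),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline complete; outputs in %s", out)
    return summary


def report(summary: dict) -> str:
    """Render a run summary as plain-text tables."""
    cohorts = summary["cohorts"]
    cols = cohorts + ["meta"]
    lines = ["eQTLs detected at %d%% FDR" % round(100 * summary["thresholds"][0]["target_fdr"])]
    lines.append("  " + "".join(f"{c:>14}" for c in [""] + cols))
    cut = {(t["cohort"], t["class"]): t["p_cutoff"] for t in summary["thresholds"]}
    for cls in ("cis", "trans"):
        vals = [f"{cut.get((c, cls), 0.0):.1e}" for c in cols]
        lines.append("  " + f"{cls + ' cutoff':>14}" + "".join(f"{v:>14}" for v in vals))
    for cls in ("cis", "trans"):
        vals = [str(summary["n_eqtls"][c][cls]) for c in cols]
        lines.append("  " + f"{'n ' + cls:>14}" + "".join(f"{v:>14}" for v in vals))
    lines.append("")
    lines.append("Replication rates:")
    for c in cohorts:
        r = summary["replication_rates"].get(c)
        lines.append(f"  {c}: " + (f"{r:.1%}" if r is not None and r == r else "n/a"))
    integ = summary["integration"]
    lines.append("")
    lines.append(
        "GWAS integration: %d eSNPs, enrichment P = %.3g, %d SNPs -> %d genes"
        % (integ["n_esnps"], integ["enrichment_p"], integ["n_linked_snps"], integ["n_linked_genes"])
    )
    nw = summary["network"]
    lines.append(
        "Network: subnetwork of %d nodes (%.0f%% seeds), %d significant drivers"
        % (
            nw["subnetwork"]["n_nodes"],
            100 * nw["subnetwork"]["seed_proportion"],
            nw["n_drivers"],
        )
    )
    if nw["top_drivers"]:
        lines.append("  top drivers: " + ", ".join(nw["top_drivers"]))
    return "\n".join(lines)
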