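"""Seeded multi-cohort genotype/expression simulator.

Emulates the data layout of a three-site lung expression study: per-cohort
genotype dosage matrices drawn from Hardy-Weinberg proportions at LD-free
SNPs, expression traits with additive cis/trans genetic effects plus
age/sex/smoking covariate effects, between-cohort heterogeneity of the true
genetic effects, a sparse gene-regulatory DAG that propagates expression
signal from parents to children, GWAS summary statistics enriched for low
P values at planted eSNPs, and a curated "canonical" gene list.

All randomness flows from ``SimConfig.seed`` through per-purpose
``numpy.random.SeedSequence`` streams, so the same configuration always
yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthTable",
    "CohortData",
    "Dataset",
    "Simulator",
    "simulate_dataset",
    "load_dataset",
]

_SMOKING_LEVELS = ("never", "ex", "current")
# Three-level smoking mix loosely matching a surgical lung-tissue cohort
# (mostly ever-smokers).
_SMOKING_PROBS = (0.15, 0.60, 0.25)

# Stream labels for per-purpose RNGs (keep stable: they define the output).
_S_SNPS, _S_PROBES, _S_TRUTH, _S_NETWORK, _S_GWAS, _S_CANON = 1, 2, 3, 4, 5, 6
_S_GENO, _S_COV, _S_NOISE, _S_HET = 10, 11, 12, 13


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs for one multi-cohort dataset.

    Defaults describe the study conditions exercised throughout: 3 cohorts of
    300 samples, 2,000 LD-free SNPs and 500 probesets on 5 chromosomes of
    10 Mb, planted cis effects sized so a single SNP explains roughly 10-20%
    of a transcript's variance, and modest between-cohort heterogeneity.
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[int, ...] = (300, 300, 300)
    n_snps: int = 2000
    n_probesets: int = 500
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    maf_range: tuple[float, float] = (0.2, 0.5)
    frac_cis: float = 0.30
    frac_trans: float = 0.05
    beta_cis: float = 0.65
    beta_trans: float = 0.65
    tau_het: float = 0.10
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.04, "sex": 0.5, "smoking_ex": 0.3, "smoking_current": 0.6}
    )
    noise_sd: float = 1.0
    network_genes: int = 100
    max_parents: int = 3
    n_hubs: int = 2
    hub_children: int = 10
    edge_weight_range: tuple[float, float] = (0.4, 0.8)
    canonical_size: int = 119
    gwas_enriched_frac: float = 0.30
    gwas_beta_a: float = 0.2
    cohort_names: tuple[str, ...] | None = None
    cis_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        spc = self.samples_per_cohort
        if isinstance(spc, int):
            object.__setattr__(self, "samples_per_cohort", (spc,) * self.n_cohorts)
        else:
            object.__setattr__(self, "samples_per_cohort", tuple(int(x) for x in spc))
        object.__setattr__(self, "maf_range", tuple(float(x) for x in self.maf_range))
        object.__setattr__(self, "edge_weight_range", tuple(float(x) for x in self.edge_weight_range))
        object.__setattr__(self, "covariate_effects", dict(self.covariate_effects))
        if self.cohort_names is not None:
            object.__setattr__(self, "cohort_names", tuple(self.cohort_names))
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts,
            "n_snps": self.n_snps,
            "n_probesets": self.n_probesets,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        if any(n <= 0 for n in self.samples_per_cohort):
            raise ValueError("sample counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.frac_cis < 0 or self.frac_trans < 0 or self.frac_cis + self.frac_trans > 1:
            raise ValueError("frac_cis and frac_trans must be nonnegative with sum <= 1")
        if self.network_genes > self.n_probesets:
            raise ValueError("network_genes must not exceed n_probesets")
        if self.canonical_size > self.n_probesets:
            raise ValueError("canonical_size must not exceed n_probesets")
        if self.max_parents < 0 or self.n_hubs < 0:
            raise ValueError("max_parents and n_hubs must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.cohort_names is not None and len(self.cohort_names) != self.n_cohorts:
            raise ValueError("cohort_names length must equal n_cohorts")

    @property
    def names(self) -> tuple[str, ...]:
        if self.cohort_names is not None:
            return self.cohort_names
        return tuple(f"cohort{i + 1}" for i in range(self.n_cohorts))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        for key in ("samples_per_cohort", "maf_range", "edge_weight_range", "cohort_names"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of planted effects, network edges and canonical genes."""

    # probeset_id -> {"snp_id", "class", "beta_global", "betas": {cohort: beta}}
    effects: dict[str, dict]
    # child gene -> list of (parent gene, weight)
    parents: dict[str, list[tuple[str, float]]]
    hubs: list[str]
    canonical: list[str]

    def planted_snps(self, eqtl_class: str | None = None) -> set[str]:
        return {
            rec["snp_id"]
            for rec in self.effects.values()
            if eqtl_class is None or rec["class"] == eqtl_class
        }

    def planted_probesets(self, eqtl_class: str | None = None) -> set[str]:
        return {
            ps
            for ps, rec in self.effects.items()
            if eqtl_class is None or rec["class"] == eqtl_class
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "effects": self.effects,
                "parents": {c: [[p, w] for p, w in ps] for c, ps in self.parents.items()},
                "hubs": self.hubs,
                "canonical": self.canonical,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        d = json.loads(text)
        parents = {c: [(p, float(w)) for p, w in ps] for c, ps in d["parents"].items()}
        return cls(effects=d["effects"], parents=parents, hubs=d["hubs"], canonical=d["canonical"])


@dataclass
class CohortData:
    name: str
    genotypes: pd.DataFrame  # SNPs x samples, dosage of the alt allele in {0,1,2}
    expression: pd.DataFrame  # probesets x samples
    covariates: pd.DataFrame  # samples x (age, sex, smoking)


@dataclass
class Dataset:
    config: SimConfig
    snps: pd.DataFrame  # snp_id, chrom, pos, ref, alt, maf
    probesets: pd.DataFrame  # probeset_id, gene_symbol, chrom, start, end, strand
    cohorts: dict[str, CohortData]
    network: nx.DiGraph
    gwas: pd.DataFrame  # snp_id, chrom, pos, p, effect_allele
    canonical: list[str]
    truth: TruthTable

    def true_pairs(self) -> set[tuple[str, str]]:
        """All SNP x probeset pairs with a nonzero true association.

        Includes the directly planted pairs and the network-mediated ones: a
        SNP planted on a regulatory ancestor gene has a true (trans) effect
        on every descendant's expression through the DAG propagation.
        """
        ps_of_gene = dict(zip(self.probesets["gene_symbol"], self.probesets["probeset_id"]))
        pairs = {(rec["snp_id"], ps) for ps, rec in self.truth.effects.items()}
        # ancestor closure over the regulatory DAG
        parents = {c: [p for p, _ in plist] for c, plist in self.truth.parents.items()}

        def ancestors(gene: str) -> set[str]:
            seen: set[str] = set()
            stack = list(parents.get(gene, []))
            while stack:
                g = stack.pop()
                if g in seen:
                    continue
                seen.add(g)
                stack.extend(parents.get(g, []))
            return seen

        for child in parents:
            child_ps = ps_of_gene.get(child)
            if child_ps is None:
                continue
            for anc in ancestors(child):
                rec = self.truth.effects.get(ps_of_gene.get(anc, ""))
                if rec is not None:
                    pairs.add((rec["snp_id"], child_ps))
        return pairs

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(self.config.to_json() + "\n")
        self.snps.to_csv(out / "snps.tsv", sep="\t", index=False)
        self.probesets.to_csv(out / "probesets.tsv", sep="\t", index=False)
        for name, cohort in self.cohorts.items():
            cdir = out / name
            cdir.mkdir(exist_ok=True)
            cohort.genotypes.to_csv(cdir / "genotypes.tsv", sep="\t", index_label="snp_id")
            cohort.expression.to_csv(cdir / "expression.tsv", sep="\t", index_label="probeset_id")
            cov = cohort.covariates.reset_index().rename(columns={"index": "sample_id"})
            cov.to_csv(cdir / "covariates.tsv", sep="\t", index=False)
        self.gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
        edges = pd.DataFrame(sorted(self.network.edges()), columns=["parent_gene", "child_gene"])
        edges.to_csv(out / "network.tsv", sep="\t", index=False)
        (out / "canonical.txt").write_text("".join(g + "\n" for g in self.canonical))
        (out / "truth.json").write_text(self.truth.to_json() + "\n")


class Simulator:
    """Deterministic generator for one :class:`Dataset`.

    Annotation tables, the planted-truth table and the regulatory DAG are
    shared across cohorts; genotypes, covariates and expression noise are
    cohort-specific streams.
    """

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self._snps = self._make_snps()
        self._probesets = self._make_probesets()
        self._network, self._parents, self._hubs = self._make_network()
        self._truth_effects = self._make_truth()
        self._canonical = self._make_canonical()

    # ---------------------------------------------------------------- annotations
    def _chrom_split(self, n: int) -> list[int]:
        base = n // self.config.n_chromosomes
        rem = n % self.config.n_chromosomes
        return [base + (1 if i < rem else 0) for i in range(self.config.n_chromosomes)]

    def _make_snps(self) -> pd.DataFrame:
        cfg = self.config
        rng = _rng(cfg.seed, _S_SNPS)
        rows = []
        bases = np.array(list("ACGT"))
        for chrom_i, count in enumerate(self._chrom_split(cfg.n_snps), start=1):
            pos = np.sort(rng.integers(1, cfg.chrom_length + 1, size=count))
            for p in pos:
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append((f"chr{chrom_i}", int(p), bases[ref], bases[alt]))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        df.insert(0, "snp_id", [f"rs{i + 1:06d}" for i in range(len(df))])
        lo, hi = cfg.maf_range
        df["maf"] = rng.uniform(lo, hi, size=len(df))
        return df

    def _make_probesets(self) -> pd.DataFrame:
        cfg = self.config
        rng = _rng(cfg.seed, _S_PROBES)
        rows = []
        idx = 0
        for chrom_i, count in enumerate(self._chrom_split(cfg.n_probesets), start=1):
            lengths = rng.integers(5_000, 100_000, size=count)
            starts = np.sort(rng.integers(1, np.maximum(cfg.chrom_length - lengths.max(), 2), size=count))
            strands = rng.choice(["+", "-"], size=count)
            for s, ln, st in zip(starts, lengths, strands):
                rows.append(
                    (
                        f"PS{idx + 1:05d}_at",
                        f"G{idx + 1:04d}",
                        f"chr{chrom_i}",
                        int(s),
                        int(s + ln - 1),
                        st,
                    )
                )
                idx += 1
        return pd.DataFrame(rows, columns=["probeset_id", "gene_symbol", "chrom", "start", "end", "strand"])

    # ---------------------------------------------------------------- network
    def _make_network(self) -> tuple[nx.DiGraph, dict[str, list[tuple[str, float]]], list[str]]:
        cfg = self.config
        rng = _rng(cfg.seed, _S_NETWORK)
        genes = list(self._probesets["gene_symbol"].iloc[: cfg.network_genes])
        lo, hi = cfg.edge_weight_range
        parents: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
        n_hubs = min(cfg.n_hubs, len(genes))
        hubs = genes[:n_hubs]
        # ordinary sparse parent draws (node order guarantees acyclicity)
        for i, gene in enumerate(genes):
            if i == 0:
                continue
            k = int(rng.integers(0, cfg.max_parents + 1))
            k = min(k, i)
            if k:
                chosen = rng.choice(i, size=k, replace=False)
                for j in sorted(int(c) for c in chosen):
                    parents[gene].append((genes[j], float(rng.uniform(lo, hi))))
        # planted hubs: force a large out-degree so key-driver analysis has signal
        for h_i, hub in enumerate(hubs):
            later = np.arange(n_hubs, len(genes))
            if later.size == 0:
                break
            size = min(cfg.hub_children, later.size)
            kids = rng.choice(later, size=size, replace=False)
            for j in sorted(int(c) for c in kids):
                gene = genes[j]
                if all(p != hub for p, _ in parents[gene]):
                    parents[gene].append((hub, float(rng.uniform(lo, hi))))
        graph = nx.DiGraph()
        graph.add_nodes_from(genes)
        for child, plist in parents.items():
            for parent, w in plist:
                graph.add_edge(parent, child, weight=w)
        assert nx.is_directed_acyclic_graph(graph)
        return graph, parents, hubs

    # ---------------------------------------------------------------- truth
    def _make_truth(self) -> dict[str, dict]:
        cfg = self.config
        rng = _rng(cfg.seed, _S_TRUTH)
        het = _rng(cfg.seed, _S_HET)
        n_cis = int(round(cfg.frac_cis * cfg.n_probesets))
        n_trans = int(round(cfg.frac_trans * cfg.n_probesets))
        order = rng.permutation(cfg.n_probesets)
        cis_ps, trans_ps = order[:n_cis], order[n_cis : n_cis + n_trans]
        snps = self._snps
        probes = self._probesets
        effects: dict[str, dict] = {}

        def plant(ps_idx: int, eqtl_class: str, beta_mag: float) -> None:
            row = probes.iloc[ps_idx]
            same = snps["chrom"] == row["chrom"]
            near = same & (snps["pos"] >= row["start"] - cfg.cis_window) & (
                snps["pos"] <= row["end"] + cfg.cis_window
            )
            cand = near if eqtl_class == "cis" else ~near
            cand_idx = np.flatnonzero(cand.to_numpy())
            if cand_idx.size == 0:
                return
            snp_i = int(cand_idx[rng.integers(0, cand_idx.size)])
            sign = -1.0 if rng.random() < 0.5 else 1.0
            beta_global = sign * beta_mag
            betas = {
                name: float(beta_global + het.normal(0.0, cfg.tau_het))
                for name in cfg.names
            }
            effects[row["probeset_id"]] = {
                "snp_id": snps["snp_id"].iloc[snp_i],
                "class": eqtl_class,
                "beta_global": beta_global,
                "betas": betas,
            }

        for ps_idx in cis_ps:
            plant(int(ps_idx), "cis", cfg.beta_cis)
        for ps_idx in trans_ps:
            plant(int(ps_idx), "trans", cfg.beta_trans)
        return effects

    def _make_canonical(self) -> list[str]:
        cfg = self.config
        rng = _rng(cfg.seed, _S_CANON)
        # seed the list with hub descendants so network enrichment has signal
        core: list[str] = []
        for hub in self._hubs:
            core.extend(sorted(nx.descendants(self._network, hub)))
        core = list(dict.fromkeys(core))[: cfg.canonical_size]
        pool = [g for g in self._probesets["gene_symbol"] if g not in set(core)]
        need = cfg.canonical_size - len(core)
        if need > 0:
            extra = rng.choice(len(pool), size=need, replace=False)
            core.extend(pool[int(i)] for i in sorted(extra))
        return sorted(core)

    # ---------------------------------------------------------------- cohort data
    def genotypes(self, cohort: int) -> pd.DataFrame:
        """Dosage matrix for one cohort: HWE draws at each SNP's MAF."""
        cfg = self.config
        if not 0 <= cohort < cfg.n_cohorts:
            raise ValueError(f"cohort index {cohort} out of range")
        rng = _rng(cfg.seed, _S_GENO, cohort)
        n = cfg.samples_per_cohort[cohort]
        maf = self._snps["maf"].to_numpy()
        dosages = rng.binomial(2, maf[:, None], size=(cfg.n_snps, n))
        samples = [f"{cfg.names[cohort]}_S{k + 1:04d}" for k in range(n)]
        return pd.DataFrame(dosages, index=self._snps["snp_id"].to_numpy(), columns=samples)

    def covariates(self, cohort: int) -> pd.DataFrame:
        cfg = self.config
        rng = _rng(cfg.seed, _S_COV, cohort)
        n = cfg.samples_per_cohort[cohort]
        age = rng.uniform(40.0, 80.0, size=n)
        sex = rng.integers(0, 2, size=n)
        smoking = rng.choice(_SMOKING_LEVELS, size=n, p=_SMOKING_PROBS)
        samples = [f"{cfg.names[cohort]}_S{k + 1:04d}" for k in range(n)]
        return pd.DataFrame({"age": age, "sex": sex, "smoking": smoking}, index=samples)

    def expression(self, cohort: int, genotypes: pd.DataFrame | None = None,
                   covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Expression matrix: covariates + planted genetics + DAG signal + noise."""
        cfg = self.config
        G = self.genotypes(cohort) if genotypes is None else genotypes
        cov = self.covariates(cohort) if covariates is None else covariates
        if list(G.columns) != list(cov.index):
            raise ValueError("genotype samples do not match covariate samples")
        n = G.shape[1]
        rng = _rng(cfg.seed, _S_NOISE, cohort)
        eff = cfg.covariate_effects
        cov_term = (
            eff.get("age", 0.0) * cov["age"].to_numpy()
            + eff.get("sex", 0.0) * cov["sex"].to_numpy()
            + eff.get("smoking_ex", 0.0) * (cov["smoking"] == "ex").to_numpy()
            + eff.get("smoking_current", 0.0) * (cov["smoking"] == "current").to_numpy()
        )
        E = np.tile(cov_term, (cfg.n_probesets, 1)) + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probesets, n))
        ps_ids = self._probesets["probeset_id"].to_numpy()
        ps_index = {p: i for i, p in enumerate(ps_ids)}
        name = cfg.names[cohort]
        for ps, rec in self._truth_effects.items():
            E[ps_index[ps]] += rec["betas"][name] * G.loc[rec["snp_id"]].to_numpy()
        # propagate regulatory signal parent -> child in construction order
        gene_to_ps = dict(zip(self._probesets["gene_symbol"], ps_ids))
        for child in self._probesets["gene_symbol"].iloc[: cfg.network_genes]:
            plist = self._parents.get(child, [])
            if not plist:
                continue
            ci = ps_index[gene_to_ps[child]]
            for parent, w in plist:
                pv = E[ps_index[gene_to_ps[parent]]]
                E[ci] += w * (pv - pv.mean())
        return pd.DataFrame(E, index=ps_ids, columns=G.columns)

    def gwas(self) -> pd.DataFrame:
        """GWAS summary table with planted-eSNP P values stochastically small."""
        cfg = self.config
        rng = _rng(cfg.seed, _S_GWAS)
        p = rng.uniform(size=cfg.n_snps)
        planted = sorted(self.truth.planted_snps())
        n_enriched = int(round(cfg.gwas_enriched_frac * len(planted)))
        if n_enriched and cfg.gwas_beta_a > 0:
            which = rng.choice(len(planted), size=n_enriched, replace=False)
            snp_pos = {s: i for i, s in enumerate(self._snps["snp_id"])}
            for i in sorted(int(w) for w in which):
                p[snp_pos[planted[i]]] = rng.beta(cfg.gwas_beta_a, 1.0)
        out = self._snps[["snp_id", "chrom", "pos"]].copy()
        out["p"] = p
        out["effect_allele"] = self._snps["alt"]
        return out

    # ---------------------------------------------------------------- assembly
    @property
    def snps(self) -> pd.DataFrame:
        return self._snps.copy()

    @property
    def probesets(self) -> pd.DataFrame:
        return self._probesets.copy()

    @property
    def network(self) -> nx.DiGraph:
        return self._network.copy()

    @property
    def truth(self) -> TruthTable:
        return TruthTable(
            effects=self._truth_effects,
            parents=self._parents,
            hubs=list(self._hubs),
            canonical=list(self._canonical),
        )

    def dataset(self) -> Dataset:
        cfg = self.config
        cohorts = {}
        for i, name in enumerate(cfg.names):
            G = self.genotypes(i)
            cov = self.covariates(i)
            E = self.expression(i, G, cov)
            cohorts[name] = CohortData(name=name, genotypes=G, expression=E, covariates=cov)
        return Dataset(
            config=cfg,
            snps=self.snps,
            probesets=self.probesets,
            cohorts=cohorts,
            network=self.network,
            gwas=self.gwas(),
            canonical=list(self._canonical),
            truth=self.truth,
        )


def simulate_dataset(config: SimConfig) -> Dataset:
    """Generate a full multi-cohort dataset from one configuration."""
    return Simulator(config).dataset()


def load_dataset(path: str | Path) -> Dataset:
    """Read a dataset previously written by :meth:`Dataset.write`."""
    root = Path(path)
    config = SimConfig.from_json((root / "config.json").read_text())
    snps = pd.read_csv(root / "snps.tsv", sep="\t")
    probesets = pd.read_csv(root / "probesets.tsv", sep="\t")
    cohorts = {}
    for name in config.names:
        cdir = root / name
        G = pd.read_csv(cdir / "genotypes.tsv", sep="\t", index_col="snp_id")
        E = pd.read_csv(cdir / "expression.tsv", sep="\t", index_col="probeset_id")
        cov = pd.read_csv(cdir / "covariates.tsv", sep="\t", index_col="sample_id")
        cohorts[name] = CohortData(name=name, genotypes=G, expression=E, covariates=cov)
    edges = pd.read_csv(root / "network.tsv", sep="\t")
    graph = nx.DiGraph()
    graph.add_edges_from(edges.itertuples(index=False, name=None))
    gwas = pd.read_csv(root / "gwas.tsv", sep="\t")
    canonical = [line.strip() for line in (root / "canonical.txt").read_text().splitlines() if line.strip()]
    truth = TruthTable.from_json((root / "truth.json").read_text())
    return Dataset(
        config=config,
        snps=snps,
        probesets=probesets,
        cohorts=cohorts,
        network=graph,
        gwas=gwas,
        canonical=canonical,
        truth=truth,
    )
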