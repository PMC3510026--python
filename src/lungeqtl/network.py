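"""Directed gene-network stage.

Validated loading of acyclic directed gene networks, a greedy hill-climbing
structure-learner stand-in (penalized linear-Gaussian likelihood), 3-edge
neighborhoods, coherent-subnetwork extraction, upper-tail hypergeometric
neighborhood enrichment, Key Driver Analysis on directed downstream
reachability, and locus-candidate ranking.

Two traversal conventions coexist deliberately: neighborhood enrichment and
locus ranking ignore edge direction (the "milieu" of a gene), while Key
Driver Analysis follows edge direction downstream (a driver is judged by the
genes it can influence).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_network",
    "validate_network",
    "learn_network_standin",
    "neighborhood",
    "downstream",
    "extract_subnetwork",
    "hypergeom_upper",
    "key_driver_analysis",
    "rank_locus_candidates",
]

DEFAULT_H = 3


def validate_network(graph: nx.DiGraph) -> None:
    """Raise if the graph has self-loops or directed cycles."""
    loops = list(nx.nodes_with_selfloops(graph))
    if loops:
        raise ValueError(f"self-loops are not allowed: {loops[:5]}")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"network contains a cycle: {path}")


def load_network(source: str | Path | Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build a validated directed gene network from a parent-child edge list.

    Accepts a two-column TSV path (header ``parent_gene\\tchild_gene``
    optional) or an iterable of (parent, child) pairs. Gene symbols are
    uppercased; duplicate edges are dropped with a warning; cycles raise.
    """
    if isinstance(source, (str, Path)):
        edges: list[tuple[str, str]] = []
        for line in Path(source).read_text().splitlines():
            line = line.strip()
            if not line or line.lower().startswith(("parent", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    else:
        edges = [(str(a), str(b)) for a, b in source]
    edges = [(a.upper(), b.upper()) for a, b in edges]
    seen = set()
    unique = []
    dup = 0
    for e in edges:
        if e in seen:
            dup += 1
            continue
        seen.add(e)
        unique.append(e)
    if dup:
        warnings.warn(f"dropped {dup} duplicate edges")
    graph = nx.DiGraph()
    graph.add_edges_from(unique)
    validate_network(graph)
    return graph


def _family_score(Y: np.ndarray, child: int, parents: tuple[int, ...]) -> float:
    """BIC-style local score of one linear-Gaussian family (higher is better)."""
    n = Y.shape[0]
    y = Y[:, child]
    if parents:
        X = np.column_stack([np.ones(n), Y[:, list(parents)]])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef) ** 2).sum())
    else:
        rss = float(((y - y.mean()) ** 2).sum())
    rss = max(rss, 1e-300)
    k = len(parents) + 1
    return -0.5 * n * np.log(rss / n) - 0.5 * k * np.log(n)


def learn_network_standin(
    expression: pd.DataFrame,
    max_parents: int = 3,
    min_samples: int = 50,
) -> nx.DiGraph:
    """Greedy hill-climbing DAG learner over gene-expression columns.

    A deliberately simple, deterministic structure learner: starting from the
    empty graph, repeatedly apply the single edge addition, deletion or
    reversal that most improves the summed penalized linear-Gaussian
    likelihood (BIC), subject to acyclicity and an in-degree cap. Ties break
    on the lexicographic edge order. ``expression`` is genes x samples.
    """
    genes = [str(g).upper() for g in expression.index]
    Y = expression.to_numpy(dtype=float).T  # samples x genes
    n, g = Y.shape
    if n < min_samples:
        raise ValueError(f"structure learning needs >= {min_samples} samples, got {n}")
    parents: dict[int, tuple[int, ...]] = {i: () for i in range(g)}
    scores = {i: _family_score(Y, i, ()) for i in range(g)}
    graph = nx.DiGraph()
    graph.add_nodes_from(range(g))

    def would_cycle(u: int, v: int) -> bool:
        # adding u -> v creates a cycle iff v reaches u
        return nx.has_path(graph, v, u)

    while True:
        best: tuple[float, tuple] | None = None
        for u in range(g):
            for v in range(g):
                if u == v:
                    continue
                has = graph.has_edge(u, v)
                if not has:
                    if len(parents[v]) >= max_parents or would_cycle(u, v):
                        continue
                    new_p = tuple(sorted(parents[v] + (u,)))
                    delta = _family_score(Y, v, new_p) - scores[v]
                    move = ("add", u, v)
                else:
                    new_p = tuple(x for x in parents[v] if x != u)
                    delta = _family_score(Y, v, new_p) - scores[v]
                    move = ("del", u, v)
                    # reversal: delete u->v, add v->u
                    graph.remove_edge(u, v)
                    rev_ok = len(parents[u]) < max_parents and not nx.has_path(graph, u, v)
                    graph.add_edge(u, v)
                    if rev_ok:
                        rev_p_v = new_p
                        rev_p_u = tuple(sorted(parents[u] + (v,)))
                        rdelta = (
                            _family_score(Y, v, rev_p_v)
                            - scores[v]
                            + _family_score(Y, u, rev_p_u)
                            - scores[u]
                        )
                        if rdelta > delta + 1e-12:
                            delta = rdelta
                            move = ("rev", u, v)
                if delta > 1e-9 and (best is None or delta > best[0] + 1e-12):
                    best = (delta, move)
        if best is None:
            break
        _, (op, u, v) = best
        if op == "add":
            graph.add_edge(u, v)
            parents[v] = tuple(sorted(parents[v] + (u,)))
        elif op == "del":
            graph.remove_edge(u, v)
            parents[v] = tuple(x for x in parents[v] if x != u)
        else:
            graph.remove_edge(u, v)
            graph.add_edge(v, u)
            parents[v] = tuple(x for x in parents[v] if x != u)
            parents[u] = tuple(sorted(parents[u] + (v,)))
            scores[u] = _family_score(Y, u, parents[u])
        scores[v] = _family_score(Y, v, parents[v])
    out = nx.DiGraph()
    out.add_nodes_from(genes)
    out.add_edges_from((genes[u], genes[v]) for u, v in graph.edges())
    validate_network(out)
    return out


def neighborhood(graph: nx.DiGraph, gene: str, h: int = DEFAULT_H) -> set[str]:
    """Genes within h edges of ``gene``, ignoring edge direction; seed excluded."""
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in network")
    if h <= 0:
        return set()
    und = graph.to_undirected(as_view=True)
    reached = nx.single_source_shortest_path_length(und, gene, cutoff=h)
    return set(reached) - {gene}


def downstream(graph: nx.DiGraph, gene: str, h: int = DEFAULT_H) -> set[str]:
    """Genes reachable within h directed edges downstream of ``gene``."""
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in network")
    if h <= 0:
        return set()
    reached = nx.single_source_shortest_path_length(graph, gene, cutoff=h)
    return set(reached) - {gene}


def extract_subnetwork(
    graph: nx.DiGraph, seeds: Sequence[str], h: int = DEFAULT_H
) -> tuple[nx.DiGraph, dict]:
    """Largest coherent subnetwork around a seed-gene set.

    Induces the graph on the union of the seeds and their h-edge undirected
    neighborhoods, then returns the weakly connected component with the
    highest proportion of seed genes (ties broken toward more nodes).
    """
    present = [s for s in seeds if s in graph]
    if not present:
        raise ValueError("no seed gene is present in the network")
    members: set[str] = set(present)
    for s in present:
        members |= neighborhood(graph, s, h)
    induced = graph.subgraph(members).copy()
    seed_set = set(present)
    best = None
    for comp in nx.weakly_connected_components(induced):
        prop = len(comp & seed_set) / len(comp)
        key = (prop, len(comp))
        if best is None or key > best[0]:
            best = (key, comp)
    (prop, size), comp = best
    sub = induced.subgraph(comp).copy()
    report = {
        "n_nodes": size,
        "n_seeds": len(comp & seed_set),
        "seed_proportion": prop,
        "n_components_considered": nx.number_weakly_connected_components(induced),
    }
    return sub, report


def hypergeom_upper(x: int, k_draw: int, m: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts successes in ``k_draw`` draws without replacement from a
    population of ``m`` successes and ``n`` failures. x = 0 gives exactly 1.
    """
    x, k_draw, m, n = int(x), int(k_draw), int(m), int(n)
    if min(x, k_draw, m, n) < 0 or x > k_draw or x > m or k_draw > m + n:
        raise ValueError(f"inconsistent counts: x={x}, k_draw={k_draw}, m={m}, n={n}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, m + n, m, k_draw))


def _enrich(graph: nx.DiGraph, gene: str, drawn: set[str], targets: set[str],
            m: int, n: int) -> dict:
    x = len(drawn & targets)
    k_draw = len(drawn)
    return {
        "gene": gene,
        "x": x,
        "k_draw": k_draw,
        "m": m,
        "n": n,
        "p": hypergeom_upper(x, k_draw, m, n),
    }


def key_driver_analysis(
    graph: nx.DiGraph,
    targets: Iterable[str],
    h: int = DEFAULT_H,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank every network gene by enrichment of targets among its downstream genes.

    For each gene g the draw is the set D of genes reachable within h
    directed edges of g (g excluded); the overlap x = \\|D and targets\\| is
    scored against a hypergeometric with m = targets present in the network
    and n = remaining network genes. P values are Bonferroni-adjusted across
    all tested genes; drivers are those with adjusted P < alpha, ranked by
    ascending P.
    """
    target_set = {str(t).upper() for t in targets}
    in_net = target_set & set(graph.nodes)
    if not in_net:
        raise ValueError("no target gene is present in the network")
    m = len(in_net)
    n = graph.number_of_nodes() - m
    rows = [
        _enrich(graph, g, downstream(graph, g, h), in_net, m, n) for g in sorted(graph.nodes)
    ]
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_adjusted"] = np.minimum(out["p"] * n_tests, 1.0)
    out["driver"] = out["p_adjusted"] < alpha
    out = out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    return out


def rank_locus_candidates(
    graph: nx.DiGraph,
    candidates: Sequence[str],
    canonical: Iterable[str],
    h: int = DEFAULT_H,
    background: int | None = None,
) -> pd.DataFrame:
    """Score locus candidate genes by canonical-gene content of their milieu.

    Per candidate: x = canonical genes within its h-edge undirected
    neighborhood, k = that neighborhood's size, m = size of the canonical
    list, n = background - m (default background = network size). Candidates
    absent from the network score (x=0, k=0, P=1). Sorted by ascending P.
    """
    canon = {str(c).upper() for c in canonical}
    if not canon:
        raise ValueError("canonical set is empty")
    m = len(canon)
    total = background if background is not None else graph.number_of_nodes()
    n = max(total - m, 0)
    rows = []
    for cand in candidates:
        cand = str(cand).upper()
        if cand not in graph:
            rows.append({"gene": cand, "x": 0, "k_draw": 0, "m": m, "n": n, "p": 1.0})
            continue
        nb = neighborhood(graph, cand, h)
        x = len(nb & canon)
        k_draw = len(nb)
        rows.append(
            {
                "gene": cand,
                "x": x,
                "k_draw": k_draw,
                "m": m,
                "n": n,
                "p": hypergeom_upper(min(x, m), min(k_draw, m + n), m, n) if k_draw else 1.0,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "x", "k_draw", "m", "n", "p"])
    return out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
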