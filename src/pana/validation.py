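"""Functional validation of a pathway network against gene-pair scores.

Given an external table of gene-pair association scores (e.g. a
probabilistic functional gene network), the association strength of a
pathway pair, ASp, is the sum of the scores of all distinct gene pairs
that can be formed between the two pathways. A network's mean edge ASp
(ASn) is compared against the *universal set* — all pathway pairs with
positive ASp — through an empirical percentile table, and each edge is
additionally ranked against a null of random pathway pairs matching its
cardinality pattern (the two pathway sizes and the shared-gene count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssociationScoreTable, PathwayAnnotation
from .network import PathwayNetwork

__all__ = [
    "ValidationReport",
    "pathway_pair_score",
    "universal_set",
    "percentile_table",
    "cardinality_null",
    "validate_network",
]

TABLE_PERCENTILES = (10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 100)


@dataclass
class ValidationReport:
    edge_scores: dict[tuple[str, str], float]
    asn: float
    percentiles: pd.DataFrame               # rows: universal, network
    null_percentiles: dict[tuple[str, str], float] = field(default_factory=dict)
    size_score_correlation: tuple[float, float] = (float("nan"), float("nan"))
    t_test: tuple[float, float] = (float("nan"), float("nan"))


def pathway_pair_score(annotation: PathwayAnnotation,
                       scores: AssociationScoreTable,
                       i: str, j: str) -> float:
    """Association strength ASp of a pathway pair.

    Sum of scores over all unordered gene pairs {g, h}, g != h, with one
    member in each pathway; a pair of genes shared by both pathways is
    counted once. Absent score pairs contribute 0.
    """
    return _pair_score(annotation[i], annotation[j], scores)


def _pair_score(genes_i: set[str], genes_j: set[str],
                scores: AssociationScoreTable) -> float:
    pairs: set[tuple[str, str]] = set()
    for g in genes_i:
        for h in genes_j:
            if g == h:
                continue
            pairs.add((g, h) if g <= h else (h, g))
    return float(sum(scores.lookup(a, b) for a, b in pairs))


def universal_set(annotation: PathwayAnnotation,
                  scores: AssociationScoreTable) -> dict[tuple[str, str], float]:
    """ASp of every unordered pathway pair with ASp > 0."""
    out: dict[tuple[str, str], float] = {}
    for i, j in combinations(sorted(annotation.pathways), 2):
        s = pathway_pair_score(annotation, scores, i, j)
        if s > 0:
            out[(i, j)] = s
    return out


def percentile_table(universal, network,
                     percentiles=TABLE_PERCENTILES) -> pd.DataFrame:
    """Empirical quantiles (linear interpolation) of both ASp sets."""
    u = np.asarray(list(universal), dtype=float)
    n = np.asarray(list(network), dtype=float)
    if u.size == 0 or n.size == 0:
        raise ValueError("both ASp sets must be non-empty")
    pct = list(percentiles)
    return pd.DataFrame(
        [np.percentile(u, pct), np.percentile(n, pct)],
        index=["universal", "network"], columns=[f"{p}%" for p in pct])


def cardinality_null(genes_i: set[str], genes_j: set[str],
                     universe, scores: AssociationScoreTable,
                     n_random: int = 100,
                     seed: int | np.random.Generator = 0) -> float:
    """Percentile of an edge's ASp within a cardinality-matched null.

    Samples ``n_random`` random pathway pairs from the gene universe
    preserving the edge's cardinality pattern (|i|, |j|, |i & j|) and
    returns the mid-rank percentile (in [0, 1]) of the observed ASp in
    the null ASp distribution; ties count half, so an edge that is
    exchangeable with the null lands near 0.5.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    universe = list(universe)
    ni, nj, nc = len(genes_i), len(genes_j), len(genes_i & genes_j)
    need = ni + nj - nc
    if need > len(universe):
        raise ValueError(
            f"gene universe of size {len(universe)} cannot host the "
            f"cardinality pattern ({ni}, {nj}, {nc})")
    observed = _pair_score(genes_i, genes_j, scores)
    null = np.empty(n_random)
    universe_arr = np.asarray(universe, dtype=object)
    for r in range(n_random):
        pick = rng.choice(len(universe_arr), size=need, replace=False)
        genes = universe_arr[pick]
        shared = set(genes[:nc])
        ri = shared | set(genes[nc:ni])
        rj = shared | set(genes[ni:])
        null[r] = _pair_score(ri, rj, scores)
    less = float((null < observed).sum())
    equal = float((null == observed).sum())
    return (less + 0.5 * equal) / n_random


def validate_network(network: PathwayNetwork, annotation: PathwayAnnotation,
                     scores: AssociationScoreTable, n_random: int = 100,
                     seed: int = 0,
                     percentiles=TABLE_PERCENTILES) -> ValidationReport:
    """Full validation report for a pathway-profile network.

    Edges are collapsed to unordered pathway pairs (profile components of
    the same pathway pair share one ASp). Includes the pathway-size vs
    ASp correlation diagnostic (Pearson r of max pathway size against
    edge ASp) and a Welch two-sample t-test of edge ASp against the
    pooled cardinality-null samples' means.
    """
    rng = np.random.default_rng(seed)
    pairs: set[tuple[str, str]] = set()
    for u, v, _ in network.graph.edges(data=True):
        pu = network.graph.nodes[u].get("pathway", u.rsplit("#", 1)[0])
        pv = network.graph.nodes[v].get("pathway", v.rsplit("#", 1)[0])
        if pu == pv:
            continue
        pairs.add((pu, pv) if pu <= pv else (pv, pu))
    if not pairs:
        raise ValueError("network has no inter-pathway edges to validate")
    edge_scores = {p: pathway_pair_score(annotation, scores, *p)
                   for p in sorted(pairs)}
    asn = float(np.mean(list(edge_scores.values())))
    uni = universal_set(annotation, scores)
    table = percentile_table(uni.values(), edge_scores.values(), percentiles)

    universe = sorted(scores.genes)
    null_pct: dict[tuple[str, str], float] = {}
    for (i, j) in edge_scores:
        gi, gj = annotation[i], annotation[j]
        null_pct[(i, j)] = cardinality_null(gi, gj, universe, scores,
                                            n_random, rng)

    # size-vs-ASp diagnostic
    sizes = [max(len(annotation[i]), len(annotation[j]))
             for (i, j) in edge_scores]
    vals = list(edge_scores.values())
    if len(vals) > 2 and np.std(sizes) > 0 and np.std(vals) > 0:
        r, p = stats.pearsonr(sizes, vals)
    else:
        r, p = float("nan"), float("nan")

    # Welch t-test: edge ASp against one resampled null ASp per edge
    null_sample = []
    for (i, j) in edge_scores:
        gi, gj = annotation[i], annotation[j]
        ni, nj, nc = len(gi), len(gj), len(gi & gj)
        need = ni + nj - nc
        pick = rng.choice(len(universe), size=need, replace=False)
        genes = np.asarray(universe, dtype=object)[pick]
        shared = set(genes[:nc])
        null_sample.append(_pair_score(shared | set(genes[nc:ni]),
                                       shared | set(genes[ni:]), scores))
    if len(vals) > 1:
        t, tp = stats.ttest_ind(vals, null_sample, equal_var=False)
    else:
        t, tp = float("nan"), float("nan")

    return ValidationReport(edge_scores, asn, table, null_pct,
                            (float(r), float(p)), (float(t), float(tp)))


def write_report(report: ValidationReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ASn\t{report.asn:.6g}\n")
        fh.write(f"# size_vs_ASp_pearson_r\t{report.size_score_correlation[0]:.4g}"
                 f"\tp\t{report.size_score_correlation[1]:.4g}\n")
        fh.write(f"# welch_t\t{report.t_test[0]:.4g}\tp\t{report.t_test[1]:.4g}\n")
        fh.write("# percentile table\n")
        fh.write(report.percentiles.to_csv(sep="\t"))
        fh.write("pathway_i\tpathway_j\tASp\tnull_percentile\n")
        for (i, j), s in report.edge_scores.items():
            pct = report.null_percentiles.get((i, j), float("nan"))
            fh.write(f"{i}\t{j}\t{s:.6g}\t{pct:.4f}\n")
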