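"""Gene-set overrepresentation statistics shared by the tissue-expression,
brain-coordinate, co-expression-module, GO and PPI-cluster analyses.

One-tailed Fisher exact and hypergeometric tests are the same upper-tail
probability under fixed 2x2 margins; both are exposed because the source
analyses name them interchangeably.  Empirical p-values for counts of
enriched terms come from repeated uniform redraws of the target gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("denovoburden")

GO_MIN_SET_SIZE = 20
GO_MAX_SET_SIZE = 500
DEFAULT_PSI_THRESHOLD = 0.05
STRING_EDGE_THRESHOLD = 0.375  # PPI-cluster similarity graphs
GO_EDGE_THRESHOLD = 0.5  # GO-term similarity graphs


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    members: frozenset[str]
    source: str = "go_term"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.set_id}: empty gene set")


@dataclass(frozen=True)
class OverrepResult:
    set_id: str
    overlap: int
    p: float
    q: float
    enrichment_ratio: float


def overrep_test(
    target: set[str],
    gene_set: GeneSet,
    universe: set[str],
    method: str = "hypergeometric",
) -> tuple[int, float, float]:
    """Upper-tail overrepresentation p for ``target`` in ``gene_set``.

    Returns (overlap, p, enrichment_ratio) where the ratio compares the
    in-target member fraction with the universe member fraction.  Members
    outside the universe are ignored.
    """
    if not universe:
        raise ValueError("empty universe")
    if not target <= universe:
        raise ValueError("target must be a subset of the universe")
    members = gene_set.members & universe
    k = len(target & members)
    N, K, n = len(universe), len(members), len(target)
    if method == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    elif method == "fisher_one_tailed":
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    expected_frac = K / N
    ratio = (k / n) / expected_frac if n > 0 and expected_frac > 0 else float("nan")
    return k, min(p, 1.0), ratio


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def test_gene_sets(
    target: set[str],
    gene_sets: list[GeneSet],
    universe: set[str],
    method: str = "hypergeometric",
    min_size: int | None = None,
    max_size: int | None = None,
) -> list[OverrepResult]:
    """Overrepresentation of ``target`` in each set, BH-adjusted across
    sets.  GO-style size filtering (20-500 members in the universe) is
    applied when ``min_size``/``max_size`` are given."""
    kept = []
    for gs in gene_sets:
        size = len(gs.members & universe)
        if min_size is not None and size < min_size:
            continue
        if max_size is not None and size > max_size:
            continue
        kept.append(gs)
    if not kept:
        return []
    rows = [overrep_test(target, gs, universe, method) for gs in kept]
    q = bh_adjust([p for _, p, _ in rows])
    return [
        OverrepResult(gs.set_id, k, p, float(qi), ratio)
        for gs, (k, p, ratio), qi in zip(kept, rows, q)
    ]


def empirical_term_count_p(
    observed_n_terms: int,
    target_size: int,
    enriched_sets: list[GeneSet],
    universe: set[str],
    q_threshold: float = 0.01,
    n_draws: int = 1000,
    seed: int = 0,
    method: str = "hypergeometric",
) -> tuple[float, float]:
    """Empirical p for observing >= ``observed_n_terms`` enriched terms.

    Draw ``target_size`` genes uniformly without replacement ``n_draws``
    times, re-test the given (already known-gene-enriched) sets at the same
    q threshold, and report the proportion of draws with at least the
    observed term count, along with the 1/n_draws resolution floor.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pool = sorted(universe)
    if target_size > len(pool):
        raise ValueError("target_size exceeds the universe")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        draw = set(rng.choice(pool, size=target_size, replace=False))
        res = test_gene_sets(draw, enriched_sets, universe, method=method)
        n_enriched = sum(1 for r in res if r.q < q_threshold)
        if n_enriched >= observed_n_terms:
            hits += 1
    return hits / n_draws, 1.0 / n_draws


def term_similarity(set_a: set[str] | GeneSet, set_b: set[str] | GeneSet) -> float:
    """Jaccard and overlap combined coefficient:
    0.5*|A&B|/|A|B| union + 0.5*|A&B|/min(|A|,|B|).  Term-similarity graphs
    draw an edge above 0.375 (PPI clusters) or 0.5 (GO terms)."""
    a = set_a.members if isinstance(set_a, GeneSet) else set(set_a)
    b = set_b.members if isinstance(set_b, GeneSet) else set(set_b)
    if not a or not b:
        raise ValueError("term_similarity requires nonempty sets")
    inter = len(a & b)
    return 0.5 * inter / len(a | b) + 0.5 * inter / min(len(a), len(b))


def similarity_edges(
    gene_sets: list[GeneSet], threshold: float = STRING_EDGE_THRESHOLD
) -> list[tuple[str, str, float]]:
    """Edges of the term-similarity graph above ``threshold``."""
    edges = []
    for i, ga in enumerate(gene_sets):
        for gb in gene_sets[i + 1 :]:
            s = term_similarity(ga, gb)
            if s > threshold:
                edges.append((ga.set_id, gb.set_id, s))
    return edges


def psi_select(
    psi_table: pd.DataFrame, threshold: float = DEFAULT_PSI_THRESHOLD
) -> list[GeneSet]:
    """One GeneSet per column (tissue or brain coordinate) holding the genes
    with pSI strictly below ``threshold`` (smaller pSI = more specific);
    empty columns are dropped with a warning."""
    sets = []
    for col in psi_table.columns:
        members = frozenset(psi_table.index[psi_table[col] < threshold])
        if not members:
            logger.warning("psi_select: no genes pass pSI < %g in %s", threshold, col)
            continue
        sets.append(GeneSet(set_id=str(col), members=members, source="tissue"))
    return sets


def read_gmt(stream) -> list[GeneSet]:
    """Parse GMT lines: set_id <tab> description <tab> gene1 <tab> gene2..."""
    sets = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(set_id=parts[0], members=frozenset(parts[2:])))
    return sets
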