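"""Hypergeometric over-representation analysis (ORA) of CNVR gene lists.

For a universe of N genes of which K belong to a term, and a query of n
genes of which k belong to the term, the enrichment p-value is the upper
tail P[X >= k] for X ~ Hypergeometric(N, K, n).  Benjamini–Hochberg
adjusted p-values are always emitted; the significance flag follows the
raw p < alpha rule by default, with BH available as the stricter option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSet


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), the ORA tail probability.

    Equals sum_{j=k..min(K,n)} C(K,j) C(N-K, n-j) / C(N,n); computed via
    the survival function, which works in log space for large arguments.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    significant: bool


def run_ora(
    query_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
    adjust: str = "none",
) -> tuple[list[EnrichmentRow], int]:
    """Test each gene set for over-representation in the query.

    Duplicate symbols collapse; query genes outside the universe are
    dropped and their count returned.  One row is produced per gene set
    with at least one member in the universe, sorted by ascending
    p-value then term_id.  With ``adjust="none"`` the significance flag
    uses raw p < alpha; with ``"BH"`` it uses the Benjamini–Hochberg
    adjusted p (adjusted values are emitted either way).
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query = set(query_genes)
    n_dropped = len(query - universe_set)
    query &= universe_set

    N = len(universe_set)
    n = len(query)
    tested = []
    for gs in gene_sets:
        members = gs.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        tested.append((gs, k, K))
    if not tested:
        return [], n_dropped

    p_values = [hypergeom_tail(k, K, n, N) for _, k, K in tested]
    p_adj = multipletests(p_values, method="fdr_bh")[1] if len(p_values) else []

    rows = [
        EnrichmentRow(
            term_id=gs.term_id,
            term_name=gs.term_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            p_adjusted=float(pa),
            significant=(p < alpha) if adjust == "none" else (float(pa) < alpha),
        )
        for (gs, k, K), p, pa in zip(tested, p_values, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows, n_dropped


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp_value\tp_adjusted\tsignificant\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\t{int(r.significant)}\n"
            )
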