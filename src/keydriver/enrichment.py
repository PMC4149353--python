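"""Hypergeometric over-representation analysis of a gene list.

For a query list of size R drawn from a universe of N genes, the
probability that its overlap with an n-gene set reaches r or more by
chance is the upper hypergeometric tail

    p = sum_{i=r}^{min(n,R)} C(R, i) C(N-R, n-i) / C(N, n).

Only over-representation is tested (depletion is out of scope). The
universe defaults to the total gene content of the collection; all
counts (r, n, R) are taken after restriction to the universe.
Benjamini-Hochberg FDR is applied across all sets of a collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: Default raw-p significance gate for "enriched" calls.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    r: int  # overlap of query and set, within universe
    n: int  # set size within universe
    R: int  # query size within universe
    N: int  # universe size
    p_value: float
    fdr: float


def hypergeom_tail(r: int, n: int, R: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    ``r``: observed overlap; ``n``: set size; ``R``: query-list size;
    ``N``: universe size. Computed via the survival function in
    log-space-stable scipy routines; exact to double precision for the
    problem sizes this pipeline meets.
    """
    for name, v in (("r", r), ("n", n), ("R", R), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if r > min(n, R):
        raise ValueError(f"r={r} exceeds min(n={n}, R={R})")
    if max(n, R) > N:
        raise ValueError(f"max(n={n}, R={R}) exceeds N={N}")
    if r == 0:
        return 1.0
    return float(stats.hypergeom.sf(r - 1, N, R, n))


def enrich(query: Iterable[str],
           collection: GeneSetCollection,
           universe: Iterable[str] | None = None) -> list[EnrichmentResult]:
    """Test a query gene list against every set of a collection.

    Query genes outside the universe are dropped (with a logged count);
    set sizes are likewise computed within the universe. Results carry
    BH-adjusted FDR across the whole collection and are sorted by
    (p-value, set name) ascending.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("empty universe")
    q_all = set(query)
    q = q_all & uni
    dropped = len(q_all) - len(q)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    N, R = len(uni), len(q)

    names, ps, rs, ns = [], [], [], []
    for gs in collection:
        members = gs.members & uni
        n = len(members)
        r = len(q & members)
        names.append(gs.name)
        rs.append(r)
        ns.append(n)
        ps.append(hypergeom_tail(r, n, R, N))
    if not names:
        return []
    fdrs = multipletests(ps, method="fdr_bh")[1]
    results = [EnrichmentResult(name, r, n, R, N, float(p), float(f))
               for name, r, n, p, f in zip(names, rs, ns, ps, fdrs)]
    results.sort(key=lambda e: (e.p_value, e.set_name))
    return results


def enriched_set_names(results: Iterable[EnrichmentResult],
                       alpha: float = DEFAULT_ALPHA,
                       on: str = "p") -> list[str]:
    """Names of sets called enriched; ``on`` selects the significance
    column (``"p"`` raw p-values, the apparent usage of the method's
    reported significance values, or ``"fdr"``)."""
    if on not in ("p", "fdr"):
        raise ValueError("on must be 'p' or 'fdr'")
    key = (lambda e: e.p_value) if on == "p" else (lambda e: e.fdr)
    return [e.set_name for e in results if key(e) <= alpha]


def genes_on_enriched_sets(results: Iterable[EnrichmentResult],
                           collection: GeneSetCollection,
                           alpha: float = DEFAULT_ALPHA,
                           on: str = "p") -> frozenset[str]:
    """Union of member genes of all enriched sets (evidence criterion
    'the gene is present on an enriched map/network')."""
    out: set[str] = set()
    for name in enriched_set_names(results, alpha, on):
        out |= collection[name].members
    return frozenset(out)
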