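"""Gene-set enrichment (Fisher/hypergeometric) and gene-list overlap tests.

Enrichment of a query gene list against a GMT collection is tested with
the one-sided hypergeometric upper tail — identical to the one-sided
Fisher exact test on the 2x2 table — against a background universe (for
exon-array studies, all genes represented on the platform).  Overlaps
between two gene lists (e.g. this study's differentially spliced genes
vs. an external study's list) are tested the same way, with the percent
overlap reported relative to the external reference list and truncated
to an integer percent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .differential import bh_adjust

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into an ordered mapping set_name -> member set.

    Each line is tab-separated: name, description, members...; duplicate
    members within a set are deduplicated, duplicate set names are an
    error.  Identifier case is preserved.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: malformed GMT line {lineno} (<3 fields)")
            name = fields[0]
            if name in collection:
                raise DataError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise DataError(f"{path}: set {name!r} at line {lineno} has no members")
            collection[name] = members
    return collection


def _restrict(genes, universe: set[str], what: str):
    genes = set(genes)
    kept = genes & universe
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("%s: dropped %d gene(s) outside the universe", what, dropped)
    return kept


def fisher_enrichment(query_genes, collection: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query list in each set.

    For a universe of N genes containing K set members, a query of n
    genes with k overlapping: p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Sets disjoint from the universe are excluded; q is BH over tested
    sets.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    query = _restrict(query_genes, universe, "query")
    if not query:
        raise DataError("query list is empty after intersection with the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def overlap_test(list_a, list_b, universe) -> dict:
    """Hypergeometric overlap test between two gene lists.

    ``list_b`` is the external/benchmark reference list: percent overlap
    is |A ∩ B| / |B| * 100, truncated to an integer percent.  Both lists
    are intersected with the universe first; p is the hypergeometric
    upper tail of drawing |A| genes from the universe and hitting the
    reference at least |A ∩ B| times.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    a = _restrict(list_a, universe, "list_a")
    b = _restrict(list_b, universe, "list_b")
    if not b:
        raise DataError("reference list is empty after intersection with the universe")
    k = len(a & b)
    N, K, n = len(universe), len(b), len(a)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {
        "overlap": k,
        "n_query": n,
        "n_reference": K,
        "n_universe": N,
        "percent_overlap": int(np.floor(100.0 * k / K)),
        "p": min(p, 1.0),
    }
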