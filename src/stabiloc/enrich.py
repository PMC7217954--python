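"""Gene-set over-representation of stability regulons.

The query (e.g. all transcripts stabilized by the RNA-binding protein) is
tested against each gene set of a GMT collection with the one-sided
hypergeometric upper-tail probability P(X >= k) — the one-sided Fisher exact
test for over-representation — conditioned on a background universe (by
default the transcripts that survived the stability filter cascade).
P-values are Benjamini-Hochberg adjusted across the collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line as name, description, members.

    Duplicate members within a line are collapsed (first occurrence order
    kept); a duplicate set name or a line with fewer than three fields is an
    error. An empty file yields an empty collection.
    """
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = fields[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            collection[name] = list(dict.fromkeys(fields[2:]))
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    """Overlap counts and hypergeometric tail for one gene set."""

    set_name: str
    universe_size: int
    query_size: int
    set_size: int  # after intersection with the universe
    overlap: int
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def overlap_test(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str],
    set_name: str = "",
) -> EnrichmentRow:
    """Exact one-sided over-representation test.

    With universe size N, query size n, set size K (the gene set intersected
    with the universe) and overlap k, the p-value is the exact hypergeometric
    upper tail P(X >= k).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query:
        raise ValueError("query is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    members = set(gene_set) & universe
    k = len(query & members)
    n_u, n_q, n_s = len(universe), len(query), len(members)
    # sf(k-1) = P(X >= k); exact, never approximated
    p = float(stats.hypergeom.sf(k - 1, n_u, n_s, n_q))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentRow(
        set_name=set_name,
        universe_size=n_u,
        query_size=n_q,
        set_size=n_s,
        overlap=k,
        p_value=p,
    )


def enrich_collection(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every set of a collection and BH-adjust across the collection.

    Returns a table sorted by raw p ascending with columns: set_name,
    universe_size, query_size, set_size, overlap, p_value, p_adjusted,
    neg_log10_p, significant (adjusted p <= alpha).
    """
    universe = set(universe)
    query = set(query)
    rows = [
        overlap_test(query, members, universe, set_name=name)
        for name, members in collection.items()
    ]
    df = pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "universe_size": r.universe_size,
                "query_size": r.query_size,
                "set_size": r.set_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "neg_log10_p": r.neg_log10_p,
            }
            for r in rows
        ]
    )
    if df.empty:
        df["p_adjusted"] = []
        df["significant"] = []
        return df
    _, p_adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["significant"] = df["p_adjusted"] <= alpha
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return df[
        [
            "set_name",
            "universe_size",
            "query_size",
            "set_size",
            "overlap",
            "p_value",
            "p_adjusted",
            "neg_log10_p",
            "significant",
        ]
    ]
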