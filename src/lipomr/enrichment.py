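"""Gene-set over-representation analysis and set-overlap testing.

MR-significant genes are tested against GMT pathway libraries with a
one-sided Fisher's exact (hypergeometric tail) test over a fixed expressed
background, with Benjamini-Hochberg FDR applied jointly across all sets of
all libraries.  The replication-overlap test is the same hypergeometric
upper tail applied to two gene lists drawn from a common universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import bh_fdr

__all__ = [
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "overlap_test",
]


@dataclass
class EnrichmentResult:
    set_name: str
    library: str
    hits: int
    query_only: int
    set_only: int
    neither: int
    odds_ratio: float
    p: float
    p_fdr: float | None = None


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: set of upper-cased gene symbols}.

    Each line is name, description, then genes, tab separated; duplicate
    genes are dropped and malformed lines skipped with a warning.
    """
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}: skipping malformed GMT line {i}", stacklevel=2)
                continue
            name = parts[0]
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def _one_sided_p(hits, query_n, set_n, background_n):
    # P(X >= hits) for X ~ Hypergeom(background, set_n, query_n)
    return float(stats.hypergeom.sf(hits - 1, background_n, set_n, query_n))


def fisher_enrichment(query, libraries: dict, background) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against every set.

    ``libraries`` maps library name -> {set name -> gene set}.  Query and
    sets are intersected with the background (case-insensitive symbols)
    before building each 2x2 table; BH adjustment is applied jointly over
    all sets of all libraries.  The odds ratio uses a Haldane 0.5 continuity
    correction for display only; p-values are exact tails.
    """
    background = {g.upper() for g in background}
    if not background:
        raise ValueError("empty background")
    query = {g.upper() for g in query} & background
    rows = []
    N = len(background)
    for lib_name, sets in libraries.items():
        for set_name, genes in sets.items():
            s = {g.upper() for g in genes} & background
            hits = len(query & s)
            q_only = len(query) - hits
            s_only = len(s) - hits
            neither = N - hits - q_only - s_only
            p = _one_sided_p(hits, len(query), len(s), N)
            orx = ((hits + 0.5) * (neither + 0.5)) / ((q_only + 0.5) * (s_only + 0.5))
            rows.append(EnrichmentResult(
                set_name=set_name, library=lib_name, hits=hits,
                query_only=q_only, set_only=s_only, neither=neither,
                odds_ratio=orx, p=p,
            ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["p_fdr"], _ = bh_fdr(df["p"].clip(lower=np.nextafter(0, 1)))
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def overlap_test(k: int, n1: int, n2: int, background_size: int) -> float:
    """Upper-tail hypergeometric p for observing >= k genes shared between
    a set of n1 and a set of n2 drawn from a common universe."""
    if k > min(n1, n2) or n1 > background_size or n2 > background_size or k < 0:
        raise ValueError("inconsistent overlap counts")
    return float(stats.hypergeom.sf(k - 1, background_size, n1, n2))
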