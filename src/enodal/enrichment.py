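"""Stage 3b: over-representation analysis of subclusters against gene sets.

One-sided hypergeometric tail test of the overlap between a subcluster
and each gene set, within a background universe (by default all features
retained in the omics matrix). Benjamini-Hochberg adjustment across the
sets tested for a subcluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection


@dataclass
class EnrichmentRow:
    subcluster_id: str
    set_name: str
    overlap: int
    subcluster_size: int
    set_size: int
    background_size: int
    p: float
    q: float
    overlap_members: tuple[str, ...]


def ora(
    subcluster_members: list[str],
    collection: GeneSetCollection,
    background: set[str] | frozenset[str],
    subcluster_id: str = "",
    adjust: str = "bh",
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each gene set in one subcluster.

    Gene sets are intersected with the background before testing; sets with
    no background overlap are skipped. p = P[X >= overlap] under sampling
    |subcluster| features from the background without replacement. Rows are
    returned sorted by ascending p.
    """
    background = frozenset(background)
    if not background:
        raise ValueError("empty background universe")
    members = frozenset(subcluster_members) & background
    if frozenset(subcluster_members) - background:
        raise ValueError("subcluster contains features outside the background universe")
    N = len(background)
    n_draw = len(members)

    rows: list[EnrichmentRow] = []
    for name in sorted(collection.sets):
        gs = collection.sets[name] & background
        K = len(gs)
        if K == 0:
            continue
        overlap = members & gs
        x = len(overlap)
        p = float(hypergeom.sf(x - 1, N, K, n_draw))
        rows.append(
            EnrichmentRow(subcluster_id, name, x, n_draw, K, N, min(p, 1.0), np.nan,
                          tuple(sorted(overlap)))
        )
    if rows:
        pvals = np.array([r.p for r in rows])
        if adjust == "bh":
            q = multipletests(pvals, method="fdr_bh")[1]
        elif adjust == "bonferroni":
            q = np.minimum(pvals * len(pvals), 1.0)
        else:
            raise ValueError(f"unknown adjustment '{adjust}'")
        for r, qv in zip(rows, q):
            r.q = float(qv)
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.subcluster_id, r.set_name, r.overlap, r.subcluster_size, r.set_size,
             r.background_size, r.p, r.q, ",".join(r.overlap_members))
            for r in rows
        ],
        columns=["subcluster", "set", "overlap", "subcluster_size", "set_size",
                 "background_size", "p", "q", "overlap_members"],
    )
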