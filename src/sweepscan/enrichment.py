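"""Hypergeometric over-representation of candidate genes in pathways.

Each pathway is tested with the upper-tail hypergeometric probability
P(X >= k) for drawing k pathway genes in a candidate set of size n from a
background of N genes of which K are in the pathway. Multiple testing is
controlled by Benjamini–Hochberg; a pathway is significant at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

Q_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    significant: bool


def hypergeom_enrich(candidates: set[str], pathways: dict[str, set[str]],
                     background: set[str], q_cutoff: float = Q_CUTOFF) -> list[EnrichmentRow]:
    """Over-representation rows for every pathway, sorted by (q, p, id).

    ``candidates`` must be a subset of ``background``; pathway gene sets are
    intersected with the background first. An empty candidate set yields no
    rows.
    """
    extra = candidates - background
    if extra:
        raise ValueError(f"{len(extra)} candidate genes missing from background")
    if not candidates:
        return []
    N = len(background)
    n = len(candidates)
    ids, ps, ks, Ks = [], [], [], []
    for pw in sorted(pathways):
        members = pathways[pw] & background
        if not members:
            continue
        K = len(members)
        k = len(candidates & members)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        ids.append(pw)
        ps.append(min(1.0, p))
        ks.append(k)
        Ks.append(K)
    if not ids:
        return []
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    rows = [EnrichmentRow(pw, k, K, n, N, p, float(q), bool(q < q_cutoff))
            for pw, k, K, p, q in zip(ids, ks, Ks, ps, qs)]
    rows.sort(key=lambda r: (r.q, r.p, r.pathway_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["pathway_id", "k", "K", "n", "N", "p", "q", "significant"])


def write_enrichment(rows: list[EnrichmentRow], path) -> None:
    df = enrichment_table(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
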