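"""Redundant siRNA activity (RSA) gene scoring.

A gene is represented by several independent siRNAs; a real on-target
phenotype should move *several* of them up the screen-wide ranking, whereas
an off-target artifact typically moves one. RSA turns this redundancy into
a gene-level significance: with N ranked siRNAs overall and k for the gene
at screen ranks r_1 < r_2 < ... < r_k, the score is

    p_min = min_{j=1..k}  P(X_j >= j),   X_j ~ Hypergeom(N, r_j, k)

i.e. for each candidate cutoff r_j, the probability that a gene whose k
siRNAs were placed uniformly at random would land at least j of them within
the top r_j ranks. The minimizing j defines the cutoff rank; the gene's
siRNAs at or above it are its "OPI hits". Genes supported by fewer than two
OPI hits are discarded as probable single-siRNA (off-target) signals.
Genes are reported ranked by log10(p_min); no multiple-testing correction
is applied because the list is a ranking, not a thresholded discovery set.

The tail probability is an exact hypergeometric survival sum (scipy), not a
normal approximation — screen sizes make exactness cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class GeneScore:
    """RSA output for one gene."""

    gene_id: str
    k: int
    ranks: tuple[int, ...]
    p_min: float
    log_p: float
    cutoff_rank: int
    opi_hit_count: int
    excluded_low_support: bool


def rank_sirnas(scores: pd.DataFrame, score_col: str = "median_z") -> pd.DataFrame:
    """Assign screen-wide integer ranks; rank 1 = strongest inhibition.

    Ties receive the worst (maximal) rank of the tied block, which is the
    conservative resolution for RSA (an arbitrary within-tie order would
    deflate p_min). siRNAs with missing scores are not ranked; they are
    placed after all ranked siRNAs with ``rank = NaN`` and do not count
    toward N.
    """
    out = scores.copy()
    finite = out[score_col].notna() & np.isfinite(out[score_col].astype(float))
    ranks = out.loc[finite, score_col].rank(ascending=False, method="max")
    out["rank"] = np.nan
    out.loc[finite, "rank"] = ranks
    return out.sort_values(
        ["rank", "sirna_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def gene_logp(
    ranks: "list[int] | tuple[int, ...]",
    n_total: int,
    gene_id: str = "",
    hit_rank_bound: int | None = None,
) -> GeneScore:
    """Minimal hypergeometric tail over cutoffs for one gene's siRNA ranks.

    ``ranks`` are the gene's screen ranks (distinct after tie resolution,
    each in 1..n_total). On ties in the tail probability the smallest j
    wins, making the OPI-hit count conservative.

    ``hit_rank_bound`` optionally restricts the cutoff search to the screen's
    hit zone: only cutoffs at siRNAs ranked within the bound are eligible
    (the "hit-siRNAs"). A strong single siRNA backed only by siRNAs deep in
    the null bulk then cannot borrow support from chance mid-ranking
    placements — the behaviour the <2-OPI-hit off-target filter relies on.
    When no siRNA of the gene lies within the bound, the gene is scored at
    j = 1 but its OPI-hit count is 0. With the default ``None`` every cutoff
    is eligible.
    """
    k = len(ranks)
    if k == 0:
        raise ValueError("gene has no ranked siRNAs")
    rs = sorted(int(r) for r in ranks)
    if len(set(rs)) != k:
        raise ValueError(f"duplicate ranks for gene {gene_id!r}: {rs}")
    if rs[0] < 1 or rs[-1] > n_total:
        raise ValueError(f"ranks out of range 1..{n_total}: {rs}")

    if hit_rank_bound is None:
        eligible = list(range(1, k + 1))
        n_in_zone = k
    else:
        n_in_zone = sum(r <= hit_rank_bound for r in rs)
        eligible = list(range(1, n_in_zone + 1)) or [1]

    p_min = math.inf
    best_j = 0
    for j in eligible:
        r_j = rs[j - 1]
        # P(X >= j) with X ~ Hypergeom(N=n_total, K=r_j "top" items, n=k draws)
        p_j = float(hypergeom.sf(j - 1, n_total, r_j, k))
        if p_j < p_min - 1e-15:
            p_min = p_j
            best_j = j
    p_min = min(p_min, 1.0)
    opi = best_j if n_in_zone >= 1 else 0
    return GeneScore(
        gene_id=gene_id,
        k=k,
        ranks=tuple(rs),
        p_min=p_min,
        log_p=math.log10(p_min),
        cutoff_rank=rs[best_j - 1],
        opi_hit_count=opi,
        excluded_low_support=opi < 2,
    )


def score_genes(
    ranked: pd.DataFrame, hit_rank_bound: int | None = None
) -> pd.DataFrame:
    """RSA-score every gene in a ranked siRNA table.

    ``ranked`` must carry ``gene_id``, ``sirna_id`` and the ``rank`` column
    produced by :func:`rank_sirnas`. siRNAs without a rank are ignored;
    genes with no ranked siRNA are omitted. ``hit_rank_bound`` is passed
    through to :func:`gene_logp` (cutoff search restricted to the screen's
    hit zone).
    """
    with_rank = ranked[ranked["rank"].notna()]
    n_total = int(with_rank["rank"].max()) if len(with_rank) else 0
    rows = []
    for gene_id, grp in with_rank.groupby("gene_id", sort=True):
        # worst-of-block tie ranks can repeat across siRNAs of one gene;
        # de-duplicate by perturbing is wrong — instead break residual ties
        # deterministically by sirna_id before ranking (rank_sirnas uses
        # method="max" so duplicates only arise from exactly tied scores).
        ranks = grp["rank"].astype(int).tolist()
        if len(set(ranks)) != len(ranks):
            ranks = _resolve_tied_ranks(with_rank, grp)
        gs = gene_logp(
            ranks, n_total, gene_id=str(gene_id), hit_rank_bound=hit_rank_bound
        )
        rows.append(
            {
                "gene_id": gs.gene_id,
                "k": gs.k,
                "ranks": ";".join(str(r) for r in gs.ranks),
                "best_rank": gs.ranks[0],
                "p_min": gs.p_min,
                "log_p": gs.log_p,
                "cutoff_rank": gs.cutoff_rank,
                "opi_hit_count": gs.opi_hit_count,
                "excluded_low_support": gs.excluded_low_support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "k",
            "ranks",
            "best_rank",
            "p_min",
            "log_p",
            "cutoff_rank",
            "opi_hit_count",
            "excluded_low_support",
        ],
    )


def _resolve_tied_ranks(universe: pd.DataFrame, grp: pd.DataFrame) -> list[int]:
    """Spread exactly-tied siRNAs of one gene over their tie block.

    Worst-of-block ranking gives identical integers to exactly tied scores;
    RSA needs distinct ranks. Within a tied block the order is arbitrary, so
    assign the gene's tied members the *worst* positions of the block
    (conservative) in deterministic sirna_id order.
    """
    resolved: list[int] = []
    for rank_val, members in grp.groupby("rank"):
        block = int(rank_val)
        n_here = len(members)
        # worst positions of the tie block: block, block-1, ...
        resolved.extend(block - i for i in range(n_here))
    if len(set(resolved)) != len(resolved):  # pragma: no cover - defensive
        raise ValueError("could not resolve tied ranks to distinct integers")
    return sorted(resolved)


def hit_rank_bound_from_scores(
    ranked: pd.DataFrame,
    ctrl_median: float,
    ctrl_sd: float,
    sd_margin: float = 2.0,
    score_col: str = "median_z",
) -> int:
    """Worst rank still inside the screen's hit zone.

    The hit zone contains siRNAs whose oriented score exceeds the
    non-targeting-control median by more than ``sd_margin`` control SDs —
    the same SD-margin construction the downstream triage rules use.
    Returns 0 when no siRNA qualifies.
    """
    hits = ranked[
        ranked["rank"].notna()
        & (ranked[score_col] > ctrl_median + sd_margin * ctrl_sd)
    ]
    return int(hits["rank"].max()) if len(hits) else 0


def filter_low_support(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Hit list after removing genes with fewer than two OPI hits.

    The full table (with the ``excluded_low_support`` flag) is what
    :func:`score_genes` returns; this view drops the flagged genes, i.e.
    those whose RSA optimum is explained by a single siRNA.
    """
    return gene_scores[~gene_scores["excluded_low_support"]].reset_index(drop=True)


def rank_genes(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Order genes by ascending log10 p (most significant first).

    Ties broken by smaller best siRNA rank, then lexicographic gene_id.
    """
    if gene_scores.empty:
        return gene_scores.copy()
    return gene_scores.sort_values(
        ["log_p", "best_rank", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
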