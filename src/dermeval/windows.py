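"""Positional enrichment along fold-change-ranked gene lists.

Two related procedures:

* *sliding-window enrichment*: genes are ranked by their IMQ response
  (log2FC, descending) and every window of ``w`` consecutive genes is
  tested for overrepresentation of a target set (e.g., genes elevated
  in suprabasal versus basal epidermis) by the hypergeometric upper
  tail against the full ranked universe. Paired target sets (increased
  / decreased) are both tested per window and the window labelled by
  whichever is more enriched.

* *cumulative overlap*: the running intersection size between a fixed
  top list (e.g., the 100 most IMQ-repressed genes) and the prefix of
  a reference ranking (genes ordered by suprabasal-vs-basal
  expression), summarized by the maximum departure above the
  chance diagonal with a permutation p-value.

Both are rank statistics, hence invariant under monotone transforms of
the fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneSet
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


def rank_genes(fc: pd.Series, pvalues: pd.Series | None = None) -> pd.Index:
    """Rank genes by log2FC descending; ties by smaller p, then symbol."""
    df = pd.DataFrame({"fc": fc})
    df["p"] = pvalues.reindex(fc.index) if pvalues is not None else 1.0
    df = df.dropna(subset=["fc"])
    df = df.sort_index().sort_values(["fc", "p"],
                                     ascending=[False, True], kind="mergesort")
    return df.index


@dataclass
class WindowEnrichmentTrack:
    """Per-window enrichment results along one ranked gene list.

    ``table`` columns: start_rank (1-based), one ``overlap_<set>`` and
    ``pvalue_<set>`` column per target set, ``direction`` (set with the
    smaller p), ``pvalue`` (that smaller p) and ``fdr`` (BH across
    windows of the winning p-values, a summary for thresholding; the
    per-set p-value tracks are reported unadjusted for plotting).
    """

    table: pd.DataFrame
    window: int
    step: int
    ranking: pd.Index = field(repr=False, default=None)
    set_ids: tuple[str, ...] = ()


def sliding_enrichment(
    fc: pd.Series,
    target_sets: list[GeneSet] | GeneSet,
    w: int = 100,
    s: int = 1,
    pvalues: pd.Series | None = None,
) -> WindowEnrichmentTrack:
    """Hypergeometric enrichment of target sets in ranked windows.

    ``fc`` maps gene symbols (already in the target sets' namespace) to
    log2 fold changes. Windows of size ``w`` start at ranks
    1, 1+s, ... while they fit. For each window and set, the p-value is
    P(X >= overlap) with X hypergeometric(N = ranked genes, K = set
    members among them, n = w).
    """
    if isinstance(target_sets, GeneSet):
        target_sets = [target_sets]
    if not target_sets:
        raise ValueError("need at least one target set")
    ranking = rank_genes(fc, pvalues)
    n = len(ranking)
    if n < w:
        raise ValueError(f"ranked list ({n}) shorter than the window ({w})")
    membership = {}
    for gs in target_sets:
        members = set(gs.members) & set(ranking)
        if not members and len(gs.members) > 0:
            raise ValueError(
                f"set {gs.set_id!r} shares no genes with the ranked list"
            )
        membership[gs.set_id] = np.isin(ranking.to_numpy(), list(members))

    starts = np.arange(0, n - w + 1, s)
    out = pd.DataFrame({"start_rank": starts + 1})
    pcols = {}
    for set_id, ind in membership.items():
        csum = np.concatenate([[0], np.cumsum(ind)])
        overlap = csum[starts + w] - csum[starts]
        K = int(ind.sum())
        pv = stats.hypergeom.sf(overlap - 1, n, K, w)
        out[f"overlap_{set_id}"] = overlap
        out[f"pvalue_{set_id}"] = pv
        pcols[set_id] = pv
    pmat = np.column_stack([pcols[sid] for sid in membership])
    best = np.argmin(pmat, axis=1)
    ids = list(membership)
    out["direction"] = [ids[j] for j in best]
    out["pvalue"] = pmat[np.arange(len(starts)), best]
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return WindowEnrichmentTrack(table=out, window=w, step=s,
                                 ranking=ranking, set_ids=tuple(ids))


@dataclass
class CumulativeOverlapResult:
    """Running-overlap curve with a permutation enrichment summary."""

    curve: np.ndarray          # value at position i (1-based prefix)
    expected: np.ndarray       # chance diagonal i * k / n
    max_departure: float       # max_i (curve_i - expected_i)
    pvalue: float              # permutation p for the departure
    n_permutations: int


def cumulative_overlap(
    top_set: set[str] | GeneSet,
    reference_ranking,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CumulativeOverlapResult:
    """Running overlap of a gene set along a reference ranking.

    curve[i] = |top_set n ranking[:i+1]|. The enrichment summary is the
    maximum signed departure above the chance line i*k/n, with a
    permutation p-value obtained by redrawing the set's positions
    uniformly along the ranking.
    """
    if isinstance(top_set, GeneSet):
        top_set = set(top_set.members)
    ranking = list(reference_ranking)
    n = len(ranking)
    if n == 0:
        raise ValueError("empty reference ranking")
    ind = np.isin(np.asarray(ranking, dtype=object), list(top_set))
    k = int(ind.sum())
    if k == 0 and top_set:
        logger.warning("cumulative_overlap: top set and ranking are disjoint")
    curve = np.cumsum(ind)
    expected = np.arange(1, n + 1) * k / n
    observed = float(np.max(curve - expected)) if n else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, k, replace=False)] = True
        d = float(np.max(np.cumsum(perm) - expected))
        if d >= observed:
            exceed += 1
    pval = (exceed + 1) / (n_permutations + 1)
    return CumulativeOverlapResult(curve=curve, expected=expected,
                                   max_departure=observed, pvalue=pval,
                                   n_permutations=n_permutations)
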