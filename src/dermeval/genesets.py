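"""Gene-set statistics on IMQ responses.

Covers the derivation of cell-type signature genes from a sorted-cell
expression compendium (Wilcoxon specificity against all other
populations, top-k selection), the signature *shift test* (rank-sum of
set members' fold changes against the detected background, flagging
coordinated movement of, say, a T-cell signature in IMQ-treated skin),
hypergeometric overrepresentation analysis for GO-style term
enrichment, representative homolog panels for enriched terms, and
summaries of cytokine-induced gene sets across strain-sex groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionSignature, GeneSet, HomologyMap, map_orthologs
from .diffexpr import DEResult, bh_adjust

logger = logging.getLogger(__name__)

EXACT_MAX_N = 50  # per side; larger groups use the normal approximation


def ranksum_p(x, y, alternative: str = "greater") -> float:
    """Wilcoxon rank-sum p-value with the conventions used throughout.

    Mid-ranks for ties; exact null enumeration when both sides have at
    most 50 observations and no ties occur, otherwise the normal
    approximation with continuity correction. The fully degenerate
    all-tied case returns 0.5 one-sided / 1.0 two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0 if alternative == "two-sided" else 0.5
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and max(x.size, y.size) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Cell-type signatures
# ---------------------------------------------------------------------------


def specificity_pvalues(expr: pd.DataFrame, labels: pd.Series,
                        target_type: str) -> pd.Series:
    """Per-gene one-sided rank-sum p for target-specific expression.

    Tests, for every gene, whether expression in the target cell type's
    samples exceeds expression in all other samples pooled.
    """
    labels = labels.reindex(expr.columns)
    in_target = (labels == target_type).to_numpy()
    if in_target.sum() < 1:
        raise ValueError(f"cell type {target_type!r} not present")
    if (~in_target).sum() < 2:
        raise ValueError("need at least 2 samples outside the target type")
    vals = expr.to_numpy(dtype=float)
    out = np.empty(len(expr))
    for i in range(vals.shape[0]):
        out[i] = ranksum_p(vals[i, in_target], vals[i, ~in_target], "greater")
    return pd.Series(out, index=expr.index, name=f"specificity_p_{target_type}")


def derive_celltype_signatures(expr: pd.DataFrame, labels: pd.Series,
                               k: int = 100) -> list[GeneSet]:
    """Top-k most type-specific genes per cell population.

    Genes are ranked by Wilcoxon specificity p (target versus all other
    populations), ties broken by larger mean log-expression difference,
    then gene symbol.
    """
    if k > len(expr):
        raise ValueError(f"k = {k} exceeds the {len(expr)}-gene universe")
    labels = labels.reindex(expr.columns)
    sets: list[GeneSet] = []
    for t in pd.unique(labels):
        p = specificity_pvalues(expr, labels, t)
        in_t = (labels == t).to_numpy()
        diff = (expr.to_numpy()[:, in_t].mean(axis=1)
                - expr.to_numpy()[:, ~in_t].mean(axis=1))
        ranking = pd.DataFrame({"p": p, "neg_diff": -diff},
                               index=expr.index).sort_values(
            ["p", "neg_diff"], kind="mergesort"
        )
        # mergesort is stable, so equal (p, diff) fall back to input
        # order; sort the index first for a symbol tie-break
        ranking = ranking.loc[ranking.index.sort_values()].sort_values(
            ["p", "neg_diff"], kind="mergesort")
        members = tuple(ranking.index[:k])
        sets.append(GeneSet(str(t), f"top-{k} {t}-specific genes", members,
                            namespace="mouse"))
    return sets


# ---------------------------------------------------------------------------
# Signature shift test
# ---------------------------------------------------------------------------


@dataclass
class ShiftTestResult:
    """Rank-sum shift tests of gene sets against the detected background.

    ``table`` rows: (set_id, group, n_members, mean_log2fc, pvalue,
    fdr, direction) with direction in {increased, decreased, ns}.
    """

    table: pd.DataFrame
    fdr_threshold: float = 0.05


def shift_test(
    fc_tables: dict[str, pd.Series],
    sets: list[GeneSet],
    min_overlap: int = 5,
    fdr_threshold: float = 0.05,
) -> ShiftTestResult:
    """Test each gene set for a coordinated fold-change shift.

    ``fc_tables`` maps group labels (strain-sex) to log2FC Series over
    the detected genes of that group. Members are compared to all
    detected non-members by a two-sided rank-sum test; BH adjustment
    spans all (set, group) pairs; direction is the sign of the mean
    member log2FC where the FDR clears ``fdr_threshold``, else ``ns``.
    """
    rows = []
    for group, fc in fc_tables.items():
        fc = fc.dropna()
        measured = set(fc.index)
        for gs in sets:
            members = [g for g in gs.members if g in measured]
            if len(members) < min_overlap:
                logger.warning("shift_test: set %s has %d measured genes in "
                               "%s; skipped", gs.set_id, len(members), group)
                continue
            member_fc = fc[members].to_numpy()
            bg = fc.drop(members).to_numpy()
            if bg.size == 0:
                logger.warning("shift_test: set %s covers the whole "
                               "background in %s; skipped", gs.set_id, group)
                continue
            p = ranksum_p(member_fc, bg, "two-sided")
            rows.append({"set_id": gs.set_id, "group": group,
                         "n_members": len(members),
                         "mean_log2fc": float(member_fc.mean()),
                         "pvalue": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
        sig = table["fdr"] < fdr_threshold
        table["direction"] = np.where(
            ~sig, "ns", np.where(table["mean_log2fc"] > 0, "increased",
                                 "decreased"))
    else:
        table = pd.DataFrame(columns=["set_id", "group", "n_members",
                                      "mean_log2fc", "pvalue", "fdr",
                                      "direction"])
    return ShiftTestResult(table=table, fdr_threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# Overrepresentation analysis
# ---------------------------------------------------------------------------


def ora(query: GeneSet | set[str], terms: list[GeneSet],
        universe: GeneSet | set[str]) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query set in each term.

    p = P(X >= overlap) for X hypergeometric(N = |universe|,
    K = |term n universe|, n = |query|); BH across terms.
    """
    uni = set(universe.members) if isinstance(universe, GeneSet) else set(universe)
    q = set(query.members) if isinstance(query, GeneSet) else set(query)
    stray = q - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    rows = []
    for term in terms:
        t = set(term.members) & uni
        k = len(t & q)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(t), len(q)))
        rows.append({"term_id": term.set_id, "description": term.description,
                     "n_term": len(t), "n_overlap": k, "pvalue": p,
                     "overlap_genes": ",".join(sorted(t & q))})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def representative_panel(
    terms: list[GeneSet],
    human_signature: ExpressionSignature,
    hmap: HomologyMap,
    fc_tables: dict[str, pd.Series] | None = None,
    k: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per term, the k signature-increased human genes with smallest p.

    Genes must be mappable to mouse homologs; if ``fc_tables`` is given
    the panel carries each homolog's log2FC per strain-sex group.
    Returns {term_id: panel DataFrame indexed by human symbol}.
    """
    sig = human_signature.table
    h2m = hmap.human_to_mouse()
    panels: dict[str, pd.DataFrame] = {}
    for term in terms:
        cand = sig.loc[sig.index.isin(term.members)
                       & (sig["log2fc"] > 0)
                       & sig.index.isin(h2m.index)]
        cand = cand.sort_values(["pvalue", "log2fc"],
                                ascending=[True, False], kind="mergesort")
        if len(cand) < k:
            logger.warning("representative_panel: term %s has only %d "
                           "mappable increased genes (k = %d)",
                           term.set_id, len(cand), k)
        panel = cand.head(k).copy()
        panel["mouse_symbol"] = h2m[panel.index].to_numpy()
        if fc_tables:
            for group, fc in fc_tables.items():
                panel[f"log2fc_{group}"] = fc.reindex(
                    panel["mouse_symbol"]).to_numpy()
        panels[term.set_id] = panel
    return panels


def induced_set_response(
    induced_sets: list[GeneSet],
    de_results: dict[str, DEResult],
    hmap: HomologyMap,
    deg_fc: float = 2.0,
    deg_fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Response of cytokine-induced (human) gene sets across groups.

    Returns (per-set x group mean log2FC of mapped members,
    per-gene count of groups in which its mouse homolog is an
    increased DEG).
    """
    h2m = hmap.human_to_mouse()
    mean_rows = []
    for gs in induced_sets:
        mapped = [h2m[h] for h in gs.members if h in h2m.index]
        for group, de in de_results.items():
            t = de.tested
            present = [m for m in mapped if m in t.index]
            mean_fc = float(t.loc[present, "log2fc"].mean()) if present else np.nan
            mean_rows.append({"set_id": gs.set_id, "group": group,
                              "n_mapped": len(present),
                              "mean_log2fc": mean_fc})
    means = pd.DataFrame(mean_rows)

    union = {h: h2m[h] for gs in induced_sets for h in gs.members
             if h in h2m.index}
    counts = pd.Series(0, index=pd.Index(sorted(union), name="gene"))
    for group, de in de_results.items():
        t = de.tested
        for h, m in union.items():
            if m in t.index:
                row = t.loc[m]
                if np.exp2(row["log2fc"]) > deg_fc and row["fdr"] < deg_fdr:
                    counts[h] += 1
    return means, counts.to_frame("induced_in")
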