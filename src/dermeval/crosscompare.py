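"""Cross-strain and cross-species comparison of IMQ responses.

The centerpiece is the disease *match score*: for one human disease
signature and one mouse strain-sex group, the mean mouse fold change
(IMQ/CTL) over the ``n`` genes most strongly increased in the disease,
averaged with the mean reciprocal mouse fold change (CTL/IMQ) over the
``n`` genes most strongly decreased — a score of 1 (ratio scale) means
no correspondence; larger means the mouse phenotype moves the disease's
top genes in the disease's direction. Signatures are homology-joined to
mouse symbols *before* ranking so each direction contributes exactly
``n`` mouse-measurable genes.

Also here: principal-component response vectors (control centroid to
treated centroid per group), Spearman fold-change correlation matrices
across strains, correlation/directional-enrichment concordance with a
psoriasis signature, top-N concordance tables, Venn-region overlap
counts, and concordance summaries over psoriasis-specificity-index
(PSI) gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionSignature, GeneSet, HomologyMap
from .diffexpr import DEResult
from .genesets import ranksum_p

logger = logging.getLogger(__name__)

MATCH_TOP_N = 200


# ---------------------------------------------------------------------------
# PC response vectors
# ---------------------------------------------------------------------------


@dataclass
class ResponseVector:
    """One strain-sex group's treatment displacement in PC space."""

    strain: str
    sex: str
    start: np.ndarray  # CTL centroid, first two PCs
    end: np.ndarray    # IMQ centroid

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        norm = np.linalg.norm(d)
        return d / norm if norm > 0 else d


def pc_scores(expr: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading PCs of gene-centered expression."""
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = (s[:n_components, None] * vt[:n_components]).T
    return pd.DataFrame(scores, index=expr.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def pc_response_vectors(expr: pd.DataFrame, design: pd.DataFrame
                        ) -> list[ResponseVector]:
    """CTL-to-IMQ centroid vectors per strain-sex in the first two PCs.

    ``expr`` is a log-cpm matrix (genes x samples) over all samples;
    the PC basis comes from the full sample set, so vectors are
    comparable across groups. Groups missing a treatment are skipped
    with a warning.
    """
    scores = pc_scores(expr, 2)
    out: list[ResponseVector] = []
    for (strain, sex), grp in design.groupby(["strain", "sex"], sort=False):
        ctl = grp.index[grp["treatment"] == "CTL"]
        imq = grp.index[grp["treatment"] == "IMQ"]
        if len(ctl) == 0 or len(imq) == 0:
            logger.warning("pc_response_vectors: %s/%s lacks a treatment arm; "
                           "skipped", strain, sex)
            continue
        out.append(ResponseVector(
            strain=strain, sex=sex,
            start=scores.loc[ctl].mean(axis=0).to_numpy(),
            end=scores.loc[imq].mean(axis=0).to_numpy(),
        ))
    return out


# ---------------------------------------------------------------------------
# Fold-change correlation matrices
# ---------------------------------------------------------------------------


def fc_correlation_matrix(fc_tables: dict[str, pd.Series],
                          method: str = "spearman",
                          min_genes: int = 10) -> pd.DataFrame:
    """Pairwise correlation of log2FC vectors over shared genes."""
    if len(fc_tables) < 2:
        raise ValueError("need at least 2 fold-change tables")
    names = list(fc_tables)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            fa = fc_tables[a].dropna()
            fb = fc_tables[b].dropna()
            shared = fa.index.intersection(fb.index)
            if len(shared) < min_genes:
                logger.warning("fc_correlation_matrix: %s vs %s share only "
                               "%d genes; undefined", a, b, len(shared))
                r = np.nan
            elif method == "spearman":
                r = stats.spearmanr(fa[shared], fb[shared]).statistic
            elif method == "pearson":
                r = stats.pearsonr(fa[shared], fb[shared]).statistic
            else:
                raise ValueError(f"unknown method {method!r}")
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


# ---------------------------------------------------------------------------
# Psoriasis concordance
# ---------------------------------------------------------------------------


def psoriasis_concordance(
    mouse_de: DEResult,
    signature: ExpressionSignature,
    hmap: HomologyMap,
    sig_fdr: float = 0.05,
) -> dict[str, float]:
    """Fold-change correlation and directional enrichment vs a signature.

    Reports Pearson and Spearman correlations of homolog-joined log2FCs
    plus one-sided rank-sum p-values testing whether mouse fold changes
    of signature-increased (-decreased) genes sit above (below) the
    fold changes of the remaining joined genes.
    """
    m2h = hmap.mouse_to_human()
    mouse = mouse_de.fc_series().dropna()
    joined = pd.DataFrame({
        "mouse_fc": mouse,
        "human": m2h.reindex(mouse.index),
    }).dropna()
    sig = signature.table
    joined = joined[joined["human"].isin(sig.index)]
    if joined.empty:
        raise ValueError("no genes joined between mouse results and signature")
    joined["human_fc"] = sig.loc[joined["human"], "log2fc"].to_numpy()
    joined["human_fdr"] = sig.loc[joined["human"], "fdr"].to_numpy()

    pear = stats.pearsonr(joined["mouse_fc"], joined["human_fc"]).statistic
    spear = stats.spearmanr(joined["mouse_fc"], joined["human_fc"]).statistic

    inc = joined[(joined["human_fc"] > 0) & (joined["human_fdr"] < sig_fdr)]
    dec = joined[(joined["human_fc"] < 0) & (joined["human_fdr"] < sig_fdr)]
    p_inc = p_dec = np.nan
    if len(inc) and len(joined) > len(inc):
        p_inc = ranksum_p(inc["mouse_fc"],
                          joined.drop(inc.index)["mouse_fc"], "greater")
    if len(dec) and len(joined) > len(dec):
        p_dec = ranksum_p(dec["mouse_fc"],
                          joined.drop(dec.index)["mouse_fc"], "less")
    return {"pearson_r": float(pear), "spearman_r": float(spear),
            "p_increased": float(p_inc), "p_decreased": float(p_dec),
            "n_joined": int(len(joined))}


# ---------------------------------------------------------------------------
# Disease match scores
# ---------------------------------------------------------------------------


def _top_signature_genes(joined: pd.DataFrame, n: int, direction: str,
                         sig_fdr: float = 0.05) -> pd.Index:
    """The n most disease-increased (or -decreased) joined genes.

    Ranked by |log2FC| among genes significant in the signature
    (FDR < ``sig_fdr``), falling back to the unrestricted ranking when
    fewer than n qualify; ties broken by smaller p, then symbol.
    """
    asc_fc = direction == "decreased"
    pool = joined[joined["human_fdr"] < sig_fdr]
    pool = pool[pool["human_fc"] < 0] if asc_fc else pool[pool["human_fc"] > 0]
    if len(pool) < n:
        pool = joined
    pool = pool.sort_index().sort_values(
        ["human_fc", "human_p"], ascending=[asc_fc, True], kind="mergesort")
    return pool.index[:n]


def match_score(
    mouse_fc: pd.Series,
    signature: ExpressionSignature,
    hmap: HomologyMap,
    n: int = MATCH_TOP_N,
    scale: str = "ratio",
    sig_fdr: float = 0.05,
    fill_undetected: bool = True,
) -> dict[str, float]:
    """Disease match score of one mouse group against one signature.

    up_component: mean mouse FC (IMQ/CTL) over the n genes most
    strongly increased in the disease; down_component: mean mouse
    reciprocal FC (CTL/IMQ) over the n most strongly decreased;
    score = their mean. On ``scale='log2'`` components are mean
    log2FC and mean negated log2FC. Undetected mouse homologs count as
    no response (FC = 1 / log2FC = 0) unless ``fill_undetected`` is
    False, in which case they are dropped before ranking.
    """
    if scale not in ("ratio", "log2"):
        raise ValueError("scale must be 'ratio' or 'log2'")
    m2h = hmap.mouse_to_human()
    sig = signature.table
    frame = pd.DataFrame({"human": m2h})
    frame = frame[frame["human"].isin(sig.index)]
    frame["mouse_fc"] = mouse_fc.reindex(frame.index)
    if fill_undetected:
        frame["mouse_fc"] = frame["mouse_fc"].fillna(0.0)
    else:
        frame = frame.dropna(subset=["mouse_fc"])
    if frame.empty:
        raise ValueError("no genes joined between mouse table and signature")
    frame["human_fc"] = sig.loc[frame["human"], "log2fc"].to_numpy()
    frame["human_p"] = sig.loc[frame["human"], "pvalue"].to_numpy()
    frame["human_fdr"] = sig.loc[frame["human"], "fdr"].to_numpy()

    n_eff = min(n, len(frame))
    if n_eff < n:
        logger.warning("match_score: only %d joined genes; n reduced from %d",
                       n_eff, n)
    top_up = _top_signature_genes(frame, n_eff, "increased", sig_fdr)
    top_down = _top_signature_genes(frame, n_eff, "decreased", sig_fdr)
    up_l2 = frame.loc[top_up, "mouse_fc"].to_numpy()
    down_l2 = frame.loc[top_down, "mouse_fc"].to_numpy()
    if scale == "ratio":
        up = float(np.mean(np.exp2(up_l2)))
        down = float(np.mean(np.exp2(-down_l2)))
    else:
        up = float(np.mean(up_l2))
        down = float(np.mean(-down_l2))
    return {"up_component": up, "down_component": down,
            "score": (up + down) / 2.0, "n_used": int(n_eff)}


def match_score_table(
    de_results: dict[str, DEResult],
    signatures: list[ExpressionSignature],
    hmap: HomologyMap,
    n: int = MATCH_TOP_N,
    scale: str = "ratio",
) -> pd.DataFrame:
    """Match scores for every (signature, strain-sex group) pair."""
    rows = []
    for sig in signatures:
        for group, de in de_results.items():
            ms = match_score(de.fc_series(), sig, hmap, n=n, scale=scale)
            rows.append({"signature_id": sig.signature_id,
                         "disease": sig.disease, "group": group, **ms})
    return pd.DataFrame(rows)


def disease_ranking(table: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank diseases by mean match score; best disease per group.

    Disease score = unweighted mean over the disease's signatures and
    over strain-sex groups. Also returns, per group, the
    highest-scoring disease (ties to the alphabetically first).
    """
    if table.empty:
        raise ValueError("empty match-score table")
    per_sig = (table.groupby(["disease", "signature_id"])["score"]
               .mean().reset_index())
    ranking = (per_sig.groupby("disease")["score"].mean()
               .sort_values(ascending=False).to_frame("mean_score"))
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    per_group_disease = (table.groupby(["group", "disease"])["score"]
                         .mean().reset_index()
                         .sort_values(["group", "score", "disease"],
                                      ascending=[True, False, True],
                                      kind="mergesort"))
    best = per_group_disease.groupby("group", sort=True).head(1)
    best = best.set_index("group").rename(columns={"disease": "best_disease",
                                                   "score": "best_score"})
    return ranking, best


# ---------------------------------------------------------------------------
# Top-N concordance, overlaps, PSI
# ---------------------------------------------------------------------------


def topn_concordance(
    signature: ExpressionSignature,
    de_results: dict[str, DEResult],
    hmap: HomologyMap,
    n: int = 50,
    direction: str = "increased",
    deg_fc: float = 2.0,
    deg_fdr: float = 0.10,
) -> pd.DataFrame:
    """Same-direction DEG flags for a signature's top genes, per group.

    Takes the n signature genes most strongly increased (or decreased)
    among those mappable to mouse, and flags, per strain-sex group,
    whether the homolog is a significant same-direction DEG. The
    ``n_groups`` column counts flagged groups per gene.
    """
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    h2m = hmap.human_to_mouse()
    sig = signature.table[signature.table.index.isin(h2m.index)].copy()
    asc = direction == "decreased"
    sig = sig.sort_index().sort_values(["log2fc", "pvalue"],
                                       ascending=[asc, True], kind="mergesort")
    top = sig.head(n)
    out = pd.DataFrame(index=top.index)
    out["mouse_symbol"] = h2m[top.index].to_numpy()
    for group, de in de_results.items():
        t = de.tested
        flags = []
        for m in out["mouse_symbol"]:
            if m in t.index:
                ratio = float(np.exp2(t.loc[m, "log2fc"]))
                ok = t.loc[m, "fdr"] < deg_fdr and (
                    ratio > deg_fc if direction == "increased"
                    else ratio < 1.0 / deg_fc)
            else:
                ok = False
            flags.append(bool(ok))
        out[group] = flags
    group_cols = list(de_results)
    out["n_groups"] = out[group_cols].sum(axis=1) if group_cols else 0
    return out


def overlap_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    """Exact Venn-region cardinalities for 2 or 3 named sets.

    Keys are '&'-joined sorted name combinations; each region counts
    elements in exactly those sets and no others.
    """
    from itertools import combinations

    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_counts handles 2 or 3 sets")
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in names if c not in combo),
                                set())
            out["&".join(sorted(combo))] = len(inside - outside)
    return out


def psi_concordance(
    psi_increased: GeneSet,
    psi_decreased: GeneSet,
    de_results: dict[str, DEResult],
    hmap: HomologyMap,
    deg_fc: float = 2.0,
    deg_fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-group concordance with psoriasis-specific gene lists.

    For the PSI-increased and PSI-decreased lists (human namespace),
    counts per strain-sex group the genes whose mouse homolog is a
    same-direction DEG and those called in the opposite direction,
    listing the gene identities.
    """
    h2m = hmap.human_to_mouse()
    rows = []
    for group, de in de_results.items():
        t = de.tested
        rec = {"group": group}
        for gs, want_up in ((psi_increased, True), (psi_decreased, False)):
            same, opp = [], []
            for h in gs.members:
                m = h2m.get(h)
                if m is None or m not in t.index:
                    continue
                ratio = float(np.exp2(t.loc[m, "log2fc"]))
                if t.loc[m, "fdr"] >= deg_fdr:
                    continue
                up_call = ratio > deg_fc
                down_call = ratio < 1.0 / deg_fc
                if (want_up and up_call) or (not want_up and down_call):
                    same.append(h)
                elif (want_up and down_call) or (not want_up and up_call):
                    opp.append(h)
            tag = "increased" if want_up else "decreased"
            rec[f"psi_{tag}_same"] = len(same)
            rec[f"psi_{tag}_opposite"] = len(opp)
            rec[f"psi_{tag}_same_genes"] = ",".join(sorted(same))
            rec[f"psi_{tag}_opposite_genes"] = ",".join(sorted(opp))
        rec["same_direction_total"] = (rec["psi_increased_same"]
                                       + rec["psi_decreased_same"])
        rec["opposite_direction_total"] = (rec["psi_increased_opposite"]
                                           + rec["psi_decreased_opposite"])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("group")
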