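"""End-to-end study orchestration.

``run_pipeline`` executes the full analysis flow on either a synthetic
study (generated with recorded ground truth) or user-supplied input
files: per-group differential expression (detection filter, TMM,
NB GLM LRT), sex x treatment interaction tests, DEG calling and
frequency tables, PC response vectors, fold-change correlation
matrices, homology-joined disease match scores with disease ranking,
psoriasis concordance, top-N concordance, Venn overlaps, cell-type
signature derivation and shift tests, GO-style overrepresentation,
sliding-window and cumulative-overlap enrichment, and PSI concordance.
Every table is written as TSV with a sha256 checksum collected into a
JSON manifest; rerunning with the same config and seed reproduces the
checksums byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosscompare, diffexpr, genesets, synthdata, windows
from .dataio import (CountMatrix, GeneSet, HomologyMap, load_homology,
                     read_counts, read_signatures, unique_filter,
                     write_counts, write_gmt, write_homology,
                     write_signatures)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``counts_path`` unset, a synthetic study is generated from
    ``synth`` (keyword arguments of :class:`synthdata.SynthConfig`).
    Thresholds default to the study's standard cut-offs: DEG fold
    change 2.0 at FDR 0.10, shift-test FDR 0.05, top-200 match-score
    genes, 100-gene windows.
    """

    out_dir: str = "dermeval_out"
    seed: int = 0
    counts_path: str | None = None
    design_path: str | None = None
    lengths_path: str | None = None
    homology_path: str | None = None
    signatures_path: str | None = None
    synth: dict = field(default_factory=dict)
    concordances: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.8)
    deg_fc: float = 2.0
    deg_fdr: float = 0.10
    shift_fdr: float = 0.05
    topn: int = 200
    window: int = 100
    window_step: int = 10
    match_scale: str = "log2"
    n_celltypes: int = 5
    celltype_reps: int = 3
    celltype_block: int = 100

    def __post_init__(self) -> None:
        if not (self.deg_fc > 1 and 0 < self.deg_fdr < 1
                and 0 < self.shift_fdr < 1 and self.topn > 0
                and self.window > 0 and self.window_step > 0):
            raise ValueError("thresholds out of range")
        for p in (self.counts_path, self.design_path, self.homology_path,
                  self.signatures_path, self.lengths_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "concordances" in data:
            data["concordances"] = tuple(data["concordances"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.entries: dict[str, str] = {}
        self.config = config

    def add(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.out_dir))] = _sha256(path)

    def write(self) -> Path:
        payload = {"config": _jsonable(asdict(self.config)),
                   "outputs": dict(sorted(self.entries.items()))}
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, manifest: Manifest,
               index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    manifest.add(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest payload."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, config)
    rng_seed = config.seed

    # ----- stage 1: inputs ------------------------------------------------
    truth = None
    if config.counts_path is None:
        synth_kwargs = dict(config.synth)
        synth_kwargs.setdefault("seed", rng_seed)
        scfg = synthdata.SynthConfig(**synth_kwargs)
        cm, truth = synthdata.generate_counts(scfg)
        raw_map = synthdata.generate_homology(scfg.n_genes, 6, seed=rng_seed)
        hmap = HomologyMap(*unique_filter(raw_map.table))
        labels = [f"disease{i + 1}" for i in range(len(config.concordances))]
        labels[int(np.argmax(config.concordances))] = "psoriasis"
        sigs = synthdata.generate_disease_signatures(
            truth, list(config.concordances), seed=rng_seed,
            disease_labels=labels)
        write_counts(cm, out / "counts.tsv", out / "design.tsv",
                     out / "gene_lengths.tsv")
        for f in ("counts.tsv", "design.tsv", "gene_lengths.tsv"):
            manifest.add(out / f)
        write_homology(hmap, out / "homology.tsv")
        manifest.add(out / "homology.tsv")
        write_signatures(sigs, out / "signatures.tsv")
        manifest.add(out / "signatures.tsv")
        truth_tab = pd.DataFrame({"membership": truth.membership})
        _write_tsv(truth_tab, out / "truth_membership.tsv", manifest)
    else:
        if config.design_path is None:
            raise ValueError("counts_path requires design_path")
        cm = read_counts(config.counts_path, config.design_path,
                         config.lengths_path)
        if config.homology_path is None or config.signatures_path is None:
            raise ValueError("loading counts requires homology and signatures")
        hmap = load_homology(config.homology_path)
        sigs = read_signatures(config.signatures_path)

    groups = cm.groups()

    # ----- stage 2: differential expression per group ---------------------
    de_results: dict[str, diffexpr.DEResult] = {}
    for strain, sex in groups:
        key = f"{strain}_{sex}"
        de = diffexpr.de_contrast(cm, strain, sex)
        de_results[key] = de
        _write_tsv(de.table, out / f"de_{key}.tsv", manifest)

    # ----- stage 3: interaction tests per strain --------------------------
    strains = list(dict.fromkeys(s for s, _ in groups))
    sexes_per_strain = {
        s: set(cm.design.loc[cm.design["strain"] == s, "sex"]) for s in strains
    }
    inter_summary = []
    for strain in strains:
        if sexes_per_strain[strain] != {"F", "M"}:
            continue
        ires = diffexpr.interaction_test(cm, strain)
        _write_tsv(ires.table, out / f"interaction_{strain}.tsv", manifest)
        n_sig = int((ires.tested["fdr"] < config.deg_fdr).sum())
        inter_summary.append({"strain": strain,
                              "n_interaction_fdr10": n_sig})
    _write_tsv(pd.DataFrame(inter_summary), out / "interaction_summary.tsv",
               manifest, index=False)

    # ----- stage 4: DEG sets and frequencies ------------------------------
    deg_sets = {k: diffexpr.call_degs(v, fc=config.deg_fc, fdr=config.deg_fdr)
                for k, v in de_results.items()}
    freq = diffexpr.deg_frequency(deg_sets, cm.genes)
    _write_tsv(freq, out / "deg_frequency.tsv", manifest)
    deg_counts = pd.DataFrame(
        [{"group": k, "n_increased": len(i), "n_decreased": len(d)}
         for k, (i, d) in deg_sets.items()])
    _write_tsv(deg_counts, out / "deg_counts.tsv", manifest, index=False)

    # ----- stage 5: PC response vectors -----------------------------------
    detected_any = diffexpr.detect(cm)
    logcpm = cm.cpm(log=True).loc[detected_any]
    vectors = crosscompare.pc_response_vectors(logcpm, cm.design)
    vec_tab = pd.DataFrame(
        [{"strain": v.strain, "sex": v.sex,
          "pc1_start": v.start[0], "pc2_start": v.start[1],
          "pc1_end": v.end[0], "pc2_end": v.end[1], "length": v.length}
         for v in vectors])
    _write_tsv(vec_tab, out / "pc_response_vectors.tsv", manifest, index=False)

    # ----- stage 6: FC correlation matrix ---------------------------------
    fc_tables = {k: v.fc_series() for k, v in de_results.items()}
    corr = crosscompare.fc_correlation_matrix(fc_tables)
    _write_tsv(corr, out / "fc_correlation.tsv", manifest)

    # ----- stage 7: match scores and disease ranking ----------------------
    mt = crosscompare.match_score_table(de_results, sigs, hmap,
                                        n=config.topn,
                                        scale=config.match_scale)
    _write_tsv(mt, out / "match_scores.tsv", manifest, index=False)
    ranking, best = crosscompare.disease_ranking(mt)
    _write_tsv(ranking, out / "disease_ranking.tsv", manifest)
    _write_tsv(best, out / "best_match.tsv", manifest)

    # ----- stage 8: psoriasis concordance ---------------------------------
    pso = [s for s in sigs if s.disease == "psoriasis"] or sigs
    conc_rows = []
    for key, de in de_results.items():
        c = crosscompare.psoriasis_concordance(de, pso[0], hmap)
        conc_rows.append({"group": key, **c})
    _write_tsv(pd.DataFrame(conc_rows), out / "psoriasis_concordance.tsv",
               manifest, index=False)

    # ----- stage 9: top-N concordance and overlaps ------------------------
    top50 = crosscompare.topn_concordance(pso[0], de_results, hmap, n=50,
                                          deg_fc=config.deg_fc,
                                          deg_fdr=config.deg_fdr)
    _write_tsv(top50, out / "top50_concordance.tsv", manifest)

    if len(sigs) >= 2 and de_results:
        g0 = next(iter(de_results))
        h2m = hmap.human_to_mouse()
        inc_mouse = deg_sets[g0][0]
        sig_sets = {}
        for s in (pso[0], [x for x in sigs if x is not pso[0]][0]):
            t = s.table
            up = t.index[(t["log2fc"] > 0) & (t["fdr"] < 0.10)]
            sig_sets[s.disease] = {h2m[h] for h in up if h in h2m.index}
        venn = crosscompare.overlap_counts(
            {f"IMQ_{g0}": inc_mouse, **sig_sets})
        (out / "overlap_counts.json").write_text(
            json.dumps(venn, indent=2, sort_keys=True))
        manifest.add(out / "overlap_counts.json")

    # ----- stage 10: cell types -------------------------------------------
    comp, labels_s, planted_sets = synthdata.generate_celltype_compendium(
        config.n_celltypes, config.celltype_reps,
        block_size=config.celltype_block, seed=rng_seed, truth=truth)
    derived = genesets.derive_celltype_signatures(comp, labels_s,
                                                  k=config.celltype_block)
    write_gmt(derived, out / "celltype_signatures.gmt")
    manifest.add(out / "celltype_signatures.gmt")
    shift = genesets.shift_test(fc_tables, derived,
                                fdr_threshold=config.shift_fdr)
    _write_tsv(shift.table, out / "celltype_shift.tsv", manifest, index=False)

    # ----- stage 11: ORA over module-derived terms ------------------------
    if truth is not None:
        universe = set(cm.genes)
        terms = [GeneSet("shared_up", "planted IMQ-induced module",
                         tuple(truth.shared_up)),
                 GeneSet("shared_down", "planted IMQ-repressed module",
                         tuple(truth.shared_down))]
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0x0AA]))
        terms.append(GeneSet("random_term", "random background term",
                             tuple(rng.choice(sorted(universe), 100,
                                              replace=False))))
        frequent_inc = set(freq.index[freq["increased_in"]
                                      >= max(1, len(groups) // 2)])
        ora_tab = genesets.ora(frequent_inc & universe, terms, universe)
        _write_tsv(ora_tab, out / "ora_frequent_increased.tsv", manifest,
                   index=False)

    # ----- stage 12: windows -----------------------------------------------
    if truth is not None:
        rank_tab = synthdata.generate_differentiation_ranking(
            truth, seed=rng_seed)
        _write_tsv(rank_tab, out / "differentiation_ranking.tsv", manifest)
        inc_set = GeneSet("suprabasal_increased", "",
                          tuple(rank_tab.index[
                              rank_tab["label"] == "suprabasal_increased"]))
        dec_set = GeneSet("suprabasal_decreased", "",
                          tuple(rank_tab.index[
                              rank_tab["label"] == "suprabasal_decreased"]))
        win_summary = []
        for key, fc in fc_tables.items():
            track = windows.sliding_enrichment(
                fc, [inc_set, dec_set], w=config.window,
                s=config.window_step,
                pvalues=de_results[key].tested["pvalue"])
            _write_tsv(track.table, out / f"windows_{key}.tsv", manifest,
                       index=False)
            n = len(track.table)
            bottom = track.table.iloc[int(0.8 * n):]
            win_summary.append({
                "group": key,
                "min_p_increased_bottom":
                    float(bottom["pvalue_suprabasal_increased"].min()),
            })
        _write_tsv(pd.DataFrame(win_summary), out / "windows_summary.tsv",
                   manifest, index=False)

        # cumulative overlap of the top IMQ-decreased genes in each of
        # the first and last strain's males against the ranking
        co_rows = []
        for key in (f"{strains[0]}_M", f"{strains[-1]}_M"):
            if key not in fc_tables:
                continue
            fc = fc_tables[key].dropna().sort_values()
            top_dec = set(fc.index[:config.window])
            co = windows.cumulative_overlap(top_dec, rank_tab.index,
                                            n_permutations=500,
                                            seed=rng_seed)
            co_rows.append({"group": key, "max_departure": co.max_departure,
                            "pvalue": co.pvalue})
        _write_tsv(pd.DataFrame(co_rows), out / "cumulative_overlap.tsv",
                   manifest, index=False)

    # ----- stage 13: PSI concordance --------------------------------------
    if truth is not None:
        psi_inc = GeneSet("psi_increased", "planted psoriasis-specific up",
                          tuple(g.upper() for g in truth.shared_up),
                          namespace="human")
        psi_dec = GeneSet("psi_decreased", "planted psoriasis-specific down",
                          tuple(g.upper() for g in truth.shared_down),
                          namespace="human")
        psi = crosscompare.psi_concordance(psi_inc, psi_dec, de_results,
                                           hmap, deg_fc=config.deg_fc,
                                           deg_fdr=config.deg_fdr)
        _write_tsv(psi, out / "psi_concordance.tsv", manifest)

    path = manifest.write()
    logger.info("pipeline complete: %d outputs, manifest at %s",
                len(manifest.entries), path)
    return json.loads(path.read_text())
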