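"""Synthetic study generator with recorded ground truth.

Emulates a topical-imiquimod (IMQ) dermatitis study across inbred mouse
strains: negative-binomial read counts over a strains x sexes x
treatments design with few replicates, a mouse/human homology map,
human disease expression signatures with tunable concordance to the
planted IMQ response, a sorted-cell-type expression compendium with
planted signature blocks, and a suprabasal-versus-basal epidermis
ranking. Every planted effect is recorded in :class:`SynthTruth`, so
downstream statistics can be scored against known truth.

Planted structure, mirroring the biology the pipeline is meant to
resolve:

* a *shared* IMQ-response module (half induced, half repressed in every
  strain), scaled per strain so one strain responds most strongly;
* optionally, the last strain's males respond to the shared module with
  inverted sign (an aberrant-responder strain, the analog of MOLF males
  whose IMQ response anticorrelates with the other strains);
* *strain-specific* modules, responding in one strain only, with sign
  alternating across strains so fold-change correlation matrices have
  planted block structure;
* a *sex x treatment interaction* module responding with opposite sign
  in females and males.

All randomness flows from explicit integer seeds; one independent RNG
stream is split off per artifact class, so generating one artifact never
perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import CountMatrix, ExpressionSignature, GeneSet, HomologyMap

DEFAULT_STRAINS = ("B6", "BALB", "CD1", "DBA", "FVB", "129", "MOLF")


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic IMQ study.

    Defaults correspond to the design the pipeline targets: 7 strains,
    both sexes, control-cream vs IMQ, n = 2 replicates per cell, library
    sizes log-normal around one million reads, and a dispersion that
    decays with the mean as phi(mu) = intercept + slope / mu.
    """

    n_genes: int = 5000
    strains: tuple[str, ...] = DEFAULT_STRAINS
    sexes: tuple[str, ...] = ("F", "M")
    treatments: tuple[str, ...] = ("CTL", "IMQ")
    n_reps: int = 2
    lib_size_mean: float = 1e6
    lib_size_log_sd: float = 0.15
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 2.0
    shared_module_size: int = 200
    strain_module_size: int = 30
    interaction_module_size: int = 50
    effect_log2fc: float = 2.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    # per-strain multiplier on the shared-module response; the first
    # strain (B6-like) responds most strongly by default
    strain_response_scale: tuple[float, ...] | None = (1.5, 1.0, 1.0, 1.0, 1.0, 1.0, 0.6)
    # invert the shared-module response in the last strain's males
    # (the aberrant-responder analog)
    flip_last_strain_males: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_reps <= 0:
            raise ConfigError("n_reps must be positive")
        if min(self.shared_module_size, self.strain_module_size,
               self.interaction_module_size) < 0:
            raise ConfigError("module sizes must be >= 0")
        total = (self.shared_module_size
                 + self.strain_module_size * len(self.strains)
                 + self.interaction_module_size)
        if total > self.n_genes:
            raise ConfigError(
                f"module sizes sum to {total} > n_genes = {self.n_genes}"
            )
        if not np.isfinite(self.effect_log2fc):
            raise ConfigError("effect_log2fc must be finite")
        if self.lib_size_log_sd <= 0:
            raise ConfigError("lib_size_log_sd must be positive")
        scale = self.strain_response_scale
        if scale is not None and len(scale) != len(self.strains):
            raise ConfigError("strain_response_scale length must match strains")

    @property
    def scales(self) -> np.ndarray:
        if self.strain_response_scale is None:
            return np.ones(len(self.strains))
        return np.asarray(self.strain_response_scale, dtype=float)


@dataclass
class SynthTruth:
    """Ground truth for one synthetic study.

    ``membership`` labels each gene ``shared_up``, ``shared_down``,
    ``strain:<name>``, ``interaction`` or ``null``; ``planted_lfc``
    holds the planted log2 fold change (IMQ vs CTL) per gene for every
    (strain, sex). Artifacts generated later (disease signatures, cell
    type blocks, the differentiation ranking) register their planted
    parameters here as well.
    """

    config: SynthConfig
    membership: pd.Series
    planted_lfc: pd.DataFrame  # genes x MultiIndex (strain, sex)
    signature_concordance: dict[str, float] = field(default_factory=dict)
    celltype_blocks: dict[str, GeneSet] = field(default_factory=dict)
    differentiation: pd.DataFrame | None = None

    def module_genes(self, label: str) -> list[str]:
        return list(self.membership.index[self.membership == label])

    @property
    def shared_up(self) -> list[str]:
        return self.module_genes("shared_up")

    @property
    def shared_down(self) -> list[str]:
        return self.module_genes("shared_down")

    def null_genes(self) -> list[str]:
        return self.module_genes("null")


def _gene_names(n: int) -> list[str]:
    return [f"Gene{i + 1}" for i in range(n)]


def _human_name(mouse: str) -> str:
    return mouse.upper()


def generate_counts(config: SynthConfig) -> tuple[CountMatrix, SynthTruth]:
    """Draw NB counts for the full design and record the planted truth.

    Counts for gene g in sample i are NB with mean
    ``lib_size_i * p_g * 2**(planted_lfc * [i is IMQ])`` and dispersion
    ``phi(mu) = dispersion_intercept + dispersion_slope / mu``,
    sampled via the gamma-Poisson mixture.
    """
    ss = np.random.SeedSequence([config.seed, 0x5EED])
    rng_base, rng_lib, rng_counts, rng_len = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    genes = _gene_names(config.n_genes)

    # module membership
    membership = pd.Series("null", index=pd.Index(genes, name="gene"))
    pos = 0
    up_n = config.shared_module_size // 2
    membership.iloc[pos:pos + up_n] = "shared_up"
    membership.iloc[pos + up_n:pos + config.shared_module_size] = "shared_down"
    pos += config.shared_module_size
    for s in config.strains:
        membership.iloc[pos:pos + config.strain_module_size] = f"strain:{s}"
        pos += config.strain_module_size
    membership.iloc[pos:pos + config.interaction_module_size] = "interaction"

    # planted log2FC per gene per (strain, sex)
    cols = pd.MultiIndex.from_product(
        [config.strains, config.sexes], names=["strain", "sex"]
    )
    lfc = pd.DataFrame(0.0, index=membership.index, columns=cols)
    eff = config.effect_log2fc
    scales = config.scales
    for si, strain in enumerate(config.strains):
        for sex in config.sexes:
            v = np.zeros(config.n_genes)
            shared_sign = 1.0
            if (config.flip_last_strain_males
                    and si == len(config.strains) - 1 and sex == "M"):
                shared_sign = -1.0
            v[(membership == "shared_up").to_numpy()] = eff * scales[si] * shared_sign
            v[(membership == "shared_down").to_numpy()] = -eff * scales[si] * shared_sign
            strain_sign = 1.0 if si % 2 == 0 else -1.0
            v[(membership == f"strain:{strain}").to_numpy()] = eff * strain_sign
            inter_sign = 1.0 if sex == config.sexes[0] else -1.0
            v[(membership == "interaction").to_numpy()] = eff * inter_sign
            lfc[(strain, sex)] = v

    # baseline relative abundances and sample design
    baseline = np.exp2(rng_base.normal(config.baseline_log2_mean,
                                       config.baseline_log2_sd, config.n_genes))
    props = baseline / baseline.sum()

    rows = []
    for strain in config.strains:
        for sex in config.sexes:
            for trt in config.treatments:
                for rep in range(1, config.n_reps + 1):
                    rows.append(
                        {"sample_id": f"{strain}_{sex}_{trt}_{rep}",
                         "strain": strain, "sex": sex,
                         "treatment": trt, "replicate": str(rep)}
                    )
    design = pd.DataFrame(rows).set_index("sample_id")

    lib = np.exp(rng_lib.normal(np.log(config.lib_size_mean),
                                config.lib_size_log_sd, len(design)))

    counts = np.zeros((config.n_genes, len(design)), dtype=np.int64)
    for j, (sample, row) in enumerate(design.iterrows()):
        fc = np.ones(config.n_genes)
        if row["treatment"] == config.treatments[1]:
            fc = np.exp2(lfc[(row["strain"], row["sex"])].to_numpy())
        mu = lib[j] * props * fc
        phi = config.dispersion_intercept + config.dispersion_slope / np.maximum(mu, 1e-8)
        counts[:, j] = _nb_draw(rng_counts, mu, phi)

    lengths = pd.Series(
        rng_len.integers(500, 10001, config.n_genes),
        index=membership.index, name="length_bp",
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=membership.index, columns=design.index),
        design=design,
        gene_lengths=lengths,
    )
    truth = SynthTruth(config=config, membership=membership, planted_lfc=lfc)
    return cm, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: NB(mean mu, variance mu + phi mu^2)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mu[~pois] * phi[~pois])
        out[~pois] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------


def generate_homology(n_pairs: int, n_ambiguous: int = 0, seed: int = 0) -> HomologyMap:
    """Generate a homologene-style table of 1:1 pairs plus decoys.

    Clean entries pair mouse ``Gene<i>`` with human ``GENE<i>`` under a
    unique homologene id, matching the symbols :func:`generate_counts`
    uses. Ambiguous entries come in groups of two or three sharing a
    mouse symbol across distinct homologene ids, so the unique filter
    drops all of them; ``n_ambiguous`` must therefore be 0 or >= 2.
    The returned map is the *raw* table (decoys included); pass it
    through :func:`dermeval.dataio.unique_filter` or round-trip it via
    :func:`dermeval.dataio.load_homology` to exercise the filter.
    """
    if n_pairs < 0 or n_ambiguous < 0:
        raise ValueError("n_pairs and n_ambiguous must be >= 0")
    if n_ambiguous == 1:
        raise ValueError(
            "a single decoy row cannot conflict with anything; "
            "use n_ambiguous = 0 or >= 2"
        )
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append((f"HG{i}", f"Gene{i}", f"GENE{i}"))
    k = 0
    hid = n_pairs
    while k < n_ambiguous:
        group = 3 if (n_ambiguous - k) == 3 else 2
        shared_mouse = f"Ambig{k + 1}"
        for g in range(group):
            hid += 1
            rows.append((f"HG{hid}", shared_mouse, f"AMBIG{k + g + 1}"))
        k += group
    table = pd.DataFrame(rows, columns=["homologene_id", "mouse_symbol", "human_symbol"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x40]))
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    return HomologyMap(table, n_dropped=0)


# ---------------------------------------------------------------------------
# Disease signatures
# ---------------------------------------------------------------------------


def generate_disease_signatures(
    truth: SynthTruth,
    concordances: list[float],
    n_genes_human: int | None = None,
    seed: int = 0,
    disease_labels: list[str] | None = None,
) -> list[ExpressionSignature]:
    """Build human disease signatures with planted IMQ-concordance.

    Each signature ranks a "top increased" and "top decreased" block of
    genes (|log2FC| in [1.5, 4], small p) against a low-|log2FC| noise
    background (|log2FC| < 1.2). A fraction ``c`` of the top genes are
    the human homologs of the planted shared-response module, in the
    matching direction; the remainder are random human genes. ``c`` is
    recorded in ``truth.signature_concordance``.
    """
    if n_genes_human is None:
        n_genes_human = truth.config.n_genes
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15]))
    up_h = [_human_name(g) for g in truth.shared_up]
    down_h = [_human_name(g) for g in truth.shared_down]
    universe = [f"GENE{i + 1}" for i in range(n_genes_human)]
    module_set = set(up_h) | set(down_h)
    background = [g for g in universe if g not in module_set]

    sigs: list[ExpressionSignature] = []
    for j, c in enumerate(concordances):
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"concordance must lie in [0, 1], got {c}")
        sig_id = f"sig{j + 1}"
        disease = (disease_labels[j] if disease_labels is not None
                   else f"disease{j + 1}")
        top_up = _concordant_pick(rng, up_h, background, c)
        remaining_bg = [g for g in background if g not in set(top_up)]
        top_down = _concordant_pick(rng, down_h, remaining_bg, c)

        lfc = pd.Series(rng.normal(0.0, 0.25, len(universe)).clip(-1.2, 1.2),
                        index=universe)
        pval = pd.Series(rng.uniform(0.05, 1.0, len(universe)), index=universe)
        lfc[top_up] = rng.uniform(1.5, 4.0, len(top_up))
        lfc[top_down] = -rng.uniform(1.5, 4.0, len(top_down))
        strong = top_up + top_down
        pval[strong] = 10.0 ** (-rng.uniform(4.0, 8.0, len(strong)))
        from .diffexpr import bh_adjust  # local import avoids a cycle
        fdr = pd.Series(bh_adjust(pval.to_numpy()), index=universe)
        table = pd.DataFrame({"log2fc": lfc, "pvalue": pval, "fdr": fdr})
        table.index.name = "gene"
        sigs.append(ExpressionSignature(sig_id, disease, table))
        truth.signature_concordance[sig_id] = float(c)
    return sigs


def _concordant_pick(rng, module_human: list[str], background: list[str],
                     c: float) -> list[str]:
    n = len(module_human)
    k = int(round(c * n))
    chosen = list(rng.choice(module_human, size=k, replace=False)) if k else []
    filler = list(rng.choice(background, size=n - k, replace=False)) if n - k else []
    return chosen + filler


# ---------------------------------------------------------------------------
# Cell-type compendium
# ---------------------------------------------------------------------------


def generate_celltype_compendium(
    n_types: int,
    n_reps_per_type: int,
    block_size: int = 100,
    seed: int = 0,
    n_genes: int | None = None,
    shift: float = 5.0,
    noise_sd: float = 0.5,
    truth: SynthTruth | None = None,
) -> tuple[pd.DataFrame, pd.Series, list[GeneSet]]:
    """Log-scale expression across sorted cell populations.

    Each cell type owns a disjoint block of ``block_size`` genes whose
    expression is elevated by ``shift`` log2 units in that type only —
    the structure of sorted-immune-cell compendia from which cell-type
    signature genes are derived.

    Returns (expression genes x samples, sample -> type labels, one
    planted GeneSet per type).
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_reps_per_type < 2:
        raise ValueError("need at least 2 replicates per type")
    if n_genes is None:
        n_genes = max(2000, 2 * n_types * block_size)
    if n_types * block_size > n_genes:
        raise ValueError(
            f"{n_types} blocks of {block_size} genes exceed the "
            f"{n_genes}-gene universe"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE11]))
    genes = _gene_names(n_genes)
    types = [f"celltype{t + 1}" for t in range(n_types)]
    samples = [f"{t}_r{r + 1}" for t in types for r in range(n_reps_per_type)]
    labels = pd.Series([t for t in types for _ in range(n_reps_per_type)],
                       index=samples, name="cell_type")

    base = rng.normal(6.0, 1.0, n_genes)
    expr = base[:, None] + rng.normal(0.0, noise_sd, (n_genes, len(samples)))
    sets: list[GeneSet] = []
    for t_i, t in enumerate(types):
        block = np.arange(t_i * block_size, (t_i + 1) * block_size)
        cols = np.array([j for j, s in enumerate(samples) if labels[s] == t])
        expr[np.ix_(block, cols)] += shift
        sets.append(GeneSet(t, f"planted signature block for {t}",
                            tuple(genes[i] for i in block), namespace="mouse"))
    table = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    if truth is not None:
        truth.celltype_blocks = {gs.set_id: gs for gs in sets}
    return table, labels, sets


# ---------------------------------------------------------------------------
# Differentiation ranking
# ---------------------------------------------------------------------------


def generate_differentiation_ranking(
    truth: SynthTruth,
    seed: int = 0,
    overlap_fraction: float = 1.0,
    set_size: int = 100,
    source_module: str = "shared_up",
) -> pd.DataFrame:
    """Rank mouse genes by suprabasal-versus-basal expression.

    Plants a "suprabasal-increased" set of ``set_size`` genes of which a
    fraction ``overlap_fraction`` is drawn from ``source_module`` (by
    default the shared IMQ-induced module — the genes an
    aberrant-responder strain represses), plus a disjoint
    "suprabasal-decreased" set from null genes. Returns a table with
    columns ``suprabasal_log2fc`` and ``label`` sorted descending, and
    records it in ``truth.differentiation``.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1FF]))
    genes = list(truth.membership.index)
    module = truth.module_genes(source_module)
    nulls = truth.null_genes()
    k_mod = min(int(round(overlap_fraction * set_size)), len(module))
    k_bg = set_size - k_mod
    if k_bg > len(nulls) - set_size:
        raise ValueError("not enough null genes to build the planted sets")
    inc = (list(rng.choice(module, k_mod, replace=False)) if k_mod else []) + \
          (list(rng.choice(nulls, k_bg, replace=False)) if k_bg else [])
    remaining_nulls = [g for g in nulls if g not in set(inc)]
    dec = list(rng.choice(remaining_nulls, min(set_size, len(remaining_nulls)),
                          replace=False)) if set_size else []

    lfc = pd.Series(rng.normal(0.0, 1.0, len(genes)), index=genes)
    lfc[inc] = rng.normal(3.0, 0.5, len(inc))
    lfc[dec] = rng.normal(-3.0, 0.5, len(dec))
    label = pd.Series("none", index=genes)
    label[inc] = "suprabasal_increased"
    label[dec] = "suprabasal_decreased"
    out = pd.DataFrame({"suprabasal_log2fc": lfc, "label": label})
    out.index.name = "gene"
    out = out.sort_values("suprabasal_log2fc", ascending=False)
    truth.differentiation = out
    return out
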