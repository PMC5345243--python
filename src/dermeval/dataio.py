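"""Readers, writers, and homology joining for the on-disk formats.

All tables are plain tab-separated text. A count matrix travels as two
files: the counts themselves (genes x samples, first column ``gene``)
and a sidecar design table (``sample_id``, ``strain``, ``sex``,
``treatment``, ``replicate``) plus an optional gene-length table.

Mouse and human gene symbols follow different case conventions
(mouse ``Il17a``, human ``IL17A``); symbols are canonicalized on load
(mouse Title-case, human upper-case) and matching afterwards is
case-sensitive, so a symbol that reaches a join in the wrong namespace
fails loudly instead of matching by accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
TREATMENTS = ("CTL", "IMQ")

DESIGN_COLUMNS = ["sample_id", "strain", "sex", "treatment", "replicate"]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def canonical_mouse(symbol: str) -> str:
    """Canonicalize a mouse gene symbol (Title-case: 'IL17A' -> 'Il17a')."""
    s = str(symbol).strip()
    return s[:1].upper() + s[1:].lower() if s else s


def canonical_human(symbol: str) -> str:
    """Canonicalize a human gene symbol (upper-case)."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with the sample design.

    Attributes
    ----------
    counts
        DataFrame of non-negative integers, index = gene symbols,
        columns = sample ids.
    design
        DataFrame indexed by sample id with columns ``strain``, ``sex``
        (F/M), ``treatment`` (CTL/IMQ) and ``replicate``.
    gene_lengths
        Series of positive integers (bp) indexed like ``counts``;
        optional but required by FPKM-style computations.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate gene symbols: {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise FormatError(
                    "non-integer count at gene "
                    f"{idx[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts present")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        for col in ("strain", "sex", "treatment", "replicate"):
            if col not in self.design.columns:
                raise FormatError(f"design lacks required column {col!r}")
        bad_sex = set(self.design["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex labels {sorted(bad_sex)}; expected {SEXES}")
        bad_trt = set(self.design["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise FormatError(
                f"unknown treatment labels {sorted(bad_trt)}; expected {TREATMENTS}"
            )
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(idx)
            if self.gene_lengths.isna().any():
                raise FormatError("gene lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise FormatError("gene lengths must be positive")

    # -- convenience --------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Total mapped reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def cpm(self, log: bool = False, prior: float = 0.5) -> pd.DataFrame:
        """Counts per million on raw library sizes.

        With ``log=True`` returns log2(cpm) computed with a prior count
        so zeros stay finite.
        """
        lib = self.library_sizes().to_numpy(dtype=float)
        if log:
            vals = np.log2((self.counts.to_numpy() + prior) / (lib + 1.0) * 1e6)
        else:
            vals = self.counts.to_numpy() / lib * 1e6
        return pd.DataFrame(vals, index=self.genes, columns=self.samples)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(
            counts=self.counts[samples].copy(),
            design=self.design.loc[samples].copy(),
            gene_lengths=self.gene_lengths,
        )

    def group_samples(self, strain: str, sex: str) -> list[str]:
        d = self.design
        mask = (d["strain"] == strain) & (d["sex"] == sex)
        return [s for s in self.samples if mask.get(s, False)]

    def groups(self) -> list[tuple[str, str]]:
        """All (strain, sex) combinations present, in design order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.design.iterrows():
            key = (row["strain"], row["sex"])
            if key not in seen:
                seen.append(key)
        return seen


def read_counts(
    counts_path, design_path, lengths_path=None
) -> CountMatrix:
    """Read a count matrix, its design sidecar, and optional gene lengths."""
    raw = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene":
        raise FormatError(
            f"first column of {counts_path} must be 'gene', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene")
    for col in raw.columns:
        col_vals = pd.to_numeric(raw[col], errors="coerce")
        if col_vals.isna().any():
            gene = raw.index[col_vals.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"non-numeric count at gene {gene!r}, sample {col!r}")
        frac = col_vals - np.round(col_vals)
        if (np.abs(frac) > 0).any():
            gene = raw.index[(np.abs(frac) > 0).to_numpy().nonzero()[0][0]]
            raise FormatError(f"non-integer count at gene {gene!r}, sample {col!r}")
    counts = raw.astype(np.int64)

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
    if missing_cols:
        raise FormatError(f"design table lacks columns {sorted(missing_cols)}")
    design = design.set_index("sample_id")

    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", dtype={0: str})
        lengths = lt.set_index(lt.columns[0]).iloc[:, 0].astype(np.int64)

    cm = CountMatrix(counts=counts, design=design, gene_lengths=lengths)
    logger.info(
        "read_counts: %d genes x %d samples from %s",
        len(cm.genes), len(cm.samples), counts_path,
    )
    return cm


def write_counts(cm: CountMatrix, counts_path, design_path, lengths_path=None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t")
    d = cm.design.copy()
    d.index.name = "sample_id"
    d.to_csv(design_path, sep="\t")
    if lengths_path is not None and cm.gene_lengths is not None:
        gl = cm.gene_lengths.copy()
        gl.index.name = "gene"
        gl.name = "length_bp"
        gl.to_csv(lengths_path, sep="\t")


# ---------------------------------------------------------------------------
# Homology maps
# ---------------------------------------------------------------------------


@dataclass
class HomologyMap:
    """Homologene-style mouse/human symbol pairing.

    ``table`` has columns ``homologene_id``, ``mouse_symbol``,
    ``human_symbol``. After :func:`unique_filter` every id and every
    symbol on either side appears at most once (the 1:1 invariant the
    downstream joins rely on).
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def mouse_to_human(self) -> pd.Series:
        return pd.Series(
            self.table["human_symbol"].to_numpy(),
            index=self.table["mouse_symbol"].to_numpy(),
        )

    def human_to_mouse(self) -> pd.Series:
        return pd.Series(
            self.table["mouse_symbol"].to_numpy(),
            index=self.table["human_symbol"].to_numpy(),
        )


def unique_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop every row involved in a many-to-anything conflict.

    A homologene id associated with more than one mouse or human symbol,
    or a symbol appearing under more than one id, disqualifies all rows
    it touches; no best-hit resolution is attempted, so the result is
    reproducible regardless of row order.
    """
    t = table.drop_duplicates()
    keep = np.ones(len(t), dtype=bool)
    for col in ("homologene_id", "mouse_symbol", "human_symbol"):
        dup = t[col].duplicated(keep=False)
        keep &= ~dup.to_numpy()
    filtered = t.loc[keep].reset_index(drop=True)
    return filtered, len(table) - len(filtered)


def load_homology(path) -> HomologyMap:
    """Load a three-column homology table and reduce it to 1:1 pairs."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("load_homology: %s is empty", path)
        return HomologyMap(
            pd.DataFrame(columns=["homologene_id", "mouse_symbol", "human_symbol"]),
            n_dropped=0,
        )
    expected = ["homologene_id", "mouse_symbol", "human_symbol"]
    if list(raw.columns[:3]) != expected:
        raise FormatError(
            f"homology table must have columns {expected}, got {list(raw.columns)}"
        )
    bad = raw[expected].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise FormatError(f"malformed homology row at line {int(bad.idxmax()) + 2}")
    raw = raw[expected].copy()
    raw["mouse_symbol"] = raw["mouse_symbol"].map(canonical_mouse)
    raw["human_symbol"] = raw["human_symbol"].map(canonical_human)
    filtered, n_dropped = unique_filter(raw)
    if len(filtered) == 0:
        logger.warning("load_homology: no usable rows in %s", path)
    logger.info(
        "load_homology: %d rows read, %d retained, %d dropped as ambiguous",
        len(raw), len(filtered), n_dropped,
    )
    return HomologyMap(filtered, n_dropped=n_dropped)


def write_homology(hmap: HomologyMap, path) -> None:
    hmap.table.to_csv(path, sep="\t", index=False)


def map_orthologs(
    mouse_table: pd.DataFrame | pd.Series,
    human_table: pd.DataFrame | pd.Series,
    hmap: HomologyMap,
) -> pd.DataFrame:
    """Inner-join mouse- and human-keyed per-gene tables via homology.

    Both inputs are keyed by unique symbols in their own namespace; the
    result is keyed by homologene id and carries both symbol columns,
    with the mouse table's columns suffixed ``_mouse`` and the human
    table's ``_human`` on collision. Genes absent from either side or
    from the (unique-filtered) map are excluded.
    """
    if isinstance(mouse_table, pd.Series):
        mouse_table = mouse_table.to_frame()
    if isinstance(human_table, pd.Series):
        human_table = human_table.to_frame()
    if mouse_table.index.duplicated().any():
        raise ValueError("mouse table index has duplicate symbols")
    if human_table.index.duplicated().any():
        raise ValueError("human table index has duplicate symbols")
    base = hmap.table.set_index("homologene_id")
    joined = base.join(
        mouse_table.add_suffix("_mouse"), on="mouse_symbol", how="inner"
    ).join(human_table.add_suffix("_human"), on="human_symbol", how="inner")
    logger.info(
        "map_orthologs: joined %d of (%d mouse, %d human, %d map) entries",
        len(joined), len(mouse_table), len(human_table), len(hmap),
    )
    return joined


# ---------------------------------------------------------------------------
# Gene sets (GMT) and expression signatures
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named gene collection in a declared namespace."""

    set_id: str
    description: str
    members: tuple[str, ...]
    namespace: str = "mouse"  # "mouse" | "human"

    def __post_init__(self) -> None:
        if self.namespace not in ("mouse", "human"):
            raise ValueError(f"namespace must be 'mouse' or 'human', got {self.namespace!r}")
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        self.members = tuple(seen)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.members)


def read_gmt(path, namespace: str = "mouse") -> list[GeneSet]:
    """Parse a GMT file (set_id TAB description TAB member...)."""
    sets: list[GeneSet] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno} has fewer than 2 fields")
            set_id, desc, *members = parts
            if set_id in ids:
                raise FormatError(f"{path}: duplicate gene set id {set_id!r}")
            ids.add(set_id)
            members = [m for m in members if m]
            if len(members) != len(set(members)):
                logger.warning(
                    "read_gmt: duplicate members in set %s deduplicated", set_id
                )
            sets.append(GeneSet(set_id, desc, tuple(members), namespace=namespace))
    logger.info("read_gmt: %d sets from %s", len(sets), path)
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


@dataclass
class ExpressionSignature:
    """One human disease comparison: per-gene log2FC, p, FDR.

    ``table`` is indexed by human symbol with columns ``log2fc``,
    ``pvalue``, ``fdr``.
    """

    signature_id: str
    disease: str
    table: pd.DataFrame
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError(
                f"signature {self.signature_id}: duplicate gene symbols"
            )
        for col in ("log2fc", "pvalue", "fdr"):
            if col not in self.table.columns:
                raise FormatError(f"signature {self.signature_id}: missing {col!r}")
        for col in ("pvalue", "fdr"):
            vals = self.table[col]
            if ((vals < 0) | (vals > 1)).any():
                raise FormatError(
                    f"signature {self.signature_id}: {col} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.table)


def read_signatures(path) -> list[ExpressionSignature]:
    """Read a long-format signature table.

    Columns: signature_id, disease, gene, log2fc, pvalue, fdr.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"signature_id": str, "disease": str, "gene": str})
    needed = ["signature_id", "disease", "gene", "log2fc", "pvalue", "fdr"]
    missing = set(needed) - set(raw.columns)
    if missing:
        raise FormatError(f"signature table lacks columns {sorted(missing)}")
    sigs: list[ExpressionSignature] = []
    for sig_id, grp in raw.groupby("signature_id", sort=False):
        disease = grp["disease"].iloc[0]
        tab = grp.set_index("gene")[["log2fc", "pvalue", "fdr"]].astype(float)
        tab.index = tab.index.map(canonical_human)
        sigs.append(ExpressionSignature(str(sig_id), str(disease), tab))
    logger.info("read_signatures: %d signatures from %s", len(sigs), path)
    return sigs


def write_signatures(sigs: list[ExpressionSignature], path) -> None:
    frames = []
    for sig in sigs:
        t = sig.table.reset_index()
        t.columns = ["gene", "log2fc", "pvalue", "fdr"]
        t.insert(0, "signature_id", sig.signature_id)
        t.insert(1, "disease", sig.disease)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
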