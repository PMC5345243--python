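"""Count-level differential expression statistics.

The model is the standard negative-binomial generalized log-linear
model for RNA-seq counts: for gene g and sample i,

    y_gi ~ NB(mu_gi, phi_g),   log mu_gi = o_i + x_i' beta_g,

with offset o_i = log(effective library size), effective library size =
raw library size x TMM factor, and NB variance mu + phi mu^2. Contrasts
are tested by likelihood-ratio tests of nested designs at fixed
gene-wise dispersion, with Benjamini-Hochberg control of the FDR.

Gene-wise dispersions at n = 2 replicates per group are hopeless
without sharing information across genes, so phi_g is estimated by a
method-of-moments statistic per gene, smoothed into a mean-dispersion
trend by local regression on average log-cpm, and shrunk gene-wise
toward the trend by empirical-Bayes weighting with a fixed prior number
of degrees of freedom (default 10).

Everything is vectorized across genes: the IRLS normal equations for
all genes are assembled with einsum and solved as a batched linear
system, which keeps a 5000-gene x 14-contrast study in the seconds
range on one core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountMatrix

logger = logging.getLogger(__name__)

CPM_DETECTION_THRESHOLD = 0.25
DEG_FC = 2.0
DEG_FDR = 0.10

_ETA_CLIP = 30.0
_IRLS_TOL = 1e-8
_IRLS_MAXIT = 50


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------


def detect(cm: CountMatrix, contrast_samples=None,
           cpm_threshold: float = CPM_DETECTION_THRESHOLD) -> pd.Series:
    """Expression-detection mask for one contrast.

    A gene is detected if, in at least one of the contrast's samples,
    its counts-per-million (on the raw library size) exceed
    ``cpm_threshold`` and at least one read was observed — the latter
    standing in for a positive lower confidence bound on expression,
    which for a count is positive exactly when the count is.
    """
    if contrast_samples is None:
        contrast_samples = list(cm.samples)
    contrast_samples = list(contrast_samples)
    if not contrast_samples:
        raise ValueError("empty contrast")
    sub = cm.counts[contrast_samples]
    lib = sub.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("contrast contains a sample with zero library size")
    cpm = sub.to_numpy() / lib * 1e6
    ok = (cpm > cpm_threshold) & (sub.to_numpy() >= 1)
    return pd.Series(ok.any(axis=1), index=cm.genes, name="detected")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(y: np.ndarray, n: float, yr: np.ndarray, nr: float,
              trim_m: float, trim_a: float) -> float:
    use = (y > 0) & (yr > 0)
    if not use.any():
        raise ValueError("sample shares no expressed genes with the reference")
    y, yr = y[use].astype(float), yr[use].astype(float)
    m = np.log2((y / n) / (yr / nr))
    a = 0.5 * np.log2((y / n) * (yr / nr))
    # delta-method variance of M; weights are reciprocal variances
    v = (n - y) / (n * y) + (nr - yr) / (nr * yr)
    if np.allclose(m, 0.0, atol=1e-10):
        return 1.0
    k = len(m)
    lo_m = np.floor(k * trim_m) + 1
    hi_m = k + 1 - lo_m
    lo_a = np.floor(k * trim_a) + 1
    hi_a = k + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        logger.warning("TMM: trimming removed all genes; factor set to 1")
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    M (log-ratio) values versus a reference sample are trimmed by 30%
    on M and 5% on A (both tails), the survivors averaged with
    precision weights, and factors rescaled so their geometric mean is
    one. The reference is the sample whose upper-quartile cpm is
    closest to the mean upper-quartile (ties to the first sample).
    """
    if len(cm.samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes().to_numpy(dtype=float)
    if (counts.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero gene")
    if ref_sample is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                       for j in range(counts.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = list(cm.samples).index(ref_sample)
    factors = np.ones(len(cm.samples))
    for j in range(counts.shape[1]):
        if j == ref_j:
            continue
        try:
            factors[j] = _tmm_pair(counts[:, j], lib[j],
                                   counts[:, ref_j], lib[ref_j],
                                   trim_m, trim_a)
        except ValueError as err:
            raise ValueError(f"sample {cm.samples[j]!r}: {err}") from None
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def effective_library_sizes(cm: CountMatrix, norm: pd.Series | None = None) -> pd.Series:
    lib = cm.library_sizes().astype(float)
    if norm is not None:
        lib = lib * norm.reindex(lib.index)
    return lib


# ---------------------------------------------------------------------------
# NB GLM fitting
# ---------------------------------------------------------------------------


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Residual deviance per gene; phi broadcast over samples."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    small = phi <= 1e-12
    if np.all(small):
        dev = 2.0 * (ylogy - (y - mu))
    else:
        phi_safe = np.maximum(phi, 1e-12)
        nb = 2.0 * (ylogy - (y + 1.0 / phi_safe)
                    * np.log((1.0 + phi_safe * y) / (1.0 + phi_safe * mu)))
        pois = 2.0 * (ylogy - (y - mu))
        dev = np.where(np.broadcast_to(small, nb.shape), pois, nb)
    return dev.sum(axis=1)


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
          phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB log-linear model at fixed dispersion.

    Parameters: y (G x n) counts, X (n x p) design, offset (n,),
    phi (G,) dispersions. Returns (beta, mu, deviance, converged).
    """
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()
    # initialize from a least-squares fit on shifted log counts
    z0 = np.log(y + 0.5) - offset[None, :]
    beta = z0 @ np.linalg.pinv(X).T
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev = _nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(_IRLS_MAXIT):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi[idx, None] * mu_a)
        z = (eta[idx] - offset[None, :]) + (y[idx] - mu_a) / mu_a
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        xtwz = np.einsum("gn,ni->gi", w * z, X, optimize=True)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        try:
            beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(
                xtwx.reshape(-1, p), xtwz.reshape(-1, 1), rcond=None
            )[0].reshape(idx.size, p)
        beta[idx] = beta_new
        eta[idx] = np.clip(offset[None, :] + beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu[idx] = np.exp(eta[idx])
        new_dev = _nb_deviance(y[idx], mu[idx], phi[idx])
        rel = np.abs(new_dev - dev[idx]) / (np.abs(dev[idx]) + 1.0)
        dev[idx] = new_dev
        done = rel < _IRLS_TOL
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, mu, dev, converged


def average_log_cpm(counts: np.ndarray, eff_lib: np.ndarray,
                    prior: float = 0.5) -> np.ndarray:
    return np.log2((counts + prior) / (eff_lib[None, :] + 1.0) * 1e6).mean(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood (rows summed over samples)."""
    from scipy.special import gammaln

    mu = np.maximum(mu, 1e-10)
    if phi <= 1e-12:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        r = 1.0 / phi
        ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
              + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=1)


def _cox_reid_apl(counts: np.ndarray, X: np.ndarray, offset: np.ndarray,
                  phi: float) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi, per gene.

    APL(phi) = ll(beta_hat(phi); phi) - 0.5 log det(X' W X), the
    adjustment integrating out the per-gene coefficients.
    """
    G = counts.shape[0]
    beta, mu, _, _ = _irls(counts, X, offset, np.full(G, phi))
    w = mu / (1.0 + phi * mu)
    xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
    xtwx += 1e-10 * np.eye(X.shape[1])[None, :, :]
    _, logdet = np.linalg.slogdet(xtwx)
    return _nb_loglik(counts, mu, phi) - 0.5 * logdet


_PHI_GRID = np.concatenate([[1e-5], np.geomspace(1e-3, 20.0, 29)])


def _grid_argmax(score: np.ndarray, log_grid: np.ndarray) -> np.ndarray:
    """Quadratic-interpolated argmax of per-gene score curves on a grid."""
    j = np.argmax(score, axis=1)
    j = np.clip(j, 1, score.shape[1] - 2)
    s0 = np.take_along_axis(score, (j - 1)[:, None], axis=1)[:, 0]
    s1 = np.take_along_axis(score, j[:, None], axis=1)[:, 0]
    s2 = np.take_along_axis(score, (j + 1)[:, None], axis=1)[:, 0]
    denom = s0 - 2.0 * s1 + s2
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * (s0 - s2) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
                     0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = log_grid[1:] - log_grid[:-1]
    # local grid spacing around j (grid is geometric => uniform in log)
    h = step[np.clip(j - 1, 0, len(step) - 1)]
    logphi = log_grid[j] + shift * h
    # genes whose maximum sits at a grid end stay there
    jraw = np.argmax(score, axis=1)
    logphi = np.where(jraw == 0, log_grid[0], logphi)
    logphi = np.where(jraw == score.shape[1] - 1, log_grid[-1], logphi)
    return np.exp(logphi)


def estimate_dispersion(
    counts: np.ndarray, X: np.ndarray, eff_lib: np.ndarray,
    prior_df: float = 10.0, span: float = 0.10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cox-Reid APL dispersion with trend and EB shrinkage.

    The adjusted profile likelihood of every gene is evaluated on a
    fixed dispersion grid. The mean-dispersion trend maximizes, at each
    gene, a moving average of the APL curves of the genes nearest in
    average log-cpm (window = ``span`` of all genes). The gene-wise
    estimate maximizes the weighted sum

        APL_g(phi) + (prior_df / df_resid) * local mean APL(phi),

    which shrinks each gene toward its neighbourhood — the weighted-
    likelihood empirical-Bayes scheme with ``prior_df`` prior degrees
    of freedom. Returns (phi_tagwise, phi_trend, phi_raw_tagwise).
    """
    from scipy.ndimage import uniform_filter1d

    G, n = counts.shape
    p = X.shape[1]
    df_resid = max(n - p, 1)
    offset = np.log(eff_lib)
    counts = counts.astype(float)

    apl = np.empty((G, len(_PHI_GRID)))
    for k, phi in enumerate(_PHI_GRID):
        apl[:, k] = _cox_reid_apl(counts, X, offset, float(phi))

    logcpm = average_log_cpm(counts, eff_lib)
    order = np.argsort(logcpm)
    width = max(int(span * G), 21)
    local = np.empty_like(apl)
    local[order] = uniform_filter1d(apl[order], size=width, axis=0,
                                    mode="nearest")
    log_grid = np.log(_PHI_GRID)
    phi_trend = _grid_argmax(local, log_grid)
    phi_raw = _grid_argmax(apl, log_grid)

    prior_n = prior_df / df_resid
    phi_tag = _grid_argmax(apl + prior_n * local, log_grid)
    return phi_tag, phi_trend, phi_raw


@dataclass
class NBFit:
    """Fitted NB GLMs for all tested genes of one contrast.

    beta is on the natural-log scale (divide by ln 2 for log2 units).
    """

    genes: pd.Index
    design: np.ndarray
    offsets: np.ndarray
    counts: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    deviance: np.ndarray
    dispersion: np.ndarray
    logcpm: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        if (self.dispersion < 0).any():
            raise ValueError("negative dispersion")


def fit_nb(
    cm: CountMatrix,
    design_matrix: np.ndarray,
    norm: pd.Series | None = None,
    mask: pd.Series | None = None,
    prior_df: float = 10.0,
    dispersion: np.ndarray | float | None = None,
) -> NBFit:
    """Fit per-gene NB GLMs with offsets = log effective library size.

    ``mask`` restricts fitting to detected genes. ``dispersion`` may be
    supplied to bypass estimation (e.g., for simulations with known
    phi); otherwise it is estimated by :func:`estimate_dispersion`.
    """
    X = np.asarray(design_matrix, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if mask is None:
        mask = pd.Series(True, index=cm.genes)
    genes = cm.genes[mask.reindex(cm.genes).to_numpy()]
    counts = cm.counts.loc[genes].to_numpy(dtype=float)
    eff_lib = effective_library_sizes(cm, norm).to_numpy(dtype=float)
    if counts.shape[1] != X.shape[0]:
        raise ValueError("design matrix rows must match sample count")
    offset = np.log(eff_lib)

    if dispersion is None:
        phi, _, _ = estimate_dispersion(counts, X, eff_lib, prior_df=prior_df)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float),
                              (len(genes),)).copy()
        if (phi < 0).any():
            raise ValueError("dispersion must be >= 0")

    beta, mu, dev, conv = _irls(counts, X, offset, phi)
    n_bad = int((~conv).sum())
    if n_bad:
        logger.warning("fit_nb: %d genes did not converge in %d iterations",
                       n_bad, _IRLS_MAXIT)
    return NBFit(
        genes=pd.Index(genes), design=X, offsets=offset, counts=counts,
        beta=beta, mu=mu, deviance=dev, dispersion=phi,
        logcpm=average_log_cpm(counts, eff_lib), converged=conv,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio testing
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-gene differential-expression summary for one contrast.

    ``table`` is indexed by gene with columns log2fc, lrt, pvalue, fdr,
    logcpm, detected; undetected genes carry NaN statistics.
    """

    table: pd.DataFrame
    contrast: str = ""

    def __len__(self) -> int:
        return len(self.table)

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["detected"]]

    def fc_series(self) -> pd.Series:
        """log2FC of tested genes, indexed by gene symbol."""
        return self.tested["log2fc"]


def _nested_rank(full: np.ndarray, reduced: np.ndarray) -> int:
    rf = np.linalg.matrix_rank(full)
    rr = np.linalg.matrix_rank(reduced)
    if np.linalg.matrix_rank(np.hstack([full, reduced])) > rf:
        raise ValueError("reduced design is not nested in the full design")
    return rf - rr


def _dropped_column(full: np.ndarray, reduced: np.ndarray) -> int | None:
    """Index of the single full-design column absent from the reduced one."""
    red_cols = [tuple(reduced[:, j]) for j in range(reduced.shape[1])]
    dropped = [j for j in range(full.shape[1])
               if tuple(full[:, j]) not in red_cols]
    return dropped[0] if len(dropped) == 1 else None


def lrt(
    fit: NBFit,
    reduced_design: np.ndarray,
    all_genes: pd.Index | None = None,
    contrast: str = "",
    coef: int | None = None,
    fc_prior_count: float = 0.125,
) -> DEResult:
    """Likelihood-ratio test of the full fit against a nested design.

    At fixed gene-wise dispersion the LRT statistic equals the drop in
    residual deviance; p-values come from chi-square with df equal to
    the rank difference. log2fc reports the coefficient the reduced
    design drops (or ``coef`` if given), in log2 units, computed from a
    refit with a small library-size-scaled prior count
    (``fc_prior_count``) so fold changes of all-zero groups stay
    finite; the test statistic itself is never penalized.
    """
    Xr = np.asarray(reduced_design, dtype=float)
    df = _nested_rank(fit.design, Xr)
    genes_tested = fit.genes[fit.converged]
    counts = fit.counts[fit.converged]
    phi = fit.dispersion[fit.converged]
    dev_full = fit.deviance[fit.converged]
    if (~fit.converged).any():
        logger.warning("lrt: %d unconverged genes excluded",
                       int((~fit.converged).sum()))
    if df == 0:
        stat = np.zeros(len(genes_tested))
        pvals = np.ones(len(genes_tested))
    else:
        _, _, dev_red, _ = _irls(counts, Xr, fit.offsets, phi)
        stat = np.maximum(dev_red - dev_full, 0.0)
        pvals = stats.chi2.sf(stat, df)
    fdr = bh_adjust(pvals)

    if coef is None:
        coef = _dropped_column(fit.design, Xr)
    if coef is not None:
        if fc_prior_count > 0:
            lib = np.exp(fit.offsets)
            adj = fc_prior_count * lib / lib.mean()
            off2 = np.log(lib + 2.0 * adj)
            beta_s, _, _, _ = _irls(counts + adj[None, :], fit.design,
                                    off2, phi)
            log2fc = beta_s[:, coef] / np.log(2.0)
        else:
            log2fc = fit.beta[fit.converged, coef] / np.log(2.0)
    else:
        log2fc = np.full(len(genes_tested), np.nan)

    tested = pd.DataFrame(
        {"log2fc": log2fc, "lrt": stat, "pvalue": pvals, "fdr": fdr,
         "logcpm": fit.logcpm[fit.converged], "detected": True},
        index=genes_tested,
    )
    if all_genes is not None:
        tested = tested.reindex(all_genes)
        tested["detected"] = (tested["detected"] == True)  # noqa: E712 — NaN -> False
    tested.index.name = "gene"
    return DEResult(table=tested, contrast=contrast)


def treatment_design(design: pd.DataFrame, treated_label: str = "IMQ") -> np.ndarray:
    """Intercept + treatment-indicator design for a two-group contrast."""
    trt = (design["treatment"] == treated_label).astype(float).to_numpy()
    return np.column_stack([np.ones(len(design)), trt])


def de_contrast(
    cm: CountMatrix, strain: str, sex: str,
    prior_df: float = 10.0, dispersion=None,
) -> DEResult:
    """IMQ-vs-CTL differential expression within one strain-sex group.

    Runs the full chain for the four samples of the group: detection
    filter, TMM factors, NB GLM fit, LRT on the treatment coefficient,
    BH adjustment.
    """
    samples = cm.group_samples(strain, sex)
    if not samples:
        raise ValueError(f"no samples for strain={strain!r}, sex={sex!r}")
    sub = cm.subset_samples(samples)
    if set(sub.design["treatment"]) != {"CTL", "IMQ"}:
        raise ValueError(f"group {strain}/{sex} lacks one of the treatments")
    mask = detect(sub)
    norm = tmm_factors(sub)
    X_full = treatment_design(sub.design)
    X_red = X_full[:, :1]
    fit = fit_nb(sub, X_full, norm=norm, mask=mask, prior_df=prior_df,
                 dispersion=dispersion)
    res = lrt(fit, X_red, all_genes=cm.genes, contrast=f"{strain}_{sex}")
    logger.info("de_contrast %s/%s: %d detected of %d genes",
                strain, sex, int(mask.sum()), len(cm.genes))
    return res


def interaction_test(
    cm: CountMatrix, strain: str, prior_df: float = 10.0, dispersion=None,
) -> DEResult:
    """Sex x treatment interaction LRT within one strain.

    Full model: sex + treatment + sex:treatment; reduced: sex +
    treatment. Genes at FDR < 0.10 are the sex-dependent responders.
    """
    d = cm.design
    samples = [s for s in cm.samples if d.loc[s, "strain"] == strain]
    if not samples:
        raise ValueError(f"no samples for strain {strain!r}")
    sub = cm.subset_samples(samples)
    if set(sub.design["sex"]) != {"F", "M"}:
        raise ValueError(f"strain {strain!r} does not include both sexes")
    if set(sub.design["treatment"]) != {"CTL", "IMQ"}:
        raise ValueError(f"strain {strain!r} does not include both treatments")
    sex = (sub.design["sex"] == "M").astype(float).to_numpy()
    trt = (sub.design["treatment"] == "IMQ").astype(float).to_numpy()
    X_full = np.column_stack([np.ones(len(sub.design)), sex, trt, sex * trt])
    X_red = X_full[:, :3]
    mask = detect(sub)
    norm = tmm_factors(sub)
    fit = fit_nb(sub, X_full, norm=norm, mask=mask, prior_df=prior_df,
                 dispersion=dispersion)
    return lrt(fit, X_red, all_genes=cm.genes,
               contrast=f"{strain}_interaction", coef=3)


# ---------------------------------------------------------------------------
# FDR, DEG calling, tallies, qPCR fold change
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving with the input; adjusted value for the i-th
    smallest p is min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(de: DEResult, fc: float = DEG_FC, fdr: float = DEG_FDR
              ) -> tuple[set[str], set[str]]:
    """DEG calling at the study thresholds (strict inequalities).

    increased: fold change > ``fc`` and FDR < ``fdr``;
    decreased: fold change < 1/``fc`` and FDR < ``fdr``.
    """
    t = de.tested.dropna(subset=["log2fc", "fdr"])
    ratio = np.exp2(t["log2fc"])
    inc = set(t.index[(ratio > fc) & (t["fdr"] < fdr)])
    dec = set(t.index[(ratio < 1.0 / fc) & (t["fdr"] < fdr)])
    return inc, dec


def deg_frequency(deg_sets: dict[str, tuple[set[str], set[str]]],
                  genes: pd.Index) -> pd.DataFrame:
    """Per-gene count of strain-sex combinations calling it a DEG."""
    if not deg_sets:
        raise ValueError("need at least one combination")
    inc = pd.Series(0, index=genes, dtype=int)
    dec = pd.Series(0, index=genes, dtype=int)
    for inc_set, dec_set in deg_sets.values():
        inc[inc.index.isin(inc_set)] += 1
        dec[dec.index.isin(dec_set)] += 1
    out = pd.DataFrame({"increased_in": inc, "decreased_in": dec})
    out.index.name = "gene"
    return out


def ddct(ct_target_sample: float, ct_ref_sample: float,
         ct_target_calibrator: float, ct_ref_calibrator: float) -> float:
    """qPCR relative fold change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(endogenous control) within each condition;
    ddCt = dCt(sample) - dCt(calibrator); FC = 2^-ddCt.
    """
    vals = (ct_target_sample, ct_ref_sample,
            ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    dd = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-dd))


def relative_expression_log2(ct_ref: float, ct_target: float) -> float:
    """Log2 relative expression: control-gene Ct minus target Ct."""
    return float(ct_ref - ct_target)
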