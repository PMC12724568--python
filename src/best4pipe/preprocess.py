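"""QC filtering, log-normalization, variable-gene selection, scaling, PCA.

The defaults reproduce a standard droplet scRNA-seq preprocessing recipe:
cells are dropped for too few genes/UMIs (<= 200), suspiciously high
complexity (>= 3500 genes, >= 3000 or 3500 UMIs depending on profile), or
high mitochondrial content (>= 20%); counts are log-normalized to 1e4 per
cell; the top 2000 variable genes are selected by raw standard deviation or
a variance-stabilizing (mean-variance trend) criterion; normalized values
are regressed against mitochondrial and ribosomal content, z-scored, and
clipped; 30 principal components feed the downstream embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from best4pipe.data_io import ExpressionDataset, NORM_SCALE

logger = logging.getLogger("best4pipe")


@dataclass
class QCProfile:
    """Cell-level QC thresholds. Both stated bounds are inclusive failures:
    a cell fails with <= min_genes detected genes or >= max_genes, and the
    same semantics for UMIs and the mitochondrial percentage."""

    min_genes: int = 200
    max_genes: int = 3500
    min_umis: int = 200
    max_umis: int = 3000
    max_mito_pct: float = 20.0
    mito_prefix: str = "mt-"
    ribo_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if self.min_umis >= self.max_umis:
            raise ValueError("min_umis must be < max_umis")


def load_ribo_genes() -> tuple[str, ...]:
    """The shipped zebrafish ribosomal gene list used as a QC covariate."""
    path = Path(__file__).parent / "data" / "ribo_genes_zebrafish.txt"
    return tuple(path.read_text().split())


#: the two shipped experiment profiles differ only in the UMI cap
QC_PROFILES = {
    "pbx3a": QCProfile(max_umis=3000, ribo_genes=load_ribo_genes()),
    "meis1b": QCProfile(max_umis=3500, ribo_genes=load_ribo_genes()),
}


@dataclass
class EmbeddingResult:
    """Per-cell principal-component coordinates with explained variance."""

    pcs: np.ndarray  # cells x n_pcs
    explained_variance: np.ndarray
    cell_ids: np.ndarray
    hvg_ids: Sequence[str] = field(default_factory=list)
    loadings: np.ndarray | None = None
    scaled_residual_clip: float = 10.0


def _dense(counts) -> np.ndarray:
    return counts.toarray() if sp.issparse(counts) else np.asarray(counts)


def mito_pct(ds: ExpressionDataset, prefix: str = "mt-") -> np.ndarray:
    """Percent of each cell's counts from genes whose id starts with prefix."""
    is_mito = np.array([str(g).startswith(prefix) for g in ds.gene_ids])
    total = np.asarray(ds.counts.sum(axis=1)).ravel()
    mito = np.asarray(ds.counts[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(ds.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return pct


def gene_set_pct(ds: ExpressionDataset, genes: Sequence[str]) -> np.ndarray:
    """Percent of counts from an explicit gene list (e.g. ribosomal genes)."""
    wanted = set(genes)
    mask = np.array([g in wanted for g in ds.gene_ids])
    total = np.asarray(ds.counts.sum(axis=1)).ravel()
    part = np.asarray(ds.counts[:, mask].sum(axis=1)).ravel() if mask.any() else np.zeros(ds.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, 100.0 * part / total, 0.0)


def qc_filter(ds: ExpressionDataset, profile: QCProfile) -> ExpressionDataset:
    """Drop cells failing any QC rule; logs a per-rule failure breakdown.

    Raises if no cell survives (with the breakdown in the message).
    """
    n_genes_det = np.asarray((ds.counts > 0).sum(axis=1)).ravel()
    n_umis = np.asarray(ds.counts.sum(axis=1)).ravel()
    mito = mito_pct(ds, profile.mito_prefix)

    fails = {
        "low_genes": n_genes_det <= profile.min_genes,
        "high_genes": n_genes_det >= profile.max_genes,
        "low_umis": n_umis <= profile.min_umis,
        "high_umis": n_umis >= profile.max_umis,
        "high_mito": mito >= profile.max_mito_pct,
    }
    breakdown = {rule: int(m.sum()) for rule, m in fails.items()}
    keep = ~np.logical_or.reduce(list(fails.values()))
    logger.info("qc_filter: %d/%d cells pass; failures %s", keep.sum(), ds.n_cells, breakdown)
    if not keep.any():
        raise ValueError(f"qc_filter removed every cell; per-rule failures: {breakdown}")
    return ds.subset_cells(keep)


def log_normalize(ds: ExpressionDataset, scale: float = NORM_SCALE) -> ExpressionDataset:
    """norm[c,g] = ln(1 + scale * counts[c,g] / total[c]).

    Cells with zero total get an all-zero row and a warning. The layer
    satisfies sum_g expm1(norm[c,g]) = scale for every nonzero cell.
    """
    counts = _dense(ds.counts).astype(float)
    total = counts.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.warning("log_normalize: %d cell(s) with zero total counts", int(zero.sum()))
    safe_total = np.where(zero, 1.0, total)
    norm = np.log1p(scale * counts / safe_total[:, None])
    norm[zero] = 0.0
    return ds.copy_with(norm=norm)


def select_hvg(ds: ExpressionDataset, n: int = 2000, method: str = "sd") -> list[str]:
    """Top-n highly variable genes.

    ``sd``: rank genes by the standard deviation of the normalized layer
    (the simple criterion used for datasets without a fitted trend).
    ``vst``: fit log10(variance) ~ poly2(log10(mean)) on raw counts,
    standardize each gene's counts by its fitted sd, clip at sqrt(n_cells),
    and rank by the variance of the clipped values.
    """
    if method not in ("sd", "vst"):
        raise ValueError(f"unknown HVG method {method!r}")
    if n >= ds.n_genes:
        if n > ds.n_genes:
            logger.warning("select_hvg: n=%d > %d genes; returning all", n, ds.n_genes)
        order = np.argsort(ds.gene_ids.astype(str))
        return list(ds.gene_ids[order])

    if method == "sd":
        norm = ds.norm_or_raise()
        score = norm.std(axis=0)
    else:
        counts = _dense(ds.counts).astype(float)
        mean = counts.mean(axis=0)
        var = counts.var(axis=0, ddof=1)
        usable = (mean > 0) & (var > 0)
        coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), deg=2)
        fitted_sd = np.ones_like(mean)
        fitted_sd[usable] = np.sqrt(10.0 ** np.polyval(coef, np.log10(mean[usable])))
        clip = np.sqrt(ds.n_cells)
        z = np.clip((counts - mean) / fitted_sd, -clip, clip)
        score = z.var(axis=0, ddof=1)
        score[~usable] = 0.0

    # stable top-n: descending score, gene id as deterministic tie-break
    order = np.lexsort((ds.gene_ids.astype(str), -score))
    return list(ds.gene_ids[order[:n]])


def scale_regress(
    ds: ExpressionDataset,
    covariates: dict[str, np.ndarray] | None = None,
    genes: Sequence[str] | None = None,
    clip: float = 10.0,
) -> np.ndarray:
    """Per-gene OLS residuals against cell covariates, z-scored and clipped.

    Each gene's normalized values are regressed (with intercept) on the
    covariate columns; residuals are divided by their standard deviation and
    clipped to +/- ``clip``. Constant covariates are dropped with a warning.
    """
    norm = ds.norm_or_raise()
    if genes is not None:
        cols = [ds.gene_index(g) for g in genes]
        norm = norm[:, cols]
    covariates = covariates or {}
    design_cols = [np.ones(ds.n_cells)]
    for name, vals in covariates.items():
        vals = np.asarray(vals, dtype=float)
        if np.ptp(vals) == 0:
            logger.warning("scale_regress: covariate %r is constant; dropped", name)
            continue
        design_cols.append(vals)
    X = np.column_stack(design_cols)
    beta, *_ = np.linalg.lstsq(X, norm, rcond=None)
    resid = norm - X @ beta
    sd = resid.std(axis=0, ddof=0)
    # residuals that are numerically zero (gene fully explained by the
    # design) must scale to zero, not to amplified rounding noise
    degenerate = sd <= 1e-10 * max(1.0, float(np.abs(norm).max()))
    sd[degenerate] = 1.0
    out = np.clip(resid / sd, -clip, clip)
    out[:, degenerate] = 0.0
    return out


def run_pca(scaled: np.ndarray, n_pcs: int = 30, cell_ids: np.ndarray | None = None) -> EmbeddingResult:
    """Principal components by SVD of the column-centered matrix.

    Deterministic sign convention: each component's largest-magnitude gene
    loading is positive. Explained variances are the covariance eigenvalues
    (ddof = 1).
    """
    scaled = np.asarray(scaled, dtype=float)
    if not np.all(np.isfinite(scaled)):
        raise ValueError("scaled matrix contains non-finite values")
    n_cells, n_genes = scaled.shape
    max_pcs = min(n_cells, n_genes)
    if n_pcs > max_pcs:
        logger.warning("run_pca: n_pcs=%d reduced to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    centered = scaled - scaled.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # sign: largest-|loading| entry of each component positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    pcs = U * S
    explained = S**2 / max(n_cells - 1, 1)
    if cell_ids is None:
        cell_ids = np.arange(n_cells)
    return EmbeddingResult(
        pcs=pcs,
        explained_variance=explained,
        cell_ids=np.asarray(cell_ids),
        loadings=Vt.T,
    )


def standard_embedding(
    ds: ExpressionDataset,
    n_hvg: int = 2000,
    hvg_method: str = "sd",
    n_pcs: int = 30,
    ribo_genes: Sequence[str] = (),
    mito_prefix: str = "mt-",
    clip: float = 10.0,
) -> EmbeddingResult:
    """The full normalize -> HVG -> regress/scale -> PCA recipe in one call."""
    if ds.norm is None:
        ds = log_normalize(ds)
    hvg = select_hvg(ds, n=n_hvg, method=hvg_method)
    covs = {
        "mito_pct": mito_pct(ds, mito_prefix),
        "ribo_pct": gene_set_pct(ds, ribo_genes),
    }
    scaled = scale_regress(ds, covariates=covs, genes=hvg, clip=clip)
    res = run_pca(scaled, n_pcs=n_pcs, cell_ids=ds.cell_ids)
    res.hvg_ids = hvg
    return res
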