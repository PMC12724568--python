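"""Diffusion-map fate-bias selection for a mutant-vs-wild-type design.

The question: when a mutation removes a terminal cell type (best4+), do any
mutant progenitors still shift toward that fate? Cells are embedded with a
diffusion map (locally scaled Gaussian kernel on a kNN graph in PC space,
density-normalized with alpha = 1), each secretory progenitor is ranked by
its Euclidean distance in DC1-DC2 to the centroid of the wild-type best4+
cluster, the closest quartile per genotype is called "biased", and the
selected sets are contrasted by differential expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from best4pipe.data_io import ExpressionDataset
from best4pipe.markers import MarkerThresholds, contrast_cell_sets


@dataclass
class DiffusionConfig:
    k_neighbors: int = 30
    n_input_pcs: int = 30
    n_dcs_kept: int = 10
    distance_dcs: int = 2
    bias_quantile: float = 0.25
    local_sigma_rank: int | None = None  # default ceil(k/2)
    scale_by_eigenvalues: bool = False

    def __post_init__(self) -> None:
        if self.distance_dcs > self.n_dcs_kept:
            raise ValueError("distance_dcs must be <= n_dcs_kept")
        if not 0 < self.bias_quantile <= 1:
            raise ValueError("bias_quantile must lie in (0,1]")

    @property
    def sigma_rank(self) -> int:
        return self.local_sigma_rank or math.ceil(self.k_neighbors / 2)


@dataclass
class DiffusionResult:
    dcs: np.ndarray  # cells x n_dcs_kept (trivial component excluded)
    eigenvalues: np.ndarray
    cell_ids: np.ndarray
    distances: pd.Series | None = None
    biased: pd.Series | None = None


def _knn_kernel(pcs: np.ndarray, cfg: DiffusionConfig) -> sp.csr_matrix:
    """Symmetric locally scaled Gaussian kernel on the union kNN graph."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist[:, cfg.sigma_rank - 1]
    sigma = np.maximum(sigma, 1e-12)

    rows = np.repeat(np.arange(n), cfg.k_neighbors)
    cols = idx.ravel()
    d = dist.ravel()
    adj = sp.coo_matrix((d, (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # union of directed edges
    adj = adj.tocoo()
    w = np.exp(-(adj.data**2) / (sigma[adj.row] * sigma[adj.col]))
    kernel = sp.coo_matrix((w, (adj.row, adj.col)), shape=(n, n)).tocsr()
    kernel = kernel + sp.identity(n, format="csr")  # d_ii = 0 -> w_ii = 1
    return kernel


def diffusion_map(
    pcs: np.ndarray, cfg: DiffusionConfig | None = None, cell_ids=None
) -> DiffusionResult:
    """Diffusion components of cells embedded in PC space.

    Kernel w_ij = exp(-d_ij^2 / (sigma_i sigma_j)) on the union kNN graph
    with sigma_i the distance to the ``sigma_rank``-th neighbor; density
    normalization divides by the product of row sums (alpha = 1); the
    row-normalized Markov matrix's right eigenvectors 2..n_dcs_kept+1,
    ordered by decreasing eigenvalue, are the DCs. Sign is fixed so each
    DC's largest-magnitude entry is positive.
    """
    cfg = cfg or DiffusionConfig()
    pcs = np.asarray(pcs, dtype=float)[:, : cfg.n_input_pcs]
    n = pcs.shape[0]
    if n < cfg.k_neighbors + 1:
        raise ValueError(f"need >= k_neighbors+1 = {cfg.k_neighbors + 1} cells, got {n}")
    kernel = _knn_kernel(pcs, cfg)

    n_comp, labels = connected_components(kernel, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"kNN graph is disconnected; component sizes {sizes}")

    q = np.asarray(kernel.sum(axis=1)).ravel()
    inv_q = sp.diags(1.0 / q)
    ktilde = inv_q @ kernel @ inv_q  # alpha = 1 density normalization
    d = np.asarray(ktilde.sum(axis=1)).ravel()
    d_isqrt = sp.diags(1.0 / np.sqrt(d))
    sym = (d_isqrt @ ktilde @ d_isqrt).toarray()
    sym = (sym + sym.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov matrix P = D^-1 Ktilde
    psi = (1.0 / np.sqrt(d))[:, None] * evecs
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)

    keep = slice(1, cfg.n_dcs_kept + 1)  # drop the trivial constant component
    dcs = psi[:, keep].copy()
    lams = evals[keep].copy()
    for k in range(dcs.shape[1]):
        j = np.argmax(np.abs(dcs[:, k]))
        if dcs[j, k] < 0:
            dcs[:, k] *= -1
    if cfg.scale_by_eigenvalues:
        dcs = dcs * lams
    if cell_ids is None:
        cell_ids = np.array([str(i) for i in range(n)], dtype=object)
    return DiffusionResult(dcs=dcs, eigenvalues=lams, cell_ids=np.asarray(cell_ids, dtype=object))


def centroid_distance(
    dm: DiffusionResult,
    reference_cells,
    query_cells=None,
    cfg: DiffusionConfig | None = None,
) -> pd.Series:
    """Euclidean distance of each query cell to the reference centroid.

    Computed in the first ``distance_dcs`` diffusion components (default
    DC1-DC2); the centroid is the mean of the reference cells. The result is
    also stored on ``dm.distances``.
    """
    cfg = cfg or DiffusionConfig()
    ids = pd.Index(dm.cell_ids)
    ref = ids.get_indexer(pd.Index(reference_cells))
    if len(ref) == 0 or (ref < 0).any():
        raise ValueError("reference cells empty or not all present in the embedding")
    sub = dm.dcs[:, : cfg.distance_dcs]
    centroid = sub[ref].mean(axis=0)
    if query_cells is None:
        q_idx = np.arange(len(ids))
        q_ids = dm.cell_ids
    else:
        q_idx = ids.get_indexer(pd.Index(query_cells))
        if (q_idx < 0).any():
            raise ValueError("query cells not all present in the embedding")
        q_ids = np.asarray(list(query_cells), dtype=object)
    dist = np.linalg.norm(sub[q_idx] - centroid, axis=1)
    out = pd.Series(dist, index=q_ids, name="distance")
    dm.distances = out
    return out


def select_biased(distances: pd.Series, group, q: float = 0.25) -> list[str]:
    """The ceil(q*|group|) group cells closest to the reference centroid.

    Boundary ties are broken by cell id for determinism.
    """
    group = list(group)
    if not group:
        raise ValueError("select_biased requires a non-empty group")
    missing = [c for c in group if c not in distances.index]
    if missing:
        raise ValueError(f"cells without distances: {missing[:5]}")
    n_take = math.ceil(q * len(group))
    ranked = sorted(group, key=lambda c: (distances[c], c))
    return ranked[:n_take]


def bias_contrast(
    ds: ExpressionDataset,
    sel_wt,
    sel_mut,
    ref_cells,
    thresholds: MarkerThresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """The three DE contrasts among selected progenitors and reference cells.

    Keys: ``wt_vs_mut`` (selected WT vs selected MUT progenitors),
    ``wt_vs_ref`` and ``mut_vs_ref`` (each selection vs the reference
    cluster); "up" = higher in the first-named set.
    """
    thresholds = thresholds or MarkerThresholds()
    for name, cells in (("sel_wt", sel_wt), ("sel_mut", sel_mut), ("ref_cells", ref_cells)):
        if len(list(cells)) < 3:
            raise ValueError(f"{name} has fewer than 3 cells")
    return {
        "wt_vs_mut": contrast_cell_sets(ds, sel_wt, sel_mut, thresholds, label="wt_vs_mut"),
        "wt_vs_ref": contrast_cell_sets(ds, sel_wt, ref_cells, thresholds, label="wt_vs_ref"),
        "mut_vs_ref": contrast_cell_sets(ds, sel_mut, ref_cells, thresholds, label="mut_vs_ref"),
    }


def run_fate_bias(
    ds: ExpressionDataset,
    pcs: np.ndarray,
    cfg: DiffusionConfig | None = None,
    reference_cluster: str = "best4",
    progenitor_cluster: str = "progenitor",
    thresholds: MarkerThresholds | None = None,
) -> dict:
    """Full fate-bias analysis on one jointly embedded WT+MUT dataset.

    The reference centroid is the wild-type reference cluster; the top
    ``bias_quantile`` of each genotype's progenitors closest to it are
    selected and contrasted. Returns the embedding, per-cell distances,
    selections, and DE tables.
    """
    cfg = cfg or DiffusionConfig()
    if ds.norm is None:
        from best4pipe.preprocess import log_normalize

        ds = log_normalize(ds)
    dm = diffusion_map(pcs, cfg, cell_ids=ds.cell_ids)
    meta = ds.cell_meta
    ref_mask = (meta["cluster"] == reference_cluster) & (meta["genotype"] == "WT")
    if not ref_mask.any():
        raise ValueError(f"no WT cells in reference cluster {reference_cluster!r}")
    ref_cells = list(meta.index[ref_mask])
    dist = centroid_distance(dm, ref_cells, cfg=cfg)

    selections: dict[str, list[str]] = {}
    for genotype in ("WT", "MUT"):
        grp = meta.index[
            (meta["cluster"] == progenitor_cluster) & (meta["genotype"] == genotype)
        ]
        selections[genotype] = select_biased(dist, list(grp), q=cfg.bias_quantile)
    biased = pd.Series(False, index=pd.Index(ds.cell_ids))
    biased[selections["WT"] + selections["MUT"]] = True
    dm.biased = biased

    contrasts = bias_contrast(
        ds, selections["WT"], selections["MUT"], ref_cells, thresholds
    )
    return {
        "diffusion": dm,
        "distances": dist,
        "selected_wt": selections["WT"],
        "selected_mut": selections["MUT"],
        "reference_cells": ref_cells,
        "contrasts": contrasts,
    }
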