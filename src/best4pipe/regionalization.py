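"""Within-cell-type spatial regionalization scored against an anchor gene.

Position along the gut is latent; the only spatial handle is an anchor gene
with known regionalized expression (otop2, anterior in the larval zebrafish
intestine). Genes are scored by their correlation with the anchor across the
cells of one cluster, with significance from a permutation null (robust to
dropout-heavy zero-inflated values), and compared across datasets by
contrast-mode differential expression plus an ortholog-family join.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from best4pipe.data_io import ExpressionDataset, OrthologTable
from best4pipe.markers import MarkerThresholds, _two_group_table

logger = logging.getLogger("best4pipe")


def _standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (z, nonconstant mask). Constant -> 0."""
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(mat, dtype=float)
    z[:, ok] = (mat[:, ok] - mu[ok]) / sd[ok]
    return z, ok


def anchor_correlation(
    ds: ExpressionDataset,
    cluster: str,
    anchor: str,
    method: str = "pearson",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlation of every gene with the anchor within one cluster.

    ``method`` is ``pearson`` (on log-normalized values) or ``spearman``
    (rank-transformed first). p-values come from ``n_perm`` permutations of
    the anchor with an add-one correction, p = (1 + #{|r_perm| >= |r|}) /
    (n_perm + 1), so the minimum attainable p is 1/(n_perm+1). Calls are
    ``correlated`` / ``anti_correlated`` when p < ``alpha``, else ``none``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if anchor not in set(ds.gene_ids):
        raise ValueError(f"anchor gene {anchor!r} not in dataset")
    mask = ds.cells_in_cluster(cluster)
    if mask.sum() < 5:
        raise ValueError(f"cluster {cluster!r} has {int(mask.sum())} cells; need >= 5")
    j = ds.gene_index(anchor)
    anchor_counts = np.asarray(ds.counts[mask][:, j].todense()).ravel()
    if (anchor_counts > 0).sum() < 5:
        raise ValueError(f"anchor {anchor!r} expressed in < 5 cells of {cluster!r}")

    norm = ds.norm_or_raise()[mask]
    n = norm.shape[0]
    if method == "spearman":
        norm = np.apply_along_axis(rankdata, 0, norm)
    z, ok = _standardize(norm)
    za = z[:, j]
    r = z.T @ za / n  # pearson r against the anchor, 0 where constant

    rng = np.random.default_rng(seed)
    exceed = np.zeros(norm.shape[1], dtype=int)
    abs_r = np.abs(r)
    for _ in range(n_perm):
        perm = rng.permutation(za)
        r_perm = z.T @ perm / n
        exceed += np.abs(r_perm) >= abs_r - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)

    call = np.where(
        (p < alpha) & ok, np.where(r > 0, "correlated", "anti_correlated"), "none"
    )
    out = pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "r": r,
            "p": p,
            "n_cells": n,
            "call": call,
        }
    )
    return out.sort_values("gene", kind="mergesort").reset_index(drop=True)


def regional_contrast(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    cluster: str,
    thresholds: MarkerThresholds | None = None,
) -> pd.DataFrame:
    """Contrast-mode DE between the same cluster of two regional datasets.

    "up" means higher in ``ds_a``; the expressing-fraction gap rule is not
    applied (same semantics as genotype contrasts).
    """
    thresholds = thresholds or MarkerThresholds()
    m_a = ds_a.cells_in_cluster(cluster)
    m_b = ds_b.cells_in_cluster(cluster)
    if not m_a.any() or not m_b.any():
        raise ValueError(f"cluster {cluster!r} empty in one region")
    return _two_group_table(ds_a, m_a, ds_b, m_b, thresholds, cluster, mode="contrast")


def join_regional_programs(
    contrast: pd.DataFrame,
    regional: pd.DataFrame,
    orth: OrthologTable,
    contrast_species: str,
    regional_species: str,
) -> pd.DataFrame:
    """Join a regional DE table and an anchor-correlation table by family.

    One row per ortholog family carrying the contrast direction (from the
    dataset pair) and the anchor-correlation call (from the other dataset);
    families present on only one side are kept with NA on the other. Under
    the convention that region A of the contrast is the anchor-high region,
    ``concordant`` marks families whose two signals agree. Genes without a
    family are dropped (counted in a warning).
    """
    def lift(table: pd.DataFrame, species: str, cols: dict[str, str]) -> pd.DataFrame:
        g2f = orth.gene_to_families(species)
        rows, dropped = [], 0
        for _, rec in table.iterrows():
            fams = g2f.get(rec["gene"])
            if not fams:
                dropped += 1
                continue
            for fam in fams:
                rows.append({"family": fam, **{new: rec[old] for old, new in cols.items()}})
        if dropped:
            logger.warning("join_regional_programs: %d %s gene(s) without family", dropped, species)
        if not rows:
            return pd.DataFrame(columns=["family", *cols.values()])
        out = pd.DataFrame(rows)
        # a family hit by several genes keeps its strongest signal, deterministically
        return out.sort_values(list(out.columns), kind="mergesort").groupby("family", as_index=False).first()

    left = lift(contrast, contrast_species, {"direction": "contrast_direction", "lfc": "contrast_lfc"})
    right = lift(regional, regional_species, {"call": "anchor_call", "r": "anchor_r"})
    joined = left.merge(right, on="family", how="outer")
    both = joined["contrast_direction"].notna() & joined["anchor_call"].notna()
    concordant = pd.Series(pd.NA, index=joined.index, dtype="object")
    concordant[both] = (
        (joined.loc[both, "contrast_direction"] == "up")
        & (joined.loc[both, "anchor_call"] == "correlated")
    ) | (
        (joined.loc[both, "contrast_direction"] == "down")
        & (joined.loc[both, "anchor_call"] == "anti_correlated")
    )
    joined["concordant"] = concordant
    return joined.sort_values("family", kind="mergesort").reset_index(drop=True)
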