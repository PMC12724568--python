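"""Differential-expression primitives and the marker filters.

The marker definition used throughout: a gene is a cluster marker when it is
at least ``min_fold`` (1.28-fold) more strongly expressed in the cluster
(natural-log fold change of de-logged normalized means with a +1
pseudocount), the two-sided Wilcoxon rank-sum p is below ``max_p`` (0.01),
and the expressing-cell fraction exceeds the complement's by at least
``min_pct_diff`` (0.10). Genotype/region contrasts use the same machinery
without the percentage-gap rule, gating on ``lfc_floor`` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from best4pipe.data_io import ExpressionDataset

_TOL = 1e-9  # float guard for inclusive >= gates


@dataclass
class MarkerThresholds:
    """Gates for marker retention.

    ``min_fold`` is the marker-mode fold gate (inclusive); ``lfc_floor`` is
    the contrast-mode natural-log gate (inclusive), the two being consistent
    by e^0.25 ~ 1.284. ``max_p`` is exclusive and applied to the raw p by
    default; set ``gate_on_adjusted`` to gate on the adjusted value instead.
    """

    min_fold: float = 1.28
    max_p: float = 0.01
    min_pct_diff: float = 0.10
    min_pct: float = 0.10
    lfc_floor: float = 0.25
    p_adjust: str = "bonferroni"
    gate_on_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if not 0 < self.max_p < 1:
            raise ValueError("max_p must lie in (0,1)")
        if abs(math.exp(self.lfc_floor) - self.min_fold) > 0.01:
            raise ValueError("lfc_floor and min_fold are inconsistent (exp(lfc_floor) != min_fold)")
        if self.p_adjust not in ("bonferroni", "bh", "none"):
            raise ValueError(f"unknown p_adjust {self.p_adjust!r}")


# ---------------------------------------------------------------------------
# scalar primitives
# ---------------------------------------------------------------------------

def rank_sum_test(x, y) -> float:
    """Two-sided Mann-Whitney p.

    Exact enumeration when the pooled sample is small (<= 10) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction. Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # no rank information at all
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 10 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def log_fold_change(ds: ExpressionDataset, group_in, group_out, gene: str) -> float:
    """ln((mean expm1(norm) in + 1) / (mean expm1(norm) out + 1))."""
    norm = ds.norm_or_raise()
    j = ds.gene_index(gene)
    g_in = _as_mask(ds, group_in)
    g_out = _as_mask(ds, group_out)
    if not g_in.any() or not g_out.any():
        raise ValueError("log_fold_change requires non-empty groups")
    m_in = np.expm1(norm[g_in, j]).mean()
    m_out = np.expm1(norm[g_out, j]).mean()
    return float(np.log((m_in + 1.0) / (m_out + 1.0)))


def pct_expressing(ds: ExpressionDataset, cells, gene: str) -> float:
    """Fraction of the cell set with a nonzero count for the gene."""
    mask = _as_mask(ds, cells)
    if not mask.any():
        raise ValueError("pct_expressing requires a non-empty cell set")
    col = np.asarray(ds.counts[:, ds.gene_index(gene)].todense()).ravel()
    return float((col[mask] > 0).mean())


def auc_marker(x, y) -> float:
    """P(random A value > random B value), ties counted half: U/(nA*nB)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("auc_marker requires non-empty groups")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    return float(u1 / (x.size * y.size))


def _as_mask(ds: ExpressionDataset, cells) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        return cells
    return ds.cell_mask(cells)


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def _adjust(p: np.ndarray, how: str) -> np.ndarray:
    if how == "none" or p.size == 0:
        return p.copy()
    if how == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(norm: np.ndarray, counts, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean de-logged expression, expressing fraction) per gene for a cell set."""
    sub_counts = counts[mask]
    pct = np.asarray((sub_counts > 0).mean(axis=0)).ravel()
    mean_delog = np.expm1(norm[mask]).mean(axis=0)
    return mean_delog, pct


def _two_group_table(
    ds_in: ExpressionDataset,
    mask_in: np.ndarray,
    ds_out: ExpressionDataset,
    mask_out: np.ndarray,
    thresholds: MarkerThresholds,
    cluster: str,
    mode: str,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Shared engine for one-vs-rest markers and two-sample contrasts.

    ``mode='marker'`` keeps up-regulated genes passing the fold, p, and
    pct-gap gates; ``mode='contrast'`` keeps either direction passing the
    lfc_floor and p gates (no pct-gap rule).
    """
    if mask_in.sum() < 3 or mask_out.sum() < 3:
        raise ValueError(
            f"need >= 3 cells per group; got {int(mask_in.sum())} vs {int(mask_out.sum())}"
        )
    if list(ds_in.gene_ids) != list(ds_out.gene_ids):
        raise ValueError("datasets have different gene universes")
    norm_in, norm_out = ds_in.norm_or_raise(), ds_out.norm_or_raise()
    m_in, pct_in = _group_stats(norm_in, ds_in.counts, mask_in)
    m_out, pct_out = _group_stats(norm_out, ds_out.counts, mask_out)
    lfc = np.log((m_in + 1.0) / (m_out + 1.0))

    testable = np.maximum(pct_in, pct_out) >= thresholds.min_pct - _TOL
    idx = np.flatnonzero(testable)
    a_all = norm_in[mask_in]
    b_all = norm_out[mask_out]
    p = np.ones(len(idx))
    auc = np.empty(len(idx))
    for k, j in enumerate(idx):
        p[k] = rank_sum_test(a_all[:, j], b_all[:, j])
        auc[k] = auc_marker(a_all[:, j], b_all[:, j])
    p_adj = _adjust(p, thresholds.p_adjust)

    table = pd.DataFrame(
        {
            "gene": ds_in.gene_ids[idx],
            "cluster": cluster,
            "lfc": lfc[idx],
            "p": p,
            "p_adj": p_adj,
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "auc": auc,
            "direction": np.where(lfc[idx] >= 0, "up", "down"),
        }
    )
    p_gate = table["p_adj"] if thresholds.gate_on_adjusted else table["p"]
    if mode == "marker":
        keep = (
            (table["lfc"] >= math.log(thresholds.min_fold) - _TOL)
            & (p_gate < thresholds.max_p)
            & (table["pct_in"] - table["pct_out"] >= thresholds.min_pct_diff - _TOL)
        )
    else:
        keep = (table["lfc"].abs() >= thresholds.lfc_floor - _TOL) & (p_gate < thresholds.max_p)
    if not keep_all:
        table = table[keep.to_numpy()]
    table = table.sort_values(
        ["p", "lfc", "gene"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def find_markers(
    ds: ExpressionDataset, cluster: str, thresholds: MarkerThresholds | None = None
) -> pd.DataFrame:
    """One-vs-rest markers of a cluster, filtered by the marker gates.

    Genes are tested only when expressed in >= ``min_pct`` of either group;
    output rows are sorted by (p, -lfc, gene) for deterministic files.
    """
    thresholds = thresholds or MarkerThresholds()
    mask_in = ds.cells_in_cluster(cluster)
    if not mask_in.any():
        raise ValueError(f"cluster {cluster!r} absent from dataset")
    return _two_group_table(ds, mask_in, ds, ~mask_in, thresholds, cluster, mode="marker")


def contrast_by_cluster(
    ds_wt: ExpressionDataset,
    ds_mut: ExpressionDataset,
    cluster: str,
    thresholds: MarkerThresholds | None = None,
) -> pd.DataFrame:
    """WT-vs-MUT differential expression within one cluster.

    Both directions are reported ("up" = higher in WT). The pct-gap rule is
    not applied; retention needs |lfc| >= lfc_floor and p < max_p, testing
    only genes expressed in >= min_pct of either genotype.
    """
    thresholds = thresholds or MarkerThresholds()
    m_wt = ds_wt.cells_in_cluster(cluster)
    m_mut = ds_mut.cells_in_cluster(cluster)
    if not m_wt.any():
        raise ValueError(f"cluster {cluster!r} absent from WT dataset")
    if not m_mut.any():
        raise ValueError(f"cluster {cluster!r} absent from MUT dataset")
    return _two_group_table(ds_wt, m_wt, ds_mut, m_mut, thresholds, cluster, mode="contrast")


def contrast_cell_sets(
    ds: ExpressionDataset,
    cells_a,
    cells_b,
    thresholds: MarkerThresholds | None = None,
    label: str = "contrast",
    keep_all: bool = False,
) -> pd.DataFrame:
    """Contrast-mode DE between two arbitrary cell sets of one dataset.

    ``keep_all`` returns every tested gene (gates not applied), for
    null-calibration checks.
    """
    thresholds = thresholds or MarkerThresholds()
    return _two_group_table(
        ds, _as_mask(ds, cells_a), ds, _as_mask(ds, cells_b), thresholds, label,
        mode="contrast", keep_all=keep_all,
    )
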