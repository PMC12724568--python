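"""Cross-dataset marker conservation over ortholog families.

Per-dataset marker lists are lifted to reference ortholog families (a family
counts as marked in a dataset when ANY of that species' genes mapping to it
is a marker — paralogs are never collapsed away), families are classified by
how many datasets mark them (conserved when >= ``conserved_min`` of
``n_datasets``; species-specific when exactly one; clade-conserved when the
pattern is confined to one clade), and each family carries a per-dataset
cell-type specificity index: the percentage of the gene's mRNA found in the
target cluster, 100 * mean / sum of per-cluster means of de-logged
normalized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from best4pipe.data_io import ExpressionDataset, OrthologTable
from best4pipe.markers import MarkerThresholds, find_markers
from best4pipe.preprocess import log_normalize

logger = logging.getLogger("best4pipe")


@dataclass
class ConservationConfig:
    conserved_min: int = 6
    n_datasets: int = 8
    species_specific_max: int = 1
    clade_labels: dict = field(default_factory=dict)  # dataset_id -> clade
    clade_min_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 1 <= self.species_specific_max < self.conserved_min <= self.n_datasets:
            raise ValueError(
                "require 1 <= species_specific_max < conserved_min <= n_datasets"
            )
        if not 0 < self.clade_min_fraction <= 1:
            raise ValueError("clade_min_fraction must lie in (0,1]")


def map_to_families(
    markers: dict[str, list[str]],
    dataset_species: dict[str, str],
    orth: OrthologTable,
) -> pd.DataFrame:
    """family x dataset boolean presence matrix from per-dataset marker lists.

    ``markers`` maps dataset_id -> marker gene ids; ``dataset_species`` maps
    dataset_id -> species used in the ortholog table. A family is flagged
    when any ortholog (including paralogs) is in the list. Marker genes with
    no family are dropped and counted in a warning.
    """
    known_species = set(orth.species())
    for dsid, species in dataset_species.items():
        if species not in known_species:
            raise ValueError(f"dataset {dsid!r}: species {species!r} absent from ortholog table")
    families = orth.families()
    flags = pd.DataFrame(False, index=pd.Index(families, name="family"), columns=list(markers))
    for dsid, genes in markers.items():
        g2f = orth.gene_to_families(dataset_species[dsid])
        unmapped = 0
        for g in genes:
            fams = g2f.get(g)
            if not fams:
                unmapped += 1
                continue
            flags.loc[fams, dsid] = True
        if unmapped:
            logger.warning("%s: %d marker gene(s) without an ortholog family", dsid, unmapped)
    return flags


def classify_conservation(flags: pd.DataFrame, cfg: ConservationConfig) -> pd.DataFrame:
    """Assign each family a conservation class from its presence pattern.

    Order of precedence: conserved (n_marked >= conserved_min); then
    clade_conserved:<clade> (marked fraction within one clade >=
    clade_min_fraction with at most species_specific_max flags outside);
    then species_specific (exactly one dataset); else shared_partial.
    Families with no flags at all are dropped.
    """
    if flags.shape[1] != cfg.n_datasets:
        raise ValueError(
            f"flags has {flags.shape[1]} dataset columns, config says {cfg.n_datasets}"
        )
    clades: dict[str, list[str]] = {}
    if cfg.clade_labels:
        missing = [d for d in flags.columns if d not in cfg.clade_labels]
        if missing:
            raise ValueError(f"datasets missing clade labels: {missing}")
        for d in flags.columns:
            clades.setdefault(cfg.clade_labels[d], []).append(d)

    records = []
    for fam, row in flags.iterrows():
        n_marked = int(row.sum())
        if n_marked == 0:
            continue
        cls = None
        if n_marked >= cfg.conserved_min:
            cls = "conserved"
        elif clades:
            for clade, members in sorted(clades.items()):
                inside = int(row[members].sum())
                outside = n_marked - inside
                if (
                    inside / len(members) >= cfg.clade_min_fraction
                    and outside <= cfg.species_specific_max
                ):
                    cls = f"clade_conserved:{clade}"
                    break
        if cls is None:
            cls = "species_specific" if n_marked == 1 else "shared_partial"
        records.append({"family": fam, "n_marked": n_marked, "class": cls})
    out = pd.DataFrame(records, columns=["family", "n_marked", "class"])
    return out.sort_values(["class", "family"], kind="mergesort").reset_index(drop=True)


def specificity_index(
    ds: ExpressionDataset, gene: str, target_cluster: str, log_means: bool = False
) -> float:
    """Percent of a gene's expression attributable to the target cluster.

    100 * mean(target) / sum over clusters of mean(cluster), with per-cluster
    arithmetic means of de-logged normalized expression (expm1 of the norm
    layer); ``log_means`` switches to means of the log values. NaN when the
    denominator is zero.
    """
    clusters = ds.cell_meta["cluster"].unique()
    if target_cluster not in clusters:
        raise ValueError(f"unknown cluster {target_cluster!r}")
    norm = ds.norm_or_raise()
    j = ds.gene_index(gene)
    vals = norm[:, j] if log_means else np.expm1(norm[:, j])
    means = {c: vals[ds.cells_in_cluster(c)].mean() for c in clusters}
    denom = sum(means.values())
    if denom == 0:
        return float("nan")
    return float(100.0 * means[target_cluster] / denom)


def _cluster_mean_expr(ds: ExpressionDataset, gene: str, cluster: str) -> float:
    norm = ds.norm_or_raise()
    j = ds.gene_index(gene)
    return float(np.expm1(norm[ds.cells_in_cluster(cluster), j]).mean())


def build_program_table(
    datasets: list[ExpressionDataset],
    orth: OrthologTable,
    cfg: ConservationConfig | None = None,
    thresholds: MarkerThresholds | None = None,
    target_cluster: str = "best4",
    include_families: list[str] | None = None,
) -> pd.DataFrame:
    """End-to-end conserved-program table across datasets.

    Runs the marker test per dataset, lifts markers to families, classifies
    conservation, and attaches per-dataset specificity and mean expression
    for each family's strongest-expressed ortholog. Families a species does
    not annotate get NaN (never counted for or against conservation).
    ``include_families`` forces manually curated families into the output
    regardless of class.
    """
    cfg = cfg or ConservationConfig(n_datasets=len(datasets))
    thresholds = thresholds or MarkerThresholds()
    if cfg.n_datasets != len(datasets):
        raise ValueError("cfg.n_datasets does not match the number of datasets")

    marker_lists: dict[str, list[str]] = {}
    dataset_species: dict[str, str] = {}
    prepared: dict[str, ExpressionDataset] = {}
    for ds in datasets:
        dsid = ds.cell_meta["dataset_id"].iloc[0]
        species = ds.cell_meta["species"].iloc[0]
        dataset_species[dsid] = species
        if ds.norm is None:
            ds = log_normalize(ds)
        prepared[dsid] = ds
        table = find_markers(ds, target_cluster, thresholds)
        marker_lists[dsid] = list(table["gene"])
        logger.info("%s: %d %s marker gene(s)", dsid, len(table), target_cluster)

    flags = map_to_families(marker_lists, dataset_species, orth)
    classes = classify_conservation(flags, cfg)
    if include_families:
        forced = [f for f in include_families if f not in set(classes["family"])]
        classes = pd.concat(
            [classes, pd.DataFrame({"family": forced, "n_marked": 0, "class": "curated"})],
            ignore_index=True,
        )

    rows = []
    for _, rec in classes.iterrows():
        fam = rec["family"]
        row = {"family": fam, "n_marked": rec["n_marked"], "class": rec["class"]}
        for dsid, ds in prepared.items():
            species = dataset_species[dsid]
            genes = [
                g
                for g, fams in orth.gene_to_families(species).items()
                if fam in fams and g in set(ds.gene_ids)
            ]
            row[f"flag:{dsid}"] = bool(flags.loc[fam, dsid])
            if not genes:  # unannotated in this species: NA, not zero
                row[f"specificity:{dsid}"] = np.nan
                row[f"mean_expr:{dsid}"] = np.nan
                continue
            best = max(genes, key=lambda g: _cluster_mean_expr(ds, g, target_cluster))
            row[f"specificity:{dsid}"] = specificity_index(ds, best, target_cluster)
            row[f"mean_expr:{dsid}"] = _cluster_mean_expr(ds, best, target_cluster)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["class", "family"], kind="mergesort").reset_index(drop=True)
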