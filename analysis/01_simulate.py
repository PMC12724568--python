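"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/:
  multispecies/   8 species count matrices (MTX triplet + metadata) with a
                  planted best4+ marker program, the ortholog table, and the
                  planted ground truth
  trajectory/     WT + meis1b-mutant-style secretory cells along a
                  progenitor -> best4+ trajectory (mutant truncated)
  regional/       best4+ cells with genes co-varying with the anterior
                  anchor otop2
  ph_series.tsv   phenol-red-like indicator colors during luminal pH
                  relaxation (pH 4 -> 7.5, tau = 5 min)
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from best4pipe.data_io import write_expression, write_table
from best4pipe.synthetic_data import (
    SimSpec,
    simulate_multispecies,
    simulate_ph_series,
    simulate_regional,
    simulate_trajectory_pair,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()

spec = SimSpec(seed=args.seed)
out = args.outdir

datasets, orth, truth = simulate_multispecies(spec)
for ds in datasets:
    write_expression(ds, out / "multispecies" / ds.cell_meta["dataset_id"].iloc[0])
write_table(orth.table, out / "multispecies" / "orthologs.tsv")
write_table(
    pd.DataFrame({"family": list(truth.family_class), "class": list(truth.family_class.values())}),
    out / "multispecies" / "ground_truth.tsv",
)
print(f"multispecies: {len(datasets)} datasets, {datasets[0].n_genes} genes each, "
      f"{len(truth.families_of_class('conserved'))} conserved families planted")

ds, ttruth = simulate_trajectory_pair(spec)
write_expression(ds, out / "trajectory" / "traj")
write_table(
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "pseudotime": ttruth.pseudotime.to_numpy(),
            "bias_flag": ttruth.bias_flag.to_numpy(),
        }
    ),
    out / "trajectory" / "ground_truth.tsv",
)
write_table(
    ttruth.gene_role.rename("role").rename_axis("gene").reset_index(),
    out / "trajectory" / "gene_roles.tsv",
)
n_mut = int((ds.cell_meta["genotype"] == "MUT").sum())
print(f"trajectory: {ds.n_cells} cells ({n_mut} mutant), terminus blocked at t = {spec.mutant_block_at}")

ds, rtruth = simulate_regional(spec)
write_expression(ds, out / "regional" / "regional")
write_table(
    rtruth.regional_sign.rename("sign").rename_axis("gene").reset_index(),
    out / "regional" / "ground_truth.tsv",
)
print(f"regional: {ds.n_cells} best4+ cells, {int((rtruth.regional_sign != 0).sum())} regional genes planted")

series = simulate_ph_series(4.0, 7.5, 5.0, list(np.arange(0.0, 31.0)), seed=args.seed)
write_table(series, out / "ph_series.tsv")
print(f"ph: {series['animal'].nunique()} animals x {series['time'].nunique()} timepoints, tau = 5 min")
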