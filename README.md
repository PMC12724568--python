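# best4pipe

Analysis pipeline for the computational biology of intestinal **best4+
cells** — the rare BEST4/OTOP2/CFTR-expressing epithelial cell type of the
vertebrate gut. The package re-implements, as tested and reusable Python,
four analyses that together characterize this cell type across species,
space, development, and physiology:

1. **Cross-species marker conservation.** Per-species best4+ markers
   (Wilcoxon rank-sum, fold ≥ 1.28, p < 0.01, expressing-fraction gap
   ≥ 0.10) are lifted to human-symbol ortholog families (paralogs kept:
   zebrafish *pbx3a* and *pbx3b* both count for PBX3) and classified:
   *conserved* when marked in ≥ 6 of 8 datasets, *clade-conserved* when the
   pattern is confined to mammals or aquatic species, *species-specific*
   when marked in exactly one. Each family carries a **specificity index**

   `S = 100 · mean_expr(best4) / Σ_c mean_expr(c)`

   — the percentage of the gene's mRNA found in best4+ cells, over
   per-cluster means of de-logged log-normalized expression.

2. **Within-cell-type regionalization.** Position along the gut is latent;
   genes are scored by their correlation with an anchor gene of known
   regionalization (*otop2*, anterior) across best4+ cells, with
   significance from a permutation null (1000 draws, add-one correction).

3. **Diffusion-map fate bias.** In a mutant lacking best4+ cells, secretory
   cells of both genotypes are embedded jointly with a diffusion map
   (locally scaled Gaussian kernel on a k = 30 nearest-neighbor graph over
   30 PCs, α = 1 density normalization). Each secretory progenitor is
   ranked by its Euclidean DC1–DC2 distance to the wild-type best4+
   centroid; the closest 25% per genotype are the "biased" progenitors,
   which are then contrasted by differential expression.

4. **Colorimetric and ratiometric pH.** Indicator colors are
   background-shifted, converted to hue–chroma–luminance (polar CIE L\*u\*v\*
   under D65), hue is rotated 180° away from the circular wrap, and the
   per-animal hue trace (mean ± t-based 95% CI) yields the luminal pH
   relaxation time. Intracellular pH uses the background-subtracted
   405/488 nm pHluorin excitation ratio; CTCF = integrated density −
   area × mean background.

Every stage runs end-to-end on synthetic data with planted ground truth
(`best4pipe.synthetic_data`): negative-binomial counts (var = μ + φμ²,
φ = 0.5 by default) with a planted conserved program, a truncated mutant
trajectory, polarized regional genes, and a Henderson–Hasselbalch color
model for the pH series. No external downloads are required.

## Worked example

The `analysis/` scripts run the whole study on simulated data:

```sh
python analysis/01_simulate.py            # writes results/data/
python analysis/02_conserved_program.py
python analysis/03_regionalization.py
python analysis/04_fate_bias.py
python analysis/05_ph_colorimetry.py
```

Output of the conservation and fate-bias steps (seed 0):

```
conserved: 20/20 planted families recovered, 0 extra calls
species_specific: 10/10 planted families recovered, 0 extra calls
background families misclassified as conserved: 0
median specificity of conserved families where flagged: 48.4% of the gene's mRNA in best4+ cells

mutant progenitors selected as best4-biased: 75; Jaccard with planted bias flags: 0.85
planted terminal best4+ markers depleted in mutant-selected progenitors vs best4+ cells: 20/20
planted progenitor markers differing between WT- and MUT-selected progenitors: 0/20
```

Reading: all 20 families planted as conserved best4+ markers across the 8
simulated species are recovered with no false conserved calls; a typical
conserved marker concentrates ~half of its mRNA in best4+ cells. In the
mutant, the diffusion-map selection finds the progenitors that had advanced
furthest toward the (absent) best4+ terminus — they have lost none of the
progenitor program but every planted terminal marker distinguishes them
from true best4+ cells. The pH step ends with:

```
hue relaxes from 251.0 deg to 173.6 deg; fitted time constant tau = 5.05 min (planted: 5.00 min)
```

The same operations are available as a CLI (`best4pipe simulate|qc|embed|
markers|contrast|conserve|regionalize|fatebias|phtrack|phluorin`); every
subcommand is deterministic given `--seed`.

## Layout

```
src/best4pipe/     library: data_io, synthetic_data, preprocess, markers,
                   conservation, regionalization, fate_bias, colorimetry, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, and end-to-end recovery)
scripts/           acceptance script
docs/methods.md    models, parameters, and design choices in detail
```
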