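# Methods

This note records the models, parameter choices, and numerical conventions
behind each stage, what the synthetic data does and does not emulate, and
the design decisions taken where more than one convention exists in the
field.

## Preprocessing

Cells are dropped when any rule fires, with both stated bounds inclusive
failures: detected genes ≤ 200 or ≥ 3500, UMIs ≤ 200 or ≥ cap, mitochondrial
percentage ≥ 20. Two shipped profiles differ only in the UMI cap
(`pbx3a`: 3000, `meis1b`: 3500), because the two experiments the defaults
mirror used different caps; the cap is a config field either way.
Mitochondrial genes are identified by the `mt-` prefix; ribosomal content
uses an explicit 79-gene zebrafish list shipped with the package
(`best4pipe/data/ribo_genes_zebrafish.txt`).

Normalization is `norm = ln(1 + 1e4·count/total)`; cells with zero totals
get zero rows and a warning. Variable genes are ranked either by the raw
standard deviation of the normalized layer (`sd`, the simple criterion) or
by a variance-stabilizing criterion (`vst`): a degree-2 polynomial of
log10 variance on log10 mean of raw counts, per-gene standardization by the
fitted sd, clipping at √n_cells, ranking by the variance of clipped values.
The trend is a polynomial rather than a loess smoother: it is deterministic,
dependency-free, and on count data the mean–variance trend is smooth enough
that the quadratic captures it.

Scaling regresses each gene's normalized values (OLS with intercept) on the
mitochondrial and ribosomal percentages, z-scores the residuals, and clips
at ±10. Residual columns whose standard deviation is numerically zero (gene
fully explained by the design) are set to zero rather than amplifying
rounding noise. PCA is a plain SVD of the column-centered matrix with a
deterministic sign convention (each component's largest-magnitude loading
positive); 30 components feed everything downstream. Batch correction is
out of scope; an optional per-batch mean-centering in PC space would be a
stand-in for a proper integration method, so none is applied by default.

## Marker statistics

The two-sided Mann–Whitney test uses exact enumeration for pooled samples
of ≤ 10 without ties, and the tie-corrected normal approximation with
continuity correction otherwise. These two branches agree only to ~0.04
absolute in p at the smallest sizes (exhaustive worst case 0.0375 at 3v3);
that is a property of the normal approximation itself, and the property
test asserts the true bound.

Fold change is natural-log on de-logged means with a +1 pseudocount:
`lfc = ln((mean expm1(norm)_in + 1)/(mean expm1(norm)_out + 1))`. The
natural-log base is fixed by the convention that a threshold of 0.25 log
units equals the 1.28-fold criterion (e^0.25 ≈ 1.284).

Marker mode retains genes with fold ≥ `min_fold` (1.28, inclusive),
p < 0.01 (exclusive, on the raw p by default — Bonferroni and BH values are
reported and a flag gates on them instead), and expressing-fraction gap
≥ 0.10 (inclusive); genes are tested only when expressed in ≥ 10% of either
group. Contrast mode (genotype or region comparisons) reports both
directions, drops the fraction-gap rule, and gates on |lfc| ≥ `lfc_floor`
(0.25). The fold gate, not the 0.25 floor, is authoritative in marker mode:
a gene at exactly 1.28-fold is a marker, and 0.25 natural-log units would
exclude it (ln 1.28 = 0.2469). Output is sorted by (p, −lfc, gene id) so
files are byte-stable.

## Conservation

A family is marked in a dataset when **any** ortholog of that species —
including paralogs — is in the dataset's marker list; families a species
does not annotate are NA and never count for or against conservation.
Classification precedence: conserved (≥ `conserved_min` of `n_datasets`,
default 6 of 8) → clade-conserved (≥ 75% of one clade's datasets marked,
at most one flag outside the clade — the numeric rule is a package
convention, since only the mammal/aquatic repetition itself is prescribed)
→ species-specific (exactly one) → shared-partial. The specificity index
uses arithmetic means of de-logged normalized expression, matching the
"percentage of mRNA" reading; means of log values are available behind a
flag. Manually curated family lists can be forced into the output but are
never added automatically.

## Regionalization

Default correlation is Pearson on log-normalized values, with Spearman as
the alternative; cells with zero anchor counts are retained, since dropout
carries positional information. Significance comes from permutation of the
anchor values (1000 draws shared across genes, add-one correction, so
min p = 1/1001) rather than a parametric null, which would be miscalibrated
under zero inflation. Calls are gated at p < 0.05. The cross-dataset join
resolves both tables to ortholog families, keeps one-sided families with
NA, and labels concordance under the convention that region A of the
contrast is the anchor-high region.

## Fate bias

The diffusion map follows the anisotropic construction standard for
single-cell data: union kNN graph (k = 30) in 30-PC space; locally adaptive
Gaussian kernel `w_ij = exp(−d_ij²/(σ_i σ_j))` with σ_i the distance to the
⌈k/2⌉-th neighbor; α = 1 density normalization (divide by the product of
row sums); row-normalize to a Markov matrix; diffusion components are right
eigenvectors 2…11 by decreasing eigenvalue, sign-fixed, computed through
the symmetric conjugate for stability. A disconnected graph is an error
naming the component sizes. Distances to the wild-type best4+ centroid are
Euclidean in raw DC1–DC2 coordinates — eigenvalue scaling is off by default
(a flag enables it), as the two conventions coexist and the dense-oracle
equivalence test pins the implementation either way. Selection takes the
⌈q·n⌉ closest cells per genotype (q = 0.25), ties broken by cell id, so a
non-empty group always yields a selection. Both genotypes are embedded in
one joint map.

## Colorimetry

"HCL" here is the polar form of CIE L\*u\*v\*: sRGB gamma decode → linear
RGB → XYZ with the ITU-R BT.709 tabulated matrix → L\*u\*v\* against the
tabulated D65 white (0.95047, 1, 1.08883) → C = √(u\*²+v\*²),
H = atan2(v\*, u\*) mod 360. The constant lineage matters: matrices derived
freshly from chromaticity primaries differ in the 4th decimal and move
chroma by ~0.02, and the tabulated matrix and white point disagree
slightly, so the gray axis sits at C ≈ 0.005 rather than exactly 0 — the
common reference implementations share both properties. Colors with
C < 1e-6 are flagged achromatic and assigned H = 0. Background shifting is
additive per record (target = experiment-mean background), which preserves
roi − bg differences exactly; out-of-gamut values produced by shifting are
clamped to [0, 255] with a logged count.

Hue is shifted by 180° before any statistics so the 0/360 wrap lies outside
the indicators' color range; after that, plain linear means and t-based 95%
confidence intervals are valid and circular statistics are unnecessary (a
bootstrap CI would also be defensible; the t interval is the convention
chosen and flagged). The quartic hue~chroma and hue~luminance fits are the
standard check that a single hue value suffices to describe the indicator
color. The luminal relaxation time constant is obtained by fitting
`h(t) = h_∞ + (h_0 − h_∞)e^{−t/τ}` directly to the mean hue trace: hue is a
smooth monotone readout of pH over the indicator's responsive range, and
the direct fit recovers the planted τ to within a few percent, whereas
inverting a hue→pH calibration first amplifies noise where hue saturates
near the asymptote. The monotone (PCHIP) hue→pH calibration against
known-pH standards is provided as an optional operation.

## Synthetic data: what it emulates, and what it does not

Counts are Gamma–Poisson (negative binomial with var = μ + φμ², φ = 0.5 — a
deliberately noisy baseline) with lognormal library-size variation
(σ = 0.3). The generators are pure functions of (spec, seed).

* **Multispecies**: 8 datasets in two alternating clades, 6 shared IEC
  clusters of 40 cells, 160 ortholog families with a 25% paralog rate.
  Conserved families get an 8-fold mean increase in the best4 cluster of a
  random ≥ 6-of-8 dataset subset; species-specific families in exactly one.
  Background genes carry mild incidental cluster modulation (lognormal
  σ = 0.1) — enough to be non-trivial, small enough that background genes
  are genuinely non-markers.
* **Trajectory**: latent pseudotime t ∈ [0,1]; the maturation program is a
  **sigmoidal cascade** — 120 genes switching on or off at staggered
  positions (width 0.1, ~8-fold dynamic range) — the structure of real
  differentiation gene waves, and the property that makes latent position
  recoverable at all: with a single shared linear ramp, the overdispersion
  bound on per-gene information (≈ (μ′/μ)²/φ) leaves even an oracle
  estimator of position short of the fidelity the selection analysis needs.
  Terminal best4+ markers rise only near the terminus and are forced to
  zero in the mutant, whose cells are truncated at t ≤ 0.5; progenitor
  markers are flat through the progenitor zone and genotype-independent. A
  goblet branch (both genotypes) leaves the trajectory at t = 0.5. The
  planted bias flag marks each genotype's top-quartile progenitors by t.
* **Regional**: 300 best4+ cells with latent position u; the anchor and the
  40 planted regional genes are strongly polarized (near-binary, ~6-fold),
  as genuinely regionalized intestinal genes are; a mild gradient is below
  the detection floor of gene–gene correlation at this depth, since the
  observed correlation is the product of two noisy readouts.
* **pH series**: pH relaxes exponentially toward the homeostatic value;
  the indicator's acid (yellow) and base (fuchsia) forms mix in linear RGB
  by the Henderson–Hasselbalch base fraction with pKa 6.0 — chosen inside
  the pH 4 → 7.5 excursion so the color actually reports the transit —
  plus a background offset and Gaussian camera noise (σ = 2 RGB units).

Not emulated: ambient RNA, doublets, batch chemistry, 3' coverage bias,
cross-species annotation error beyond the paralog structure, image
formation beyond flat ROI patches, or indicator bleaching. Passing the
recovery tests therefore shows the pipeline is correct and calibrated under
a clean generative model at realistic depth and overdispersion — not that
real atlases would yield these recovery rates.

## Problem sizes

The shipped defaults (8 × 240-cell datasets, 708 trajectory cells, 300
regional cells, 6 animals × 31 timepoints) were chosen so the full
simulated study is informative for every stage yet runs in seconds, making
the end-to-end recovery checks cheap to repeat.

## Known limitations

* The rank-sum normal approximation is anticonservative by up to ~0.04 in p
  at the smallest group sizes; marker analyses at n ≥ ~20 cells per group
  are unaffected.
* Permutation p-values share permutation draws across genes; gene-level
  false-positive rates fluctuate around the nominal level with slightly
  more correlation than independent draws would give.
* The specificity index depends on the cluster partition supplied in the
  metadata; merging or splitting clusters changes the denominator.
* Conservation classes depend on the ortholog table as given; no ortholog
  inference is attempted.
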