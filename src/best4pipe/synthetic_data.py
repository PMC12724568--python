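"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the statistical structure the analyses assume:

* :func:`simulate_multispecies` — one count matrix per species with a
  best4+-specific marker program planted as conserved (most datasets),
  clade-restricted, or species-specific; ortholog families with paralogs.
* :func:`simulate_trajectory_pair` — wild-type secretory progenitors
  differentiating into best4+ cells along a latent pseudotime, and a mutant
  in which the trajectory truncates before the best4+ terminus.
* :func:`simulate_regional` — within-best4+ spatial heterogeneity: genes
  whose means rise or fall along a latent anterior-posterior position, with
  a strictly anterior (position-decreasing) anchor gene.
* :func:`simulate_ph_series` — pH-indicator color time series: exponential
  luminal pH relaxation, Henderson-Hasselbalch two-form color mixing in
  linear RGB, background offsets, and Gaussian camera noise.

Counts are Gamma-Poisson (negative binomial parameterized by mean and
dispersion phi, var = mu + phi mu^2) with lognormal library-size variation.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from best4pipe.data_io import META_COLUMNS, ExpressionDataset, OrthologTable

DEFAULT_CLUSTERS = ("progenitor", "enterocyte", "goblet", "EEC", "best4", "tuft")

#: lognormal sigma for per-cell library-size variation
LIBSIZE_SIGMA = 0.3
#: lognormal sigma for incidental between-cluster modulation of background genes
BACKGROUND_CLUSTER_SIGMA = 0.1


@dataclass
class SimSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets: 8 species
    datasets, 6 shared intestinal epithelial clusters, a conserved best4+
    program planted in >= 6 of 8 datasets, and an 8-fold planted marker
    effect over an overdispersed (phi = 0.5) negative-binomial baseline.
    """

    n_datasets: int = 8
    clusters: Sequence[str] = DEFAULT_CLUSTERS
    cells_per_cluster: int = 40
    n_families: int = 160
    n_conserved: int = 20
    n_species_specific: int = 10
    n_clade: int = 0
    paralog_rate: float = 0.25
    nb_mean_base: float = 1.0
    nb_dispersion: float = 0.5
    marker_fold: float = 8.0
    conserved_min: int = 6
    regional_genes: int = 40
    regional_sign_mix: float = 0.5
    traj_n: int = 300
    mutant_block_at: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conserved + self.n_species_specific + self.n_clade > self.n_families:
            raise ValueError("planted families exceed n_families")
        if not 0 < self.mutant_block_at < 1:
            raise ValueError("mutant_block_at must lie in (0,1)")
        if not 1 <= self.conserved_min <= self.n_datasets:
            raise ValueError("conserved_min must lie in [1, n_datasets]")
        if self.nb_mean_base <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean_base and nb_dispersion must be positive")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    family_class: dict = field(default_factory=dict)
    #: family x dataset booleans: where the family was planted as a best4 marker
    planted_flags: pd.DataFrame | None = None
    #: per-gene regional sign relative to the anchor (+1, -1, 0)
    regional_sign: pd.Series | None = None
    #: per-cell latent pseudotime (NaN off the best4 branch)
    pseudotime: pd.Series | None = None
    #: per-cell fate-bias flag (top-quartile pseudotime among progenitors)
    bias_flag: pd.Series | None = None
    #: gene -> role map for the trajectory simulation
    gene_role: pd.Series | None = None
    ph_params: dict = field(default_factory=dict)

    def families_of_class(self, cls: str) -> list[str]:
        return sorted(f for f, c in self.family_class.items() if c == cls)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + phi mu^2; zero mean gives zero."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    pos = mean > 0
    # Gamma(shape=1/phi, scale=mu*phi) has mean mu, var phi*mu^2
    lam[pos] = rng.gamma(1.0 / phi, mean[pos] * phi)
    return rng.poisson(lam)


def _assemble_dataset(
    rng: np.random.Generator,
    dataset_id: str,
    species: str,
    gene_ids: np.ndarray,
    cell_means: np.ndarray,
    phi: float,
    meta_extra: dict[str, np.ndarray | str],
) -> ExpressionDataset:
    n_cells = cell_means.shape[0]
    libsize = np.exp(rng.normal(0.0, LIBSIZE_SIGMA, size=n_cells))
    counts = _nb_counts(rng, cell_means * libsize[:, None], phi)
    cell_ids = np.array([f"{dataset_id}:c{i:04d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    for col in META_COLUMNS:
        meta[col] = meta_extra.get(col, "NA")
    meta["dataset_id"] = dataset_id
    meta["species"] = species
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=meta,
    )


# ---------------------------------------------------------------------------
# multi-species marker conservation
# ---------------------------------------------------------------------------

def simulate_multispecies(
    spec: SimSpec,
) -> tuple[list[ExpressionDataset], OrthologTable, GroundTruth]:
    """Per-species count matrices with a planted best4+ marker program.

    Families are planted as ``conserved`` (up-regulated ``marker_fold``-fold
    in the best4 cluster of a random subset of >= ``conserved_min`` datasets),
    ``clade`` (all datasets of one clade only), ``species_specific`` (exactly
    one dataset), or ``background``. Datasets alternate between a "mammal"
    and an "aquatic" clade. Each family contributes one gene per species, or
    two paralogs with probability ``paralog_rate``.
    """
    if spec.cells_per_cluster < 3:
        raise ValueError("cells_per_cluster must be >= 3 (group tests need >= 3 cells)")
    rng = np.random.default_rng(spec.seed)

    families = np.array([f"FAM{i:04d}" for i in range(spec.n_families)], dtype=object)
    classes = np.array(["background"] * spec.n_families, dtype=object)
    classes[: spec.n_conserved] = "conserved"
    classes[spec.n_conserved : spec.n_conserved + spec.n_species_specific] = "species_specific"
    n_cs = spec.n_conserved + spec.n_species_specific
    classes[n_cs : n_cs + spec.n_clade] = "clade"

    dataset_ids = [f"ds{i}" for i in range(spec.n_datasets)]
    species_ids = [f"sp{i}" for i in range(spec.n_datasets)]
    clades = ["mammal" if i % 2 == 0 else "aquatic" for i in range(spec.n_datasets)]

    # where is each family planted?
    flags = pd.DataFrame(False, index=families, columns=dataset_ids)
    for i, fam in enumerate(families):
        cls = classes[i]
        if cls == "conserved":
            k = int(rng.integers(spec.conserved_min, spec.n_datasets + 1))
            chosen = rng.choice(spec.n_datasets, size=k, replace=False)
            flags.loc[fam, [dataset_ids[j] for j in chosen]] = True
        elif cls == "species_specific":
            j = int(rng.integers(spec.n_datasets))
            flags.loc[fam, dataset_ids[j]] = True
        elif cls == "clade":
            clade = "mammal" if rng.random() < 0.5 else "aquatic"
            members = [d for d, c in zip(dataset_ids, clades) if c == clade]
            flags.loc[fam, members] = True

    base_mean = spec.nb_mean_base * np.exp(rng.normal(0.0, 0.4, size=spec.n_families))
    best4_idx = list(spec.clusters).index("best4")

    datasets: list[ExpressionDataset] = []
    orth_rows: list[tuple[str, str, str]] = []
    for d, (dsid, species) in enumerate(zip(dataset_ids, species_ids)):
        n_paralogs = 1 + (rng.random(spec.n_families) < spec.paralog_rate).astype(int)
        gene_ids, gene_fam_idx = [], []
        for i, fam in enumerate(families):
            for p in range(n_paralogs[i]):
                gid = f"{species}:{fam.lower()}{'ab'[p]}"
                gene_ids.append(gid)
                gene_fam_idx.append(i)
                orth_rows.append((species, gid, fam))
        gene_ids = np.array(gene_ids, dtype=object)
        gene_fam_idx = np.array(gene_fam_idx)

        n_clusters = len(spec.clusters)
        # incidental cluster modulation + per-paralog expression level
        cluster_mod = np.exp(
            rng.normal(0.0, BACKGROUND_CLUSTER_SIGMA, size=(n_clusters, len(gene_ids)))
        )
        paralog_level = np.exp(rng.normal(0.0, 0.3, size=len(gene_ids)))
        mu = base_mean[gene_fam_idx] * paralog_level * cluster_mod  # clusters x genes
        planted = flags[dsid].to_numpy()[gene_fam_idx]
        mu[best4_idx, planted] *= spec.marker_fold

        cluster_labels = np.repeat(list(spec.clusters), spec.cells_per_cluster)
        cell_means = mu[
            np.repeat(np.arange(n_clusters), spec.cells_per_cluster)
        ]
        ds = _assemble_dataset(
            rng,
            dsid,
            species,
            gene_ids,
            cell_means,
            spec.nb_dispersion,
            {"cluster": cluster_labels, "batch": dsid, "genotype": "NA"},
        )
        datasets.append(ds)

    orth = OrthologTable(pd.DataFrame(orth_rows, columns=["species", "gene_id", "family"]))
    truth = GroundTruth(
        family_class=dict(zip(families, classes)),
        planted_flags=flags,
    )
    return datasets, orth, truth


# ---------------------------------------------------------------------------
# mutant-vs-wild-type trajectory
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _terminal_profile(t: np.ndarray) -> np.ndarray:
    """0 at t=0, 1 at t=1, essentially zero below t ~ 0.6 (late sigmoidal rise)."""
    raw = _sigmoid((t - 0.8) / 0.07)
    lo, hi = _sigmoid(-0.8 / 0.07), _sigmoid(0.2 / 0.07)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def _progenitor_profile(t: np.ndarray) -> np.ndarray:
    """Flat near 1 through the progenitor zone, decaying only near the terminus."""
    return 1.0 - 0.9 * _terminal_profile(t)


N_PROGENITOR_MARKERS = 20
N_GRADIENT_GENES = 120
N_TERMINAL_MARKERS = 20
N_GOBLET_MARKERS = 12
N_TRAJ_BACKGROUND = 128
#: amplitude of the maturation cascade relative to the baseline mean; the
#: differentiation continuum is deliberately strong and many-gene, as
#: whole-transcriptome maturation programs are
GRADIENT_AMPLITUDE = 8.0
#: pseudotime width of each cascade gene's sigmoidal switch
GRADIENT_SWITCH_WIDTH = 0.1
GOBLET_FRACTION = 0.18  # goblet-branch cells per genotype, relative to traj_n


def simulate_trajectory_pair(spec: SimSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """WT + mutant secretory cells along a progenitor-to-best4 trajectory.

    WT cells carry latent pseudotime t ~ U(0,1); cells with t >= 0.75 are
    best4+ (terminal markers near their planted maximum at t = 1), earlier
    cells are secretory progenitors. Mutant cells are drawn only from
    t <= ``mutant_block_at`` and terminal best4 markers are forced to a zero
    baseline. Progenitor markers are genotype-independent and flat through
    the progenitor zone; gradient genes ramp linearly in t and give the
    manifold its maturation axis. A goblet branch (both genotypes) leaves
    the trajectory at t = 0.5. The per-genotype bias flag marks progenitors
    above their genotype's 75th percentile of t.
    """
    if spec.traj_n < 40:
        raise ValueError("traj_n must be >= 40")
    rng = np.random.default_rng(spec.seed)

    roles = (
        ["progenitor_marker"] * N_PROGENITOR_MARKERS
        + ["gradient"] * N_GRADIENT_GENES
        + ["terminal_marker"] * N_TERMINAL_MARKERS
        + ["goblet_marker"] * N_GOBLET_MARKERS
        + ["background"] * N_TRAJ_BACKGROUND
    )
    prefixes = {
        "progenitor_marker": "prog",
        "gradient": "grad",
        "terminal_marker": "term",
        "goblet_marker": "gob",
        "background": "bg",
    }
    counters: dict[str, int] = {}
    gene_ids = []
    for role in roles:
        k = counters.get(role, 0)
        counters[role] = k + 1
        gene_ids.append(f"{prefixes[role]}{k:03d}")
    gene_ids = np.array(gene_ids, dtype=object)
    roles = np.array(roles, dtype=object)
    amp = 4.0 * spec.nb_mean_base * np.exp(rng.normal(0.0, 0.3, size=len(gene_ids)))
    amp[roles == "gradient"] *= GRADIENT_AMPLITUDE / 4.0
    base = spec.nb_mean_base * np.exp(rng.normal(0.0, 0.4, size=len(gene_ids)))

    n_goblet = max(10, int(round(GOBLET_FRACTION * spec.traj_n)))
    rows: list[dict] = []
    for genotype in ("WT", "MUT"):
        t_max = 1.0 if genotype == "WT" else spec.mutant_block_at
        t_traj = rng.uniform(0.0, t_max, size=spec.traj_n)
        for t in t_traj:
            cluster = "best4" if (genotype == "WT" and t >= 0.75) else "progenitor"
            rows.append({"genotype": genotype, "branch": "best4", "t": t, "cluster": cluster})
        for t in rng.uniform(0.5, 1.0, size=n_goblet):
            rows.append({"genotype": genotype, "branch": "goblet", "t": t, "cluster": "goblet"})
    cells = pd.DataFrame(rows)

    n_cells = len(cells)
    mean = np.tile(base, (n_cells, 1))
    t = cells["t"].to_numpy()
    on_traj = (cells["branch"] == "best4").to_numpy()
    goblet = ~on_traj
    mut = (cells["genotype"] == "MUT").to_numpy()

    for j in np.flatnonzero(roles == "progenitor_marker"):
        mean[on_traj, j] = amp[j] * _progenitor_profile(t[on_traj])
        mean[goblet, j] = 0.1 * amp[j]
    # maturation cascade: each gene switches on or off sigmoidally at its own
    # position along the trajectory, as differentiation gene waves do
    grad_idx = np.flatnonzero(roles == "gradient")
    centers = rng.uniform(0.1, 0.9, size=grad_idx.size)
    rising = rng.random(grad_idx.size) < 0.5
    for g, j in enumerate(grad_idx):
        def profile(tt):
            s = _sigmoid((tt - centers[g]) / GRADIENT_SWITCH_WIDTH)
            return 0.1 + 0.9 * (s if rising[g] else 1.0 - s)

        mean[on_traj, j] = amp[j] * profile(t[on_traj])
        # goblet branch leaves the trajectory at t = 0.5; cascade frozen there
        mean[goblet, j] = amp[j] * profile(np.array([0.5]))[0]
    for j in np.flatnonzero(roles == "terminal_marker"):
        mean[on_traj, j] = amp[j] * _terminal_profile(t[on_traj])
        mean[goblet, j] = 0.0
        mean[mut, j] = 0.0  # mutant terminus absent: forced to baseline
    for j in np.flatnonzero(roles == "goblet_marker"):
        mean[:, j] = 0.0
        mean[goblet, j] = amp[j] * (0.2 + 0.8 * (t[goblet] - 0.5) / 0.5)

    cell_ids = np.array([f"traj:c{i:04d}" for i in range(n_cells)], dtype=object)
    libsize = np.exp(rng.normal(0.0, LIBSIZE_SIGMA, size=n_cells))
    counts = _nb_counts(rng, mean * libsize[:, None], spec.nb_dispersion)
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    meta["cluster"] = cells["cluster"].to_numpy()
    meta["dataset_id"] = "traj"
    meta["species"] = "zebrafish"
    meta["genotype"] = cells["genotype"].to_numpy()
    meta["batch"] = "traj"
    meta["region"] = "NA"
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts), gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta
    )

    pseudotime = pd.Series(np.where(on_traj, t, np.nan), index=cell_ids)
    bias = pd.Series(False, index=cell_ids)
    prog = (meta["cluster"] == "progenitor").to_numpy()
    for genotype in ("WT", "MUT"):
        grp = prog & (meta["genotype"] == genotype).to_numpy()
        if grp.any():
            q75 = np.quantile(t[grp], 0.75)
            bias[grp & (np.nan_to_num(pseudotime.to_numpy(), nan=-1.0) > q75)] = True
    truth = GroundTruth(
        pseudotime=pseudotime,
        bias_flag=bias,
        gene_role=pd.Series(roles, index=gene_ids),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# within-cell-type regionalization
# ---------------------------------------------------------------------------

def simulate_regional(
    spec: SimSpec, anchor: str = "otop2", n_cells: int = 300, n_genes: int = 200
) -> tuple[ExpressionDataset, GroundTruth]:
    """best4+ cells with genes co-varying with a latent anterior-posterior axis.

    Each cell carries u ~ U(0,1) (0 = anterior). The anchor's mean decreases
    strictly in u (an anterior marker, as otop2 is in the larval zebrafish
    intestine). ``regional_genes`` planted genes are monotone in u, a
    ``regional_sign_mix`` fraction of them anti-correlated with the anchor;
    all other genes are independent of u.
    """
    if spec.regional_genes > n_genes - 1:
        raise ValueError("regional_genes must leave room for the anchor and null genes")
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(0.0, 1.0, size=n_cells)

    n_anti = int(round(spec.regional_sign_mix * spec.regional_genes))
    n_pos = spec.regional_genes - n_anti
    gene_ids = np.array(
        [anchor]
        + [f"reg_pos{i:03d}" for i in range(n_pos)]
        + [f"reg_neg{i:03d}" for i in range(n_anti)]
        + [f"null{i:03d}" for i in range(n_genes - 1 - spec.regional_genes)],
        dtype=object,
    )
    sign = pd.Series(0, index=gene_ids, dtype=int)
    sign.iloc[1 : 1 + n_pos] = 1
    sign.iloc[1 + n_pos : 1 + spec.regional_genes] = -1

    # regionalized genes are strongly polarized (near-binary along the axis),
    # as the anchor itself is: anterior-restricted genes are nearly absent
    # posteriorly and vice versa
    amp = 6.0 * spec.nb_mean_base * np.exp(rng.normal(0.0, 0.3, size=len(gene_ids)))
    base = spec.nb_mean_base * np.exp(rng.normal(0.0, 0.4, size=len(gene_ids)))
    mean = np.tile(base, (n_cells, 1))
    anterior = 0.05 + 0.95 * (1.0 - u)  # strictly decreasing in u
    posterior = 0.05 + 0.95 * u
    mean[:, 0] = 8.0 * spec.nb_mean_base * anterior
    for j in range(1, 1 + n_pos):
        mean[:, j] = amp[j] * anterior
    for j in range(1 + n_pos, 1 + spec.regional_genes):
        mean[:, j] = amp[j] * posterior

    meta_extra = {
        "cluster": np.array(["best4"] * n_cells, dtype=object),
        "genotype": "NA",
        "batch": "regional",
    }
    ds = _assemble_dataset(
        rng, "regional", "zebrafish", gene_ids, mean, spec.nb_dispersion, meta_extra
    )
    truth = GroundTruth(
        regional_sign=sign,
        pseudotime=pd.Series(u, index=ds.cell_ids),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# pH indicator color series
# ---------------------------------------------------------------------------

#: phenol-red-like acid (yellow) and base (fuchsia) forms in sRGB
DEFAULT_ACID_RGB = (240.0, 210.0, 60.0)
DEFAULT_BASE_RGB = (225.0, 50.0, 130.0)


def _srgb_decode01(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode01(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.maximum(c, 0.0) ** (1 / 2.4) - 0.055)


def ph_curve(t, ph0: float, ph_home: float, tau: float):
    """Exponential relaxation of luminal pH toward the homeostatic value."""
    return ph_home + (ph0 - ph_home) * np.exp(-np.asarray(t, dtype=float) / tau)


def indicator_fraction(ph, pKa: float):
    """Henderson-Hasselbalch base-form fraction: 1/(1+10^(pKa - pH))."""
    return 1.0 / (1.0 + 10.0 ** (pKa - np.asarray(ph, dtype=float)))


def indicator_rgb(
    ph,
    pKa: float = 6.0,
    acid_rgb: Sequence[float] = DEFAULT_ACID_RGB,
    base_rgb: Sequence[float] = DEFAULT_BASE_RGB,
) -> np.ndarray:
    """Noise-free indicator color: linear-space mix of acid and base forms."""
    f = np.atleast_1d(indicator_fraction(ph, pKa))[:, None]
    acid = _srgb_decode01(np.asarray(acid_rgb, dtype=float) / 255.0)
    base = _srgb_decode01(np.asarray(base_rgb, dtype=float) / 255.0)
    mix = (1.0 - f) * acid[None, :] + f * base[None, :]
    return 255.0 * _srgb_encode01(mix)


def simulate_ph_series(
    ph0: float,
    ph_home: float,
    tau: float,
    timepoints: Sequence[float],
    pKa: float = 6.0,
    acid_rgb: Sequence[float] = DEFAULT_ACID_RGB,
    base_rgb: Sequence[float] = DEFAULT_BASE_RGB,
    bg_offset: Sequence[float] = (12.0, 10.0, 8.0),
    noise_sd: float = 2.0,
    n_animals: int = 6,
    seed: int = 0,
    condition: str = "indicator",
) -> pd.DataFrame:
    """Per-animal indicator ROI + background colors over time.

    pH relaxes exponentially from ``ph0`` to ``ph_home`` with time constant
    ``tau``; the indicator's two forms mix in linear RGB by the base-form
    fraction; every channel then receives the background offset and Gaussian
    noise. Returns a ColorSeries frame with columns
    animal, time, R, G, B, bgR, bgG, bgB, condition, true_ph.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for animal in range(n_animals):
        for tp in timepoints:
            ph = float(ph_curve(tp, ph0, ph_home, tau))
            rgb = indicator_rgb(ph, pKa, acid_rgb, base_rgb)[0]
            roi = rgb + np.asarray(bg_offset) + rng.normal(0.0, noise_sd, 3)
            bg = np.asarray(bg_offset, dtype=float) + rng.normal(0.0, noise_sd, 3)
            rows.append(
                {
                    "animal": f"a{animal}",
                    "time": float(tp),
                    "R": roi[0],
                    "G": roi[1],
                    "B": roi[2],
                    "bgR": bg[0],
                    "bgG": bg[1],
                    "bgB": bg[2],
                    "condition": condition,
                    "true_ph": ph,
                }
            )
    return pd.DataFrame(rows)


def simulate_ph_standards(
    ph_values: Sequence[float],
    pKa: float = 6.0,
    acid_rgb: Sequence[float] = DEFAULT_ACID_RGB,
    base_rgb: Sequence[float] = DEFAULT_BASE_RGB,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Known-pH calibration standards (imaged solutions of known pH)."""
    rng = np.random.default_rng(seed)
    rgb = indicator_rgb(np.asarray(ph_values, dtype=float), pKa, acid_rgb, base_rgb)
    rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    out = pd.DataFrame(rgb, columns=["R", "G", "B"])
    out.insert(0, "ph", list(ph_values))
    return out
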