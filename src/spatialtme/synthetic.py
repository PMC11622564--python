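"""Synthetic CosMx-like cohort generator with known ground truth.

Emulates cell-resolution spatial transcriptomics of tumor/stroma tissue-core
fields of view (FOVs): a ~1,000-gene panel, negative-binomial counts with
phenotype-specific expression profiles and lognormal library sizes,
clustered (Thomas) or completely spatially random (CSR) cell positions,
planted gene-set hotspots, spatially coupled ligand/receptor fields with a
tunable latent Gaussian process, cohort-specific abundance shifts, and
malignant proximal-tubule cells carrying a VEGFA-high signature on
tumor-compartment FOVs.  Every generated dataset ships with per-cell and
per-FOV truth tables so each analysis stage has a recovery oracle.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.linalg import cholesky
from scipy.spatial.distance import cdist

from . import io as io_mod
from .errors import ConfigError

COHORT_NAMES = list(io_mod.COHORTS)


@dataclass
class ThomasProcess:
    """Thomas cluster process: Poisson parents, Gaussian offspring dispersal."""

    kappa: float = 20.0  # expected parents per FOV
    sigma: float = 30.0  # offspring displacement sd, µm

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.sigma <= 0:
            raise ConfigError("Thomas process parameters must be > 0")


@dataclass
class HotspotSpec:
    """Plant a multiplicative gene-set hotspot inside a disc on matching FOVs."""

    set_name: str
    genes: tuple[str, ...]
    radius: float = 100.0
    effect: float = 2.0
    center: tuple[float, float] | None = None  # default: FOV center
    compartment: str = "tumor"
    cohorts: tuple[str, ...] | None = None  # None = all cohorts


@dataclass
class CouplingSpec:
    """Spatially couple a ligand/receptor pair through a shared latent field."""

    ligand: str
    receptor: str
    range_um: float = 100.0
    beta: float = 1.0
    compartment: str = "stroma"
    cohorts: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.range_um <= 0:
            raise ConfigError("coupling range must be > 0")


@dataclass
class AbundanceShift:
    """Shift one phenotype's log-odds of occurrence in one cohort."""

    phenotype: str
    cohort: str
    delta: float  # added to log-odds, both compartments
    compartment: str | None = None  # None = both


@dataclass
class SimConfig:
    """Full description of a synthetic cohort; every field has a realistic default."""

    n_patients: dict[str, int] = field(
        default_factory=lambda: {"io_naive_nonsarc": 12, "io_naive_sarc": 4, "io_exposed": 5}
    )
    fovs_per_sample: dict[str, int] = field(default_factory=lambda: {"tumor": 1, "stroma": 1})
    n_cells_range: tuple[int, int] = (900, 6100)
    fov_extent: tuple[float, float] = (900.0, 700.0)  # µm
    panel: list[str] | None = None  # None → default ~1,000-gene panel
    phenotypes: list[str] = field(default_factory=lambda: list(DEFAULT_PROPORTIONS["tumor"]))
    proportions: dict[str, dict[str, float]] | None = None  # compartment → phenotype → prob
    profiles: pd.DataFrame | None = None  # phenotype × gene relative expression
    theta: float = 5.0  # NB dispersion of counts
    libsize_meanlog: float = 5.5  # median counts/cell ≈ 250
    libsize_sdlog: float = 0.4
    area_meanlog: float = np.log(120.0)  # µm²
    area_sdlog: float = 0.35
    # realistic technical failures: a few near-empty cells (failed probes /
    # tissue edge) and oversized segmentation blobs, for the QC filters to catch
    frac_low_quality: float = 0.02
    low_quality_scale: tuple[float, float] = (0.02, 0.12)  # library-size multiplier
    frac_oversegmented: float = 0.01
    overseg_area_factor: float = 8.0
    spatial_modes: dict[str, ThomasProcess | str] = field(default_factory=dict)  # default CSR
    malignant_phenotype: str = "proximal tubule"
    malignancy_effects: dict[str, float] | None = None  # None → default VEGFA-high signature
    hotspots: list[HotspotSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    abundance_shifts: list[AbundanceShift] = field(default_factory=list)
    seed: int = 0

    def resolve(self) -> "SimConfig":
        """Fill derived defaults (panel, profiles, proportions) and validate."""
        cfg = dataclasses.replace(self)
        if cfg.panel is None:
            cfg.panel = default_panel()
        cfg.panel = [g.strip() for g in cfg.panel]
        if cfg.proportions is None:
            cfg.proportions = {c: dict(p) for c, p in DEFAULT_PROPORTIONS.items()}
        for comp, props in cfg.proportions.items():
            tot = sum(props.values())
            if abs(tot - 1.0) > 1e-8:
                raise ConfigError(f"{comp} phenotype proportions sum to {tot}, not 1")
            if any(v < 0 for v in props.values()):
                raise ConfigError("phenotype proportions must be >= 0")
        if cfg.profiles is None:
            cfg.profiles = default_profiles(cfg.panel, cfg.phenotypes)
        if cfg.malignancy_effects is None:
            cfg.malignancy_effects = dict(DEFAULT_MALIGNANCY_EFFECTS)
        if cfg.theta <= 0 or cfg.libsize_sdlog <= 0:
            raise ConfigError("dispersion and library-size spread must be > 0")
        if not (0 <= cfg.frac_low_quality < 1 and 0 <= cfg.frac_oversegmented < 1):
            raise ConfigError("failure fractions must lie in [0, 1)")
        w, h = cfg.fov_extent
        for hs in cfg.hotspots:
            cx, cy = hs.center if hs.center is not None else (w / 2, h / 2)
            if not (0 <= cx - hs.radius and cx + hs.radius <= w and 0 <= cy - hs.radius and cy + hs.radius <= h):
                raise ConfigError(f"hotspot disc for set {hs.set_name!r} extends outside the FOV")
            missing = [g for g in hs.genes if g not in cfg.panel]
            if missing:
                raise ConfigError(f"hotspot genes not in panel: {missing}")
        for cp in cfg.couplings:
            for g in (cp.ligand, cp.receptor):
                if g not in cfg.panel:
                    raise ConfigError(f"coupling gene {g!r} not in panel")
        return cfg


DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "tumor": {
        "proximal tubule": 0.45,
        "T cell": 0.15,
        "mononuclear phagocyte": 0.12,
        "fibroblast": 0.10,
        "endothelium": 0.08,
        "B cell": 0.04,
        "glomerular endothelium": 0.02,
        "plasma cell": 0.04,
    },
    "stroma": {
        "proximal tubule": 0.20,
        "T cell": 0.18,
        "mononuclear phagocyte": 0.12,
        "fibroblast": 0.22,
        "endothelium": 0.12,
        "B cell": 0.05,
        "glomerular endothelium": 0.06,
        "plasma cell": 0.05,
    },
}

# Marker genes boosted in each phenotype's expression profile.
DEFAULT_MARKERS: dict[str, list[str]] = {
    "proximal tubule": ["CUBN", "LRP2", "SLC34A1", "GPX3"],
    "T cell": ["CD3E", "CD8A", "CD4", "PTPRC", "FOXP3"],
    "mononuclear phagocyte": ["CD68", "LYZ", "ITGAM", "CSF1R"],
    "fibroblast": ["COL1A1", "ACTA2", "COL4A1", "TGFB1", "PDGFRB"],
    "endothelium": ["PECAM1", "VWF", "ITGAV", "ACVRL1"],
    "B cell": ["MS4A1", "CD79A"],
    "glomerular endothelium": ["EMCN", "EHD3", "PECAM1"],
    "plasma cell": ["IGHG1", "MZB1"],
}

# Multiplicative malignant signature applied to proximal-tubule cells on
# tumor-compartment FOVs (clear-cell RCC arises from proximal tubule and is
# VEGFA/CA9-high; WIF1 is lost).
DEFAULT_MALIGNANCY_EFFECTS: dict[str, float] = {
    "VEGFA": 6.0,
    "CA9": 6.0,
    "NDUFA4L2": 5.0,
    "EGFR": 3.0,
    "MYC": 2.5,
    "YES1": 2.0,
    "COL4A1": 2.0,
    "ITGB5": 2.0,
    "WIF1": 0.15,
    "CUBN": 0.4,
    "LRP2": 0.4,
    "SLC34A1": 0.3,
}

_REAL_GENES = [
    "VEGFA", "CA9", "NDUFA4L2", "EGFR", "MYC", "TP53", "WIF1", "YES1",
    "COL4A1", "ITGAV", "ITGB5", "TGFB1", "ACVRL1", "COL1A1", "ACTA2",
    "PDGFRB", "PECAM1", "VWF", "EMCN", "EHD3", "CD3E", "CD8A", "CD4",
    "FOXP3", "PTPRC", "MS4A1", "CD79A", "CD68", "LYZ", "ITGAM", "CSF1R",
    "IGHG1", "MZB1", "CUBN", "LRP2", "SLC34A1", "GPX3", "TPSB2", "IL17A",
    "IL6", "JAK1", "JAK2", "STAT3", "CXCL12", "CXCR4", "IL6R", "IL6ST",
    "FN1", "SPARC", "TIMP1",
]


def default_panel(n_genes: int = 1000) -> list[str]:
    """The default gene panel: named markers padded with filler probes."""
    if n_genes < len(_REAL_GENES):
        raise ConfigError(f"panel must hold at least the {len(_REAL_GENES)} named genes")
    fillers = [f"GENE{i:04d}" for i in range(1, n_genes - len(_REAL_GENES) + 1)]
    return list(_REAL_GENES) + fillers


def default_profiles(
    panel: list[str],
    phenotypes: list[str],
    marker_fold: float = 8.0,
    profile_seed: int = 20_240_101,
) -> pd.DataFrame:
    """Phenotype × gene relative-expression profiles.

    A shared lognormal baseline per gene, with each phenotype's marker genes
    (named markers plus a reserved block of filler genes) boosted
    ``marker_fold``-fold.  Deterministic: the baseline uses its own fixed seed
    so profiles are a function of (panel, phenotypes) only.
    """
    rng = np.random.default_rng(profile_seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(panel))
    prof = pd.DataFrame(
        np.tile(base, (len(phenotypes), 1)), index=list(phenotypes), columns=list(panel)
    )
    fillers = [g for g in panel if g.startswith("GENE")]
    block = max(1, len(fillers) // max(1, len(phenotypes)) // 4)
    for i, ph in enumerate(phenotypes):
        for g in DEFAULT_MARKERS.get(ph, []):
            if g in prof.columns:
                prof.loc[ph, g] *= marker_fold
        extra = fillers[i * block : (i + 1) * block]
        if extra:
            prof.loc[ph, extra] *= marker_fold
    return prof


def gaussian_field(
    coords: np.ndarray,
    range_um: float,
    rng: np.random.Generator,
    grid_max: int = 40,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Sample a latent Gaussian field with exponential covariance at ``coords``.

    The field is drawn exactly on a coarse grid spanning the points (exact
    Cholesky of exp(-d/range)), bilinearly interpolated to the cells, then
    standardized to mean 0 / sd 1 across cells.  The grid spacing is at most
    range/3 so structure at the stated range is resolved.
    """
    if range_um <= 0:
        raise ConfigError("field range must be > 0")
    lo = coords.min(axis=0) - 1.0
    hi = coords.max(axis=0) + 1.0
    span = np.maximum(hi - lo, 1e-6)
    nx = int(np.clip(np.ceil(span[0] / (range_um / 3)) + 1, 2, grid_max))
    ny = int(np.clip(np.ceil(span[1] / (range_um / 3)) + 1, 2, grid_max))
    gx = np.linspace(lo[0], hi[0], nx)
    gy = np.linspace(lo[1], hi[1], ny)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([gxx.ravel(), gyy.ravel()])
    cov = np.exp(-cdist(pts, pts) / range_um)
    cov[np.diag_indices_from(cov)] += jitter
    z = cholesky(cov, lower=True) @ rng.standard_normal(len(pts))
    interp = RegularGridInterpolator((gx, gy), z.reshape(nx, ny), method="linear")
    f = interp(coords)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(len(coords))
    return (f - f.mean()) / sd


def _sample_positions(
    n: int,
    mode: ThomasProcess | str,
    extent: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    w, h = extent
    if n == 0:
        return np.empty((0, 2))
    if isinstance(mode, str):
        if mode.lower() != "csr":
            raise ConfigError(f"unknown spatial mode {mode!r}")
        return rng.uniform([0, 0], [w, h], size=(n, 2))
    n_parents = max(1, rng.poisson(mode.kappa))
    parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
    assign = rng.integers(0, n_parents, size=n)
    pos = parents[assign] + rng.normal(scale=mode.sigma, size=(n, 2))
    # resample offspring that fall outside the FOV; clamp as a last resort
    for _ in range(50):
        outside = (pos[:, 0] < 0) | (pos[:, 0] > w) | (pos[:, 1] < 0) | (pos[:, 1] > h)
        if not outside.any():
            break
        pos[outside] = parents[assign[outside]] + rng.normal(
            scale=mode.sigma, size=(int(outside.sum()), 2)
        )
    pos[:, 0] = np.clip(pos[:, 0], 0, w)
    pos[:, 1] = np.clip(pos[:, 1], 0, h)
    return pos


def _nb_sample(mean: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean, theta) via the gamma–Poisson mixture; var = mean + mean²/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-300) / theta)
    lam[mean <= 0] = 0.0
    return rng.poisson(lam)


def simulate_fov(
    config: SimConfig,
    compartment: str,
    cohort: str,
    rng: np.random.Generator,
    n_cells: int | None = None,
) -> tuple[pd.DataFrame, sp.csr_matrix, pd.DataFrame]:
    """Simulate one FOV; returns (local cell table, counts, per-cell truth).

    The local cell table has columns x, y (µm), area, compartment and truth
    columns are aligned row-for-row (true_phenotype, malignant, in_hotspot).
    """
    cfg = config.resolve()
    if compartment not in cfg.proportions:
        raise ConfigError(f"no proportions configured for compartment {compartment!r}")
    if n_cells is None:
        n_cells = int(rng.integers(cfg.n_cells_range[0], cfg.n_cells_range[1] + 1))
    props = _shifted_proportions(cfg, compartment, cohort)
    phenos = list(props)
    p = np.array([props[ph] for ph in phenos])
    counts_per_pheno = rng.multinomial(n_cells, p / p.sum())

    positions, labels = [], []
    for ph, m in zip(phenos, counts_per_pheno):
        mode = cfg.spatial_modes.get(ph, "csr")
        positions.append(_sample_positions(int(m), mode, cfg.fov_extent, rng))
        labels.extend([ph] * int(m))
    coords = np.vstack(positions) if positions else np.empty((0, 2))
    labels = np.array(labels, dtype=object)
    order = rng.permutation(n_cells)  # shuffle so row order carries no phenotype info
    coords, labels = coords[order], labels[order]

    gene_index = {g: i for i, g in enumerate(cfg.panel)}
    prof = cfg.profiles.reindex(columns=cfg.panel).fillna(0.0)
    frac = prof.to_numpy(dtype=float)
    frac = frac / frac.sum(axis=1, keepdims=True)
    ph_idx = np.array([prof.index.get_loc(ph) for ph in labels]) if n_cells else np.empty(0, int)

    L = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, size=n_cells)
    low_quality = rng.random(n_cells) < cfg.frac_low_quality
    L[low_quality] *= rng.uniform(*cfg.low_quality_scale, size=int(low_quality.sum()))
    mean = L[:, None] * frac[ph_idx]

    malignant = np.zeros(n_cells, dtype=bool)
    if compartment == "tumor":
        malignant = labels == cfg.malignant_phenotype
        for g, fold in cfg.malignancy_effects.items():
            if g in gene_index:
                mean[malignant, gene_index[g]] *= fold

    in_hotspot = np.zeros(n_cells, dtype=bool)
    planted_sets = []
    for hs in cfg.hotspots:
        if hs.compartment != compartment:
            continue
        if hs.cohorts is not None and cohort not in hs.cohorts:
            continue
        cx, cy = hs.center if hs.center is not None else (cfg.fov_extent[0] / 2, cfg.fov_extent[1] / 2)
        inside = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2 <= hs.radius**2
        cols = [gene_index[g] for g in hs.genes]
        mean[np.ix_(inside, cols)] *= hs.effect
        in_hotspot |= inside
        planted_sets.append(hs.set_name)

    coupled_pairs = []
    for cp in cfg.couplings:
        if cp.compartment != compartment:
            continue
        if cp.cohorts is not None and cohort not in cp.cohorts:
            continue
        f = gaussian_field(coords, cp.range_um, rng) if n_cells > 1 else np.zeros(n_cells)
        factor = np.exp(cp.beta * f)
        mean[:, gene_index[cp.ligand]] *= factor
        mean[:, gene_index[cp.receptor]] *= factor
        coupled_pairs.append((cp.ligand, cp.receptor, cp.beta))

    counts = sp.csr_matrix(_nb_sample(mean, cfg.theta, rng).astype(np.int64))

    areas = rng.lognormal(cfg.area_meanlog, cfg.area_sdlog, size=n_cells)
    overseg = rng.random(n_cells) < cfg.frac_oversegmented
    areas[overseg] *= cfg.overseg_area_factor
    cells = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "area": areas,
            "compartment": compartment,
        }
    )
    truth = pd.DataFrame(
        {
            "true_phenotype": labels,
            "malignant": malignant,
            "in_hotspot": in_hotspot,
        }
    )
    truth.attrs["planted_sets"] = planted_sets
    truth.attrs["coupled_pairs"] = coupled_pairs
    return cells, counts, truth


def _shifted_proportions(cfg: SimConfig, compartment: str, cohort: str) -> dict[str, float]:
    props = dict(cfg.proportions[compartment])
    for shift in cfg.abundance_shifts:
        if shift.cohort != cohort:
            continue
        if shift.compartment is not None and shift.compartment != compartment:
            continue
        ph = shift.phenotype
        if ph not in props:
            raise ConfigError(f"abundance shift names unknown phenotype {ph!r}")
        p = props[ph]
        p = min(max(p, 1e-9), 1 - 1e-9)
        newp = 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p)) + shift.delta)))
        scale = (1 - newp) / (1 - p)
        props = {k: (newp if k == ph else v * scale) for k, v in props.items()}
    return props


def plant_lr_coupling(
    counts: sp.spmatrix,
    coords: np.ndarray,
    genes: list[str],
    pair: tuple[str, str],
    range_um: float,
    beta: float,
    rng: np.random.Generator,
    theta: float = 5.0,
) -> sp.csr_matrix:
    """Re-draw one ligand/receptor pair's counts under a shared latent field.

    Baseline per-cell means for the two genes are taken as ``L_j * p_g`` from
    the matrix itself (library size × gene fraction); both genes' means are
    multiplied by ``exp(beta * f)`` with ``f`` a standardized Gaussian field of
    exponential covariance and the stated range, and the two columns are
    resampled from NB(mean, theta).  With ``beta = 0`` the counts distribution
    is unchanged.
    """
    if range_um <= 0:
        raise ConfigError("coupling range must be > 0")
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in pair:
        if g not in gene_index:
            raise ConfigError(f"pair gene {g!r} not in panel")
    X = sp.csr_matrix(counts, dtype=np.float64).tolil()
    L = np.asarray(sp.csr_matrix(counts).sum(axis=1), dtype=float).ravel()
    grand = L.sum()
    f = gaussian_field(coords, range_um, rng)
    factor = np.exp(beta * f)
    for g in pair:
        col = gene_index[g]
        p_g = np.asarray(sp.csr_matrix(counts)[:, col].sum(), dtype=float) / max(grand, 1.0)
        mu = L * float(p_g) * factor
        X[:, col] = _nb_sample(mu, theta, rng)[:, None]
    return sp.csr_matrix(X, dtype=np.int64)


def simulate_cohort(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Simulate the full multi-patient cohort; optionally write it to disk.

    Returns ``(dataset, truth_cells, truth_fovs)``.  On disk the dataset uses
    the package's standard layout (cells.csv, counts.mtx triplet) plus
    ``truth_cells.csv`` and ``truth_fovs.csv``; identical seeds give
    byte-identical files.
    """
    cfg = config.resolve()
    rng = np.random.default_rng(cfg.seed)
    all_cells, all_counts, all_truth, fov_rows = [], [], [], []
    fov_no = 0
    pat_no = 0
    for cohort in COHORT_NAMES:
        for _ in range(cfg.n_patients.get(cohort, 0)):
            pat_no += 1
            pid = f"P{pat_no:03d}"
            for compartment in ("tumor", "stroma"):
                sid = f"{pid}_{'T' if compartment == 'tumor' else 'S'}"
                for _ in range(cfg.fovs_per_sample.get(compartment, 0)):
                    fov_no += 1
                    fid = f"FOV{fov_no:03d}"
                    cells, counts, truth = simulate_fov(cfg, compartment, cohort, rng)
                    n = len(cells)
                    cells = cells.assign(
                        cell_id=[f"{fid}_c{i + 1}" for i in range(n)],
                        fov_id=fid,
                        sample_id=sid,
                        patient_id=pid,
                        cohort=cohort,
                    )
                    truth = truth.assign(cell_id=cells["cell_id"].to_numpy(), fov_id=fid)
                    all_cells.append(cells)
                    all_counts.append(counts)
                    all_truth.append(truth)
                    fov_rows.append(
                        {
                            "fov_id": fid,
                            "sample_id": sid,
                            "patient_id": pid,
                            "compartment": compartment,
                            "cohort": cohort,
                            "n_cells": n,
                            "planted_sets": ";".join(truth.attrs["planted_sets"]),
                            "coupled_pairs": ";".join(
                                f"{l}-{r}@{b:g}" for l, r, b in truth.attrs["coupled_pairs"]
                            ),
                        }
                    )
    cells = pd.concat(all_cells, ignore_index=True)
    counts = sp.vstack(all_counts, format="csr")
    truth_cells = pd.concat(all_truth, ignore_index=True)
    truth_fovs = pd.DataFrame(fov_rows)
    adata = io_mod.build_dataset(cells, counts, cfg.panel)
    if out_dir is not None:
        out_dir = Path(out_dir)
        io_mod.save_dataset(adata, out_dir)
        truth_cells.to_csv(out_dir / "truth_cells.csv", index=False)
        truth_fovs.to_csv(out_dir / "truth_fovs.csv", index=False)
    return adata, truth_cells, truth_fovs
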