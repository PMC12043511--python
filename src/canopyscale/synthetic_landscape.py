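"""Synthetic tropical-forest landscapes with known ground truth.

Generates everything the downstream pipeline consumes: a species pool with a
realistic trait covariance structure (an acquisitive--conservative chemistry
axis and a leaf-size/structure axis), stem-mapped plot inventories with DBH
and crown allometry, smooth environmental gradients, monthly climate series,
and trait-coupled multiband reflectance. Every stochastic draw flows from the
config seed, so identical configs give byte-identical landscapes.

The simulated world is deliberately simple: communities assemble along two
environmental gradients via Gaussian niche filtering on species trait scores,
and canopy reflectance is an affine function of the pixel's true
community-weighted mean (CWM) traits plus Gaussian noise. That makes signal
strength a single controllable quantity and parameter recovery a well-posed
question.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import PixelGrid

# The 13 canopy traits carried through the whole pipeline.
TRAITS: tuple[str, ...] = (
    "leaf_area",          # cm^2
    "sla",                # cm^2 g^-1
    "leaf_thickness",     # mm
    "leaf_fresh_mass",    # g
    "leaf_dry_mass",      # g
    "leaf_water_content", # %
    "leaf_c",             # %
    "leaf_n",             # %
    "leaf_p",             # %
    "leaf_ca",            # %
    "leaf_k",             # %
    "leaf_mg",            # %
    "wood_density",       # g cm^-3
)

PERCENT_TRAITS = frozenset(
    {"leaf_water_content", "leaf_c", "leaf_n", "leaf_p", "leaf_ca", "leaf_k", "leaf_mg"}
)

# Geometric means and coefficients of variation of the log-normal trait
# marginals. Magnitudes are plausible for tropical canopy trees (leaf area in
# cm^2, SLA in cm^2/g, chemistry in % dry mass, wood density in g/cm^3).
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "leaf_area": 100.0,
    "sla": 120.0,
    "leaf_thickness": 0.35,
    "leaf_fresh_mass": 2.5,
    "leaf_dry_mass": 1.0,
    "leaf_water_content": 55.0,
    "leaf_c": 47.0,
    "leaf_n": 2.2,
    "leaf_p": 0.11,
    "leaf_ca": 0.8,
    "leaf_k": 0.6,
    "leaf_mg": 0.25,
    "wood_density": 0.60,
}
DEFAULT_TRAIT_CV: dict[str, float] = {
    "leaf_area": 0.60,
    "sla": 0.35,
    "leaf_thickness": 0.35,
    "leaf_fresh_mass": 0.70,
    "leaf_dry_mass": 0.70,
    "leaf_water_content": 0.10,
    "leaf_c": 0.04,
    "leaf_n": 0.30,
    "leaf_p": 0.35,
    "leaf_ca": 0.45,
    "leaf_k": 0.40,
    "leaf_mg": 0.40,
    "wood_density": 0.20,
}

# Loadings of the two latent strategy axes. Axis 1 is the acquisitive
# (nutrient-rich, high-SLA, low wood density) vs conservative axis; axis 2 is
# a leaf-size/mass axis. The default log-scale correlation matrix is
# L L' + diag(1 - rowsum), which is positive semi-definite by construction.
_AXIS_LOADINGS: dict[str, tuple[float, float]] = {
    "leaf_area": (0.05, 0.72),
    "sla": (0.60, -0.35),
    "leaf_thickness": (-0.50, 0.30),
    "leaf_fresh_mass": (-0.05, 0.75),
    "leaf_dry_mass": (-0.15, 0.72),
    "leaf_water_content": (0.30, 0.25),
    "leaf_c": (-0.45, 0.10),
    "leaf_n": (0.70, 0.10),
    "leaf_p": (0.65, 0.05),
    "leaf_ca": (0.60, 0.05),
    "leaf_k": (0.60, 0.10),
    "leaf_mg": (0.55, 0.05),
    "wood_density": (-0.55, 0.10),
}


def default_correlation_matrix() -> np.ndarray:
    L = np.array([_AXIS_LOADINGS[t] for t in TRAITS])
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return corr


def default_band_loading_matrix() -> np.ndarray:
    """Fixed 13-trait x 10-band loading matrix for the reflectance model.

    A constant, seeded draw: dense loadings so every band mixes several
    traits, as real reflectance does.
    """
    rs = np.random.RandomState(20240917)
    M = rs.normal(scale=1.0, size=(len(TRAITS), len(BANDS)))
    # normalize columns so each band's signal has comparable magnitude
    M /= np.linalg.norm(M, axis=0, keepdims=True)
    return M


BANDS: tuple[str, ...] = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

REGION_NAMES: tuple[str, ...] = ("west", "central", "east")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic landscape; the seed fixes every draw."""

    seed: int = 0
    n_species: int = 200
    n_plots: int = 50
    plot_size: float = 100.0   # m, square side
    pixel_size: float = 10.0   # m
    plot_gap: float = 40.0     # m between plots
    trait_correlation_targets: np.ndarray | None = None
    trait_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_cv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_CV))
    niche_strength: float = 2.0          # >=0, Gaussian niche filter width
    optimum_scale: float = 1.2           # amplitude of niche optima (score s.d. units)
    region_dispersion: tuple[float, ...] = (1.25, 1.0, 0.8)
    stem_density: float = 0.045          # stems per m^2 (450 per ha)
    dbh_log_mean: float = math.log(18.0)  # cm
    dbh_log_sd: float = 0.45
    crown_a: float = 0.5                 # crown radius = a * dbh^b (m, dbh in cm)
    crown_b: float = 0.6
    trait_missing_frac: float = 0.12     # species without field trait records
    genus_missing_frac: float = 0.06     # genera never sampled at all
    band_loading_matrix: np.ndarray | None = None
    reflectance_noise_sd: float | None = None  # None -> calibrated to target_band_r2
    target_band_r2: float = 0.8
    env_smooth_sigma: float = 8.0        # pixels, Gaussian smoothing of noise fields
    env_noise: float = 0.35              # noise s.d. relative to trend amplitude
    # climate
    n_years: int = 30
    climate_coarse_factor: int = 10      # climate cell = factor * pixel_size
    precip_base: float = 150.0           # mm / month
    precip_seasonal_amp: float = 0.25    # relative seasonal amplitude
    dry_season_depth: float = 60.0       # mm extra deficit at dry-season peak
    pet_base: float = 95.0
    pet_seasonal_amp: float = 0.08
    tmax_base: float = 31.0
    tmax_seasonal_amp: float = 2.0
    climate_noise_sd: float = 8.0        # mm
    peak_month: int = 0                  # climatological wettest month
    forest_cover_bare_frac: float = 0.05

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.plot_size <= 0 or self.pixel_size <= 0:
            raise ValueError("plot_size and pixel_size must be positive")
        if self.plot_size % self.pixel_size != 0:
            raise ValueError("plot_size must be a multiple of pixel_size")
        if self.niche_strength < 0:
            raise ValueError("niche_strength must be >= 0")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.trait_correlation_targets is not None:
            validate_correlation_matrix(np.asarray(self.trait_correlation_targets))

    def correlation_matrix(self) -> np.ndarray:
        if self.trait_correlation_targets is None:
            return default_correlation_matrix()
        return np.asarray(self.trait_correlation_targets, dtype=float)

    def loading_matrix(self) -> np.ndarray:
        if self.band_loading_matrix is None:
            return default_band_loading_matrix()
        M = np.asarray(self.band_loading_matrix, dtype=float)
        if M.shape != (len(TRAITS), len(BANDS)):
            raise ValueError(
                f"band_loading_matrix must have shape {(len(TRAITS), len(BANDS))}, got {M.shape}"
            )
        return M


def validate_correlation_matrix(corr: np.ndarray) -> None:
    n = len(TRAITS)
    if corr.shape != (n, n):
        raise ValueError(f"correlation target must be {n}x{n}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation target must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation target must have a unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("correlation target must be positive semi-definite")


# ---------------------------------------------------------------------------
# species pool


def generate_species_pool(config: SimulationConfig) -> pd.DataFrame:
    """Draw the species trait table.

    Traits are multivariate log-normal: the log-scale correlation matrix is
    the config's target, the marginals have the configured geometric means
    and CVs. Genera are assigned by k-means clustering of species in
    standardized log-trait space (k = n_species // 4), which yields congeneric
    species with similar traits -- the behaviour the genus-mean fallback
    relies on.

    Returns a DataFrame with one row per species: columns ``species``,
    ``genus``, the 13 traits, and ``provenance`` (``species-mean``).
    """
    config.validate()
    corr = config.correlation_matrix()
    validate_correlation_matrix(corr)
    rng = np.random.default_rng(config.seed)

    n = config.n_species
    # Cholesky with a tiny jitter so exactly-singular targets still factor.
    jitter = 1e-10 * np.eye(len(TRAITS))
    L = np.linalg.cholesky(corr + jitter)
    z = rng.standard_normal(size=(n, len(TRAITS))) @ L.T

    sigmas = np.array([math.sqrt(math.log(1.0 + config.trait_cv[t] ** 2)) for t in TRAITS])
    mus = np.array(
        [math.log(config.trait_means[t]) - 0.5 * s**2 for t, s in zip(TRAITS, sigmas)]
    )
    values = np.exp(mus + sigmas * z)
    for k, t in enumerate(TRAITS):
        if t in PERCENT_TRAITS:
            values[:, k] = np.clip(values[:, k], 1e-6, 99.0)

    genus = _assign_genera(z, config)
    species = [f"{genus[i]} sp{i:04d}" for i in range(n)]
    table = pd.DataFrame(values, columns=list(TRAITS))
    table.insert(0, "species", species)
    table.insert(1, "genus", genus)
    table["provenance"] = "species-mean"
    return table


def _assign_genera(z: np.ndarray, config: SimulationConfig) -> list[str]:
    from sklearn.cluster import KMeans

    k = max(1, config.n_species // 4)
    km = KMeans(n_clusters=k, n_init=4, random_state=(config.seed + 1) % (2**31))
    labels = km.fit_predict(z)
    return [f"Genus{c:03d}" for c in labels]


def species_scores(table: pd.DataFrame) -> np.ndarray:
    """First two principal-component scores of standardized log traits.

    These are the strategy scores the niche filter acts on; standardized to
    unit variance per axis.
    """
    logt = np.log(table[list(TRAITS)].to_numpy())
    z = (logt - logt.mean(axis=0)) / logt.std(axis=0)
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    scores = u[:, :2] * s[:2]
    scores /= scores.std(axis=0)
    # sign convention: axis 1 positively aligned with leaf N
    n_idx = TRAITS.index("leaf_n")
    for a in range(2):
        if vt[a, n_idx] < 0:
            scores[:, a] *= -1
    return scores


def field_trait_table(pool: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """The 'field campaign' trait table: the pool minus unsampled taxa.

    A seeded fraction of species is dropped (these resolve through the
    genus-mean fallback downstream when congeners were sampled) and a seeded
    fraction of whole genera is dropped (these stay unresolved and push pixel
    coverage below 1, exercising the 70% filter).
    """
    rng = np.random.default_rng(config.seed + 7)
    n_drop = int(round(config.trait_missing_frac * len(pool)))
    drop = set(rng.choice(len(pool), size=n_drop, replace=False).tolist())
    genera = pool["genus"].unique()
    n_gdrop = int(round(config.genus_missing_frac * len(genera)))
    if n_gdrop > 0:
        gdrop = set(rng.choice(genera, size=n_gdrop, replace=False).tolist())
        drop |= set(np.nonzero(pool["genus"].isin(gdrop).to_numpy())[0].tolist())
    keep = [i for i in range(len(pool)) if i not in drop]
    if not keep:
        raise ValueError("missingness settings removed every species")
    return pool.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# landscape frame


def landscape_layout(config: SimulationConfig) -> tuple[PixelGrid, list[tuple[float, float]]]:
    """Pixel grid and plot origins (SW corners), plots on a jittered lattice.

    Plot origins are aligned to pixel boundaries so every in-plot pixel is
    fully inside its plot; plots never overlap.
    """
    n_cols_p = int(math.ceil(math.sqrt(config.n_plots)))
    n_rows_p = int(math.ceil(config.n_plots / n_cols_p))
    pitch = config.plot_size + config.plot_gap
    width = n_cols_p * pitch + config.plot_gap
    height = n_rows_p * pitch + config.plot_gap
    s = config.pixel_size
    grid = PixelGrid(0.0, 0.0, s, int(math.ceil(height / s)), int(math.ceil(width / s)))
    origins = []
    for p in range(config.n_plots):
        r, c = divmod(p, n_cols_p)
        x = config.plot_gap + c * pitch
        y = config.plot_gap + r * pitch
        # snap to pixel boundaries
        origins.append((round(x / s) * s, round(y / s) * s))
    return grid, origins


def region_labels(grid: PixelGrid) -> np.ndarray:
    """Integer region layer: vertical thirds of the landscape (0=west)."""
    j = np.arange(grid.n_cols)
    thirds = np.minimum(j * 3 // grid.n_cols, 2)
    return np.tile(thirds, (grid.n_rows, 1))


# ---------------------------------------------------------------------------
# environment


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_environment(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Soil, terrain, and latent gradient layers on the pixel grid.

    Two standardized latent gradients drive everything: ``fertility``
    (west-east trend + smooth noise) and ``wetness`` (south-north trend +
    smooth noise). Soil chemistry follows fertility, texture follows wetness,
    elevation is an independent smooth surface. ``sand + clay`` never exceeds
    100%.
    """
    config.validate()
    grid, _ = landscape_layout(config)
    rng = np.random.default_rng(config.seed + 11)
    nr, nc = grid.shape
    X, Y = grid.centers()
    ex = (X - X.mean()) / max(X.std(), 1e-12)  # standardized easting
    ny = (Y - Y.mean()) / max(Y.std(), 1e-12)

    noise = config.env_noise
    fert = ex + noise * _smooth_field((nr, nc), config.env_smooth_sigma, rng)
    wet = ny + noise * _smooth_field((nr, nc), config.env_smooth_sigma, rng)
    fert = (fert - fert.mean()) / fert.std()
    wet = (wet - wet.mean()) / wet.std()

    ph = 5.5 + 0.8 * fert + 0.1 * _smooth_field((nr, nc), config.env_smooth_sigma, rng)
    cec = np.exp(2.3 + 0.45 * fert + 0.05 * _smooth_field((nr, nc), config.env_smooth_sigma, rng))
    sand_frac = 1.0 / (1.0 + np.exp(-(0.8 * wet - 0.2 * fert
                                      + 0.3 * _smooth_field((nr, nc), config.env_smooth_sigma, rng))))
    sand = 100.0 * 0.9 * sand_frac
    clay = (100.0 - sand) * 0.6  # remainder split with silt; sand+clay <= 100
    elevation = 200.0 + 80.0 * _smooth_field((nr, nc), 2.0 * config.env_smooth_sigma, rng) + 0.02 * X

    cover = 100.0 * np.ones((nr, nc))
    if config.forest_cover_bare_frac > 0:
        bare = _smooth_field((nr, nc), config.env_smooth_sigma, rng)
        thresh = np.quantile(bare, 1.0 - config.forest_cover_bare_frac)
        cover[bare > thresh] = 10.0

    return {
        "fertility": fert,
        "wetness": wet,
        "soil_ph": ph,
        "soil_cec": cec,
        "soil_sand": sand,
        "soil_clay": clay,
        "elevation": elevation,
        "forest_cover": cover,
    }


# ---------------------------------------------------------------------------
# climate


@dataclass
class ClimateCube:
    """Monthly climate series on a coarse grid (climate-product resolution)."""

    grid: PixelGrid
    precipitation: np.ndarray  # (n_months, n_rows, n_cols), mm
    pet: np.ndarray            # same shape, mm
    tmax: np.ndarray           # same shape, deg C


def generate_monthly_climate(
    config: SimulationConfig, environment: Mapping[str, np.ndarray] | None = None
) -> ClimateCube:
    """Monthly P, PET and Tmax series on the coarse climate grid.

    Seasonal cycle: sinusoid peaking at ``peak_month``; the dry season is
    deepened by ``dry_season_depth`` mm at the trough. Spatial structure
    follows the wetness gradient (wetter pixels get more rain) and elevation
    (cooler Tmax). Precipitation is clipped at 0, PET at 1 mm.
    """
    config.validate()
    grid, _ = landscape_layout(config)
    if environment is None:
        environment = generate_environment(config)
    f = config.climate_coarse_factor
    coarse = PixelGrid(
        grid.x0, grid.y0, grid.pixel_size * f,
        int(math.ceil(grid.n_rows / f)), int(math.ceil(grid.n_cols / f)),
    )
    # block-average the wetness and elevation fields onto the coarse grid
    wet = _block_reduce(environment["wetness"], f, coarse.shape)
    elev = _block_reduce(environment["elevation"], f, coarse.shape)

    rng = np.random.default_rng(config.seed + 23)
    n_months = 12 * config.n_years
    months = np.arange(n_months)
    theta = 2.0 * np.pi * (months % 12 - config.peak_month) / 12.0
    cos = np.cos(theta)[:, None, None]
    dry_shape = np.maximum(0.0, -np.cos(theta))[:, None, None]

    base = config.precip_base * (1.0 + 0.25 * wet)[None, :, :]
    p = base * (1.0 + config.precip_seasonal_amp * cos) - config.dry_season_depth * dry_shape
    p = p + config.climate_noise_sd * rng.standard_normal(p.shape)
    p = np.maximum(p, 0.0)

    pet = config.pet_base * (1.0 + config.pet_seasonal_amp * (-cos)) * np.ones_like(p)
    pet = np.maximum(pet + 0.2 * config.climate_noise_sd * rng.standard_normal(pet.shape), 1.0)

    tmax = (
        config.tmax_base
        - 0.005 * (elev - elev.mean())[None, :, :]
        + config.tmax_seasonal_amp * (-cos)
        + 0.3 * rng.standard_normal(p.shape)
    )
    return ClimateCube(coarse, p, pet, tmax)


def _block_reduce(layer: np.ndarray, f: int, out_shape: tuple[int, int]) -> np.ndarray:
    nr, nc = out_shape
    out = np.empty(out_shape)
    for i in range(nr):
        for j in range(nc):
            out[i, j] = layer[i * f:(i + 1) * f, j * f:(j + 1) * f].mean()
    return out


# ---------------------------------------------------------------------------
# plots and truth


@dataclass
class TreeRecord:
    """A stem: plot-local coordinates (m from the plot SW corner), DBH (cm)."""

    plot_id: str
    x: float
    y: float
    dbh: float
    species: str
    genus: str

    @property
    def basal_area(self) -> float:
        """m^2; pi * (DBH/200)^2 with DBH in cm."""
        return math.pi * (self.dbh / 200.0) ** 2


@dataclass
class PlotInventory:
    plot_id: str
    origin_x: float
    origin_y: float
    side: float
    trees: list[TreeRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [t.plot_id for t in self.trees],
                "x": [t.x for t in self.trees],
                "y": [t.y for t in self.trees],
                "dbh": [t.dbh for t in self.trees],
                "species": [t.species for t in self.trees],
                "genus": [t.genus for t in self.trees],
                "basal_area": [t.basal_area for t in self.trees],
            }
        )


@dataclass
class LandscapeTruth:
    """Ground truth for parameter-recovery tests.

    ``realized_cwm`` is the crown-area-weighted mean of the assigned species
    traits per pixel (NaN outside plots) -- by construction identical to what
    the CWM rasterizer computes with the full trait table. ``expected_cwm``
    is the smooth niche-model expectation, defined at every landscape pixel;
    it is what reflectance is driven by outside the plots.
    """

    grid: PixelGrid
    realized_cwm: dict[str, np.ndarray]
    expected_cwm: dict[str, np.ndarray]
    environment: dict[str, np.ndarray]
    plot_compositions: dict[str, pd.Series]
    optima: dict[str, tuple[float, float]]
    trait_table: pd.DataFrame  # full pool (no missing species)
    config: SimulationConfig

    def cwm_surface(self, trait: str) -> np.ndarray:
        """Realized CWM inside plots, expected CWM elsewhere."""
        r = self.realized_cwm[trait]
        return np.where(np.isfinite(r), r, self.expected_cwm[trait])


def _niche_weights(
    scores: np.ndarray, base_abund: np.ndarray, o1, o2, niche_strength: float
) -> np.ndarray:
    """Abundance weights for species at optima (o1, o2); rows sum to 1."""
    d2 = (scores[:, 0] - np.atleast_1d(o1)[..., None]) ** 2 + (
        scores[:, 1] - np.atleast_1d(o2)[..., None]
    ) ** 2
    w = base_abund * np.exp(-niche_strength * d2)
    return w / w.sum(axis=-1, keepdims=True)


def assemble_plots(
    pool: pd.DataFrame,
    environment: Mapping[str, np.ndarray],
    config: SimulationConfig,
) -> tuple[list[PlotInventory], LandscapeTruth]:
    """Place plots, sample communities, and record ground truth.

    Species abundance in a plot is proportional to
    ``base_abundance * exp(-niche_strength * |score - optimum|^2)`` where the
    optimum is a linear function of the local fertility and wetness gradients
    (scaled per region by ``region_dispersion``). Stem count is Poisson, stem
    locations uniform, DBH log-normal.
    """
    config.validate()
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    grid, origins = landscape_layout(config)
    rng = np.random.default_rng(config.seed + 31)

    scores = species_scores(pool)
    base_abund = np.exp(rng.normal(0.0, 1.0, size=len(pool)))  # lognormal rank-abundance
    regions = region_labels(grid)
    disp = np.asarray(config.region_dispersion, dtype=float)[regions]
    o1_field = config.optimum_scale * disp * environment["fertility"]
    o2_field = config.optimum_scale * disp * environment["wetness"]

    species_names = pool["species"].to_numpy()
    genus_names = pool["genus"].to_numpy()
    trait_vals = pool[list(TRAITS)].to_numpy()

    inventories: list[PlotInventory] = []
    compositions: dict[str, pd.Series] = {}
    optima: dict[str, tuple[float, float]] = {}
    for p, (ox, oy) in enumerate(origins):
        plot_id = f"plot{p:03d}"
        ci, cj = grid.pixel_index(ox + config.plot_size / 2, oy + config.plot_size / 2)
        o1, o2 = float(o1_field[ci, cj]), float(o2_field[ci, cj])
        w = _niche_weights(scores, base_abund, o1, o2, config.niche_strength)[0]
        n_stems = max(1, rng.poisson(config.stem_density * config.plot_size**2))
        idx = rng.choice(len(pool), size=n_stems, p=w)
        xs = rng.uniform(0.0, config.plot_size, size=n_stems)
        ys = rng.uniform(0.0, config.plot_size, size=n_stems)
        dbhs = np.maximum(np.exp(rng.normal(config.dbh_log_mean, config.dbh_log_sd, n_stems)), 5.0)
        trees = [
            TreeRecord(plot_id, float(xs[k]), float(ys[k]), float(dbhs[k]),
                       str(species_names[idx[k]]), str(genus_names[idx[k]]))
            for k in range(n_stems)
        ]
        inventories.append(PlotInventory(plot_id, ox, oy, config.plot_size, trees))
        compositions[plot_id] = pd.Series(idx).value_counts().rename(
            lambda i: species_names[i]
        )
        optima[plot_id] = (o1, o2)

    # expected CWM surface: niche-model expectation at every pixel
    flat_w = _niche_weights(
        scores, base_abund, o1_field.ravel(), o2_field.ravel(), config.niche_strength
    )
    expected = flat_w @ trait_vals  # (n_pix, n_traits)
    expected_cwm = {
        t: expected[:, k].reshape(grid.shape) for k, t in enumerate(TRAITS)
    }

    realized_cwm = _realized_cwm(inventories, pool, grid, config)

    truth = LandscapeTruth(
        grid=grid,
        realized_cwm=realized_cwm,
        expected_cwm=expected_cwm,
        environment=dict(environment),
        plot_compositions=compositions,
        optima=optima,
        trait_table=pool,
        config=config,
    )
    return inventories, truth


def _realized_cwm(
    inventories: list[PlotInventory],
    pool: pd.DataFrame,
    grid: PixelGrid,
    config: SimulationConfig,
) -> dict[str, np.ndarray]:
    """Crown-area-weighted CWM per pixel from the full pool (no missingness)."""
    from .cwm_scaling import crown_polygons, plot_pixel_tree_areas

    trait_vals = pool.set_index("species")[list(TRAITS)]
    out = {t: np.full(grid.shape, np.nan) for t in TRAITS}
    num = {t: np.zeros(grid.shape) for t in TRAITS}
    den = np.zeros(grid.shape)
    for inv in inventories:
        crowns = crown_polygons(inv, config.crown_a, config.crown_b)
        rows, cols, tree_idx, areas = plot_pixel_tree_areas(inv, crowns, grid)
        vals = trait_vals.loc[[inv.trees[k].species for k in range(len(inv.trees))]].to_numpy()
        np.add.at(den, (rows, cols), areas)
        for k, t in enumerate(TRAITS):
            np.add.at(num[t], (rows, cols), areas * vals[tree_idx, k])
    covered = den > 0
    for t in TRAITS:
        out[t][covered] = num[t][covered] / den[covered]
    return out


# ---------------------------------------------------------------------------
# reflectance


def simulate_reflectance(
    truth: LandscapeTruth, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Multiband surface reflectance driven by the true CWM surfaces.

    Each band is an affine function (the band loading matrix) of the
    standardized true CWM traits plus Gaussian noise, clipped to [0, 1]. When
    ``reflectance_noise_sd`` is None the noise s.d. is calibrated per band so
    that the trait signal explains ``target_band_r2`` of band variance.
    """
    M = config.loading_matrix()
    grid = truth.grid
    cwm = np.stack([truth.cwm_surface(t).ravel() for t in TRAITS], axis=1)
    mu = np.nanmean(cwm, axis=0)
    sd = np.nanstd(cwm, axis=0)
    sd[sd == 0] = 1.0
    z = (cwm - mu) / sd

    signal = z @ M  # (n_pix, n_bands)
    # scale signal into reflectance units and centre each band; offsets keep
    # bands well inside (0, 1) so clipping is rare
    offsets = 0.15 + 0.02 * np.arange(len(BANDS))
    amp = 0.04
    signal = amp * signal / np.maximum(signal.std(axis=0), 1e-12) + offsets

    rng = np.random.default_rng(config.seed + 41)
    if config.reflectance_noise_sd is None:
        r2 = config.target_band_r2
        noise_sd = signal.std(axis=0) * math.sqrt(max(1.0 / r2 - 1.0, 0.0))
    else:
        noise_sd = np.full(len(BANDS), config.reflectance_noise_sd)
    bands = signal + noise_sd * rng.standard_normal(signal.shape)
    bands = np.clip(bands, 0.0, 1.0)
    return {b: bands[:, k].reshape(grid.shape) for k, b in enumerate(BANDS)}


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class Landscape:
    """Everything the pipeline consumes, generated from one config."""

    config: SimulationConfig
    grid: PixelGrid
    pool: pd.DataFrame
    field_table: pd.DataFrame
    environment: dict[str, np.ndarray]
    climate: ClimateCube
    inventories: list[PlotInventory]
    truth: LandscapeTruth
    reflectance: dict[str, np.ndarray]
    regions: np.ndarray


def generate_landscape(config: SimulationConfig) -> Landscape:
    """Run every generator stage in dependency order."""
    config.validate()
    pool = generate_species_pool(config)
    env = generate_environment(config)
    climate = generate_monthly_climate(config, env)
    inventories, truth = assemble_plots(pool, env, config)
    reflectance = simulate_reflectance(truth, config)
    grid, _ = landscape_layout(config)
    return Landscape(
        config=config,
        grid=grid,
        pool=pool,
        field_table=field_trait_table(pool, config),
        environment=env,
        climate=climate,
        inventories=inventories,
        truth=truth,
        reflectance=reflectance,
        regions=region_labels(grid),
    )
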