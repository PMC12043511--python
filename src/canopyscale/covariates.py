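"""Spectral indices, canopy texture, climate and terrain covariates.

Band-to-wavelength mapping follows the standard Sentinel-2 convention:
green = B3, red = B4, red edge = B5, NIR = B8. Index formulas are the
standard closed forms (MCARI, MSAVI2, NDRE). Texture is computed from a
per-pixel grey-level co-occurrence matrix (GLCM) over a square window
(default 9x9 pixels), quantized to equal-width grey levels over the layer's
global range, symmetric, averaged over the four distance-1 direction
offsets.

The maximum climatological water deficit (MCWD) accumulates the monthly
water balance P - PET within a hydrological year that starts at the
climatological wettest month (deficit reset to 0 there), caps the running
deficit at 0, and takes the most negative value per year; multi-year series
report the mean of the annual minima by default.
"""

from __future__ import annotations

import numpy as np

from .grids import PixelGrid, resample_to_grid

# ---------------------------------------------------------------------------
# spectral indices (pointwise; NaN marks undefined pixels)


def mcari(b3: np.ndarray, b4: np.ndarray, b5: np.ndarray) -> np.ndarray:
    """Modified chlorophyll absorption reflectance index.

    ``[(B5 - B4) - 0.2 (B5 - B3)] * (B5 / B4)``; pixels with B4 = 0 are NaN.
    """
    b3, b4, b5 = (np.asarray(a, dtype=float) for a in (b3, b4, b5))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ((b5 - b4) - 0.2 * (b5 - b3)) * (b5 / b4)
    return np.where(b4 == 0, np.nan, out)


def msavi2(b4: np.ndarray, b8: np.ndarray) -> np.ndarray:
    """Modified soil-adjusted vegetation index 2 (closed form).

    ``(2 B8 + 1 - sqrt((2 B8 + 1)^2 - 8 (B8 - B4))) / 2``. The radicand is
    non-negative for reflectance in [0, 1]; a negative radicand raises.
    """
    b4, b8 = np.asarray(b4, dtype=float), np.asarray(b8, dtype=float)
    radicand = (2.0 * b8 + 1.0) ** 2 - 8.0 * (b8 - b4)
    if np.any(radicand < 0):
        raise ValueError("MSAVI2 radicand negative: inputs are not reflectances in [0, 1]")
    return (2.0 * b8 + 1.0 - np.sqrt(radicand)) / 2.0


def ndre(b5: np.ndarray, b8: np.ndarray) -> np.ndarray:
    """Normalized difference red edge: ``(B8 - B5) / (B8 + B5)``; NaN at 0/0."""
    b5, b8 = np.asarray(b5, dtype=float), np.asarray(b8, dtype=float)
    denom = b8 + b5
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (b8 - b5) / denom
    return np.where(denom == 0, np.nan, out)


# ---------------------------------------------------------------------------
# GLCM texture

_OFFSETS_4 = ((0, 1), (1, 0), (1, 1), (1, -1))  # E, N, NE, NW at distance 1


def glcm_texture(
    layer: np.ndarray,
    window: int = 9,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = _OFFSETS_4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel GLCM entropy and correlation over a sliding window.

    The layer is quantized once to ``levels`` equal-width bins over its
    global finite range. For each pixel whose window fits inside the layer, a
    symmetric co-occurrence matrix is accumulated over the offsets, averaged
    and normalized to probabilities p_ij; then

    * entropy = -sum p_ij ln p_ij
    * correlation = sum (i - mu_i)(j - mu_j) p_ij / (sigma_i sigma_j),
      defined as 0 where sigma_i * sigma_j = 0 (e.g. constant windows).

    Border pixels (window not fully inside) are NaN. NaN cells inside a
    window are excluded pairwise; a pixel is NaN only when no valid pair
    remains.
    """
    layer = np.asarray(layer, dtype=float)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    nr, nc = layer.shape
    if window > nr or window > nc:
        raise ValueError("window larger than layer")

    finite = np.isfinite(layer)
    lo = np.nanmin(layer) if finite.any() else 0.0
    hi = np.nanmax(layer) if finite.any() else 1.0
    span = hi - lo
    q = np.zeros(layer.shape, dtype=np.int64)
    if span > 0:
        q[finite] = np.minimum(((layer[finite] - lo) / span * levels).astype(np.int64), levels - 1)

    half = window // 2
    entropy = np.full(layer.shape, np.nan)
    correlation = np.full(layer.shape, np.nan)
    lev = np.arange(levels, dtype=float)

    for i in range(half, nr - half):
        for j in range(half, nc - half):
            W = q[i - half: i + half + 1, j - half: j + half + 1]
            F = finite[i - half: i + half + 1, j - half: j + half + 1]
            all_ok = F.all()
            counts = np.zeros(levels * levels, dtype=np.int64)
            for dy, dx in offsets:
                a = W[max(0, -dy): window - max(0, dy), max(0, -dx): window - max(0, dx)]
                b = W[max(0, dy): window - max(0, -dy), max(0, dx): window - max(0, -dx)]
                codes = (a * levels + b).ravel()
                if not all_ok:
                    fa = F[max(0, -dy): window - max(0, dy), max(0, -dx): window - max(0, dx)]
                    fb = F[max(0, dy): window - max(0, -dy), max(0, dx): window - max(0, -dx)]
                    codes = codes[(fa & fb).ravel()]
                counts += np.bincount(codes, minlength=levels * levels)
            mat = counts.reshape(levels, levels)
            mat = mat + mat.T  # symmetric GLCM
            total = mat.sum()
            if total == 0:
                continue
            p = mat / total
            nz = p[p > 0]
            entropy[i, j] = float(-(nz * np.log(nz)).sum())
            pi = p.sum(axis=1)
            mu = float(lev @ pi)
            var = float(((lev - mu) ** 2) @ pi)
            if var <= 0:
                correlation[i, j] = 0.0
            else:
                cov = float(((lev[:, None] - mu) * (lev[None, :] - mu) * p).sum())
                correlation[i, j] = cov / var
    return entropy, correlation


# ---------------------------------------------------------------------------
# climate summaries


def mcwd(
    precipitation: np.ndarray,
    pet: np.ndarray,
    multi_year: str = "mean",
    start_month: int | None = None,
) -> np.ndarray | float:
    """Maximum climatological water deficit (mm, <= 0).

    Series are monthly with length a multiple of 12; trailing axes may carry
    pixels. Per year, the running deficit starts at 0 at the climatological
    wettest month (argmax of the mean monthly precipitation, unless
    ``start_month`` is given) and follows ``WD_n = min(0, WD_{n-1} + P_n -
    PET_n)``; the annual MCWD is the most negative WD of the year.
    ``multi_year`` is ``"mean"`` (mean of annual minima, default) or
    ``"min"`` (minimum over the whole record).
    """
    P = np.asarray(precipitation, dtype=float)
    E = np.asarray(pet, dtype=float)
    if P.shape != E.shape:
        raise ValueError("precipitation and PET must have the same shape")
    n = P.shape[0]
    if n < 12 or n % 12 != 0:
        raise ValueError("series length must be a positive multiple of 12")
    n_years = n // 12
    flatP = P.reshape(n, -1)
    flatE = E.reshape(n, -1)

    if start_month is None:
        monthly_mean = flatP.reshape(n_years, 12, -1).mean(axis=(0, 2))
        start_month = int(np.argmax(monthly_mean))
    rolledP = np.roll(flatP, -start_month, axis=0).reshape(n_years, 12, -1)
    rolledE = np.roll(flatE, -start_month, axis=0).reshape(n_years, 12, -1)
    # rolling wraps the first start_month months into the last year; with a
    # climatological (periodic) series this is the standard hydrological-year
    # alignment.
    balance = rolledP - rolledE
    wd = np.zeros(balance.shape[::2])  # (n_years, n_pix) running deficit
    annual_min = np.zeros_like(wd)
    for m in range(12):
        wd = np.minimum(0.0, wd + balance[:, m, :])
        annual_min = np.minimum(annual_min, wd)
    out = annual_min.mean(axis=0) if multi_year == "mean" else annual_min.min(axis=0)
    if P.ndim == 1:
        return float(out[0])
    return out.reshape(P.shape[1:])


def tmax_mean(tmax: np.ndarray) -> np.ndarray | float:
    """Mean of the monthly maximum-temperature series (leading month axis)."""
    T = np.asarray(tmax, dtype=float)
    if T.shape[0] < 12:
        raise ValueError("need at least 12 monthly values")
    out = T.mean(axis=0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# terrain


def slope_from_dem(elevation: np.ndarray, pixel_size: float) -> np.ndarray:
    """Slope in degrees from Horn's eight-neighbour finite differences."""
    from scipy.ndimage import convolve

    dem = np.asarray(elevation, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 3:
        raise ValueError("elevation grid must be at least 3x3")
    if not np.isfinite(dem).all():
        raise ValueError("elevation contains non-finite values")
    kx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / (8.0 * pixel_size)
    # row 0 is the southernmost row, so +y is +row
    ky = kx.T
    dzdx = convolve(dem, kx[::-1, ::-1], mode="nearest")
    dzdy = convolve(dem, ky[::-1, ::-1], mode="nearest")
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


# ---------------------------------------------------------------------------
# stack assembly


class CovariateStack:
    """Named co-registered layers on one pixel grid."""

    def __init__(self, grid: PixelGrid):
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}

    def add(self, name: str, values: np.ndarray,
            source_grid: PixelGrid | None = None, method: str = "nearest") -> None:
        """Add a layer, resampling from ``source_grid`` if it differs."""
        values = np.asarray(values, dtype=float)
        if source_grid is not None and source_grid != self.grid:
            sx0, sy0, sx1, sy1 = source_grid.extent
            tx0, ty0, tx1, ty1 = self.grid.extent
            if sx0 > tx0 + 1e-9 or sy0 > ty0 + 1e-9 or sx1 < tx1 - 1e-9 or sy1 < ty1 - 1e-9:
                raise ValueError(f"layer {name!r} does not cover the target grid")
            values = resample_to_grid(values, source_grid, self.grid, method=method)
        if values.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape {values.shape} != grid {self.grid.shape}")
        self.layers[name] = values

    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_pixels, n_layers) matrix in row-major pixel order."""
        names = names or self.names()
        return np.stack([self.layers[n].ravel() for n in names], axis=1)


def build_stack(
    reflectance: dict[str, np.ndarray],
    grid: PixelGrid,
    climate=None,
    environment: dict[str, np.ndarray] | None = None,
    texture_window: int = 9,
    texture_levels: int = 32,
    climate_resampling: str = "nearest",
    mcwd_multi_year: str = "mean",
) -> CovariateStack:
    """Assemble the full covariate stack on the pixel grid.

    Bands, the three vegetation indices, GLCM entropy/correlation per index,
    MCWD and mean Tmax (resampled from the coarse climate grid), slope from
    the elevation layer, and the four soil layers.
    """
    stack = CovariateStack(grid)
    for b, layer in reflectance.items():
        stack.add(b, layer)
    idx_layers = {
        "mcari": mcari(reflectance["B3"], reflectance["B4"], reflectance["B5"]),
        "msavi2": msavi2(reflectance["B4"], reflectance["B8"]),
        "ndre": ndre(reflectance["B5"], reflectance["B8"]),
    }
    for name, layer in idx_layers.items():
        stack.add(name, layer)
        ent, corr = glcm_texture(layer, window=texture_window, levels=texture_levels)
        stack.add(f"{name}_entropy", ent)
        stack.add(f"{name}_correlation", corr)
    if climate is not None:
        wd = mcwd(climate.precipitation, climate.pet, multi_year=mcwd_multi_year)
        tm = tmax_mean(climate.tmax)
        stack.add("mcwd", wd, source_grid=climate.grid, method=climate_resampling)
        stack.add("tmax", tm, source_grid=climate.grid, method=climate_resampling)
    if environment is not None:
        stack.add("slope", slope_from_dem(environment["elevation"], grid.pixel_size))
        for soil in ("soil_ph", "soil_cec", "soil_sand", "soil_clay"):
            stack.add(soil, environment[soil])
    return stack
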