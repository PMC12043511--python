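"""Functional trait space: PCA, trait probability densities, FRich, FDiv.

The predicted trait maps are standardized and decomposed with PCA; the first
two component scores span the functional trait space. A Gaussian kernel
density on a rectangular grid of PC-space cells gives the trait probability
density (TPD): per-cell probability mass summing to 1. Trimming keeps the
highest-density cells holding a stated total mass (default 0.99).

Functional richness (FRich) is the area of the retained cells. Functional
divergence (FDiv) measures how much probability mass sits far from the
centre of gravity of the retained cells:

    FDiv = (Dd + d_bar) / (D|d| + d_bar)

with d_i the distance of cell i to the unweighted centroid of retained
cells, d_bar their unweighted mean, Dd = sum p_i (d_i - d_bar) and
D|d| = sum p_i |d_i - d_bar| over renormalized retained mass. FDiv is 1 when
all mass sits on a ring equidistant from the centroid and tends to 0.5-0.8
for diffuse distributions; it is bounded in [0, 1].

Regional TPDs are evaluated on the shared global grid with the global
bandwidth so their FRich/FDiv are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCAModel:
    loadings: np.ndarray            # (n_components, n_traits), orthonormal rows
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                # per-trait centering
    scale: np.ndarray               # per-trait standardization
    scores: np.ndarray              # (n_pixels, n_components)
    trait_names: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.scale) @ self.loadings.T


@dataclass
class TPDGrid:
    """Probability mass over a rectangular grid of (PC1, PC2) cells."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    p: np.ndarray                # (ny, nx) cell probability mass, sums to 1
    retained: np.ndarray         # bool mask after trimming
    trim_level: float
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return np.meshgrid(cx, cy)


@dataclass
class DiversityMetrics:
    region: str
    frich: float
    fdiv: float


# ---------------------------------------------------------------------------
# PCA


def fit_pca(X: np.ndarray, trait_names: list[str] | None = None, n_components: int = 3) -> PCAModel:
    """PCA of a pixel x trait matrix, traits standardized first.

    Rows with any NaN are dropped before fitting; scores are returned for the
    complete rows in their original order.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 pixels and 2 traits")
    ok = np.isfinite(X).all(axis=1)
    Xc = X[ok]
    mean = Xc.mean(axis=0)
    scale = Xc.std(axis=0)
    if np.any(scale == 0):
        bad = [i for i, s in enumerate(scale) if s == 0]
        raise ValueError(f"constant trait column(s): {bad}")
    Z = (Xc - mean) / scale
    k = min(n_components, Z.shape[1])
    pca = PCA(n_components=Z.shape[1], svd_solver="full")
    scores_full = pca.fit_transform(Z)
    if trait_names is None:
        trait_names = [f"trait{i}" for i in range(X.shape[1])]
    return PCAModel(
        loadings=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=mean,
        scale=scale,
        scores=scores_full[:, :k],
        trait_names=list(trait_names),
    )


# ---------------------------------------------------------------------------
# TPD


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule per axis for a 2-D KDE: h = sigma * n^(-1/6)."""
    n = len(x)
    return float(np.std(x) * n ** (-1.0 / 6.0))


def estimate_tpd(
    scores: np.ndarray,
    grid_size: int = 200,
    bandwidth: tuple[float, float] | None = None,
    trim_level: float = 0.99,
    extent: tuple[float, float, float, float] | None = None,
    max_points: int | None = None,
    seed: int = 0,
) -> TPDGrid:
    """Gaussian-kernel TPD of (PC1, PC2) scores on a rectangular cell grid.

    The grid spans the score range plus 3 bandwidths of padding (or the given
    ``extent``); density at cell centres is converted to per-cell mass and
    normalized to sum to 1. Trimming retains the highest-density cells that
    jointly hold ``trim_level`` of the mass.
    """
    S = np.asarray(scores, dtype=float)
    S = S[np.isfinite(S).all(axis=1)]
    if S.shape[0] < 10:
        raise ValueError("need at least 10 score points")
    if max_points is not None and len(S) > max_points:
        rng = np.random.default_rng(seed)
        S = S[rng.choice(len(S), size=max_points, replace=False)]
    x, y = S[:, 0], S[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance scores")
    if bandwidth is None:
        bandwidth = (silverman_bandwidth(x), silverman_bandwidth(y))
    hx, hy = bandwidth
    if extent is None:
        extent = (x.min() - 3 * hx, x.max() + 3 * hx, y.min() - 3 * hy, y.max() + 3 * hy)
    x0, x1, y0, y1 = extent
    x_edges = np.linspace(x0, x1, grid_size + 1)
    y_edges = np.linspace(y0, y1, grid_size + 1)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])

    # separable Gaussian kernels: density = (Ky @ Kx^T)/n with per-point columns
    # computed in chunks to bound memory
    dens = np.zeros((grid_size, grid_size))
    chunk = 2000
    for s in range(0, len(x), chunk):
        xe = np.exp(-0.5 * ((cx[:, None] - x[None, s:s + chunk]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
        ye = np.exp(-0.5 * ((cy[:, None] - y[None, s:s + chunk]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
        dens += ye @ xe.T
    dens /= len(x)

    p = dens * (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate density")
    p = p / total
    retained = _trim_mask(p, trim_level)
    return TPDGrid(
        x_edges=x_edges, y_edges=y_edges, p=p, retained=retained,
        trim_level=trim_level, bandwidth=(hx, hy),
    )


def _trim_mask(p: np.ndarray, level: float) -> np.ndarray:
    """Highest-density cells jointly holding ``level`` of the total mass."""
    if not 0 < level <= 1:
        raise ValueError("trim level must be in (0, 1]")
    flat = p.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level * flat.sum() - 1e-12)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(p.shape)


def quantile_contours(tpd: TPDGrid, levels: tuple[float, ...] = (0.5, 0.99)) -> dict[float, np.ndarray]:
    """Minimal highest-density cell sets containing each probability level."""
    out = {}
    for level in levels:
        if not 0 < level < 1:
            raise ValueError("contour levels must be in (0, 1)")
        out[level] = _trim_mask(tpd.p, level)
    return out


# ---------------------------------------------------------------------------
# diversity metrics


def frich(tpd: TPDGrid) -> float:
    """Functional richness: area of the retained cells (PC-space units^2)."""
    k = int(tpd.retained.sum())
    if k == 0:
        raise ValueError("empty retained set")
    return k * tpd.cell_area


def fdiv(tpd: TPDGrid) -> float:
    """Functional divergence in [0, 1] (see module docstring for the form)."""
    mask = tpd.retained
    if mask.sum() < 2:
        raise ValueError("need at least 2 retained cells")
    CX, CY = tpd.cell_centers()
    cx, cy = CX[mask], CY[mask]
    p = tpd.p[mask]
    psum = p.sum()
    if psum <= 0:
        raise ValueError("no probability mass on retained cells")
    p = p / psum
    gx, gy = cx.mean(), cy.mean()  # unweighted centre of gravity
    d = np.hypot(cx - gx, cy - gy)
    dbar = d.mean()
    if dbar == 0 and np.allclose(d, 0):
        raise ValueError("all retained cells coincident")
    delta_d = float(np.sum(p * (d - dbar)))
    delta_abs = float(np.sum(p * np.abs(d - dbar)))
    return (delta_d + dbar) / (delta_abs + dbar)


def regional_tpd(
    scores_by_region: dict[str, np.ndarray],
    global_tpd: TPDGrid,
    min_pixels: int = 10,
) -> dict[str, TPDGrid]:
    """Per-region TPDs evaluated on the global grid with the global bandwidth.

    Sharing the grid and bandwidth makes regional FRich/FDiv directly
    comparable with each other and with the global values.
    """
    extent = (
        float(global_tpd.x_edges[0]), float(global_tpd.x_edges[-1]),
        float(global_tpd.y_edges[0]), float(global_tpd.y_edges[-1]),
    )
    grid_size = len(global_tpd.x_edges) - 1
    out = {}
    for region, scores in scores_by_region.items():
        S = np.asarray(scores)
        S = S[np.isfinite(S).all(axis=1)]
        if len(S) < min_pixels:
            raise ValueError(f"region {region!r} has fewer than {min_pixels} pixels")
        out[region] = estimate_tpd(
            S, grid_size=grid_size, bandwidth=global_tpd.bandwidth,
            trim_level=global_tpd.trim_level, extent=extent,
        )
    return out


def diversity_metrics(tpds: dict[str, TPDGrid]) -> list[DiversityMetrics]:
    return [DiversityMetrics(region=r, frich=frich(t), fdiv=fdiv(t)) for r, t in tpds.items()]
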