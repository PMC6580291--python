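"""Climatic-niche overlap between species (Schoener's D in a 2-D environment space).

Occurrence-by-climate tables (five bioclimatic variables per occurrence) are
standardized and projected onto the two leading principal axes of the pooled
data; each species' occupancy is kernel-smoothed on a shared grid and
normalized to a density, and overlap between two species is
D = 1 - 0.5 * sum|z1 - z2| (0 = disjoint niches, 1 = identical).  Densities
are smoothed in environment space only; no geographic background correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

__all__ = [
    "CLIMATE_VARIABLES",
    "EnvGrid",
    "env_axes",
    "density_grid",
    "schoener_d",
    "niche_overlap",
]

#: default bioclimatic variables expected in occurrence tables
CLIMATE_VARIABLES = (
    "precip_seasonality",
    "annual_precip",
    "annual_mean_temp",
    "mean_diurnal_range",
    "annual_temp_range",
)


@dataclass
class EnvGrid:
    """Per-species occupancy densities on a shared R x R environment grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    densities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for sp, z in self.densities.items():
            if (z < 0).any():
                raise ValueError(f"negative density for {sp}")
            if abs(z.sum() - 1.0) > 1e-9:
                raise ValueError(f"density for {sp} does not sum to 1")


def env_axes(occ: pd.DataFrame, variables=CLIMATE_VARIABLES):
    """Standardize the climate variables on the pooled data and project onto
    the two leading principal axes.

    Returns ``(coords, info)`` where *coords* is a DataFrame with columns
    ``species, pc1, pc2`` and *info* carries loadings and explained variance.
    """
    if occ["species"].nunique() < 2:
        raise ValueError("need at least 2 species pooled")
    X = occ[list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing climate values are not allowed")
    sd = X.std(axis=0)
    for name, s in zip(variables, sd):
        if s == 0:
            raise ValueError(f"variable {name!r} is constant")
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2)
    Y = pca.fit_transform(Xs)
    coords = pd.DataFrame({"species": occ["species"].to_numpy(), "pc1": Y[:, 0], "pc2": Y[:, 1]})
    info = {
        "loadings": pd.DataFrame(pca.components_.T, index=list(variables), columns=["pc1", "pc2"]),
        "explained_variance": pca.explained_variance_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    return coords, info


def density_grid(coords: pd.DataFrame, R: int = 100, bandwidth="scott", pad: float = 0.1) -> EnvGrid:
    """Gaussian-kernel occupancy density per species on a shared R x R grid.

    The grid spans the pooled extent padded by *pad* times the range on each
    axis; *bandwidth* is passed to the kernel density estimator (Scott's rule
    by default).  Each species' density is normalized to sum to 1.
    """
    x, y = coords["pc1"].to_numpy(), coords["pc2"].to_numpy()
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("all points identical: no density can be estimated")
    dx = np.ptp(x) or 1.0
    dy = np.ptp(y) or 1.0
    x_edges = np.linspace(x.min() - pad * dx, x.max() + pad * dx, R + 1)
    y_edges = np.linspace(y.min() - pad * dy, y.max() + pad * dy, R + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    pts = np.vstack([gx.ravel(), gy.ravel()])
    densities = {}
    for sp, sub in coords.groupby("species"):
        pxy = np.vstack([sub["pc1"].to_numpy(), sub["pc2"].to_numpy()])
        if pxy.shape[1] < 3 or np.linalg.matrix_rank(np.cov(pxy)) < 2:
            # degenerate cloud: fall back to an isotropic kernel around points
            z = _isotropic_density(pxy, gx, gy, dx, dy)
        else:
            kde = gaussian_kde(pxy, bw_method=bandwidth)
            z = kde(pts).reshape(R, R)
        tot = z.sum()
        if tot <= 0:
            raise ValueError(f"zero density mass for species {sp!r}")
        densities[sp] = z / tot
    return EnvGrid(x_edges, y_edges, densities)


def _isotropic_density(pxy, gx, gy, dx, dy):
    bw = 0.05 * max(dx, dy)
    z = np.zeros_like(gx)
    for px, py in pxy.T:
        z += np.exp(-0.5 * (((gx - px) / bw) ** 2 + ((gy - py) / bw) ** 2))
    return z


def schoener_d(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's overlap D = 1 - 0.5 * sum|z1 - z2| for two normalized
    densities on the same grid."""
    z1, z2 = np.asarray(z1), np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("density grids mismatch")
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


def niche_overlap(occ: pd.DataFrame, R: int = 100, variables=CLIMATE_VARIABLES, bandwidth="scott") -> pd.DataFrame:
    """Pairwise Schoener's D matrix from an occurrence-by-climate table."""
    coords, _ = env_axes(occ, variables)
    grid = density_grid(coords, R=R, bandwidth=bandwidth)
    species = sorted(grid.densities)
    mat = pd.DataFrame(1.0, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            d = schoener_d(grid.densities[a], grid.densities[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat
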