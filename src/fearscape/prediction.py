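"""Per-occasion prediction surfaces of intensity of space use.

Covariates are extended from the 21 sites to a regular grid — distance
covariates exactly per cell centre, availability covariates by
inverse-distance-weighted interpolation of the site values — standardized
with the training scaling record, and combined with conditional (kriging)
simulation of the latent field given each retained posterior draw.  The map
value is the posterior mean of exp(z beta + xi) - 1, the inverse of the
log(x + 1) response transform, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon

from .landscape import Landscape
from .stmodel import PosteriorFit, matern1_correlation


@dataclass
class GridSpec:
    """Regular grid: origin is the lower-left corner of the lower-left cell."""

    x0: float
    y0: float
    cell_size: float = 50.0
    n_rows: int = 100
    n_cols: int = 100

    def cell_centres(self) -> np.ndarray:
        """(n_rows * n_cols, 2) centres, row-major from the top row down."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class PredictionRaster:
    """One gridded surface per occasion plus georeferencing metadata."""

    grid: GridSpec
    layers: dict[int, np.ndarray]  # occasion -> (n_rows, n_cols)
    nodata_mask: np.ndarray | None = None  # True where outside data support

    def to_ascii_grid(self, occasion: int, nodata: float = -9999.0) -> str:
        """Serialise one occasion layer as an ESRI ASCII grid."""
        layer = self.layers[occasion].copy()
        if self.nodata_mask is not None:
            layer[self.nodata_mask] = nodata
        head = (
            f"ncols {self.grid.n_cols}\n"
            f"nrows {self.grid.n_rows}\n"
            f"xllcorner {self.grid.x0}\n"
            f"yllcorner {self.grid.y0}\n"
            f"cellsize {self.grid.cell_size}\n"
            f"NODATA_value {nodata}\n"
        )
        body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in layer)
        return head + body + "\n"


def idw_interpolate(
    site_coords: np.ndarray,
    site_values: np.ndarray,
    targets: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation, exact at the data nodes."""
    d = cdist(np.asarray(targets, float), np.asarray(site_coords, float))
    out = np.empty(len(targets))
    at_node = d < 1e-9
    w = 1.0 / np.maximum(d, 1e-9) ** power
    out = (w * site_values).sum(axis=1) / w.sum(axis=1)
    hit = at_node.any(axis=1)
    if hit.any():
        out[hit] = site_values[np.argmax(at_node[hit], axis=1)]
    return out


def covariate_surfaces(
    landscape: Landscape,
    availability: dict[str, np.ndarray],
    grid: GridSpec,
    occasion: int,
    scaling=None,
    idw_power: float = 2.0,
    clip_polygon: Polygon | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate matrix at grid-cell centres for one occasion.

    ``availability`` maps covariate name -> (S, T) site x occasion values for
    availability-type covariates; distance covariates are recognised by name
    (dist_village, dist_road, dist_agriculture, dist_forest) and evaluated
    exactly from the landscape geometry.  ``scaling`` (a ScalingRecord from
    model training) fixes both the covariate order and the z-scoring.
    Returns (z_grid (n_cells, p), nodata mask (n_cells,)).
    """
    if scaling is None:
        raise ValueError("a training ScalingRecord is required to order and scale covariates")
    centres = grid.cell_centres()
    village_like = list(landscape.villages) + list(landscape.settlements)
    dist_features = {
        "dist_village": village_like,
        "dist_road": list(landscape.roads),
        "dist_agriculture": list(landscape.agriculture),
        "dist_forest": [landscape.forest_block] if landscape.forest_block is not None else [],
    }
    site_xy = landscape.site_coords()
    cols = []
    for name in scaling.names:
        if name in dist_features:
            feats = dist_features[name]
            if not feats:
                raise ValueError(f"landscape lacks features for covariate {name!r}")
            import shapely

            geoms = shapely.points(centres[:, 0], centres[:, 1])
            dmat = np.column_stack([shapely.distance(geoms, f) for f in feats])
            cols.append(dmat.min(axis=1))
        elif name in availability:
            vals = np.asarray(availability[name], float)[:, occasion - 1]
            cols.append(idw_interpolate(site_xy, vals, centres, power=idw_power))
        else:
            raise KeyError(f"no surface source for covariate {name!r}")
    z_raw = np.column_stack(cols)
    z = scaling.apply(z_raw)

    nodata = np.zeros(len(centres), dtype=bool)
    if clip_polygon is not None:
        import shapely

        pts = shapely.points(centres[:, 0], centres[:, 1])
        nodata = ~shapely.contains(clip_polygon, pts)
    return z, nodata


def predict_surface(
    fit: PosteriorFit,
    z_grid: np.ndarray,
    grid: GridSpec,
    occasion: int,
    seed: int = 0,
    max_draws: int = 100,
    nodata_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One occasion's predicted intensity layer from a fitted model.

    For each retained posterior draw, the latent field at the grid cells is
    simulated from its conditional Gaussian given that draw's site-level
    field and Matern range (simple kriging; separability makes the weights
    purely spatial), cell-wise.  The layer is the posterior mean of
    exp(z beta + xi) - 1 floored at 0, on the response (rate) scale.
    """
    T = fit.draws["xi"].shape[2]
    if not (1 <= occasion <= T):
        raise ValueError(f"occasion must be in 1..{T}")
    rng = np.random.default_rng(seed)
    centres = grid.cell_centres()
    n_cells = len(centres)
    draws = fit.draws
    n_keep = len(draws["beta"])
    use = np.linspace(0, n_keep - 1, min(max_draws, n_keep)).astype(int)

    d_ss = cdist(fit.coords, fit.coords)
    d_gs = cdist(centres, fit.coords)
    acc = np.zeros(n_cells)
    for i in use:
        rho = draws["rho"][i]
        marg = draws["sigma2_omega"][i] / (1.0 - draws["a"][i] ** 2)
        R_ss = matern1_correlation(d_ss, rho) + 1e-10 * np.eye(len(fit.coords))
        R_gs = matern1_correlation(d_gs, rho)
        cf = linalg.cho_factor(R_ss, lower=True, check_finite=False)
        W = linalg.cho_solve(cf, R_gs.T, check_finite=False).T  # kriging weights
        xi_site = draws["xi"][i][:, occasion - 1]
        mu = W @ xi_site
        cond_var = np.maximum(marg * (1.0 - np.sum(R_gs * W, axis=1)), 0.0)
        xi_cell = mu + np.sqrt(cond_var) * rng.standard_normal(n_cells)
        eta = z_grid @ draws["beta"][i][1:] + draws["beta"][i][0] + xi_cell
        acc += np.maximum(np.expm1(eta), 0.0)
    layer = (acc / len(use)).reshape(grid.n_rows, grid.n_cols)
    if nodata_mask is not None:
        layer = layer.copy()
    return layer


def quicklook_png(layer: np.ndarray, grid: GridSpec, path: str, title: str = "") -> None:
    """Write a single-panel PNG of one prediction layer (for animation frames)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    extent = (
        grid.x0,
        grid.x0 + grid.n_cols * grid.cell_size,
        grid.y0,
        grid.y0 + grid.n_rows * grid.cell_size,
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(layer, extent=extent, origin="upper", cmap="viridis")
    fig.colorbar(im, ax=ax, label="predicted intensity of use")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
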