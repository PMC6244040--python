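"""Ordinary kriging over 2D scattered points.

Used to interpolate the canopy-maximum point set of a plot into a continuous
height surface whose maximum serves as the plot-scale plant height.  Ordinary
kriging with a zero nugget is an exact interpolator: the surface passes
through every data point, so the predicted maximum can never fall below the
largest observed canopy maximum.

The variogram is fitted to the isotropic empirical semivariogram by bounded
least squares: a spherical model first, falling back to a linear model when
the spherical fit fails (too few lag bins, or a degenerate optimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class Variogram:
    """Fitted semivariogram model, nugget fixed at zero."""

    model: str  # "spherical" | "linear" | "constant"
    sill: float = 0.0
    range_: float = 1.0
    slope: float = 0.0

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.model == "spherical":
            hr = np.minimum(h / self.range_, 1.0)
            return self.sill * (1.5 * hr - 0.5 * hr**3)
        if self.model == "linear":
            return self.slope * h
        return np.zeros_like(h)


def empirical_semivariogram(
    xy: np.ndarray, z: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Binned isotropic semivariogram: lag centers and mean 0.5*(dz)^2."""
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    gamma = 0.5 * (z[:, None] - z[None, :]) ** 2
    iu = np.triu_indices(len(z), k=1)
    d, g = dist[iu], gamma[iu]
    if d.size == 0 or d.max() == 0:
        return np.array([]), np.array([])
    edges = np.linspace(0, d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    lags, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            lags.append(d[sel].mean())
            means.append(g[sel].mean())
    return np.asarray(lags), np.asarray(means)


def fit_variogram(xy: np.ndarray, z: np.ndarray) -> Variogram:
    if np.ptp(z) == 0:
        return Variogram("constant")
    lags, gammas = empirical_semivariogram(xy, z)
    if len(lags) >= 3 and gammas.max() > 0:
        def spherical(h, sill, rng):
            hr = np.minimum(h / rng, 1.0)
            return sill * (1.5 * hr - 0.5 * hr**3)

        try:
            (sill, rng_), _ = curve_fit(
                spherical, lags, gammas,
                p0=[gammas.max(), max(lags.max() / 2, 1e-9)],
                bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=2000,
            )
            return Variogram("spherical", sill=float(sill), range_=float(rng_))
        except (RuntimeError, ValueError):
            pass
    # linear fallback through the origin
    denom = float((lags**2).sum()) if len(lags) else 0.0
    slope = float((lags * gammas).sum() / denom) if denom > 0 else 0.0
    if slope <= 0:
        return Variogram("constant")
    return Variogram("linear", slope=slope)


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse coincident locations, keeping the larger value (canopy maxima)."""
    order = np.lexsort((-z, xy[:, 1], xy[:, 0]))
    xy, z = xy[order], z[order]
    keep = np.ones(len(z), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(xy, axis=0)) > 1e-9, axis=1)
    return xy[keep], z[keep]


def krige(
    xy: np.ndarray, z: np.ndarray, query_xy: np.ndarray,
    variogram: Variogram | None = None,
) -> np.ndarray:
    """Ordinary-kriging predictions at ``query_xy`` from data (xy, z)."""
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    query_xy = np.asarray(query_xy, dtype=float)
    if len(z) == 0:
        raise ValueError("kriging requires at least one data point")
    xy, z = _dedupe(xy, z)
    n = len(z)
    if n == 1 or np.ptp(z) == 0:
        return np.full(len(query_xy), z.max())
    vg = variogram or fit_variogram(xy, z)
    if vg.model == "constant":
        return np.full(len(query_xy), z.mean())

    diff = xy[:, None, :] - xy[None, :, :]
    gamma_dd = vg(np.sqrt((diff**2).sum(-1)))
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = gamma_dd
    lhs[n, :], lhs[:, n] = 1.0, 1.0
    lhs[n, n] = 0.0

    dq = query_xy[:, None, :] - xy[None, :, :]
    rhs = np.empty((n + 1, len(query_xy)))
    rhs[:n] = vg(np.sqrt((dq**2).sum(-1))).T
    rhs[n] = 1.0
    try:
        weights = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        weights = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return weights[:n].T @ z
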