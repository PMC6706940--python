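"""Two-dimensional locally weighted polynomial regression (LOESS).

Used to smooth log10 C-peptide over the (age at onset, duration) plane:
a degree-2 local polynomial with tricube weights over the nearest
``span`` fraction of points, evaluated on a grid and back-transformed to the
geometric-mean C-peptide surface.  Distances are Euclidean on predictors
standardized to unit SD.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

_N_TERMS = {1: 3, 2: 6}


def _basis(dx: np.ndarray, dy: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(dx), dx, dy]
    if degree == 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.column_stack(cols)


def loess_fit_grid(x1, x2, y, grid1, grid2, degree: int = 2,
                   span: float = 0.25) -> np.ndarray:
    """Local polynomial fit of ``y`` on (x1, x2) evaluated at the grid.

    Returns an array of shape (len(grid1), len(grid2)) on the scale of
    ``y``.  Raises if the span gives fewer neighbours than the polynomial
    needs.
    """
    if degree not in _N_TERMS:
        raise ConfigurationError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ConfigurationError("span must be in (0, 1]")
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    y = np.asarray(y, float)
    n = len(y)
    k = int(np.ceil(span * n))
    if k < _N_TERMS[degree]:
        raise ConfigurationError(
            f"span {span} gives {k} local points; degree {degree} needs "
            f">= {_N_TERMS[degree]}")
    s1 = x1.std() or 1.0
    s2 = x2.std() or 1.0
    u1, u2 = x1 / s1, x2 / s2

    out = np.empty((len(grid1), len(grid2)))
    for i, g1 in enumerate(grid1):
        for j, g2 in enumerate(grid2):
            dx = u1 - g1 / s1
            dy = u2 - g2 / s2
            d = np.hypot(dx, dy)
            dmax = np.partition(d, k - 1)[k - 1]
            if dmax == 0:
                # all selected points coincide with the node
                out[i, j] = y[d == 0].mean()
                continue
            w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
            use = w > 0
            if use.sum() < _N_TERMS[degree]:
                # boundary tie: fall back to the k nearest with equal weight
                use = d <= dmax
                w = np.where(use, 1.0, 0.0)
            B = _basis(dx[use], dy[use], degree)
            sw = np.sqrt(w[use])
            coef, *_ = np.linalg.lstsq(B * sw[:, None], y[use] * sw, rcond=None)
            out[i, j] = coef[0]
    return out


def loess_surface(age_onset, duration, log_cpep, grid_onset=None,
                  grid_duration=None, degree: int = 2,
                  span: float = 0.25) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric-mean C-peptide surface over (onset, duration).

    Fits log10 C-peptide locally and back-transforms (10**fit).  Returns
    (grid_onset, grid_duration, surface) with surface shaped
    (len(grid_onset), len(grid_duration)).
    """
    age_onset = np.asarray(age_onset, float)
    duration = np.asarray(duration, float)
    if grid_onset is None:
        grid_onset = np.linspace(age_onset.min(), age_onset.max(), 25)
    if grid_duration is None:
        grid_duration = np.linspace(duration.min(), duration.max(), 25)
    fit = loess_fit_grid(age_onset, duration, np.asarray(log_cpep, float),
                         grid_onset, grid_duration, degree=degree, span=span)
    return np.asarray(grid_onset), np.asarray(grid_duration), np.power(10.0, fit)
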