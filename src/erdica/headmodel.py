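"""Analytic spherical head model: dipole forward solutions and inverse fits.

A single homogeneous conducting sphere stands in for anatomical head
geometry.  The scalp potential of a current dipole at radius ``b`` inside a
sphere of radius ``R`` and conductivity ``sigma`` is the classical Legendre
series

    V(r_e) = 1/(4*pi*sigma) * sum_{n>=1} (2n+1)/n * b^(n-1)/R^(n+1)
             * [ n*q_r*P_n(cos g) + q_t*P_n^1(cos g) ]

with ``g`` the angle between the dipole position and the electrode, ``q_r``
the radial and ``q_t`` the tangential moment component.  The series is
evaluated with stable recurrences and truncated adaptively; potentials are
returned average-referenced, matching how EEG scalp maps are analysed.

The inverse problem (equivalent current dipole for a scalp topography) is
solved by a deterministic multi-start search: the moment enters the forward
model linearly, so for every candidate location the optimal moment is a
linear least-squares solve, and only the 3-D location is optimised
nonlinearly.  Goodness of fit is reported as residual variance (RV), the
fraction of scalp-map variance the dipole does not explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SphereModel",
    "DipoleFit",
    "scalp_potential",
    "dipole_gain",
    "fit_dipole",
    "fibonacci_scalp_montage",
]


def fibonacci_scalp_montage(n_channels: int, sphere: "SphereModel | None" = None,
                            zmin_frac: float = -0.25) -> np.ndarray:
    """Deterministic quasi-uniform electrode layout on the upper scalp.

    Points of a Fibonacci lattice on the sphere, restricted to
    ``z >= zmin_frac * R`` (EEG caps extend a little below the equator but do
    not cover the face or neck).  Returns an (n_channels, 3) array in mm.
    """
    sphere = sphere or SphereModel()
    golden = (1 + 5 ** 0.5) / 2
    # oversample the full sphere, keep the top band, take the first n points
    n_total = max(int(np.ceil(n_channels / ((1 - zmin_frac) / 2))) * 2, n_channels)
    i = np.arange(n_total)
    z = 1 - (2 * i + 1) / n_total            # uniform in [-1, 1]
    theta = 2 * np.pi * i / golden
    keep = z >= zmin_frac
    z, theta = z[keep], theta[keep]
    if z.size < n_channels:
        raise ValueError("cannot place that many electrodes in the scalp band")
    idx = np.linspace(0, z.size - 1, n_channels).round().astype(int)
    z, theta = z[idx], theta[idx]
    rho = np.sqrt(1 - z ** 2)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts * sphere.radius


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous conducting sphere.

    Parameters are in the head frame used throughout the package: origin at
    the sphere centre, +X right, +Y anterior, +Z superior, millimetres.
    """

    radius: float = 85.0            # scalp radius, mm
    conductivity: float = 0.33      # S/m
    brain_radius_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        if not 0 < self.brain_radius_fraction < 1:
            raise ValueError("brain_radius_fraction must lie in (0, 1)")

    @property
    def brain_radius(self) -> float:
        return self.brain_radius_fraction * self.radius


@dataclass
class DipoleFit:
    """Equivalent current dipole explaining a scalp topography."""

    location: np.ndarray        # (3,) mm
    moment: np.ndarray          # (3,) arbitrary source units (nominally nA*m)
    residual_variance: float    # fraction of scalp-map variance unexplained

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if not 0.0 <= self.residual_variance <= 1.0 + 1e-12:
            raise ValueError("residual variance must lie in [0, 1]")


def _check_electrodes(electrode_positions: np.ndarray, sphere: SphereModel) -> np.ndarray:
    pos = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    if pos.shape[1] != 3:
        raise ValueError("electrode_positions must be (n_electrodes, 3)")
    radii = np.linalg.norm(pos, axis=1)
    if np.any(np.abs(radii - sphere.radius) > 0.01 * sphere.radius):
        raise ValueError("electrodes must lie on the scalp sphere (1% radial tolerance)")
    return pos


def dipole_gain(
    r0: np.ndarray,
    electrode_positions: np.ndarray,
    sphere: SphereModel | None = None,
    *,
    rtol: float = 1e-10,
    max_terms: int = 200,
    check: bool = True,
) -> np.ndarray:
    """Forward gain matrix G such that ``V = G @ q`` for a dipole at ``r0``.

    Returns an (n_electrodes, 3) average-referenced gain matrix.  The
    Legendre series is truncated once the largest per-electrode term falls
    below ``rtol`` of the accumulated potential scale, with a hard cap of
    ``max_terms`` terms.
    """
    sphere = sphere or SphereModel()
    r0 = np.asarray(r0, dtype=float).reshape(3)
    pos = _check_electrodes(electrode_positions, sphere) if check else np.atleast_2d(electrode_positions)
    R = sphere.radius
    b = float(np.linalg.norm(r0))
    if b >= R:
        raise ValueError(f"dipole at radius {b:.1f} mm lies outside the sphere (R={R:.1f} mm)")

    r_hat = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    e_hat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    x = np.clip(e_hat @ r_hat, -1.0, 1.0)            # cos(gamma), per electrode
    # u = sin(gamma) * tangential unit vector; keeps the series free of a
    # division by sin(gamma) because P_n^1 = sin(gamma) * dP_n/dx.
    u = e_hat - x[:, None] * r_hat[None, :]

    n_e = pos.shape[0]
    G = np.zeros((n_e, 3))
    # Legendre recurrences: P_n and the derivative D_n = dP_n/dx.
    P_prev = np.ones(n_e)          # P_0
    P_cur = x.copy()               # P_1
    D_prev = np.zeros(n_e)         # P_0'
    D_cur = np.ones(n_e)           # P_1'
    scale = 1.0 / (4.0 * np.pi * sphere.conductivity * R ** 2)
    f = b / R
    f_pow = 1.0                    # (b/R)^(n-1) for n = 1
    below = 0
    for n in range(1, max_terms + 1):
        c_n = scale * (2 * n + 1) / n * f_pow
        term = c_n * (n * P_cur[:, None] * r_hat[None, :] + D_cur[:, None] * u)
        G += term
        ref = max(float(np.abs(G).max()), 1e-300)
        if float(np.abs(term).max()) < rtol * ref:
            below += 1
            if below >= 2:        # two consecutive negligible terms
                break
        else:
            below = 0
        if b == 0.0:              # only n=1 survives for a central dipole
            break
        # advance recurrences to n+1
        P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
        D_next = D_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        D_prev, D_cur = D_cur, D_next
        f_pow *= f
    G -= G.mean(axis=0, keepdims=True)
    return G


def scalp_potential(
    r0: np.ndarray,
    q: np.ndarray,
    electrode_positions: np.ndarray,
    sphere: SphereModel | None = None,
    *,
    rtol: float = 1e-10,
    max_terms: int = 200,
) -> np.ndarray:
    """Average-referenced scalp potential of a dipole (location ``r0``, moment ``q``)."""
    q = np.asarray(q, dtype=float).reshape(3)
    G = dipole_gain(r0, electrode_positions, sphere, rtol=rtol, max_terms=max_terms)
    return G @ q


# --- inverse fit -----------------------------------------------------------

# Cache of precomputed source-space scan grids keyed by electrode layout,
# sphere geometry and grid spacing; scanning the grid is the expensive part
# of a fit and is identical across topographies on the same montage.
_GRID_CACHE: dict = {}


def _scan_grid(electrode_positions: np.ndarray, sphere: SphereModel, spacing: float):
    key = (
        hash(np.ascontiguousarray(electrode_positions, dtype=float).tobytes()),
        sphere.radius,
        sphere.conductivity,
        sphere.brain_radius_fraction,
        float(spacing),
    )
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    r_max = sphere.brain_radius * 0.999
    ax = np.arange(-r_max, r_max + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= r_max]
    # deterministic ordering for tie-breaks: lexicographic (x, y, z)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    gains = _batched_gains(pts, electrode_positions, sphere)
    # per-point pseudo-inverse via normal equations (3x3 solves)
    gtg = np.einsum("pec,ped->pcd", gains, gains)
    gtg += 1e-12 * np.eye(3)[None]
    pinv = np.linalg.solve(gtg, np.transpose(gains, (0, 2, 1)))
    result = (pts, gains, pinv)
    _GRID_CACHE[key] = result
    return result


def _batched_gains(points: np.ndarray, electrode_positions: np.ndarray, sphere: SphereModel,
                   max_terms: int = 200) -> np.ndarray:
    """Gain matrices for many source points at once (vectorised recurrence)."""
    pos = _check_electrodes(electrode_positions, sphere)
    R = sphere.radius
    P = points.shape[0]
    E = pos.shape[0]
    b = np.linalg.norm(points, axis=1)
    b = np.maximum(b, 1e-12)
    r_hat = points / b[:, None]
    e_hat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    x = np.clip(r_hat @ e_hat.T, -1.0, 1.0)                      # (P, E)
    u = e_hat[None, :, :] - x[..., None] * r_hat[:, None, :]      # (P, E, 3)

    G = np.zeros((P, E, 3))
    P_prev = np.ones((P, E))
    P_cur = x.copy()
    D_prev = np.zeros((P, E))
    D_cur = np.ones((P, E))
    scale = 1.0 / (4.0 * np.pi * sphere.conductivity * R ** 2)
    ratio = b / R
    f_pow = np.ones(P)
    for n in range(1, max_terms + 1):
        c_n = scale * (2 * n + 1) / n * f_pow
        G += c_n[:, None, None] * (n * P_cur[..., None] * r_hat[:, None, :] + D_cur[..., None] * u)
        if np.max(ratio) ** n < 1e-12 and n > 10:
            break
        P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
        D_next = D_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        D_prev, D_cur = D_cur, D_next
        f_pow *= ratio
    G -= G.mean(axis=1, keepdims=True)
    return G


def _rv_at(r0: np.ndarray, topo: np.ndarray, electrode_positions: np.ndarray,
           sphere: SphereModel, ss_tot: float, r_lim: float):
    """Residual variance and optimal moment for a candidate location."""
    b = np.linalg.norm(r0)
    if b > r_lim:
        # soft barrier: project the excess into the RV so the optimiser
        # turns back, while remaining continuous at the boundary
        return 1.0 + (b - r_lim) / r_lim, np.zeros(3)
    G = dipole_gain(r0, electrode_positions, sphere, check=False)
    q, *_ = np.linalg.lstsq(G, topo, rcond=None)
    resid = topo - G @ q
    return float(resid @ resid) / ss_tot, q


def fit_dipole(
    topography: np.ndarray,
    electrode_positions: np.ndarray,
    sphere: SphereModel | None = None,
    n_restarts: int = 5,
    *,
    grid_spacing: float = 5.0,
) -> DipoleFit:
    """Fit an equivalent current dipole to a scalp topography.

    A deterministic coarse grid over the brain volume is scanned with the
    moment solved linearly at every node; the ``n_restarts`` best nodes seed
    local nonlinear refinements of the location.  The fit with the lowest
    residual variance wins; exact ties break lexicographically on location.
    """
    sphere = sphere or SphereModel()
    topo = np.asarray(topography, dtype=float).ravel()
    pos = _check_electrodes(electrode_positions, sphere)
    if topo.shape[0] != pos.shape[0]:
        raise ValueError("topography length must equal the number of electrodes")
    if pos.shape[0] < 8:
        raise ValueError("dipole fitting requires at least 8 electrodes")
    if np.allclose(topo, 0):
        raise ValueError("cannot fit a dipole to an all-zero topography")

    topo = topo - topo.mean()
    ss_tot = float(topo @ topo)

    pts, gains, pinv = _scan_grid(pos, sphere, grid_spacing)
    q_all = np.einsum("pce,e->pc", pinv, topo)
    model = np.einsum("pec,pc->pe", gains, q_all)
    resid = model - topo[None, :]
    rv_all = np.einsum("pe,pe->p", resid, resid) / ss_tot
    n_restarts = max(int(n_restarts), 1)
    seeds = np.argsort(rv_all, kind="stable")[:n_restarts]

    r_lim = sphere.radius * 0.99    # physical cap: inside the scalp sphere
    best = None
    for idx in seeds:
        res = minimize(
            lambda r: _rv_at(r, topo, pos, sphere, ss_tot, r_lim)[0],
            pts[idx],
            method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 1e-11, "maxiter": 250},
        )
        rv, q = _rv_at(res.x, topo, pos, sphere, ss_tot, r_lim)
        cand = (rv, tuple(np.round(res.x, 9)), res.x.copy(), q)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if best[0] < 1e-10:          # numerically perfect: no restart can improve
            break
    rv, _, loc, q = best
    return DipoleFit(location=loc, moment=q, residual_variance=float(np.clip(rv, 0.0, 1.0)))
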