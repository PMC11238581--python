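"""Independent numerical oracles used to validate the package's solvers.

Each oracle deliberately takes a different numerical route from the
implementation it checks: finite differences instead of eigenfunction
series, bisection instead of the closed-form quadratic, a brute-force grid
scan instead of bracketed root finding, explicit Henderson–Hasselbalch
speciation instead of the package's buffer arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def crank_nicolson_profile(
    diffusivity: float,
    total_time: float,
    stream_fraction: float,
    width: float,
    n_cells: int = 2000,
    n_steps: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Reflecting-wall 1-D diffusion by Crank–Nicolson on a cell-centered grid.

    Returns (cell-center coordinates normalized to [0,1], concentration
    normalized so the discrete mean equals 1/stream_fraction·stream area,
    i.e. integral one).
    """
    h = 1.0 / n_cells
    x = (np.arange(n_cells) + 0.5) * h
    c = np.where(x < stream_fraction, 1.0, 0.0)
    # fractional cell at the stream edge
    edge = stream_fraction / h
    j = int(edge)
    if j < n_cells:
        c[j] = edge - j
    tau_total = diffusivity * total_time / width**2
    dt = tau_total / n_steps
    r = dt / (2.0 * h * h)
    # Banded matrices for (I - r L) c_new = (I + r L) c_old, L the no-flux Laplacian
    main = np.full(n_cells, 1.0 + 2.0 * r)
    main[0] = main[-1] = 1.0 + r
    upper = np.full(n_cells, -r)
    lower = np.full(n_cells, -r)
    ab = np.zeros((3, n_cells))
    ab[0, 1:] = upper[:-1]
    ab[1] = main
    ab[2, :-1] = lower[1:]
    for _ in range(n_steps):
        rhs = c.copy()
        rhs[1:-1] += r * (c[:-2] - 2.0 * c[1:-1] + c[2:])
        rhs[0] += r * (c[1] - c[0])
        rhs[-1] += r * (c[-2] - c[-1])
        c = solve_banded((1, 1), ab, rhs)
    return x, c / stream_fraction


def bisect_bound_fraction(
    k_d: float, a: float, b: int, lipid_total: float, protein_total: float,
    iters: int = 200,
) -> float:
    """Bound fraction by bisection on the untransformed mass-action system."""
    p0 = protein_total / b
    s0 = a * lipid_total
    if p0 <= 0 or s0 <= 0:
        return 0.0

    def h(ps: float) -> float:
        return (p0 - ps) * (s0 - ps) - k_d * ps

    lo, hi = 0.0, min(p0, s0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / p0


def grid_scan_competition(
    kd_m: float, a_m: float, b_m: int,
    kd_o: float, a_o: float, b_o: int,
    lipid_total: float, monomer_total: float, oligomer_total: float,
    n_grid: int = 4_000_001,
) -> tuple[float, float]:
    """Competitive equilibrium by brute-force scan over free lipid.

    Evaluates the lipid-balance residual on a dense grid of free-lipid
    values and linearly interpolates the sign change.
    """
    p_m = monomer_total / b_m
    p_o = oligomer_total / b_o
    a_free = np.linspace(0.0, lipid_total, n_grid)

    def bound(kd, a, p0):
        s = a * a_free
        return p0 * s / (kd + s)

    g = a_free + bound(kd_m, a_m, p_m) / a_m + bound(kd_o, a_o, p_o) / a_o - lipid_total
    i = int(np.searchsorted(g > 0, True))
    if i == 0:
        af = 0.0
    else:
        x0, x1, g0, g1 = a_free[i - 1], a_free[i], g[i - 1], g[i]
        af = x0 - g0 * (x1 - x0) / (g1 - g0)
    f_m = (a_m * af / (kd_m + a_m * af)) if p_m > 0 else 0.0
    f_o = (a_o * af / (kd_o + a_o * af)) if p_o > 0 else 0.0
    return f_m, f_o


def phosphate_ionic_strength(p_total: float, pH: float,
                             pkas=(2.15, 7.21, 12.33)) -> float:
    """Ionic strength of sodium phosphate by explicit speciation.

    Henderson–Hasselbalch fractions for the four protonation states and an
    electroneutral Na+ counter-ion concentration.
    """
    h = 10.0 ** (-pH)
    k1, k2, k3 = (10.0 ** (-p) for p in pkas)
    denom = h**3 + k1 * h**2 + k1 * k2 * h + k1 * k2 * k3
    f1 = k1 * h**2 / denom  # H2PO4-
    f2 = k1 * k2 * h / denom  # HPO4 2-
    f3 = k1 * k2 * k3 / denom  # PO4 3-
    na = p_total * (f1 + 2 * f2 + 3 * f3)
    return 0.5 * (
        p_total * f1 * 1 + p_total * f2 * 4 + p_total * f3 * 9 + na * 1
    )


def normal_loglik(residuals: np.ndarray, sigma: float) -> float:
    """Sum of independent normal log densities, written out longhand."""
    out = 0.0
    for r in np.asarray(residuals, dtype=float):
        out += -0.5 * (r / sigma) ** 2 - np.log(sigma * np.sqrt(2.0 * np.pi))
    return float(out)
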