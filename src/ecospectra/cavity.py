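"""Cavity-method (mean-field) fluctuation spectra of large random communities.

For a large locally tree-like random system the mean diagonal resolvent
r(omega) of the community matrix closes on itself,

    1/r = -E[A_ii] + i omega - r c E[A_ij A_ji],

and the mean power spectral density follows as

    phi = |r|^2 (E[B_ii] + 2 c Re(r) E[A_ij B_ij]) / (1 - c |r|^2 E[A_ij^2]).

This module implements that self-consistency, its closed-form special cases,
the single-defect refinement that keeps one focal species' actual couplings,
and the two-group (bipartite predator-prey) generalisation together with the
critical frequencies bounding its excited band.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .communities import LVCommunity, LVParams, TrophicParams, trophic_fixed_point
from .spectral import SpectralDensity

__all__ = [
    "MomentInputs",
    "MeanFieldSolution",
    "BipartiteSolution",
    "lv_moment_map",
    "resolvent_mean_field",
    "psd_mean_field",
    "closed_form_psd",
    "psd_single_defect",
    "psd_single_defect_all",
    "critical_frequencies",
    "representative_2d_eigenvalues",
    "solve_bipartite_mean_field",
]

_DEGENERATE_CORR = 1e-12


@dataclass(frozen=True)
class MomentInputs:
    """Aggregate moments of the community and noise matrices.

    Expectations over off-diagonal entries are taken over the *nonzero*
    (connected) pairs; ``c`` is the mean degree.
    """

    EAii: float
    EBii: float
    EAij2: float
    EAijAji: float
    EAijBij: float
    c: float

    def __post_init__(self) -> None:
        if self.EAij2 < 0 or self.EBii < 0 or self.c < 0:
            raise ValueError("EAij2, EBii and c must be nonnegative")
        if abs(self.EAijAji) > self.EAij2 + 1e-12:
            raise ValueError("|E[Aij Aji]| cannot exceed E[Aij^2]")


@dataclass
class MeanFieldSolution:
    omegas: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    converged: np.ndarray

    def to_spectral_density(self) -> SpectralDensity:
        return SpectralDensity(omegas=self.omegas, values=self.phi, columns=["phi_mean"])


@dataclass
class BipartiteSolution:
    omegas: np.ndarray
    r_x: np.ndarray
    r_y: np.ndarray
    phi_x: np.ndarray
    phi_y: np.ndarray
    converged: np.ndarray
    band: tuple[float, float]


def lv_moment_map(params: LVParams) -> MomentInputs:
    """Moments of the sampled Lotka-Volterra ensemble.

    E[A_ii] = -b, E[B_ii] = 2b + c*mu, E[A_ij^2] = sigma^2 over edges,
    E[A_ij A_ji] = gamma sigma^2, and E[A_ij B_ij] = 0 (the noise correlator
    couples only predation pairs, whose two signed rates cancel in the mean).
    """
    return MomentInputs(
        EAii=-params.b,
        EBii=2.0 * params.b + params.c * params.mu,
        EAij2=params.sigma2,
        EAijAji=params.gamma * params.sigma2,
        EAijBij=0.0,
        c=params.c,
    )


def resolvent_mean_field(omega: float | np.ndarray, m: MomentInputs) -> complex | np.ndarray:
    """Mean diagonal resolvent r(omega) from the scalar self-consistency.

    The closing quadratic g r^2 - w r + 1 = 0 (w = -E[A_ii] + i omega,
    g = c E[A_ij A_ji]) has two roots; the physical resolvent of a stable
    system has Re(r) > 0 and decays like 1/(i omega), so the root with
    positive real part (smallest magnitude on ties) is selected. When g
    vanishes the explicit limit r = 1/w is used.
    """
    omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
    g = m.c * m.EAijAji
    w = -m.EAii + 1j * omega_arr
    if abs(g) < _DEGENERATE_CORR:
        r = 1.0 / w
    else:
        sq = np.sqrt(w * w - 4.0 * g + 0j)
        r1 = (w - sq) / (2.0 * g)
        r2 = (w + sq) / (2.0 * g)
        r = _select_physical_root(r1, r2)
    if np.isscalar(omega):
        return complex(r[0])
    return r


def _select_physical_root(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Pick, per frequency, the root with Re > 0; break ties by smaller |r|."""
    pos1 = r1.real > 0
    pos2 = r2.real > 0
    smaller1 = np.abs(r1) <= np.abs(r2)
    use1 = np.where(pos1 & pos2, smaller1, pos1)
    # if neither has positive real part (outside the stable regime), fall back
    # to the smaller-magnitude root so downstream validity flags can fire
    neither = ~(pos1 | pos2)
    use1 = np.where(neither, smaller1, use1)
    return np.where(use1, r1, r2)


def psd_mean_field(omegas: np.ndarray, m: MomentInputs) -> MeanFieldSolution:
    """Mean power spectral density on a frequency grid.

    Frequencies where the denominator 1 - c |r|^2 E[A_ij^2] is nonpositive lie
    outside the validity/stability region: they are flagged unconverged and
    the spectrum is set to +inf there.
    """
    omegas = np.asarray(omegas, dtype=float)
    r = np.atleast_1d(resolvent_mean_field(omegas, m))
    r2 = np.abs(r) ** 2
    denom = 1.0 - m.c * r2 * m.EAij2
    numer = r2 * (m.EBii + 2.0 * m.c * r.real * m.EAijBij)
    ok = denom > 0
    phi = np.where(ok, numer / np.where(ok, denom, 1.0), np.inf)
    phi = np.where(ok & (phi < 0), 0.0, phi)
    return MeanFieldSolution(omegas=omegas, r=r, phi=phi, converged=ok)


def closed_form_psd(variant: str, omega: float | np.ndarray, params: LVParams) -> float | np.ndarray:
    """Printed closed-form limits of the mean spectrum.

    ``weak``             - sigma^2 << 1 Lorentzian (2b + c mu)/(b^2 + omega^2);
    ``quarter_circle``   - gamma = -1, small b, inside omega^2 < 4 c sigma^2;
    ``gamma_zero``       - gamma = 0 exact form (2b + c mu)/(b^2 - c sigma^2 + omega^2);
    ``gamma_one_margin`` - gamma = +1 at the marginal point b^2 = 4 c sigma^2.
    """
    omega_arr = np.asarray(omega, dtype=float)
    b, c, s2, mu = params.b, params.c, params.sigma2, params.mu
    cs2 = c * s2
    cmu = c * mu
    if variant == "weak":
        out = (2.0 * b + cmu) / (b * b + omega_arr**2)
    elif variant == "quarter_circle":
        if params.gamma != -1:
            raise ValueError("quarter_circle requires gamma = -1")
        if np.any(omega_arr**2 >= 4.0 * cs2):
            raise ValueError(
                "quarter_circle closed form only holds inside the band omega^2 < 4 c sigma^2"
            )
        out = (2.0 * b + cmu) / (2.0 * cs2) * (
            np.sqrt(4.0 * cs2 - omega_arr**2) / b - cmu / (2.0 * b + cmu)
        )
    elif variant == "gamma_zero":
        if params.gamma != 0:
            raise ValueError("gamma_zero requires gamma = 0")
        out = (2.0 * b + cmu) / (b * b - cs2 + omega_arr**2)
    elif variant == "gamma_one_margin":
        if params.gamma != 1:
            raise ValueError("gamma_one_margin requires gamma = 1")
        if not math.isclose(b * b, 4.0 * cs2, rel_tol=1e-9):
            raise ValueError("gamma_one_margin requires b^2 = 4 c sigma^2")
        k = 4.0 * math.sqrt(cs2) + cmu
        root = np.sqrt(16.0 * cs2 * omega_arr**2 + omega_arr**4) - omega_arr**2
        out = math.sqrt(2.0) * k / np.sqrt(cs2 * root) - k / (2.0 * cs2)
    else:
        raise ValueError(f"unknown closed-form variant {variant!r}")
    if np.isscalar(omega):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# single defect approximation


def _local_sums(community: LVCommunity, i: int) -> tuple[float, float, float, float]:
    a_row = community.A[i].copy()
    a_col = community.A[:, i].copy()
    b_row = community.B[i].copy()
    a_row[i] = 0.0
    a_col[i] = 0.0
    b_row[i] = 0.0
    s_a2 = float(np.sum(a_row**2))
    s_ab = float(np.sum(a_row * b_row))
    s_aa = float(np.sum(a_row * a_col))
    return s_a2, s_ab, s_aa, float(community.B[i, i])


def psd_single_defect(i: int, community: LVCommunity, mf: MeanFieldSolution) -> np.ndarray:
    """Single-defect spectrum of one focal species over the mean-field grid.

    Embeds species ``i`` with its actual couplings in the mean-field
    background:

        phi_i = (phi^MF sum A_ij^2 + 2 Re(r^MF) sum A_ij B_ij + B_ii)
                / |A_ii + i omega + conj(r^MF) sum A_ij A_ji|^2.
    """
    if not (0 <= i < community.N):
        raise IndexError(f"species index {i} out of range for N={community.N}")
    s_a2, s_ab, s_aa, b_ii = _local_sums(community, i)
    a_ii = float(community.A[i, i])
    numer = mf.phi * s_a2 + 2.0 * mf.r.real * s_ab + b_ii
    denom = np.abs(a_ii + 1j * mf.omegas + np.conj(mf.r) * s_aa) ** 2
    return numer / denom


def psd_single_defect_all(community: LVCommunity, mf: MeanFieldSolution) -> SpectralDensity:
    """Single-defect spectra for every species (rows = frequencies)."""
    A = community.A
    Bm = community.B
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    b_off = Bm.copy()
    np.fill_diagonal(b_off, 0.0)
    s_a2 = np.sum(off**2, axis=1)
    s_ab = np.sum(off * b_off, axis=1)
    s_aa = np.sum(off * off.T, axis=1)
    b_ii = np.diag(Bm)
    a_ii = np.diag(A)
    numer = mf.phi[:, None] * s_a2[None, :] + 2.0 * mf.r.real[:, None] * s_ab[None, :] + b_ii[None, :]
    denom = (
        np.abs(a_ii[None, :] + 1j * mf.omegas[:, None] + np.conj(mf.r)[:, None] * s_aa[None, :]) ** 2
    )
    return SpectralDensity(omegas=mf.omegas, values=np.maximum(numer / denom, 0.0))


# ---------------------------------------------------------------------------
# bipartite (two-group) solver


def critical_frequencies(b: float, d: float, cx: float, cy: float) -> tuple[float, float]:
    """Edges of the excited frequency band of the bipartite trophic model.

    omega_{+/-} = sqrt( b d (1/cx + 1/cy +/- 2/sqrt(cx cy)) ). For cx = cy the
    lower edge closes to zero.
    """
    if b <= 0 or d <= 0 or cx <= 0 or cy <= 0:
        raise ValueError("b, d, cx, cy must be positive")
    base = 1.0 / cx + 1.0 / cy
    cross = 2.0 / math.sqrt(cx * cy)
    lo = b * d * max(base - cross, 0.0)
    hi = b * d * (base + cross)
    return math.sqrt(lo), math.sqrt(hi)


def representative_2d_eigenvalues(params: TrophicParams) -> tuple[complex, complex]:
    """Eigenvalues of the averaged predator-prey pair linearised at (x*, y*).

    The 2x2 Jacobian [[-x*, cx a x*], [-cy a y*, -y*]] of the group-averaged
    dynamics; its imaginary part locates the small finite-size quasi-cycle
    peak that the full mean-field spectrum does not carry.
    """
    x_star, y_star = trophic_fixed_point(params)
    J = np.array(
        [
            [-x_star, params.cx * params.alpha * x_star],
            [-params.cy * params.alpha * y_star, -y_star],
        ]
    )
    ev = np.linalg.eigvals(J)
    ev = ev[np.argsort(-ev.imag)]
    return complex(ev[0]), complex(ev[1])


def _bipartite_phi(rx: complex, ry: complex, x: float, y: float,
                   kx: float, ky: float, d: float, b: float) -> tuple[float, float, bool]:
    """Solve the linear pair of equations for (phi_x, phi_y) given (rx, ry)."""
    ax = abs(rx) ** 2
    ay = abs(ry) ** 2
    p = ax * kx * x / y    # kx = alpha^2 cx x y  ->  alpha^2 cx x^2 = kx x / y
    q = ay * ky * y / x
    cx_term = ax * (2.0 * x * (x + d) - 2.0 * (kx * x / y) * y * ry.real)
    cy_term = ay * (2.0 * y * b + 2.0 * (ky * y / x) * x * rx.real)
    det = 1.0 - p * q
    if det <= 0:
        return math.inf, math.inf, False
    phi_x = (cx_term + p * cy_term) / det
    phi_y = (cy_term + q * cx_term) / det
    return phi_x, phi_y, phi_x >= -1e-9 and phi_y >= -1e-9


def solve_bipartite_mean_field(
    params: TrophicParams,
    omegas: np.ndarray,
    eps: float = 1e-6,
    damping: float = 0.5,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> BipartiteSolution:
    """Two-group cavity solution (r_x, r_y, phi_x, phi_y) on a frequency grid.

    The resolvent pair solves

        1/r_x = x* + i omega + a^2 cx x* y* r_y,
        1/r_y = y* + i omega + a^2 cy x* y* r_x,

    iterated with damping from the non-interacting initial values and warm
    starts along the grid; the physical in-band solution is selected by a
    small spectral shift omega -> omega - i eps (halved until the set of
    excited frequencies stabilises). Unconverged frequencies are flagged,
    never silently returned.
    """
    omegas = np.asarray(omegas, dtype=float)
    x, y = trophic_fixed_point(params)
    kx = params.alpha**2 * params.cx * x * y
    ky = params.alpha**2 * params.cy * x * y

    def solve_at(eps_val: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rx = np.empty(omegas.size, dtype=complex)
        ry = np.empty(omegas.size, dtype=complex)
        conv = np.zeros(omegas.size, dtype=bool)
        rx_prev: complex | None = None
        ry_prev: complex | None = None
        for k, om in enumerate(omegas):
            z = eps_val + 1j * om
            cur_x = rx_prev if rx_prev is not None else 1.0 / (x + z)
            cur_y = ry_prev if ry_prev is not None else 1.0 / (y + z)
            ok = False
            for _ in range(max_iter):
                new_x = 1.0 / (x + z + kx * cur_y)
                new_y = 1.0 / (y + z + ky * cur_x)
                dx = abs(new_x - cur_x) + abs(new_y - cur_y)
                cur_x = (1.0 - damping) * cur_x + damping * new_x
                cur_y = (1.0 - damping) * cur_y + damping * new_y
                if dx < tol:
                    ok = True
                    break
            res = abs(1.0 / cur_x - (x + z + kx * cur_y)) + abs(
                1.0 / cur_y - (y + z + ky * cur_x)
            )
            rx[k], ry[k] = cur_x, cur_y
            conv[k] = ok and res < 1e-8
            rx_prev, ry_prev = cur_x, cur_y
        return rx, ry, conv

    rx, ry, conv = solve_at(eps)
    # halve the regulariser until the classification of excited frequencies
    # (phi above a fixed fraction of its maximum) stops changing
    def band_mask(rx_a, ry_a):
        phi = np.array([_bipartite_phi(a, bb, x, y, kx, ky, params.d, params.b)[0]
                        for a, bb in zip(rx_a, ry_a)])
        finite = np.isfinite(phi)
        if not finite.any():
            return np.zeros_like(phi, dtype=bool)
        return phi > 0.01 * np.nanmax(phi[finite])

    mask = band_mask(rx, ry)
    for _ in range(6):
        eps /= 2.0
        rx2, ry2, conv2 = solve_at(eps)
        mask2 = band_mask(rx2, ry2)
        same = np.array_equal(mask, mask2)
        rx, ry, conv, mask = rx2, ry2, conv2, mask2
        if same:
            break

    phi_x = np.empty(omegas.size)
    phi_y = np.empty(omegas.size)
    for k in range(omegas.size):
        px, py, ok = _bipartite_phi(rx[k], ry[k], x, y, kx, ky, params.d, params.b)
        phi_x[k], phi_y[k] = max(px, 0.0) if np.isfinite(px) else np.inf, (
            max(py, 0.0) if np.isfinite(py) else np.inf
        )
        conv[k] = conv[k] and ok
    band = critical_frequencies(params.b, params.d, params.cx, params.cy)
    return BipartiteSolution(
        omegas=omegas, r_x=rx, r_y=ry, phi_x=phi_x, phi_y=phi_y, converged=conv, band=band
    )
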