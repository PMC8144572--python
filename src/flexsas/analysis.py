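"""Model-free curve analysis: Guinier fits, regularized indirect Fourier
transform to P(r), P(r) moments/peaks, dimensionless Kratky representation.

The IFT solves

    min_P  Σ[(I_exp(q) − I_P(q))/σ(q)]²  +  α ‖P''‖²,   P ≥ 0,
           P(0) = P(Dmax) = 0,
    I_P(q) = 4π ∫ P(r) sinc(qr) dr,

on a uniform r grid by non-negative least squares on the Tikhonov-stacked
system; α="auto" picks the L-curve corner (maximum curvature in the
log-residual / log-seminorm plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .scattering import ScatteringCurve


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_window: tuple[float, float]
    q_rg_max: float
    n_points: int
    residual_rms: float


@dataclass
class PofR:
    """Regularized pair distance distribution on a uniform r grid."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    alpha: float
    i_fit: ScatteringCurve
    chi2: float
    metadata: dict = field(default_factory=dict)


def guinier_fit(curve: ScatteringCurve, qmin: float = 0.0,
                qrg_max: float = 1.3) -> GuinierResult:
    """Guinier fit ln I = ln I(0) − q²Rg²/3 over the widest window with
    q_max·Rg ≤ qrg_max, iterated to self-consistency."""
    sel = (curve.q >= qmin) & (curve.I > 0)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 usable points above qmin")
    q, I = curve.q[sel], curve.I[sel]
    w = None
    if curve.sigma is not None:
        w = (I / curve.sigma[sel]) ** 2  # weights for ln I
    hi = len(q)
    for _ in range(50):
        qq, y = q[:hi] ** 2, np.log(I[:hi])
        ww = w[:hi] if w is not None else np.ones(hi)
        slope, intercept = np.polyfit(qq, y, 1, w=np.sqrt(ww))
        if slope >= 0:
            raise ValueError("non-Guinier behaviour: positive ln I vs q² slope")
        rg = float(np.sqrt(-3.0 * slope))
        new_hi = int(np.searchsorted(q, qrg_max / rg, side="right"))
        new_hi = max(new_hi, 5)
        if new_hi >= hi:
            break
        hi = new_hi
    if hi < 5:
        raise ValueError("Guinier window smaller than 5 points")
    resid = np.log(I[:hi]) - (intercept + slope * q[:hi] ** 2)
    return GuinierResult(rg, float(np.exp(intercept)),
                         (float(q[0]), float(q[hi - 1])),
                         float(q[hi - 1] * rg), hi,
                         float(np.sqrt((resid ** 2).mean())))


def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Design matrix A with I(q) = A @ P: trapezoid quadrature of
    4π sinc(qr) P(r)."""
    dr = r[1] - r[0]
    wq = np.full(len(r), dr)
    wq[0] = wq[-1] = dr / 2
    return 4 * np.pi * np.sinc(np.outer(q, r) / np.pi) * wq[None, :]


def _second_diff(m: int) -> np.ndarray:
    """Second-difference operator on an m-vector (interior rows)."""
    D = np.zeros((m - 2, m))
    for i in range(m - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def _ift_solve(Aw: np.ndarray, yw: np.ndarray, D: np.ndarray,
               alpha: float) -> np.ndarray:
    stack_A = np.vstack([Aw, np.sqrt(alpha) * D])
    stack_y = np.concatenate([yw, np.zeros(D.shape[0])])
    sol, _ = nnls(stack_A, stack_y, maxiter=10 * stack_A.shape[1])
    return sol


def ift_pr(curve: ScatteringCurve, dmax: float, alpha="auto",
           n_r: int = 101, positivity: bool = True) -> PofR:
    """Regularized indirect Fourier transform of a curve to P(r).

    Endpoint values P(0) and P(Dmax) are pinned to zero; α="auto" scans a
    log-spaced grid and applies the discrepancy principle: the strongest
    smoothing whose reduced χ² stays below max(1, 1.1·χ²_min).
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if curve.sigma is None:
        raise ValueError("IFT requires error estimates (sigma)")
    if dmax < np.pi / curve.q[-1]:
        import warnings
        warnings.warn("dmax below the scale resolvable by the q range",
                      stacklevel=2)
    q, I, s = curve.q, curve.I, curve.sigma
    r = np.linspace(0.0, dmax, n_r)
    A = _ift_design(q, r)
    # endpoints fixed at zero: solve for interior values only
    Ai = A[:, 1:-1]
    Aw = Ai / s[:, None]
    yw = I / s
    D = _second_diff(n_r)[:, 1:-1]
    if not positivity:
        raise NotImplementedError("only the non-negative variant is provided")

    def full_p(p_int: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], p_int, [0.0]])

    if alpha == "auto":
        alphas = np.logspace(-8, 6, 29) * np.median(np.abs(Aw)) ** 2
        dof = max(len(q) - 1, 1)
        sols = [_ift_solve(Aw, yw, D, a) for a in alphas]
        chi2s = np.array([((Aw @ p - yw) ** 2).sum() / dof for p in sols])
        tol = max(1.0, 1.1 * chi2s.min())
        ok = np.nonzero(chi2s <= tol)[0]
        k = int(ok.max()) if len(ok) else int(np.argmin(chi2s))
        a_star, p_int = float(alphas[k]), sols[k]
    else:
        a_star = float(alpha)
        p_int = _ift_solve(Aw, yw, D, a_star)
    p = full_p(p_int)
    I_back = A @ p
    chi2 = float((((I - I_back) / s) ** 2).sum() / max(len(q) - 1, 1))
    fit = ScatteringCurve(q, I_back, None, curve.radiation,
                          {"kind": "ift_backtransform"})
    return PofR(r, p, dmax, a_star, fit, chi2)


def pr_moments(pr: PofR) -> tuple[float, float]:
    """(Rg, I(0)) from P(r):  Rg² = ∫r²P dr / (2∫P dr),  I(0) = 4π∫P dr."""
    total = np.trapezoid(pr.p, pr.r)
    if total <= 0:
        raise ValueError("∫P(r) dr <= 0")
    rg = float(np.sqrt(np.trapezoid(pr.r ** 2 * pr.p, pr.r) / (2 * total)))
    return rg, float(4 * np.pi * total)


def kratky_dimensionless(curve: ScatteringCurve, rg: float,
                         i0: float) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: (qRg, (qRg)²·I(q)/I(0)).

    Globular particles peak near qRg = √3 at height 3/e; extended or
    flexible particles peak at larger qRg (4-7 for the hinge-bent rods
    studied here).
    """
    if rg <= 0 or i0 <= 0:
        raise ValueError("Rg and I(0) must be positive")
    x = curve.q * rg
    return x, x ** 2 * curve.I / i0


def pr_peaks(pr: PofR, min_prominence: float = 0.05) -> list[float]:
    """r positions of local maxima of P(r) with prominence above
    ``min_prominence``·max(P), sorted by r."""
    pmax = pr.p.max()
    if pmax <= 0:
        return []
    idx, _ = find_peaks(pr.p, prominence=min_prominence * pmax)
    return [float(pr.r[i]) for i in idx]
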