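"""Ensemble and mixture inference.

Two procedures sit at the core of the package:

1. hinge-ensemble fitting — an experimental curve is approximated by a
   Tikhonov-regularized non-negative combination of curves computed from
   hinge-bent conformers of the dimer (three hinges, −90°…90° in 30° steps,
   343 members), summarised by per-hinge RMS bending angles;
2. oligomer mixture fitting — dimer vs trimer-of-dimers weight fractions
   obtained by non-negative least squares on per-complex-mass normalized
   component curves, with 1σ uncertainties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .geometry import bend_at_hinge
from .model import HingeBend, ParticleModel, SegmentMap
from .scattering import ScatteringCurve, SolventModel, debye_curve, interp_to

HINGE_ORDER = ("HAMP1", "HAMP2", "Gly")
DEFAULT_ANGLE_GRID = tuple(range(-90, 91, 30))


@dataclass
class EnsembleBasis:
    """Conformer curves on a common q grid, one per hinge-angle triple."""

    q: np.ndarray
    curves: np.ndarray          # (n_members, n_q)
    angles: np.ndarray          # (n_members, 3) degrees, order HINGE_ORDER
    excluded: list[tuple] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.curves)


@dataclass
class WeightSolution:
    weights: np.ndarray
    alpha: float
    chi2: float
    scale: float
    rms_angles: dict[str, float]

    def __post_init__(self) -> None:
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class MixtureResult:
    labels: tuple[str, ...]
    fractions: np.ndarray        # percent, sums to 100
    uncertainties: np.ndarray    # percent, 1σ
    chi2: float
    scale: float
    warnings: list[str] = field(default_factory=list)


def _has_clash(model: ParticleModel, cutoff: float = 1.0) -> bool:
    """Any non-adjacent scatterer pair closer than ``cutoff`` Å (belt
    excluded; bonded neighbours along a chain don't count)."""
    prot = model.select(~model.is_belt)
    from scipy.spatial import cKDTree
    pairs = cKDTree(prot.positions).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return False
    same_chain = prot.chain_id[pairs[:, 0]] == prot.chain_id[pairs[:, 1]]
    adjacent = np.abs(prot.residue_index[pairs[:, 0]]
                      - prot.residue_index[pairs[:, 1]]) <= 1
    return bool(np.any(~(same_chain & adjacent)))


def build_hinge_basis(dimer_model: ParticleModel,
                      q_grid: np.ndarray,
                      solvent: SolventModel | None = None,
                      radiation: str = "xray",
                      angle_grid: tuple = DEFAULT_ANGLE_GRID,
                      segment_map: SegmentMap | None = None,
                      belt_spec=None,
                      clash_cutoff: float = 1.0) -> EnsembleBasis:
    """One Debye curve per hinge-angle triple (lexicographic member order).

    Bends are applied proximal to distal (HAMP1 → HAMP2 → Gly).  When a
    ``belt_spec`` is given the detergent corona is added to each bent
    conformer before the curve is evaluated.  Conformers with steric clashes
    (non-adjacent scatterers closer than ``clash_cutoff``) are excluded and
    recorded in ``basis.excluded``.
    """
    if len(angle_grid) == 0:
        raise ValueError("empty angle grid")
    smap = segment_map or SegmentMap()
    q = np.asarray(q_grid, float)
    curves, angles, excluded = [], [], []
    for triple in itertools.product(angle_grid, repeat=3):
        m = dimer_model
        for hinge, theta in zip(HINGE_ORDER, triple):
            if theta != 0:
                m = bend_at_hinge(m, HingeBend(hinge, float(theta)), smap)
        if m is dimer_model:
            m = dimer_model.copy()
        if _has_clash(m, clash_cutoff):
            excluded.append(triple)
            continue
        if belt_spec is not None:
            from .belt import build_belt
            m = build_belt(m, belt_spec)
        c = debye_curve(m, solvent, q, radiation)
        curves.append(c.I)
        angles.append(triple)
    if not curves:
        raise ValueError("all conformers clash-excluded")
    return EnsembleBasis(q, np.array(curves), np.array(angles, float),
                         excluded)


def hinge_angle_stats(weights: np.ndarray,
                      basis: EnsembleBasis) -> dict[str, float]:
    """Per-hinge RMS bending angle √(Σ_m w_m θ_{m,h}²), degrees."""
    return {h: float(np.sqrt((weights * basis.angles[:, i] ** 2).sum()))
            for i, h in enumerate(HINGE_ORDER)}


def _nnls_stacked(Aw: np.ndarray, yw: np.ndarray, alpha: float,
                  G: np.ndarray) -> np.ndarray:
    if alpha > 0:
        A = np.vstack([Aw, np.sqrt(alpha) * G])
        y = np.concatenate([yw, np.zeros(G.shape[0])])
    else:
        A, y = Aw, yw
    sol, _ = nnls(A, y, maxiter=30 * A.shape[1])
    return sol


def tikhonov_nnls(basis: EnsembleBasis, exp_curve: ScatteringCurve,
                  alpha="auto") -> WeightSolution:
    """Fit data as a regularized non-negative combination of basis curves.

    Minimises ‖(A u − I_exp)/σ‖² + α‖u‖² subject to u ≥ 0 (Γ = identity),
    then normalises w = u/Σu; the overall scale is refit.  α="auto" takes
    the L-curve corner over a log-spaced grid.
    """
    if exp_curve.sigma is None:
        raise ValueError("experimental curve must carry sigma")
    qlo, qhi = max(basis.q[0], exp_curve.q[0]), min(basis.q[-1], exp_curve.q[-1])
    if qlo >= qhi:
        raise ValueError("basis and data q ranges do not overlap")
    sel = (exp_curve.q >= qlo) & (exp_curve.q <= qhi)
    q, Ie, s = exp_curve.q[sel], exp_curve.I[sel], exp_curve.sigma[sel]
    A = np.array([np.interp(q, basis.q, c) for c in basis.curves]).T
    Aw, yw = A / s[:, None], Ie / s
    G = np.eye(basis.n_members)

    if alpha == "auto":
        # discrepancy principle: strongest damping whose misfit stays within
        # 10 % of the best achievable — the L-curve of NNLS ensemble bases is
        # too flat to carry a usable corner
        scale0 = np.median((Aw ** 2).sum(axis=0))
        alphas = np.concatenate([[0.0], np.logspace(-6, 2, 17) * scale0])
        sols = [_nnls_stacked(Aw, yw, a, G) for a in alphas]
        rho = np.array([np.linalg.norm(Aw @ u - yw) if u.sum() > 0 else np.inf
                        for u in sols])
        tol = rho.min() * 1.02  # ~4 % on the squared misfit
        k = int(np.max(np.nonzero(rho <= tol)[0]))
        a_star, u = float(alphas[k]), sols[k]
    else:
        a_star = float(alpha)
        u = _nnls_stacked(Aw, yw, a_star, G)
    if u.sum() <= 0:
        raise ValueError("data incompatible with basis (all-zero solution)")
    w = u / u.sum()
    # refit scale on the normalized combination
    comb = A @ w
    c = float(((comb / s) @ yw) / ((comb / s) @ (comb / s)))
    resid = (Ie - c * comb) / s
    chi2 = float((resid ** 2).sum() / max(len(q) - 1, 1))
    return WeightSolution(w, a_star, chi2, c, hinge_angle_stats(w, basis))


def mass_normalize(curve: ScatteringCurve, mass: float) -> ScatteringCurve:
    """Scale a component curve to per-unit-mass intensity (I/mass²·mass =
    I/mass), so fitted combination weights read as weight fractions."""
    return ScatteringCurve(curve.q, curve.I / mass, None, curve.radiation,
                           dict(curve.metadata, mass_normalized=True))


def mixture_fractions(component_curves: list[ScatteringCurve],
                      exp_curve: ScatteringCurve,
                      labels: tuple[str, ...] = ("dimer", "trimer_of_dimers"),
                      n_bootstrap: int = 0, seed: int = 0) -> MixtureResult:
    """Weight fractions of mixture components by non-negative least squares.

    Component curves are assumed normalized per complex mass (see
    :func:`mass_normalize`); fractions are returned in percent with 1σ
    uncertainties from the fit covariance (optionally checked by residual
    bootstrap).  The result is invariant to the overall scale of the data.
    """
    if len(component_curves) < 2:
        raise ValueError("need at least 2 component curves")
    if exp_curve.sigma is None:
        raise ValueError("experimental curve must carry sigma")
    q, Ie, s = exp_curve.q, exp_curve.I, exp_curve.sigma
    A = np.array([interp_to(c, q) for c in component_curves]).T
    Aw, yw = A / s[:, None], Ie / s
    warnings_: list[str] = []
    cond = np.linalg.cond(Aw)
    if cond > 1e8:
        warnings_.append(f"component curves nearly collinear "
                         f"(condition number {cond:.3g})")
    u, _ = nnls(Aw, yw)
    if u.sum() <= 0:
        raise ValueError("all-zero mixture solution")

    def fractions_of(uvec: np.ndarray) -> np.ndarray:
        return 100.0 * uvec / uvec.sum()

    frac = fractions_of(u)
    resid = yw - Aw @ u
    dof = max(len(q) - len(u), 1)
    chi2 = float((resid ** 2).sum() / dof)
    # covariance of u from the (unconstrained) normal equations at the
    # solution, inflated by reduced χ²; delta method to the fractions
    cov_u = np.linalg.pinv(Aw.T @ Aw) * max(chi2, 1.0)
    S = u.sum()
    J = (np.eye(len(u)) * S - np.outer(u, np.ones(len(u)))) / S ** 2 * 100.0
    cov_f = J @ cov_u @ J.T
    unc = np.sqrt(np.clip(np.diag(cov_f), 0, None))
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        fit0 = Aw @ u
        for _ in range(n_bootstrap):
            yb = fit0 + rng.standard_normal(len(q)) * np.abs(resid).mean()
            ub, _ = nnls(Aw, yb)
            if ub.sum() > 0:
                boots.append(fractions_of(ub))
        if boots:
            unc = np.maximum(unc, np.std(np.array(boots), axis=0))
    return MixtureResult(tuple(labels), frac, unc, chi2, float(u.sum()),
                         warnings_)


def compare_trimer_hypotheses(exp_curve: ScatteringCurve,
                              dimer_curve: ScatteringCurve,
                              trimer_curves: dict[str, ScatteringCurve],
                              ) -> list[tuple[str, MixtureResult]]:
    """Mixture fit of the data once per trimer hypothesis, ranked by χ².

    ``trimer_curves`` maps hypothesis names (e.g. "tripod", "tm_bound") to
    per-mass-normalized trimer curves.  Ties are reported in input order,
    not broken.
    """
    results = []
    for name, tc in trimer_curves.items():
        res = mixture_fractions([dimer_curve, tc], exp_curve,
                                labels=("dimer", f"trimer_{name}"))
        results.append((name, res))
    results.sort(key=lambda kv: kv[1].chi2)
    return results


def compare_trimer_models(exp_curve: ScatteringCurve,
                          dimer_model: ParticleModel,
                          tripod_model: ParticleModel,
                          tm_bound_model: ParticleModel,
                          solvent=None, radiation: str = "neutron"
                          ) -> list[tuple[str, MixtureResult]]:
    """Model-level wrapper: forward curves per hypothesis, then ranked
    mixture fits (tripod vs TM-bound trimer of dimers)."""
    from .scattering import excess_amplitudes
    q = exp_curve.q
    def norm_curve(model):
        c = debye_curve(model, solvent, q, radiation)
        mass = float(np.abs(excess_amplitudes(model, solvent, radiation).sum()))
        return mass_normalize(c, mass)
    return compare_trimer_hypotheses(
        exp_curve, norm_curve(dimer_model),
        {"tripod": norm_curve(tripod_model),
         "tm_bound": norm_curve(tm_bound_model)})
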