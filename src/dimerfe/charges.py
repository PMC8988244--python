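"""Constrained partial-charge fitting against metal-site energy/force targets.

Metal-coordinating residues polarize in the field of bound Cu²⁺/Zn²⁺, so
fixed-geometry point charges are refit to reproduce (i) a target
metal–environment interaction energy U° and (ii) target potential-energy
gradients g°_{α,i} at each metal position α (zero in an experimentally
resolved equilibrium geometry), by minimizing

    loss = w_U (U − U°)² + w_g Σ_{α,i} (g_{α,i} − g°_{α,i})²,

with default weights w_U = 1 and w_g = 10.  Electrostatics is vacuum
Coulomb, k_C = 332.0637 kcal·Å/(mol·e²), with no cutoffs.  Both U and every
g_{α,i} are affine in the fittable charges, so the loss is a convex
quadratic program; box bounds keep each charge within a window of its
initial value (±0.1 e generally, ±0.5 e for the bridging-histidine set) and
optional linear floors (e.g. ring nitrogens not below −0.7 e) enter as
general linear constraints.  The solver is scipy's constrained trust-region
minimizer with the analytic Jacobian and Hessian of the quadratic.

Sign convention: ``metal_gradients`` returns the gradient ∇_α U of the total
Coulomb energy with respect to the metal position (the force on the metal is
its negative).  A single −1 e charge 2 Å up the +x axis from a +2 e metal
therefore gives a gradient of −166.03 kcal/mol/Å along x (the attractive
force on the metal points toward +x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt as math_sqrt
from pathlib import Path

import numpy as np
from scipy.optimize import LinearConstraint, lsq_linear, minimize

from .thermo import COULOMB_KCAL

__all__ = [
    "ChargeFitProblem",
    "ChargeFitResult",
    "interaction_energy",
    "metal_gradients",
    "loss",
    "fit_charges",
    "load_problem",
    "save_result",
]


@dataclass
class ChargeFitProblem:
    """Fixed geometry, targets, weights and constraints of one charge fit.

    ``fit_positions``/``q0`` describe the fittable charges; ``fixed_*`` are
    non-metal charges held constant; metals carry fixed charges and are the
    sites where gradients are evaluated.  ``linear_constraints`` is a list of
    ``(coefficients, lower, upper)`` rows over the fittable charges.
    """

    fit_positions: np.ndarray          # (n, 3) Å
    q0: np.ndarray                     # (n,) initial charges, e
    metal_positions: np.ndarray        # (m, 3) Å
    metal_charges: np.ndarray          # (m,) e
    target_energy: float               # U°, kcal/mol
    target_gradients: np.ndarray       # (m, 3) kcal/mol/Å
    lower: np.ndarray | None = None    # per-charge bounds, e
    upper: np.ndarray | None = None
    fixed_positions: np.ndarray | None = None
    fixed_charges: np.ndarray | None = None
    w_U: float = 1.0
    w_g: float = 10.0
    linear_constraints: list[tuple[np.ndarray, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fit_positions = np.atleast_2d(np.asarray(self.fit_positions, float))
        self.q0 = np.atleast_1d(np.asarray(self.q0, float))
        self.metal_positions = np.atleast_2d(np.asarray(self.metal_positions, float))
        self.metal_charges = np.atleast_1d(np.asarray(self.metal_charges, float))
        self.target_gradients = np.asarray(self.target_gradients, float).reshape(
            len(self.metal_charges), 3
        )
        if self.lower is None:
            self.lower = self.q0 - 0.1
        if self.upper is None:
            self.upper = self.q0 + 0.1
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if np.any(self.lower > self.upper):
            raise ValueError("infeasible bounds: lower > upper")
        if self.fixed_positions is not None:
            self.fixed_positions = np.atleast_2d(np.asarray(self.fixed_positions, float))
            self.fixed_charges = np.atleast_1d(np.asarray(self.fixed_charges, float))
        self._check_distances()

    def _check_distances(self) -> None:
        others = [self.fit_positions]
        if self.fixed_positions is not None and len(self.fixed_positions):
            others.append(self.fixed_positions)
        env = np.vstack(others)
        for pos in self.metal_positions:
            d = np.linalg.norm(env - pos, axis=1)
            if np.any(d < 1e-9):
                raise ValueError("a charge coincides with a metal position")
        for i in range(len(self.metal_positions)):
            for j in range(i + 1, len(self.metal_positions)):
                if np.linalg.norm(self.metal_positions[i] - self.metal_positions[j]) < 1e-9:
                    raise ValueError("coincident metal positions")

    @property
    def n_fit(self) -> int:
        return len(self.q0)


@dataclass(frozen=True)
class ChargeFitResult:
    charges: np.ndarray
    loss: float
    active_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.loss < -1e-12:
            raise ValueError("loss cannot be negative")


# ---------------------------------------------------------------------------
# Affine maps q -> U and q -> g  (assembled once, reused everywhere)
# ---------------------------------------------------------------------------

def _energy_affine(problem: ChargeFitProblem) -> tuple[np.ndarray, float]:
    """U(q) = a·q + a0: metal↔fittable couplings plus constant background."""
    a = np.zeros(problem.n_fit)
    a0 = 0.0
    for qm, pm in zip(problem.metal_charges, problem.metal_positions):
        d = np.linalg.norm(problem.fit_positions - pm, axis=1)
        a += COULOMB_KCAL * qm / d
        if problem.fixed_positions is not None and len(problem.fixed_positions):
            df = np.linalg.norm(problem.fixed_positions - pm, axis=1)
            a0 += COULOMB_KCAL * qm * np.sum(problem.fixed_charges / df)
    for i in range(len(problem.metal_positions)):
        for j in range(i + 1, len(problem.metal_positions)):
            dmm = np.linalg.norm(problem.metal_positions[i] - problem.metal_positions[j])
            a0 += COULOMB_KCAL * problem.metal_charges[i] * problem.metal_charges[j] / dmm
    return a, float(a0)


def _gradient_affine(problem: ChargeFitProblem) -> tuple[np.ndarray, np.ndarray]:
    """g(q) = B q + b0 flattened over (metal α, direction i): ∇_α U."""
    m = len(problem.metal_charges)
    B = np.zeros((3 * m, problem.n_fit))
    b0 = np.zeros(3 * m)
    for alpha, (qm, pm) in enumerate(zip(problem.metal_charges, problem.metal_positions)):
        rows = slice(3 * alpha, 3 * alpha + 3)
        diff = pm - problem.fit_positions          # (n, 3)
        d = np.linalg.norm(diff, axis=1)
        # d/dR_alpha of kC q_m q_j / |R - r_j| = -kC q_m q_j (R - r_j)/d^3
        B[rows, :] = (-COULOMB_KCAL * qm / d**3 * diff.T)
        if problem.fixed_positions is not None and len(problem.fixed_positions):
            diff_f = pm - problem.fixed_positions
            df = np.linalg.norm(diff_f, axis=1)
            b0[rows] += (-COULOMB_KCAL * qm * problem.fixed_charges / df**3) @ diff_f
        for beta, (qb, pb) in enumerate(zip(problem.metal_charges, problem.metal_positions)):
            if beta == alpha:
                continue
            diff_m = pm - pb
            dm = np.linalg.norm(diff_m)
            b0[rows] += -COULOMB_KCAL * qm * qb * diff_m / dm**3
    return B, b0


def interaction_energy(problem: ChargeFitProblem, q: np.ndarray) -> float:
    """Coulomb interaction energy (kcal/mol) of the metals with all charges.

    Pairwise sum over metal↔fittable, metal↔fixed and metal↔metal pairs;
    affine in each fittable charge.
    """
    a, a0 = _energy_affine(problem)
    return float(a @ np.asarray(q, float) + a0)


def metal_gradients(problem: ChargeFitProblem, q: np.ndarray) -> np.ndarray:
    """Analytic Coulomb energy gradient (kcal/mol/Å) at each metal position.

    Returns an (m, 3) array ∇_α U; affine in each fittable charge.
    """
    B, b0 = _gradient_affine(problem)
    return (B @ np.asarray(q, float) + b0).reshape(-1, 3)


def loss(problem: ChargeFitProblem, q: np.ndarray) -> float:
    """w_U (U−U°)² + w_g Σ (g−g°)² at charges q."""
    du = interaction_energy(problem, q) - problem.target_energy
    dg = metal_gradients(problem, q) - problem.target_gradients
    return float(problem.w_U * du**2 + problem.w_g * np.sum(dg**2))


def _quadratic_form(problem: ChargeFitProblem):
    """loss(q) = q'Hq/2 + c'q + const with H PSD."""
    a, a0 = _energy_affine(problem)
    B, b0 = _gradient_affine(problem)
    ru = a0 - problem.target_energy           # residual at q = 0
    rg = b0 - problem.target_gradients.ravel()
    H = 2.0 * (problem.w_U * np.outer(a, a) + problem.w_g * B.T @ B)
    c = 2.0 * (problem.w_U * ru * a + problem.w_g * B.T @ rg)
    const = problem.w_U * ru**2 + problem.w_g * rg @ rg
    return H, c, float(const)


def _kkt_polish(problem: ChargeFitProblem, H, c, q, active_tol):
    """Solve the equality-KKT system for the near-active set of a candidate.

    Returns the polished point if it is feasible, else None.
    """
    n = problem.n_fit
    rows, vals = [], []
    for i in range(n):
        if q[i] - problem.lower[i] <= active_tol:
            e = np.zeros(n); e[i] = 1.0
            rows.append(e); vals.append(problem.lower[i])
        elif problem.upper[i] - q[i] <= active_tol:
            e = np.zeros(n); e[i] = 1.0
            rows.append(e); vals.append(problem.upper[i])
    for coeff, lb, ub in problem.linear_constraints:
        val = float(np.dot(coeff, q))
        if np.isfinite(lb) and val - lb <= active_tol:
            rows.append(np.asarray(coeff, float)); vals.append(lb)
        elif np.isfinite(ub) and ub - val <= active_tol:
            rows.append(np.asarray(coeff, float)); vals.append(ub)
    if rows:
        E = np.vstack(rows)
        m = len(rows)
        kkt = np.block([[H, E.T], [E, np.zeros((m, m))]])
        rhs = np.concatenate([-c, vals])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            return None
        q_new = sol[:n]
    else:
        try:
            q_new = np.linalg.solve(H, -c)
        except np.linalg.LinAlgError:
            return None
    feasible = np.all(q_new >= problem.lower - 1e-9) and np.all(q_new <= problem.upper + 1e-9)
    for coeff, lb, ub in problem.linear_constraints:
        val = float(np.dot(coeff, q_new))
        feasible &= (not np.isfinite(lb) or val >= lb - 1e-9)
        feasible &= (not np.isfinite(ub) or val <= ub + 1e-9)
    if not feasible:
        return None
    return np.clip(q_new, problem.lower, problem.upper)


def fit_charges(
    problem: ChargeFitProblem,
    tol: float = 1e-12,
    active_tol: float = 1e-7,
) -> ChargeFitResult:
    """Minimize the loss subject to box bounds and linear constraints.

    The loss is a convex quadratic in the charges, solved with scipy's
    trust-region constrained minimizer using the analytic gradient and
    Hessian (scaled to unit curvature for well-behaved termination).  For
    box-only problems the solution is then refined by bounded-variable
    least squares on the weighted residual system, which resolves the
    active set to machine precision; with extra linear constraints the
    trust-region iterate is polished by solving the KKT system of its
    near-active set.  The returned active set names the bounds/constraints
    tight at the optimum.
    """
    H, c, const = _quadratic_form(problem)
    scale = max(np.abs(H).max(), 1.0)

    def fun(q):
        return (0.5 * q @ H @ q + c @ q + const) / scale

    def jac(q):
        return (H @ q + c) / scale

    constraints = []
    if problem.linear_constraints:
        A = np.vstack([row[0] for row in problem.linear_constraints])
        lb = np.array([row[1] for row in problem.linear_constraints])
        ub = np.array([row[2] for row in problem.linear_constraints])
        if np.any(lb > ub):
            raise ValueError("infeasible linear constraints")
        constraints.append(LinearConstraint(A, lb, ub))

    q_start = 0.5 * (problem.lower + problem.upper)
    q_start = np.where(np.isfinite(q_start),
                       q_start, np.clip(problem.q0, problem.lower, problem.upper))
    res = minimize(
        fun, q_start, jac=jac, hess=lambda q: H / scale, method="trust-constr",
        bounds=list(zip(problem.lower, problem.upper)),
        constraints=constraints,
        options={"gtol": tol, "xtol": 1e-14, "maxiter": 2000},
    )
    q = np.clip(res.x, problem.lower, problem.upper)

    if not problem.linear_constraints:
        a, a0 = _energy_affine(problem)
        B, b0 = _gradient_affine(problem)
        rows = np.vstack([math_sqrt(problem.w_U) * a[None, :],
                          math_sqrt(problem.w_g) * B])
        rhs = np.concatenate([
            [math_sqrt(problem.w_U) * (problem.target_energy - a0)],
            math_sqrt(problem.w_g) * (problem.target_gradients.ravel() - b0),
        ])
        refined = lsq_linear(rows, rhs, bounds=(problem.lower, problem.upper),
                             method="bvls", tol=1e-14)
        if loss(problem, refined.x) <= loss(problem, q):
            q = np.clip(refined.x, problem.lower, problem.upper)
    else:
        polished = _kkt_polish(problem, H, c, q, max(active_tol, 1e-5))
        if polished is not None and loss(problem, polished) <= loss(problem, q):
            q = polished

    active: list[str] = []
    for i in range(problem.n_fit):
        if q[i] - problem.lower[i] <= active_tol:
            active.append(f"lower[{i}]")
        elif problem.upper[i] - q[i] <= active_tol:
            active.append(f"upper[{i}]")
    for j, (coeff, lb, ub) in enumerate(problem.linear_constraints):
        val = float(np.dot(coeff, q))
        if val - lb <= active_tol:
            active.append(f"linear[{j}]:lower")
        elif ub - val <= active_tol:
            active.append(f"linear[{j}]:upper")

    return ChargeFitResult(charges=q, loss=max(loss(problem, q), 0.0),
                           active_set=tuple(active))


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def load_problem(path) -> ChargeFitProblem:
    """Read a charge-fit problem from JSON."""
    spec = json.loads(Path(path).read_text())
    lc = [
        (np.asarray(row["coefficients"], float), float(row["lower"]), float(row["upper"]))
        for row in spec.get("linear_constraints", [])
    ]
    return ChargeFitProblem(
        fit_positions=np.asarray(spec["fit_positions"], float),
        q0=np.asarray(spec["q0"], float),
        metal_positions=np.asarray(spec["metal_positions"], float),
        metal_charges=np.asarray(spec["metal_charges"], float),
        target_energy=float(spec["target_energy"]),
        target_gradients=np.asarray(spec["target_gradients"], float),
        lower=np.asarray(spec["lower"], float) if "lower" in spec else None,
        upper=np.asarray(spec["upper"], float) if "upper" in spec else None,
        fixed_positions=np.asarray(spec["fixed_positions"], float) if spec.get("fixed_positions") else None,
        fixed_charges=np.asarray(spec["fixed_charges"], float) if spec.get("fixed_charges") else None,
        w_U=float(spec.get("w_U", 1.0)),
        w_g=float(spec.get("w_g", 10.0)),
        linear_constraints=lc,
    )


def save_result(result: ChargeFitResult, path) -> None:
    payload = {
        "charges": result.charges.tolist(),
        "loss": result.loss,
        "active_set": list(result.active_set),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
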