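"""Umbrella-sampling free-energy estimation: MBAR, PMFs, FEP, and I*.

Umbrella windows carry equilibrium samples of a scalar reaction coordinate
(separation distance, an RMSD, or an angle) under a harmonic bias.  The
multistate Bennett acceptance ratio (MBAR) estimator combines the windows
into per-window dimensionless free energies f_k, from which an unbiased
potential of mean force W is reconstructed on a grid.  The cost of imposing
a restraint u on an unbiased ensemble follows from free energy perturbation,

    ΔG = −kT ln ⟨e^{−βu}⟩,

and the bound-region line integral of the separation PMF,

    I* = ∫ e^{−β(W(r) − W(r*))} dr,

feeds the combined separation + axial-angle term
ΔG_dist+a = −kT ln(c° S* I*).

Numerical policy: MBAR is solved by log-sum-exp-stabilized self-consistent
iteration followed by quasi-Newton polish of the convex MBAR objective
(convergence max|Δf| < 1e-8).  Statistical errors use a moving-block
bootstrap with block length set by an integrated-autocorrelation estimate;
systematic (convergence) errors recompute an estimate on growing trailing
fractions of the series after discarding the initial half, and the reported
error is the larger of the two.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .geometry import wrap_angle
from .thermo import ThermoContext

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "FreeEnergyEstimate",
    "DisconnectedSamplingError",
    "mbar_solve",
    "mbar_bootstrap",
    "pmf_from_windows",
    "fep_cost",
    "i_star",
    "dg_dist_a",
    "convergence_error",
    "integrated_autocorrelation_time",
    "read_colvar",
    "write_colvar",
    "load_windows",
]


class DisconnectedSamplingError(RuntimeError):
    """The window overlap graph is disconnected: MBAR cannot link all states."""


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free energy (kcal/mol) with statistical and systematic errors.

    The reported ``error`` is the larger of the two sources.
    """

    value: float
    stat_error: float = 0.0
    sys_error: float = 0.0

    def __post_init__(self) -> None:
        if self.stat_error < 0 or self.sys_error < 0:
            raise ValueError("errors must be non-negative")

    @property
    def error(self) -> float:
        return max(self.stat_error, self.sys_error)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: harmonic bias parameters plus ordered samples."""

    center: float
    k: float
    samples: np.ndarray
    label: str = ""
    periodic: bool = False
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.atleast_1d(np.asarray(self.samples, float)))
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")

    @property
    def n(self) -> int:
        return self.samples.size

    def bias_energy(self, x) -> np.ndarray:
        """Harmonic bias (kcal/mol) at coordinate value(s) x."""
        x = np.asarray(x, float)
        delta = wrap_angle(x - self.center) if self.periodic else x - self.center
        return 0.5 * self.k * np.square(delta)

    def truncated(self, fraction: float, discard: float = 0.0) -> "UmbrellaWindow":
        """First ``fraction`` of the series with its initial ``discard`` dropped."""
        n_keep = max(1, int(round(self.n * fraction)))
        series = self.samples[:n_keep]
        start = int(round(len(series) * discard))
        series = series[start:] if start < len(series) else series[-1:]
        return replace(self, samples=series)


@dataclass
class PMFProfile:
    """W on a grid of bin centers with per-bin uncertainties.

    ``offset`` records the additive convention: "min-zero" anchors the lowest
    occupied bin at zero; "value-at-r*" anchors W(anchor) = 0.
    """

    grid: np.ndarray
    values: np.ndarray
    uncertainties: np.ndarray
    offset: str = "min-zero"
    anchor: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        self.uncertainties = np.asarray(self.uncertainties, float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.values)

    def value_at(self, x: float) -> float:
        """Linear interpolation of W at x over occupied bins."""
        g, v = self.grid[self.occupied], self.values[self.occupied]
        if not g.size or x < g[0] - 1e-9 or x > g[-1] + 1e-9:
            raise ValueError(f"{x} outside the occupied PMF range [{g[0]}, {g[-1]}]")
        return float(np.interp(x, g, v))


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _reduced_bias_matrix(windows: Sequence[UmbrellaWindow], beta: float):
    x = np.concatenate([w.samples for w in windows])
    n_k = np.array([w.n for w in windows])
    u_kn = np.vstack([beta * w.bias_energy(x) for w in windows])
    return x, n_k, u_kn


def _check_overlap(windows: Sequence[UmbrellaWindow], min_count: int = 10) -> None:
    """Warn on weak neighbor overlap; raise if the overlap graph is disconnected."""
    order = np.argsort([w.center for w in windows])
    ws = [windows[i] for i in order]
    ranges = [(w.samples.min(), w.samples.max()) for w in ws]
    k = len(ws)
    adj = np.zeros((k, k), dtype=bool)
    for i in range(k):
        lo_i, hi_i = ranges[i]
        for j in range(i + 1, k):
            lo_j, hi_j = ranges[j]
            lo, hi = max(lo_i, lo_j), min(hi_i, hi_j)
            if lo > hi:
                continue
            count = int(np.sum((ws[i].samples >= lo) & (ws[i].samples <= hi))
                        + np.sum((ws[j].samples >= lo) & (ws[j].samples <= hi)))
            if count > 0:
                adj[i, j] = adj[j, i] = True
            if j == i + 1 and 0 < count < min_count:
                warnings.warn(
                    f"windows {ws[i].label or i} and {ws[j].label or j} "
                    f"share only {count} samples",
                    stacklevel=3,
                )
    # connectivity by BFS
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    if len(seen) < k:
        raise DisconnectedSamplingError(
            f"umbrella windows form {k - len(seen) + 1}+ disconnected groups; "
            "add bridging windows"
        )


def _mbar_objective(f, u_kn, n_k):
    """Convex MBAR objective; its stationary point solves the MBAR equations."""
    n_tot = n_k.sum()
    log_n = np.log(n_k / n_tot)
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    obj = log_denom.sum() / n_tot - np.dot(n_k / n_tot, f)
    w = np.exp(log_n[:, None] + f[:, None] - u_kn - log_denom[None, :])
    grad = w.sum(axis=1) / n_tot - n_k / n_tot
    return obj, grad


def mbar_solve(
    windows: Sequence[UmbrellaWindow],
    thermo: ThermoContext | None = None,
    tol: float = 1e-8,
    max_iter: int = 150,
    f_init: np.ndarray | None = None,
    check_overlap: bool = True,
) -> np.ndarray:
    """Per-window dimensionless free energies f_k solving the MBAR equations.

    f is gauge-fixed to f[0] = 0.  A single window returns (0,).  Raises
    :class:`DisconnectedSamplingError` when windows do not overlap pairwise
    into one connected component.
    """
    thermo = thermo or ThermoContext()
    if len(windows) == 1:
        return np.zeros(1)
    if check_overlap:
        _check_overlap(windows)
    x, n_k, u_kn = _reduced_bias_matrix(windows, thermo.beta)
    log_nk = np.log(n_k)
    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, float)
    # self-consistent iteration with log-sum-exp stabilization
    converged = False
    for _ in range(max_iter):
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        # quasi-Newton polish on the convex objective, then one SC sweep to
        # confirm the self-consistency residual
        res = minimize(
            _mbar_objective, f, args=(u_kn, n_k), jac=True, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 1000},
        )
        f = res.x - res.x[0]
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f = f_new - f_new[0]
    return f


def _unbiased_log_weights(windows, f, beta):
    x, n_k, u_kn = _reduced_bias_matrix(windows, beta)
    log_denom = logsumexp(np.log(n_k)[:, None] + f[:, None] - u_kn, axis=0)
    return x, -log_denom


def mbar_bootstrap(
    windows: Sequence[UmbrellaWindow],
    statistic: Callable[[Sequence[UmbrellaWindow], np.ndarray], float],
    thermo: ThermoContext | None = None,
    n_boot: int = 30,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float]:
    """Bootstrap a scalar statistic(windows, f) of an MBAR solve.

    Samples are resampled by moving blocks within each window; each replicate
    re-solves MBAR warm-started from the full-data solution.  Returns
    (statistic, standard error).
    """
    thermo = thermo or ThermoContext()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f_full = mbar_solve(windows, thermo)
    value = statistic(windows, f_full)
    reps = []
    for _ in range(n_boot):
        resampled = [
            replace(w, samples=_moving_block_resample(w.samples, rng))
            for w in windows
        ]
        f_b = mbar_solve(resampled, thermo, f_init=f_full, check_overlap=False)
        reps.append(statistic(resampled, f_b))
    return value, float(np.std(reps, ddof=1)) if n_boot > 1 else (value, 0.0)


# ---------------------------------------------------------------------------
# PMF reconstruction
# ---------------------------------------------------------------------------

def default_grid(windows: Sequence[UmbrellaWindow]) -> np.ndarray:
    """Bin edges with width = half the median umbrella-center spacing."""
    centers = np.sort([w.center for w in windows])
    spacing = np.median(np.diff(centers)) if len(centers) > 1 else 1.0
    width = max(spacing / 2.0, 1e-6)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def pmf_from_windows(
    windows: Sequence[UmbrellaWindow],
    f: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    thermo: ThermoContext | None = None,
    offset: str = "min-zero",
    anchor: float | None = None,
    n_boot: int = 0,
    rng: np.random.Generator | int | None = 0,
    min_count: int = 5,
) -> PMFProfile:
    """MBAR-reweighted PMF on a grid of bin edges.

    ``offset`` is "min-zero" (lowest occupied bin at 0) or "value-at-r*"
    (requires ``anchor``).  Bins holding fewer than ``min_count`` samples are
    flagged with W = nan: lone samples in barely-visited regions carry very
    large reweighting factors, and the density estimate there is pure noise.
    ``n_boot`` > 0 adds bootstrap per-bin uncertainties.
    """
    thermo = thermo or ThermoContext()
    if f is None:
        f = mbar_solve(windows, thermo)
    edges = default_grid(windows) if grid is None else np.asarray(grid, float)

    def _histogram(ws, fk):
        x, logw = _unbiased_log_weights(ws, fk, thermo.beta)
        idx = np.digitize(x, edges) - 1
        n_bins = len(edges) - 1
        w_vals = np.full(n_bins, np.nan)
        widths = np.diff(edges)
        for b in range(n_bins):
            mask = idx == b
            if np.count_nonzero(mask) >= max(min_count, 1):
                w_vals[b] = -thermo.kT * (logsumexp(logw[mask]) - np.log(widths[b]))
        return w_vals

    values = _histogram(windows, f)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = np.isfinite(values)
    interior = occupied.cumsum() > 0
    interior &= occupied[::-1].cumsum()[::-1] > 0
    if np.any(interior & ~occupied):
        warnings.warn("empty bins inside the sampled range; W undefined there")

    def _shift(vals):
        if offset == "min-zero":
            return vals - np.nanmin(vals)
        if offset == "value-at-r*":
            if anchor is None:
                raise ValueError("offset 'value-at-r*' requires an anchor")
            g, v = centers[np.isfinite(vals)], vals[np.isfinite(vals)]
            return vals - np.interp(anchor, g, v)
        raise ValueError(f"unknown offset convention {offset!r}")

    values = _shift(values)
    sigmas = np.zeros_like(values)
    if n_boot > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        reps = []
        for _ in range(n_boot):
            resampled = [
                replace(w, samples=_moving_block_resample(w.samples, rng))
                for w in windows
            ]
            f_b = mbar_solve(resampled, thermo, f_init=f, check_overlap=False)
            reps.append(_shift(_histogram(resampled, f_b)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sigmas = np.nanstd(np.vstack(reps), axis=0, ddof=1)
    return PMFProfile(centers, values, sigmas, offset=offset, anchor=anchor)


# ---------------------------------------------------------------------------
# FEP, I*, and the combined separation + axial term
# ---------------------------------------------------------------------------

def integrated_autocorrelation_time(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time by the initial-positive-sequence rule."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return 1.0
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    tau = 1.0
    for lag in range(1, min(max_lag or n // 2, n // 2)):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return float(max(tau, 1.0))


def _moving_block_resample(x: np.ndarray, rng: np.random.Generator,
                           block: int | None = None) -> np.ndarray:
    n = x.size
    if block is None:
        block = int(np.clip(np.ceil(integrated_autocorrelation_time(x)), 1, max(n // 2, 1)))
    if block >= n:
        block = max(1, n // 2) or 1
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    out = np.concatenate([x[s:s + block] for s in starts])[:n]
    return out


def fep_cost(
    u_samples: np.ndarray,
    thermo: ThermoContext | None = None,
    n_boot: int = 50,
    rng: np.random.Generator | int | None = 0,
) -> FreeEnergyEstimate:
    """Free energy (kcal/mol) of imposing a restraint via exponential averaging.

    ``u_samples`` are restraint energies evaluated on an unbiased equilibrium
    ensemble; ΔG = −kT ln⟨e^{−βu}⟩ computed overflow-safe.  The statistical
    error is a moving-block bootstrap over ``n_boot`` resamples.
    """
    thermo = thermo or ThermoContext()
    u = np.asarray(u_samples, float)
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    if np.all(np.isinf(u)):
        raise ValueError("all restraint energies are infinite")

    def _estimate(uu):
        return -thermo.kT * (logsumexp(-thermo.beta * uu) - np.log(uu.size))

    value = float(_estimate(u))
    stat = 0.0
    if n_boot > 1:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        reps = [float(_estimate(_moving_block_resample(u, rng))) for _ in range(n_boot)]
        stat = float(np.std(reps, ddof=1))
    return FreeEnergyEstimate(value, stat_error=stat)


def i_star(
    pmf: PMFProfile,
    r_star: float,
    thermo: ThermoContext | None = None,
    r_min: float | None = None,
    r_max: float | None = None,
) -> float:
    """Bound-region line integral I* = ∫ e^{−β(W(r) − W(r*))} dr (Å).

    Trapezoid rule over the occupied grid from ``r_min`` (default: smallest
    occupied point) to ``r_max`` (default: r*).  Boltzmann weighting makes
    contributions far above the bound well negligible, so the full sampled
    support is a safe default integration range.
    """
    thermo = thermo or ThermoContext()
    w_ref = pmf.value_at(r_star)  # raises if r* is outside the grid
    g, v = pmf.grid[pmf.occupied], pmf.values[pmf.occupied]
    lo = g[0] if r_min is None else r_min
    hi = r_star if r_max is None else r_max
    mask = (g >= lo - 1e-9) & (g <= hi + 1e-9)
    g, v = g[mask], v[mask]
    if g.size < 2:
        raise ValueError("integration range covers fewer than 2 PMF points")
    return float(np.trapezoid(np.exp(-thermo.beta * (v - w_ref)), g))


def dg_dist_a(i_star_value: float, s_star_value: float,
              thermo: ThermoContext | None = None) -> float:
    """Combined separation + axial-angle term ΔG = −kT ln(c° S* I*) (kcal/mol)."""
    thermo = thermo or ThermoContext()
    if i_star_value <= 0 or s_star_value <= 0:
        raise ValueError("S* and I* must be positive")
    return -thermo.kT * np.log(s_star_value * i_star_value / thermo.standard_volume)


def convergence_error(
    windows: Sequence[UmbrellaWindow],
    estimator: Callable[[Sequence[UmbrellaWindow]], FreeEnergyEstimate | float],
    fractions: Sequence[float] = (0.4, 0.6, 0.8, 1.0),
    discard: float = 0.5,
) -> FreeEnergyEstimate:
    """Convergence (systematic) error of an estimate over growing trajectories.

    For each fraction the windows are truncated to that portion of their
    series, the initial ``discard`` of the truncated series is dropped, and
    the estimator re-run.  The systematic error is the largest deviation from
    the final estimate; the reported error is max(statistical, systematic).
    """
    if len(fractions) < 4:
        raise ValueError("need at least 4 fractions to assess convergence")
    estimates = []
    for frac in sorted(fractions):
        est = estimator([w.truncated(frac, discard) for w in windows])
        if not isinstance(est, FreeEnergyEstimate):
            est = FreeEnergyEstimate(float(est))
        estimates.append(est)
    final = estimates[-1]
    sys_err = max(abs(e.value - final.value) for e in estimates)
    return FreeEnergyEstimate(final.value, stat_error=final.stat_error, sys_error=sys_err)


# ---------------------------------------------------------------------------
# COLVAR-style I/O
# ---------------------------------------------------------------------------

def read_colvar(path) -> np.ndarray:
    """Read the cv column of a whitespace-separated `#! FIELDS time cv` file."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            values.append(float(parts[1] if len(parts) > 1 else parts[0]))
    if not values:
        raise ValueError(f"no samples in {path}")
    return np.asarray(values)


def write_colvar(path, values: np.ndarray, times: np.ndarray | None = None) -> None:
    values = np.asarray(values, float)
    times = np.arange(values.size, dtype=float) if times is None else times
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.3f} {v:.8f}\n")


def load_windows(manifest_path) -> list[UmbrellaWindow]:
    """Load windows from a JSON manifest: [{file, center, k, label?, periodic?}]."""
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    windows = []
    for entry in spec["windows"] if isinstance(spec, dict) else spec:
        samples = read_colvar(manifest_path.parent / entry["file"])
        windows.append(
            UmbrellaWindow(
                center=float(entry["center"]),
                k=float(entry["k"]),
                samples=samples,
                label=entry.get("label", entry["file"]),
                periodic=bool(entry.get("periodic", False)),
            )
        )
    return windows
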