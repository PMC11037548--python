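"""Gaussian-accelerated dynamics on analytic potentials.

Gaussian accelerated MD (GaMD) flattens a potential-energy surface by
adding a harmonic boost

    dV(r) = 1/2 k (E - V(r))^2      when V(r) < E,   else 0,

where E is a threshold energy and k a force constant chosen so that the
boost distribution stays near-Gaussian; the unbiased free-energy surface
is then recovered by cumulant-expansion reweighting of the boosted
ensemble.  This module runs the whole loop — adaptive (E, k) estimation in
the lower-bound mode (E = Vmax), BAOAB Langevin sampling on the boosted
surface, and second-order cumulant reweighting — on low-dimensional
analytic potentials where the exact answer is known, so the sampling and
reweighting machinery can be validated without a force field.

Dual boost (independent boosts on two energy components, e.g. a
"dihedral" term and the total) is supported through composite potentials.

Units: energies kcal/mol, temperatures K, k_B = 0.0019872041 kcal/(mol K).
Mass is 1 in reduced units; time/friction units follow from that choice,
which leaves equilibrium (Boltzmann) statistics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .ensemble_model import KB_KCAL


class DegenerateInputError(ValueError):
    pass


class DivergenceError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"non-finite energy encountered at step {step}")
        self.step = step


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------


class Harmonic:
    """V(x) = 1/2 kappa |x - center|^2."""

    def __init__(self, kappa: float = 1.0, center: float = 0.0, dim: int = 1):
        self.kappa = kappa
        self.center = np.full(dim, float(center))
        self.dim = dim

    def energy(self, x: np.ndarray) -> float:
        d = x - self.center
        return 0.5 * self.kappa * float(d @ d)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.kappa * (x - self.center)


class DoubleWell1D:
    """V(x) = h ((x/a)^2 - 1)^2: minima at ±a, barrier height h at x = 0."""

    def __init__(self, height: float, half_separation: float = 1.0):
        self.h = height
        self.a = half_separation
        self.dim = 1

    def energy(self, x: np.ndarray) -> float:
        u = (x[0] / self.a) ** 2 - 1.0
        return self.h * u * u

    def gradient(self, x: np.ndarray) -> np.ndarray:
        u = (x[0] / self.a) ** 2 - 1.0
        return np.array([4.0 * self.h * u * x[0] / self.a**2])

    def barrier_height(self) -> float:
        return self.h


class CompositePotential:
    """Sum of independent components, each eligible for its own boost."""

    def __init__(self, components: Sequence):
        self.components = list(components)
        self.dim = self.components[0].dim
        if any(c.dim != self.dim for c in self.components):
            raise ValueError("all components must share the same dimension")

    def component_energies(self, x: np.ndarray) -> list[float]:
        return [c.energy(x) for c in self.components]

    def energy(self, x: np.ndarray) -> float:
        return float(sum(self.component_energies(x)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(self.dim)
        for c in self.components:
            g += c.gradient(x)
        return g


# ---------------------------------------------------------------------------
# Boost potential
# ---------------------------------------------------------------------------


@dataclass
class BoostParameters:
    """Threshold E, force constant k (both the harmonic k and the
    dimensionless k0 = k (Vmax - Vmin)), and the user bound sigma0 on the
    boost standard deviation."""

    E: float
    k: float
    k0: float = 1.0
    sigma0: float = 6.0

    def __post_init__(self):
        if not (0.0 < self.k0 <= 1.0):
            raise ValueError("k0 must lie in (0, 1]")
        if self.k < 0:
            raise ValueError("k must be nonnegative")


def compute_boost(V: float | np.ndarray, params: BoostParameters):
    """dV = 1/2 k (E - V)^2 below the threshold, 0 at and above it."""
    V = np.asarray(V, dtype=float)
    dv = np.where(V < params.E, 0.5 * params.k * (params.E - V) ** 2, 0.0)
    return float(dv) if dv.ndim == 0 else dv


def boost_force_factor(V: float, params: Optional[BoostParameters]) -> float:
    """Force scaling on the boosted surface: grad(V + dV) = factor * grad V."""
    if params is None or V >= params.E:
        return 1.0
    return 1.0 - params.k * (params.E - V)


def estimate_parameters(cmd_potentials: Sequence[float], sigma0: float = 6.0) -> BoostParameters:
    """Adaptive lower-bound GaMD parameters from unboosted potential samples.

    E = Vmax and k = k0/(Vmax - Vmin) with
    k0 = min(1, (sigma0/sigma_V) (Vmax - Vmin)/(Vmax - Vavg)),
    which bounds the standard deviation of the resulting boost near sigma0.
    """
    v = np.asarray(cmd_potentials, dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 potential samples")
    vmax, vmin = float(v.max()), float(v.min())
    if vmax <= vmin:
        raise DegenerateInputError("potential samples are constant (Vmax == Vmin)")
    vavg, sigma_v = float(v.mean()), float(v.std())
    k0 = min(1.0, (sigma0 / sigma_v) * (vmax - vmin) / (vmax - vavg))
    return BoostParameters(E=vmax, k=k0 / (vmax - vmin), k0=k0, sigma0=sigma0)


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------


@dataclass
class GaMDRun:
    """Saved trajectory of a (possibly boosted) Langevin run."""

    positions: np.ndarray  # (S, d)
    potential: np.ndarray  # (S,) unbiased V, kcal/mol
    boost: np.ndarray  # (S,) dV, kcal/mol
    temperature: float
    params: Optional[BoostParameters | list[BoostParameters]] = None

    def __post_init__(self):
        if np.any(self.boost < -1e-12):
            raise ValueError("boost must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {f"x{i}" if self.positions.shape[1] > 1 else "x": self.positions[:, i]
                for i in range(self.positions.shape[1])}
        cols["V"] = self.potential
        cols["dV"] = self.boost
        pd.DataFrame(cols).to_csv(path, sep="\t", index_label="step")


def _resolve_boosts(potential, boost):
    """Normalize the boost argument to a per-component list (or None)."""
    if boost is None:
        return None
    if isinstance(boost, BoostParameters):
        if isinstance(potential, CompositePotential):
            # single boost on the total energy of the composite
            return [("total", boost)]
        return [("total", boost)]
    # dual boost: one BoostParameters per component
    if not isinstance(potential, CompositePotential):
        raise ValueError("per-component boosts require a CompositePotential")
    if len(boost) != len(potential.components):
        raise ValueError("one BoostParameters per component required")
    return [("component", b) for b in boost]


def run_langevin(
    potential,
    steps: int,
    dt: float,
    friction: float,
    temperature: float,
    seed: int,
    boost: Optional[BoostParameters | Sequence[BoostParameters]] = None,
    x0: Optional[Sequence[float]] = None,
    stride: int = 1,
) -> GaMDRun:
    """BAOAB-discretized Langevin dynamics on V (+ dV when boosted).

    Records the unbiased potential V and the boost dV every ``stride``
    steps; bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    d = potential.dim
    x = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float).copy()
    kT = KB_KCAL * temperature
    v = rng.normal(0.0, np.sqrt(kT), size=d)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    boosts = _resolve_boosts(potential, boost)
    dual = boosts is not None and boosts[0][0] == "component"

    def force_and_energies(x):
        if dual:
            comps = potential.component_energies(x)
            f = np.zeros(d)
            dv = 0.0
            for c, (_, bp), Vc in zip(potential.components, boosts, comps):
                f -= c.gradient(x) * boost_force_factor(Vc, bp)
                dv += compute_boost(Vc, bp)
            return f, float(sum(comps)), dv
        V = potential.energy(x)
        if boosts is None:
            return -potential.gradient(x), V, 0.0
        bp = boosts[0][1]
        return -potential.gradient(x) * boost_force_factor(V, bp), V, compute_boost(V, bp)

    f, V, dv = force_and_energies(x)
    n_saved = steps // stride
    xs = np.empty((n_saved, d))
    Vs = np.empty(n_saved)
    dVs = np.empty(n_saved)
    isave = 0
    for step in range(steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(d)
        x += 0.5 * dt * v
        f, V, dv = force_and_energies(x)
        if not np.isfinite(V):
            raise DivergenceError(step)
        v += 0.5 * dt * f
        if (step + 1) % stride == 0:
            xs[isave] = x
            Vs[isave] = V
            dVs[isave] = dv
            isave += 1
    params = None if boosts is None else (
        [b for _, b in boosts] if dual else boosts[0][1]
    )
    return GaMDRun(xs, Vs, dVs, temperature, params)


def count_barrier_crossings(x: np.ndarray, low: float = -0.5, high: float = 0.5) -> int:
    """Full well-to-well transitions of a 1D coordinate with hysteresis."""
    x = np.asarray(x).ravel()
    state = 0  # -1 left, +1 right, 0 undecided
    crossings = 0
    for xi in x:
        if xi <= low:
            if state == 1:
                crossings += 1
            state = -1
        elif xi >= high:
            if state == -1:
                crossings += 1
            state = 1
    return crossings


# ---------------------------------------------------------------------------
# Cumulant reweighting
# ---------------------------------------------------------------------------


@dataclass
class ReweightedPMF:
    bin_centers: np.ndarray
    pmf: np.ndarray  # kcal/mol, min over valid bins shifted to 0; NaN where missing
    counts: np.ndarray
    valid: np.ndarray  # bool mask: bin populated with >= min_samples
    order: int


def reweight_cumulant(
    run: GaMDRun,
    order: int = 2,
    bins: int | np.ndarray = 50,
    coord_index: int = 0,
    min_samples: int = 20,
) -> ReweightedPMF:
    """Recover the unbiased PMF along one coordinate by cumulant reweighting.

    Per bin j the boosted density is multiplied by
    exp(beta C1 + beta^2 C2 / 2) with C1 = <dV>_j and C2 = Var(dV)_j
    (order 1 drops the C2 term); the PMF is -k_B T ln of the reweighted
    density, shifted so its minimum over valid bins is zero.  Bins with
    fewer than ``min_samples`` samples are flagged invalid (NaN), never
    interpolated.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = run.positions[:, coord_index]
    dv = run.boost
    kT = KB_KCAL * run.temperature
    beta = 1.0 / kT
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    c1 = np.zeros(nb)
    c2 = np.zeros(nb)
    idx = np.clip(np.digitize(x, edges) - 1, 0, nb - 1)
    for j in range(nb):
        m = idx == j
        if counts[j] > 0:
            dvj = dv[m]
            c1[j] = dvj.mean()
            c2[j] = dvj.var()
    valid = counts >= min_samples
    with np.errstate(divide="ignore"):
        log_density = np.log(counts / counts.sum() / np.diff(edges))
    log_rw = log_density + beta * c1
    if order == 2:
        log_rw = log_rw + 0.5 * beta**2 * c2
    pmf = np.full(nb, np.nan)
    pmf[valid] = -kT * log_rw[valid]
    pmf[valid] -= np.nanmin(pmf[valid])
    return ReweightedPMF(centers, pmf, counts, valid, order)


def gamd_double_well_demo(
    barrier_kT: float = 4.0,
    temperature: float = 300.0,
    steps: int = 200_000,
    cmd_steps: int = 20_000,
    dt: float = 0.02,
    friction: float = 1.0,
    sigma0: float = 6.0,
    seed: int = 0,
    bins: int = 48,
) -> dict:
    """Full desk-scale workflow: short unboosted run -> adaptive (E, k) ->
    boosted run -> order-2 reweighting; returns runs, PMFs and the barrier
    estimate alongside the analytic value."""
    kT = KB_KCAL * temperature
    pot = DoubleWell1D(height=barrier_kT * kT, half_separation=1.0)
    cmd = run_langevin(pot, cmd_steps, dt, friction, temperature, seed=seed, x0=[-1.0])
    params = estimate_parameters(cmd.potential, sigma0=sigma0)
    boosted = run_langevin(
        pot, steps, dt, friction, temperature, seed=seed + 1, boost=params, x0=[-1.0]
    )
    unboosted = run_langevin(pot, steps, dt, friction, temperature, seed=seed + 1, x0=[-1.0])
    pmf = reweight_cumulant(boosted, order=2, bins=bins)
    barrier = estimate_barrier(pmf)
    return {
        "potential": pot,
        "params": params,
        "boosted": boosted,
        "unboosted": unboosted,
        "pmf": pmf,
        "barrier_estimate": barrier,
        "barrier_analytic": pot.barrier_height(),
        "crossings_boosted": count_barrier_crossings(boosted.positions),
        "crossings_unboosted": count_barrier_crossings(unboosted.positions),
    }


def estimate_barrier(pmf: ReweightedPMF, center_halfwidth: float = 0.25) -> float:
    """Barrier = PMF maximum near the origin minus the global PMF minimum."""
    near0 = pmf.valid & (np.abs(pmf.bin_centers) <= center_halfwidth)
    if not near0.any():
        raise DegenerateInputError("no valid bins near the barrier top")
    return float(np.nanmax(pmf.pmf[near0]) - np.nanmin(pmf.pmf[pmf.valid]))
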