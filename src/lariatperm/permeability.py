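"""Two-solvent permeability prediction for cyclic peptides.

The method converts each solvent's conformational ensemble into a free
energy profile and pushes it through an inhomogeneous solubility-diffusion
resistivity integral:

1.  Per-frame RMSD to a common reference structure (Kabsch superposition)
    collapses each ensemble onto a 1-D conformational coordinate.
2.  K-means clustering of the RMSD series gives cluster populations p_i;
    Boltzmann inversion W_i = -k_B T ln p_i turns them into free energies.
3.  The two solvents' cluster free energies are placed on a composite
    conformational coordinate z in [z_aq, z_oct] (aqueous half, octanol
    half) and interpolated into a potential of mean force W(z).
4.  The Stokes-Einstein relation D = k_B T / (6 pi eta R_o), with R_o the
    radius of the smallest sphere enclosing the average conformation,
    gives a per-solvent diffusion coefficient.
5.  The resistivity R = \int exp(W(z)/k_B T) / D(z) dz accumulates over
    the composite coordinate; permeability P = 1/R and the prediction is
    log10 P.

The z coordinate is an interpretation: the integral's boundaries stand
for the peptide's conformation in each solvent, so z spans a fixed length
(default 40 Å) split equally between an aqueous and an octanol segment,
with each solvent's sorted cluster centers placed proportionally on its
segment.  D(z) is piecewise constant per segment by default; an explicit
profile may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .ensemble_model import KB_KCAL, KB_SI, ConformationalEnsemble, select_atoms
from .descriptors import iterative_mean_structure, kabsch_rotation

ANGSTROM_TO_CM = 1.0e-8


class GeometryError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# RMSD to reference
# ---------------------------------------------------------------------------


def rmsd_to_reference(
    ensemble: ConformationalEnsemble,
    reference: np.ndarray,
    subset: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-frame optimal-superposition RMSD (Å) over an atom subset."""
    X = ensemble.coordinates
    if subset is not None:
        subset = sorted(subset)
        X = X[:, subset]
        ref = np.asarray(reference, dtype=float)
        ref = ref[subset] if ref.shape[0] == ensemble.n_atoms else ref
    else:
        ref = np.asarray(reference, dtype=float)
    if X.shape[1] < 3:
        raise GeometryError("RMSD subset must contain at least 3 atoms")
    if ref.shape != X.shape[1:]:
        raise GeometryError("reference does not match the selected subset")
    refc = ref - ref.mean(axis=0)
    out = np.empty(X.shape[0])
    for f in range(X.shape[0]):
        P = X[f] - X[f].mean(axis=0)
        R = kabsch_rotation(P, refc)
        out[f] = np.sqrt(np.mean(np.sum((P @ R.T - refc) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# K-means clustering of the RMSD coordinate
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray  # sorted ascending, Å
    populations: np.ndarray  # fractions, sum 1
    assignments: np.ndarray  # (F,) labels into the sorted centers

    def __post_init__(self):
        if abs(self.populations.sum() - 1.0) > 1e-12:
            raise ValueError("populations must sum to 1")
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("centers must be sorted ascending")

    @property
    def n_frames(self) -> int:
        return len(self.assignments)


def fit_clusters(
    rmsd_series: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 20,
    frame_weights: Optional[np.ndarray] = None,
) -> ClusterModel:
    """Seeded 1-D k-means++ (best of ``n_init`` restarts by inertia);
    populations are (weighted) assignment fractions."""
    from sklearn.cluster import KMeans

    x = np.asarray(rmsd_series, dtype=float).reshape(-1, 1)
    F = x.shape[0]
    if F < k:
        raise DegenerateInputError(f"{F} frames cannot support k={k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = centers[order]
    if frame_weights is None:
        w = np.full(F, 1.0 / F)
    else:
        w = np.asarray(frame_weights, dtype=float)
        w = w / w.sum()
    pops = np.array([w[labels == j].sum() for j in range(k)])
    pops = pops / pops.sum()
    return ClusterModel(k, centers, pops, labels)


# ---------------------------------------------------------------------------
# PMF over the composite conformational coordinate
# ---------------------------------------------------------------------------


@dataclass
class PMFProfile:
    z: np.ndarray  # Å, uniform grid from z_aq (0) to z_oct (span)
    W: np.ndarray  # kcal/mol, min shifted to 0
    segment: np.ndarray  # "water"/"octanol" label per grid point
    span: float
    floored_clusters: int = 0  # clusters whose population hit the floor

    def __post_init__(self):
        if not np.all(np.isfinite(self.W)):
            raise ValueError("PMF must be finite everywhere")


def _segment_knots(model: ClusterModel, z0: float, z1: float, T: float, p_min: float):
    """Free-energy knots for one solvent segment: sorted cluster centers
    mapped proportionally onto [z0, z1]."""
    c = model.centers
    if c.max() - c.min() > 1e-12:
        u = (c - c.min()) / (c.max() - c.min())
    else:
        u = np.full(len(c), 0.5)
    p = np.maximum(model.populations, p_min)
    n_floored = int(np.sum(model.populations < p_min))
    W = -KB_KCAL * T * np.log(p)
    return z0 + u * (z1 - z0), W, n_floored


def pmf_from_populations(
    model_water: ClusterModel,
    model_octanol: ClusterModel,
    T: float = 310.0,
    span: float = 40.0,
    n_grid: int = 1001,
    interface_fraction: float = 0.1,
) -> PMFProfile:
    """Composite PMF from per-solvent cluster populations.

    W_i = -k_B T ln p_i per cluster (populations floored at 1/(10 F) so an
    empty cluster stays finite); water clusters occupy the inner part of
    [0, span/2] and octanol of [span/2, span], with ``interface_fraction``
    of the span kept knot-free around the midpoint so the linearly
    interpolated profile stays continuous across the solvent change;
    global minimum shifted to zero.
    """
    if model_water.populations.sum() <= 0 or model_octanol.populations.sum() <= 0:
        raise DegenerateInputError("all cluster populations are zero")
    mid = span / 2.0
    gap = 0.5 * interface_fraction * span
    pw = 1.0 / (10.0 * max(model_water.n_frames, 1))
    po = 1.0 / (10.0 * max(model_octanol.n_frames, 1))
    zw, Ww, fw = _segment_knots(model_water, 0.0, mid - gap, T, pw)
    zo, Wo, fo = _segment_knots(model_octanol, mid + gap, span, T, po)
    zk = np.concatenate([zw, zo])
    Wk = np.concatenate([Ww, Wo])
    order = np.argsort(zk, kind="stable")
    zk, Wk = zk[order], Wk[order]
    z = np.linspace(0.0, span, n_grid)
    W = np.interp(z, zk, Wk)
    W = W - W.min()
    segment = np.where(z < mid, "water", "octanol")
    return PMFProfile(z, W, segment, span, fw + fo)


# ---------------------------------------------------------------------------
# Minimal enclosing sphere (Welzl, exact)
# ---------------------------------------------------------------------------


def _circumsphere(support: list[np.ndarray]) -> Optional[tuple[np.ndarray, float]]:
    """Smallest sphere with all support points on its boundary (1-4 points);
    None when the points are degenerate (handled by the caller falling back
    to a smaller support)."""
    n = len(support)
    if n == 0:
        return np.zeros(3), 0.0
    if n == 1:
        return support[0].copy(), 0.0
    p0 = support[0]
    A = np.array([2.0 * (p - p0) for p in support[1:]])
    b = np.array([p @ p - p0 @ p0 for p in support[1:]])
    # minimum-norm solution restricted to the affine hull of the support
    try:
        AAt = A @ A.T
        lam = np.linalg.solve(AAt, b - A @ p0)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(lam)):
        return None
    c = p0 + A.T @ lam
    r = float(np.linalg.norm(c - p0))
    return c, r


def _in_sphere(p: np.ndarray, ball, tol: float = 1e-9) -> bool:
    c, r = ball
    return np.linalg.norm(p - c) <= r + tol


def _welzl(points: list[np.ndarray], boundary: list[np.ndarray]):
    if not points or len(boundary) == 4:
        ball = _circumsphere(boundary)
        if ball is None:
            ball = _circumsphere(boundary[:-1]) or (np.zeros(3), 0.0)
        return ball
    p = points[-1]
    ball = _welzl(points[:-1], boundary)
    if ball is not None and _in_sphere(p, ball):
        return ball
    return _welzl(points[:-1], boundary + [p])


def min_enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing sphere of a 3-D point cloud (Welzl)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise GeometryError("need at least one point")
    # deterministic shuffle: Welzl expects random order for O(n) behaviour
    rng = np.random.default_rng(0)
    order = rng.permutation(pts.shape[0])
    plist = [pts[i] for i in order]
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(plist) + 100))
    try:
        c, r = _welzl(plist, [])
    finally:
        sys.setrecursionlimit(old)
    # polish: the true radius is the max distance to the computed center
    r = float(np.max(np.linalg.norm(pts - c, axis=1)))
    return c, r


# ---------------------------------------------------------------------------
# Stokes-Einstein diffusion and the resistivity integral
# ---------------------------------------------------------------------------


def stokes_einstein(T: float, eta: float, R_o_angstrom: float) -> float:
    """D = k_B T / (6 pi eta R_o) in cm^2/s (T in K, eta in Pa s, R_o in Å)."""
    if T <= 0 or eta <= 0 or R_o_angstrom <= 0:
        raise ValueError("T, eta and R_o must all be positive")
    D_m2_s = KB_SI * T / (6.0 * np.pi * eta * R_o_angstrom * 1.0e-10)
    return D_m2_s * 1.0e4


@dataclass
class PermeabilityResult:
    R_o: float  # Å
    D_water: float  # cm^2/s
    D_octanol: float  # cm^2/s
    resistivity: float  # s/cm
    permeability: float  # cm/s
    logP_calc: float
    overflow_flag: bool = False
    max_W: float = 0.0

    def to_dict(self) -> dict:
        return {
            "R_o_angstrom": self.R_o,
            "D_water_cm2_s": self.D_water,
            "D_octanol_cm2_s": self.D_octanol,
            "resistivity_s_cm": self.resistivity,
            "permeability_cm_s": self.permeability,
            "logP_calc": self.logP_calc,
            "overflow_flag": self.overflow_flag,
            "max_W_kcal_mol": self.max_W,
        }


def _trapezoid_resistivity(W: np.ndarray, z_cm: np.ndarray, D: np.ndarray, beta: float):
    """Composite trapezoid of exp(beta W)/D, evaluated in log space when
    beta*W risks overflow."""
    bW = beta * W
    if bW.max() < 500.0:
        return float(np.trapezoid(np.exp(bW) / D, z_cm)), False
    # log-sum-exp form: R = sum_i w_i exp(bW_i)/D_i with trapezoid weights
    from scipy.special import logsumexp

    h = np.diff(z_cm)
    wts = np.zeros_like(z_cm)
    wts[:-1] += 0.5 * h
    wts[1:] += 0.5 * h
    logR = logsumexp(bW + np.log(wts) - np.log(D))
    return float(np.exp(logR)), True


def resistivity_integral(
    pmf: PMFProfile,
    D_water: float,
    D_octanol: float,
    T: float = 310.0,
    R_o: float = float("nan"),
    D_profile: Optional[np.ndarray] = None,
) -> PermeabilityResult:
    """R = \int exp(W(z)/k_B T)/D(z) dz over the composite coordinate;
    P = 1/R, prediction logP_calc = log10 P.

    D(z) defaults to piecewise-constant per solvent segment (integrated
    segment-by-segment so a flat PMF recovers R = L1/D1 + L2/D2 exactly);
    an explicit per-grid-point ``D_profile`` (cm^2/s) overrides it.
    """
    if D_water <= 0 or D_octanol <= 0:
        raise ValueError("diffusion coefficients must be positive")
    dz = np.diff(pmf.z)
    if dz.size and not np.allclose(dz, dz[0], rtol=1e-9):
        raise ValueError("PMF grid must be uniform")
    beta = 1.0 / (KB_KCAL * T)
    z_cm = pmf.z * ANGSTROM_TO_CM
    overflow = False
    if D_profile is not None:
        D = np.asarray(D_profile, dtype=float)
        R, overflow = _trapezoid_resistivity(pmf.W, z_cm, D, beta)
    else:
        water = pmf.segment == "water"
        octanol = ~water
        # include the boundary point in both halves so the two trapezoids
        # tile [0, span] exactly
        iw = np.where(water)[0]
        io = np.where(octanol)[0]
        if iw.size and io.size:
            iw = np.append(iw, io[0])
        R = 0.0
        for idx, D in ((iw, D_water), (io, D_octanol)):
            if idx.size >= 2:
                part, ov = _trapezoid_resistivity(
                    pmf.W[idx], z_cm[idx], np.full(idx.size, D), beta
                )
                R += part
                overflow = overflow or ov
    P = 1.0 / R
    return PermeabilityResult(
        R_o=R_o,
        D_water=D_water,
        D_octanol=D_octanol,
        resistivity=R,
        permeability=P,
        logP_calc=float(np.log10(P)),
        overflow_flag=overflow,
        max_W=float(pmf.W.max()),
    )


# ---------------------------------------------------------------------------
# Full two-solvent pipeline
# ---------------------------------------------------------------------------


def permeability_from_ensembles(
    water: ConformationalEnsemble,
    octanol: ConformationalEnsemble,
    k: int = 5,
    seed: int = 0,
    n_init: int = 20,
    span: float = 40.0,
    n_grid: int = 1001,
    rmsd_selector: str = "backbone_heavy",
    T: Optional[float] = None,
    reference: str | np.ndarray = "water_start",
) -> tuple[PermeabilityResult, PMFProfile, ClusterModel, ClusterModel]:
    """End-to-end permeability prediction from a two-solvent ensemble pair.

    Both solvents' RMSD series are measured against one common reference so
    the two cluster models live on one scale.  The default reference is the
    water ensemble's first frame (the analogue of a minimized starting
    structure): RMSD to the *average* of a multi-cluster ensemble
    degenerates, because distinct conformers can sit equidistant from their
    mean.  ``reference`` may also be ``"pooled_mean"`` (two-pass
    iteratively superposed mean of both ensembles) or an explicit
    (n_subset, 3) array.
    """
    top = water.topology
    T = T if T is not None else water.solvent.temperature
    subset = select_atoms(top, rmsd_selector)
    if isinstance(reference, str):
        if reference == "water_start":
            ref_sub = water.coordinates[0, subset]
        elif reference == "pooled_mean":
            pooled = np.concatenate(
                [water.coordinates[:, subset], octanol.coordinates[:, subset]]
            )
            ref_sub, _ = iterative_mean_structure(pooled)
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref_sub = np.asarray(reference, dtype=float)
    rmsd_w = _rmsd_series(water.coordinates[:, subset], ref_sub)
    rmsd_o = _rmsd_series(octanol.coordinates[:, subset], ref_sub)
    model_w = fit_clusters(rmsd_w, k=k, seed=seed, n_init=n_init, frame_weights=water.frame_weights)
    model_o = fit_clusters(rmsd_o, k=k, seed=seed, n_init=n_init, frame_weights=octanol.frame_weights)
    pmf = pmf_from_populations(model_w, model_o, T=T, span=span, n_grid=n_grid)
    # R_o from the pooled mean over ALL atoms (average conformation)
    pooled_all = np.concatenate([water.coordinates, octanol.coordinates])
    mean_all, _ = iterative_mean_structure(pooled_all)
    _c, R_o = min_enclosing_sphere(mean_all)
    D_w = stokes_einstein(T, water.solvent.viscosity, R_o)
    D_o = stokes_einstein(T, octanol.solvent.viscosity, R_o)
    result = resistivity_integral(pmf, D_w, D_o, T=T, R_o=R_o)
    return result, pmf, model_w, model_o


def _rmsd_series(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    refc = ref - ref.mean(axis=0)
    out = np.empty(X.shape[0])
    for f in range(X.shape[0]):
        P = X[f] - X[f].mean(axis=0)
        R = kabsch_rotation(P, refc)
        out[f] = np.sqrt(np.mean(np.sum((P @ R.T - refc) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Library-level aggregation and experimental comparison
# ---------------------------------------------------------------------------


def aggregate_by_group(
    results: Mapping[str, float],
    grouping: Mapping[str, int],
    drop_outliers: int = 2,
):
    """Group summaries of logP_calc with the two-farthest-outliers rule.

    Per group, the ``drop_outliers`` values farthest from the group median
    are removed (only when the group has more than drop_outliers + 2
    members), then mean, quartiles, min, max and n are reported.
    """
    import pandas as pd

    rows = []
    groups: dict[int, list[float]] = {}
    for pid, v in results.items():
        if pid in grouping:
            groups.setdefault(grouping[pid], []).append(float(v))
    for g in sorted(groups):
        vals = np.array(groups[g], dtype=float)
        n_raw = len(vals)
        if drop_outliers > 0 and n_raw > drop_outliers + 2:
            med = np.median(vals)
            dist = np.abs(vals - med)
            # stable tie-break: farthest first, then larger value first
            order = np.lexsort((-vals, -dist))
            keep = np.ones(n_raw, dtype=bool)
            keep[order[:drop_outliers]] = False
            vals = vals[keep]
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "n_raw": n_raw,
                "mean": vals.mean(),
                "q1": np.percentile(vals, 25),
                "median": np.median(vals),
                "q3": np.percentile(vals, 75),
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows)


def correlate_with_experiment(
    logp_calc: Mapping[str, float], logp_app: Mapping[str, float]
):
    """Pearson r and R^2 between predicted and experimental log P over the
    intersection of peptide ids; unmatched ids are reported, not dropped
    silently."""
    import pandas as pd
    from scipy import stats

    common = sorted(set(logp_calc) & set(logp_app))
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} paired ids; need at least 3 for a correlation"
        )
    x = np.array([logp_calc[i] for i in common])
    y = np.array([logp_app[i] for i in common])
    r = float(stats.pearsonr(x, y).statistic)
    table = pd.DataFrame({"peptide_id": common, "logP_calc": x, "logP_app": y})
    unmatched = sorted((set(logp_calc) | set(logp_app)) - set(common))
    return r, r * r, table, unmatched
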