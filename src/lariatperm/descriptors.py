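"""Conformational descriptors: omega torsions, hydrogen bonds, SASA, PCA.

These are the observables used to interpret two-solvent permeability
predictions for cyclic peptides: cis/trans populations of the backbone
omega dihedral (N-methylation shifts the cis fraction), intramolecular
NH···O=C hydrogen-bond occupancies (octanol promotes them), solvent
accessible surface area, and principal component analysis of either
heavy-atom Cartesian coordinates (after iterative superposition) or
backbone dihedrals embedded as (sin, cos) pairs (rotation-invariant by
construction).  A Bhattacharyya overlap of the two solvents' (PC1, PC2)
densities quantifies how conformationally distinct a peptide is between
water and octanol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble_model import (
    KB_KCAL,
    ConformationalEnsemble,
    PeptideTopology,
    TopologyError,
    select_atoms,
)


class InsufficientSamplingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees, in (-180, 180]) for stacked points (..., 3)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # wrap to (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q (Kabsch)."""
    H = P.T @ Q
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid superposition of one frame onto a target (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    R = kabsch_rotation(mc, tc)
    return mc @ R.T + target.mean(axis=0)


def iterative_mean_structure(
    coords: np.ndarray, n_iter: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass iterative superposition to the mean structure.

    Returns (mean structure, aligned coordinates); pass 0 aligns to the
    first frame, subsequent passes to the running mean.
    """
    coords = np.asarray(coords, dtype=float)
    ref = coords[0]
    aligned = coords
    for _ in range(n_iter):
        aligned = np.stack([superpose(f, ref) for f in coords])
        ref = aligned.mean(axis=0)
    return ref, aligned


# ---------------------------------------------------------------------------
# Omega dihedrals and cis/trans
# ---------------------------------------------------------------------------


@dataclass
class OmegaProfile:
    """Per-linkage omega samples; linkage i is the peptide bond residue i ->
    i+1.  The macrocycle-closing linkage through the depsipeptide ester has
    no amide nitrogen, so its omega is reported in ``excluded_positions``
    rather than measured."""

    omega: np.ndarray  # (F, L) degrees
    linkage_labels: list[str]
    excluded_positions: frozenset[int]


def compute_omega(
    ensemble: ConformationalEnsemble, topology: Optional[PeptideTopology] = None
) -> OmegaProfile:
    """Omega = CA(i)-C(i)-N(i+1)-CA(i+1) for every chain peptide bond."""
    top = topology or ensemble.topology
    X = ensemble.coordinates
    cols = []
    labels = []
    for i in range(top.n_residues - 1):
        ids = [
            top.find_atom(i, "CA"),
            top.find_atom(i, "C"),
            top.find_atom(i + 1, "N"),
            top.find_atom(i + 1, "CA"),
        ]
        cols.append(dihedral_angles(X[:, ids[0]], X[:, ids[1]], X[:, ids[2]], X[:, ids[3]]))
        labels.append(f"{top.residues[i].name}{i}-{top.residues[i + 1].name}{i + 1}")
    omega = np.stack(cols, axis=1) if cols else np.empty((ensemble.n_frames, 0))
    # the ester closure (last macrocycle residue C -> sidechain O) interrupts
    # the final omega: no N, not measurable
    excluded = frozenset({top.n_residues - 1})
    return OmegaProfile(omega, labels, excluded)


def classify_cis_trans(profile: OmegaProfile, cutoff_deg: float = 90.0) -> np.ndarray:
    """Per-linkage cis fraction: a frame is cis iff |omega| < cutoff."""
    if profile.omega.size == 0:
        raise ValueError("empty omega profile")
    return (np.abs(profile.omega) < cutoff_deg).mean(axis=0)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondMap:
    donors: list[tuple[int, str]]  # (residue index, donor label "N-H")
    acceptors: list[tuple[int, str]]  # (residue index, acceptor label "C=O")
    occupancy: np.ndarray  # (n_donors, n_acceptors) fractions


def _amide_hydrogen_positions(X, top, res_idx):
    """Ideal amide H for residue res_idx in every frame: 1.01 Å from N along
    the outward bisector of the two heavy-atom substituents."""
    n_id = top.find_atom(res_idx, "N")
    ca_id = top.find_atom(res_idx, "CA")
    n = X[:, n_id]
    u = n - X[:, ca_id]
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    if res_idx > 0:
        c_prev = top.find_atom(res_idx - 1, "C", required=False)
    else:
        c_prev = None
    if c_prev is not None:
        v = n - X[:, c_prev]
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        u = u + v
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
    return n + 1.01 * u


def detect_hbonds(
    ensemble: ConformationalEnsemble,
    topology: Optional[PeptideTopology] = None,
    d_cut: float = 3.5,
    angle_cut_deg: float = 30.0,
    rebuild_hydrogens: bool = True,
) -> HBondMap:
    """Intramolecular NH···O=C occupancies.

    A donor-acceptor pair is bonded in a frame iff the N···O distance is
    <= ``d_cut`` Å and the N-H···O deviation from linearity is
    <= ``angle_cut_deg``.  N-methylated residues contribute no donor row
    (their amide nitrogen has no H); i -> i self pairs are excluded.
    Hydrogens absent from the topology are rebuilt at ideal amide geometry
    when ``rebuild_hydrogens`` is on.
    """
    top = topology or ensemble.topology
    X = ensemble.coordinates
    donors = []
    h_pos = {}
    for r in range(top.n_residues):
        if top.residues[r].n_methylated:
            continue
        n_id = top.find_atom(r, "N", required=False)
        if n_id is None:
            continue
        h_id = top.find_atom(r, "H", required=False)
        if h_id is None:
            if not rebuild_hydrogens:
                raise TopologyError(
                    f"residue {r} has no amide H and hydrogen rebuilding is disabled"
                )
            h_pos[r] = _amide_hydrogen_positions(X, top, r)
        else:
            h_pos[r] = X[:, h_id]
        donors.append((r, "N-H"))
    acceptors = []
    for r in range(top.n_residues):
        if top.find_atom(r, "C", required=False) is not None and (
            top.find_atom(r, "O", required=False) is not None
        ):
            acceptors.append((r, "C=O"))
    F = ensemble.n_frames
    occ = np.zeros((len(donors), len(acceptors)))
    for di, (rd, _) in enumerate(donors):
        n = X[:, top.find_atom(rd, "N")]
        h = h_pos[rd]
        for ai, (ra, _) in enumerate(acceptors):
            if ra == rd:
                continue
            o = X[:, top.find_atom(ra, "O")]
            dist = np.linalg.norm(n - o, axis=-1)
            hn = n - h
            ho = o - h
            cosang = np.sum(hn * ho, axis=-1) / (
                np.linalg.norm(hn, axis=-1) * np.linalg.norm(ho, axis=-1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            bonded = (dist <= d_cut) & (180.0 - ang <= angle_cut_deg)
            occ[di, ai] = bonded.mean()
    return HBondMap(donors, acceptors, occ)


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------


@dataclass
class SASAProfile:
    per_frame_total: np.ndarray  # (F,) Å^2 over the chosen subset
    per_atom: np.ndarray  # (F, n_subset) Å^2
    subset: list[int]
    probe_radius: float
    n_sphere_points: int


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def compute_sasa(
    ensemble: ConformationalEnsemble,
    topology: Optional[PeptideTopology] = None,
    subset: Optional[Sequence[int]] = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SASAProfile:
    """Shrake–Rupley SASA of a subset, with every peptide atom occluding.

    Each subset atom gets ``n_sphere_points`` test points on its
    solvent-augmented sphere (r_vdw + probe); the accessible fraction
    times the sphere area is its SASA, summed per frame.
    """
    top = topology or ensemble.topology
    if subset is None:
        subset = select_atoms(top, "all")
    subset = sorted(subset)
    radii = top.radii()
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need positive vdW radii for SASA")
    aug = radii + probe_radius
    sph = _sphere_points(n_sphere_points)
    X = ensemble.coordinates
    F = ensemble.n_frames
    per_atom = np.zeros((F, len(subset)))
    for f in range(F):
        pos = X[f]
        for si, i in enumerate(subset):
            pts = pos[i] + aug[i] * sph  # (n_points, 3)
            # neighbors whose augmented sphere can reach atom i's surface
            d_atoms = np.linalg.norm(pos - pos[i], axis=1)
            nbr = np.where((d_atoms < aug + aug[i]) & (np.arange(len(pos)) != i))[0]
            if nbr.size:
                d2 = np.sum(
                    (pts[:, None, :] - pos[nbr][None, :, :]) ** 2, axis=2
                )
                buried = (d2 <= (aug[nbr] ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
            per_atom[f, si] = frac * 4.0 * np.pi * aug[i] ** 2
    return SASAProfile(per_atom.sum(axis=1), per_atom, list(subset), probe_radius, n_sphere_points)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    mode: str  # "cartesian_heavy" or "dihedral"
    projections: np.ndarray  # (F, C)
    components: np.ndarray  # (C, n_features)
    variance_fractions: np.ndarray  # descending
    mean: np.ndarray


def backbone_dihedral_features(
    ensemble: ConformationalEnsemble, topology: Optional[PeptideTopology] = None
) -> np.ndarray:
    """All consecutive backbone torsions (phi/psi/omega along the chain),
    each embedded as (sin, cos) so the features are rotation-invariant and
    free of angular wrap-around."""
    top = topology or ensemble.topology
    chain = []
    for r in range(top.n_residues):
        for name in ("N", "CA", "C"):
            chain.append(top.find_atom(r, name))
    X = ensemble.coordinates
    angles = []
    for a in range(len(chain) - 3):
        ids = chain[a : a + 4]
        angles.append(
            np.radians(dihedral_angles(X[:, ids[0]], X[:, ids[1]], X[:, ids[2]], X[:, ids[3]]))
        )
    th = np.stack(angles, axis=1)
    return np.concatenate([np.sin(th), np.cos(th)], axis=1)


def _pca_on_features(feats: np.ndarray, mode: str, n_components: Optional[int]) -> PCAResult:
    F = feats.shape[0]
    mean = feats.mean(axis=0)
    Xc = feats - mean
    cov = (Xc.T @ Xc) / (F - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    nc = n_components or min(F - 1, feats.shape[1])
    comps = evecs[:, :nc].T.copy()
    # deterministic sign: make the largest-|loading| entry positive
    for c in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[c])))
        if comps[c, j] < 0:
            comps[c] *= -1.0
    proj = Xc @ comps.T
    var_frac = evals[:nc] / total if total > 0 else np.zeros(nc)
    return PCAResult(mode, proj, comps, var_frac, mean)


def pca(
    ensemble: ConformationalEnsemble,
    topology: Optional[PeptideTopology] = None,
    mode: str = "dihedral",
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of the conformational ensemble.

    ``cartesian_heavy`` operates on heavy-atom coordinates after two-pass
    iterative superposition to the mean structure; ``dihedral`` on sin/cos
    embedded backbone torsions (no superposition needed).
    """
    top = topology or ensemble.topology
    if ensemble.n_frames <= 2:
        raise InsufficientSamplingError("PCA needs more than 2 frames")
    if mode == "cartesian_heavy":
        heavy = select_atoms(top, "all_heavy")
        _, aligned = iterative_mean_structure(ensemble.coordinates[:, heavy])
        feats = aligned.reshape(ensemble.n_frames, -1)
    elif mode == "dihedral":
        feats = backbone_dihedral_features(ensemble, top)
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")
    return _pca_on_features(feats, mode, n_components)


def project_onto(result: PCAResult, feats: np.ndarray) -> np.ndarray:
    return (feats - result.mean) @ result.components.T


# ---------------------------------------------------------------------------
# Solvent distinctness
# ---------------------------------------------------------------------------


def bhattacharyya_overlap(
    proj_a: np.ndarray, proj_b: np.ndarray, bins: int = 25
) -> float:
    """Bhattacharyya coefficient of two 2D point clouds on a shared grid
    spanning the pooled range: 1 identical distributions, 0 disjoint."""
    a = np.asarray(proj_a)[:, :2]
    b = np.asarray(proj_b)[:, :2]
    pooled = np.vstack([a, b])
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    hi = lo + span
    edges = [np.linspace(lo[d], hi[d], bins + 1) for d in range(2)]
    ha, _, _ = np.histogram2d(a[:, 0], a[:, 1], bins=edges)
    hb, _, _ = np.histogram2d(b[:, 0], b[:, 1], bins=edges)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(np.sqrt(pa * pb).sum())


def solvent_overlap_score(
    ensemble_water: ConformationalEnsemble,
    ensemble_octanol: ConformationalEnsemble,
    topology: Optional[PeptideTopology] = None,
    mode: str = "dihedral",
    bins: int = 25,
) -> float:
    """Overlap of the two solvents' (PC1, PC2) densities in a common basis
    fitted on the pooled frames.  Scores below ~0.5 mark peptides whose
    conformational ensembles differ between water and octanol."""
    top = topology or ensemble_water.topology
    if mode == "dihedral":
        fa = backbone_dihedral_features(ensemble_water, top)
        fb = backbone_dihedral_features(ensemble_octanol, top)
        pooled = np.vstack([fa, fb])
        res = _pca_on_features(pooled, mode, n_components=2)
        pa = project_onto(res, fa)
        pb = project_onto(res, fb)
    elif mode == "cartesian_heavy":
        heavy = select_atoms(top, "all_heavy")
        both = np.concatenate(
            [ensemble_water.coordinates[:, heavy], ensemble_octanol.coordinates[:, heavy]]
        )
        _, aligned = iterative_mean_structure(both)
        feats = aligned.reshape(both.shape[0], -1)
        res = _pca_on_features(feats, mode, n_components=2)
        na = ensemble_water.n_frames
        pa = res.projections[:na]
        pb = res.projections[na:]
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")
    return bhattacharyya_overlap(pa, pb, bins=bins)
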