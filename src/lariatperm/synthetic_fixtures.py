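"""Synthetic lariat-peptide topologies and two-solvent ensembles with
planted, known statistical structure.

Every stage of the pipeline gets a ground-truth oracle without any MD:
ensembles are drawn from weighted template-conformer mixtures (known
cluster weights), backbone omega torsions are set cis with planted
per-linkage probabilities, ideal NH···O=C hydrogen-bond geometries are
imposed in a planted fraction of frames, and the end-to-end log P_calc of
a benchmark pair is pre-computed by an independent fine-grid quadrature
of the diffusion/resistivity formulas.

Template conformers are built from ideal internal coordinates (bond
lengths 1.33/1.46/1.52 Å, angles 110-123°), not from a force field; they
are geometrically sane but deliberately non-physical.  Jitter is
isotropic Gaussian per atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .ensemble_model import (
    DEFAULT_VDW_RADII,
    Atom,
    ConformationalEnsemble,
    PeptideTopology,
    Residue,
    SolventSpec,
    octanol_spec,
    select_atoms,
    water_spec,
)


class FixtureSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------


@dataclass
class TemplateDef:
    """Ideal backbone torsions of one template conformer (degrees)."""

    phi: float
    psi: float
    omega: float = 180.0


@dataclass
class ClusterDef:
    template: str
    weight: float
    jitter: float = 0.08  # Å, isotropic Gaussian per atom


@dataclass
class FixtureSpec:
    """Recipe for one synthetic lariat peptide and its two-solvent ensembles.

    ``planted_cis`` maps a chain linkage index l (the peptide bond between
    residues l and l+1, i.e. omega column l) to the fraction of frames
    generated cis at that linkage.  ``planted_hbonds`` maps a (donor
    residue, acceptor residue) pair to a target occupancy; in that
    fraction of frames the acceptor carbonyl O is moved onto the donor's
    N-H axis at 2.9 Å.
    """

    name: str = "peptide"
    n_macrocycle: int = 7
    n_tail: int = 2
    methylation: tuple[int, ...] = ()
    d_residues: tuple[int, ...] = ()
    templates: dict[str, TemplateDef] = field(
        default_factory=lambda: {
            "extended": TemplateDef(phi=-120.0, psi=140.0),
            "compact": TemplateDef(phi=-60.0, psi=-45.0),
        }
    )
    clusters: dict[str, list[ClusterDef]] = field(
        default_factory=lambda: {
            "water": [ClusterDef("extended", 0.7), ClusterDef("compact", 0.3)],
            "octanol": [ClusterDef("extended", 0.3), ClusterDef("compact", 0.7)],
        }
    )
    planted_cis: dict[int, float] = field(default_factory=dict)
    planted_hbonds: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return self.n_macrocycle + self.n_tail

    def __post_init__(self):
        if self.n_residues < 4:
            raise FixtureSpecError("need at least 4 residues")
        if self.n_tail < 1:
            raise FixtureSpecError("a lariat needs at least one tail residue")
        for pos in self.methylation:
            if not 0 <= pos < self.n_residues:
                raise FixtureSpecError(f"methylation position {pos} out of range")
        for pos in self.d_residues:
            if not 0 <= pos < self.n_residues:
                raise FixtureSpecError(f"D-residue position {pos} out of range")
        for solvent, defs in self.clusters.items():
            w = sum(c.weight for c in defs)
            if abs(w - 1.0) > 1e-9:
                raise FixtureSpecError(f"{solvent} cluster weights sum to {w}, not 1")
            for c in defs:
                if c.jitter <= 0:
                    raise FixtureSpecError("jitter sigma must be > 0")
                if c.template not in self.templates:
                    raise FixtureSpecError(f"unknown template {c.template!r}")
        for l, frac in self.planted_cis.items():
            if not 0 <= l < self.n_residues - 1:
                raise FixtureSpecError(f"cis linkage index {l} out of range")
            if not 0.0 <= frac <= 1.0:
                raise FixtureSpecError("cis fraction must be in [0, 1]")
        for (dres, ares), occ in self.planted_hbonds.items():
            if dres == ares:
                raise FixtureSpecError("donor and acceptor residues must differ")
            if dres in self.methylation:
                raise FixtureSpecError(f"residue {dres} is N-methylated: no donor H")
            if not 0.0 <= occ <= 1.0:
                raise FixtureSpecError("occupancy target must be in [0, 1]")

    # -- YAML ---------------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "n_macrocycle": self.n_macrocycle,
            "n_tail": self.n_tail,
            "methylation": list(self.methylation),
            "d_residues": list(self.d_residues),
            "templates": {
                k: {"phi": t.phi, "psi": t.psi, "omega": t.omega}
                for k, t in self.templates.items()
            },
            "clusters": {
                s: [{"template": c.template, "weight": c.weight, "jitter": c.jitter} for c in defs]
                for s, defs in self.clusters.items()
            },
            "planted_cis": {int(k): float(v) for k, v in self.planted_cis.items()},
            "planted_hbonds": {f"{d},{a}": float(v) for (d, a), v in self.planted_hbonds.items()},
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            name=doc.get("name", "peptide"),
            n_macrocycle=doc.get("n_macrocycle", 7),
            n_tail=doc.get("n_tail", 2),
            methylation=tuple(doc.get("methylation", [])),
            d_residues=tuple(doc.get("d_residues", [])),
            templates={
                k: TemplateDef(t["phi"], t["psi"], t.get("omega", 180.0))
                for k, t in doc["templates"].items()
            },
            clusters={
                s: [ClusterDef(c["template"], c["weight"], c.get("jitter", 0.08)) for c in defs]
                for s, defs in doc["clusters"].items()
            },
            planted_cis={int(k): float(v) for k, v in doc.get("planted_cis", {}).items()},
            planted_hbonds={
                tuple(int(x) for x in k.split(",")): float(v)
                for k, v in doc.get("planted_hbonds", {}).items()
            },
            seed=int(doc.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def build_topology(spec: FixtureSpec) -> PeptideTopology:
    """Backbone-level lariat topology: N, (H | methyl C), CA, C, O per
    residue; the first macrocycle residue carries a CB-OG sidechain whose
    oxygen forms the depsi ester to the C-terminal carbonyl carbon."""
    n = spec.n_residues
    depsi_res = spec.n_tail  # first macrocycle residue (threonine-like)
    residues = []
    for i in range(n):
        if i < spec.n_tail:
            name = "ALA"
        elif i == depsi_res:
            name = "THR"
        elif i == n - 1:
            name = "PRO"
        else:
            name = "LEU"
        residues.append(
            Residue(
                name,
                "D" if i in spec.d_residues else "L",
                i in spec.methylation,
            )
        )
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    per_res_ids: list[dict[str, int]] = []

    def add(element, res_idx, name):
        atoms.append(Atom(len(atoms), element, res_idx, name, DEFAULT_VDW_RADII[element]))
        return atoms[-1].id

    for i in range(n):
        ids = {}
        ids["N"] = add("N", i, "N")
        if residues[i].n_methylated:
            ids["CN"] = add("C", i, "CN")
            bonds.append((ids["N"], ids["CN"]))
        else:
            ids["H"] = add("H", i, "H")
            bonds.append((ids["N"], ids["H"]))
        ids["CA"] = add("C", i, "CA")
        ids["C"] = add("C", i, "C")
        ids["O"] = add("O", i, "O")
        bonds += [(ids["N"], ids["CA"]), (ids["CA"], ids["C"]), (ids["C"], ids["O"])]
        if i == depsi_res:
            ids["CB"] = add("C", i, "CB")
            ids["OG"] = add("O", i, "OG")
            bonds += [(ids["CA"], ids["CB"]), (ids["CB"], ids["OG"])]
        if i > 0:
            bonds.append((per_res_ids[i - 1]["C"], ids["N"]))
        per_res_ids.append(ids)
    depsi = (per_res_ids[depsi_res]["OG"], per_res_ids[n - 1]["C"])
    bonds.append(depsi)
    return PeptideTopology(
        residues=residues,
        atoms=atoms,
        bonds=bonds,
        macrocycle_residues=frozenset(range(spec.n_tail, n)),
        tail_residues=frozenset(range(spec.n_tail)),
        depsi_linkage=depsi,
    )


# ---------------------------------------------------------------------------
# Ideal-geometry chain building (natural extension reference frame)
# ---------------------------------------------------------------------------

_BOND = {"C-N": 1.33, "N-CA": 1.46, "CA-C": 1.52, "C-O": 1.23, "N-H": 1.01,
         "N-CN": 1.45, "CA-CB": 1.53, "CB-OG": 1.42}
_ANGLE = {"CA-C-N": 116.0, "C-N-CA": 122.0, "N-CA-C": 110.0, "CA-C-O": 121.0,
          "C-N-H": 119.0, "N-CA-CB": 110.0, "CA-CB-OG": 109.0}


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d bonded to c: |cd| = bond, angle(b,c,d) = angle,
    dihedral(a,b,c,d) = torsion."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * nrm


def build_template_coords(
    spec: FixtureSpec,
    topology: PeptideTopology,
    template: TemplateDef,
    cis_linkages: frozenset[int] = frozenset(),
) -> np.ndarray:
    """Ideal-geometry coordinates for one template conformer; linkages in
    ``cis_linkages`` get omega = 0 instead of the template value."""
    n = topology.n_residues
    X = np.zeros((topology.n_atoms, 3))
    phi, psi = template.phi, template.psi

    def aid(r, name):
        return topology.find_atom(r, name)

    def setpos(r, name, pos):
        X[aid(r, name)] = pos

    # seed residue 0 in the xy-plane
    setpos(0, "N", np.zeros(3))
    setpos(0, "CA", np.array([_BOND["N-CA"], 0.0, 0.0]))
    th = np.radians(_ANGLE["N-CA-C"])
    setpos(0, "C", X[aid(0, "CA")] + _BOND["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0]))
    setpos(0, "O", _place(X[aid(0, "N")], X[aid(0, "CA")], X[aid(0, "C")],
                          _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0))
    h0 = "CN" if topology.residues[0].n_methylated else "H"
    setpos(0, h0, _place(X[aid(0, "C")], X[aid(0, "CA")], X[aid(0, "N")],
                         _BOND["N-CN"] if h0 == "CN" else _BOND["N-H"], 118.0, 180.0))
    for i in range(1, n):
        omega = 0.0 if (i - 1) in cis_linkages else template.omega
        Np = _place(X[aid(i - 1, "N")], X[aid(i - 1, "CA")], X[aid(i - 1, "C")],
                    _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        setpos(i, "N", Np)
        CAp = _place(X[aid(i - 1, "CA")], X[aid(i - 1, "C")], Np,
                     _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        setpos(i, "CA", CAp)
        Cp = _place(X[aid(i - 1, "C")], Np, CAp, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        setpos(i, "C", Cp)
        setpos(i, "O", _place(Np, CAp, Cp, _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0))
        hname = "CN" if topology.residues[i].n_methylated else "H"
        setpos(i, hname, _place(X[aid(i - 1, "CA")], X[aid(i - 1, "C")], Np,
                                _BOND["N-CN"] if hname == "CN" else _BOND["N-H"],
                                _ANGLE["C-N-H"], omega + 180.0))
        if topology.find_atom(i, "CB", required=False) is not None:
            CB = _place(X[aid(i - 1, "C")], Np, CAp, _BOND["CA-CB"], _ANGLE["N-CA-CB"],
                        phi + 120.0)
            setpos(i, "CB", CB)
            setpos(i, "OG", _place(Np, CAp, CB, _BOND["CB-OG"], _ANGLE["CA-CB-OG"], 180.0))
    return X


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

_SOLVENT_SEED_OFFSET = {"water": 0, "octanol": 1}


def _solvent_spec(name: str) -> SolventSpec:
    return water_spec() if name == "water" else octanol_spec()


def _generate(spec: FixtureSpec, solvent: str, F: int, topology: PeptideTopology):
    """Internal generator returning the ensemble plus all planted draws."""
    if solvent not in spec.clusters:
        raise FixtureSpecError(f"spec defines no clusters for solvent {solvent!r}")
    defs = spec.clusters[solvent]
    rng = np.random.default_rng(
        int(spec.seed) * 8 + _SOLVENT_SEED_OFFSET.get(solvent, 2)
    )
    cis_keys = sorted(spec.planted_cis)
    # precompute every (template, cis-state) variant once
    variants: dict[tuple[str, frozenset[int]], np.ndarray] = {}
    for tname, tdef in spec.templates.items():
        n_states = 1 << len(cis_keys)
        for mask in range(n_states):
            on = frozenset(k for b, k in enumerate(cis_keys) if mask >> b & 1)
            variants[(tname, on)] = build_template_coords(spec, topology, tdef, on)
    max_jitter = max(c.jitter for c in defs)
    if max_jitter > 0.3:
        warnings.warn(
            f"jitter sigma {max_jitter} Å may break bond-length sanity (> 0.3 Å)",
            stacklevel=3,
        )
    weights = np.array([c.weight for c in defs])
    assign = rng.choice(len(defs), size=F, p=weights)
    cis_draws = {
        k: rng.random(F) < spec.planted_cis[k] for k in cis_keys
    }
    coords = np.empty((F, topology.n_atoms, 3))
    for f in range(F):
        on = frozenset(k for k in cis_keys if cis_draws[k][f])
        cdef = defs[assign[f]]
        base = variants[(cdef.template, on)]
        coords[f] = base + rng.normal(0.0, cdef.jitter, size=base.shape)
    # impose ideal H-bond geometry in the planted fraction of frames
    hbond_masks = {}
    for (dres, ares), occ in spec.planted_hbonds.items():
        mask = rng.random(F) < occ
        hbond_masks[(dres, ares)] = mask
        n_id = topology.find_atom(dres, "N")
        h_id = topology.find_atom(dres, "H")
        o_id = topology.find_atom(ares, "O")
        nh = coords[mask, h_id] - coords[mask, n_id]
        nh /= np.linalg.norm(nh, axis=-1, keepdims=True)
        coords[mask, o_id] = coords[mask, n_id] + 2.9 * nh
    # snap to PDB precision so file round trips are exact
    coords = np.round(coords, 3)
    ens = ConformationalEnsemble(coords, topology, _solvent_spec(solvent))
    return ens, assign, cis_draws, hbond_masks


def generate_ensemble(spec: FixtureSpec, solvent: str, F: int) -> ConformationalEnsemble:
    """F frames from the solvent's weighted template mixture with Gaussian
    jitter and all planted features; fully reproducible from spec.seed."""
    topology = build_topology(spec)
    ens, *_ = _generate(spec, solvent, F, topology)
    return ens


# ---------------------------------------------------------------------------
# Independent fine-grid permeability oracle
# ---------------------------------------------------------------------------


def _oracle_mean_structure(coords: np.ndarray, n_iter: int = 2):
    """Two-pass superposed mean via scipy rotations (route independent of
    the package's own Kabsch implementation)."""
    from scipy.spatial.transform import Rotation

    ref = coords[0]
    aligned = coords
    for _ in range(n_iter):
        refc = ref - ref.mean(axis=0)
        out = []
        for f in coords:
            fc = f - f.mean(axis=0)
            rot, _ = Rotation.align_vectors(refc, fc)
            out.append(rot.apply(fc) + ref.mean(axis=0))
        aligned = np.stack(out)
        ref = aligned.mean(axis=0)
    return ref


def _oracle_rmsd(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    refc = ref - ref.mean(axis=0)
    out = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        fc = coords[f] - coords[f].mean(axis=0)
        _, rssd = Rotation.align_vectors(refc, fc)
        out[f] = rssd / np.sqrt(coords.shape[1])
    return out


def expected_logp(
    water: ConformationalEnsemble,
    octanol: ConformationalEnsemble,
    assign_water: np.ndarray,
    assign_octanol: np.ndarray,
    span: float = 40.0,
    n_grid: int = 10001,
    rmsd_selector: str = "backbone_heavy",
) -> dict:
    """Straight-line fine-grid evaluation of the permeability prediction
    from known frame-to-cluster assignments: Boltzmann inversion of the
    exact populations, composite-coordinate knot placement, Stokes-
    Einstein arithmetic, and a 10^4-point trapezoid of the resistivity
    integral.  Used as the ground-truth record for benchmark pairs."""
    kB = 0.0019872041
    T = water.solvent.temperature
    top = water.topology
    subset = select_atoms(top, rmsd_selector)
    # common reference = water start structure, as in the pipeline default
    ref = water.coordinates[0, subset]
    segments = []
    mid = span / 2.0
    gap = 0.05 * span  # knot-free interface bridge, half the 10% default
    for ens, assign, (z0, z1) in (
        (water, assign_water, (0.0, mid - gap)),
        (octanol, assign_octanol, (mid + gap, span)),
    ):
        r = _oracle_rmsd(ens.coordinates[:, subset], ref)
        labels = np.unique(assign)
        centers = np.array([r[assign == l].mean() for l in labels])
        pops = np.array([(assign == l).mean() for l in labels])
        order = np.argsort(centers)
        centers, pops = centers[order], pops[order]
        p_min = 1.0 / (10.0 * ens.n_frames)
        W = -kB * T * np.log(np.maximum(pops, p_min))
        if centers.max() - centers.min() > 1e-12:
            u = (centers - centers.min()) / (centers.max() - centers.min())
        else:
            u = np.full(len(centers), 0.5)
        segments.append((z0 + u * (z1 - z0), W, pops, centers))
    zk = np.concatenate([segments[0][0], segments[1][0]])
    Wk = np.concatenate([segments[0][1], segments[1][1]])
    order = np.argsort(zk, kind="stable")
    zk, Wk = zk[order], Wk[order]
    z = np.linspace(0.0, span, n_grid)
    W = np.interp(z, zk, Wk)
    W = W - W.min()
    pooled_all = np.concatenate([water.coordinates, octanol.coordinates])
    mean_all = _oracle_mean_structure(pooled_all)
    from .permeability import min_enclosing_sphere

    _c, R_o = min_enclosing_sphere(mean_all)
    D = {}
    for ens, key in ((water, "water"), (octanol, "octanol")):
        D[key] = 1.380649e-23 * T / (6.0 * np.pi * ens.solvent.viscosity * R_o * 1e-10) * 1e4
    beta = 1.0 / (kB * T)
    z_cm = z * 1e-8
    wmask = z <= mid
    omask = z >= mid
    R = float(
        np.trapezoid(np.exp(beta * W[wmask]) / D["water"], z_cm[wmask])
        + np.trapezoid(np.exp(beta * W[omask]) / D["octanol"], z_cm[omask])
    )
    return {
        "logP_calc": float(np.log10(1.0 / R)),
        "resistivity_s_cm": R,
        "R_o_angstrom": float(R_o),
        "D_water_cm2_s": D["water"],
        "D_octanol_cm2_s": D["octanol"],
        "populations_water": segments[0][2].tolist(),
        "populations_octanol": segments[1][2].tolist(),
        "centers_water": segments[0][3].tolist(),
        "centers_octanol": segments[1][3].tolist(),
    }


# ---------------------------------------------------------------------------
# Benchmark pairs and libraries
# ---------------------------------------------------------------------------


def make_benchmark_pair(
    spec: FixtureSpec, F: int = 2000, span: float = 40.0
) -> tuple[ConformationalEnsemble, ConformationalEnsemble, dict]:
    """Water + octanol ensembles plus a ground-truth record of every
    planted quantity (empirical cluster weights, cis fractions, H-bond
    occupancies) and the expected log P_calc from the fine-grid oracle."""
    topology = build_topology(spec)
    ens_w, assign_w, cis_w, hb_w = _generate(spec, "water", F, topology)
    ens_o, assign_o, cis_o, hb_o = _generate(spec, "octanol", F, topology)
    record = {
        "name": spec.name,
        "n_frames": F,
        "n_methylations": topology.n_methylations,
        "n_d_residues": topology.n_d_residues,
        "cluster_weights": {
            "water": [float((assign_w == j).mean()) for j in range(len(spec.clusters["water"]))],
            "octanol": [float((assign_o == j).mean()) for j in range(len(spec.clusters["octanol"]))],
        },
        "planted_cluster_weights": {
            s: [c.weight for c in spec.clusters[s]] for s in ("water", "octanol")
        },
        "cis_fractions": {
            "water": {int(k): float(v.mean()) for k, v in cis_w.items()},
            "octanol": {int(k): float(v.mean()) for k, v in cis_o.items()},
        },
        "hbond_occupancies": {
            "water": {f"{d},{a}": float(m.mean()) for (d, a), m in hb_w.items()},
            "octanol": {f"{d},{a}": float(m.mean()) for (d, a), m in hb_o.items()},
        },
        "k": max(len(spec.clusters["water"]), len(spec.clusters["octanol"])),
        "span": span,
    }
    record["expected"] = expected_logp(ens_w, ens_o, assign_w, assign_o, span=span)
    return ens_w, ens_o, record


def make_library(
    n_peptides: int = 10, seed: int = 0, f_frames: int = 1000
) -> list[tuple[FixtureSpec, ConformationalEnsemble, ConformationalEnsemble, dict]]:
    """A small library of benchmark pairs with varied N-methylation and
    heterochirality patterns, for screening/aggregation tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_peptides):
        n_me = int(rng.integers(0, 5))
        n_d = int(rng.integers(0, 4))
        me = tuple(sorted(rng.choice(9, size=n_me, replace=False).tolist())) if n_me else ()
        dd = tuple(sorted(rng.choice(9, size=n_d, replace=False).tolist())) if n_d else ()
        w_a = float(rng.uniform(0.2, 0.8))
        o_a = float(rng.uniform(0.2, 0.8))
        spec = FixtureSpec(
            name=f"pep{i:03d}",
            methylation=me,
            d_residues=dd,
            clusters={
                "water": [ClusterDef("extended", w_a), ClusterDef("compact", 1.0 - w_a)],
                "octanol": [ClusterDef("extended", o_a), ClusterDef("compact", 1.0 - o_a)],
            },
            seed=seed * 1000 + i,
        )
        ens_w, ens_o, record = make_benchmark_pair(spec, F=f_frames)
        out.append((spec, ens_w, ens_o, record))
    return out
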