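"""Domain model for lariat-peptide conformational ensembles.

A lariat peptide is a cyclic peptide closed tail-to-sidechain through a
depsipeptide (ester) linkage rather than head-to-tail, leaving a short
linear tail.  The types here carry the peptide topology (residues with
chirality and N-methylation flags, atoms, bonds, the macrocycle/tail split
and the single depsi bond), the per-solvent conformational ensemble
(frames x atoms x 3, in Å), and the solvent physical parameters used by
the Stokes–Einstein diffusion estimate.

Topology is carried explicitly (and serialized to a YAML sidecar) rather
than re-derived from PDB CONECT records, because depsipeptide linkages are
not reliably encoded in PDB files.  Structure/trajectory I/O goes through
MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Physical constants and defaults
# ---------------------------------------------------------------------------

#: Boltzmann constant in kcal/(mol K); energies are kcal/mol package-wide,
#: SI conversions happen only inside the diffusion/resistivity formulas.
KB_KCAL = 0.0019872041
#: Boltzmann constant in J/K (SI), for Stokes–Einstein.
KB_SI = 1.380649e-23

#: Default van der Waals radii (Å) used for SASA when the topology does not
#: override them.
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

#: Dynamic viscosities at 310 K (Pa s).
WATER_VISCOSITY_310K = 6.913e-4
OCTANOL_VISCOSITY_310K = 4.99e-3

CHIRALITIES = ("L", "D", "achiral")
SELECTORS = ("backbone_heavy", "backbone_oxygens", "all_heavy", "all")


class EnsembleFormatError(ValueError):
    """Structure/trajectory content inconsistent with the declared topology."""


class TopologyError(ValueError):
    """Topology violates a structural invariant (connectivity, flags...)."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    name: str
    chirality: str = "L"
    n_methylated: bool = False

    def __post_init__(self):
        if self.chirality not in CHIRALITIES:
            raise TopologyError(f"unknown chirality {self.chirality!r}")


@dataclass(frozen=True)
class Atom:
    id: int
    element: str
    residue_index: int
    name: str
    radius: float


@dataclass
class SolventSpec:
    """Solvent label plus the physical parameters entering D = kT/(6 pi eta R)."""

    name: str
    temperature: float  # K
    viscosity: float  # Pa s

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0 Pa s")


def water_spec(temperature: float = 310.0) -> SolventSpec:
    return SolventSpec("water", temperature, WATER_VISCOSITY_310K)


def octanol_spec(temperature: float = 310.0) -> SolventSpec:
    return SolventSpec("octanol", temperature, OCTANOL_VISCOSITY_310K)


@dataclass
class PeptideTopology:
    """Atoms, bonds and residue annotations of one lariat peptide.

    ``atoms[i].id == i`` is enforced so atom ids double as array indices.
    ``depsi_linkage`` is the (sidechain-oxygen atom id, C-terminal carbonyl-C
    atom id) pair closing the macrocycle.
    """

    residues: list[Residue]
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    macrocycle_residues: frozenset[int]
    tail_residues: frozenset[int]
    depsi_linkage: tuple[int, int]

    def __post_init__(self):
        self.macrocycle_residues = frozenset(self.macrocycle_residues)
        self.tail_residues = frozenset(self.tail_residues)
        self.depsi_linkage = tuple(self.depsi_linkage)
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        n_res = len(self.residues)
        for i, a in enumerate(self.atoms):
            if a.id != i:
                raise TopologyError(f"atom id {a.id} at position {i}; ids must be 0..A-1")
            if not (0 <= a.residue_index < n_res):
                raise TopologyError(f"atom {a.id} references residue {a.residue_index}")
        if self.macrocycle_residues & self.tail_residues:
            raise TopologyError("macrocycle and tail residue sets overlap")
        if self.macrocycle_residues | self.tail_residues != set(range(n_res)):
            raise TopologyError("macrocycle + tail sets must cover all residues")
        if len(self.depsi_linkage) != 2:
            raise TopologyError("exactly one depsi linkage (two atom ids) required")
        o_id, c_id = self.depsi_linkage
        if self.atoms[o_id].element != "O" or self.atoms[c_id].element != "C":
            raise TopologyError("depsi linkage must be (sidechain O, carbonyl C)")
        # bond graph connectivity
        adj: dict[int, set[int]] = {a.id: set() for a in self.atoms}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(self.atoms):
            raise TopologyError("bond graph is not connected")
        # every N-methylated backbone N carries a methyl carbon
        for r_idx, res in enumerate(self.residues):
            if not res.n_methylated:
                continue
            n_atom = self.find_atom(r_idx, "N", required=False)
            if n_atom is None:
                continue
            has_methyl = any(
                self.atoms[nb].element == "C" and self.atoms[nb].name not in ("CA", "C")
                for nb in adj[n_atom]
            )
            if not has_methyl:
                raise TopologyError(
                    f"residue {r_idx} flagged N-methylated but its N has no methyl C"
                )

    # -- helpers ------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_methylations(self) -> int:
        """Library descriptor N: number of N-methylated residues."""
        return sum(r.n_methylated for r in self.residues)

    @property
    def n_d_residues(self) -> int:
        """Heterochirality descriptor: number of D residues."""
        return sum(r.chirality == "D" for r in self.residues)

    def find_atom(self, residue_index: int, name: str, required: bool = True) -> Optional[int]:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a.id
        if required:
            raise TopologyError(
                f"residue {residue_index} ({self.residues[residue_index].name}) "
                f"is missing atom {name!r}"
            )
        return None

    def bonded_to(self, atom_id: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == atom_id:
                out.append(j)
            elif j == atom_id:
                out.append(i)
        return sorted(out)

    def radii(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.radius for a in atoms], dtype=float)

    # -- YAML sidecar -------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "residues": [
                {"name": r.name, "chirality": r.chirality, "n_methylated": bool(r.n_methylated)}
                for r in self.residues
            ],
            "atoms": [
                {
                    "id": a.id,
                    "element": a.element,
                    "residue": a.residue_index,
                    "name": a.name,
                    "radius": float(a.radius),
                }
                for a in self.atoms
            ],
            "bonds": [[int(i), int(j)] for i, j in self.bonds],
            "macrocycle_residues": sorted(self.macrocycle_residues),
            "tail_residues": sorted(self.tail_residues),
            "depsi_linkage": [int(x) for x in self.depsi_linkage],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeptideTopology":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            residues=[
                Residue(r["name"], r.get("chirality", "L"), bool(r.get("n_methylated", False)))
                for r in doc["residues"]
            ],
            atoms=[
                Atom(a["id"], a["element"], a["residue"], a["name"], float(a["radius"]))
                for a in doc["atoms"]
            ],
            bonds=[tuple(b) for b in doc["bonds"]],
            macrocycle_residues=frozenset(doc["macrocycle_residues"]),
            tail_residues=frozenset(doc["tail_residues"]),
            depsi_linkage=tuple(doc["depsi_linkage"]),
        )


@dataclass
class ConformationalEnsemble:
    """F frames x A atoms x 3 coordinates (Å) with normalized frame weights."""

    coordinates: np.ndarray
    topology: PeptideTopology
    solvent: SolventSpec
    frame_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise EnsembleFormatError("coordinates must have shape (F, A, 3)")
        if self.coordinates.shape[0] < 1:
            raise EnsembleFormatError("ensemble must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise EnsembleFormatError(
                f"{self.coordinates.shape[1]} atoms per frame, topology declares "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleFormatError("non-finite coordinates")
        if self.frame_weights is None:
            self.frame_weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            w = np.asarray(self.frame_weights, dtype=float)
            if w.shape != (self.n_frames,):
                raise EnsembleFormatError("frame_weights length must equal frame count")
            if np.any(w < 0) or w.sum() <= 0:
                raise EnsembleFormatError("frame_weights must be nonnegative, not all zero")
            self.frame_weights = w / w.sum()

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------


def select_atoms(
    topology: PeptideTopology,
    selector: str,
    include_tail: bool = True,
) -> list[int]:
    """Return sorted atom indices for a named selection.

    ``backbone_heavy`` is N, CA, C, O per residue plus the depsi-linkage
    sidechain oxygen; ``backbone_oxygens`` the carbonyl O per residue;
    ``all_heavy`` every non-hydrogen atom; ``all`` everything.  With
    ``include_tail=False`` backbone selections are restricted to macrocycle
    residues (the depsi O belongs to a macrocycle residue and is kept).
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; choose from {SELECTORS}")
    keep_res = set(range(topology.n_residues))
    if not include_tail:
        keep_res = set(topology.macrocycle_residues)
    out: list[int] = []
    if selector == "all":
        out = [a.id for a in topology.atoms]
    elif selector == "all_heavy":
        out = [a.id for a in topology.atoms if a.element != "H"]
    elif selector == "backbone_oxygens":
        out = [
            a.id
            for a in topology.atoms
            if a.name == "O" and a.residue_index in keep_res
        ]
    elif selector == "backbone_heavy":
        out = [
            a.id
            for a in topology.atoms
            if a.name in ("N", "CA", "C", "O") and a.residue_index in keep_res
        ]
        depsi_o = topology.depsi_linkage[0]
        if topology.atoms[depsi_o].residue_index in keep_res and depsi_o not in out:
            out.append(depsi_o)
    return sorted(out)


# ---------------------------------------------------------------------------
# I/O via MDAnalysis
# ---------------------------------------------------------------------------


def _load_universe(structure_path, trajectory_path):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                return mda.Universe(str(structure_path))
            return mda.Universe(str(structure_path), str(trajectory_path))
    except OSError as exc:
        raise IOError(f"cannot read ensemble input: {exc}") from exc


def read_ensemble(
    structure_path: str | Path,
    trajectory_path: Optional[str | Path] = None,
    solvent: Optional[SolventSpec] = None,
    topology: Optional[PeptideTopology] = None,
) -> ConformationalEnsemble:
    """Read a multi-model PDB (or single-frame PDB + DCD) into an ensemble.

    The chemical topology comes from an explicit ``topology`` or, when
    omitted, from the YAML sidecar ``<structure stem>.yaml`` next to the
    structure file.  Frame weights are uniform.
    """
    structure_path = Path(structure_path)
    if topology is None:
        sidecar = structure_path.with_suffix(".yaml")
        if not sidecar.exists():
            raise IOError(f"no topology given and sidecar {sidecar} not found")
        topology = PeptideTopology.from_yaml(sidecar)
    if solvent is None:
        solvent = water_spec()

    try:
        u = _load_universe(structure_path, trajectory_path)
        if len(u.atoms) != topology.n_atoms:
            raise EnsembleFormatError(
                f"structure has {len(u.atoms)} atoms, topology declares {topology.n_atoms}"
            )
        frames = []
        for i, _ts in enumerate(u.trajectory):
            xyz = u.atoms.positions.astype(float)
            if xyz.shape != (topology.n_atoms, 3):
                raise EnsembleFormatError(
                    f"frame {i}: {xyz.shape[0]} atoms, expected {topology.n_atoms}"
                )
            frames.append(xyz.copy())
    except EnsembleFormatError:
        raise
    except ValueError as exc:
        # MDAnalysis raises ValueError on PDB/DCD atom-count mismatch
        raise EnsembleFormatError(str(exc)) from exc
    coords = np.stack(frames)
    return ConformationalEnsemble(coords, topology, solvent)


def write_ensemble(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (coordinates to 1e-3 Å)."""
    import MDAnalysis as mda

    top = ensemble.topology
    n_res = top.n_residues
    resindex = np.array([a.residue_index for a in top.atoms])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            top.n_atoms,
            n_residues=n_res,
            atom_resindex=resindex,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in top.atoms])
        u.add_TopologyAttr("elements", [a.element for a in top.atoms])
        u.add_TopologyAttr("resnames", [r.name[:3].upper() or "UNK" for r in top.residues])
        u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
        with mda.Writer(str(path), n_atoms=top.n_atoms, multiframe=True) as w:
            for f in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coordinates[f]
                w.write(u.atoms)


def read_logp_table(path: str | Path) -> dict[str, float]:
    """Read an experimental log(P_app) table: 2 columns (peptide_id, logPapp)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise IOError("expected a 2-column TSV (peptide_id, logPapp)")
    ids = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1].astype(float)
    return dict(zip(ids, vals))
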