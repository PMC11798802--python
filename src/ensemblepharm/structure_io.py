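"""Conformational-ensemble and ligand-library I/O, superposition, site selection.

Coordinates are in Angstrom throughout.  Atom indices are 0-based internally;
residue numbering follows the input file.  Frame order is the file's model
order and is authoritative for the recurrence (time-series) analysis
downstream — never reorder frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

__all__ = [
    "ConformationEnsemble",
    "SiteDefinition",
    "LigandLibrary",
    "Molecule",
    "read_ensemble",
    "write_ensemble",
    "superpose_ensemble",
    "select_site_atoms",
    "read_ligand_library",
    "write_ligand_library",
]

_HYDROGEN = frozenset({"H", "D"})


@dataclass
class ConformationEnsemble:
    """An ensemble of protein (or pseudo-atom pocket) conformations.

    All frames share one atom order.  ``coords`` has shape
    ``(n_frames, n_atoms, 3)``; per-atom metadata arrays have length
    ``n_atoms``.
    """

    coords: np.ndarray
    elements: np.ndarray       # element symbols, e.g. "C", "N"
    atom_names: np.ndarray     # PDB atom names, e.g. "CA", "OD1"
    res_ids: np.ndarray        # residue numbers as in the file
    res_names: np.ndarray      # residue names, e.g. "ASP"
    chain_ids: np.ndarray
    frame_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ensemble coordinates must be finite")
        if not self.frame_ids:
            self.frame_ids = list(range(self.n_frames))
        if len(self.frame_ids) != self.n_frames:
            raise ValueError("frame_ids length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.elements.astype(str)), list(_HYDROGEN))


@dataclass
class SiteDefinition:
    """Binding-site definition: an explicit residue list, or proximity to
    reference points (default cutoff 6.5 A, the radius used around the
    detected site in the original protocol)."""

    mode: str  # "residue_list" | "ligand_proximity"
    residues: list[tuple[str, int]] | None = None   # (chain_id, res_id)
    reference_points: np.ndarray | None = None
    cutoff: float = 6.5

    def __post_init__(self):
        if self.mode not in ("residue_list", "ligand_proximity"):
            raise ValueError(f"unknown site mode {self.mode!r}")
        if self.mode == "residue_list":
            if not self.residues:
                raise ValueError("residue_list site requires at least one residue")
        else:
            if self.reference_points is None or len(self.reference_points) == 0:
                raise ValueError("ligand_proximity site requires reference points")
            self.reference_points = np.atleast_2d(
                np.asarray(self.reference_points, dtype=float))
            if self.cutoff <= 0:
                raise ValueError("site cutoff must be > 0")


@dataclass
class Molecule:
    """One library molecule: an activity class and >=1 conformer sharing an
    atom order.  ``annotation_classes`` optionally carries per-atom feature
    classes (synthetic pseudo-molecules); empty string means untyped."""

    mol_id: str
    activity: str  # "active" | "decoy" | "unknown"
    conformers: list[np.ndarray]
    elements: list[str]
    # (i, j) or (i, j, order) with order 1/2/3/1.5 (aromatic)
    bonds: list[tuple] = field(default_factory=list)
    annotation_classes: list[str] | None = None

    def __post_init__(self):
        if not self.conformers:
            raise ValueError(f"molecule {self.mol_id} has no conformers")
        n = len(self.elements)
        for c in self.conformers:
            if len(c) != n:
                raise ValueError(
                    f"molecule {self.mol_id}: conformer atom count mismatch")


@dataclass
class LigandLibrary:
    molecules: list[Molecule]

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def actives(self) -> list[Molecule]:
        return [m for m in self.molecules if m.activity == "active"]

    @property
    def decoys(self) -> list[Molecule]:
        return [m for m in self.molecules if m.activity == "decoy"]


# ---------------------------------------------------------------------------
# ensemble I/O (multi-model PDB)

def read_ensemble(path) -> ConformationEnsemble:
    """Read a multi-model PDB file into a :class:`ConformationEnsemble`.

    Every model must contain the same atoms in the same order; a mismatch is
    a hard error naming the offending frame (1-based, as in the file).
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    first = pdb.get_structure(model=1)
    coords = np.empty((n_models, first.array_length(), 3), dtype=float)
    coords[0] = first.coord
    for m in range(2, n_models + 1):
        frame = pdb.get_structure(model=m)
        if frame.array_length() != first.array_length():
            raise ValueError(
                f"atom count mismatch at frame {m}: "
                f"{frame.array_length()} atoms vs {first.array_length()} in frame 1")
        coords[m - 1] = frame.coord
    return ConformationEnsemble(
        coords=coords,
        elements=np.asarray(first.element, dtype=str),
        atom_names=np.asarray(first.atom_name, dtype=str),
        res_ids=np.asarray(first.res_id, dtype=int),
        res_names=np.asarray(first.res_name, dtype=str),
        chain_ids=np.asarray(first.chain_id, dtype=str),
    )


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write the ensemble as a multi-model PDB (3-decimal coordinates)."""
    n = ensemble.n_atoms
    template = struc.AtomArray(n)
    template.element = ensemble.elements
    template.atom_name = ensemble.atom_names
    template.res_id = ensemble.res_ids
    template.res_name = ensemble.res_names
    template.chain_id = ensemble.chain_ids
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = ensemble.coords.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# site selection and superposition

def select_site_atoms(ensemble: ConformationEnsemble, site: SiteDefinition,
                      frame: int = 0) -> np.ndarray:
    """Return the sorted 0-based indices of the site atoms.

    residue_list mode selects every atom of the listed residues;
    ligand_proximity mode selects every atom within ``site.cutoff`` of any
    reference point, evaluated on ``frame`` (atoms, not residues, so a long
    side chain can dip in and out of the site between frames — the site set
    is always taken from one frame, by default the first).
    """
    if site.mode == "residue_list":
        mask = np.zeros(ensemble.n_atoms, dtype=bool)
        for chain, rid in site.residues:
            sel = ensemble.res_ids == rid
            if chain:
                sel &= ensemble.chain_ids == chain
            mask |= sel
    else:
        pts = site.reference_points
        d = np.linalg.norm(
            ensemble.coords[frame][:, None, :] - pts[None, :, :], axis=2)
        mask = (d <= site.cutoff).any(axis=1)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("site definition selects no atoms")
    return idx


def superpose_ensemble(ensemble: ConformationEnsemble,
                       site: SiteDefinition) -> ConformationEnsemble:
    """Superpose every frame onto frame 1 on the heavy atoms of the site.

    Frame 1 is left untouched; each other frame receives the least-squares
    (Kabsch) proper rigid transform minimizing the RMSD of the site heavy
    atoms to frame 1.  Hydrogens never participate in the fit.
    """
    if ensemble.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    idx = select_site_atoms(ensemble, site, frame=0)
    fit_idx = idx[ensemble.heavy_mask[idx]]
    if fit_idx.size < 3:
        raise ValueError(
            f"superposition underdetermined: only {fit_idx.size} site heavy atoms")
    ref = ensemble.coords[0][fit_idx]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("site heavy atoms are collinear; superposition underdetermined")
    out = ensemble.coords.copy()
    rc = ref.mean(axis=0)
    for f in range(1, ensemble.n_frames):
        mob = out[f][fit_idx]
        mc = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
        out[f] = rot.apply(out[f] - mc) + rc
    return ConformationEnsemble(
        coords=out, elements=ensemble.elements, atom_names=ensemble.atom_names,
        res_ids=ensemble.res_ids, res_names=ensemble.res_names,
        chain_ids=ensemble.chain_ids, frame_ids=list(ensemble.frame_ids))


def site_rmsd_to_first(ensemble: ConformationEnsemble,
                       site: SiteDefinition) -> np.ndarray:
    """Per-frame RMSD of site heavy atoms to frame 1 (no fitting)."""
    idx = select_site_atoms(ensemble, site, frame=0)
    fit_idx = idx[ensemble.heavy_mask[idx]]
    ref = ensemble.coords[0][fit_idx]
    d = ensemble.coords[:, fit_idx, :] - ref[None]
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=1))


# ---------------------------------------------------------------------------
# ligand library I/O (SDF V2000)

_ACTIVITY_TAG = "ACTIVITY"
_CLASS_TAG = "FEATURE_CLASSES"


def read_ligand_library(path, activity_tag: str = _ACTIVITY_TAG,
                        default_activity: str = "unknown") -> LigandLibrary:
    """Read a multi-record SDF into a :class:`LigandLibrary`.

    Consecutive records sharing a molecule title are conformers of one
    molecule.  The activity class is read from the SD tag ``activity_tag``
    ("active"/"decoy"); a ``FEATURE_CLASSES`` tag (comma-separated, one entry
    per atom, empty allowed) marks pseudo-molecules carrying explicit
    annotation classes.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    molecules: list[Molecule] = []
    current: Molecule | None = None
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record at index {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        activity = (mol.GetProp(activity_tag).strip().lower()
                    if mol.HasProp(activity_tag) else default_activity)
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(a).x,
                            conf.GetAtomPosition(a).y,
                            conf.GetAtomPosition(a).z]
                           for a in range(mol.GetNumAtoms())])
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                  b.GetBondTypeAsDouble()) for b in mol.GetBonds()]
        classes = None
        if mol.HasProp(_CLASS_TAG):
            classes = [c.strip() for c in mol.GetProp(_CLASS_TAG).split(",")]
            if len(classes) != len(elements):
                raise ValueError(
                    f"molecule {name}: {_CLASS_TAG} length != atom count")
        if current is not None and current.mol_id == name:
            current.conformers.append(coords)
        else:
            current = Molecule(mol_id=name, activity=activity,
                               conformers=[coords], elements=elements,
                               bonds=bonds, annotation_classes=classes)
            molecules.append(current)
    return LigandLibrary(molecules=molecules)


def write_ligand_library(library: LigandLibrary, path,
                         activity_tag: str = _ACTIVITY_TAG,
                         extra_tags: dict[str, dict[str, str]] | None = None) -> None:
    """Write a library as SDF V2000, one record per conformer.

    ``extra_tags`` maps mol_id -> {tag: value} for per-molecule SD tags
    (e.g. MATCH_RMSD on a hit list).
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for m in library.molecules:
        for coords in m.conformers:
            rw = Chem.RWMol()
            pseudo = m.annotation_classes is not None
            for el in m.elements:
                a = Chem.Atom(el)
                if pseudo:
                    a.SetNoImplicit(True)
                rw.AddAtom(a)
            bond_type = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                         3: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
            for b in m.bonds:
                order = b[2] if len(b) > 2 else 1
                rw.AddBond(int(b[0]), int(b[1]),
                           bond_type.get(order, Chem.BondType.SINGLE))
            conf = Chem.Conformer(len(m.elements))
            for k, (x, y, z) in enumerate(coords):
                conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", m.mol_id)
            mol.SetProp(activity_tag, m.activity)
            if m.annotation_classes is not None:
                mol.SetProp(_CLASS_TAG, ",".join(m.annotation_classes))
            if extra_tags and m.mol_id in extra_tags:
                for tag, val in extra_tags[m.mol_id].items():
                    mol.SetProp(tag, val)
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
            writer.write(mol)
    writer.close()
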