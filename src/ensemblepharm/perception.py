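"""Pharmacophore annotation-point perception and feature building.

Protein site atoms are typed through the residue-template rule table in
:mod:`ensemblepharm.rules` (multi-model PDB carries no bonds, so templates
stand in for connectivity).  Ligands are typed either from an explicit
per-atom class list (synthetic pseudo-molecules) or, for real chemistry,
through RDKit's chemical-feature factory.

Feature building turns points into radius-bearing spheres: Don/Acc/Cat/Ani
1.2 A, aromatic 1.4 A, hydrophobic 1.6 A.  Hydrophobic points within 1 A of
one another are transitively grouped into a single feature whose radius
grows to cover the members, capped at 3 A.  Co-located Don and Acc (or Don
and Cat) merge into the combined classes Don|Acc / Don|Cat; co-located
Aro/PiR and Hyd/HydA points likewise yield Aro|PiR and Hyd|HydA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rules
from .structure_io import ConformationEnsemble, Molecule, SiteDefinition, select_site_atoms

__all__ = [
    "AnnotationPoint",
    "PharmacophoreFeature",
    "perceive_site_annotations",
    "perceive_ligand_annotations",
    "build_features",
    "perceive_site",
    "PerceptionConfig",
]


@dataclass(frozen=True)
class AnnotationPoint:
    cls: str
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("annotation point position must be finite")
        if not self.source_atoms:
            raise ValueError("annotation point needs at least one source atom")


@dataclass(frozen=True)
class PharmacophoreFeature:
    cls: str
    center: tuple[float, float, float]
    radius: float
    frame_id: int = -1

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")


@dataclass
class PerceptionConfig:
    radii: dict = field(default_factory=lambda: dict(rules.DEFAULT_RADII))
    hyd_merge_distance: float = rules.HYD_MERGE_DISTANCE
    hyd_max_radius: float = rules.HYD_MAX_RADIUS
    overlap_tolerance: float = rules.OVERLAP_TOLERANCE


# ---------------------------------------------------------------------------
# annotation perception

def perceive_site_annotations(ensemble: ConformationEnsemble,
                              site_indices: np.ndarray,
                              frame: int) -> list[AnnotationPoint]:
    """Type the site atoms of one frame via the residue template table.

    An atom rule fires for each named atom present in the selection; a
    centroid rule fires only when all its member atoms are present (a ring
    half inside the site gives no centroid).  Unknown residues yield nothing.
    """
    coords = ensemble.coords[frame]
    points: list[AnnotationPoint] = []
    site_set = set(int(i) for i in site_indices)
    # group selected atoms by (chain, res_id)
    by_res: dict[tuple, list[int]] = {}
    for i in site_indices:
        i = int(i)
        key = (str(ensemble.chain_ids[i]), int(ensemble.res_ids[i]))
        by_res.setdefault(key, []).append(i)
    for key in sorted(by_res):
        atom_idx = by_res[key]
        res_name = str(ensemble.res_names[atom_idx[0]]).upper()
        name_to_idx = {str(ensemble.atom_names[i]): i for i in atom_idx}
        if res_name in rules.PSEUDO_RESIDUES:
            for i in atom_idx:
                for cls in rules.PSEUDO_RESIDUES[res_name]:
                    points.append(AnnotationPoint(
                        cls, tuple(coords[i]), (i,)))
            continue
        res_rules = rules.residue_rules(res_name)
        if res_rules is None:
            continue
        for kind, cls, names in res_rules:
            if kind == "atom":
                for nm in names:
                    if nm in name_to_idx:
                        i = name_to_idx[nm]
                        points.append(AnnotationPoint(cls, tuple(coords[i]), (i,)))
            else:  # centroid
                if all(nm in name_to_idx for nm in names):
                    idx = tuple(name_to_idx[nm] for nm in names)
                    c = coords[list(idx)].mean(axis=0)
                    points.append(AnnotationPoint(cls, tuple(c), idx))
        hyd_names = [nm for nm in rules.hydrophobic_atoms(res_name)
                     if nm in name_to_idx]
        for nm in hyd_names:
            i = name_to_idx[nm]
            points.append(AnnotationPoint("Hyd", tuple(coords[i]), (i,)))
        if len(hyd_names) >= 3:
            idx = tuple(name_to_idx[nm] for nm in hyd_names)
            c = coords[list(idx)].mean(axis=0)
            points.append(AnnotationPoint("HydA", tuple(c), idx))
    # keep site_set reference for clarity of contract (atoms outside never typed)
    assert all(set(p.source_atoms) <= site_set for p in points)
    return _canonical_points(points)


_HETERO = frozenset("N O S P F Cl Br I".split())


def perceive_ligand_annotations(molecule: Molecule,
                                conformer: int = 0) -> list[AnnotationPoint]:
    """Annotation points for one conformer of a library molecule.

    If the molecule carries explicit per-atom classes (synthetic
    pseudo-molecules) those are authoritative; otherwise RDKit's
    BaseFeatures chemical-feature factory types the real chemistry.
    """
    coords = np.asarray(molecule.conformers[conformer], dtype=float)
    points: list[AnnotationPoint] = []
    if molecule.annotation_classes is not None:
        for i, cls in enumerate(molecule.annotation_classes):
            if not cls:
                continue
            for sub in cls.split("+"):
                points.append(AnnotationPoint(sub, tuple(coords[i]), (i,)))
        return _canonical_points(points)
    return _canonical_points(_rdkit_annotations(molecule, coords))


_FDEF_FAMILY_MAP = {
    "Donor": "Don", "Acceptor": "Acc",
    "PosIonizable": "Cat", "NegIonizable": "Ani",
    "Aromatic": "Aro", "Hydrophobe": "Hyd", "LumpedHydrophobe": "HydA",
}

_factory = None


def _feature_factory():
    global _factory
    if _factory is None:
        import os
        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures
        _factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef"))
    return _factory


def _rdkit_annotations(molecule: Molecule, coords: np.ndarray):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for el in molecule.elements:
        rw.AddAtom(Chem.Atom(el))
    bond_type = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for b in molecule.bonds:
        order = b[2] if len(b) > 2 else 1
        rw.AddBond(int(b[0]), int(b[1]),
                   bond_type.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    conf = Chem.Conformer(len(molecule.elements))
    for k, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    points = []
    for feat in _feature_factory().GetFeaturesForMol(mol):
        cls = _FDEF_FAMILY_MAP.get(feat.GetFamily())
        if cls is None:
            continue
        pos = feat.GetPos()
        points.append(AnnotationPoint(
            cls, (pos.x, pos.y, pos.z), tuple(feat.GetAtomIds())))
    return points


def _canonical_points(points):
    return sorted(points, key=lambda p: (p.cls, p.position))


# ---------------------------------------------------------------------------
# feature building

def build_features(points: list[AnnotationPoint],
                   frame_id: int = -1,
                   config: PerceptionConfig | None = None
                   ) -> list[PharmacophoreFeature]:
    """Turn one conformation's annotation points into radius-bearing features.

    Order-independent: hydrophobic grouping is a transitive closure and the
    output is canonically sorted by class then center.
    """
    cfg = config or PerceptionConfig()
    hyd = [p for p in points if p.cls in ("Hyd", "HydA")]
    aro = [p for p in points if p.cls in ("Aro", "PiR")]
    don = [p for p in points if p.cls == "Don"]
    acc = [p for p in points if p.cls == "Acc"]
    cat = [p for p in points if p.cls == "Cat"]
    ani = [p for p in points if p.cls == "Ani"]

    feats: list[PharmacophoreFeature] = []

    # hydrophobic transitive grouping within hyd_merge_distance
    for group in _connected_groups(hyd, cfg.hyd_merge_distance):
        pos = np.array([g.position for g in group])
        center = pos.mean(axis=0)
        classes = {g.cls for g in group}
        cls = "Hyd|HydA" if classes == {"Hyd", "HydA"} else classes.pop()
        if len(group) == 1:
            radius = cfg.radii[cls]
        else:
            spread = np.linalg.norm(pos - center, axis=1).max()
            radius = min(cfg.hyd_max_radius, spread + cfg.radii["Hyd"])
        feats.append(PharmacophoreFeature(cls, tuple(center), radius, frame_id))

    # aromatic / pi-ring coincidence
    feats.extend(_pair_merge(aro, "Aro", "PiR", "Aro|PiR", cfg, frame_id))

    # Don & Acc and Don & Cat overlap ("Boolean and" of co-located points);
    # a donor consumed by Don|Acc is not reused for Don|Cat
    da, used_don, used_acc = _overlap_pairs(don, acc, cfg.overlap_tolerance)
    rem_don = [p for i, p in enumerate(don) if i not in used_don]
    dc, used_don2, used_cat = _overlap_pairs(rem_don, cat, cfg.overlap_tolerance)
    for a, b in da:
        c = (np.array(a.position) + np.array(b.position)) / 2
        feats.append(PharmacophoreFeature("Don|Acc", tuple(c),
                                          cfg.radii["Don|Acc"], frame_id))
    for a, b in dc:
        c = (np.array(a.position) + np.array(b.position)) / 2
        feats.append(PharmacophoreFeature("Don|Cat", tuple(c),
                                          cfg.radii["Don|Cat"], frame_id))
    for i, p in enumerate(rem_don):
        if i not in used_don2:
            feats.append(PharmacophoreFeature("Don", p.position,
                                              cfg.radii["Don"], frame_id))
    for i, p in enumerate(acc):
        if i not in used_acc:
            feats.append(PharmacophoreFeature("Acc", p.position,
                                              cfg.radii["Acc"], frame_id))
    for i, p in enumerate(cat):
        if i not in used_cat:
            feats.append(PharmacophoreFeature("Cat", p.position,
                                              cfg.radii["Cat"], frame_id))
    for p in ani:
        feats.append(PharmacophoreFeature("Ani", p.position,
                                          cfg.radii["Ani"], frame_id))
    return sorted(feats, key=lambda f: (f.cls, f.center))


def _connected_groups(points, cutoff):
    """Transitive closure of the within-cutoff relation (union-find)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pos = np.array([p.position for p in points]) if n else np.empty((0, 3))
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(points[i])
    return [groups[k] for k in sorted(groups)]


def _pair_merge(points, cls_a, cls_b, combined, cfg, frame_id):
    """Merge co-located points of two sister classes into the combined class."""
    a_pts = [p for p in points if p.cls == cls_a]
    b_pts = [p for p in points if p.cls == cls_b]
    pairs, used_a, used_b = _overlap_pairs(a_pts, b_pts, cfg.overlap_tolerance)
    feats = []
    for a, b in pairs:
        c = (np.array(a.position) + np.array(b.position)) / 2
        feats.append(PharmacophoreFeature(combined, tuple(c),
                                          cfg.radii[combined], frame_id))
    for i, p in enumerate(a_pts):
        if i not in used_a:
            feats.append(PharmacophoreFeature(cls_a, p.position,
                                              cfg.radii[cls_a], frame_id))
    for i, p in enumerate(b_pts):
        if i not in used_b:
            feats.append(PharmacophoreFeature(cls_b, p.position,
                                              cfg.radii[cls_b], frame_id))
    return feats


def _overlap_pairs(a_pts, b_pts, tol):
    """Greedy nearest-first pairing of points closer than tol."""
    cands = []
    for i, a in enumerate(a_pts):
        for j, b in enumerate(b_pts):
            d = float(np.linalg.norm(np.array(a.position) - np.array(b.position)))
            if d <= tol:
                cands.append((d, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a_pts[i], b_pts[j]))
    return pairs, used_a, used_b


# ---------------------------------------------------------------------------

def perceive_site(ensemble: ConformationEnsemble, site: SiteDefinition,
                  config: PerceptionConfig | None = None
                  ) -> dict[int, list[PharmacophoreFeature]]:
    """Per-frame pharmacophore features for the site atoms of every frame.

    The site atom set is fixed from frame 1 in residue_list mode; in
    ligand_proximity mode it is re-evaluated per frame so that atoms moving
    out of the cutoff sphere drop their features (a rotamer flip that swings
    a hydroxyl out of the site removes the corresponding donor).
    """
    per_frame: dict[int, list[PharmacophoreFeature]] = {}
    fixed_idx = None
    if site.mode == "residue_list":
        fixed_idx = select_site_atoms(ensemble, site, frame=0)
    for f, fid in enumerate(ensemble.frame_ids):
        idx = (fixed_idx if fixed_idx is not None
               else select_site_atoms(ensemble, site, frame=f))
        pts = perceive_site_annotations(ensemble, idx, f)
        per_frame[fid] = build_features(pts, frame_id=fid, config=config)
    return per_frame
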