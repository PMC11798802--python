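"""Pharmacophore query construction and RMSD-based library screening.

A query is a set of typed spheres (the selected consensus features).  A
conformer matches when some assignment of its annotation points to the query
features — classes compatible, one point per feature — admits a proper rigid
superposition placing every point inside its feature sphere (plus an
optional tolerance).  The match RMSD is the least-squares residual of that
superposition; among accepted assignments the minimum-RMSD one is kept, and
among a molecule's conformers only the best-matching conformer is retained.

The correspondence search is a backtracking enumeration over class-
compatible assignments pruned by pairwise-distance consistency:
|d_query(i,j) - d_ligand(i,j)| <= r_i + r_j for every assigned pair.  The
pruning is admissible (any assignment violating it cannot place both points
inside their spheres), so the search is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .consensus import ConsensusFeature
from .perception import AnnotationPoint, perceive_ligand_annotations
from .rules import classes_compatible
from .structure_io import LigandLibrary, Molecule

__all__ = [
    "PharmacophoreQuery",
    "MatchResult",
    "build_query",
    "match_conformer",
    "search_library",
]


@dataclass
class PharmacophoreQuery:
    features: list[tuple[str, str, tuple[float, float, float], float]]
    # (id, class, center, radius)
    match_mode: str = "all"   # "all" or "m-of-n"
    m: int | None = None      # required matches in m-of-n mode

    def __post_init__(self):
        ids = [f[0] for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("query feature ids must be unique")
        if len(self.features) < 3:
            raise ValueError(
                "a query needs >=3 features (geometric matching is "
                "underdetermined below that)")
        if self.match_mode == "m-of-n":
            if self.m is None or not (3 <= self.m <= len(self.features)):
                raise ValueError("m-of-n mode needs 3 <= m <= n features")
        elif self.match_mode != "all":
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    @property
    def required(self) -> int:
        return len(self.features) if self.match_mode == "all" else int(self.m)

    def to_dict(self) -> dict:
        return {"features": [{"id": i, "class": c,
                              "center": list(map(float, ctr)),
                              "radius": float(r)}
                             for i, c, ctr, r in self.features],
                "match_mode": self.match_mode,
                **({"m": self.m} if self.m is not None else {})}

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreQuery":
        feats = [(f["id"], f["class"], tuple(f["center"]), f["radius"])
                 for f in d["features"]]
        return cls(feats, d.get("match_mode", "all"), d.get("m"))


@dataclass
class MatchResult:
    molecule_id: str
    conformer_index: int
    matched: bool
    rmsd: float = float("nan")
    correspondence: dict = field(default_factory=dict)  # feature id -> point idx
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None


def build_query(consensus: list[ConsensusFeature],
                selected_ids: list[str],
                match_mode: str = "all",
                m: int | None = None) -> PharmacophoreQuery:
    """Assemble a query from consensus features by id (vote winners or an
    explicit manual list)."""
    by_id = {c.id: c for c in consensus}
    missing = [i for i in selected_ids if i not in by_id]
    if missing:
        raise ValueError(f"unknown consensus feature ids: {missing}")
    feats = [(i, by_id[i].cls, tuple(map(float, by_id[i].center)),
              float(by_id[i].radius)) for i in selected_ids]
    return PharmacophoreQuery(feats, match_mode=match_mode, m=m)


def _superpose(points: np.ndarray, targets: np.ndarray):
    """Proper (det = +1) least-squares rigid fit of points onto targets.

    Returns (rotation matrix, translation, per-point residual vectors)."""
    pc, tc = points.mean(axis=0), targets.mean(axis=0)
    rot, _ = Rotation.align_vectors(targets - tc, points - pc)
    moved = rot.apply(points - pc) + tc
    return rot.as_matrix(), tc - rot.apply(pc[None])[0], moved - targets, moved


def _evaluate_assignment(q_centers, q_radii, p_coords, tolerance):
    """Kabsch the chosen points onto the feature centers; accept iff every
    residual is inside radius + tolerance.  Returns (ok, rmsd, R, t)."""
    R, t, resid, moved = _superpose(p_coords, q_centers)
    dist = np.linalg.norm(resid, axis=1)
    if np.all(dist <= q_radii + tolerance):
        rmsd = float(np.sqrt((dist ** 2).mean()))
        return True, rmsd, R, t
    return False, float("inf"), None, None


def match_conformer(query: PharmacophoreQuery,
                    points: list[AnnotationPoint],
                    tolerance: float = 0.0,
                    molecule_id: str = "", conformer_index: int = 0
                    ) -> MatchResult:
    """Best accepted correspondence of one conformer against the query.

    In m-of-n mode every size-m feature subset is searched and the overall
    minimum-RMSD accepted match wins.  Unmatched is a valid result, never an
    error.
    """
    n = len(query.features)
    feature_subsets = ([tuple(range(n))] if query.match_mode == "all"
                       else itertools.combinations(range(n), query.required))
    best = MatchResult(molecule_id, conformer_index, matched=False)
    p_pos = np.array([p.position for p in points]) if points else np.empty((0, 3))
    for subset in feature_subsets:
        feats = [query.features[i] for i in subset]
        res = _match_feature_set(feats, points, p_pos, tolerance)
        if res is not None and (not best.matched or res[0] < best.rmsd):
            rmsd, corr, R, t = res
            best = MatchResult(molecule_id, conformer_index, True, rmsd,
                               corr, R, t)
    return best


def _match_feature_set(feats, points, p_pos, tolerance):
    """Exact min-RMSD search for one feature subset; None when unmatched."""
    k = len(feats)
    q_centers = np.array([f[2] for f in feats])
    q_radii = np.array([f[3] for f in feats])
    candidates = []
    for i, (fid, fcls, _, _) in enumerate(feats):
        cand = [j for j, p in enumerate(points)
                if classes_compatible(fcls, p.cls)]
        if not cand:
            return None
        candidates.append(cand)
    qd = np.linalg.norm(q_centers[:, None] - q_centers[None, :], axis=2)
    pd_all = (np.linalg.norm(p_pos[:, None] - p_pos[None, :], axis=2)
              if len(p_pos) else np.empty((0, 0)))

    # search features in order of fewest candidates first
    order = sorted(range(k), key=lambda i: len(candidates[i]))
    best: list = [float("inf"), None, None, None]

    def backtrack(depth, assigned):
        if depth == k:
            centers = q_centers[list(order)]
            radii = q_radii[list(order)]
            coords = p_pos[list(assigned)]
            ok, rmsd, R, t = _evaluate_assignment(centers, radii, coords,
                                                  tolerance)
            if ok and rmsd < best[0]:
                corr = {feats[order[d]][0]: assigned[d] for d in range(k)}
                best[:] = [rmsd, corr, R, t]
            return
        qi = order[depth]
        for j in candidates[qi]:
            if j in assigned:
                continue
            ok = True
            for d in range(depth):
                qj = order[d]
                if abs(qd[qi, qj] - pd_all[j, assigned[d]]) > (
                        q_radii[qi] + q_radii[qj] + 2 * tolerance):
                    ok = False
                    break
            if ok:
                backtrack(depth + 1, assigned + [j])

    backtrack(0, [])
    if best[1] is None:
        return None
    return best[0], best[1], best[2], best[3]


def search_library(query: PharmacophoreQuery, library: LigandLibrary,
                   tolerance: float = 0.0
                   ) -> tuple[dict[str, MatchResult], list[str]]:
    """Screen every conformer of every molecule; retain per molecule only
    the matched conformer of minimum RMSD.

    Returns (per-molecule best MatchResult, hit list of molecule ids in
    library order).  Molecules with no matched conformer are excluded from
    the hit list but present (unmatched) in the result map.
    """
    if len(library) == 0:
        raise ValueError("empty ligand library")
    results: dict[str, MatchResult] = {}
    hits: list[str] = []
    for mol in library.molecules:
        best = MatchResult(mol.mol_id, -1, matched=False)
        for ci in range(len(mol.conformers)):
            pts = perceive_ligand_annotations(mol, conformer=ci)
            res = match_conformer(query, pts, tolerance=tolerance,
                                  molecule_id=mol.mol_id, conformer_index=ci)
            if res.matched and (not best.matched or res.rmsd < best.rmsd):
                best = res
        results[mol.mol_id] = best
        if best.matched:
            hits.append(mol.mol_id)
    return results, hits
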