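import itertools

import numpy as np
import pytest

from ensemblepharm.consensus import ConsensusFeature
from ensemblepharm.perception import AnnotationPoint
from ensemblepharm.rules import classes_compatible
from ensemblepharm.search import (PharmacophoreQuery, build_query,
                                  match_conformer, search_library)
from ensemblepharm.structure_io import LigandLibrary, Molecule

from conftest import kabsch_oracle_rmsd, random_rigid


def query_from(classes_positions, radius=1.2, **kwargs):
    feats = [(f"F{i+1}_{c}", c, tuple(map(float, p)), radius)
             for i, (c, p) in enumerate(classes_positions)]
    return PharmacophoreQuery(feats, **kwargs)


def points_from(classes_positions):
    return [AnnotationPoint(c, tuple(map(float, p)), (i,))
            for i, (c, p) in enumerate(classes_positions)]


BASE = [("Don", (0, 0, 0)), ("Acc", (4, 0, 0)), ("Aro", (0, 4, 0)),
        ("Hyd", (0, 0, 4))]


def oracle_match(query, points, tolerance=0.0):
    """Exhaustive assignment enumeration: every injective class-compatible
    mapping, Kabsch each, keep the minimum accepted RMSD."""
    n = len(query.features)
    centers = np.array([f[2] for f in query.features])
    radii = np.array([f[3] for f in query.features])
    cand = [[j for j, p in enumerate(points)
             if classes_compatible(f[1], p.cls)] for f in query.features]
    ppos = np.array([p.position for p in points])
    best = None
    for choice in itertools.product(*cand):
        if len(set(choice)) != n:
            continue
        sel = ppos[list(choice)]
        # proper Kabsch of the points onto the query centers
        P = sel - sel.mean(axis=0)
        Q = centers - centers.mean(axis=0)
        H = P.T @ Q
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        moved = (R @ P.T).T + centers.mean(axis=0)
        dist = np.linalg.norm(moved - centers, axis=1)
        if np.all(dist <= radii + tolerance):
            rmsd = float(np.sqrt((dist ** 2).mean()))
            if best is None or rmsd < best:
                best = rmsd
    return best


class TestQueryConstruction:
    def test_fewer_than_three_features_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            query_from(BASE[:2])

    def test_duplicate_ids_rejected(self):
        feats = [("F1", "Don", (0, 0, 0), 1.2), ("F1", "Acc", (4, 0, 0), 1.2),
                 ("F2", "Aro", (0, 4, 0), 1.4)]
        with pytest.raises(ValueError, match="unique"):
            PharmacophoreQuery(feats)

    def test_build_query_from_consensus_selection(self):
        cons = [ConsensusFeature(f"F{i+1}_{c}", c, p, 1.2, 0.5, 5)
                for i, (c, p) in enumerate(
                    [("Don", (0.0, 0, 0)), ("Acc", (4.0, 0, 0)),
                     ("Aro", (0.0, 4, 0)), ("Hyd", (0.0, 0, 4))])]
        q = build_query(cons, ["F1_Don", "F2_Acc", "F3_Aro"])
        assert [f[0] for f in q.features] == ["F1_Don", "F2_Acc", "F3_Aro"]
        q7 = build_query(cons, [c.id for c in cons])  # manual override style
        assert len(q7.features) == 4

    def test_build_query_unknown_id_rejected(self):
        cons = [ConsensusFeature("F1_Don", "Don", (0.0, 0, 0), 1.2, 0.5, 5)]
        with pytest.raises(ValueError, match="unknown"):
            build_query(cons, ["F1_Don", "F9_Acc", "F10_Aro"])

    def test_json_round_trip(self):
        q = query_from(BASE, match_mode="m-of-n", m=3)
        back = PharmacophoreQuery.from_dict(q.to_dict())
        assert back.features == q.features
        assert back.match_mode == q.match_mode and back.m == q.m


class TestMatchConformer:
    def test_exact_placement_matches_with_zero_rmsd(self):
        q = query_from(BASE)
        res = match_conformer(q, points_from(BASE))
        assert res.matched
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert set(res.correspondence) == {f[0] for f in q.features}

    def test_missing_class_is_unmatched_not_error(self):
        q = query_from(BASE)
        res = match_conformer(q, points_from(BASE[:3]))
        assert not res.matched

    def test_combined_class_satisfied_by_either_member(self):
        q = query_from([("Don|Acc", (0, 0, 0))] + BASE[1:])
        pts = points_from([("Acc", (0, 0, 0))] + BASE[1:])
        assert match_conformer(q, pts).matched
        pts = points_from([("Don", (0, 0, 0))] + BASE[1:])
        assert match_conformer(q, pts).matched
        pts = points_from([("Hyd", (0, 0, 0))] + BASE[1:])
        assert not match_conformer(q, pts).matched

    def test_jittered_conformer_matches_oracle(self):
        rng = np.random.default_rng(21)
        q = query_from(BASE)
        for trial in range(20):
            jitter = rng.normal(scale=0.3, size=(4, 3))
            pos = np.array([p for _, p in BASE]) + jitter
            pts = points_from(list(zip([c for c, _ in BASE],
                                       random_rigid(rng)(pos))))
            res = match_conformer(q, pts, tolerance=0.5)
            expected = oracle_match(q, pts, tolerance=0.5)
            if expected is None:
                assert not res.matched
            else:
                assert res.matched
                assert res.rmsd == pytest.approx(expected, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(33)
        q = query_from(BASE)
        base_pts = points_from(BASE)
        ref = match_conformer(q, base_pts)
        for _ in range(10):
            move = random_rigid(rng)
            moved = points_from(
                [(p.cls, tuple(move(np.array([p.position]))[0]))
                 for p in base_pts])
            res = match_conformer(q, moved)
            assert res.matched == ref.matched
            assert res.rmsd == pytest.approx(ref.rmsd, abs=1e-6)

    def test_accepted_rmsd_bounded_by_max_radius_plus_tolerance(self):
        rng = np.random.default_rng(8)
        q = query_from(BASE, radius=1.0)
        for _ in range(30):
            pos = (np.array([p for _, p in BASE])
                   + rng.normal(scale=0.8, size=(4, 3)))
            pts = points_from(list(zip([c for c, _ in BASE], pos)))
            res = match_conformer(q, pts, tolerance=0.2)
            if res.matched:
                assert res.rmsd <= 1.0 + 0.2 + 1e-9

    def test_proper_rotation_enforced(self):
        # a mirrored conformer with scalene geometry cannot match at rmsd 0
        q = query_from([("Don", (0, 0, 0)), ("Acc", (3, 0, 0)),
                        ("Aro", (0, 5, 0)), ("Hyd", (0, 0, 7))], radius=0.5)
        mirrored = [(c, (p[0], p[1], -p[2]))
                    for (c, p) in [("Don", (0, 0, 0)), ("Acc", (3, 0, 0)),
                                   ("Aro", (0, 5, 0)), ("Hyd", (0, 0, 7))]]
        res = match_conformer(q, points_from(mirrored))
        if res.matched:
            assert res.rmsd > 0.5  # reflection residual, not exact overlay

    def test_m_of_n_relaxation_never_shrinks_hits(self):
        rng = np.random.default_rng(55)
        q_all = query_from(BASE)
        q_rel = query_from(BASE, match_mode="m-of-n", m=3)
        for _ in range(15):
            keep = rng.choice(4, size=int(rng.integers(3, 5)), replace=False)
            pos = (np.array([p for _, p in BASE])[keep]
                   + rng.normal(scale=0.2, size=(len(keep), 3)))
            pts = points_from(
                list(zip([BASE[i][0] for i in keep], pos)))
            hit_all = match_conformer(q_all, pts, tolerance=0.3).matched
            hit_rel = match_conformer(q_rel, pts, tolerance=0.3).matched
            assert hit_rel or not hit_all


class TestSearchLibrary:
    @staticmethod
    def library_one_molecule(conformers, classes):
        mols = [Molecule(
            mol_id="m", activity="active",
            conformers=[np.asarray(c, dtype=float) for c in conformers],
            elements=["C"] * len(classes),
            annotation_classes=list(classes))]
        return LigandLibrary(mols)

    def test_best_conformer_retained(self):
        q = query_from(BASE)
        good = np.array([p for _, p in BASE], dtype=float)
        close = good + 0.05
        far = good * 3.0
        lib = self.library_one_molecule([far, close, good],
                                        [c for c, _ in BASE])
        results, hits = search_library(q, lib, tolerance=0.5)
        assert hits == ["m"]
        assert results["m"].conformer_index == 2
        assert results["m"].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_lower_rmsd_conformer_wins(self):
        q = query_from(BASE)
        good = np.array([p for _, p in BASE], dtype=float)
        # distort internal geometry (a shared translation would be removed
        # by the superposition): move one point only
        off1, off2 = good.copy(), good.copy()
        off1[0] += [0.8, 0, 0]
        off2[0] += [0.2, 0, 0]
        lib = self.library_one_molecule([off1, off2], [c for c, _ in BASE])
        results, hits = search_library(q, lib, tolerance=0.5)
        assert results["m"].conformer_index == 1

    def test_empty_library_rejected(self):
        q = query_from(BASE)
        with pytest.raises(ValueError, match="empty"):
            search_library(q, LigandLibrary([]))

    def test_unmatched_molecules_excluded_from_hits(self):
        q = query_from(BASE)
        good = np.array([p for _, p in BASE], dtype=float)
        mols = [
            Molecule(mol_id="hit", activity="active", conformers=[good],
                     elements=["C"] * 4,
                     annotation_classes=[c for c, _ in BASE]),
            Molecule(mol_id="miss", activity="decoy", conformers=[good[:3]],
                     elements=["C"] * 3,
                     annotation_classes=[c for c, _ in BASE[:3]]),
        ]
        results, hits = search_library(q, LigandLibrary(mols))
        assert hits == ["hit"]
        assert not results["miss"].matched
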