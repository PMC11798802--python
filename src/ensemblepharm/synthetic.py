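"""Seeded synthetic fixtures: labeled conformational ensembles with planted
binding-associated features, and matched active/decoy conformer libraries.

The ensemble generator emulates the study design the pipeline consumes: a
pocket of pseudo-atoms jittered across frames, a minority of "binding"
frames, pharmacophore features planted at chosen positions whose per-frame
presence is a labeled Bernoulli draw (high occupancy in binding frames, low
elsewhere), and nuisance features at assorted label-independent
frequencies.  An absent feature's pseudo-atom is displaced far outside the
site sphere rather than deleted, so every frame keeps the identical atom
count a multi-model file requires.  The generator records its own draws, so
downstream occurrence frequencies are checkable bit-exactly.

The library generator plants actives whose best conformer sits within a
configurable jitter of the query centers (guaranteed matchable at tolerance
>= jitter) and decoys that either miss one required feature ("drop-one") or
carry geometry scaled past any distance-consistent assignment ("scramble").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusFeature
from .search import PharmacophoreQuery
from .structure_io import ConformationEnsemble, LigandLibrary, Molecule, SiteDefinition

__all__ = ["EnsembleSpec", "LibrarySpec", "PlantedFeature",
           "make_ensemble", "make_library", "end_to_end_recovery"]

_CLASS_RESNAME = {
    "Don": "DON", "Acc": "ACC", "Cat": "CAT", "Ani": "ANI",
    "Aro": "ARO", "PiR": "PIR", "Hyd": "HYD", "HydA": "HDA",
    "Don+Acc": "DAC", "Don+Cat": "DCT",
}
_CLASS_ELEMENT = {
    "Don": "N", "Acc": "O", "Cat": "P", "Ani": "S",
    "Aro": "C", "PiR": "C", "Hyd": "C", "HydA": "C",
    "Don+Acc": "N", "Don+Cat": "N",
}
_ABSENT_SHIFT = np.array([60.0, 60.0, 60.0])


@dataclass
class PlantedFeature:
    cls: str
    position: tuple[float, float, float]
    freq_binding: float
    freq_nonbinding: float

    def __post_init__(self):
        for f in (self.freq_binding, self.freq_nonbinding):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"infeasible frequency {f}")


@dataclass
class EnsembleSpec:
    n_frames: int = 200
    n_site_atoms: int = 20
    binding_fraction: float = 0.1
    jitter_sigma: float = 0.1
    planted: list[PlantedFeature] = field(default_factory=list)
    nuisance: list[PlantedFeature] = field(default_factory=list)
    pocket_radius: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.binding_fraction < 1.0):
            raise ValueError("binding_fraction must be in (0, 1)")
        if self.binding_fraction * self.n_frames < 1:
            raise ValueError("binding_fraction * n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def default_planted(n: int = 3, freq_binding: float = 0.9,
                    freq_nonbinding: float = 0.05) -> list[PlantedFeature]:
    """Well-separated planted features (>= 4 A apart, one per class cycle)."""
    classes = ["Don", "Acc", "Aro", "Hyd", "Cat", "Ani"]
    positions = [(4.0, 0.0, 0.0), (-4.0, 0.0, 0.0), (0.0, 4.0, 0.0),
                 (0.0, -4.0, 0.0), (0.0, 0.0, 4.0), (0.0, 0.0, -4.0),
                 (4.0, 4.0, 0.0), (-4.0, -4.0, 0.0)]
    return [PlantedFeature(classes[i % len(classes)], positions[i],
                           freq_binding, freq_nonbinding)
            for i in range(n)]


def default_nuisance(n: int = 4) -> list[PlantedFeature]:
    """Label-independent features at assorted frequencies."""
    classes = ["Acc", "Don", "Hyd", "Aro", "Ani", "Cat"]
    positions = [(7.0, 2.0, 2.0), (-7.0, -2.0, 2.0), (2.0, 7.0, -2.0),
                 (-2.0, -7.0, -2.0), (2.0, -2.0, 7.0), (-2.0, 2.0, -7.0)]
    freqs = [0.5, 0.15, 0.35, 0.08, 0.6, 0.25]
    return [PlantedFeature(classes[i % 6], positions[i % 6],
                           freqs[i % 6], freqs[i % 6]) for i in range(n)]


def make_ensemble(spec: EnsembleSpec
                  ) -> tuple[ConformationEnsemble, np.ndarray, dict]:
    """Generate the labeled ensemble and its bit-exact ground truth.

    Returns ``(ensemble, labels, truth)`` where ``truth`` holds the site
    definition, per-frame occupancy of every planted/nuisance feature
    (frames x features DataFrame of the recorded Bernoulli draws) and the
    planted/nuisance descriptions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n_bind = int(np.ceil(spec.binding_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_bind]] = 1

    # inert scaffold pseudo-atoms, fixed base positions in the pocket sphere
    scaffold = rng.normal(scale=spec.pocket_radius / 2,
                          size=(spec.n_site_atoms, 3))

    features = list(spec.planted) + list(spec.nuisance)
    names = ([f"P{i+1}_{f.cls}" for i, f in enumerate(spec.planted)]
             + [f"N{i+1}_{f.cls}" for i, f in enumerate(spec.nuisance)])
    occupancy = np.zeros((n, len(features)), dtype=int)
    for j, feat in enumerate(features):
        p = np.where(labels == 1, feat.freq_binding, feat.freq_nonbinding)
        occupancy[:, j] = rng.random(n) < p

    n_atoms = spec.n_site_atoms + len(features)
    coords = np.empty((n, n_atoms, 3))
    for f in range(n):
        jitter = rng.normal(scale=spec.jitter_sigma, size=(n_atoms, 3))
        coords[f, :spec.n_site_atoms] = scaffold + jitter[:spec.n_site_atoms]
        for j, feat in enumerate(features):
            base = np.asarray(feat.position, dtype=float)
            if not occupancy[f, j]:
                base = base + _ABSENT_SHIFT
            coords[f, spec.n_site_atoms + j] = base + jitter[spec.n_site_atoms + j]

    elements = (["C"] * spec.n_site_atoms
                + [_CLASS_ELEMENT[f.cls] for f in features])
    res_names = (["SCF"] * spec.n_site_atoms
                 + [_CLASS_RESNAME[f.cls] for f in features])
    atom_names = [f"X{i+1}" for i in range(spec.n_site_atoms)] + \
                 [f"Y{j+1}" for j in range(len(features))]
    res_ids = list(range(1, n_atoms + 1))
    ensemble = ConformationEnsemble(
        coords=coords,
        elements=np.array(elements), atom_names=np.array(atom_names),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(["A"] * n_atoms))

    extent = max(
        float(np.linalg.norm(scaffold, axis=1).max(initial=0.0)),
        max((float(np.linalg.norm(f.position)) for f in features), default=0.0))
    site = SiteDefinition(
        mode="ligand_proximity", reference_points=np.zeros((1, 3)),
        cutoff=extent + 3.0 + 5 * max(spec.jitter_sigma, 0.1))
    truth = {
        "site": site,
        "occupancy": pd.DataFrame(occupancy, columns=names),
        "planted": list(spec.planted),
        "nuisance": list(spec.nuisance),
        "planted_names": names[:len(spec.planted)],
    }
    return ensemble, labels, truth


# ---------------------------------------------------------------------------
# ligand libraries

@dataclass
class LibrarySpec:
    query: PharmacophoreQuery
    n_actives: int = 50
    n_decoys: int = 500
    conformers_per_molecule: int = 3
    active_jitter: float = 0.3
    decoy_mode: str = "drop-one"   # or "scramble"
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 1 or self.n_decoys < 0:
            raise ValueError("molecule counts must be >= 1 active, >= 0 decoys")
        if not (1 <= self.conformers_per_molecule <= 100):
            raise ValueError("conformers_per_molecule must be in [1, 100]")
        if self.decoy_mode not in ("drop-one", "scramble"):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")


def _random_rigid(rng):
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng)
    t = rng.uniform(-20, 20, size=3)
    return lambda x: rot.apply(x) + t


def _jitter_in_ball(rng, radius, n):
    """Uniform points in a ball — every offset strictly within `radius`."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return v * r[:, None]


def make_library(spec: LibrarySpec) -> tuple[LigandLibrary, dict]:
    """Generate the active/decoy library and ground-truth hit labels.

    Every active has exactly one guaranteed-matchable conformer (annotation
    points within ``active_jitter`` of the query centers, then a random
    rigid motion); its other conformers are scrambled.  Decoys can never
    match the full query: drop-one decoys carry one point fewer than the
    query has features; scramble decoys have their geometry scaled so that
    every pairwise distance violates distance consistency.
    """
    import warnings

    q = spec.query
    centers = np.array([f[2] for f in q.features])
    classes = [f[1] for f in q.features]
    radii = np.array([f[3] for f in q.features])
    if spec.active_jitter > radii.min():
        warnings.warn("active_jitter exceeds the smallest feature radius; "
                      "actives may legitimately fail to match", stacklevel=2)
    rng = np.random.default_rng(spec.seed)

    # scale factor guaranteeing scrambled geometry violates
    # |d_q - d_lig| <= r_i + r_j + 2*tol for any pair, up to tol ~ jitter
    dmat = np.linalg.norm(centers[:, None] - centers[None], axis=2)
    dmin = dmat[dmat > 0].min()
    scale = 1.0 + (2 * radii.max() + 2 * spec.active_jitter + 1.0) / dmin + 0.5

    def scrambled_conformer(cls_list, base_centers):
        return _random_rigid(rng)(base_centers * scale
                                  + _jitter_in_ball(rng, spec.active_jitter,
                                                    len(base_centers)))

    molecules: list[Molecule] = []
    truth_hits: list[str] = []
    for a in range(spec.n_actives):
        mol_id = f"active{a:04d}"
        good_idx = int(rng.integers(spec.conformers_per_molecule))
        conformers = []
        for c in range(spec.conformers_per_molecule):
            if c == good_idx:
                pts = centers + _jitter_in_ball(rng, spec.active_jitter,
                                                len(centers))
                conformers.append(_random_rigid(rng)(pts))
            else:
                conformers.append(scrambled_conformer(classes, centers))
        molecules.append(Molecule(
            mol_id=mol_id, activity="active", conformers=conformers,
            elements=[_CLASS_ELEMENT.get(c.split("|")[0], "C") for c in classes],
            annotation_classes=["+".join(c.split("|")) for c in classes]))
        truth_hits.append(mol_id)

    for d in range(spec.n_decoys):
        mol_id = f"decoy{d:04d}"
        if spec.decoy_mode == "drop-one":
            drop = int(rng.integers(len(classes)))
            keep = [i for i in range(len(classes)) if i != drop]
            sub_centers = centers[keep]
            sub_classes = [classes[i] for i in keep]
            conformers = [
                _random_rigid(rng)(sub_centers
                                   + _jitter_in_ball(rng, spec.active_jitter,
                                                     len(sub_centers)))
                for _ in range(spec.conformers_per_molecule)]
        else:
            sub_classes = classes
            conformers = [scrambled_conformer(classes, centers)
                          for _ in range(spec.conformers_per_molecule)]
        molecules.append(Molecule(
            mol_id=mol_id, activity="decoy", conformers=conformers,
            elements=[_CLASS_ELEMENT.get(c.split("|")[0], "C")
                      for c in sub_classes],
            annotation_classes=["+".join(c.split("|")) for c in sub_classes]))

    truth = {"hits": truth_hits, "non_hits":
             [m.mol_id for m in molecules if m.activity == "decoy"]}
    return LigandLibrary(molecules), truth


# ---------------------------------------------------------------------------
# end-to-end recovery

def end_to_end_recovery(ensemble_spec: EnsembleSpec,
                        band: tuple[float | None, float | None] = (None, None),
                        k: int | None = None,
                        cluster_radius: float = 1.5,
                        library_kwargs: dict | None = None,
                        tolerance: float | None = None) -> dict:
    """Full pipeline on synthetic data; reports planted-feature recall and
    the enrichment factor on the matched synthetic library.

    ``k`` defaults to twice the number of planted features.  The screening
    query is built from the selected consensus features; when fewer than 3
    are selected no query can be built and the EF is reported as None.
    """
    from .model import EnsemblePharmacophoreModel

    ensemble, labels, truth = make_ensemble(ensemble_spec)
    if k is None:
        k = max(1, 2 * len(ensemble_spec.planted))
    model = EnsemblePharmacophoreModel(ensemble, labels, truth["site"],
                                       cluster_radius=cluster_radius)
    try:
        results = model.fit(band=band, k=k)
        selected = results.selected_features()
        selected_ids = results.selected_ids
    except ValueError:
        # band left fewer than k usable columns: nothing can be selected
        results, selected, selected_ids = None, [], []

    recall, matched_ids = planted_recall(selected, truth["planted"],
                                         cluster_radius)
    out = {"recall": recall, "n_selected": len(selected_ids),
           "selected_ids": selected_ids,
           "planted_matched": matched_ids, "ef": None, "ef_flag": None}

    if results is not None and len(selected_ids) >= 3:
        query = results.query()
        lk = dict(library_kwargs or {})
        lk.setdefault("seed", ensemble_spec.seed + 1)
        lib_spec = LibrarySpec(query=query, **lk)
        library, lib_truth = make_library(lib_spec)
        tol = (lib_spec.active_jitter + 3 * ensemble_spec.jitter_sigma
               if tolerance is None else tolerance)
        report = results.screen(library, tolerance=tol)
        out["ef"] = None if report.ef.is_na else report.ef.value
        out["ef_flag"] = report.ef.flag
        out["active_hits"] = report.counts.active_hits
        out["decoy_hits"] = report.counts.decoy_hits
        out["truth_hits"] = lib_truth["hits"]
        out["hit_ids"] = report.active_hit_ids + report.decoy_hit_ids
    return out


def planted_recall(selected: list[ConsensusFeature],
                   planted: list[PlantedFeature],
                   match_radius: float = 1.5) -> tuple[float, list[int]]:
    """Fraction of planted features recovered by the selected consensus set:
    a planted feature counts as recovered when a selected feature of a
    compatible class lies within ``match_radius`` of its position."""
    from .rules import classes_compatible

    matched = []
    for i, pf in enumerate(planted):
        pos = np.asarray(pf.position)
        for cf in selected:
            if (classes_compatible(pf.cls, cf.cls)
                    and np.linalg.norm(np.asarray(cf.center) - pos)
                    <= match_radius):
                matched.append(i)
                break
    recall = len(matched) / len(planted) if planted else float("nan")
    return recall, matched
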