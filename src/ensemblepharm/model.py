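"""Model / Results interface over the ensemble-pharmacophore workflow.

:class:`EnsemblePharmacophoreModel` holds the data (a superposed labeled
conformational ensemble plus a binding-site definition) and the structural
hyper-parameters; ``fit()`` runs perception, consensus clustering, binary
encoding, frequency-band thresholding and four-method majority voting, and
returns a :class:`PharmacophoreResults` carrying the consensus features,
the per-feature statistics and ranks, the selected feature set, and a
``summary()`` table.  Screening a ligand library and computing enrichment
hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import (ConsensusFeature, OccurrenceMatrix, build_consensus,
                        encode_binary, threshold_by_frequency)
from .enrichment import ScreeningReport, screening_report
from .perception import PerceptionConfig, perceive_site
from .ranking import rank_and_vote
from .search import PharmacophoreQuery, build_query, search_library
from .structure_io import (ConformationEnsemble, LigandLibrary, SiteDefinition,
                           read_ensemble, superpose_ensemble)

__all__ = ["EnsemblePharmacophoreModel", "PharmacophoreResults"]


class EnsemblePharmacophoreModel:
    """Ensemble pharmacophore model of a labeled conformation set.

    Parameters
    ----------
    ensemble : ConformationEnsemble
        Superposed (or to-be-superposed) conformations of one binding site.
    labels : array-like of {0, 1}
        Per-frame binding class: 1 marks a binding-selected conformation.
    site : SiteDefinition
        Binding-site definition (residue list or reference-point proximity,
        default cutoff 6.5 A around the reference points).
    cluster_radius : float
        Leader-clustering radius for consensus features (A).
    superpose : bool
        Superpose the ensemble onto its first frame on the site heavy atoms
        before perception (skip when the input is already aligned).
    """

    def __init__(self, ensemble: ConformationEnsemble, labels,
                 site: SiteDefinition, cluster_radius: float = 1.5,
                 perception_config: PerceptionConfig | None = None,
                 superpose: bool = False):
        labels = np.asarray(labels, dtype=int)
        if len(labels) != ensemble.n_frames:
            raise ValueError("labels length must equal number of frames")
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be binary")
        if superpose:
            ensemble = superpose_ensemble(ensemble, site)
        self.ensemble = ensemble
        self.labels = labels
        self.site = site
        self.cluster_radius = float(cluster_radius)
        self.perception_config = perception_config or PerceptionConfig()
        self._per_frame = None
        self._consensus: list[ConsensusFeature] | None = None
        self._matrix: OccurrenceMatrix | None = None

    @classmethod
    def from_files(cls, ensemble_path, labels_path, site: SiteDefinition,
                   **kwargs) -> "EnsemblePharmacophoreModel":
        """Build from a multi-model PDB and a one-column label CSV
        (column ``label``, one row per frame in frame order)."""
        ensemble = read_ensemble(ensemble_path)
        labels = pd.read_csv(labels_path)["label"].to_numpy()
        return cls(ensemble, labels, site, **kwargs)

    # perception / consensus are label-independent; cache across fits
    @property
    def per_frame_features(self):
        if self._per_frame is None:
            self._per_frame = perceive_site(self.ensemble, self.site,
                                            self.perception_config)
        return self._per_frame

    @property
    def consensus(self) -> list[ConsensusFeature]:
        if self._consensus is None:
            self._consensus = build_consensus(self.per_frame_features,
                                              self.cluster_radius)
        return self._consensus

    @property
    def occurrence(self) -> OccurrenceMatrix:
        if self._matrix is None:
            self._matrix = encode_binary(self.consensus,
                                         self.per_frame_features, self.labels)
        return self._matrix

    def fit(self, band: tuple[float | None, float | None] = (None, None),
            k: int = 8, l_min: int = 2,
            manual_ids: list[str] | None = None) -> "PharmacophoreResults":
        """Threshold by frequency band, rank by the four statistics, vote.

        ``band=(low, high)`` keeps features with low <= frequency <= high
        (None bounds are open); ``k`` is the per-method top-k before voting.
        ``manual_ids`` overrides the voted selection with an explicit list
        (manual curation), leaving the vote table intact.
        """
        matrix = threshold_by_frequency(self.occurrence, band[0], band[1])
        votes = rank_and_vote(matrix, k=k, l_min=l_min)
        selected = (list(manual_ids) if manual_ids is not None
                    else [f for f in votes.index[votes["selected"]]])
        return PharmacophoreResults(self, matrix, votes, selected,
                                    band=band, k=k)


class PharmacophoreResults:
    """Fit results: banded occurrence matrix, vote table, selected features."""

    def __init__(self, model: EnsemblePharmacophoreModel,
                 matrix: OccurrenceMatrix, votes: pd.DataFrame,
                 selected_ids: list[str],
                 band: tuple[float | None, float | None], k: int):
        self.model = model
        self.matrix = matrix
        self.votes = votes
        self.selected_ids = list(selected_ids)
        self.band = band
        self.k = k

    def selected_features(self) -> list[ConsensusFeature]:
        by_id = {c.id: c for c in self.model.consensus}
        return [by_id[i] for i in self.selected_ids]

    def query(self, match_mode: str = "all",
              m: int | None = None) -> PharmacophoreQuery:
        """Pharmacophore query from the selected features (>=3 required)."""
        return build_query(self.model.consensus, self.selected_ids,
                           match_mode=match_mode, m=m)

    def screen(self, library: LigandLibrary, tolerance: float = 0.0,
               match_mode: str = "all", m: int | None = None
               ) -> ScreeningReport:
        """RMSD-screen a ligand library with the selected-feature query and
        tally the enrichment factor."""
        q = self.query(match_mode=match_mode, m=m)
        results, hits = search_library(q, library, tolerance=tolerance)
        report = screening_report(hits, library)
        report.match_results = results  # attach per-molecule detail
        return report

    def summary(self) -> str:
        """Human-readable fit summary in the style of a regression table."""
        lo = 0.0 if self.band[0] is None else self.band[0]
        hi = "none" if self.band[1] is None else f"{self.band[1]:.0%}"
        lines = [
            "Ensemble Pharmacophore Model — majority-vote feature selection",
            "=" * 66,
            f"Frames:             {self.model.ensemble.n_frames}"
            f"  (binding: {int(self.model.labels.sum())})",
            f"Consensus features: {len(self.model.consensus)}"
            f"  (in band: {len(self.matrix.feature_ids)})",
            f"Frequency band:     [{lo:.0%}, {hi}]    top-k: {self.k}",
            f"Selected (score 4): {len(self.selected_ids)}",
            "-" * 66,
        ]
        cols = ["f_value", "mi", "rqa_entr", "spearman_abs", "score"]
        header = f"{'feature':<14}" + "".join(f"{c:>13}" for c in cols) + "  sel"
        lines.append(header)
        for fid, row in self.votes.iterrows():
            vals = "".join(
                f"{row[c]:>13.4g}" if c != "score" else f"{int(row[c]):>13d}"
                for c in cols)
            lines.append(f"{fid:<14}" + vals
                         + ("    *" if row["selected"] else ""))
        lines.append("=" * 66)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<PharmacophoreResults: {len(self.selected_ids)} selected of "
                f"{len(self.matrix.feature_ids)} in band, k={self.k}>")
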