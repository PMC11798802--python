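"""Enrichment factor and screening summaries.

The enrichment factor used here is a hit-ratio EF:

    EF = (active_hits / decoy_hits) / (actives_total / decoys_total)

i.e. the active:decoy odds among the molecules passing the pharmacophore
filter, relative to the odds in the screened database.  EF = 1 means the
filter is no better than proportional sampling.  Edge cases are flagged,
never silently propagated: no decoy hits with at least one active hit is an
infinite-EF sentinel ("no-decoy-hits"); no active hits gives EF = 0; an
empty hit list is "NA" (nothing passed the filter, so no enrichment is
defined).

A conventional top-x% EF (active fraction among the top x% by RMSD over the
active fraction of the database) is provided as a clearly separate extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure_io import LigandLibrary

__all__ = ["ScreenCounts", "EFResult", "enrichment_factor", "screening_report"]


@dataclass
class ScreenCounts:
    active_hits: int
    decoy_hits: int
    actives_total: int
    decoys_total: int

    def __post_init__(self):
        if self.actives_total <= 0 or self.decoys_total < 0:
            raise ValueError("library totals must be positive")
        if not (0 <= self.active_hits <= self.actives_total):
            raise ValueError("active_hits out of range")
        if not (0 <= self.decoy_hits <= self.decoys_total):
            raise ValueError("decoy_hits out of range")


@dataclass
class EFResult:
    value: float          # inf for the no-decoy-hits sentinel, nan for NA
    flag: str | None = None  # None | "no-decoy-hits" | "NA"

    @property
    def is_na(self) -> bool:
        return self.flag == "NA"

    def __str__(self) -> str:
        if self.is_na:
            return "NA"
        if self.flag == "no-decoy-hits":
            return "inf (no decoy hits)"
        return f"{self.value:.2f}"


def enrichment_factor(counts: ScreenCounts) -> EFResult:
    """Hit-ratio enrichment factor with flagged edge cases.

    A decoy-free library (decoys_total = 0) can only yield the NA or
    no-decoy-hits sentinel — the base odds are undefined."""
    if counts.active_hits == 0 and counts.decoy_hits == 0:
        return EFResult(float("nan"), "NA")
    if counts.decoy_hits == 0:
        return EFResult(float("inf"), "no-decoy-hits")
    if counts.active_hits == 0:
        return EFResult(0.0)
    base = counts.actives_total / counts.decoys_total
    return EFResult((counts.active_hits / counts.decoy_hits) / base)


@dataclass
class ScreeningReport:
    counts: ScreenCounts
    ef: EFResult
    active_hit_ids: list[str] = field(default_factory=list)
    decoy_hit_ids: list[str] = field(default_factory=list)
    unknown_hit_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "active_hits": self.counts.active_hits,
            "decoy_hits": self.counts.decoy_hits,
            "actives_total": self.counts.actives_total,
            "decoys_total": self.counts.decoys_total,
            "ef": None if self.ef.is_na else self.ef.value,
            "ef_flag": self.ef.flag,
            "active_hit_ids": self.active_hit_ids,
            "decoy_hit_ids": self.decoy_hit_ids,
            "unknown_hit_ids": self.unknown_hit_ids,
        }


def screening_report(hits: list[str], library: LigandLibrary) -> ScreeningReport:
    """Tally a hit list against the library's activity classes.

    Molecules of unknown class are listed separately and excluded from the
    EF (with a warning), so a partially annotated library cannot silently
    bias the enrichment.
    """
    import warnings

    activity = {m.mol_id: m.activity for m in library.molecules}
    hit_set = set(hits)
    unknown_ids = [m for m in hits if activity.get(m) not in ("active", "decoy")]
    if unknown_ids:
        warnings.warn(f"{len(unknown_ids)} hits with unknown activity class "
                      "excluded from EF", stacklevel=2)
    active_ids = [m.mol_id for m in library.actives if m.mol_id in hit_set]
    decoy_ids = [m.mol_id for m in library.decoys if m.mol_id in hit_set]
    counts = ScreenCounts(
        active_hits=len(active_ids), decoy_hits=len(decoy_ids),
        actives_total=len(library.actives), decoys_total=len(library.decoys))
    return ScreeningReport(counts, enrichment_factor(counts),
                           active_ids, decoy_ids, unknown_ids)


def ef_at_fraction(rmsds: dict[str, float], library: LigandLibrary,
                   fraction: float = 0.01) -> float:
    """Conventional EF@x%: actives fraction among the best-RMSD x% of
    matched molecules over the actives fraction of the whole library.
    Separate from the hit-ratio EF above; off by default in reports."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    activity = {m.mol_id: m.activity for m in library.molecules}
    ranked = sorted(rmsds.items(), key=lambda kv: (kv[1], kv[0]))
    n_top = max(1, int(round(fraction * len(library))))
    top = ranked[:n_top]
    if not top:
        return float("nan")
    act_top = sum(1 for mid, _ in top if activity.get(mid) == "active")
    base = len(library.actives) / len(library)
    return (act_top / len(top)) / base
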