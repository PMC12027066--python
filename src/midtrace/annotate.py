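"""Candidate-compound matching by m/z and adduct, and neighbor-guided
selection of the most plausible candidate for unknown peaks.

Unknown peaks are matched against a compound list (id, name, formula,
monoisotopic neutral mass) within a ppm tolerance over a small set of
common adducts.  Candidates are then screened for consistency with the
observed 13C labeling (a peak showing M+6 labeling cannot be a 5-carbon
compound) and scored by structure-class tag overlap with the peak's nearest
previously known neighbors in MID-distance space — a reproducible stand-in
for the manual "structurally similar to nearby knowns" judgment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mid import DistanceMatrix, PeakTable, nearest_neighbors
from .preprocess import CorrectionModel, correct_natural_abundance

__all__ = [
    "AdductSpec",
    "DEFAULT_ADDUCTS",
    "Compound",
    "CompoundTable",
    "Candidate",
    "AnnotationResult",
    "match_mz",
    "max_labeled_carbons",
    "neighbor_support",
    "annotate_peaks",
    "formula_monoisotopic_mass",
    "formula_carbon_count",
]

PROTON_MASS = 1.007276
NH4_SHIFT = 18.033823
H2O_MASS = 18.010565


@dataclass(frozen=True)
class AdductSpec:
    """Neutral-mass-to-m/z transform: m/z = neutral + mass_shift (|charge|=1)."""

    name: str
    mass_shift: float
    polarity: str  # "+" or "-"


DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("M+H", PROTON_MASS, "+"),
    AdductSpec("M-H", -PROTON_MASS, "-"),
    AdductSpec("M+NH4", NH4_SHIFT, "+"),
    AdductSpec("M+H-H2O", PROTON_MASS - H2O_MASS, "+"),
    AdductSpec("M-H-H2O", -PROTON_MASS - H2O_MASS, "-"),
)


def formula_monoisotopic_mass(formula: str) -> float:
    from pyteomics.mass import calculate_mass

    return float(calculate_mass(formula=formula))


def formula_carbon_count(formula: str) -> int:
    from pyteomics.mass import Composition

    return int(Composition(formula=formula).get("C", 0))


@dataclass
class Compound:
    compound_id: str
    name: str
    formula: str | None = None
    monoisotopic_mass: float | None = None
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.monoisotopic_mass is None:
            if not self.formula:
                raise ValueError(
                    f"compound {self.compound_id!r}: need a formula or a mass"
                )
            self.monoisotopic_mass = formula_monoisotopic_mass(self.formula)
        elif self.formula:
            expected = formula_monoisotopic_mass(self.formula)
            if abs(expected - self.monoisotopic_mass) > 1e-4:
                raise ValueError(
                    f"compound {self.compound_id!r}: mass "
                    f"{self.monoisotopic_mass} inconsistent with formula "
                    f"{self.formula} ({expected:.6f})"
                )

    @property
    def n_carbons(self) -> int | None:
        if self.formula:
            return formula_carbon_count(self.formula)
        return None


class CompoundTable:
    """Candidate compounds (an HMDB-style extract) keyed by id."""

    def __init__(self, compounds=()):
        self.compounds: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.compound_id in self.compounds:
            raise ValueError(f"duplicate compound id {compound.compound_id!r}")
        self.compounds[compound.compound_id] = compound

    def __len__(self):
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds.values())

    @classmethod
    def read(cls, path) -> "CompoundTable":
        df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
        out = cls()
        for _, row in df.iterrows():
            mass = row.get("monoisotopic_mass")
            tags = row.get("tags", "")
            out.add(
                Compound(
                    compound_id=str(row["compound_id"]),
                    name=str(row.get("name", row["compound_id"])),
                    formula=(
                        None
                        if pd.isna(row.get("formula")) or row.get("formula") == ""
                        else str(row["formula"])
                    ),
                    monoisotopic_mass=None if pd.isna(mass) else float(mass),
                    tags=frozenset(
                        t for t in str("" if pd.isna(tags) else tags).split(";") if t
                    ),
                )
            )
        return out

    def write(self, path) -> None:
        rows = [
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "formula": c.formula or "",
                "monoisotopic_mass": repr(c.monoisotopic_mass),
                "tags": ";".join(sorted(c.tags)),
            }
            for c in self.compounds.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Candidate:
    compound_id: str
    adduct: str
    ppm_error: float
    carbon_consistent: bool = True
    neighbor_score: int = 0


@dataclass
class AnnotationResult:
    peak_id: str
    candidates: list[Candidate] = field(default_factory=list)
    call: str | None = None  # compound id, or None for "undetermined"

    @property
    def undetermined(self) -> bool:
        return self.call is None


def match_mz(
    mz: float,
    polarity: str,
    compounds: CompoundTable,
    adducts=DEFAULT_ADDUCTS,
    tolerance_ppm: float = 10.0,
    n_carbons: int | None = None,
) -> list[Candidate]:
    """Candidates whose theoretical adduct m/z lies within ``tolerance_ppm``.

    The adduct set is restricted to the peak's ionization polarity.  When the
    peak's carbon count (MID length) is known, candidates whose formula
    carbon count differs are excluded.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if polarity not in ("+", "-"):
        raise ValueError("polarity must be '+' or '-'")
    out: list[Candidate] = []
    for compound in sorted(compounds, key=lambda c: c.compound_id):
        if n_carbons is not None and compound.n_carbons is not None:
            if compound.n_carbons != n_carbons:
                continue
        for adduct in adducts:
            if adduct.polarity != polarity:
                continue
            theo = compound.monoisotopic_mass + adduct.mass_shift
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                out.append(Candidate(compound.compound_id, adduct.name, ppm))
    return out


def max_labeled_carbons(
    peak, model: CorrectionModel | None = None, floor: float = 0.01
) -> dict[str, int]:
    """Largest observed 13C atom count per experiment.

    The count is the highest MI index whose natural-abundance-corrected
    fraction exceeds ``floor``.
    """
    if model is None:
        model = CorrectionModel()
    out: dict[str, int] = {}
    for exp, mid in peak.mids.items():
        corr = correct_natural_abundance(mid, model)
        above = np.nonzero(corr.fractions > floor)[0]
        out[exp] = int(above.max()) if above.size else 0
    return out


def neighbor_support(
    peak_id: str,
    candidates: list[Candidate],
    distances: DistanceMatrix,
    table: PeakTable,
    compounds: CompoundTable,
    k: int = 20,
    score_threshold: int = 1,
    model: CorrectionModel | None = None,
    labeling_floor: float = 0.01,
) -> AnnotationResult:
    """Rank candidates by structure-tag overlap with nearby known peaks.

    A candidate is rejected outright if, in any experiment, the peak shows
    more labeled carbons than the candidate's formula contains.  Remaining
    candidates score the maximum tag overlap with the annotations of the k
    nearest *known* neighbors; the top candidate is called only if its score
    reaches ``score_threshold``, otherwise the peak stays undetermined for
    human review.  Ordering is deterministic (score desc, |ppm|, id).
    """
    peak = table.peaks[peak_id]
    observed = max_labeled_carbons(peak, model, labeling_floor)
    max_obs = max(observed.values(), default=0)
    known_ids = [
        pid for pid in distances.ids if pid != peak_id and table.peaks[pid].known
    ]
    neighbor_tags: list[frozenset[str]] = []
    if known_ids:
        ordered = nearest_neighbors(peak_id, distances, len(distances.ids) - 1)
        known_ranked = [nid for nid, _, _ in ordered if nid in set(known_ids)]
        for nid in known_ranked[:k]:
            ann = table.peaks[nid].annotation
            if ann and ann in compounds.compounds:
                neighbor_tags.append(compounds.compounds[ann].tags)
    scored: list[Candidate] = []
    for cand in candidates:
        compound = compounds.compounds[cand.compound_id]
        n_c = compound.n_carbons
        consistent = n_c is None or max_obs <= n_c
        score = 0
        if neighbor_tags and compound.tags:
            score = max(len(compound.tags & tags) for tags in neighbor_tags)
        scored.append(
            Candidate(
                cand.compound_id,
                cand.adduct,
                cand.ppm_error,
                carbon_consistent=consistent,
                neighbor_score=score,
            )
        )
    kept = [c for c in scored if c.carbon_consistent]
    kept.sort(key=lambda c: (-c.neighbor_score, abs(c.ppm_error), c.compound_id))
    call = None
    if kept and neighbor_tags and kept[0].neighbor_score >= score_threshold:
        call = kept[0].compound_id
    return AnnotationResult(peak_id=peak_id, candidates=kept, call=call)


def annotate_peaks(
    table: PeakTable,
    distances: DistanceMatrix,
    compounds: CompoundTable,
    adducts=DEFAULT_ADDUCTS,
    tolerance_ppm: float = 10.0,
    k: int = 20,
    score_threshold: int = 1,
) -> list[AnnotationResult]:
    """Annotate every unknown peak: m/z match then neighbor-guided selection."""
    out = []
    for pid in sorted(table.peaks):
        peak = table.peaks[pid]
        if peak.known or math.isnan(peak.mz):
            continue
        cands = match_mz(
            peak.mz,
            peak.polarity,
            compounds,
            adducts,
            tolerance_ppm,
            n_carbons=peak.n_carbons,
        )
        out.append(
            neighbor_support(
                pid, cands, distances, table, compounds, k, score_threshold
            )
        )
    return out


def annotations_to_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        if not res.candidates:
            rows.append(
                {
                    "peak_id": res.peak_id,
                    "compound_id": "",
                    "adduct": "",
                    "ppm_error": float("nan"),
                    "neighbor_score": 0,
                    "call": res.call or "undetermined",
                }
            )
        for cand in res.candidates:
            rows.append(
                {
                    "peak_id": res.peak_id,
                    "compound_id": cand.compound_id,
                    "adduct": cand.adduct,
                    "ppm_error": cand.ppm_error,
                    "neighbor_score": cand.neighbor_score,
                    "call": res.call or "undetermined",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "compound_id", "adduct", "ppm_error", "neighbor_score", "call"],
    )
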