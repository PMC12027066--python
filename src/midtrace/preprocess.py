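"""Natural-13C correction and peak/isotopomer filtering for MID tables.

The correction removes the contribution of naturally occurring 13C (~1.07%)
from measured MIDs: with j of n carbons tracer-labeled, the n-j remaining
positions each carry a natural 13C with probability p13, shifting mass by a
Binomial(n-j, p13) amount.  Only the tracer element (carbon) is considered;
non-carbon isotopes are assumed removed upstream.

Filters encode the processing rules used for untargeted 13C data sets:
unlabeled peaks are dropped (max corrected enrichment over labeled substrates
< 10%), and "false" mass isotopomers arising from peak overlap are zeroed
when a non-base MI exceeds 0.03 in more than 10 experiments after correction.
MID distances downstream are computed on uncorrected MIDs; corrections here
are used only for the filter tests (and for display).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .mid import MIDVector, PeakTable, enrichment, normalize, pairwise_distances

__all__ = [
    "CorrectionModel",
    "FilterReport",
    "correct_natural_abundance",
    "apply_natural_abundance",
    "correct_table",
    "enrichment_filter",
    "false_isotopomer_filter",
    "group_coeluting_artefacts",
]

P13_DEFAULT = 0.0107


class CorrectionModel:
    """Binomial natural-13C correction matrices, cached per carbon count.

    ``matrix(n)[k, j] = C(n-j, k-j) * p13**(k-j) * (1-p13)**(n-k)`` is the
    probability that a molecule with j tracer carbons is measured at M+k.
    p13 = 0 yields identity matrices.
    """

    def __init__(self, p13: float = P13_DEFAULT):
        if not 0.0 <= p13 < 0.5:
            raise ValueError("p13 must be in [0, 0.5)")
        self.p13 = float(p13)
        self._cache: dict[int, np.ndarray] = {}

    def matrix(self, n_carbons: int) -> np.ndarray:
        m = self._cache.get(n_carbons)
        if m is None:
            n = n_carbons
            p = self.p13
            m = np.zeros((n + 1, n + 1))
            from math import comb

            for j in range(n + 1):
                for k in range(j, n + 1):
                    m[k, j] = comb(n - j, k - j) * p ** (k - j) * (1 - p) ** (n - k)
            self._cache[n_carbons] = m
        return m


def apply_natural_abundance(x: MIDVector, model: CorrectionModel) -> MIDVector:
    """Forward model: predict the measured MID from a natural-13C-free one."""
    out = model.matrix(x.n_carbons) @ x.fractions
    return MIDVector(out / out.sum())


def correct_natural_abundance(
    x: MIDVector, model: CorrectionModel, clip_tol: float = 1e-10
) -> MIDVector:
    """Invert the natural-abundance model (exact lower-triangular solve).

    When the exact solution has negative components (noise), falls back to
    non-negative least squares, then renormalizes.
    """
    m = model.matrix(x.n_carbons)
    sol = solve_triangular(m, x.fractions, lower=True)
    if np.any(sol < -clip_tol):
        sol, _ = nnls(m, x.fractions)
    sol = np.clip(sol, 0.0, None)
    total = sol.sum()
    if total <= 0:
        raise ValueError("natural-abundance correction produced an empty MID")
    return MIDVector(sol / total)


def correct_table(table: PeakTable, model: CorrectionModel) -> PeakTable:
    """Return a copy of the table with every MID corrected (for display)."""
    out = table.copy()
    for peak in out.peaks.values():
        for exp, mid in list(peak.mids.items()):
            peak.mids[exp] = correct_natural_abundance(mid, model)
    out.corrected = True
    return out


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int
    removed: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Ordered record of filtering stages with input/output peak counts."""

    stages: list[FilterStage] = field(default_factory=list)
    #: (peak_id, mi_index) pairs zeroed by the false-isotopomer filter
    zeroed: list[tuple[str, int]] = field(default_factory=list)

    def add_stage(self, stage: FilterStage) -> None:
        self.stages.append(stage)

    def to_json(self, path=None) -> str:
        payload = {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "removed": s.removed,
                    "details": s.details,
                }
                for s in self.stages
            ],
            "zeroed": [[pid, int(mi)] for pid, mi in self.zeroed],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_zeroing_mask(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            sorted(self.zeroed), columns=["peak_id", "mi_index"]
        ).to_csv(path, sep="\t", index=False)


def enrichment_filter(
    table: PeakTable,
    threshold: float = 0.10,
    model: CorrectionModel | None = None,
    unlabeled_controls: Iterable[str] = (),
    report: FilterReport | None = None,
) -> tuple[PeakTable, FilterReport]:
    """Retain peaks with >= ``threshold`` 13C enrichment in some labeled experiment.

    Enrichment is evaluated on natural-abundance-corrected MIDs; experiments
    listed in ``unlabeled_controls`` are excluded from the maximum.  The
    boundary is inclusive ("at least 10%").
    """
    if model is None:
        model = CorrectionModel()
    controls = set(unlabeled_controls)
    labeled = [e for e in table.experiments if e not in controls]
    if not labeled:
        raise ValueError("table has no labeled experiment")
    report = report or FilterReport()
    keep: list[str] = []
    removed: list[str] = []
    no_data: list[str] = []
    for pid in sorted(table.peaks):
        peak = table.peaks[pid]
        if peak.n_carbons < 1:
            removed.append(pid)
            continue
        values = [
            enrichment(correct_natural_abundance(peak.mids[e], model))
            for e in labeled
            if e in peak.mids
        ]
        if not values:
            no_data.append(pid)
        elif max(values) >= threshold:
            keep.append(pid)
        else:
            removed.append(pid)
    out = table.subset(keep)
    report.add_stage(
        FilterStage(
            name="enrichment_filter",
            n_in=len(table),
            n_out=len(out),
            removed=removed + no_data,
            details={
                "threshold": threshold,
                "no_labeled_data": no_data,
                "unlabeled_controls": sorted(controls),
            },
        )
    )
    return out, report


def false_isotopomer_filter(
    table: PeakTable,
    mi_threshold: float = 0.03,
    experiment_count: int = 10,
    model: CorrectionModel | None = None,
    include_controls: bool = True,
    unlabeled_controls: Iterable[str] = (),
    report: FilterReport | None = None,
) -> tuple[PeakTable, FilterReport]:
    """Zero mass isotopomers that look like overlapping-peak artefacts.

    For each peak, any MI above the base isotopomer whose *corrected* fraction
    exceeds ``mi_threshold`` in strictly more than ``experiment_count``
    experiments is set to zero in every experiment (on the stored, uncorrected
    fractions), and the MIDs renormalized.  M+0 is never zeroed.
    """
    if model is None:
        model = CorrectionModel()
    controls = set(unlabeled_controls)
    exps = [
        e for e in table.experiments if include_controls or e not in controls
    ]
    report = report or FilterReport()
    out = table.copy()
    zeroed: list[tuple[str, int]] = []
    for pid in sorted(out.peaks):
        peak = out.peaks[pid]
        n = peak.n_carbons
        if n < 1:
            continue
        counts = np.zeros(n + 1, dtype=int)
        for e in exps:
            if e not in peak.mids:
                continue
            corr = correct_natural_abundance(peak.mids[e], model)
            counts += corr.fractions > mi_threshold
        bad = [i for i in range(1, n + 1) if counts[i] > experiment_count]
        if not bad:
            continue
        for i in bad:
            zeroed.append((pid, i))
        for e, mid in list(peak.mids.items()):
            fr = mid.fractions.copy()
            fr[bad] = 0.0
            peak.mids[e] = normalize(fr)
    report.zeroed.extend(zeroed)
    report.add_stage(
        FilterStage(
            name="false_isotopomer_filter",
            n_in=len(table),
            n_out=len(out),
            details={
                "mi_threshold": mi_threshold,
                "experiment_count": experiment_count,
                "n_zeroed": len(zeroed),
            },
        )
    )
    return out, report


def group_coeluting_artefacts(
    table: PeakTable,
    rt_tolerance: float = 5.0,
    d_cutoff: float = 0.3,
    distances=None,
) -> list[dict]:
    """Group co-eluting peaks with similar MIDs (in-source fragments/adducts).

    Peaks within ``rt_tolerance`` seconds of each other AND with pairwise
    multi-experiment MID distance < ``d_cutoff`` are merged by single linkage.
    Co-eluting peaks with dissimilar MIDs stay separate: distinct labeling
    rules out a shared source molecule.  Each group reports a representative
    (largest carbon count, then lowest id).  Returns a list of dicts with
    ``members``, ``representative`` and ``excluded_no_rt``.
    """
    import math as _math

    with_rt = [
        pid
        for pid in sorted(table.peaks)
        if not _math.isnan(table.peaks[pid].rt_seconds)
    ]
    no_rt = [pid for pid in sorted(table.peaks) if pid not in set(with_rt)]
    if distances is None and len(with_rt) >= 2:
        distances = pairwise_distances(table.subset(with_rt))
    # union-find single linkage
    parent = {pid: pid for pid in with_rt}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(with_rt):
        for b in with_rt[i + 1 :]:
            if abs(table.peaks[a].rt_seconds - table.peaks[b].rt_seconds) > rt_tolerance:
                continue
            d = distances.distance(a, b)
            res = distances.result(a, b)
            if _math.isnan(d) or res.is_sentinel or d >= d_cutoff:
                continue
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = {}
    for pid in with_rt:
        clusters.setdefault(find(pid), []).append(pid)
    groups = []
    for members in clusters.values():
        members.sort()
        rep = sorted(
            members, key=lambda pid: (-table.peaks[pid].n_carbons, pid)
        )[0]
        groups.append({"members": members, "representative": rep})
    groups.sort(key=lambda g: g["representative"])
    if no_rt:
        groups.append({"members": [], "representative": None, "excluded_no_rt": no_rt})
    return groups
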