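"""Simulation-study metrics: precision-recall of the MID distance against the
carbon-contribution gold standard, robustness to noise and metabolite dropout,
neighbor-rank and discoverability statistics, and greedy tracer selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .mid import (
    DistanceMatrix,
    ExperimentSet,
    PeakTable,
    nearest_neighbors,
    pairwise_distances,
)
from .simulate import add_noise

__all__ = [
    "PRCurve",
    "RankReport",
    "precision_recall",
    "aupr",
    "noise_robustness",
    "dropout_robustness",
    "discoverability",
    "neighbor_ranks",
    "greedy_tracer_selection",
]

PairSet = set  # of frozenset({peak_a, peak_b})


@dataclass
class PRCurve:
    """Precision-recall points swept over the distance threshold (ascending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    prevalence: float
    n_positive: int
    n_pairs: int
    n_sentinel_excluded: int = 0
    n_incomparable_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "recall": self.recall,
                "precision": self.precision,
            }
        )


def _comparable_pairs(
    distances: DistanceMatrix, sentinel_rank_last: bool = False
) -> tuple[list[tuple[str, str, float]], int, int]:
    pairs: list[tuple[str, str, float]] = []
    n_sentinel = 0
    n_incomparable = 0
    sentinel_pairs: list[tuple[str, str, float]] = []
    for res in distances.results():
        if math.isnan(res.distance):
            n_incomparable += 1
            continue
        if res.is_sentinel:
            n_sentinel += 1
            sentinel_pairs.append((res.peak_a, res.peak_b, res.distance))
            continue
        pairs.append((res.peak_a, res.peak_b, res.distance))
    if sentinel_rank_last:
        pairs.extend(sentinel_pairs)
        n_sentinel = 0
    return pairs, n_sentinel, n_incomparable


def precision_recall(
    distances: DistanceMatrix,
    labels: PairSet,
    sentinel_rank_last: bool = False,
) -> PRCurve:
    """PR curve of the distance ranking against a positive-pair label set.

    Missing-convolutant (sentinel) pairs carry no information and are
    excluded from the sweep by default (``sentinel_rank_last=True`` instead
    appends them at the maximum distance); incomparable pairs are always
    excluded.  Precision = TP/(TP+FP) and recall = TP/P at each unique
    distance threshold; AUPR integrates precision over recall by trapezoids
    with an initial point at (0, precision of the smallest threshold).
    """
    pairs, n_sent, n_inc = _comparable_pairs(distances, sentinel_rank_last)
    if not pairs:
        raise ValueError("no comparable pairs")
    d = np.array([p[2] for p in pairs])
    y = np.array([frozenset((p[0], p[1])) in labels for p in pairs], dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive pairs among comparable pairs")
    order = np.argsort(d, kind="stable")
    d, y = d[order], y[order]
    # group tied distances: cumulative counts at each unique threshold
    uniq, last_idx = np.unique(d, return_index=True)
    # index of the last occurrence of each unique value
    ends = np.append(last_idx[1:], d.size) - 1
    tp = np.cumsum(y)[ends]
    n_pred = ends + 1
    precision = tp / n_pred
    recall = tp / n_pos
    auc = float(np.trapezoid(np.concatenate([[precision[0]], precision]),
                             np.concatenate([[0.0], recall])))
    return PRCurve(
        thresholds=uniq,
        precision=precision,
        recall=recall,
        auc=auc,
        prevalence=n_pos / len(pairs),
        n_positive=n_pos,
        n_pairs=len(pairs),
        n_sentinel_excluded=n_sent,
        n_incomparable_excluded=n_inc,
    )


def aupr(distances: DistanceMatrix, labels: PairSet, **kwargs) -> float:
    return precision_recall(distances, labels, **kwargs).auc


def noise_robustness(
    clean_table: PeakTable,
    labels: PairSet,
    noise_sds: Sequence[float],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """AUPR per noise level: Gaussian MI noise re-drawn per replicate.

    Returns a tidy frame (noise_sd, replicate, aupr); AUPR is expected to
    degrade with noise on average, which is reported, not enforced here.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(noise_sds) * replicates)
    rows = []
    for i, sd in enumerate(noise_sds):
        for rep in range(replicates):
            rng = np.random.default_rng(children[i * replicates + rep])
            noisy = add_noise(clean_table, sd, rng)
            value = aupr(pairwise_distances(noisy), labels)
            rows.append({"noise_sd": sd, "replicate": rep, "aupr": value})
    return pd.DataFrame(rows)


def dropout_robustness(
    table: PeakTable,
    labels: PairSet,
    keep_fractions: Sequence[float],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """AUPR when random metabolite subsets are retained.

    Distances are recomputed within each subset (the missing-convolutant
    sentinel binds harder on small subsets); labels are restricted to the
    subset.  Replicates whose subset has no positive pair are skipped and
    flagged.  Returns (keep_fraction, replicate, n_peaks, aupr, skipped).
    """
    ids = sorted(table.peaks)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(keep_fractions) * replicates)
    rows = []
    for i, frac in enumerate(keep_fractions):
        if not 0.0 < frac <= 1.0:
            raise ValueError("keep fraction must be in (0, 1]")
        n_keep = max(2, int(round(frac * len(ids))))
        for rep in range(replicates):
            rng = np.random.default_rng(children[i * replicates + rep])
            subset = sorted(rng.choice(ids, size=n_keep, replace=False))
            sub_labels = {
                p for p in labels if all(m in set(subset) for m in p)
            }
            row = {
                "keep_fraction": frac,
                "replicate": rep,
                "n_peaks": n_keep,
                "aupr": float("nan"),
                "skipped": False,
            }
            if not sub_labels:
                row["skipped"] = True
            else:
                sub = table.subset(subset)
                try:
                    row["aupr"] = aupr(pairwise_distances(sub), sub_labels)
                except ValueError:
                    row["skipped"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def discoverability(
    distances: DistanceMatrix,
    labels: PairSet,
    k: int = 20,
    min_fraction: float = 0.5,
) -> tuple[dict[str, bool], float]:
    """Which metabolites recover >= ``min_fraction`` of their true biochemical
    partners among their k nearest neighbors.

    Metabolites with no true partner are excluded from the overall fraction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    partners: dict[str, set[str]] = {pid: set() for pid in distances.ids}
    for pair in labels:
        a, b = tuple(pair)
        if a in partners and b in partners:
            partners[a].add(b)
            partners[b].add(a)
    flags: dict[str, bool] = {}
    n_eligible = 0
    n_discoverable = 0
    for pid in distances.ids:
        true_set = partners[pid]
        if not true_set:
            continue
        n_eligible += 1
        top = {nid for nid, _, _ in nearest_neighbors(pid, distances, k)}
        frac = len(true_set & top) / len(true_set)
        flags[pid] = frac >= min_fraction
        n_discoverable += flags[pid]
    overall = n_discoverable / n_eligible if n_eligible else float("nan")
    return flags, overall


@dataclass
class RankReport:
    """Distance ranks of each metabolite's true partners vs a random baseline."""

    ranks: dict[str, list[int]]
    median_rank: float
    random_median_rank: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peak_id": pid, "partner_rank": r}
            for pid, rs in self.ranks.items()
            for r in rs
        ]
        return pd.DataFrame(rows, columns=["peak_id", "partner_rank"])


def neighbor_ranks(
    distances: DistanceMatrix, labels: PairSet, seed: int = 0
) -> RankReport:
    """1-based rank of every true partner in each metabolite's neighbor list."""
    rng = np.random.default_rng(seed)
    n_other = len(distances.ids) - 1
    ranks: dict[str, list[int]] = {}
    random_ranks: list[int] = []
    all_ranks: list[int] = []
    for pid in distances.ids:
        true_set = {
            next(iter(pair - {pid}))
            for pair in labels
            if pid in pair
        }
        if not true_set:
            continue
        ordered = [nid for nid, _, _ in nearest_neighbors(pid, distances, n_other)]
        rs = sorted(ordered.index(t) + 1 for t in true_set if t in ordered)
        ranks[pid] = rs
        all_ranks.extend(rs)
        random_ranks.extend(
            rng.choice(n_other, size=len(rs), replace=False) + 1
        )
    return RankReport(
        ranks=ranks,
        median_rank=float(np.median(all_ranks)) if all_ranks else float("nan"),
        random_median_rank=(
            float(np.median(random_ranks)) if random_ranks else float("nan")
        ),
    )


def greedy_tracer_selection(
    table: PeakTable, labels: PairSet
) -> list[tuple[str, float]]:
    """Forward selection of tracer experiments by combined-distance AUPR.

    Starts from the single best experiment; each step adds the experiment
    maximizing the AUPR of distances recomputed from scratch on the grown
    subset.  Ties break toward the lexicographically smaller experiment name.
    Returns (experiment, cumulative AUPR) in selection order; the final entry
    equals the all-experiment AUPR.
    """
    experiments = list(table.experiments)
    if len(experiments) < 2:
        raise ValueError("need at least two tracer experiments")
    selected: list[str] = []
    out: list[tuple[str, float]] = []
    remaining = sorted(experiments)
    while remaining:
        best_name, best_value = None, -np.inf
        for cand in remaining:
            subset = ExperimentSet(selected + [cand])
            value = aupr(pairwise_distances(table, subset), labels)
            if value > best_value:
                best_name, best_value = cand, value
        selected.append(best_name)
        remaining.remove(best_name)
        out.append((best_name, best_value))
    return out
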