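"""Mass isotopomer distributions (MIDs) and the convolution-based MID distance.

An n-carbon compound has n+1 mass isotopomers (M+0 ... M+n); its MID is the
vector of their fractional abundances.  Two compounds A (m carbons) and B
(n carbons, m <= n) are compared by searching, over all measured compounds C
with n-m carbons ("convolutants"), for the convolution of A's and C's MIDs
that best matches B's MID.  Across parallel labeling experiments the Euclidean
distances are summed per experiment and the minimum is taken over convolutants.
A small distance suggests B is biosynthesized from A plus a C-sized moiety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MIDVector",
    "ExperimentSet",
    "Peak",
    "PeakTable",
    "DistanceResult",
    "DistanceMatrix",
    "EmptyMIDError",
    "normalize",
    "convolve",
    "enrichment",
    "euclidean_mid_distance",
    "mid_distance",
    "pairwise_distances",
    "nearest_neighbors",
    "threshold_network",
    "read_peak_table",
    "write_peak_table",
]

#: marker used in DistanceResult.best_convolutant for equal-carbon pairs
DIRECT = "direct"
#: marker for pairs where no convolutant of the required size exists
NO_CONVOLUTANT = "none"

_SUM_TOL = 1e-9


class EmptyMIDError(ValueError):
    """Raised when a raw intensity vector contains no signal."""


class IncomparablePairError(ValueError):
    """Raised when two peaks share no labeling experiment."""


class MIDVector:
    """Fractional abundances of the n+1 mass isotopomers of an n-carbon species.

    Parameters
    ----------
    fractions:
        Sequence of length ``n_carbons + 1``; non-negative, summing to 1.
    n_carbons:
        Optional; checked against ``len(fractions) - 1`` when given.
    """

    __slots__ = ("fractions",)

    def __init__(self, fractions: Sequence[float], n_carbons: int | None = None):
        arr = np.asarray(fractions, dtype=np.float64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("MID must be a non-empty 1-D sequence")
        if n_carbons is not None and arr.size != n_carbons + 1:
            raise ValueError(
                f"MID of length {arr.size} inconsistent with {n_carbons} carbons"
            )
        if np.any(arr < 0):
            raise ValueError("MID fractions must be non-negative")
        total = float(arr.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"MID fractions must sum to 1 (got {total!r})")
        self.fractions = arr

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    def __len__(self) -> int:
        return self.fractions.size

    def __eq__(self, other) -> bool:
        return isinstance(other, MIDVector) and np.array_equal(
            self.fractions, other.fractions
        )

    def __repr__(self) -> str:
        vals = ", ".join(f"{v:.4g}" for v in self.fractions)
        return f"MIDVector([{vals}])"


def normalize(fractions: Sequence[float], neg_tol: float = 1e-6) -> MIDVector:
    """Scale raw (peak-area) intensities to a MID summing to 1.

    Small negative entries (|x| <= ``neg_tol`` * max) are clipped to zero;
    larger negatives are rejected.  An all-zero input raises
    :class:`EmptyMIDError` so the caller can decide to drop the peak.
    """
    arr = np.asarray(fractions, dtype=np.float64).copy()
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a non-empty 1-D sequence")
    scale = float(np.max(np.abs(arr))) if arr.size else 0.0
    floor = -neg_tol * max(scale, 1.0)
    if np.any(arr < floor):
        raise ValueError("negative intensities beyond tolerance")
    arr[arr < 0] = 0.0
    total = float(arr.sum())
    if total <= 0.0:
        raise EmptyMIDError("empty MID: all intensities are zero")
    return MIDVector(arr / total)


def convolve(a: MIDVector, c: MIDVector) -> MIDVector:
    """MID of the molecule formed by joining the carbon skeletons of a and c.

    (a x c)_k = sum_{i+j=k} a_i c_j; the result has ``a.n_carbons +
    c.n_carbons`` carbons and sums to 1.
    """
    out = np.convolve(a.fractions, c.fractions)
    # renormalize away accumulated rounding so the invariant holds exactly
    return MIDVector(out / out.sum())


def enrichment(x: MIDVector, mode: str = "weighted") -> float:
    """Fractional 13C enrichment of a MID.

    ``weighted`` (default): sum_i i*x_i / n, the average fraction of carbon
    atoms that are 13C (0 = unlabeled, 1 = fully labeled).  ``any_labeled``:
    sum_{i>=1} x_i, the fraction of molecules carrying at least one 13C.
    """
    n = x.n_carbons
    if n < 1:
        raise ValueError("enrichment undefined for a 0-carbon species")
    if mode == "weighted":
        return float(np.dot(np.arange(n + 1), x.fractions) / n)
    if mode == "any_labeled":
        return float(x.fractions[1:].sum())
    raise ValueError(f"unknown enrichment mode {mode!r}")


def euclidean_mid_distance(a: MIDVector, b: MIDVector) -> float:
    """Euclidean norm ||a - b|| between two equal-carbon MIDs."""
    if a.n_carbons != b.n_carbons:
        raise ValueError(
            "carbon-count mismatch: use the convolutant search for unequal sizes"
        )
    return float(np.linalg.norm(a.fractions - b.fractions))


@dataclass
class Peak:
    """One LCMS peak with per-experiment MIDs."""

    peak_id: str
    n_carbons: int
    mz: float = float("nan")
    rt_seconds: float = float("nan")
    polarity: str = "+"
    formula: str | None = None
    known: bool = False
    annotation: str | None = None
    mids: dict[str, MIDVector] = field(default_factory=dict)

    def set_mid(self, experiment: str, mid: MIDVector) -> None:
        if mid.n_carbons != self.n_carbons:
            raise ValueError(
                f"MID with {mid.n_carbons} carbons for peak "
                f"{self.peak_id} ({self.n_carbons} carbons)"
            )
        self.mids[experiment] = mid


class ExperimentSet:
    """Ordered, unique labeling-experiment labels (e.g. tracer substrates)."""

    def __init__(self, experiment_ids: Iterable[str]):
        ids = list(experiment_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("experiment labels must be unique")
        self.experiment_ids: tuple[str, ...] = tuple(ids)

    def __iter__(self):
        return iter(self.experiment_ids)

    def __len__(self) -> int:
        return len(self.experiment_ids)

    def __contains__(self, item) -> bool:
        return item in self.experiment_ids

    def __repr__(self) -> str:
        return f"ExperimentSet({list(self.experiment_ids)!r})"


class PeakTable:
    """Collection of peaks with one MID per labeling experiment (sparse)."""

    def __init__(self, experiments: ExperimentSet | Iterable[str]):
        if not isinstance(experiments, ExperimentSet):
            experiments = ExperimentSet(experiments)
        self.experiments = experiments
        self.peaks: dict[str, Peak] = {}
        #: set by preprocessing when natural-13C correction has been applied
        self.corrected: bool = False

    def add_peak(self, peak: Peak) -> None:
        if peak.peak_id in self.peaks:
            raise ValueError(f"duplicate peak id {peak.peak_id!r}")
        for exp in peak.mids:
            if exp not in self.experiments:
                raise ValueError(f"unknown experiment {exp!r}")
        self.peaks[peak.peak_id] = peak

    def __len__(self) -> int:
        return len(self.peaks)

    def __contains__(self, peak_id) -> bool:
        return peak_id in self.peaks

    def __getitem__(self, peak_id: str) -> Peak:
        return self.peaks[peak_id]

    def peak_ids(self) -> list[str]:
        return list(self.peaks)

    def subset(self, peak_ids: Iterable[str]) -> "PeakTable":
        out = PeakTable(self.experiments)
        out.corrected = self.corrected
        for pid in peak_ids:
            out.add_peak(self.peaks[pid])
        return out

    def copy(self) -> "PeakTable":
        out = PeakTable(self.experiments)
        out.corrected = self.corrected
        for p in self.peaks.values():
            out.add_peak(
                Peak(
                    peak_id=p.peak_id,
                    n_carbons=p.n_carbons,
                    mz=p.mz,
                    rt_seconds=p.rt_seconds,
                    polarity=p.polarity,
                    formula=p.formula,
                    known=p.known,
                    annotation=p.annotation,
                    mids={e: MIDVector(m.fractions.copy()) for e, m in p.mids.items()},
                )
            )
        return out


@dataclass
class DistanceResult:
    """MID distance between one pair of peaks."""

    peak_a: str
    peak_b: str
    distance: float
    best_convolutant: str  # peak id, DIRECT, or NO_CONVOLUTANT
    per_experiment: dict[str, float] = field(default_factory=dict)
    n_experiments: int = 0
    is_sentinel: bool = False

    def __post_init__(self):
        if not self.is_sentinel and not math.isnan(self.distance):
            assert self.distance >= 0.0


class DistanceMatrix:
    """Symmetric pairwise MID distances with per-pair metadata.

    ``values[i, j]`` holds the distance (NaN for incomparable pairs, i.e.
    no shared experiment); pairs lacking a convolutant of the required size
    carry the global maximum over defined distances and are flagged via
    ``result(a, b).is_sentinel``.
    """

    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        n = len(self.ids)
        self.values = np.zeros((n, n), dtype=np.float64)
        self._results: dict[tuple[str, str], DistanceResult] = {}

    def _key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_result(self, res: DistanceResult) -> None:
        i, j = self._index[res.peak_a], self._index[res.peak_b]
        self.values[i, j] = self.values[j, i] = res.distance
        self._results[self._key(res.peak_a, res.peak_b)] = res

    def result(self, a: str, b: str) -> DistanceResult:
        return self._results[self._key(a, b)]

    def results(self) -> list[DistanceResult]:
        return list(self._results.values())

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.values[self._index[a], self._index[b]]

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peak_a": r.peak_a,
                "peak_b": r.peak_b,
                "distance": r.distance,
                "best_convolutant": r.best_convolutant,
                "n_experiments": r.n_experiments,
                "is_sentinel": r.is_sentinel,
            }
            for r in self._results.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "peak_a",
                "peak_b",
                "distance",
                "best_convolutant",
                "n_experiments",
                "is_sentinel",
            ],
        )

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, long_path, dense_path=None) -> None:
        self.to_long_frame().to_csv(long_path, sep="\t", index=False)
        if dense_path is not None:
            self.to_dense_frame().to_csv(dense_path, sep="\t")


def _distance_for_pair(
    a: Peak,
    b: Peak,
    table: PeakTable,
    experiments: ExperimentSet,
    conv_cache: dict | None = None,
) -> DistanceResult:
    """Convolutant-search distance for one ordered pair (a.n_carbons <= b's)."""
    shared = [e for e in experiments if e in a.mids and e in b.mids]
    if not shared:
        return DistanceResult(
            a.peak_id, b.peak_id, float("nan"), NO_CONVOLUTANT, {}, 0, is_sentinel=True
        )
    m, n = a.n_carbons, b.n_carbons
    if m == n:
        per = {
            e: float(np.linalg.norm(a.mids[e].fractions - b.mids[e].fractions))
            for e in shared
        }
        total = 0.0
        for e in shared:
            total += per[e]
        return DistanceResult(a.peak_id, b.peak_id, total, DIRECT, per, len(shared))

    size = n - m
    candidates = sorted(
        pid for pid, p in table.peaks.items() if p.n_carbons == size
    )
    best: tuple[float, str, dict[str, float], int] | None = None
    for cid in candidates:
        c = table.peaks[cid]
        per: dict[str, float] = {}
        total = 0.0
        count = 0
        for e in shared:
            if e not in c.mids:
                continue
            if conv_cache is not None:
                key = (a.peak_id, cid, e)
                conv = conv_cache.get(key)
                if conv is None:
                    conv = np.convolve(a.mids[e].fractions, c.mids[e].fractions)
                    conv_cache[key] = conv
            else:
                conv = np.convolve(a.mids[e].fractions, c.mids[e].fractions)
            d = float(np.linalg.norm(conv - b.mids[e].fractions))
            per[e] = d
            total += d
            count += 1
        if count == 0:
            continue
        if best is None or total < best[0]:
            best = (total, cid, per, count)
    if best is None:
        # convolutant size absent (or never co-measured): sentinel, filled later
        return DistanceResult(
            a.peak_id, b.peak_id, float("nan"), NO_CONVOLUTANT, {}, 0, is_sentinel=True
        )
    total, cid, per, count = best
    return DistanceResult(a.peak_id, b.peak_id, total, cid, per, count)


def mid_distance(
    peak_a: str, peak_b: str, table: PeakTable, experiments: ExperimentSet | None = None
) -> DistanceResult:
    """Multi-experiment convolution MID distance between two peaks.

    The smaller-carbon peak plays the role of A.  Distances are intended to be
    computed on MIDs *not* corrected for natural 13C.  Raises
    :class:`IncomparablePairError` if the peaks share no experiment.  If no
    convolutant of the required size exists the result is a sentinel (NaN
    distance here; :func:`pairwise_distances` replaces it by the global
    maximum over defined pairs).
    """
    if peak_a == peak_b:
        raise ValueError("mid_distance requires two distinct peaks")
    if experiments is None:
        experiments = table.experiments
    _warn_if_corrected(table)
    a, b = table.peaks[peak_a], table.peaks[peak_b]
    swapped = a.n_carbons > b.n_carbons
    if swapped:
        a, b = b, a
    res = _distance_for_pair(a, b, table, experiments)
    if res.n_experiments == 0 and not any(
        e in table.peaks[peak_a].mids and e in table.peaks[peak_b].mids
        for e in experiments
    ):
        raise IncomparablePairError(
            f"peaks {peak_a!r} and {peak_b!r} share no experiment"
        )
    if swapped:
        res = DistanceResult(
            peak_a,
            peak_b,
            res.distance,
            res.best_convolutant,
            res.per_experiment,
            res.n_experiments,
            res.is_sentinel,
        )
    return res


def _warn_if_corrected(table: PeakTable) -> None:
    if getattr(table, "corrected", False):
        import warnings

        warnings.warn(
            "computing MID distances on a natural-13C-corrected table; the "
            "distance is designed for uncorrected MIDs",
            stacklevel=3,
        )


def pairwise_distances(
    table: PeakTable, experiments: ExperimentSet | None = None
) -> DistanceMatrix:
    """All-pairs MID distance matrix.

    Convolutions are cached per (small peak, convolutant, experiment) and
    reused for every larger peak of matching size; results are identical to
    the naive per-pair loop.  Missing-convolutant pairs are assigned the
    largest defined distance in a second pass (sentinel), matching the rule
    used for the original data set; pairs with no shared experiment stay NaN.
    """
    if experiments is None:
        experiments = table.experiments
    _warn_if_corrected(table)
    ids = sorted(table.peaks)
    if len(ids) < 2:
        raise ValueError("need at least two peaks")
    matrix = DistanceMatrix(ids)
    conv_cache: dict = {}
    sentinels: list[DistanceResult] = []
    defined_max = 0.0
    for i, pid_a in enumerate(ids):
        for pid_b in ids[i + 1 :]:
            a, b = table.peaks[pid_a], table.peaks[pid_b]
            if a.n_carbons > b.n_carbons:
                a, b = b, a
            res = _distance_for_pair(a, b, table, experiments, conv_cache)
            if res.is_sentinel:
                sentinels.append(res)
            else:
                defined_max = max(defined_max, res.distance)
            matrix.set_result(res)
    for res in sentinels:
        shared = any(
            e in table.peaks[res.peak_a].mids and e in table.peaks[res.peak_b].mids
            for e in experiments
        )
        if shared:
            # missing convolutant: global-max sentinel
            filled = DistanceResult(
                res.peak_a,
                res.peak_b,
                defined_max,
                NO_CONVOLUTANT,
                {},
                0,
                is_sentinel=True,
            )
            matrix.set_result(filled)
        # no shared experiment: stays NaN (incomparable)
    return matrix


def nearest_neighbors(
    peak_id: str, distances: DistanceMatrix, k: int
) -> list[tuple[str, float, str]]:
    """The k nearest peaks to ``peak_id``, ascending by distance.

    Ties are broken by peak id; incomparable (NaN) pairs rank last.
    Returns (peak id, distance, best convolutant) triples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if peak_id not in distances._index:
        raise KeyError(peak_id)
    entries = []
    for other in distances.ids:
        if other == peak_id:
            continue
        res = distances.result(peak_id, other)
        d = res.distance
        entries.append((math.isnan(d), d if not math.isnan(d) else 0.0, other, res))
    entries.sort(key=lambda t: (t[0], t[1], t[2]))
    return [(o, r.distance, r.best_convolutant) for _, _, o, r in entries[:k]]


def threshold_network(distances: DistanceMatrix, cutoff: float):
    """Undirected graph with an edge for every pair with distance < cutoff.

    Sentinel (missing-convolutant) and incomparable pairs never form edges
    below a finite cutoff smaller than the sentinel value, matching the use
    of a conservative cutoff on real data.  Returns a networkx Graph with
    ``distance`` and ``best_convolutant`` edge attributes.
    """
    import networkx as nx

    if cutoff <= 0:
        g = nx.Graph()
        g.add_nodes_from(distances.ids)
        return g
    g = nx.Graph()
    g.add_nodes_from(distances.ids)
    for res in distances.results():
        if not math.isnan(res.distance) and res.distance < cutoff:
            g.add_edge(
                res.peak_a,
                res.peak_b,
                distance=res.distance,
                best_convolutant=res.best_convolutant,
                n_experiments=res.n_experiments,
            )
    return g


def write_edge_list(graph, path) -> None:
    rows = [
        {
            "peak_a": a,
            "peak_b": b,
            "distance": d["distance"],
            "best_convolutant": d["best_convolutant"],
            "n_experiments": d.get("n_experiments", 0),
        }
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["peak_a", "peak_b", "distance", "best_convolutant", "n_experiments"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSV I/O: one row per peak x experiment, M0..Mn fraction columns


def write_peak_table(table: PeakTable, path) -> None:
    max_n = max((p.n_carbons for p in table.peaks.values()), default=0)
    mi_cols = [f"M{i}" for i in range(max_n + 1)]
    rows = []
    for pid in sorted(table.peaks):
        p = table.peaks[pid]
        for exp in table.experiments:
            if exp not in p.mids:
                continue
            row = {
                "peak_id": pid,
                "experiment": exp,
                "n_carbons": p.n_carbons,
                "formula": p.formula or "",
                "mz": p.mz,
                "rt_seconds": p.rt_seconds,
                "polarity": p.polarity,
                "known": int(p.known),
            }
            fr = p.mids[exp].fractions
            for i, col in enumerate(mi_cols):
                row[col] = repr(float(fr[i])) if i < fr.size else ""
            rows.append(row)
    cols = [
        "peak_id",
        "experiment",
        "n_carbons",
        "formula",
        "mz",
        "rt_seconds",
        "polarity",
        "known",
    ] + mi_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"peak_id": str, "experiment": str},
        float_precision="round_trip",
    )
    mi_cols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]
    mi_cols.sort(key=lambda c: int(c[1:]))
    experiments = ExperimentSet(pd.unique(df["experiment"]))
    table = PeakTable(experiments)
    for pid, group in df.groupby("peak_id", sort=True):
        first = group.iloc[0]
        n = int(first["n_carbons"])
        formula = first.get("formula", "")
        peak = Peak(
            peak_id=str(pid),
            n_carbons=n,
            mz=float(first.get("mz", float("nan"))),
            rt_seconds=float(first.get("rt_seconds", float("nan"))),
            polarity=str(first.get("polarity", "+")),
            formula=None if pd.isna(formula) or formula == "" else str(formula),
            known=bool(int(first.get("known", 0))),
        )
        for _, row in group.iterrows():
            vals = [float(row[c]) for c in mi_cols[: n + 1]]
            peak.set_mid(str(row["experiment"]), MIDVector(np.asarray(vals)))
        table.add_peak(peak)
    return table
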