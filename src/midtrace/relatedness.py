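"""Biochemical relatedness f: the fraction of carbon one metabolite derives
from another, used as the gold standard when evaluating MID distances.

The directional contribution of A to B is computed by network surgery: A is
turned into a network substrate (the isotope-label contribution of every
reaction producing A is thereby removed, while all fluxes stay at the same
flux state), A's pool is fixed fully 13C-labeled, and the steady-state EMU
equations are solved.  The 13C enrichment of B is then the fraction of B's
carbon atoms derived from A.  Since the two directions generally differ,
f(A, B) is the larger of the two contributions; pairs with f > 1/2 are
labeled "biochemically related".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mid import enrichment
from .network import AtomMappedNetwork, TracerConfig
from .simulate import simulate_steady_state

__all__ = [
    "RelatednessMatrix",
    "carbon_contribution",
    "directional_contributions",
    "relatedness_matrix",
    "related_pairs",
]


@dataclass
class RelatednessMatrix:
    """Symmetric f values plus the directional contributions behind them."""

    ids: list[str]
    values: np.ndarray  # symmetric, f(A,A) = 1
    contributions: np.ndarray  # contributions[i, j] = fraction of j from i

    def f(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_frame(self, threshold: float = 0.5) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                b = self.ids[j]
                f = float(self.values[i, j])
                rows.append(
                    {
                        "metabolite_a": a,
                        "metabolite_b": b,
                        "f": f,
                        "contribution_a_to_b": float(self.contributions[i, j]),
                        "contribution_b_to_a": float(self.contributions[j, i]),
                        "related": int(f > threshold),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, dense_path, long_path=None, threshold: float = 0.5) -> None:
        self.to_dense_frame().to_csv(dense_path, sep="\t")
        if long_path is not None:
            self.to_long_frame(threshold).to_csv(long_path, sep="\t", index=False)


def directional_contributions(
    network: AtomMappedNetwork, source: str
) -> dict[str, float]:
    """Fraction of each metabolite's carbon derived from ``source``.

    One network surgery and one steady-state EMU solve cover all targets.
    """
    if source not in network.metabolites:
        raise KeyError(f"unknown metabolite {source!r}")
    modified = network.with_substrate(source)
    tracer = TracerConfig(substrate=source, labeled_fraction=1.0, purity=1.0)
    targets = [
        m
        for m in network.metabolites
        if not modified.metabolites[m].is_substrate or m == source
    ]
    mids = simulate_steady_state(modified, tracer, targets)
    out: dict[str, float] = {}
    for met_id, met in network.metabolites.items():
        if met_id == source:
            out[met_id] = 1.0
        elif modified.metabolites[met_id].is_substrate:
            # original substrates derive carbon only from themselves
            out[met_id] = 0.0
        elif met.n_carbons == 0:
            out[met_id] = 0.0
        else:
            out[met_id] = enrichment(mids[met_id])
    return out


def carbon_contribution(network: AtomMappedNetwork, a: str, b: str) -> float:
    """Fraction of B's carbon atoms derived from A at the given flux state."""
    if a == b:
        return 1.0
    return directional_contributions(network, a)[b]


def relatedness_matrix(network: AtomMappedNetwork) -> RelatednessMatrix:
    """All-pairs f matrix; one steady-state solve per source metabolite."""
    ids = sorted(network.metabolites)
    n = len(ids)
    contrib = np.zeros((n, n))
    for i, src in enumerate(ids):
        row = directional_contributions(network, src)
        for j, tgt in enumerate(ids):
            contrib[i, j] = row[tgt]
    values = np.maximum(contrib, contrib.T)
    np.fill_diagonal(values, 1.0)
    return RelatednessMatrix(ids=ids, values=values, contributions=contrib)


def related_pairs(
    matrix: RelatednessMatrix, threshold: float = 0.5
) -> set[frozenset]:
    """Unordered pairs with f strictly greater than ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    out: set[frozenset] = set()
    for i, a in enumerate(matrix.ids):
        for j in range(i + 1, len(matrix.ids)):
            if matrix.values[i, j] > threshold:
                out.add(frozenset((a, matrix.ids[j])))
    return out
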