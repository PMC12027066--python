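"""Elementary metabolite unit (EMU) decomposition of atom-mapped networks.

An EMU is a metabolite together with a subset of its carbon positions whose
labeling state can be balanced independently of the rest of the molecule.
Starting from the full-carbon EMUs of the target metabolites, each EMU is
traced backward through every producing reaction: the product positions map
to reactant positions, grouping by reactant molecule.  A product EMU drawing
from two or more reactant molecules yields a convolution (condensation) EMU
reaction whose source sizes sum to the target size.  The resulting system is
ordered by EMU size; dependencies only point from smaller to equal/larger
sizes, so it can be solved block by block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .network import AtomMappedNetwork

__all__ = ["EMU", "EMUReaction", "EMUSystem", "decompose_emu"]


@dataclass(frozen=True, order=True)
class EMU:
    met_id: str
    positions: tuple[int, ...]  # sorted, 0-based carbon positions

    @property
    def size(self) -> int:
        return len(self.positions)

    def __repr__(self) -> str:
        pos = "".join(str(p + 1) for p in self.positions)
        return f"{self.met_id}:{pos}"


@dataclass(frozen=True)
class EMUReaction:
    """One labeled-material route into ``target``: sources -> target at ``flux``.

    ``sources`` holds one EMU per contributing reactant molecule; when there
    are several, the target MID is the convolution of the source MIDs.
    """

    rxn_id: str
    target: EMU
    sources: tuple[EMU, ...]
    flux: float


def full_emu(network: AtomMappedNetwork, met_id: str) -> EMU:
    n = network.metabolites[met_id].n_carbons
    return EMU(met_id, tuple(range(n)))


class EMUSystem:
    """Size-blocked EMU set with the producing reactions of each EMU."""

    def __init__(self, network: AtomMappedNetwork):
        self.network = network
        self.producers: dict[EMU, list[EMUReaction]] = {}

    @property
    def emus(self) -> list[EMU]:
        return sorted(self.producers, key=lambda e: (e.size, e.met_id, e.positions))

    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.producers})

    def block(self, size: int) -> list[EMU]:
        return [e for e in self.emus if e.size == size]

    def is_substrate(self, emu: EMU) -> bool:
        return self.network.metabolites[emu.met_id].is_substrate

    def unknown_emus(self) -> list[EMU]:
        return [e for e in self.emus if not self.is_substrate(e)]


def decompose_emu(
    network: AtomMappedNetwork, targets: Iterable[str]
) -> EMUSystem:
    """Minimal EMU system reaching the full-carbon EMUs of ``targets``."""
    system = EMUSystem(network)
    targets = list(targets)
    for t in targets:
        if t not in network.metabolites:
            raise KeyError(f"unknown target metabolite {t!r}")
    worklist = [full_emu(network, t) for t in targets]
    seen: set[EMU] = set()
    while worklist:
        emu = worklist.pop()
        if emu in seen:
            continue
        seen.add(emu)
        system.producers.setdefault(emu, [])
        if emu.size == 0 or system.is_substrate(emu):
            continue  # trivial or fixed by the tracer; no backward tracing
        for rxn in network.reactions:
            for term in rxn.products:
                if term.met_id != emu.met_id:
                    continue
                # trace each tracked position to its reactant atom
                by_reactant: dict[int, list[int]] = {}
                for pos in emu.positions:
                    letter = term.atoms[pos]
                    for ridx, rterm in enumerate(rxn.reactants):
                        q = rterm.atoms.find(letter)
                        if q >= 0:
                            by_reactant.setdefault(ridx, []).append(q)
                            break
                    else:  # unreachable: parser guarantees a source
                        raise AssertionError(
                            f"{rxn.rxn_id}: unmapped product atom {letter!r}"
                        )
                sources = tuple(
                    sorted(
                        (
                            EMU(
                                rxn.reactants[ridx].met_id,
                                tuple(sorted(positions)),
                            )
                            for ridx, positions in by_reactant.items()
                        ),
                        key=lambda e: (e.size, e.met_id, e.positions),
                    )
                )
                system.producers[emu].append(
                    EMUReaction(rxn.rxn_id, emu, sources, rxn.flux)
                )
                for src in sources:
                    if src not in seen:
                        worklist.append(src)
    return system
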