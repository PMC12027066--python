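"""Atom-mapped metabolic network model and reaction-file parser.

Reaction grammar (one reaction per line, '#' comments)::

    rxn_id : term [+ term ...] -> [term [+ term ...]]

    term   := [coef] metabolite_id ( atoms )
    atoms  := lowercase letters, one per carbon, position-matched between
              the reactant and product sides of the same reaction

Every product carbon letter must occur exactly once among the reactants of
that reaction (each product carbon derives from exactly one reactant carbon).
Reactant letters missing from the product side leave the system (e.g. CO2
that is not tracked).  A reaction with an empty product side is a sink.
Reversible reactions are encoded as two opposing irreversible reactions.

Fluxes are non-negative; at every non-substrate metabolite total producing
flux must equal total consuming flux (steady state).  Substrates are external
sources whose isotope labeling is fixed by the tracer configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "ReactionTerm",
    "Reaction",
    "AtomMappedNetwork",
    "TracerConfig",
    "NetworkValidationError",
    "parse_network",
    "parse_reactions",
]

FLUX_BALANCE_RTOL = 1e-9


class NetworkValidationError(ValueError):
    pass


@dataclass
class Metabolite:
    met_id: str
    n_carbons: int
    is_substrate: bool = False
    pool_size: float = 1.0


@dataclass(frozen=True)
class ReactionTerm:
    """One molecule instance in a reaction, with its atom letters."""

    met_id: str
    atoms: str  # one lowercase letter per carbon


@dataclass
class Reaction:
    rxn_id: str
    reactants: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]
    flux: float = 0.0


_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z0-9_.\-]+)\s*\(([a-z]*)\)\s*$")


def _parse_side(side: str, rxn_id: str) -> tuple[ReactionTerm, ...]:
    side = side.strip()
    if not side:
        return ()
    terms: list[ReactionTerm] = []
    for chunk in side.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise NetworkValidationError(
                f"reaction {rxn_id!r}: cannot parse term {chunk.strip()!r}"
            )
        coef = int(m.group(1) or 1)
        for _ in range(coef):
            terms.append(ReactionTerm(m.group(2), m.group(3)))
    return tuple(terms)


def parse_reactions(text: str) -> list[Reaction]:
    reactions: list[Reaction] = []
    seen = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line or "->" not in line:
            raise NetworkValidationError(f"malformed reaction line: {raw!r}")
        rxn_id, rest = line.split(":", 1)
        rxn_id = rxn_id.strip()
        if rxn_id in seen:
            raise NetworkValidationError(f"duplicate reaction id {rxn_id!r}")
        seen.add(rxn_id)
        lhs, rhs = rest.split("->", 1)
        reactants = _parse_side(lhs, rxn_id)
        products = _parse_side(rhs, rxn_id)
        if not reactants:
            raise NetworkValidationError(
                f"reaction {rxn_id!r}: needs at least one reactant"
            )
        reactions.append(Reaction(rxn_id, reactants, products))
    return reactions


class AtomMappedNetwork:
    """Validated atom-mapped network with fluxes and pool sizes."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        check_balance: bool = True,
    ):
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.met_id in self.metabolites:
                raise NetworkValidationError(f"duplicate metabolite {met.met_id!r}")
            if met.n_carbons < 0:
                raise NetworkValidationError(f"{met.met_id!r}: negative carbon count")
            self.metabolites[met.met_id] = met
        self.reactions: list[Reaction] = list(reactions)
        self._validate_atoms()
        if check_balance:
            self._validate_balance()

    # -- validation ---------------------------------------------------------

    def _validate_atoms(self) -> None:
        for rxn in self.reactions:
            if rxn.flux < 0:
                raise NetworkValidationError(f"{rxn.rxn_id!r}: negative flux")
            reactant_letters: dict[str, tuple[int, int]] = {}
            for idx, term in enumerate(rxn.reactants + rxn.products):
                met = self.metabolites.get(term.met_id)
                if met is None:
                    raise NetworkValidationError(
                        f"{rxn.rxn_id!r}: unknown metabolite {term.met_id!r}"
                    )
                if len(term.atoms) != met.n_carbons:
                    raise NetworkValidationError(
                        f"{rxn.rxn_id!r}: atom mismatch for {term.met_id!r} "
                        f"({len(term.atoms)} letters, {met.n_carbons} carbons)"
                    )
            for ridx, term in enumerate(rxn.reactants):
                for pos, letter in enumerate(term.atoms):
                    if letter in reactant_letters:
                        raise NetworkValidationError(
                            f"{rxn.rxn_id!r}: atom letter {letter!r} appears twice "
                            "among reactants"
                        )
                    reactant_letters[letter] = (ridx, pos)
            product_letters: set[str] = set()
            for term in rxn.products:
                for letter in term.atoms:
                    if letter not in reactant_letters:
                        raise NetworkValidationError(
                            f"{rxn.rxn_id!r}: product atom {letter!r} has no "
                            "reactant source"
                        )
                    if letter in product_letters:
                        raise NetworkValidationError(
                            f"{rxn.rxn_id!r}: product atom {letter!r} mapped twice"
                        )
                    product_letters.add(letter)

    def _validate_balance(self) -> None:
        resid = self.flux_balance_residuals()
        for met_id, (prod, cons) in resid.items():
            scale = max(prod, cons, 1.0)
            if abs(prod - cons) > FLUX_BALANCE_RTOL * scale:
                raise NetworkValidationError(
                    f"flux imbalance at {met_id!r}: production {prod}, "
                    f"consumption {cons}"
                )

    def flux_balance_residuals(self) -> dict[str, tuple[float, float]]:
        """(production, consumption) flux per non-substrate metabolite."""
        prod: dict[str, float] = {m: 0.0 for m in self.metabolites}
        cons: dict[str, float] = {m: 0.0 for m in self.metabolites}
        for rxn in self.reactions:
            for term in rxn.reactants:
                cons[term.met_id] += rxn.flux
            for term in rxn.products:
                prod[term.met_id] += rxn.flux
        return {
            m: (prod[m], cons[m])
            for m, met in self.metabolites.items()
            if not met.is_substrate
        }

    # -- convenience --------------------------------------------------------

    def production_flux(self, met_id: str) -> float:
        return sum(
            rxn.flux
            for rxn in self.reactions
            for term in rxn.products
            if term.met_id == met_id
        )

    def consumption_flux(self, met_id: str) -> float:
        return sum(
            rxn.flux
            for rxn in self.reactions
            for term in rxn.reactants
            if term.met_id == met_id
        )

    def substrates(self) -> list[str]:
        return [m for m, met in self.metabolites.items() if met.is_substrate]

    def with_substrate(self, met_id: str) -> "AtomMappedNetwork":
        """Copy of the network in which ``met_id`` is (also) a substrate.

        Fluxes are untouched: the metabolite's pool becomes an external
        source at the same flux state, which removes the isotope-label
        contribution of all reactions producing it.
        """
        mets = [
            replace(m, is_substrate=True) if m.met_id == met_id else replace(m)
            for m in self.metabolites.values()
        ]
        return AtomMappedNetwork(mets, list(self.reactions), check_balance=False)

    def scaled(self, factor: float) -> "AtomMappedNetwork":
        """Uniformly scale all fluxes (steady-state MIDs are invariant)."""
        mets = [replace(m) for m in self.metabolites.values()]
        rxns = [
            Reaction(r.rxn_id, r.reactants, r.products, r.flux * factor)
            for r in self.reactions
        ]
        return AtomMappedNetwork(mets, rxns)

    def write(self, reactions_path, fluxes_path=None, pools_path=None) -> None:
        lines = []
        for rxn in self.reactions:
            lhs = " + ".join(f"{t.met_id} ({t.atoms})" for t in rxn.reactants)
            rhs = " + ".join(f"{t.met_id} ({t.atoms})" for t in rxn.products)
            lines.append(f"{rxn.rxn_id}: {lhs} -> {rhs}")
        with open(reactions_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        if fluxes_path is not None:
            pd.DataFrame(
                {"reaction": [r.rxn_id for r in self.reactions],
                 "flux": [repr(r.flux) for r in self.reactions]}
            ).to_csv(fluxes_path, sep="\t", index=False)
        if pools_path is not None:
            rows = []
            for m in self.metabolites.values():
                rows.append(
                    {
                        "metabolite": m.met_id,
                        "n_carbons": m.n_carbons,
                        "is_substrate": int(m.is_substrate),
                        "pool_size": repr(m.pool_size),
                    }
                )
            pd.DataFrame(rows).to_csv(pools_path, sep="\t", index=False)


def parse_network(
    reactions_text: str,
    fluxes: Mapping[str, float],
    pool_sizes: Mapping[str, float] | None = None,
    substrates: Iterable[str] = (),
    n_carbons: Mapping[str, int] | None = None,
) -> AtomMappedNetwork:
    """Build a validated network from reaction text plus flux/pool vectors.

    Carbon counts are inferred from atom strings unless given explicitly;
    conflicting atom-string lengths for the same metabolite are rejected.
    """
    reactions = parse_reactions(reactions_text)
    inferred: dict[str, int] = dict(n_carbons or {})
    for rxn in reactions:
        for term in rxn.reactants + rxn.products:
            prev = inferred.get(term.met_id)
            if prev is None:
                inferred[term.met_id] = len(term.atoms)
            elif prev != len(term.atoms):
                raise NetworkValidationError(
                    f"{rxn.rxn_id!r}: atom mismatch for {term.met_id!r} "
                    f"({len(term.atoms)} letters, {prev} carbons)"
                )
    subs = set(substrates)
    pools = dict(pool_sizes or {})
    mets = [
        Metabolite(
            met_id=m,
            n_carbons=c,
            is_substrate=m in subs,
            pool_size=float(pools.get(m, 1.0)),
        )
        for m, c in inferred.items()
    ]
    for rxn in reactions:
        if rxn.rxn_id not in fluxes:
            raise NetworkValidationError(f"no flux given for {rxn.rxn_id!r}")
        rxn.flux = float(fluxes[rxn.rxn_id])
    return AtomMappedNetwork(mets, reactions)


def read_network(reactions_path, fluxes_path, pools_path=None) -> AtomMappedNetwork:
    with open(reactions_path) as fh:
        text = fh.read()
    fdf = pd.read_csv(fluxes_path, sep="\t")
    fluxes = {str(r["reaction"]): float(r["flux"]) for _, r in fdf.iterrows()}
    pools: dict[str, float] = {}
    substrates: list[str] = []
    if pools_path is not None:
        pdf = pd.read_csv(pools_path, sep="\t")
        for _, row in pdf.iterrows():
            pools[str(row["metabolite"])] = float(row["pool_size"])
            if int(row.get("is_substrate", 0)):
                substrates.append(str(row["metabolite"]))
    return parse_network(text, fluxes, pools, substrates)


@dataclass(frozen=True)
class TracerConfig:
    """One isotope labeling experiment: which substrate carries the label.

    ``positions`` is None for uniform (U-13C) labeling or an explicit tuple
    of 0-based labeled carbon positions.  ``labeled_fraction`` is the share
    of the substrate pool entering the system in labeled form; ``purity`` is
    the per-position 13C isotopic purity of the labeled material.
    """

    substrate: str
    positions: tuple[int, ...] | None = None
    labeled_fraction: float = 1.0
    purity: float = 1.0
    name: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")

    @property
    def experiment_id(self) -> str:
        return self.name or f"U13C-{self.substrate}"

    def atom_label_probability(self, position: int) -> float:
        """P(13C at this substrate carbon | molecule from the labeled batch)."""
        if self.positions is None or position in self.positions:
            return self.purity
        return 0.0


def tracers_from_json(payload) -> list[TracerConfig]:
    """Load a tracer panel from a JSON list of objects."""
    import json as _json

    if isinstance(payload, (str, bytes)):
        payload = _json.loads(payload)
    out = []
    for item in payload:
        out.append(
            TracerConfig(
                substrate=item["substrate"],
                positions=tuple(item["positions"]) if item.get("positions") else None,
                labeled_fraction=float(item.get("labeled_fraction", 1.0)),
                purity=float(item.get("purity", 1.0)),
                name=item.get("name"),
            )
        )
    return out
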