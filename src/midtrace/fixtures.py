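"""Synthetic toy networks, tracer panels and simulated MID tables.

Every template is a small, flux-balanced, atom-mapped network on which the
whole pipeline (simulation, distances, relatedness, evaluation, annotation)
can run in seconds.  The default evaluation network (``eval_default``)
emulates moiety assembly in central metabolism: five labeled substrates feed
carbon-preserving transformation chains, conjugate metabolites are built by
condensing moieties from different chains, and one cleavage produces small
one- and two-carbon products.  Condensation products are given small pools
(low-abundance conjugates), so their MIDs track their precursors closely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mid import MIDVector, Peak, PeakTable
from .network import AtomMappedNetwork, Metabolite, Reaction, ReactionTerm, parse_network
from .relatedness import RelatednessMatrix, related_pairs, relatedness_matrix
from .simulate import run_tracer_panel
from .network import TracerConfig

__all__ = ["FixtureSpec", "make_network", "make_tracers", "make_peak_table"]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic data set.

    Identical specs produce bit-identical networks and tables.
    """

    template: str = "eval_default"
    n_metabolites: int = 25  # used by random_dag / linear_chain
    n_carbons: int = 3  # linear_chain carbon count
    n_tracers: int = 5
    noise_sd: float = 0.0
    fraction_of_t_ss: float = 0.5
    seed: int = 0
    n_decoys: int = 0


def _reactions(text: str, fluxes: dict, pools: dict, substrates: list[str]):
    return parse_network(text, fluxes, pools, substrates)


def _linear_chain(length: int, carbons: int) -> AtomMappedNetwork:
    if length < 2:
        raise ValueError("chain needs at least substrate + one product")
    atoms = _ALPHABET[:carbons]
    names = ["S"] + [f"M{i}" for i in range(1, length)]
    lines = [
        f"v{i}: {names[i]} ({atoms}) -> {names[i + 1]} ({atoms})"
        for i in range(length - 1)
    ]
    lines.append(f"sink: {names[-1]} ({atoms}) ->")
    fluxes = {f"v{i}": 1.0 for i in range(length - 1)}
    fluxes["sink"] = 1.0
    return _reactions("\n".join(lines), fluxes, {}, ["S"])


def _branched() -> AtomMappedNetwork:
    text = """
    v0: S (abc) -> A (abc)
    v1: A (abc) -> B1 (abc)
    v2: B1 (abc) -> B2 (abc)
    v3: A (abc) -> C1 (cab)
    v4: C1 (abc) -> C2 (abc)
    sb: B2 (abc) ->
    sc: C2 (abc) ->
    """
    fluxes = {"v0": 2.0, "v1": 1.0, "v2": 1.0, "v3": 1.0, "v4": 1.0,
              "sb": 1.0, "sc": 1.0}
    return _reactions(text, fluxes, {}, ["S"])


def _condensation() -> AtomMappedNetwork:
    text = """
    v1: A (ab) + B (c) -> C (abc)
    sink: C (abc) ->
    """
    return _reactions(text, {"v1": 1.0, "sink": 1.0}, {}, ["A", "B"])


def _toy_tca() -> AtomMappedNetwork:
    # two-carbon substrate condenses onto a four-carbon acceptor; two
    # one-carbon units leave per turn, so the cycle is flux balanced
    text = """
    v1: ACA (ab) + OAA (cdef) -> CIT (abcdef)
    v2: CIT (abcdef) -> AKG (abcde) + CO2 (f)
    v3: AKG (abcde) -> SUC (bcde) + CO2 (a)
    v4: SUC (abcd) -> OAA (abcd)
    v5: CO2 (a) ->
    """
    fluxes = {"v1": 1.0, "v2": 1.0, "v3": 1.0, "v4": 1.0, "v5": 2.0}
    return _reactions(text, fluxes, {}, ["ACA"])


# pool sizes proportional to turnover: a common ~300 time-unit relaxation
# time for pathway intermediates keeps the sampled pre-steady-state point
# genuinely mid-transient (labeling deficits 0.004-0.3, far above solver
# precision); conjugates and cleavage products get 10x faster pools
# (low-abundance species tracking the convolution of their precursors)
_EVAL_POOLS = {
    "h1": 40000.0, "h2": 40000.0, "h3": 40000.0, "h4": 40000.0,
    "p1": 80000.0, "p2": 80000.0, "p3": 40000.0,
    "g1": 40000.0, "g2": 40000.0, "g3": 40000.0,
    "o1": 40000.0, "o2": 40000.0, "o3": 40000.0,
    "m1": 40000.0, "m2": 40000.0, "m3": 40000.0,
    "ace": 4000.0, "fmt": 4000.0,
    "x1": 1000.0,
}

_EVAL_TEXT = """
# substrate uptake / transformation chains (carbon preserving)
vh1: glc (abcdef) -> h1 (abcdef)
vh2: h1 (abcdef) -> h2 (abcdef)
vh3: h2 (abcdef) -> h3 (abcdef)
vh4: h3 (abcdef) -> h4 (abcdef)
sh4: h4 (abcdef) ->
vp1: ala (abc) -> p1 (abc)
vp2: p1 (abc) -> p2 (abc)
vp3: p2 (abc) -> p3 (abc)
sp3: p3 (abc) ->
vg1: gly (ab) -> g1 (ab)
vg2: g1 (ab) -> g2 (ab)
vg3: g2 (ab) -> g3 (ab)
sg3: g3 (ab) ->
vo1: asp (abcd) -> o1 (abcd)
vo2: o1 (abcd) -> o2 (abcd)
vo3: o2 (abcd) -> o3 (abcd)
so3: o3 (abcd) ->
vm1: met (abcde) -> m1 (abcde)
vm2: m1 (abcde) -> m2 (abcde)
vm3: m2 (abcde) -> m3 (abcde)
sm3: m3 (abcde) ->
# cleavage of a three-carbon intermediate into 2C + 1C products
clv: p2 (abc) -> ace (ab) + fmt (c)
sace: ace (ab) ->
sfmt: fmt (a) ->
# one condensation joining two one-carbon units (C1 metabolism)
cx1: fmt (a) + fmt (b) -> x1 (ab)
sx1: x1 (ab) ->
"""

_EVAL_FLUXES = {
    "vh1": 1.0, "vh2": 1.0, "vh3": 1.0, "vh4": 1.0, "sh4": 1.0,
    "vp1": 2.0, "vp2": 2.0, "vp3": 1.0, "sp3": 1.0,
    "vg1": 1.0, "vg2": 1.0, "vg3": 1.0, "sg3": 1.0,
    "vo1": 1.0, "vo2": 1.0, "vo3": 1.0, "so3": 1.0,
    "vm1": 1.0, "vm2": 1.0, "vm3": 1.0, "sm3": 1.0,
    "clv": 1.0, "sace": 1.0, "sfmt": 0.5,
    "cx1": 0.25, "sx1": 0.25,
}

_EVAL_SUBSTRATES = ["glc", "ala", "gly", "asp", "met"]


def _eval_default() -> AtomMappedNetwork:
    return _reactions(_EVAL_TEXT, _EVAL_FLUXES, _EVAL_POOLS, _EVAL_SUBSTRATES)


def _random_dag(n_metabolites: int, seed: int) -> AtomMappedNetwork:
    """Random acyclic moiety-assembly network with back-propagated fluxes."""
    if n_metabolites < 4:
        raise ValueError("random_dag needs at least 4 metabolites")
    rng = np.random.default_rng(seed)
    carbons: dict[str, int] = {}
    substrates = []
    for i, c in enumerate((2, 3, 4)):
        name = f"s{i}"
        substrates.append(name)
        carbons[name] = c
    mets = list(substrates)
    reactions: list[tuple[str, list[tuple[str, str]], list[tuple[str, str]]]] = []
    produced_by: dict[str, int] = {}
    for i in range(n_metabolites - len(substrates)):
        name = f"n{i}"
        condense = len(mets) >= 2 and rng.random() < 0.4
        if condense:
            pa, pb = rng.choice(len(mets), size=2, replace=False)
            parents = [mets[int(pa)], mets[int(pb)]]
            if carbons[parents[0]] + carbons[parents[1]] > 12:
                condense = False
        if condense:
            ca, cb = carbons[parents[0]], carbons[parents[1]]
            carbons[name] = ca + cb
            atoms = _ALPHABET[: ca + cb]
            reactions.append(
                (
                    f"r{i}",
                    [(parents[0], atoms[:ca]), (parents[1], atoms[ca:])],
                    [(name, atoms)],
                )
            )
        else:
            parent = mets[int(rng.integers(len(mets)))]
            c = carbons[parent]
            carbons[name] = c
            perm = rng.permutation(c)
            src = "".join(_ALPHABET[j] for j in range(c))
            dst = "".join(_ALPHABET[int(j)] for j in perm)
            reactions.append((f"r{i}", [(parent, src)], [(name, dst)]))
        produced_by[name] = len(reactions) - 1
        mets.append(name)
    # sinks for every childless metabolite
    consumed = {m for _, lhs, _ in reactions for m, _ in lhs}
    sink_lines = []
    for m in mets:
        if m not in consumed:
            sink_lines.append((f"sink_{m}", [(m, _ALPHABET[: carbons[m]])], []))
    # back-propagate fluxes (each non-substrate has exactly one producer)
    fluxes: dict[str, float] = {rid: 1.0 for rid, _, _ in sink_lines}
    demand: dict[str, float] = {m: 0.0 for m in mets}
    for rid, lhs, _ in sink_lines:
        for m, _a in lhs:
            demand[m] += 1.0
    for rid, lhs, rhs in reversed(reactions):
        flux = sum(demand[m] for m, _ in rhs)
        fluxes[rid] = flux
        for m, _a in lhs:
            demand[m] += flux
    lines = []
    for rid, lhs, rhs in reactions + sink_lines:
        left = " + ".join(f"{m} ({a})" for m, a in lhs)
        right = " + ".join(f"{m} ({a})" for m, a in rhs)
        lines.append(f"{rid}: {left} -> {right}")
    return _reactions("\n".join(lines), fluxes, {}, substrates)


def make_network(spec: FixtureSpec) -> AtomMappedNetwork:
    """Build the network named by ``spec.template``."""
    if spec.template == "linear_chain":
        return _linear_chain(spec.n_metabolites, spec.n_carbons)
    if spec.template == "branched":
        return _branched()
    if spec.template == "condensation":
        return _condensation()
    if spec.template == "toy_tca":
        return _toy_tca()
    if spec.template == "random_dag":
        return _random_dag(spec.n_metabolites, spec.seed)
    if spec.template == "eval_default":
        return _eval_default()
    raise ValueError(f"unknown template {spec.template!r}")


def make_tracers(
    network: AtomMappedNetwork, n_tracers: int | None = None
) -> list[TracerConfig]:
    """One U-13C tracer per substrate (alphabetical), up to ``n_tracers``."""
    subs = sorted(network.substrates())
    if n_tracers is not None:
        if n_tracers > len(subs):
            raise ValueError(
                f"requested {n_tracers} tracers but only {len(subs)} substrates"
            )
        subs = subs[:n_tracers]
    return [TracerConfig(substrate=s) for s in subs]


def make_peak_table(
    spec: FixtureSpec,
) -> tuple[PeakTable, RelatednessMatrix, set]:
    """Simulate a tracer panel for the network named by ``spec.template``.

    Returns the peak table, the ground-truth relatedness matrix, and the
    f > 1/2 positive-pair labels.  ``spec.n_decoys`` extra peaks with random
    MIDs (unrelated to everything) can be injected to stress false-positive
    behavior.
    """
    network = make_network(spec)
    n_tracers = min(spec.n_tracers, len(network.substrates()))
    tracers = make_tracers(network, n_tracers)
    table = run_tracer_panel(
        network,
        tracers,
        fraction_of_t_ss=spec.fraction_of_t_ss,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    truth = relatedness_matrix(network)
    labels = related_pairs(truth)
    if spec.n_decoys:
        rng = np.random.default_rng(spec.seed + 10_000)
        sizes = sorted({m.n_carbons for m in network.metabolites.values()})
        base = len(table)
        for i in range(spec.n_decoys):
            n = int(sizes[int(rng.integers(len(sizes)))])
            peak = Peak(
                peak_id=f"decoy{i}",
                n_carbons=n,
                mz=12.0 * n + 1.007276 + 0.001 * (base + i),
                rt_seconds=60.0 + 10.0 * (base + i),
            )
            for exp in table.experiments:
                fr = rng.random(n + 1)
                peak.set_mid(exp, MIDVector(fr / fr.sum()))
            table.add_peak(peak)
    return table, truth, labels
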