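"""Isotopically nonstationary and steady-state MID simulation of EMU systems.

Each mass isotopomer of each non-substrate EMU obeys

    dX_E/dt = (1/pool_M) * sum_r v_r * (S_r - X_E)

where the sum runs over the EMU reactions producing E, S_r is the MID of the
source (a single EMU, or the convolution of several for condensations), and
pool_M is the pool size of E's parent metabolite.  At flux steady state the
total producing flux equals the metabolite's consumption, so labeling relaxes
toward the flux-weighted source mixture.  Substrate EMU MIDs are fixed by the
tracer configuration; all other EMUs start unlabeled ([1, 0, ..., 0]).

Steady-state MIDs solve the same balances as a linear system, block by block
in EMU size (convolution sources always involve strictly smaller EMUs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .emu import EMU, EMUSystem, decompose_emu, full_emu
from .mid import ExperimentSet, MIDVector, Peak, PeakTable
from .network import AtomMappedNetwork, TracerConfig

__all__ = [
    "SimulationResult",
    "simulate_nonstationary",
    "simulate_steady_state",
    "sample_pre_steady_state",
    "run_tracer_panel",
    "add_noise",
    "substrate_emu_mid",
]

STEADY_RATE_TOL = 1e-6


def substrate_emu_mid(emu: EMU, tracer: TracerConfig) -> np.ndarray:
    """Fixed MID of a substrate EMU under a tracer configuration.

    A fraction ``labeled_fraction`` of entering molecules carries the label
    (each tracked position 13C with probability given by the labeling pattern
    and purity, independently); the rest is unlabeled.  Natural 13C is not
    modeled here.
    """
    size = emu.size
    unlabeled = np.zeros(size + 1)
    unlabeled[0] = 1.0
    if emu.met_id != tracer.substrate or tracer.labeled_fraction == 0.0:
        return unlabeled
    labeled = np.array([1.0])
    for pos in emu.positions:
        q = tracer.atom_label_probability(pos)
        labeled = np.convolve(labeled, np.array([1.0 - q, q]))
    lf = tracer.labeled_fraction
    return (1.0 - lf) * unlabeled + lf * labeled


@dataclass
class SimulationResult:
    """Per-metabolite MID time courses on a common grid."""

    times: np.ndarray
    mids: dict[str, np.ndarray]  # met -> (n_times, n_carbons+1)
    tracer: TracerConfig
    steady_state_time: float | None = None
    sampled_time: float | None = None

    def mid_at(self, met_id: str, index: int) -> MIDVector:
        fr = np.clip(self.mids[met_id][index], 0.0, None)
        return MIDVector(fr / fr.sum())

    def final_mids(self) -> dict[str, MIDVector]:
        last = len(self.times) - 1
        return {m: self.mid_at(m, last) for m in self.mids}

    def write_tsv(self, path) -> None:
        """Long-form time courses: metabolite, experiment, time, M0..Mn."""
        import pandas as pd

        max_n = max(arr.shape[1] for arr in self.mids.values()) - 1
        rows = []
        exp = self.tracer.experiment_id
        for met in sorted(self.mids):
            arr = self.mids[met]
            for ti, t in enumerate(self.times):
                row = {"metabolite": met, "experiment": exp, "time": t}
                for i in range(max_n + 1):
                    row[f"M{i}"] = (
                        repr(float(arr[ti, i])) if i < arr.shape[1] else ""
                    )
                rows.append(row)
        cols = ["metabolite", "experiment", "time"] + [
            f"M{i}" for i in range(max_n + 1)
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _auto_t_max(network: AtomMappedNetwork) -> float:
    taus = []
    for met in network.metabolites.values():
        if met.is_substrate:
            continue
        cons = network.consumption_flux(met.met_id)
        if cons <= 0:
            continue
        taus.append(met.pool_size / cons)
    if not taus:
        return 1.0
    n = sum(1 for m in network.metabolites.values() if not m.is_substrate)
    return max(taus) * (20.0 + 3.0 * n)


def _build_ode(
    system: EMUSystem, network: AtomMappedNetwork, tracer: TracerConfig
):
    unknowns = [e for e in system.unknown_emus() if e.size > 0]
    slices: dict[EMU, slice] = {}
    offset = 0
    for emu in unknowns:
        slices[emu] = slice(offset, offset + emu.size + 1)
        offset += emu.size + 1
    n_state = offset

    fixed: dict[EMU, np.ndarray] = {}

    def source_vec(emu: EMU, y: np.ndarray) -> np.ndarray:
        if emu in slices:
            return y[slices[emu]]
        v = fixed.get(emu)
        if v is None:
            v = substrate_emu_mid(emu, tracer)
            fixed[emu] = v
        return v

    entries = []  # (slice, pool, [(flux, sources)], total_flux)
    for emu in unknowns:
        met = network.metabolites[emu.met_id]
        if met.pool_size <= 0:
            raise ValueError(f"zero or negative pool size for {emu.met_id!r}")
        prods = system.producers[emu]
        total = sum(p.flux for p in prods)
        entries.append((slices[emu], met.pool_size, prods, total))

    def rhs(t, y):
        dy = np.empty_like(y)
        for sl, pool, prods, total in entries:
            acc = -total * y[sl]
            for p in prods:
                if p.flux == 0.0:
                    continue
                if len(p.sources) == 1:
                    s = source_vec(p.sources[0], y)
                else:
                    s = source_vec(p.sources[0], y)
                    for src in p.sources[1:]:
                        s = np.convolve(s, source_vec(src, y))
                acc = acc + p.flux * s
            dy[sl] = acc / pool
        return dy

    y0 = np.zeros(n_state)
    for emu in unknowns:
        y0[slices[emu].start] = 1.0
    return rhs, y0, slices


def simulate_nonstationary(
    network: AtomMappedNetwork,
    tracer: TracerConfig,
    targets: Iterable[str] | None = None,
    system: EMUSystem | None = None,
    t_max: float | None = None,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the nonstationary EMU ODEs on a log-spaced time grid."""
    if targets is None:
        targets = list(network.metabolites)
    else:
        targets = list(targets)
    if system is None:
        system = decompose_emu(network, targets)
    if t_max is None:
        t_max = _auto_t_max(network)
    rhs, y0, slices = _build_ode(system, network, tracer)
    grid = np.concatenate(
        [[0.0], np.geomspace(t_max * 1e-5, t_max, n_points)]
    )
    if y0.size:
        sol = solve_ivp(
            rhs,
            (0.0, t_max),
            y0,
            method=method,
            t_eval=grid,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed: {sol.message}; consider loosening rtol/atol "
                "or switching method to 'BDF'"
            )
        ys = sol.y  # (n_state, n_times)
    else:
        ys = np.zeros((0, grid.size))
    mids: dict[str, np.ndarray] = {}
    for met_id in targets:
        met = network.metabolites[met_id]
        femu = full_emu(network, met_id)
        if met.n_carbons == 0:
            mids[met_id] = np.ones((grid.size, 1))
        elif met.is_substrate:
            row = substrate_emu_mid(femu, tracer)
            mids[met_id] = np.tile(row, (grid.size, 1))
        else:
            mids[met_id] = ys[slices[femu], :].T.copy()
    return SimulationResult(times=grid, mids=mids, tracer=tracer)


def simulate_steady_state(
    network: AtomMappedNetwork,
    tracer: TracerConfig,
    targets: Iterable[str] | None = None,
    system: EMUSystem | None = None,
) -> dict[str, MIDVector]:
    """Solve the steady-state EMU balances block-by-block (linear)."""
    if targets is None:
        targets = list(network.metabolites)
    else:
        targets = list(targets)
    if system is None:
        system = decompose_emu(network, targets)
    solved: dict[EMU, np.ndarray] = {}

    def known_vec(emu: EMU) -> np.ndarray:
        if system.is_substrate(emu):
            return substrate_emu_mid(emu, tracer)
        return solved[emu]

    for size in system.sizes():
        if size == 0:
            continue
        block = [e for e in system.block(size) if not system.is_substrate(e)]
        if not block:
            continue
        index = {e: i for i, e in enumerate(block)}
        n = len(block)
        a = np.zeros((n, n))
        b = np.zeros((n, size + 1))
        for emu in block:
            i = index[emu]
            prods = system.producers[emu]
            total = sum(p.flux for p in prods)
            a[i, i] += total
            for p in prods:
                if p.flux == 0.0:
                    continue
                if len(p.sources) == 1 and p.sources[0] in index:
                    a[i, index[p.sources[0]]] -= p.flux
                else:
                    if len(p.sources) == 1:
                        vec = known_vec(p.sources[0])
                    else:
                        vec = known_vec(p.sources[0])
                        for src in p.sources[1:]:
                            vec = np.convolve(vec, known_vec(src))
                    b[i, :] += p.flux * vec
        try:
            x = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as err:
            dead = [e.met_id for e in block if sum(
                p.flux for p in system.producers[e]) <= 0]
            raise ValueError(
                "singular EMU block at size "
                f"{size}: metabolite(s) without production path: {dead or block}"
            ) from err
        for emu in block:
            solved[emu] = x[index[emu]]
    out: dict[str, MIDVector] = {}
    for met_id in targets:
        if network.metabolites[met_id].n_carbons == 0:
            out[met_id] = MIDVector(np.array([1.0]))
            continue
        femu = full_emu(network, met_id)
        fr = np.clip(known_vec(femu), 0.0, None)
        out[met_id] = MIDVector(fr / fr.sum())
    return out


def sample_pre_steady_state(
    result: SimulationResult,
    fraction_of_t_ss: float,
    rate_tol: float = STEADY_RATE_TOL,
) -> tuple[dict[str, MIDVector], float]:
    """MIDs at ``fraction_of_t_ss`` times the steady-state attainment time.

    t_ss is the earliest grid time at which the maximum |dMID/dt| (finite
    difference across the grid) falls below ``rate_tol``.  If the grid never
    reaches steady state a warning is issued and the last time point is used.
    Returns (MIDs at the nearest grid point, sampled time).
    """
    if not 0.0 < fraction_of_t_ss <= 1.0:
        raise ValueError("fraction_of_t_ss must be in (0, 1]")
    times = result.times
    stacked = np.hstack([result.mids[m] for m in sorted(result.mids)])
    dt = np.diff(times)
    rates = np.max(np.abs(np.diff(stacked, axis=0)), axis=1) / dt
    below = np.nonzero(rates < rate_tol)[0]
    if below.size == 0:
        warnings.warn(
            "steady state not reached on the simulation grid; sampling from "
            "the last time point",
            stacklevel=2,
        )
        t_ss = times[-1]
    else:
        t_ss = times[below[0] + 1]
    result.steady_state_time = float(t_ss)
    t_sample = fraction_of_t_ss * t_ss
    idx = int(np.argmin(np.abs(times - t_sample)))
    result.sampled_time = float(times[idx])
    return {m: result.mid_at(m, idx) for m in result.mids}, float(times[idx])


def add_noise(table: PeakTable, noise_sd: float, rng: np.random.Generator) -> PeakTable:
    """Additive Gaussian noise on MI fractions, clipped at 0 and renormalized.

    Peaks (sorted by id) and experiments are traversed in a fixed order, so
    a fixed seed reproduces the table bit-identically.
    """
    out = table.copy()
    if noise_sd == 0.0:
        return out
    for pid in sorted(out.peaks):
        peak = out.peaks[pid]
        for exp in out.experiments:
            if exp not in peak.mids:
                continue
            fr = peak.mids[exp].fractions + rng.normal(
                0.0, noise_sd, peak.n_carbons + 1
            )
            fr = np.clip(fr, 0.0, None)
            total = fr.sum()
            if total <= 0.0:  # extreme noise wiped the signal; keep unlabeled
                fr = np.zeros_like(fr)
                fr[0] = 1.0
                total = 1.0
            peak.mids[exp] = MIDVector(fr / total)
    return out


def run_tracer_panel(
    network: AtomMappedNetwork,
    tracers: Sequence[TracerConfig],
    fraction_of_t_ss: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    targets: Iterable[str] | None = None,
    t_max: float | None = None,
    **solver_kwargs,
) -> PeakTable:
    """Simulate a panel of parallel tracer experiments into a PeakTable.

    One experiment per tracer (distinct substrates required); every target
    metabolite becomes one peak.  MIDs are sampled at ``fraction_of_t_ss``
    of each experiment's steady-state attainment time, then optionally
    perturbed with Gaussian noise (see :func:`add_noise`).
    """
    subs = [t.substrate for t in tracers]
    if len(set(subs)) != len(subs):
        raise ValueError("tracers must reference distinct substrates")
    if targets is None:
        targets = list(network.metabolites)
    else:
        targets = list(targets)
    table = PeakTable(ExperimentSet([t.experiment_id for t in tracers]))
    system = decompose_emu(network, targets)
    sampled: dict[str, dict[str, MIDVector]] = {}
    for tracer in tracers:
        if fraction_of_t_ss >= 1.0:
            mids = simulate_steady_state(network, tracer, targets, system=system)
        else:
            result = simulate_nonstationary(
                network, tracer, targets, system=system, t_max=t_max, **solver_kwargs
            )
            mids, _ = sample_pre_steady_state(result, fraction_of_t_ss)
        sampled[tracer.experiment_id] = mids
    for i, met_id in enumerate(sorted(targets)):
        met = network.metabolites[met_id]
        peak = Peak(
            peak_id=met_id,
            n_carbons=met.n_carbons,
            mz=12.0 * met.n_carbons + 1.007276 + 0.001 * i,
            rt_seconds=60.0 + 10.0 * i,
            polarity="+",
            known=met.is_substrate,
        )
        for tracer in tracers:
            peak.set_mid(tracer.experiment_id, sampled[tracer.experiment_id][met_id])
        table.add_peak(peak)
    if noise_sd > 0.0:
        table = add_noise(table, noise_sd, np.random.default_rng(seed))
    return table
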