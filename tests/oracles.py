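"""Independent reference implementations used to check the package.

Everything here is deliberately written in the most direct style possible
(explicit loops, full enumerations) and shares no search/bookkeeping logic
with the package: brute-force convolution, exhaustive convolutant-search
distances, full positional-isotopomer ODE simulation, flux-weighted
atom-fate enumeration, and confusion-count precision-recall.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp


def convolve_bruteforce(a, b):
    """Double-sum convolution (x*y)_k = sum_{i+j=k} x_i y_j."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(a.size + b.size - 1)
    for k in range(out.size):
        acc = 0.0
        for i in range(a.size):
            j = k - i
            if 0 <= j < b.size:
                acc += a[i] * b[j]
        out[k] = acc
    return out


def exhaustive_distances(table, experiments=None):
    """All-pairs convolutant-search distance, naive triple loop.

    Returns dict {(id_a, id_b): (distance, best_convolutant, sentinel_flag)}
    with id_a < id_b; missing-convolutant pairs get the global max over
    defined pairs; pairs with no shared experiment get NaN.
    """
    if experiments is None:
        experiments = list(table.experiments)
    else:
        experiments = list(experiments)
    ids = sorted(table.peaks)
    raw = {}
    for ia in range(len(ids)):
        for ib in range(ia + 1, len(ids)):
            pa, pb = table.peaks[ids[ia]], table.peaks[ids[ib]]
            small, big = (pa, pb) if pa.n_carbons <= pb.n_carbons else (pb, pa)
            shared = [
                e for e in experiments if e in pa.mids and e in pb.mids
            ]
            if not shared:
                raw[(ids[ia], ids[ib])] = (float("nan"), "none", True)
                continue
            if small.n_carbons == big.n_carbons:
                total = 0.0
                for e in shared:
                    total += float(
                        np.linalg.norm(small.mids[e].fractions - big.mids[e].fractions)
                    )
                raw[(ids[ia], ids[ib])] = (total, "direct", False)
                continue
            need = big.n_carbons - small.n_carbons
            best = None
            best_id = None
            for cid in sorted(table.peaks):
                pc = table.peaks[cid]
                if pc.n_carbons != need:
                    continue
                total = 0.0
                used = 0
                for e in shared:
                    if e not in pc.mids:
                        continue
                    conv = np.convolve(
                        small.mids[e].fractions, pc.mids[e].fractions
                    )
                    total += float(np.linalg.norm(conv - big.mids[e].fractions))
                    used += 1
                if used == 0:
                    continue
                if best is None or total < best:
                    best, best_id = total, cid
            if best is None:
                raw[(ids[ia], ids[ib])] = (float("nan"), "none", True)
            else:
                raw[(ids[ia], ids[ib])] = (best, best_id, False)
    defined = [d for d, _, s in raw.values() if not s and not math.isnan(d)]
    global_max = max(defined) if defined else 0.0
    out = {}
    for key, (d, c, s) in raw.items():
        pa, pb = key
        has_shared = any(
            e in table.peaks[pa].mids and e in table.peaks[pb].mids
            for e in experiments
        )
        if s and has_shared:
            out[key] = (global_max, "none", True)
        else:
            out[key] = (d, c, s)
    return out


# ---------------------------------------------------------------------------
# full positional-isotopomer simulation


def _substrate_isotopomer_dist(met, tracer):
    """Joint labeling-state distribution of a substrate (independent atoms)."""
    c = met.n_carbons
    dist = np.zeros(2**c)
    if met.met_id != tracer.substrate or tracer.labeled_fraction == 0.0:
        dist[0] = 1.0
        return dist
    lf = tracer.labeled_fraction
    for state in range(2**c):
        p = 1.0
        for pos in range(c):
            q = tracer.atom_label_probability(pos)
            p *= q if state >> pos & 1 else 1.0 - q
        dist[state] += lf * p
    dist[0] += 1.0 - lf
    return dist


def isotopomer_simulation(network, tracer, t_eval):
    """Integrate the full positional-isotopomer ODEs for every metabolite.

    Returns {met_id: array (n_times, n_carbons + 1)} of MIDs (isotopomer
    distributions summed by number of labeled positions).
    """
    mets = network.metabolites
    unknown = [m for m in sorted(mets) if not mets[m].is_substrate]
    offs = {}
    n_state = 0
    for m in unknown:
        offs[m] = n_state
        n_state += 2 ** mets[m].n_carbons
    fixed = {
        m: _substrate_isotopomer_dist(mets[m], tracer)
        for m in sorted(mets)
        if mets[m].is_substrate
    }

    def met_dist(m, y):
        if m in fixed:
            return fixed[m]
        o = offs[m]
        return y[o : o + 2 ** mets[m].n_carbons]

    def marginal(dist, positions):
        """Distribution of the labeling pattern restricted to ``positions``."""
        out = np.zeros(2 ** len(positions))
        for state, p in enumerate(dist):
            if p == 0.0:
                continue
            pat = 0
            for bit, pos in enumerate(positions):
                if state >> pos & 1:
                    pat |= 1 << bit
            out[pat] += p
        return out

    cons = {m: network.consumption_flux(m) for m in unknown}

    def rhs(t, y):
        dy = np.zeros_like(y)
        for rxn in network.reactions:
            if rxn.flux == 0.0:
                continue
            dists = [met_dist(term.met_id, y) for term in rxn.reactants]
            for term in rxn.products:
                m = term.met_id
                if mets[m].is_substrate:
                    continue
                c = mets[m].n_carbons
                # product position p sourced from (reactant idx, position q)
                src = []
                for p in range(c):
                    letter = term.atoms[p]
                    for ridx, rterm in enumerate(rxn.reactants):
                        q = rterm.atoms.find(letter)
                        if q >= 0:
                            src.append((ridx, q))
                            break
                by_r = {}
                for p, (ridx, q) in enumerate(src):
                    by_r.setdefault(ridx, []).append((p, q))
                q_dist = np.zeros(2**c)
                margs = [
                    (plist, marginal(dists[ridx], [q for _, q in plist]))
                    for ridx, plist in sorted(by_r.items())
                ]
                for state in range(2**c):
                    prob = 1.0
                    for plist, marg in margs:
                        pat = 0
                        for bit, (p, _q) in enumerate(plist):
                            if state >> p & 1:
                                pat |= 1 << bit
                        prob *= marg[pat]
                    q_dist[state] = prob
                o = offs[m]
                dy[o : o + 2**c] += rxn.flux * q_dist
        for m in unknown:
            o = offs[m]
            size = 2 ** mets[m].n_carbons
            dy[o : o + size] -= cons[m] * y[o : o + size]
            dy[o : o + size] /= mets[m].pool_size
        return dy

    y0 = np.zeros(n_state)
    for m in unknown:
        y0[offs[m]] = 1.0
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), y0, method="LSODA", t_eval=t_eval,
        rtol=1e-10, atol=1e-12,
    )
    assert sol.success, sol.message
    out = {}
    for m in sorted(mets):
        c = mets[m].n_carbons
        mid = np.zeros((t_eval.size, c + 1))
        if m in fixed:
            for state, p in enumerate(fixed[m]):
                mid[:, bin(state).count("1")] += p
        else:
            o = offs[m]
            for state in range(2**c):
                mid[:, bin(state).count("1")] += sol.y[o + state, :]
        out[m] = mid
    return out


def atom_fate_contribution(network, source, target):
    """Fraction of ``target``'s carbon from ``source`` by atom-fate solving.

    Linear system over atoms: the from-source fraction of a carbon equals the
    production-flux-weighted average of the fractions of its reactant atoms;
    atoms of ``source`` are 1, atoms of other substrates 0.
    """
    mets = network.metabolites
    atoms = []
    index = {}
    for m in sorted(mets):
        for pos in range(mets[m].n_carbons):
            index[(m, pos)] = len(atoms)
            atoms.append((m, pos))
    n = len(atoms)
    a = np.eye(n)
    b = np.zeros(n)
    for (m, pos), i in index.items():
        if m == source:
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = 1.0
            continue
        if mets[m].is_substrate:
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = 0.0
            continue
        production = network.production_flux(m)
        # equation: production * x_i - sum_r flux * x_source = 0
        a[i, :] = 0.0
        a[i, i] = production
        for rxn in network.reactions:
            for term in rxn.products:
                if term.met_id != m:
                    continue
                letter = term.atoms[pos]
                for rterm in rxn.reactants:
                    q = rterm.atoms.find(letter)
                    if q >= 0:
                        if rterm.met_id == source:
                            b[i] += rxn.flux
                        elif mets[rterm.met_id].is_substrate:
                            pass  # contributes 0
                        else:
                            a[i, index[(rterm.met_id, q)]] -= rxn.flux
                        break
    x = np.linalg.solve(a, b)
    if target == source:
        return 1.0
    c = mets[target].n_carbons
    if c == 0:
        return 0.0
    return float(np.mean([x[index[(target, pos)]] for pos in range(c)]))


def pr_curve_bruteforce(pair_distances, positive_pairs):
    """PR points by explicit confusion counting at every unique threshold.

    ``pair_distances``: dict {frozenset({a, b}): distance}.  Returns
    (thresholds, precision, recall, aupr).
    """
    items = sorted(pair_distances.items(), key=lambda kv: kv[1])
    n_pos = sum(1 for pair in pair_distances if pair in positive_pairs)
    thresholds = sorted(set(pair_distances.values()))
    precision, recall = [], []
    for t in thresholds:
        tp = fp = 0
        for pair, d in items:
            if d <= t:
                if pair in positive_pairs:
                    tp += 1
                else:
                    fp += 1
        precision.append(tp / (tp + fp))
        recall.append(tp / n_pos)
    xs = [0.0] + recall
    ys = [precision[0]] + precision
    aupr = 0.0
    for i in range(1, len(xs)):
        aupr += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2.0
    return thresholds, precision, recall, aupr


def single_linkage_groups(ids, linked):
    """Connected components given a set of linked unordered pairs."""
    groups = {i: {i} for i in ids}
    for a, b in linked:
        ga, gb = groups[a], groups[b]
        if ga is not gb:
            merged = ga | gb
            for m in merged:
                groups[m] = merged
    seen, out = set(), []
    for i in ids:
        key = frozenset(groups[i])
        if key not in seen:
            seen.add(key)
            out.append(sorted(groups[i]))
    return sorted(out)
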