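"""Numba-compiled inner loops for the agent-based simulation.

One generation is: a movement realization with one round of games fixing
realized fitness, a return home, a second movement realization with no
games, and a single birth-death replacement inside the reproducer's current
group.  Everything operates on preallocated scratch arrays; the legacy
NumPy global RNG is seeded per replicate so runs are reproducible and
order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MECH_INDEPENDENT = 0
MECH_FTM = 1
MECH_URN = 2
MECH_WHEEL = 3

GAME_PGG = 0
GAME_HD = 1

DYN_BDB = 0
DYN_BDD = 1


@njit(cache=True)
def _sample_places(place, parts, N, M, p_home, p_rand, mech, B, theta_frac):
    """Fill ``place`` with one movement realization of all N individuals."""
    n_parts = 0
    if p_home + p_rand == 0.0:
        for i in range(N):
            parts[i] = i
            place[i] = -1
        n_parts = N
    else:
        for i in range(N):
            u = np.random.random()
            if u < p_home:
                place[i] = i
            elif u < p_home + p_rand:
                j = np.random.randint(0, M - 1)
                place[i] = j if j < i else j + 1
            else:
                parts[n_parts] = i
                n_parts += 1
                place[i] = -1
    if n_parts == 0:
        return
    # uniformly random mover order (Fisher-Yates)
    for t in range(n_parts - 1, 0, -1):
        j = np.random.randint(0, t + 1)
        tmp = parts[t]
        parts[t] = parts[j]
        parts[j] = tmp
    if mech == MECH_INDEPENDENT:
        for t in range(n_parts):
            place[parts[t]] = np.random.randint(0, M)
    elif mech == MECH_FTM or (mech == MECH_URN and B == 0.0):
        L = np.random.randint(0, M)
        for t in range(n_parts):
            place[parts[t]] = L
    elif mech == MECH_URN:
        occ = np.zeros(M, np.int64)
        a = B / M
        for t in range(n_parts):
            total = B + t
            r = np.random.random() * total
            acc = 0.0
            m_sel = M - 1
            for m in range(M):
                acc += a + occ[m]
                if r <= acc:
                    m_sel = m
                    break
            place[parts[t]] = m_sel
            occ[m_sel] += 1
    else:  # wheel, equal arcs of length 1/M
        phi = np.random.random()
        for t in range(n_parts):
            pos = (t * theta_frac + phi) % 1.0
            m = int(pos * M)
            if m >= M:
                m = M - 1
            place[parts[t]] = m


@njit(cache=True)
def _assign_payoffs(fit, place, types, n_tot, n_mut, N, M, game, mutant_is_A, R, V, C):
    """Realized one-round payoffs from the current placement."""
    for m in range(M):
        n_tot[m] = 0
        n_mut[m] = 0
    for i in range(N):
        n_tot[place[i]] += 1
        if types[i] == 1:
            n_mut[place[i]] += 1
    for i in range(N):
        g_tot = n_tot[place[i]]
        g_mut = n_mut[place[i]]
        a = g_mut if mutant_is_A else g_tot - g_mut
        b = g_tot - a
        is_A = (types[i] == 1) == mutant_is_A
        if game == GAME_PGG:
            if is_A:
                if a == 1:
                    fit[i] = R - C
                else:
                    fit[i] = R - C + (a - 1) / (g_tot - 1) * V
            else:
                if a == 0:
                    fit[i] = R
                else:
                    fit[i] = R + a / (g_tot - 1) * V
        else:
            if is_A:
                fit[i] = R + (V - (a - 1) * C) / a
            else:
                if a > 0:
                    fit[i] = R
                else:
                    fit[i] = R + V / b


@njit(cache=True)
def run_batch(
    n_reps,
    N,
    M,
    mech,
    p_home,
    p_rand,
    B,
    theta_frac,
    game,
    mutant_is_A,
    R,
    V,
    C,
    dynamics,
    exclude_parent,
    max_steps,
    seeds,
    idealized,
    FM_by_k,
    FR_by_k,
):
    """Run ``n_reps`` independent invasion trials.

    Returns (outcome, steps): outcome 1 = mutant fixed, 0 = extinct,
    -1 = not absorbed within ``max_steps``.  In idealized mode, fitnesses
    are the state-dependent means ``FM_by_k``/``FR_by_k`` instead of
    realized payoffs.
    """
    outcome = np.empty(n_reps, np.int8)
    steps = np.empty(n_reps, np.int64)
    place = np.empty(N, np.int64)
    place2 = np.empty(N, np.int64)
    parts = np.empty(N, np.int64)
    types = np.empty(N, np.int8)
    fit = np.empty(N, np.float64)
    n_tot = np.empty(M, np.int64)
    n_tot2 = np.empty(M, np.int64)
    n_mut = np.empty(M, np.int64)
    members = np.empty(N, np.int64)
    for rep in range(n_reps):
        np.random.seed(seeds[rep])
        for i in range(N):
            types[i] = 0
        types[np.random.randint(0, N)] = 1
        k = 1
        t = 0
        while 0 < k < N and t < max_steps:
            t += 1
            # The replacement-round placement is independent of the game
            # round, so sample it first: if every individual is alone the
            # offspring necessarily replaces its own parent and the
            # generation cannot change the state, whatever the fitnesses.
            _sample_places(place, parts, N, M, p_home, p_rand, mech, B, theta_frac)
            any_pair = False
            for m in range(M):
                n_tot[m] = 0
            for i in range(N):
                n_tot[place[i]] += 1
                if n_tot[place[i]] >= 2:
                    any_pair = True
            if not any_pair:
                continue
            if idealized:
                for i in range(N):
                    fit[i] = FM_by_k[k] if types[i] == 1 else FR_by_k[k]
            else:
                # game-round placement and realized payoffs
                _sample_places(
                    place2, parts, N, M, p_home, p_rand, mech, B, theta_frac
                )
                _assign_payoffs(
                    fit, place2, types, n_tot2, n_mut, N, M, game, mutant_is_A, R, V, C
                )
            if dynamics == DYN_BDB:
                tot = 0.0
                for i in range(N):
                    tot += fit[i]
                r = np.random.random() * tot
                acc = 0.0
                rep_i = N - 1
                for i in range(N):
                    acc += fit[i]
                    if r <= acc:
                        rep_i = i
                        break
            else:
                rep_i = np.random.randint(0, N)
            pm = place[rep_i]
            nmem = 0
            for i in range(N):
                if place[i] == pm and i != rep_i:
                    members[nmem] = i
                    nmem += 1
            if nmem == 0:
                victim = rep_i
            elif dynamics == DYN_BDB:
                if exclude_parent:
                    victim = members[np.random.randint(0, nmem)]
                else:
                    j = np.random.randint(0, nmem + 1)
                    victim = rep_i if j == nmem else members[j]
            else:
                totw = 0.0
                for j in range(nmem):
                    totw += 1.0 / fit[members[j]]
                r = np.random.random() * totw
                acc = 0.0
                victim = members[nmem - 1]
                for j in range(nmem):
                    acc += 1.0 / fit[members[j]]
                    if r <= acc:
                        victim = members[j]
                        break
            if types[victim] != types[rep_i]:
                if types[rep_i] == 1:
                    k += 1
                else:
                    k -= 1
                types[victim] = types[rep_i]
        steps[rep] = t
        if k == N:
            outcome[rep] = 1
        elif k == 0:
            outcome[rep] = 0
        else:
            outcome[rep] = -1
    return outcome, steps
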