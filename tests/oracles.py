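"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the purine-tract
oracle checks every O(L^2) substring with prefix sums, and the steady-state
oracle writes out the circuit's rate equations by hand and solves them with
a generic root finder.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import fsolve

PURINES = set("AG")


def brute_force_sites(seq: str) -> set[tuple[int, int]]:
    """All maximal qualifying purine tracts of a sequence, by exhaustive
    enumeration of substrings.

    A substring [a, b) qualifies when it starts and ends with a purine,
    contains no N and no two consecutive non-purines.  It is maximal when
    it is not properly contained in another qualifying substring (one-sided
    extension may need two characters to reach the next purine, so
    containment, not single-character extension, is the right test).
    Equivalently: with R(a) the furthest qualifying end from start a, the
    maximal set is {(a, R(a)) : R(a) > R(a') for every a' < a}.
    """
    L = len(seq)
    if L == 0:
        return set()
    pur = np.array([c in PURINES for c in seq])
    nonpur = ~pur
    isn = np.array([c == "N" for c in seq])
    # cumulative counts: cn[i] = #N in seq[:i]; cp[i] = #bad pairs fully in seq[:i+1]
    cn = np.concatenate([[0], np.cumsum(isn)])
    pair = nonpur[:-1] & nonpur[1:]
    cp = np.concatenate([[0], np.cumsum(pair)])

    valid = np.zeros((L, L + 1), dtype=bool)
    for start in range(L):
        if not pur[start]:
            continue
        for end in range(start + 1, L + 1):
            if not pur[end - 1]:
                continue
            if cn[end] - cn[start] > 0:
                continue
            if end - start >= 2 and cp[end - 1] - cp[start] > 0:
                continue
            valid[start, end] = True

    maximal = set()
    best_end = -1
    for start in range(L):
        ends = [end for end in range(start + 1, L + 1) if valid[start, end]]
        if not ends:
            continue
        furthest = max(ends)
        if furthest > best_end:
            maximal.add((start, furthest))
            best_end = furthest
    return maximal


def brute_force_sites_fast(seq: str) -> set[tuple[int, int]]:
    """Vectorized variant of :func:`brute_force_sites` (same definition,
    numpy broadcasting over all substring (start, end) pairs)."""
    L = len(seq)
    if L == 0:
        return set()
    pur = np.array([c in PURINES for c in seq])
    nonpur = ~pur
    isn = np.array([c == "N" for c in seq])
    cn = np.concatenate([[0], np.cumsum(isn)])
    pair = nonpur[:-1] & nonpur[1:]
    cp = np.concatenate([[0], np.cumsum(pair)])

    starts = np.arange(L)[:, None]
    ends = np.arange(L + 1)[None, :]
    nonempty = ends > starts
    end_idx = np.clip(ends - 1, 0, L - 1)
    valid = (
        nonempty
        & pur[starts[:, 0]][:, None]
        & pur[end_idx]
        & (cn[ends] - cn[np.minimum(starts, L)] == 0)
        & (
            (ends - starts < 2)
            | (cp[np.clip(ends - 1, 0, L)] - cp[starts[:, 0]][:, None] == 0)
        )
    )
    has_any = valid.any(axis=1)
    furthest = np.where(has_any, (valid * np.arange(L + 1)[None, :]).max(axis=1), -1)
    maximal = set()
    best_end = -1
    for a in range(L):
        if furthest[a] > best_end:
            maximal.add((a, int(furthest[a])))
            best_end = int(furthest[a])
    return maximal


def steady_state_handwritten(p, n: int | None = None) -> dict[str, float]:
    """Steady state of the circuit rate equations, written out by hand and
    solved with a generic root finder.

    ``p`` is a CircuitParameters-like object.  Returns a name->value dict.
    """
    n = p.copy_number if n is None else n

    def equations(v):
        X, D1, D2, M, T, C, G = v
        D0 = n - D1 - D2
        dX = p.f * p.dox_ext - p.g_dox * X - p.k_seq_on * T * X + p.k_seq_off * C
        dC = p.k_seq_on * T * X - (p.k_seq_off + p.d_complex) * C
        dD1 = 2 * p.r * D0 * T - p.k_off * D1 - p.r * D1 * T + 2 * p.k_off * D2
        dD2 = p.r * D1 * T - 2 * p.k_off * D2
        dM = p.m * (D0 + p.leak_r1 * D1 + p.leak_r2 * D2) - p.d_m * M
        dT = (
            p.k_tl_tetr * M
            - p.d_tetr * T
            - 2 * p.r * D0 * T
            + p.k_off * D1
            - p.r * D1 * T
            + 2 * p.k_off * D2
            - p.k_seq_on * T * X
            + p.k_seq_off * C
        )
        dG = p.k_tl_gfp * M - p.d_gfp * G
        return [dX, dC, dD1, dD2, dM, dT, dG]

    # crude but adequate starting point
    m_eff = n * p.m * max(p.leak_r2, 0.01)
    guess = [
        p.f * p.dox_ext / max(p.g_dox, 1e-6) * 0.1,
        n * 0.3,
        n * 0.3,
        m_eff / p.d_m if p.d_m > 0 else 1.0,
        10.0,
        1.0,
        10.0,
    ]
    sol, info, ier, msg = fsolve(equations, guess, full_output=True, xtol=1e-13)
    if ier != 1:  # retry from a repression-free guess
        guess2 = [0.1, 0.0, 0.0, n * p.m / max(p.d_m, 1e-9), 1.0, 0.1, 1.0]
        sol, info, ier, msg = fsolve(equations, guess2, full_output=True, xtol=1e-13)
    assert ier == 1, f"oracle root-find failed: {msg}"
    X, D1, D2, M, T, C, G = sol
    return {
        "Dox_int": X,
        "D_free": n - D1 - D2,
        "D_R1": D1,
        "D_R2": D2,
        "mRNA": M,
        "TetR_free": T,
        "TetR_Dox": C,
        "eGFP": G,
    }
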