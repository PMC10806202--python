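"""Compiled replay kernels.

The likelihood of a session is a strictly sequential recursion over ~10^3
events, evaluated ~10^4 times per fit by the optimizer, so the inner loop is
JIT-compiled.  `loglik_core` computes only the summed log-likelihood;
`replay_core` additionally fills per-event trajectory arrays.  Both must
agree with the pure-Python reference path in :mod:`prtrace.models` /
:mod:`prtrace.task` to ~1e-12 (asserted in the test suite).

Model kind codes: 0 SimpleQ, 1 asymmetry, 2 perseverance, 3 NoLearn.
Event codes: 0 ALP, 1 MNP, 2 ILP, 3 REWARD.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_CODE = {"simpleq": 0, "asymmetry": 1, "perseverance": 2, "nolearn": 3}


@njit(cache=True)
def loglik_core(codes, kind, alpha, alpha_pos, alpha_neg, beta,
                q0a, q0m, q0i, tau, pha, phm, phi):
    """Summed log choice probability over free-choice events.

    REWARD events (code 3) apply the forced-MNP update with r = 1 and add no
    likelihood term.  Returns (loglik, n_choice_events).
    """
    q = np.empty(3)
    q[0] = q0a; q[1] = q0m; q[2] = q0i
    c = np.zeros(3)
    trace = kind >= 2
    ll = 0.0
    n = 0
    for idx in range(codes.shape[0]):
        ev = codes[idx]
        if ev == 3:
            chosen = 1
            r = 1.0
        else:
            chosen = ev
            r = 0.0
            l0 = beta * q[0]
            l1 = beta * q[1]
            l2 = beta * q[2]
            if trace:
                l0 += pha * c[0]
                l1 += phm * c[1]
                l2 += phi * c[2]
            m = l0
            if l1 > m:
                m = l1
            if l2 > m:
                m = l2
            lse = m + math.log(math.exp(l0 - m) + math.exp(l1 - m) + math.exp(l2 - m))
            if ev == 0:
                ll += l0 - lse
            elif ev == 1:
                ll += l1 - lse
            else:
                ll += l2 - lse
            n += 1
        rpe = r - q[chosen]
        if kind == 0 or kind == 2:
            a_eff = alpha
        elif kind == 1:
            a_eff = alpha_pos if rpe >= 0.0 else alpha_neg
        else:
            a_eff = 0.0
        q[chosen] += a_eff * rpe
        if trace:
            for a in range(3):
                ind = 1.0 if a == chosen else 0.0
                c[a] += tau * (ind - c[a])
    return ll, n


@njit(cache=True)
def replay_core(codes, kind, alpha, alpha_pos, alpha_neg, beta,
                q0a, q0m, q0i, tau, pha, phm, phi,
                p_chosen, rpe_out, q_out, c_out):
    """Full replay: same recursion as `loglik_core`, also recording the
    probability of each chosen action (NaN at rewards), the RPE and the
    post-update q/c triples per event."""
    q = np.empty(3)
    q[0] = q0a; q[1] = q0m; q[2] = q0i
    c = np.zeros(3)
    trace = kind >= 2
    ll = 0.0
    n = 0
    for idx in range(codes.shape[0]):
        ev = codes[idx]
        if ev == 3:
            chosen = 1
            r = 1.0
            p_chosen[idx] = np.nan
        else:
            chosen = ev
            r = 0.0
            l0 = beta * q[0]
            l1 = beta * q[1]
            l2 = beta * q[2]
            if trace:
                l0 += pha * c[0]
                l1 += phm * c[1]
                l2 += phi * c[2]
            m = l0
            if l1 > m:
                m = l1
            if l2 > m:
                m = l2
            lse = m + math.log(math.exp(l0 - m) + math.exp(l1 - m) + math.exp(l2 - m))
            if ev == 0:
                lp = l0 - lse
            elif ev == 1:
                lp = l1 - lse
            else:
                lp = l2 - lse
            ll += lp
            p_chosen[idx] = math.exp(lp)
            n += 1
        rpe = r - q[chosen]
        rpe_out[idx] = rpe
        if kind == 0 or kind == 2:
            a_eff = alpha
        elif kind == 1:
            a_eff = alpha_pos if rpe >= 0.0 else alpha_neg
        else:
            a_eff = 0.0
        q[chosen] += a_eff * rpe
        if trace:
            for a in range(3):
                ind = 1.0 if a == chosen else 0.0
                c[a] += tau * (ind - c[a])
        for a in range(3):
            q_out[idx, a] = q[a]
            c_out[idx, a] = c[a]
    return ll, n
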