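"""Independent brute-force oracle for the replay likelihood.

Deliberately written in a different style from the package (dict state,
label strings, naive softmax without log-space tricks) so that agreement
with the compiled replay kernel is evidence of correctness, not shared
bugs.  Only suitable for moderate logits (naive exp), which the random
test regimes respect.
"""

import math

ACTIONS = ["ALP", "MNP", "ILP"]


def oracle_replay(labels, params, kind):
    """Step through `labels` (event label strings incl. "REWARD") under a
    parameter dict on the natural scale.

    Returns (loglik, n_choice_terms, rpe_list, q_history, c_history).
    """
    q = {a: params[f"q0_{a}"] for a in ACTIONS}
    c = {a: 0.0 for a in ACTIONS}
    has_trace = kind in ("perseverance", "nolearn")
    loglik = 0.0
    n = 0
    rpes = []
    q_hist, c_hist = [], []
    for lab in labels:
        if lab == "REWARD":
            chosen, r = "MNP", 1.0
        else:
            chosen, r = lab, 0.0
            weights = {}
            for a in ACTIONS:
                logit = params["beta"] * q[a]
                if has_trace:
                    logit += params[f"phi_{a}"] * c[a]
                weights[a] = math.exp(logit)
            total = sum(weights.values())
            loglik += math.log(weights[chosen] / total)
            n += 1
        rpe = r - q[chosen]
        rpes.append(rpe)
        if kind == "simpleq" or kind == "perseverance":
            lr = params["alpha"]
        elif kind == "asymmetry":
            lr = params["alpha_pos"] if rpe >= 0 else params["alpha_neg"]
        else:  # nolearn
            lr = 0.0
        q[chosen] = q[chosen] + lr * rpe
        if has_trace:
            for a in ACTIONS:
                ind = 1.0 if a == chosen else 0.0
                c[a] = c[a] + params["tau"] * (ind - c[a])
        q_hist.append(dict(q))
        c_hist.append(dict(c))
    return loglik, n, rpes, q_hist, c_hist


def random_params(rng, kind):
    """Natural-scale parameter dict with moderate values (naive-exp safe)."""
    p = {
        "beta": rng.uniform(0.0, 8.0),
        "alpha": rng.uniform(0.0, 1.0),
        "alpha_pos": rng.uniform(0.0, 1.0),
        "alpha_neg": rng.uniform(0.0, 1.0),
        # tau >= 0 keeps traces in [0, 1] (negative tau makes them diverge
        # geometrically, overflowing the naive exp; covered by a smoke test)
        "tau": rng.uniform(0.0, 1.0),
    }
    for a in ACTIONS:
        p[f"q0_{a}"] = rng.uniform(-1.0, 1.0)
        p[f"phi_{a}"] = rng.uniform(-6.0, 6.0)
    return p


def random_labels(rng, n):
    """A random event sequence; REWARD events sprinkled in like a PR log."""
    labs = [ACTIONS[i] for i in rng.integers(0, 3, size=n)]
    for i in rng.choice(n, size=max(1, n // 12), replace=False):
        labs[i] = "REWARD"
    return labs
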