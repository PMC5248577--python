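"""Independent reference implementations used only by the test suite.

Deliberately written from first principles (explicit truth tables,
scalar loops, independent optimisers) so they share no code path with
the package internals they check.
"""

import math

import numpy as np
from scipy.optimize import minimize


def brute_force_site_loglik(yA_row, yB_row, p):
    """Enumerate the four latent states and multiply per-occasion terms.

    ``p`` is a dict with keys psiA, psiBA, psiBa, pA, pB, rA, rBA, rBa.
    NaN observations are unsurveyed and contribute factor 1.
    """
    priors = {
        "both": p["psiA"] * p["psiBA"],
        "a_only": p["psiA"] * (1 - p["psiBA"]),
        "b_only": (1 - p["psiA"]) * p["psiBa"],
        "neither": (1 - p["psiA"]) * (1 - p["psiBa"]),
    }
    total = 0.0
    for state, prior in priors.items():
        prob = prior
        for a, b in zip(yA_row, yB_row):
            if math.isnan(a):
                continue
            a, b = int(a), int(b)
            if state == "both":
                pa = p["rA"] if a == 1 else 1 - p["rA"]
                rb = p["rBA"] if a == 1 else p["rBa"]
                pb = rb if b == 1 else 1 - rb
                prob *= pa * pb
            elif state == "a_only":
                prob *= 0.0 if b == 1 else (p["pA"] if a == 1 else 1 - p["pA"])
            elif state == "b_only":
                prob *= 0.0 if a == 1 else (p["pB"] if b == 1 else 1 - p["pB"])
            else:
                prob *= 0.0 if (a == 1 or b == 1) else 1.0
        total += prob
    return math.log(total)


def single_species_mle(y):
    """Numerical MLE of the standard single-season occupancy model.

    ``y``: (S, J) binary detection matrix, no missing values. Returns
    (psi_hat, p_hat, loglik) by direct maximisation of
    sum_i log( psi p^d_i (1-p)^(J-d_i) + (1-psi) [d_i = 0] ).
    """
    y = np.asarray(y, float)
    S, J = y.shape
    d = y.sum(axis=1)

    def nll(x):
        psi, p = 1 / (1 + np.exp(-x[0])), 1 / (1 + np.exp(-x[1]))
        like = psi * p**d * (1 - p) ** (J - d) + (1 - psi) * (d == 0)
        return -np.sum(np.log(like))

    best = None
    for x0 in ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0]):
        r = minimize(nll, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or r.fun < best.fun:
            best = r
    psi, p = 1 / (1 + np.exp(-best.x[0])), 1 / (1 + np.exp(-best.x[1]))
    return psi, p, -best.fun


def random_history(rng, max_sites=3, max_occ=4, allow_missing=True):
    """A random tiny paired detection instance with a shared mask."""
    S = rng.integers(1, max_sites + 1)
    J = rng.integers(1, max_occ + 1)
    yA = rng.integers(0, 2, (S, J)).astype(float)
    yB = rng.integers(0, 2, (S, J)).astype(float)
    if allow_missing:
        mask = rng.random((S, J)) < 0.25
        # keep at least one surveyed occasion per site
        for i in range(S):
            if mask[i].all():
                mask[i, rng.integers(0, J)] = False
        yA[mask] = np.nan
        yB[mask] = np.nan
    return yA, yB


def random_params(rng):
    keys = ("psiA", "psiBA", "psiBa", "pA", "pB", "rA", "rBA", "rBa")
    return {k: float(rng.uniform(0.05, 0.95)) for k in keys}
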