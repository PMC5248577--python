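"""Conditional two-species occupancy model with covariates.

The single-season conditional parameterisation describes co-occurrence
of a dominant species A and a subordinate species B at S sites over J
repeat survey occasions with imperfect detection. Eight parameter types:

occupancy
    psiA — probability a site is used by A;
    psiBA — probability B uses the site given A does;
    psiBa — probability B uses the site given A does not;
detection (time-constant within the season)
    pA — detection of A when B is absent;
    pB — detection of B when A is absent;
    rA — detection of A when both are present;
    rBA — detection of B when both are present and A was detected
    that occasion;
    rBa — detection of B when both are present and A was not detected.

The site likelihood marginalises the 4 latent states (both, A only,
B only, neither). The derived Species Interaction Factor

    phi = psiA*psiBA / (psiA * (psiA*psiBA + (1 - psiA)*psiBa))

is the ratio of joint occupancy to the product of the marginals: 1 under
independence, > 1 when B aggregates with A, < 1 under avoidance.

All eight parameters use a logit link; covariates (site-level prey
detection proportions, a road flag, survey-year groups) enter additively
on the logit scale. Model ranking uses AICc with the number of site-year
units as effective sample size.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit as _logit, logsumexp
from sklearn.base import BaseEstimator

from .records import TwoSpeciesHistory

__all__ = [
    "PARAM_NAMES",
    "OccupancyParams",
    "ModelSpec",
    "ConditionalTwoSpeciesOccupancy",
    "logit",
    "inv_logit",
    "state_probs",
    "occasion_prob",
    "site_loglik",
    "aicc",
    "model_selection_table",
    "sif",
    "sif_se",
    "psi2",
    "fit_model",
    "DEFAULT_MODEL_STRINGS",
]

PARAM_NAMES = ("psiA", "psiBA", "psiBa", "pA", "pB", "rA", "rBA", "rBa")

_EPS = 1e-12


def logit(p):
    """Log-odds; domain (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires 0 < p < 1")
    out = _logit(p)
    return float(out) if out.ndim == 0 else out

def inv_logit(x):
    """Inverse logit (logistic); monotone, inv_logit(0) = 0.5."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OccupancyParams:
    """The eight real-scale parameters for one site."""

    psiA: float
    psiBA: float
    psiBa: float
    pA: float
    pB: float
    rA: float
    rBA: float
    rBa: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


def state_probs(psiA, psiBA, psiBa) -> np.ndarray:
    """Prior over latent states (both, A only, B only, neither); sums to 1."""
    psiA, psiBA, psiBa = (np.asarray(v, dtype=float) for v in (psiA, psiBA, psiBa))
    return np.stack(
        [
            psiA * psiBA,
            psiA * (1.0 - psiBA),
            (1.0 - psiA) * psiBa,
            (1.0 - psiA) * (1.0 - psiBa),
        ],
        axis=-1,
    )


_STATES = ("AB", "A", "B", "none")


def occasion_prob(state: str, obs, params: OccupancyParams) -> float:
    """Probability of one occasion's observation given the latent state.

    ``obs`` is a (yA, yB) pair or None for a missing occasion (which
    contributes probability 1). States that cannot produce the observed
    detections (e.g. B detected where B is absent) have probability 0 —
    there are no false positives.
    """
    if obs is None:
        return 1.0
    yA, yB = obs
    if state == "AB":
        a = params.rA if yA else 1.0 - params.rA
        r_b = params.rBA if yA else params.rBa
        return a * (r_b if yB else 1.0 - r_b)
    if state == "A":
        if yB:
            return 0.0
        return params.pA if yA else 1.0 - params.pA
    if state == "B":
        if yA:
            return 0.0
        return params.pB if yB else 1.0 - params.pB
    if state == "none":
        return 0.0 if (yA or yB) else 1.0
    raise ValueError(f"unknown state {state!r}")


def site_loglik(yA_row, yB_row, params: OccupancyParams) -> float:
    """Log-likelihood of one site's paired detection history.

    Marginalises the latent state: log sum over the 4 states of the
    state prior times the product of per-occasion observation
    probabilities. NaN entries are unsurveyed occasions and contribute
    a factor of 1. A fully unsurveyed site contributes 0 (with warning).
    """
    yA_row = np.asarray(yA_row, dtype=float)
    yB_row = np.asarray(yB_row, dtype=float)
    obs = [
        None if np.isnan(a) else (int(a), int(b))
        for a, b in zip(yA_row, yB_row)
    ]
    if all(o is None for o in obs):
        warnings.warn("site with no surveyed occasion contributes 0", stacklevel=2)
        return 0.0
    priors = state_probs(params.psiA, params.psiBA, params.psiBa)
    total = 0.0
    for prior, state in zip(priors, _STATES):
        prod = prior
        for o in obs:
            prod *= occasion_prob(state, o, params)
        total += prod
    return float(np.log(total))


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative design for the eight parameters.

    ``design`` maps each parameter to a formula string: ``"."``
    (intercept only), ``"y"`` (year-group factor), a covariate name
    (e.g. ``"deer"``), or ``"y*<cov>"`` (year-by-covariate interaction).
    ``constraints`` lists groups of parameters forced to share one
    design and one coefficient block, e.g. ``(("pA", "rA"),)``.
    """

    design: dict = field(default_factory=dict)
    constraints: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        for p in PARAM_NAMES:
            if p not in self.design:
                raise ValueError(f"design missing parameter {p}")
        for group in self.constraints:
            forms = {self.design[p] for p in group}
            if len(forms) != 1:
                raise ValueError(f"constrained group {group} must share one design")

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        """Parse a compact model string.

        Example: ``"psiA(deer) psiBA(y*peccary) psiBa(y*peccary)
        pA=rA(.) pB=rBA=rBa(.)"``.
        """
        design: dict[str, str] = {}
        constraints: list[tuple[str, ...]] = []
        for token in re.findall(r"([\w=]+)\(([^()]*)\)", text):
            names = tuple(token[0].split("="))
            formula = token[1].strip() or "."
            for nm in names:
                if nm not in PARAM_NAMES:
                    raise ValueError(f"unknown parameter {nm!r} in model string")
                if nm in design:
                    raise ValueError(f"parameter {nm} specified twice")
                design[nm] = formula
            if len(names) > 1:
                constraints.append(names)
        return cls(design=design, constraints=tuple(constraints), name=text.strip())

    def blocks(self) -> list[tuple[str, ...]]:
        """Coefficient blocks: constrained groups plus free singletons."""
        grouped = {p for g in self.constraints for p in g}
        out = list(self.constraints)
        out.extend((p,) for p in PARAM_NAMES if p not in grouped)
        # stable order: by first member's position in PARAM_NAMES
        return sorted(out, key=lambda g: PARAM_NAMES.index(g[0]))


# candidate set following the stepwise recipe: detection structures first,
# then dominant-species presence, then subordinate presence
DEFAULT_MODEL_STRINGS = [
    "psiA(deer) psiBA(y*peccary) psiBa(y*peccary) pA=rA(.) pB=rBA=rBa(.)",
    "psiA(deer) psiBA(y*peccary) psiBa(y*calf) pA=rA(.) pB=rBA=rBa(.)",
    "psiA(deer) psiBA(y*peccary) psiBa(.) pA=rA(.) pB=rBA=rBa(.)",
    "psiA(deer) psiBA(y*peccary) psiBa(deer) pA=rA(.) pB=rBA=rBa(.)",
    "psiA(deer) psiBA(y*peccary) psiBa(calf) pA=rA(.) pB=rBA=rBa(.)",
]


def _design_matrix(formula: str, sites: pd.DataFrame, year_levels: list) -> tuple[np.ndarray, list[str]]:
    """Build one parameter's design matrix from its formula string."""
    S = len(sites)
    cols: list[np.ndarray] = [np.ones(S)]
    names = ["(Int)"]
    if formula == ".":
        pass
    elif formula == "y":
        for lev in year_levels[1:]:
            cols.append((sites["year"] == lev).to_numpy(float))
            names.append(f"y{lev}")
    elif "*" in formula:
        left, cov = (s.strip() for s in formula.split("*", 1))
        if left != "y":
            raise ValueError(f"unsupported interaction {formula!r}")
        if cov not in sites:
            raise ValueError(f"unknown covariate {cov!r}")
        x = sites[cov].to_numpy(float)
        for lev in year_levels[1:]:
            cols.append((sites["year"] == lev).to_numpy(float))
            names.append(f"y{lev}")
        cols.append(x)
        names.append(cov)
        for lev in year_levels[1:]:
            cols.append((sites["year"] == lev).to_numpy(float) * x)
            names.append(f"y{lev}:{cov}")
    else:
        if formula not in sites:
            raise ValueError(f"unknown covariate {formula!r}")
        cols.append(sites[formula].to_numpy(float))
        names.append(formula)
    return np.column_stack(cols), names


def _suff_stats(data: TwoSpeciesHistory) -> np.ndarray:
    """Per-site counts of (1,1), (1,0), (0,1), (0,0) occasions."""
    a, b, m = data.yA, data.yB, data.mask
    az = np.where(m, a, 0.0)
    bz = np.where(m, b, 0.0)
    n11 = (az * bz).sum(axis=1)
    n10 = (az * (1 - bz) * m).sum(axis=1)
    n01 = ((1 - az) * bz * m).sum(axis=1)
    n00 = ((1 - az) * (1 - bz) * m).sum(axis=1)
    return np.column_stack([n11, n10, n01, n00])


def _state_logliks(theta: dict[str, np.ndarray], stats: np.ndarray) -> np.ndarray:
    """(S, 4) conditional log-likelihoods per latent state.

    Valid because detection is time-constant within the season: the
    per-occasion product depends only on the counts of the four
    observation outcomes.
    """
    n11, n10, n01, n00 = stats.T
    nA = n11 + n10
    nB = n11 + n01

    def lg(x):
        return np.log(np.clip(x, _EPS, None))

    rA, rBA, rBa = theta["rA"], theta["rBA"], theta["rBa"]
    pA, pB = theta["pA"], theta["pB"]
    l_ab = (
        n11 * (lg(rA) + lg(rBA))
        + n10 * (lg(rA) + lg(1 - rBA))
        + n01 * (lg(1 - rA) + lg(rBa))
        + n00 * (lg(1 - rA) + lg(1 - rBa))
    )
    l_a = np.where(nB > 0, -np.inf, n10 * lg(pA) + n00 * lg(1 - pA))
    l_b = np.where(nA > 0, -np.inf, n01 * lg(pB) + n00 * lg(1 - pB))
    l_none = np.where(nA + nB > 0, -np.inf, 0.0)
    return np.column_stack([l_ab, l_a, l_b, l_none])


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample Akaike criterion: -2*loglik + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(
            f"effective sample size n={n} must exceed K+1={K + 1} for AICc"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def sif(psiA, psiBA, psiBa):
    """Species Interaction Factor phi from the three occupancy parameters."""
    psiA, psiBA, psiBa = (np.asarray(v, dtype=float) for v in (psiA, psiBA, psiBa))
    denom = psiA * (psiA * psiBA + (1.0 - psiA) * psiBa)
    if np.any(denom <= 0):
        raise ZeroDivisionError("SIF undefined: zero marginal occupancy product")
    out = psiA * psiBA / denom
    return float(out) if out.ndim == 0 else out


def psi2(psiA, psiBA):
    """Joint occupancy: proportion of sites used by both species."""
    out = np.asarray(psiA, dtype=float) * np.asarray(psiBA, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# numerical differentiation (central differences)


def _num_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h * (1.0 + abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2.0 * e[i])
    return g


def _num_hess(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    hs = h * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


class ConditionalTwoSpeciesOccupancy(BaseEstimator):
    """Maximum-likelihood conditional two-species occupancy model.

    Parameters
    ----------
    model : ModelSpec or str, optional
        Parameter designs and sharing constraints; default is the
        intercept-only model for all eight parameters.
    n_starts : int, default 5
        Multi-start count for the quasi-Newton optimiser; the first
        start is the zero vector, the rest are drawn from U(-2, 2) on
        the logit scale.
    random_state : int, default 0
    maxiter : int, default 1000

    Attributes
    ----------
    coef_ : pandas.Series — logit-scale coefficient estimates.
    loglik_ : float — maximised log-likelihood.
    K_ : int — number of free coefficients.
    aicc_ : float — AICc at n = number of site-year units.
    vcov_ : ndarray or None — inverse numerical Hessian at the optimum.
    reals_ : DataFrame — back-transformed parameters per year group
        (evaluated at within-group covariate means) with delta-method SEs.
    sif_, psi2_ : DataFrame — derived quantities per year group with SEs.
    converged_, se_reliable_, boundary_ : bool flags.
    """

    def __init__(self, model=None, n_starts: int = 5, random_state: int = 0,
                 maxiter: int = 1000, start=None):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state
        self.maxiter = maxiter
        self.start = start

    # -- internal design plumbing ------------------------------------------

    def _resolve_model(self) -> ModelSpec:
        if self.model is None:
            return ModelSpec(design={p: "." for p in PARAM_NAMES}, name="null")
        if isinstance(self.model, str):
            return ModelSpec.from_string(self.model)
        return self.model

    def _build_designs(self, sites: pd.DataFrame, spec: ModelSpec):
        year_levels = sorted(sites["year"].unique())
        X: dict[str, np.ndarray] = {}
        slices: dict[str, slice] = {}
        names: list[str] = []
        offset = 0
        for group in spec.blocks():
            mat, colnames = _design_matrix(spec.design[group[0]], sites, year_levels)
            if np.linalg.matrix_rank(mat) < mat.shape[1]:
                raise ValueError(
                    f"design for {'='.join(group)}({spec.design[group[0]]}) is rank-deficient"
                )
            sl = slice(offset, offset + mat.shape[1])
            for p in group:
                X[p] = mat
                slices[p] = sl
            names.extend(f"{'='.join(group)}:{c}" for c in colnames)
            offset += mat.shape[1]
        return X, slices, names, offset, year_levels

    def _theta(self, beta: np.ndarray) -> dict[str, np.ndarray]:
        return {
            p: np.clip(expit(self._X[p] @ beta[self._slices[p]]), _EPS, 1 - _EPS)
            for p in PARAM_NAMES
        }

    def _negloglik(self, beta: np.ndarray) -> float:
        th = self._theta(beta)
        cond = _state_logliks(th, self._stats)  # (S, 4)
        priors = state_probs(th["psiA"], th["psiBA"], th["psiBa"])  # (S, 4)
        with np.errstate(divide="ignore"):
            ll = logsumexp(np.log(np.clip(priors, _EPS, None)) + cond, axis=1)
        return -float(ll[self._has_data].sum())

    # -- fitting -----------------------------------------------------------

    def fit(self, data: TwoSpeciesHistory, y=None):
        spec = self._resolve_model()
        sites = data.sites.reset_index(drop=True)
        self._X, self._slices, self.coef_names_, K, self.year_levels_ = (
            self._build_designs(sites, spec)
        )
        self.model_spec_ = spec
        stats = _suff_stats(data)
        n_surveyed = data.mask.sum(axis=1)
        self._has_data = n_surveyed > 0
        if not self._has_data.all():
            warnings.warn(
                f"{(~self._has_data).sum()} site(s) with no surveyed occasion "
                "contribute 0 to the likelihood",
                stacklevel=2,
            )
        self._stats = stats
        nll = self._negloglik

        rng = np.random.default_rng(self.random_state)
        starts = [np.zeros(K) if self.start is None else np.asarray(self.start, float)]
        starts += [rng.uniform(-2, 2, size=K) for _ in range(self.n_starts - 1)]

        best = None
        for s0 in starts:
            res = minimize(nll, s0, method="L-BFGS-B",
                           options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-8})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        self.coef_ = pd.Series(best.x, index=self.coef_names_)
        self.loglik_ = -float(best.fun)
        self.K_ = K
        self.n_sites_ = int(self._has_data.sum())
        self.converged_ = bool(best.success)
        if not self.converged_:
            warnings.warn(
                f"optimizer did not report convergence ({best.message}); "
                "best point retained",
                stacklevel=2,
            )
        if self.n_sites_ > K + 1:
            self.aicc_ = aicc(self.loglik_, K, self.n_sites_)
        else:
            self.aicc_ = np.nan
            warnings.warn(
                f"model {spec.name or 'unnamed'!r}: n={self.n_sites_} site-years "
                f"cannot support AICc with K={K}",
                stacklevel=2,
            )

        # variance matrix from the numerical Hessian of the negative loglik
        H = _num_hess(nll, best.x)
        self.se_reliable_ = True
        try:
            self.vcov_ = np.linalg.inv(H)
            if not np.all(np.isfinite(self.vcov_)) or np.any(np.diag(self.vcov_) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            self.vcov_ = None
            self.se_reliable_ = False
            warnings.warn("singular Hessian: coefficient SEs unavailable", stacklevel=2)

        self._sites = sites
        self._derive_reals(nll_beta=best.x)
        return self

    # -- derived quantities ------------------------------------------------

    def _group_rows(self) -> dict:
        """One representative covariate row per year group (within-group means)."""
        rows = {}
        num = self._sites.select_dtypes("number")
        for lev in self.year_levels_:
            sub = self._sites[self._sites["year"] == lev]
            r = num.loc[sub.index].mean()
            r["year"] = lev
            rows[lev] = r
        return rows

    def _param_at(self, beta: np.ndarray, param: str, row: pd.Series) -> float:
        spec = self.model_spec_
        one = pd.DataFrame([row])
        mat, _ = _design_matrix(spec.design[param], one, self.year_levels_)
        return float(expit(mat[0] @ beta[self._slices[param]]))

    def _derive_reals(self, nll_beta: np.ndarray) -> None:
        beta = nll_beta
        rows = self._group_rows()
        boundary = False
        real_recs, sif_recs, psi2_recs = [], [], []
        for lev, row in rows.items():
            vals = {p: self._param_at(beta, p, row) for p in PARAM_NAMES}
            if any(v < 1e-4 or v > 1 - 1e-4 for v in vals.values()):
                boundary = True
            for p, v in vals.items():
                se = self._delta_se(lambda b, p=p: self._param_at(b, p, row), beta)
                real_recs.append({"year": lev, "param": p, "estimate": v, "se": se})

            def phi_of(b):
                return sif(
                    self._param_at(b, "psiA", row),
                    self._param_at(b, "psiBA", row),
                    self._param_at(b, "psiBa", row),
                )

            def psi2_of(b):
                return psi2(
                    self._param_at(b, "psiA", row), self._param_at(b, "psiBA", row)
                )

            sif_recs.append(
                {"year": lev, "estimate": phi_of(beta), "se": self._delta_se(phi_of, beta)}
            )
            psi2_recs.append(
                {"year": lev, "estimate": psi2_of(beta), "se": self._delta_se(psi2_of, beta)}
            )
        self.boundary_ = boundary
        if boundary:
            self.se_reliable_ = False
        self.reals_ = pd.DataFrame(real_recs)
        self.sif_ = pd.DataFrame(sif_recs)
        self.psi2_ = pd.DataFrame(psi2_recs)

    def _delta_se(self, f, beta: np.ndarray) -> float:
        if self.vcov_ is None:
            return np.nan
        g = _num_grad(f, beta)
        var = float(g @ self.vcov_ @ g)
        return float(np.sqrt(max(var, 0.0)))

    def predict_site_params(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Real-scale parameter values for each row of a site table."""
        beta = self.coef_.to_numpy()
        out = {
            p: [self._param_at(beta, p, row) for _, row in sites.iterrows()]
            for p in PARAM_NAMES
        }
        return pd.DataFrame(out, index=sites.index)


def sif_se(fit: ConditionalTwoSpeciesOccupancy) -> pd.Series:
    """Delta-method SE of the Species Interaction Factor per year group."""
    return fit.sif_.set_index("year")["se"]


def fit_model(
    model,
    data: TwoSpeciesHistory,
    start=None,
    seed: int = 0,
    n_starts: int = 5,
) -> ConditionalTwoSpeciesOccupancy:
    """Fit one model specification; thin wrapper over the estimator class."""
    est = ConditionalTwoSpeciesOccupancy(
        model=model, n_starts=n_starts, random_state=seed, start=start
    )
    return est.fit(data)


def model_selection_table(fits) -> pd.DataFrame:
    """AICc ranking: delta AICc, Akaike weights, model likelihood, K.

    ``weight = exp(-delta/2) / sum exp(-delta/2)``; ``model likelihood
    = exp(-delta/2)``. Sorted ascending by AICc.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    rows = []
    for f in fits:
        name = f.model_spec_.name or "unnamed"
        rows.append({"model": name, "AICc": f.aicc_, "loglik": f.loglik_, "K": f.K_})
    tab = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].min()
    rel = np.exp(-tab["delta_AICc"] / 2.0)
    tab["model_likelihood"] = rel
    tab["weight"] = rel / rel.sum()
    return tab[["model", "AICc", "delta_AICc", "weight", "model_likelihood", "K", "loglik"]]
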