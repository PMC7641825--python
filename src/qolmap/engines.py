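"""Regression engines for utility mapping.

Seven methods are supported for predicting the EQ-5D-5L index from
subscale scores, age and sex.  Six are *direct* (the index itself is the
response): ordinary linear regression, beta regression on the rescaled
index, Tweedie regression on the disutility 1 - index (log link), tobit
regression censored at the tariff bounds, and two-part variants that
first model the probability of full health (index exactly 1) with
logistic regression and then model the non-full-health index with linear
or beta regression.  The seventh is *indirect* (response mapping): a
proportional-odds cumulative-logit model per EQ-5D item, from which the
index is recovered as an expectation under a value set.

Index transforms (Japanese tariff constants):

    beta_full:     u = (y - L) / (1 - L),   L = -0.025
    beta_twopart:  u = (y - L) / (U2 - L),  U2 = 0.895 (second-best index)

Transformed responses sitting exactly on 0 or 1 are squeezed inward by
0.005 before the beta likelihood is evaluated.

Ordinal parameterization (stated because software conventions differ):

    logit P(level <= j | x) = alpha_j + x . beta,   alpha_1 < ... < alpha_4

so a positive coefficient on a better-health covariate increases the
probability of the good (low) levels.  statsmodels' OrderedModel uses
the opposite sign on beta; the conversion happens at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.base.model import GenericLikelihoodModel
from statsmodels.genmod.families import Tweedie
from statsmodels.genmod.families.links import Log
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.othermod.betareg import BetaModel

from .dataset import MappingDataset
from .valueset import DIMENSIONS, ValueSet, index_of_levels

TARIFF_MIN = -0.025  #: L, lowest index in the Japanese tariff
SECOND_LARGEST_INDEX = 0.895  #: U2, second-largest index in the Japanese tariff
BOUNDARY_EPS = 0.005  #: boundary squeeze for beta likelihoods

DIRECT_METHODS = ("linear", "beta", "tweedie", "tobit", "twopart_linear", "twopart_beta")
TWOPART_METHODS = ("twopart_linear", "twopart_beta")

__all__ = [
    "TARIFF_MIN", "SECOND_LARGEST_INDEX", "BOUNDARY_EPS",
    "DIRECT_METHODS", "TWOPART_METHODS",
    "ConvergenceError", "LinearPart", "FittedDirectModel",
    "OrdinalItemModel", "IndirectModel",
    "transform_index", "inverse_transform_index", "squeeze_boundaries",
    "fit_direct", "predict_expected_index",
    "fit_ordinal_item", "item_level_probs", "predict_indirect_index",
    "simulate_index",
]


class ConvergenceError(RuntimeError):
    """An engine's optimiser failed to converge (details in the message)."""


# ---------------------------------------------------------------------------
# transforms

def transform_index(y, mode: str):
    """Rescale an index to the unit interval for beta-family likelihoods."""
    y = np.asarray(y, dtype=float)
    L = TARIFF_MIN
    if mode == "beta_full":
        upper = 1.0
    elif mode == "beta_twopart":
        upper = SECOND_LARGEST_INDEX
    else:
        raise ValueError(f"mode must be 'beta_full' or 'beta_twopart', got {mode!r}")
    if np.any(y < L - 1e-12):
        raise ValueError(f"index below the tariff minimum {L}")
    if np.any(y > upper + 1e-12):
        raise ValueError(
            f"index above {upper} not allowed in mode {mode!r} "
            "(full-health rows belong to the logistic part)"
        )
    return (y - L) / (upper - L)


def inverse_transform_index(u, mode: str):
    """Exact inverse of :func:`transform_index`."""
    u = np.asarray(u, dtype=float)
    L = TARIFF_MIN
    upper = 1.0 if mode == "beta_full" else SECOND_LARGEST_INDEX
    if mode not in ("beta_full", "beta_twopart"):
        raise ValueError(f"unknown mode {mode!r}")
    return L + (upper - L) * u


def squeeze_boundaries(u, eps: float = BOUNDARY_EPS):
    """Move unit-interval values at exactly 0 or 1 inward by ``eps``."""
    u = np.asarray(u, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("values must lie in [0, 1]")
    out = u.copy()
    out[u <= 0] = eps
    out[u >= 1] = 1.0 - eps
    return out


# ---------------------------------------------------------------------------
# fitted-model containers

def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    X = df[list(covariates)].astype(float).copy()
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class LinearPart:
    """One estimated linear predictor: intercept + named coefficients."""

    covariates: list
    params: pd.Series      # index: ['intercept'] + covariates
    pvalues: pd.Series     # Wald P per covariate (intercept included)
    converged: bool = True
    bse: pd.Series | None = None

    def linpred(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.covariates)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()


@dataclass
class FittedDirectModel:
    """A fitted direct mapping model (any of the six direct methods).

    ``part`` is the (single or continuous) linear predictor; two-part
    methods additionally carry ``logistic``.  ``aux`` holds method
    auxiliaries: beta precision ``phi``, residual/latent ``sigma``,
    Tweedie ``power`` and ``dispersion``.
    """

    method: str
    part: LinearPart
    logistic: LinearPart | None = None
    aux: dict = field(default_factory=dict)
    L: float = TARIFF_MIN
    U2: float = SECOND_LARGEST_INDEX

    @property
    def covariates(self):
        return list(self.part.covariates)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "part": {"covariates": list(self.part.covariates),
                     "params": self.part.params.to_dict()},
            "aux": {k: float(v) for k, v in self.aux.items()},
            "L": self.L, "U2": self.U2,
        }
        if self.logistic is not None:
            d["logistic"] = {"covariates": list(self.logistic.covariates),
                             "params": self.logistic.params.to_dict()}
        return d


# ---------------------------------------------------------------------------
# direct fitting

def _wrap_part(res, covariates) -> LinearPart:
    k = len(covariates) + 1
    names = ["intercept"] + list(covariates)
    params = pd.Series(np.asarray(res.params)[:k], index=names)
    pvalues = pd.Series(np.asarray(res.pvalues)[:k], index=names)
    bse = pd.Series(np.asarray(res.bse)[:k], index=names)
    conv = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    return LinearPart(list(covariates), params, pvalues, conv, bse)


def _check_converged(res, what: str) -> None:
    retvals = getattr(res, "mle_retvals", None)
    if retvals is not None and not retvals.get("converged", True):
        raise ConvergenceError(f"{what} did not converge: {retvals}")


def _fit_logit(df: pd.DataFrame, ybin: np.ndarray, covariates) -> LinearPart:
    X = _design(df, covariates)
    try:
        res = sm.Logit(ybin, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ConvergenceError(f"logistic part failed: {exc}") from exc
    _check_converged(res, "logistic part")
    return _wrap_part(res, covariates)


def _fit_beta_part(u: np.ndarray, df: pd.DataFrame, covariates) -> tuple[LinearPart, float]:
    X = _design(df, covariates)
    res = BetaModel(squeeze_boundaries(u), X).fit(disp=0, maxiter=500)
    _check_converged(res, "beta regression")
    phi = float(np.exp(np.asarray(res.params)[-1]))
    return _wrap_part(res, covariates), phi


class _TobitModel(GenericLikelihoodModel):
    """Two-sided censored normal regression (censoring at fixed bounds)."""

    def __init__(self, endog, exog, lower, upper, **kwds):
        super().__init__(endog, exog, **kwds)
        self.lower, self.upper = lower, upper
        self.k_extra = 1
        self.exog_names.append("log_sigma")

    def loglikeobs(self, params):
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        xb = self.exog @ beta
        y = self.endog
        z = (y - xb) / sigma
        ll = norm.logpdf(z) - log_sigma
        at_lo = y <= self.lower + 1e-12
        at_hi = y >= self.upper - 1e-12
        ll = np.where(at_lo, norm.logcdf((self.lower - xb) / sigma), ll)
        ll = np.where(at_hi, norm.logsf((self.upper - xb) / sigma), ll)
        return ll


def _fit_tobit(y: np.ndarray, df: pd.DataFrame, covariates) -> tuple[LinearPart, float]:
    X = _design(df, covariates)
    ols = sm.OLS(y, X).fit()
    start = np.r_[ols.params.to_numpy(), np.log(max(np.sqrt(ols.scale), 1e-3))]
    mod = _TobitModel(y, X.to_numpy(), TARIFF_MIN, 1.0)
    res = mod.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
    _check_converged(res, "tobit regression")
    names = ["intercept"] + list(covariates)
    part = LinearPart(
        list(covariates),
        pd.Series(res.params[:-1], index=names),
        pd.Series(res.pvalues[:-1], index=names),
        True,
        pd.Series(res.bse[:-1], index=names),
    )
    return part, float(np.exp(res.params[-1]))


def _tweedie_unit_deviance(y, mu, p):
    return 2.0 * (
        np.power(y, 2 - p) / ((1 - p) * (2 - p))
        - y * np.power(mu, 1 - p) / (1 - p)
        + np.power(mu, 2 - p) / (2 - p)
    )


def _fit_tweedie(y: np.ndarray, df: pd.DataFrame, covariates,
                 power: float | None, power_grid) -> tuple[LinearPart, dict]:
    d = 1.0 - y  # disutility from full health; exact zeros allowed
    X = _design(df, covariates)

    def fit_at(p):
        res = sm.GLM(d, X, family=Tweedie(var_power=p, link=Log())).fit()
        dev = _tweedie_unit_deviance(d, res.mu, p)
        phi = float(res.scale)
        # extended quasi-likelihood; zeros floored inside the log V(y) term
        d_adj = np.maximum(d, BOUNDARY_EPS)
        eql = -0.5 * np.sum(dev / phi + np.log(2 * np.pi * phi * np.power(d_adj, p)))
        return res, phi, eql

    if power is None:
        best = None
        for p in power_grid:
            res, phi, eql = fit_at(p)
            if best is None or eql > best[3]:
                best = (p, res, phi, eql)
        power, res, phi, _ = best
    else:
        if not 1.0 < power < 2.0:
            raise ValueError("tweedie power must lie in (1, 2)")
        res, phi, _ = fit_at(power)
    return _wrap_part(res, covariates), {"power": float(power), "dispersion": phi}


def _full_health_mask(y: np.ndarray) -> np.ndarray:
    return y >= 1.0 - 1e-12


def fit_direct(method: str, data: MappingDataset, covariates,
               logistic_covariates=None, tweedie_power: float | None = None,
               tweedie_power_grid=tuple(np.round(np.arange(1.1, 1.95, 0.1), 2)),
               ) -> FittedDirectModel:
    """Fit one of the six direct mapping methods.

    Rows missing the observed index or any required covariate are dropped
    (complete-case analysis; the count is recorded in the dataset meta).
    Two-part methods require at least one full-health (y = 1) and one
    non-full-health row; ``logistic_covariates`` defaults to the same set
    as the continuous part.
    """
    if method not in DIRECT_METHODS:
        raise ValueError(f"unknown direct method {method!r}; choose from {DIRECT_METHODS}")
    if not data.has_index:
        raise ValueError("dataset has no observed index column 'y'")
    covariates = list(covariates)
    logi_cov = list(logistic_covariates) if logistic_covariates is not None else list(covariates)
    needed = ["y"] + sorted(set(covariates) | set(logi_cov))
    cc = data.complete_cases(needed)
    df, y = cc.df, cc.df["y"].to_numpy(dtype=float)
    if len(df) == 0:
        raise ValueError("no complete rows to fit on")

    if method == "linear":
        X = _design(df, covariates)
        res = sm.OLS(y, X).fit()
        part = _wrap_part(res, covariates)
        return FittedDirectModel(method, part, aux={"sigma": float(np.sqrt(res.scale))})

    if method == "beta":
        u = transform_index(y, "beta_full")
        part, phi = _fit_beta_part(u, df, covariates)
        return FittedDirectModel(method, part, aux={"phi": phi})

    if method == "tweedie":
        part, aux = _fit_tweedie(y, df, covariates, tweedie_power, tweedie_power_grid)
        return FittedDirectModel(method, part, aux=aux)

    if method == "tobit":
        part, sigma = _fit_tobit(y, df, covariates)
        return FittedDirectModel(method, part, aux={"sigma": sigma})

    # two-part methods
    full = _full_health_mask(y)
    if not full.any():
        raise ValueError("two-part fit needs at least one full-health (y = 1) row")
    if full.all():
        raise ValueError("two-part fit needs at least one non-full-health row")
    logistic = _fit_logit(df, full.astype(float), logi_cov)
    rest = df.loc[~full]
    if method == "twopart_linear":
        X = _design(rest, covariates)
        res = sm.OLS(y[~full], X).fit()
        part = _wrap_part(res, covariates)
        return FittedDirectModel(method, part, logistic=logistic,
                                 aux={"sigma": float(np.sqrt(res.scale))})
    u = transform_index(y[~full], "beta_twopart")
    part, phi = _fit_beta_part(u, rest, covariates)
    return FittedDirectModel(method, part, logistic=logistic, aux={"phi": phi})


def _tobit_expectation(mu, sigma, a, b):
    alpha, beta = (a - mu) / sigma, (b - mu) / sigma
    Fa, Fb = norm.cdf(alpha), norm.cdf(beta)
    return a * Fa + b * (1 - Fb) + mu * (Fb - Fa) - sigma * (norm.pdf(beta) - norm.pdf(alpha))


def predict_expected_index(model: FittedDirectModel, x) -> np.ndarray:
    """Expected EQ-5D-5L index under a fitted direct model.

    ``x`` is a DataFrame (or dict/Series for one row) supplying every
    model covariate.  Method-specific expectations:

    - linear: x.b
    - beta: L + (1 - L) * invlogit(x.b)
    - tweedie: 1 - exp(x.b)
    - tobit: closed-form mean of the two-sided censored normal
    - two-part: p(x) * 1 + (1 - p(x)) * m(x), with m the continuous
      part's mean (for beta: L + (U2 - L) * invlogit(x.b))
    """
    df = x if isinstance(x, pd.DataFrame) else pd.DataFrame([pd.Series(x)])
    m = model.method
    xb = model.part.linpred(df)
    if m == "linear":
        cont = xb
    elif m == "beta":
        cont = model.L + (1.0 - model.L) * expit(xb)
    elif m == "tweedie":
        cont = 1.0 - np.exp(xb)
    elif m == "tobit":
        cont = _tobit_expectation(xb, model.aux["sigma"], model.L, 1.0)
    elif m == "twopart_linear":
        cont = xb
    elif m == "twopart_beta":
        cont = model.L + (model.U2 - model.L) * expit(xb)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {m!r}")
    if m in TWOPART_METHODS:
        p = expit(model.logistic.linpred(df))
        cont = p * 1.0 + (1.0 - p) * cont
    return cont


# ---------------------------------------------------------------------------
# ordinal (indirect) engine

@dataclass
class OrdinalItemModel:
    """Proportional-odds model of one EQ-5D item.

    ``alphas`` are the four cumulative-logit intercepts (boundaries
    after levels 1..4); +/-inf entries encode levels unobserved at fit
    time.  Convention: logit P(level <= j | x) = alphas[j-1] + x.beta.
    """

    item: str
    alphas: np.ndarray
    covariates: list
    params: pd.Series      # beta over covariates (no intercept entry)
    pvalues: pd.Series
    converged: bool = True
    bse: pd.Series | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.shape != (4,):
            raise ValueError("alphas must have length 4")
        finite = a[np.isfinite(a)]
        if np.any(np.diff(a) < 0):
            raise ValueError(f"cumulative intercepts must be non-decreasing, got {a}")
        self.alphas = a

    def linpred(self, df: pd.DataFrame) -> np.ndarray:
        X = df[list(self.covariates)].astype(float).to_numpy()
        return X @ self.params.reindex(self.covariates).to_numpy()


def fit_ordinal_item(data: MappingDataset, item: str, covariates) -> OrdinalItemModel:
    """Fit the cumulative-logit model of one EQ-5D item on subscales/age/sex."""
    if item not in DIMENSIONS:
        raise ValueError(f"item must be one of {DIMENSIONS}, got {item!r}")
    if item not in data.df.columns:
        raise ValueError(f"dataset has no column for item {item!r}")
    covariates = list(covariates)
    cc = data.complete_cases([item] + covariates)
    df = cc.df
    lev = df[item].astype(int)
    observed = np.sort(lev.unique())
    if len(observed) < 2:
        raise ValueError(f"item {item!r} has a single observed category; cannot fit")
    endog = pd.Categorical(lev, categories=observed, ordered=True)
    X = df[covariates].astype(float)
    mod = OrderedModel(endog, X, distr="logit")
    res = mod.fit(method="bfgs", maxiter=500, disp=0)
    if not res.mle_retvals.get("converged", True):
        res = mod.fit(method="nm", maxiter=5000, disp=0, start_params=res.params)
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError(f"ordinal fit for {item!r} did not converge")
    k = len(covariates)
    beta = -np.asarray(res.params)[:k]  # statsmodels models P(<=j)=F(tau_j - x.b)
    taus = mod.transform_threshold_params(res.params)[1:-1]  # interior thresholds
    # map interior thresholds of observed categories onto the 4 level boundaries
    alphas = np.empty(4)
    for j in range(1, 5):
        n_below = int((observed <= j).sum())
        if n_below == 0:
            alphas[j - 1] = -np.inf
        elif n_below == len(observed):
            alphas[j - 1] = np.inf
        else:
            alphas[j - 1] = taus[n_below - 1]
    return OrdinalItemModel(
        item=item,
        alphas=alphas,
        covariates=covariates,
        params=pd.Series(beta, index=covariates),
        pvalues=pd.Series(np.asarray(res.pvalues)[:k], index=covariates),
        bse=pd.Series(np.asarray(res.bse)[:k], index=covariates),
    )


def item_level_probs(m: OrdinalItemModel, x) -> np.ndarray:
    """Level probabilities (n, 5) for one item model at covariates ``x``."""
    df = x if isinstance(x, pd.DataFrame) else pd.DataFrame([pd.Series(x)])
    missing = [c for c in m.covariates if c not in df.columns]
    if missing:
        raise KeyError(f"missing covariate(s) for item {m.item!r}: {missing}")
    xb = m.linpred(df)
    cum = expit(m.alphas[None, :] + xb[:, None])  # P(level <= j), j = 1..4
    cum = np.concatenate([np.zeros((len(xb), 1)), cum, np.ones((len(xb), 1))], axis=1)
    probs = np.diff(cum, axis=1)
    if np.any(probs < -1e-10):
        raise ValueError(f"inconsistent cumulative probabilities for item {m.item!r}")
    return np.clip(probs, 0.0, 1.0)


@dataclass
class IndirectModel:
    """Five per-item proportional-odds models plus a value set."""

    items: dict
    valueset: ValueSet

    def __post_init__(self) -> None:
        missing = [d for d in DIMENSIONS if d not in self.items]
        if missing:
            raise ValueError(f"missing item model(s): {missing}")

    def all_item_probs(self, x) -> dict:
        return {d: item_level_probs(self.items[d], x) for d in DIMENSIONS}

    def to_dict(self) -> dict:
        return {
            "tariff": self.valueset.label,
            "items": {
                d: {
                    "alphas": [float(a) for a in self.items[d].alphas],
                    "covariates": list(self.items[d].covariates),
                    "params": self.items[d].params.to_dict(),
                }
                for d in DIMENSIONS
            },
        }


def predict_indirect_index(m: IndirectModel, x) -> np.ndarray:
    """Expected index: 1 minus probability-weighted decrements over items.

    Because the tariff is additive, this equals the expectation of the
    index over the full product distribution of the 3125 states.
    """
    df = x if isinstance(x, pd.DataFrame) else pd.DataFrame([pd.Series(x)])
    total_dec = np.zeros(len(df))
    for d_idx, dim in enumerate(DIMENSIONS):
        probs = item_level_probs(m.items[dim], df)
        total_dec += probs @ m.valueset.decrements[d_idx]
    return 1.0 - total_dec


# ---------------------------------------------------------------------------
# predictive simulation

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_index(model, x, seed=0):
    """Draw EQ-5D-5L indexes from a fitted model's generative law.

    Direct methods: linear and two-part linear draw normal residuals;
    beta and two-part beta draw from Beta(mu*phi, (1-mu)*phi) rescaled to
    the index range (with a Bernoulli full-health part where two-part);
    tobit draws the latent normal and clamps to the tariff bounds.
    Tweedie has no generative law here and raises.  Indirect models draw
    each item's level from its predicted category distribution and
    return ``(draws, states)``.
    """
    rng = _rng(seed)
    df = x if isinstance(x, pd.DataFrame) else pd.DataFrame([pd.Series(x)])
    n = len(df)
    if isinstance(model, IndirectModel):
        levels = np.empty((n, 5), dtype=int)
        for d_idx, dim in enumerate(DIMENSIONS):
            probs = item_level_probs(model.items[dim], df)
            cum = np.cumsum(probs, axis=1)
            u = rng.random((n, 1))
            levels[:, d_idx] = 1 + (u > cum[:, :-1]).sum(axis=1)
        return index_of_levels(levels, model.valueset), levels

    m = model.method
    if m == "tweedie":
        raise ValueError("tweedie has no generative law; simulate_index unsupported")
    xb = model.part.linpred(df)
    if m == "linear":
        return xb + rng.normal(0.0, model.aux["sigma"], size=n)
    if m == "tobit":
        latent = xb + rng.normal(0.0, model.aux["sigma"], size=n)
        return np.clip(latent, model.L, 1.0)
    if m == "beta":
        mu, phi = expit(xb), model.aux["phi"]
        u = rng.beta(mu * phi, (1.0 - mu) * phi)
        return model.L + (1.0 - model.L) * u
    # two-part laws
    p = expit(model.logistic.linpred(df))
    full = rng.random(n) < p
    if m == "twopart_linear":
        cont = xb + rng.normal(0.0, model.aux["sigma"], size=n)
    elif m == "twopart_beta":
        mu, phi = expit(xb), model.aux["phi"]
        cont = model.L + (model.U2 - model.L) * rng.beta(mu * phi, (1.0 - mu) * phi)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {m!r}")
    return np.where(full, 1.0, cont)
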