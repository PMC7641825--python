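"""Synthetic cancer-cohort generator with known generating truth.

The study data behind the published algorithms are restricted, so this
module emulates their structure: correlated bounded subscale scores, an
EQ-5D-5L index with a ceiling mass at full health and support down to
the tariff minimum, and item responses consistent with ordinal-logistic
generation.

Construction: a one-factor Gaussian copula drives the subscales.  A
latent health factor h ~ N(0,1) is shared by all subscales with loading
``latent_correlation`` (sign flipped for symptom scales, where higher is
worse); each subscale's latent normal is pushed through a
piecewise-linear quantile function interpolating the study population's
printed quantiles (min/5%/25%/median/75%/95%/max) and snapped onto the
subscale's attainable score grid.  Age is drawn the same way from its
printed median/IQR; sex is Bernoulli with 46% female.

EQ-5D responses then come from the published mapping models used as the
generating truth: ``ordinal_truth`` draws each item's level from the
published proportional-odds equations and computes the index under the
tariff; ``twopart_truth`` draws a full-health indicator from the
published logistic part and a rescaled beta index otherwise.  The exact
generating coefficients are recorded in the dataset's truth record so
parameter-recovery tests can compare refitted models against them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .dataset import MappingDataset, subscales_for
from .engines import (
    SECOND_LARGEST_INDEX,
    TARIFF_MIN,
    item_level_probs,
)
from .published import published_direct_model, published_indirect_model
from .valueset import DIMENSIONS, ValueSet, index_of_levels, japan_synthetic_tariff

__all__ = ["SyntheticConfig", "generate", "truth_report"]

_PROBS = np.array([0.0, 0.05, 0.25, 0.50, 0.75, 0.95, 1.0])

# printed population quantiles (min, 5%, 25%, median, 75%, 95%, max)
_EORTC_QUANTILES = {
    "pf": (0, 33.3, 66.7, 86.7, 93.3, 100, 100),
    "rf": (0, 0, 66.7, 83.3, 100, 100, 100),
    "ef": (0, 44.4, 75, 83.3, 100, 100, 100),
    "cf": (0, 33.3, 66.7, 83.3, 100, 100, 100),
    "sf": (0, 33.3, 66.7, 83.3, 100, 100, 100),
    "ghs": (0, 16.7, 50, 66.7, 83.3, 100, 100),
    "fa": (0, 0, 22.2, 33.3, 55.6, 77.8, 100),
    "nv": (0, 0, 0, 0, 16.7, 33.3, 100),
    "pa": (0, 0, 0, 16.7, 33.3, 66.7, 100),
    "dy": (0, 0, 0, 33.3, 33.3, 100, 100),
    "sl": (0, 0, 0, 33.3, 33.3, 66.7, 100),
    "ap": (0, 0, 0, 0, 33.3, 100, 100),
    "co": (0, 0, 0, 33.3, 33.3, 66.7, 100),
    "di": (0, 0, 0, 0, 33.3, 66.7, 100),
    "fi": (0, 0, 0, 33.3, 33.3, 100, 100),
}
_FACTG_QUANTILES = {
    "pwb": (1, 9, 16, 22, 25, 28, 28),
    "swb": (0, 5, 14, 18, 22, 26.8, 28),
    "ewb": (0, 7, 13, 17, 20, 23, 24),
    "fwb": (0, 6, 13, 17, 22, 27, 28),
}

#: score-grid step per subscale (items x 3-point range for EORTC; integers
#: for FACT-G).  Used to snap continuous quantiles onto attainable scores.
_GRID_STEP = {
    "pf": 100 / 15, "rf": 100 / 6, "ef": 100 / 12, "cf": 100 / 6, "sf": 100 / 6,
    "ghs": 100 / 12, "fa": 100 / 9, "nv": 100 / 6, "pa": 100 / 6,
    "dy": 100 / 3, "sl": 100 / 3, "ap": 100 / 3, "co": 100 / 3, "di": 100 / 3,
    "fi": 100 / 3,
    "pwb": 1.0, "swb": 1.0, "ewb": 1.0, "fwb": 1.0,
}

_SYMPTOM_SCALES = {"fa", "nv", "pa", "dy", "sl", "ap", "co", "di", "fi"}

_AGE_QUANTILES = ((0.0, 0.25, 0.5, 0.75, 1.0), (25, 58, 68, 74, 90))
_FEMALE_RATE = 0.46


@dataclass
class SyntheticConfig:
    """Conditions for one synthetic cohort.

    ``generator`` chooses the generating law for the EQ-5D outcome:
    ``ordinal_truth`` (item levels from the published proportional-odds
    equations, index via the tariff) or ``twopart_truth`` (index from
    the published two-part beta model; no item levels).
    """

    n: int = 903
    seed: int = 0
    source: str = "eortc"
    latent_correlation: float = 0.75
    generator: str = "ordinal_truth"
    tariff: ValueSet | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.source not in ("eortc", "factg"):
            raise ValueError("source must be 'eortc' or 'factg'")
        if not -1 < self.latent_correlation < 1:
            raise ValueError("latent_correlation must lie in (-1, 1)")
        if self.generator not in ("ordinal_truth", "twopart_truth"):
            raise ValueError("generator must be 'ordinal_truth' or 'twopart_truth'")


def _quantile_fn(probs, values):
    probs, values = np.asarray(probs, float), np.asarray(values, float)

    def q(u):
        return np.interp(u, probs, values)

    return q


def _snap(values, step, lo, hi):
    snapped = np.round(values / step) * step
    return np.clip(snapped, lo, hi)


def _draw_subscales(rng, n, source, lam):
    quantiles = _EORTC_QUANTILES if source == "eortc" else _FACTG_QUANTILES
    h = rng.normal(size=n)
    out = {}
    for name in subscales_for(source):
        load = -lam if name in _SYMPTOM_SCALES else lam
        z = load * h + np.sqrt(1 - load**2) * rng.normal(size=n)
        u = norm.cdf(z)
        vals = _quantile_fn(_PROBS, quantiles[name])(u)
        lo, hi = 0.0, max(quantiles[name])
        out[name] = _snap(vals, _GRID_STEP[name], lo, hi)
    return pd.DataFrame(out)


def _df_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()


def generate(config: SyntheticConfig) -> MappingDataset:
    """Draw a synthetic cohort; the generating truth rides in ``meta``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    vs = config.tariff if config.tariff is not None else japan_synthetic_tariff()

    age = np.round(_quantile_fn(*_AGE_QUANTILES)(rng.random(n)))
    female = (rng.random(n) < _FEMALE_RATE).astype(int)
    subs = _draw_subscales(rng, n, config.source, config.latent_correlation)
    df = pd.concat(
        [pd.DataFrame({"age": age, "female": female}), subs], axis=1
    )

    direct = published_direct_model(config.source)
    indirect = published_indirect_model(config.source, vs)
    if n > 0:
        if config.generator == "ordinal_truth":
            levels = np.empty((n, 5), dtype=int)
            for d_idx, dim in enumerate(DIMENSIONS):
                probs = item_level_probs(indirect.items[dim], df)
                cum = np.cumsum(probs, axis=1)
                levels[:, d_idx] = 1 + (rng.random((n, 1)) > cum[:, :-1]).sum(axis=1)
            for d_idx, dim in enumerate(DIMENSIONS):
                df[dim] = levels[:, d_idx]
            df["y"] = index_of_levels(levels, vs)
        else:
            p_full = expit(direct.logistic.linpred(df))
            full = rng.random(n) < p_full
            mu = expit(direct.part.linpred(df))
            phi = direct.aux["phi"]
            u = rng.beta(mu * phi, (1.0 - mu) * phi)
            df["y"] = np.where(
                full, 1.0, TARIFF_MIN + (SECOND_LARGEST_INDEX - TARIFF_MIN) * u
            )
    else:
        df["y"] = pd.Series(dtype=float)
        if config.generator == "ordinal_truth":
            for dim in DIMENSIONS:
                df[dim] = pd.Series(dtype=int)

    truth = {
        "source": config.source,
        "generator": config.generator,
        "seed": config.seed,
        "latent_correlation": config.latent_correlation,
        "tariff": vs.label,
        "direct": direct.to_dict(),
        "indirect": indirect.to_dict(),
    }
    ds = MappingDataset(df, source=config.source)
    ds.meta["truth"] = truth
    ds.meta["data_hash"] = _df_hash(ds.df)
    return ds


def truth_report(dataset: MappingDataset) -> dict:
    """Return the generating-parameter record of a generated dataset.

    Raises if the dataset was not produced by :func:`generate` or has
    been modified since (hash check), so recovery tests cannot silently
    compare against the wrong truth.
    """
    if "truth" not in dataset.meta or "data_hash" not in dataset.meta:
        raise ValueError("dataset carries no generating truth (not from generate())")
    if _df_hash(dataset.df) != dataset.meta["data_hash"]:
        raise ValueError("dataset was modified after generation; truth no longer applies")
    return dataset.meta["truth"]
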