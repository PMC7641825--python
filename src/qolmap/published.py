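"""The four recommended mapping algorithms as ready-to-use predictors.

Two algorithms per source measure: a direct two-part beta model of the
index (logistic part for the probability of full health, beta part for
the rescaled non-full-health index) and an indirect response-mapping
model (one proportional-odds equation per EQ-5D item, combined with a
value set).  Coefficients live in the versioned data file
``data/table4.csv`` (source, equation, term, value) rather than in code,
and are checksummed for auditability.

Covariate units: EORTC subscales 0-100; FACT-G pwb/swb/fwb 0-28 and ewb
0-24; age in years; female coded 1 for female, 0 for male.  Inputs
outside the fitted ranges are rejected, not clamped.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import SUBSCALE_RANGES, subscales_for
from .engines import (
    FittedDirectModel,
    IndirectModel,
    LinearPart,
    OrdinalItemModel,
    predict_expected_index,
    predict_indirect_index,
    item_level_probs,
)
from .valueset import DIMENSIONS, ValueSet, bundled_file_sha256

#: frozen checksum of the bundled coefficient table
TABLE4_SHA256 = "90188aaf8752d255501895fba3b14d8d9094c29d0cb3ceb8ec71cc53807b1e23"

_ORDERED_TERMS = [
    "age", "female",
    "pf", "rf", "ef", "cf", "sf", "ghs", "fa", "nv", "pa",
    "dy", "sl", "ap", "co", "di", "fi",
    "pwb", "swb", "ewb", "fwb",
]

__all__ = [
    "TABLE4_SHA256",
    "load_coefficient_table",
    "verify_bundled_coefficients",
    "published_direct_model",
    "published_indirect_model",
    "map_direct",
    "map_indirect",
    "batch_map",
]


@lru_cache(maxsize=1)
def load_coefficient_table() -> pd.DataFrame:
    with resources.as_file(resources.files("qolmap.data").joinpath("table4.csv")) as p:
        return pd.read_csv(p)


def verify_bundled_coefficients() -> bool:
    """True iff the shipped coefficient file matches its frozen checksum."""
    return bundled_file_sha256("table4.csv") == TABLE4_SHA256


def _equation_terms(source: str, equation: str) -> pd.Series:
    t4 = load_coefficient_table()
    rows = t4[(t4["source"] == source) & (t4["equation"] == equation)]
    if rows.empty:
        raise ValueError(f"no published equation {equation!r} for source {source!r}")
    return rows.set_index("term")["value"]


def _linear_part(source: str, equation: str) -> LinearPart:
    terms = _equation_terms(source, equation)
    covs = [t for t in _ORDERED_TERMS if t in terms.index]
    params = pd.Series(
        [terms["intercept"]] + [terms[c] for c in covs],
        index=["intercept"] + covs,
    )
    pvals = pd.Series(np.nan, index=params.index)
    return LinearPart(covs, params, pvals)


@lru_cache(maxsize=4)
def published_direct_model(source: str) -> FittedDirectModel:
    """The published direct two-part beta mapping model for one source."""
    beta_terms = _equation_terms(source, "beta")
    return FittedDirectModel(
        method="twopart_beta",
        part=_linear_part(source, "beta"),
        logistic=_linear_part(source, "logistic"),
        aux={"phi": float(beta_terms["scale"])},
    )


def _ordinal_item(source: str, item: str) -> OrdinalItemModel:
    terms = _equation_terms(source, item)
    alphas = np.array([terms[f"intercept{j}"] for j in range(1, 5)])
    covs = [t for t in _ORDERED_TERMS if t in terms.index]
    return OrdinalItemModel(
        item=item,
        alphas=alphas,
        covariates=covs,
        params=pd.Series([terms[c] for c in covs], index=covs),
        pvalues=pd.Series(np.nan, index=covs),
    )


def published_indirect_model(source: str, vs: ValueSet) -> IndirectModel:
    """The published indirect (response-mapping) model under a tariff."""
    return IndirectModel(
        items={d: _ordinal_item(source, d) for d in DIMENSIONS}, valueset=vs
    )


def _required_covariates(source: str, form: str) -> set:
    t4 = load_coefficient_table()
    eqs = ["logistic", "beta"] if form == "direct" else list(DIMENSIONS)
    rows = t4[(t4["source"] == source) & t4["equation"].isin(eqs)]
    skip = {"intercept", "intercept1", "intercept2", "intercept3", "intercept4", "scale"}
    return set(rows["term"]) - skip


def _validate_row(source: str, row: dict, required: set) -> None:
    missing = sorted(c for c in required if c not in row or pd.isna(row[c]))
    if missing:
        raise KeyError(f"missing required covariate(s): {missing}")
    for c in required:
        v = float(row[c])
        if c in SUBSCALE_RANGES:
            lo, hi = SUBSCALE_RANGES[c]
            if not lo - 1e-9 <= v <= hi + 1e-9:
                raise ValueError(f"{c}={v} outside fitted range [{lo}, {hi}]")
        elif c == "female" and v not in (0.0, 1.0):
            raise ValueError(f"female must be 0 or 1, got {v}")
        elif c == "age" and not 0 <= v <= 120:
            raise ValueError(f"implausible age {v}")


def map_direct(source: str, subscales: dict, age=None, female=None) -> float:
    """Predict the EQ-5D-5L index with the published two-part beta model.

    ``subscales`` maps subscale names to scores (EORTC: pf, rf, ef, ghs,
    pa needed; FACT-G: pwb, ewb, fwb); ``age``/``female`` are required
    where the published model uses them.
    """
    row = dict(subscales)
    if age is not None:
        row["age"] = age
    if female is not None:
        row["female"] = female
    _validate_row(source, row, _required_covariates(source, "direct"))
    model = published_direct_model(source)
    return float(predict_expected_index(model, row)[0])


def map_indirect(source: str, subscales: dict, age, female, vs: ValueSet):
    """Predict the index with the published response-mapping model.

    Returns ``(index, probs)`` where probs maps each EQ-5D item to its
    predicted level-probability 5-vector.  The tariff enters only the
    expectation, so any national value set can be supplied.
    """
    row = dict(subscales)
    row["age"], row["female"] = age, female
    _validate_row(source, row, _required_covariates(source, "indirect"))
    model = published_indirect_model(source, vs)
    x = pd.DataFrame([row])
    index = float(predict_indirect_index(model, x)[0])
    probs = {d: item_level_probs(model.items[d], x)[0] for d in DIMENSIONS}
    return index, probs


def batch_map(data, source: str, form: str, vs: ValueSet | None = None) -> pd.DataFrame:
    """Apply a published algorithm to a table of respondents.

    ``data`` is a CSV path or DataFrame with covariate columns.  Returns
    the input plus ``index_pred`` and ``error`` columns; rows failing
    validation get an error message there instead of being dropped.
    """
    if form not in ("direct", "indirect"):
        raise ValueError("form must be 'direct' or 'indirect'")
    if form == "indirect" and vs is None:
        raise ValueError("indirect mapping requires a value set")
    df = pd.read_csv(data) if not isinstance(data, pd.DataFrame) else data.copy()
    subs = subscales_for(source)
    preds, errors = [], []
    for _, row in df.iterrows():
        r = row.to_dict()
        sub_vals = {s: r[s] for s in subs if s in r}
        try:
            if form == "direct":
                val = map_direct(source, sub_vals, r.get("age"), r.get("female"))
            else:
                val, _ = map_indirect(source, sub_vals, r.get("age"), r.get("female"), vs)
            preds.append(val)
            errors.append("")
        except (KeyError, ValueError) as exc:
            preds.append(np.nan)
            errors.append(str(exc))
    out = df.copy()
    out["index_pred"] = preds
    out["error"] = errors
    return out
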