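"""Scoring of EORTC QLQ-C30 and FACT-G item responses into subscale scores.

EORTC QLQ-C30 (version 3) has 30 items: q1..q28 on a 1-4 scale and the two
global items q29, q30 on 1-7.  Items are averaged into a raw score RS per
subscale and linearly transformed to 0-100:

    functioning subscales:  (1 - (RS - 1) / range) * 100   (higher = better)
    symptoms / financial:   ((RS - 1) / range) * 100        (higher = worse)
    global health status:   ((RS - 1) / range) * 100        (higher = better)

with range 3 (range 6 for global health).  A subscale is scored when at
least half of its items were answered; otherwise it is marked unavailable
(NaN), never silently zero.

FACT-G (version 4) has 27 Likert items on 0-4 grouped into physical (7),
social/family (7), emotional (6), and functional (7) well-being.
Negatively worded items (all of PWB; all of EWB except GE2) are reversed
to 4 - response.  The subscale score is the prorated sum

    sum(answered item scores) * n_items / n_answered

requiring at least 50% of the domain's items answered; higher is better
on every domain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import MappingDataset, EORTC_SUBSCALES, FACTG_SUBSCALES
from .valueset import DIMENSIONS

__all__ = [
    "EORTC_ITEM_COLUMNS",
    "FACTG_ITEM_COLUMNS",
    "score_eortc",
    "score_factg",
    "read_cohort",
]

# EORTC QLQ-C30 subscale -> (items, range, upward transform flag);
# upward means the 0-100 score rises with the raw response (symptoms, GHS)
_EORTC_SCALES: dict[str, tuple[tuple[str, ...], int, bool]] = {
    "pf": (("q1", "q2", "q3", "q4", "q5"), 3, False),
    "rf": (("q6", "q7"), 3, False),
    "ef": (("q21", "q22", "q23", "q24"), 3, False),
    "cf": (("q20", "q25"), 3, False),
    "sf": (("q26", "q27"), 3, False),
    # q29/q30 run 1 (worst) .. 7 (best), so GHS uses the upward transform
    "ghs": (("q29", "q30"), 6, True),
    "fa": (("q10", "q12", "q18"), 3, True),
    "nv": (("q14", "q15"), 3, True),
    "pa": (("q9", "q19"), 3, True),
    "dy": (("q8",), 3, True),
    "sl": (("q11",), 3, True),
    "ap": (("q13",), 3, True),
    "co": (("q16",), 3, True),
    "di": (("q17",), 3, True),
    "fi": (("q28",), 3, True),
}

EORTC_ITEM_COLUMNS = tuple(f"q{i}" for i in range(1, 31))

# FACT-G domain -> (items, max score, reversed items)
_FACTG_SCALES: dict[str, tuple[tuple[str, ...], frozenset]] = {
    "pwb": (tuple(f"gp{i}" for i in range(1, 8)),
            frozenset(f"gp{i}" for i in range(1, 8))),
    "swb": (tuple(f"gs{i}" for i in range(1, 8)), frozenset()),
    "ewb": (tuple(f"ge{i}" for i in range(1, 7)),
            frozenset({"ge1", "ge3", "ge4", "ge5", "ge6"})),
    "fwb": (tuple(f"gf{i}" for i in range(1, 8)), frozenset()),
}

FACTG_ITEM_COLUMNS = tuple(c for items, _ in _FACTG_SCALES.values() for c in items)


def _as_frame(items) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        return items
    if isinstance(items, pd.Series):
        return items.to_frame().T
    return pd.DataFrame([items])


def _validate_levels(df: pd.DataFrame, col: str, lo: int, hi: int) -> None:
    v = pd.to_numeric(df[col], errors="coerce")
    raw_bad = df[col].notna() & v.isna()
    if raw_bad.any():
        raise ValueError(f"non-numeric response in item {col!r}, rows {df.index[raw_bad].tolist()}")
    out = v.notna() & ((v < lo) | (v > hi) | (v % 1 != 0))
    if out.any():
        raise ValueError(
            f"item {col!r} has responses outside {lo}..{hi} in rows {df.index[out].tolist()}"
        )


def score_eortc(items) -> pd.DataFrame:
    """Score EORTC QLQ-C30 items (q1..q30) into the 15 subscale scores.

    Accepts a dict/Series (one respondent) or DataFrame (many); returns a
    DataFrame with columns pf..fi on the 0-100 scale.  Subscales with
    fewer than half their items answered come back as NaN.
    """
    df = _as_frame(items)
    missing_cols = [c for c in EORTC_ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing EORTC item columns: {missing_cols}")
    for c in EORTC_ITEM_COLUMNS:
        hi = 7 if c in ("q29", "q30") else 4
        _validate_levels(df, c, 1, hi)
    out = {}
    for name, (cols, rng, upward) in _EORTC_SCALES.items():
        vals = df[list(cols)].apply(pd.to_numeric, errors="coerce")
        n_ans = vals.notna().sum(axis=1)
        rs = vals.mean(axis=1)
        # half rule: score when answered items are at least half of the scale
        rs = rs.where(2 * n_ans >= len(cols))
        frac = (rs - 1.0) / rng
        out[name] = (frac if upward else 1.0 - frac) * 100.0
    return pd.DataFrame(out, index=df.index)[list(EORTC_SUBSCALES)]


def score_factg(items) -> pd.DataFrame:
    """Score FACT-G items into the four well-being subscale scores.

    Accepts a dict/Series or DataFrame with columns gp1..gp7, gs1..gs7,
    ge1..ge6, gf1..gf7 (Likert 0-4, missing allowed).  Returns pwb, swb,
    ewb, fwb as prorated sums; domains with under 50% of items answered
    are NaN.
    """
    df = _as_frame(items)
    missing_cols = [c for c in FACTG_ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing FACT-G item columns: {missing_cols}")
    for c in FACTG_ITEM_COLUMNS:
        _validate_levels(df, c, 0, 4)
    out = {}
    for name, (cols, reversed_items) in _FACTG_SCALES.items():
        vals = df[list(cols)].apply(pd.to_numeric, errors="coerce")
        for c in cols:
            if c in reversed_items:
                vals[c] = 4.0 - vals[c]
        n_ans = vals.notna().sum(axis=1)
        total = vals.sum(axis=1, min_count=1)
        prorated = total * len(cols) / n_ans.replace(0, np.nan)
        out[name] = prorated.where(2 * n_ans >= len(cols))
    return pd.DataFrame(out, index=df.index)[list(FACTG_SUBSCALES)]


def read_cohort(path, source: str) -> MappingDataset:
    """Read a respondent CSV into a MappingDataset.

    ``source`` is ``'eortc'`` or ``'factg'``.  The file may be
    subscale-level (columns age, female, pf..fi / pwb..fwb) or item-level
    (q1..q30 / gp1..gf7), in which case subscales are computed via the
    scoring functions.  Optional EQ-5D-5L columns (mo, sc, ua, pd, ad,
    levels 1-5) and an observed index column ``y`` are carried through.
    """
    df = pd.read_csv(path)
    item_cols = EORTC_ITEM_COLUMNS if source == "eortc" else FACTG_ITEM_COLUMNS
    if any(c in df.columns for c in item_cols):
        present = [c for c in item_cols if c in df.columns]
        if len(present) != len(item_cols):
            raise ValueError(
                f"item-level file is missing columns: {sorted(set(item_cols) - set(present))}"
            )
        scorer = score_eortc if source == "eortc" else score_factg
        subs = scorer(df[list(item_cols)])
        df = pd.concat([df.drop(columns=list(item_cols)), subs], axis=1)
    for dim in DIMENSIONS:
        if dim in df.columns:
            v = pd.to_numeric(df[dim], errors="coerce")
            bad = df[dim].notna() & (v.isna() | ~v.isin([1, 2, 3, 4, 5]))
            if bad.any():
                raise ValueError(
                    f"EQ-5D column {dim!r} has invalid levels in rows {df.index[bad].tolist()}"
                )
    return MappingDataset(df, source=source)
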