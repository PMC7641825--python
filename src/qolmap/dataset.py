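"""The MappingDataset container shared by all pipeline stages.

A mapping dataset is a table with one row per respondent holding the
covariates the mapping algorithms consume (age in years, a female 0/1
indicator, and the source measure's subscale scores), optionally the
observed EQ-5D-5L item levels (columns mo, sc, ua, pd, ad in 1..5) and
the observed index ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .valueset import DIMENSIONS

EORTC_SUBSCALES = (
    "pf", "rf", "ef", "cf", "sf", "ghs",
    "fa", "nv", "pa", "dy", "sl", "ap", "co", "di", "fi",
)
FACTG_SUBSCALES = ("pwb", "swb", "ewb", "fwb")

#: inclusive (low, high) bounds per subscale score
SUBSCALE_RANGES = {
    **{s: (0.0, 100.0) for s in EORTC_SUBSCALES},
    "pwb": (0.0, 28.0), "swb": (0.0, 28.0), "ewb": (0.0, 24.0), "fwb": (0.0, 28.0),
}


def subscales_for(source: str) -> tuple[str, ...]:
    if source == "eortc":
        return EORTC_SUBSCALES
    if source == "factg":
        return FACTG_SUBSCALES
    raise ValueError(f"source must be 'eortc' or 'factg', got {source!r}")


@dataclass
class MappingDataset:
    """Respondent-level table of covariates, EQ-5D items and index.

    ``df`` holds (at least) age and female plus the source subscales;
    EQ-5D item columns and the observed index ``y`` are optional and
    only required for model fitting.
    """

    df: pd.DataFrame
    source: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        subs = subscales_for(self.source)
        self.df = self.df.reset_index(drop=True)
        for col in ("age", "female"):
            if col not in self.df.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        missing = [s for s in subs if s not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing subscale columns {missing}")
        bad = []
        for s in subs:
            v = pd.to_numeric(self.df[s], errors="coerce")
            lo, hi = SUBSCALE_RANGES[s]
            out = v.notna() & ((v < lo - 1e-9) | (v > hi + 1e-9))
            if out.any():
                bad.append((s, self.df.index[out].tolist()))
        if bad:
            raise ValueError(f"subscale values out of range: {bad}")
        fem = self.df["female"]
        if not fem.dropna().isin([0, 1]).all():
            raise ValueError("female must be coded 0/1")
        if self.has_states:
            lev = self.df[list(DIMENSIONS)]
            ok = lev.isin([1, 2, 3, 4, 5]) | lev.isna()
            if not ok.all().all():
                offenders = [
                    (c, self.df.index[~ok[c]].tolist()) for c in lev.columns if not ok[c].all()
                ]
                raise ValueError(f"EQ-5D levels outside 1..5: {offenders}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def subscale_columns(self) -> tuple[str, ...]:
        return subscales_for(self.source)

    @property
    def has_index(self) -> bool:
        return "y" in self.df.columns

    @property
    def has_states(self) -> bool:
        return all(d in self.df.columns for d in DIMENSIONS)

    def complete_cases(self, columns) -> "MappingDataset":
        """Rows with every listed column non-missing (complete-case analysis)."""
        keep = self.df[list(columns)].notna().all(axis=1)
        out = MappingDataset(self.df.loc[keep].copy(), self.source, dict(self.meta))
        out.meta["n_dropped_incomplete"] = int((~keep).sum())
        return out

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)
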