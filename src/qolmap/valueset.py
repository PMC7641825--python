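"""EQ-5D-5L value sets (tariffs) as additive disutility decrements.

An EQ-5D-5L health state assigns one of five levels to each of five
dimensions: mobility (mo), self-care (sc), usual activities (ua),
pain/discomfort (pd), and anxiety/depression (ad).  A value set maps each
(dimension, level) pair to a utility decrement; the index of a state is

    index = 1 - sum over dimensions of decrement[dimension, level]

so that full health (1,1,1,1,1) scores exactly 1 and 0 anchors death.
Level-1 decrements are zero and decrements are non-decreasing in level.

The bundled tariff ``tariff_japan_synthetic.csv`` is a synthetic stand-in
for the Japanese EQ-5D-5L value set: the published per-level decrements
are not redistributable here, so the file contains constructed decrements
calibrated so that the two extremes of the real Japanese tariff hold
exactly -- the worst state (5,5,5,5,5) scores -0.025 and the second
largest attainable index is 0.895.  Any real national tariff can be used
by supplying a CSV in the same 25-row ``dimension,level,decrement``
format.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")
N_LEVELS = 5

__all__ = [
    "DIMENSIONS",
    "N_LEVELS",
    "Eq5dState",
    "ValueSet",
    "index_of_state",
    "load_value_set",
    "japan_synthetic_tariff",
]


@dataclass(frozen=True)
class Eq5dState:
    """One respondent's five EQ-5D-5L item levels, each in 1..5."""

    mo: int
    sc: int
    ua: int
    pd: int
    ad: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            lev = getattr(self, dim)
            if not (isinstance(lev, (int, np.integer)) and 1 <= lev <= 5):
                raise ValueError(
                    f"EQ-5D-5L level for {dim!r} must be an integer in 1..5, got {lev!r}"
                )

    def levels(self) -> tuple[int, int, int, int, int]:
        return (self.mo, self.sc, self.ua, self.pd, self.ad)


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L tariff: decrement per (dimension, level).

    ``decrements`` is a (5, 5) array indexed [dimension, level-1] in the
    dimension order ``DIMENSIONS``.  Column 0 (level 1) is all zeros and
    rows are non-decreasing.
    """

    decrements: np.ndarray
    label: str = "unnamed"
    _summaries: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        dec = np.asarray(self.decrements, dtype=float)
        if dec.shape != (5, 5):
            raise ValueError(f"decrement table must be 5x5, got {dec.shape}")
        if not np.all(np.isfinite(dec)):
            raise ValueError("decrements must be finite")
        if not np.allclose(dec[:, 0], 0.0):
            raise ValueError("level-1 decrements must all be 0")
        if np.any(np.diff(dec, axis=1) < -1e-12):
            raise ValueError("decrements must be non-decreasing in level")
        object.__setattr__(self, "decrements", dec)

    def decrement(self, dimension: str, level: int) -> float:
        return float(self.decrements[DIMENSIONS.index(dimension), level - 1])

    @property
    def min_index(self) -> float:
        """Index of the worst state (5,5,5,5,5)."""
        return 1.0 - float(self.decrements[:, -1].sum())

    def enumerate_indexes(self) -> np.ndarray:
        """Indexes of all 5^5 = 3125 states, in itertools.product order."""
        key = "all_indexes"
        if key not in self._summaries:
            vals = np.array(
                [
                    1.0 - sum(self.decrements[d, lev - 1] for d, lev in enumerate(state))
                    for state in itertools.product(range(1, 6), repeat=5)
                ]
            )
            self._summaries[key] = vals
        return self._summaries[key]

    @property
    def second_largest_index(self) -> float:
        """Largest attainable index below 1 (enumerated over all states)."""
        vals = np.unique(self.enumerate_indexes())
        return float(vals[-2])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (dim, lev, self.decrements[d, lev - 1])
            for d, dim in enumerate(DIMENSIONS)
            for lev in range(1, 6)
        ]
        return pd.DataFrame(rows, columns=["dimension", "level", "decrement"])


def index_of_state(state: Eq5dState, vs: ValueSet) -> float:
    """Utility index of one health state: 1 minus the summed decrements."""
    return float(
        1.0 - sum(vs.decrements[d, lev - 1] for d, lev in enumerate(state.levels()))
    )


def index_of_levels(levels: np.ndarray, vs: ValueSet) -> np.ndarray:
    """Vectorised index for an (n, 5) integer array of levels in 1..5."""
    levels = np.asarray(levels)
    if levels.ndim != 2 or levels.shape[1] != 5:
        raise ValueError("levels must be an (n, 5) array")
    if levels.size and (levels.min() < 1 or levels.max() > 5):
        raise ValueError("levels must lie in 1..5")
    dec = vs.decrements[np.arange(5)[None, :], levels - 1]
    return 1.0 - dec.sum(axis=1)


def load_value_set(path, label: str | None = None) -> ValueSet:
    """Read a 25-row ``dimension,level,decrement`` CSV into a ValueSet.

    Validates completeness (every dimension x level cell exactly once),
    zero level-1 decrements and monotone levels; raises ValueError with
    the offending cells otherwise.
    """
    df = pd.read_csv(path)
    required = {"dimension", "level", "decrement"}
    if not required.issubset(df.columns):
        raise ValueError(f"value-set file must have columns {sorted(required)}")
    if len(df) != 25:
        raise ValueError(f"value-set file must have 25 data rows, found {len(df)}")
    dec = np.full((5, 5), np.nan)
    for _, row in df.iterrows():
        dim = str(row["dimension"]).strip().lower()
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown dimension {row['dimension']!r}")
        lev = int(row["level"])
        if not 1 <= lev <= 5:
            raise ValueError(f"level out of range for {dim}: {row['level']!r}")
        if not np.isnan(dec[DIMENSIONS.index(dim), lev - 1]):
            raise ValueError(f"duplicate cell ({dim}, {lev})")
        dec[DIMENSIONS.index(dim), lev - 1] = float(row["decrement"])
    if np.isnan(dec).any():
        missing = [
            (DIMENSIONS[d], l + 1)
            for d, l in zip(*np.nonzero(np.isnan(dec)))
        ]
        raise ValueError(f"missing cells: {missing}")
    if label is None:
        label = getattr(path, "stem", None) or str(path)
    return ValueSet(decrements=dec, label=str(label))


def _bundled_path(name: str):
    return resources.files("qolmap.data").joinpath(name)


def bundled_file_sha256(name: str) -> str:
    """SHA-256 of a bundled data file (auditability of shipped tables)."""
    return hashlib.sha256(_bundled_path(name).read_bytes()).hexdigest()


def japan_synthetic_tariff() -> ValueSet:
    """The bundled synthetic Japan-anchored tariff.

    Synthetic stand-in calibrated to the two published extremes of the
    Japanese EQ-5D-5L value set: min index -0.025, second-largest 0.895.
    Per-level decrements are constructed, not the published ones.
    """
    with resources.as_file(_bundled_path("tariff_japan_synthetic.csv")) as p:
        return load_value_set(p, label="japan-synthetic")
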