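"""Array-backed population state and snapshot I/O.

The population is stored as a structure of aligned numpy arrays (one
entry per living fish) rather than a list of objects: annual steps are
then vectorised numpy operations, which keeps multi-century runs with
thousands of individuals fast.  :class:`Individual` is a per-row record
view used by tests and small-scale code.

Snapshots round-trip through plain CSV (one row per individual) so a
spin-up endpoint can seed later scenario runs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Individual", "Population", "SNAPSHOT_COLUMNS"]

SNAPSHOT_COLUMNS = [
    "id",
    "age",
    "length",
    "weight",
    "gonad_mass",
    "mature",
    "years_post_maturation",
    "appetite_gv",
    "pmrn_intercept_gv",
    "appetite_phen",
    "pmrn_intercept_phen",
]

_FLOAT_COLS = (
    "length",
    "weight",
    "gonad_mass",
    "appetite_gv",
    "pmrn_intercept_gv",
    "appetite_phen",
    "pmrn_intercept_phen",
)
_INT_COLS = ("id", "age", "years_post_maturation")


@dataclass
class Individual:
    """One fish, as a plain record (row view of a :class:`Population`)."""

    id: int
    age: int
    length: float
    weight: float
    gonad_mass: float
    mature: bool
    years_post_maturation: int
    appetite_gv: float
    pmrn_intercept_gv: float
    appetite_phen: float
    pmrn_intercept_phen: float


@dataclass
class Population:
    """All living fish plus the calendar year, as aligned arrays."""

    id: np.ndarray
    age: np.ndarray
    length: np.ndarray
    weight: np.ndarray
    gonad_mass: np.ndarray
    mature: np.ndarray
    years_post_maturation: np.ndarray
    appetite_gv: np.ndarray
    pmrn_intercept_gv: np.ndarray
    appetite_phen: np.ndarray
    pmrn_intercept_phen: np.ndarray
    year: int = 0
    next_id: int = 0

    def __post_init__(self) -> None:
        self.id = np.asarray(self.id, dtype=np.int64)
        for c in ("age", "years_post_maturation"):
            setattr(self, c, np.asarray(getattr(self, c), dtype=np.int64))
        for c in _FLOAT_COLS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))
        self.mature = np.asarray(self.mature, dtype=bool)
        n = self.id.size
        for c in SNAPSHOT_COLUMNS:
            if getattr(self, c).size != n:
                raise ValueError(f"column {c!r} misaligned with id column")
        if n and self.next_id <= int(self.id.max()):
            self.next_id = int(self.id.max()) + 1

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.id.size)

    @property
    def total_biomass(self) -> float:
        """Sum of somatic weights, kg (gonads are transient within a year)."""
        return float(self.weight.sum())

    def __len__(self) -> int:
        return self.n

    def get(self, i: int) -> Individual:
        """Record view of row ``i`` (copies scalars; for inspection/tests)."""
        return Individual(**{c: getattr(self, c)[i].item() for c in SNAPSHOT_COLUMNS})

    def validate(self) -> None:
        """Assert the state invariants; raises ``AssertionError`` on breach."""
        assert np.all(self.length > 0), "non-positive length"
        assert np.all(self.weight > 0), "non-positive weight"
        assert np.all(self.gonad_mass >= 0), "negative gonad mass"
        assert np.all((self.age >= 1)), "age below 1"
        assert np.all(self.years_post_maturation >= 0)
        assert np.all(self.mature | (self.years_post_maturation == 0))
        assert np.unique(self.id).size == self.n, "duplicate ids"

    # -- construction / combination --------------------------------------
    @classmethod
    def empty(cls, year: int = 0, next_id: int = 0) -> "Population":
        z = np.empty(0)
        return cls(*([z] * len(SNAPSHOT_COLUMNS)), year=year, next_id=next_id)

    def filter(self, mask: np.ndarray) -> "Population":
        """Keep only rows where ``mask`` is True (same year/id counter)."""
        cols = {c: getattr(self, c)[mask] for c in SNAPSHOT_COLUMNS}
        return Population(**cols, year=self.year, next_id=self.next_id)

    def extend(self, other: "Population") -> "Population":
        """Append ``other``'s rows (used to add recruits)."""
        cols = {
            c: np.concatenate([getattr(self, c), getattr(other, c)])
            for c in SNAPSHOT_COLUMNS
        }
        return Population(
            **cols, year=self.year, next_id=max(self.next_id, other.next_id)
        )

    # -- I/O --------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in SNAPSHOT_COLUMNS})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, year: int = 0) -> "Population":
        missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"snapshot missing column(s): {sorted(missing)}")
        cols = {c: df[c].to_numpy() for c in SNAPSHOT_COLUMNS}
        return cls(**cols, year=year)

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, year: int = 0) -> "Population":
        return cls.from_dataframe(pd.read_csv(path), year=year)
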