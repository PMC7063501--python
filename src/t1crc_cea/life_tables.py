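"""Period life tables supplying age-dependent background (all-cause) mortality.

The cohort engine needs a monthly probability of death from causes other than
colorectal cancer at every attained age. That comes from a standard period life
table — ``(age, q_annual)`` rows where ``q_annual`` is the probability of dying
within the year of age. A CSV in the same two-column shape as the CDC national
life tables loads directly; a synthetic Gompertz table (see
:mod:`t1crc_cea.synthetic`) ships as the offline default.

Annual-to-monthly conversion assumes a constant hazard within each year of age,
the usual actuarial convention: ``q_month = 1 - (1 - q_annual)**(1/12)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "load_life_table", "monthly_background_mortality"]


class LifeTableError(ValueError):
    """Life table fails validation (gap in ages, probability out of bounds)."""


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, annual death probability) entries, contiguous in age."""

    ages: np.ndarray          # integer years, contiguous
    q_annual: np.ndarray      # P(death within the year) at each age
    provenance: str = ""

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if ages.size != q.size or ages.size == 0:
            raise LifeTableError("ages and q_annual must be equal-length and non-empty")
        if not np.all(np.diff(ages) == 1):
            missing = int(ages[np.where(np.diff(ages) != 1)[0][0]]) + 1
            raise LifeTableError(f"ages must be contiguous; gap at age {missing}")
        if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
            bad = int(ages[np.where((q < 0) | (q > 1) | ~np.isfinite(q))[0][0]])
            raise LifeTableError(f"q_annual outside [0, 1] at age {bad}")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age_years: int) -> float:
        if age_years < self.min_age or age_years > self.max_age:
            raise LifeTableError(
                f"age {age_years} outside table range [{self.min_age}, {self.max_age}]"
            )
        return float(self.q_annual[age_years - self.min_age])

    def monthly_q(self, age_years: int) -> float:
        return 1.0 - (1.0 - self.q_at(age_years)) ** (1.0 / 12.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.q_annual})

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(
    source: Union[str, Path, io.TextIOBase],
    *,
    required_span: tuple[int, int] = (65, 100),
    provenance: str = "",
) -> LifeTable:
    """Read a life table from CSV text or a path.

    Expected columns: ``age, qx`` (header optional). An optional ``sex`` column
    is accepted; per-age probabilities are then averaged across sexes, since the
    model follows a single mixed cohort.
    """
    if isinstance(source, io.TextIOBase):
        buf = source
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        buf = Path(source)
        provenance = provenance or str(source)
    else:
        buf = io.StringIO(str(source))

    df = pd.read_csv(buf, header=None, comment="#", skip_blank_lines=True)
    # Drop a header row if the first cell is not numeric.
    if not str(df.iloc[0, 0]).strip().lstrip("-").replace(".", "", 1).isdigit():
        names = [str(c).strip().lower() for c in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
        df.columns = names
    else:
        df.columns = ["age", "qx", "sex"][: df.shape[1]]

    if "age" not in df.columns or "qx" not in df.columns:
        raise LifeTableError("life table needs 'age' and 'qx' columns")

    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    df["qx"] = pd.to_numeric(df["qx"], errors="raise").astype(float)
    if "sex" in df.columns:
        df = df.groupby("age", as_index=False)["qx"].mean()
    df = df.sort_values("age")

    lt = LifeTable(df["age"].to_numpy(), df["qx"].to_numpy(), provenance=provenance)
    lo, hi = required_span
    if lt.min_age > lo or lt.max_age < hi:
        raise LifeTableError(
            f"table spans ages [{lt.min_age}, {lt.max_age}]; model needs [{lo}, {hi}]"
        )
    return lt


def monthly_background_mortality(lt: LifeTable, age_months: int) -> float:
    """Monthly all-cause death probability at an attained age given in months.

    Constant hazard within each year of age: compounding the returned value
    twelve times reproduces the annual probability exactly.
    """
    return lt.monthly_q(age_months // 12)
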