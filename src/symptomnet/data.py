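"""Rating-scale data container used throughout the pipeline.

A :class:`RatingMatrix` holds a persons x variables table of subscale
scores (missing values as NaN), per-variable orientation flags and score
bounds, and optional per-person age and group columns.  Orientation is
"higher score = more difficulty"; instruments scored the other way round
(e.g. communication checklists where low scores flag problems) carry a
False flag and are reflected by :func:`symptomnet.preprocessing.orient_scores`
before any correlation is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["RatingMatrix"]


@dataclass
class RatingMatrix:
    """Persons x variables rating table with metadata.

    Parameters
    ----------
    values : DataFrame
        Numeric scores, one row per person, NaN for missing cells.
    orientation : Series of bool, optional
        Per variable, True if higher scores mean greater difficulty.
        Defaults to all True.
    bounds : mapping variable -> (min, max), optional
        Admissible score range per variable, used for reflection when
        re-orienting.  Variables without bounds are negated instead.
    age : Series, optional
        Age in years per person (aligned on the row index).
    group : Series, optional
        Categorical group label per person (e.g. diagnostic status).
    """

    values: pd.DataFrame
    orientation: Optional[pd.Series] = None
    bounds: Optional[Mapping[str, tuple]] = None
    age: Optional[pd.Series] = None
    group: Optional[pd.Series] = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        if not self.values.index.is_unique:
            raise ValueError("row identifiers must be unique")
        if self.orientation is None:
            self.orientation = pd.Series(True, index=self.values.columns)
        else:
            self.orientation = pd.Series(self.orientation).reindex(self.values.columns)
            if self.orientation.isna().any():
                missing = list(self.orientation.index[self.orientation.isna()])
                raise ValueError(f"orientation undefined for variables: {missing}")
            self.orientation = self.orientation.astype(bool)
        all_missing = self.values.isna().all(axis=0)
        if all_missing.any():
            raise ValueError(
                f"all-missing variables: {list(self.values.columns[all_missing])}"
            )
        for series_name in ("age", "group"):
            s = getattr(self, series_name)
            if s is not None:
                setattr(self, series_name, pd.Series(s).reindex(self.values.index))

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def variable_names(self) -> list:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    def copy(self) -> "RatingMatrix":
        return RatingMatrix(
            values=self.values.copy(),
            orientation=self.orientation.copy(),
            bounds=dict(self.bounds) if self.bounds is not None else None,
            age=self.age.copy() if self.age is not None else None,
            group=self.group.copy() if self.group is not None else None,
            log=list(self.log),
        )

    def subset_rows(self, index) -> "RatingMatrix":
        """Return a new RatingMatrix restricted to (or resampled over) rows.

        ``index`` may repeat labels (bootstrap resampling); the resulting
        row index is made unique by position.
        """
        vals = self.values.loc[index]
        vals = vals.reset_index(drop=True)
        out = RatingMatrix(
            values=vals,
            orientation=self.orientation.copy(),
            bounds=dict(self.bounds) if self.bounds is not None else None,
            age=self.age.loc[index].reset_index(drop=True) if self.age is not None else None,
            group=self.group.loc[index].reset_index(drop=True) if self.group is not None else None,
            log=list(self.log),
        )
        return out

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        orientation: Optional[Mapping[str, bool]] = None,
        bounds: Optional[Mapping[str, tuple]] = None,
        age_col: Optional[str] = None,
        group_col: Optional[str] = None,
    ) -> "RatingMatrix":
        """Build a RatingMatrix from a flat table, splitting off age/group."""
        df = df.copy()
        age = df.pop(age_col) if age_col is not None and age_col in df else None
        group = df.pop(group_col) if group_col is not None and group_col in df else None
        return cls(values=df, orientation=orientation, bounds=bounds, age=age, group=group)

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path, age_col: str = "age", group_col: str = "group") -> None:
        out = self.values.copy()
        if self.age is not None:
            out[age_col] = self.age
        if self.group is not None:
            out[group_col] = self.group
        out.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def read_csv(
        cls,
        path,
        orientation: Optional[Mapping[str, bool]] = None,
        bounds: Optional[Mapping[str, tuple]] = None,
        age_col: str = "age",
        group_col: str = "group",
    ) -> "RatingMatrix":
        df = pd.read_csv(path, na_values=["NA", ""])
        return cls.from_dataframe(
            df, orientation=orientation, bounds=bounds, age_col=age_col, group_col=group_col
        )
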