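"""Analysis-ready dataset containers.

``PKDataset`` wraps a pandas frame in the NONMEM-style event layout: one dose
row per subject (``EVID=1``) followed by observation rows (``EVID=0``), with
subject covariates joined on every row.  All kinetic code consumes the padded
array view produced by :meth:`PKDataset.to_fit_arrays`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLUMNS",
    "DesignSpec",
    "Subject",
    "Cohort",
    "PKDataset",
    "FitArrays",
    "DatasetError",
]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV"]
COVARIATE_COLUMNS = ["AGE", "WT", "HT", "BMI", "SEX", "RACE"]

#: clinical sampling schedule (h) for a single 600 ug inhaled dose
DEFAULT_SAMPLING_TIMES = (
    0.0, 0.08, 0.17, 0.33, 0.50, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0,
)
DEFAULT_DOSE_UG = 600.0


class DatasetError(ValueError):
    """Raised when a dataset violates the event-record contract."""


@dataclass(frozen=True)
class DesignSpec:
    """Trial design: sampling grid (h) and dose amount (ug) at t=0."""

    times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    dose_ug: float = DEFAULT_DOSE_UG

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise DatasetError("sampling times must be strictly increasing")
        if self.dose_ug <= 0:
            raise DatasetError("dose must be positive")


@dataclass(frozen=True)
class Subject:
    """A (virtual) study participant."""

    id: int
    age: float  # years
    weight: float  # kg
    height: float  # cm
    gender: str  # "M" / "F"
    race: str  # "AmericanIndianAlaskanNative" / "Japanese" / "Chinese"

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def race_group(self) -> str:
        """Two-level race grouping used in the covariate model."""
        return (
            "AmericanIndianAlaskanNative"
            if self.race == "AmericanIndianAlaskanNative"
            else "EastAsian"
        )


@dataclass
class Cohort:
    """An ordered collection of subjects."""

    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ID": s.id,
                "AGE": s.age,
                "WT": s.weight,
                "HT": s.height,
                "BMI": round(s.bmi, 2),
                "SEX": s.gender,
                "RACE": s.race,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        subjects = [
            Subject(
                id=int(r.ID),
                age=float(r.AGE),
                weight=float(r.WT),
                height=float(r.HT),
                gender=str(r.SEX),
                race=str(r.RACE),
            )
            for r in df.itertuples()
        ]
        return cls(subjects)


@dataclass
class FitArrays:
    """Padded per-subject arrays consumed by the estimation code.

    ``mask`` marks real (non-padded, non-missing) observations.
    """

    ids: np.ndarray  # (n,)
    times: np.ndarray  # (n, m)
    y: np.ndarray  # (n, m)
    mask: np.ndarray  # (n, m) bool
    dose: np.ndarray  # (n,)
    dose_time: np.ndarray  # (n,)
    covariates: pd.DataFrame = field(repr=False)  # indexed by subject id

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


class PKDataset:
    """Longitudinal dose + observation records in analysis-ready form."""

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing required columns: {missing}")
        df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
        df = df.reset_index(drop=True)
        for sid, sub in df.groupby("ID", sort=True):
            doses = sub[sub["EVID"] == 1]
            if len(doses) == 0:
                raise DatasetError(f"subject {sid} has no dose (EVID=1) record")
            if len(doses) > 1:
                raise DatasetError(f"subject {sid} has multiple dose records")
            obs = sub[sub["EVID"] == 0]
            bad = obs[(obs["MDV"] == 0) & ~(obs["DV"] >= 0)]
            if len(bad):
                raise DatasetError(
                    f"subject {sid}: non-missing observations must have DV >= 0 "
                    f"(rows {list(bad.index)})"
                )
        return df

    # -- views ---------------------------------------------------------------

    @property
    def subject_ids(self) -> np.ndarray:
        return np.sort(self.df["ID"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self, include_missing: bool = False) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if not include_missing:
            obs = obs[obs["MDV"] == 0]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def covariates(self) -> pd.DataFrame:
        cols = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        return (
            self.df.groupby("ID", sort=True)[cols].first()
            if cols
            else pd.DataFrame(index=pd.Index(self.subject_ids, name="ID"))
        )

    def to_fit_arrays(self) -> FitArrays:
        ids = self.subject_ids
        obs = self.observations()
        m = int(obs.groupby("ID").size().max())
        n = len(ids)
        times = np.zeros((n, m))
        y = np.zeros((n, m))
        mask = np.zeros((n, m), bool)
        dose = np.zeros(n)
        dose_time = np.zeros(n)
        dose_df = self.doses().set_index("ID")
        for i, sid in enumerate(ids):
            sub = obs[obs["ID"] == sid]
            k = len(sub)
            times[i, :k] = sub["TIME"].to_numpy()
            y[i, :k] = sub["DV"].to_numpy()
            mask[i, :k] = True
            # pad with the last time so the structural model stays in domain
            if k and k < m:
                times[i, k:] = times[i, k - 1]
            dose[i] = float(dose_df.loc[sid, "AMT"])
            dose_time[i] = float(dose_df.loc[sid, "TIME"])
        return FitArrays(ids, times, y, mask, dose, dose_time, self.covariates())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        return self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)
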