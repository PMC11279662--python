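"""Reading and writing analysis-ready datasets and cohort tables.

Files are NONMEM-style CSV (decimal point, comma separator, header row):
columns ID, TIME, AMT, DV, EVID, MDV plus joined covariates.  Dose rows are
EVID=1/MDV=1; observation rows EVID=0.  Missing DV may be coded ".".  The
canonical concentration unit is ug/L; a leading comment line of the form
``# units: ug/mL`` (or ``units="ug/mL"``) rescales on import.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import Cohort, DatasetError, PKDataset, REQUIRED_COLUMNS

__all__ = ["read_dataset", "write_dataset", "read_cohort", "write_cohort"]

_UNIT_SCALE = {"ug/L": 1.0, "ug/mL": 1000.0, "ng/mL": 1.0}


def read_dataset(path, units: str | None = None) -> PKDataset:
    """Read and validate a PK dataset CSV.

    Raises :class:`DatasetError` naming offending line numbers for malformed
    numeric fields, subjects without a dose record, or observation times that
    are not nondecreasing within a subject (in file order).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "units:" in first and units is None:
            units = first.split("units:")[1].strip()
    df = pd.read_csv(path, skiprows=skip, na_values=["."], dtype={"DV": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path.name}: missing required columns {missing}")

    # numeric conversion with line-number reporting (header + comment offset)
    offset = 2 + skip
    dv = pd.to_numeric(df["DV"], errors="coerce")
    bad = df.index[df["DV"].notna() & dv.isna()]
    if len(bad):
        lines = [int(i) + offset for i in bad]
        raise DatasetError(f"{path.name}: malformed DV values at lines {lines}")
    df["DV"] = dv
    for col in ("ID", "TIME", "AMT", "EVID", "MDV"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & vals.isna()]
        if len(bad):
            lines = [int(i) + offset for i in bad]
            raise DatasetError(
                f"{path.name}: malformed {col} values at lines {lines}"
            )
        df[col] = vals

    # missing DV ('.') on observation rows maps to the missing-data flag
    obs = df["EVID"] == 0
    df.loc[obs & df["DV"].isna(), "MDV"] = 1

    scale = _UNIT_SCALE.get(units or "ug/L")
    if scale is None:
        raise DatasetError(f"unknown concentration unit {units!r}")
    df.loc[obs, "DV"] = df.loc[obs, "DV"] * scale

    for sid, sub in df[obs].groupby("ID"):
        t = sub["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetError(
                f"{path.name}: non-monotone observation times for subject {sid}"
            )
    for sid, sub in df.groupby("ID"):
        if not (sub["EVID"] == 1).any():
            raise DatasetError(
                f"{path.name}: subject {sid} has no dose (EVID=1) record"
            )
    return PKDataset(df)


def write_dataset(dataset: PKDataset, path, units: str = "ug/L") -> None:
    """Write a dataset CSV with a declared-units header line."""
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise DatasetError(f"unknown concentration unit {units!r}")
    df = dataset.df.copy()
    obs = df["EVID"] == 0
    df.loc[obs, "DV"] = df.loc[obs, "DV"] / scale
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False, na_rep=".")


def read_cohort(path) -> Cohort:
    return Cohort.from_frame(pd.read_csv(path))


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)
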