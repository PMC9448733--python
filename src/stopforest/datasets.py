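"""Convenience loaders for the classic benchmark datasets.

Only the Boston Housing table can be materialised without user-supplied
files: it ships with the R package MASS, so :func:`load_boston_crime`
shells out to ``Rscript`` (R and MASS must be installed).  The other
benchmarks (MIT Servo rise-time, Tasmanian Abalone, Los Angeles Ozone,
NHANES glycohemoglobin) must be provided as CSV files by the user;
:func:`load_servo` documents the expected schema.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .data import ConfigurationError, Dataset, load_csv

__all__ = ["BENCHMARK_MSPE", "load_boston_crime", "load_servo"]

#: Reference minimum cross-validated / holdout MSPE reported for the five
#: classic benchmark datasets under each tree-expansion stopping rule
#: (rows: rule; columns: dataset).  Used for excess-table arithmetic and as
#: the comparison point for reproduction runs.
BENCHMARK_MSPE = pd.DataFrame(
    {
        "nhanes": [0.1395, 0.1398, 0.1398, 0.1398, 0.1399, 0.1397],
        "abalone": [4.5088, 4.5119, 4.5475, 4.5475, 4.5497, 4.5398],
        "boston": [32.2552, 30.9823, 33.7808, 32.6826, 33.7754, 32.4181],
        "ozone": [15.6340, 15.8862, 15.9173, 15.8043, 15.8223, 15.9343],
        "servo": [0.2729, 0.2774, 0.2601, 0.2676, 0.2241, 0.2235],
    },
    index=["parent", "leaf", "variance", "range", "icr10", "icr25"],
)


def load_boston_crime() -> Dataset:
    """Boston Housing data with per-capita crime rate as the outcome.

    506 census tracts, 13 numeric features (zn, indus, chas, nox, rm, age,
    dis, rad, tax, ptratio, black, lstat, medv).  Requires an ``Rscript``
    executable with the MASS package on PATH; the table is exported to a
    temporary CSV and loaded through the ordinary CSV path.
    """
    if shutil.which("Rscript") is None:
        raise ConfigurationError(
            "load_boston_crime needs an R installation with the MASS package "
            "(Rscript not found on PATH)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        csv_path = Path(tmp) / "boston.csv"
        script = (
            f'data(Boston, package="MASS"); '
            f'write.csv(Boston, "{csv_path.as_posix()}", row.names=FALSE)'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0 or not csv_path.exists():
            raise ConfigurationError(
                f"Rscript failed to export MASS::Boston: {proc.stderr.strip()}"
            )
        return load_csv(csv_path, outcome_column="crim")


def load_servo(path: str | Path = "data/servo.csv") -> Dataset:
    """MIT Servo rise-time data from a user-supplied CSV.

    Expected schema: header row with columns ``motor``, ``screw`` (the two
    five-level linkage types, numerically coded 1..5), ``pgain``, ``vgain``
    and the outcome column ``rise_time``.  167 rows.  This table is not
    redistributable with the package; supply it at ``path``.
    """
    return load_csv(path, outcome_column="rise_time")
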