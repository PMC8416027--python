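"""Long-format CSV I/O and table-level pre-processing.

The exchange format is a tidy long table with one row per
(condition, replicate, metabolite, mass shift, time) and columns::

    condition, replicate, metabolite, n_carbons, mass_shift, time_s,
    value, value_type

where ``value_type`` is ``intensity`` (raw ion counts) or ``fraction``
(normalised MID entries).  UTF-8, header row mandatory, '.' decimal separator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .isotope import (
    MassIsotopologueDistribution,
    correct_mid,
    natural_abundance_matrix,
    normalize_to_mid,
)

__all__ = [
    "TABLE_COLUMNS",
    "read_timecourse",
    "write_timecourse",
    "validate_table",
    "to_fractions",
    "correct_table",
]

TABLE_COLUMNS = (
    "condition", "replicate", "metabolite", "n_carbons",
    "mass_shift", "time_s", "value", "value_type",
)

_VALUE_TYPES = {"intensity", "fraction"}

_SAMPLE_KEYS = ["condition", "replicate", "metabolite", "n_carbons", "time_s"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")
    bad = set(table["value_type"].unique()) - _VALUE_TYPES
    if bad:
        raise ValueError(f"unknown value_type entries: {sorted(bad)}")
    if (table["time_s"] < 0).any():
        raise ValueError("negative time_s in measurement table")
    if (table["mass_shift"] > table["n_carbons"]).any():
        raise ValueError("mass_shift exceeds n_carbons in measurement table")
    return table


def read_timecourse(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV."""
    table = pd.read_csv(path)
    return validate_table(table)


def write_timecourse(table: pd.DataFrame, path: str | Path) -> None:
    validate_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def _sample_mids(table: pd.DataFrame):
    """Yield (group_key, sub-table, MID) per sample, building the MID from rows."""
    for key, sub in table.groupby(_SAMPLE_KEYS, sort=False):
        condition, replicate, metabolite, n_carbons, time_s = key
        n = int(n_carbons)
        values = np.zeros(n + 1)
        values[sub["mass_shift"].to_numpy(int)] = sub["value"].to_numpy(float)
        label = f"{condition}/rep{replicate}/{metabolite}/t={time_s}s"
        yield key, sub, values, label


def to_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise intensity rows to fractions; fraction rows pass through.

    Normalisation divides each sample's intensities by their sum, so it is
    correct only when all monitored mass shifts of the sample are present.
    """
    validate_table(table)
    out = table.copy()
    is_intensity = out["value_type"] == "intensity"
    if not is_intensity.any():
        return out
    for key, sub, values, label in _sample_mids(out[is_intensity]):
        mid = normalize_to_mid(values, str(key[2]), key=label)
        out.loc[sub.index, "value"] = mid.fractions[sub["mass_shift"].to_numpy(int)]
    out.loc[is_intensity, "value_type"] = "fraction"
    return out


def correct_table(table: pd.DataFrame, p13C: float) -> pd.DataFrame:
    """Apply natural-abundance correction to every sample in a fraction table.

    Samples whose rows cover only part of the envelope (e.g. m0..m2 of a
    six-carbon metabolite) are corrected on the padded envelope; the reported
    rows keep their original mass shifts.
    """
    table = to_fractions(table)
    out = table.copy()
    matrices: dict[int, object] = {}
    for key, sub, values, label in _sample_mids(out):
        n = int(key[3])
        matrix = matrices.setdefault(n, natural_abundance_matrix(n, p13C))
        mid = MassIsotopologueDistribution(str(key[2]), n, values)
        corrected = correct_mid(mid, matrix)
        out.loc[sub.index, "value"] = corrected.fractions[sub["mass_shift"].to_numpy(int)]
    return out
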