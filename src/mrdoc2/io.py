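"""CSV readers/writers for twin tables and YAML run configuration."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import GroupMoments, MomentData
from .simulate import TWIN_COLUMNS

__all__ = [
    "read_twin_csv",
    "write_twin_csv",
    "moments_from_table",
    "load_config",
    "echo_config",
]

_NUMERIC = TWIN_COLUMNS[2:]


def read_twin_csv(path) -> pd.DataFrame:
    """Read and validate a wide-format twin-pair table.

    Errors carry the 1-based file line number (header is line 1).
    """
    table = pd.read_csv(path)
    missing = [c for c in TWIN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad_zyg = table.index[~table["zygosity"].isin(["MZ", "DZ"])]
    if len(bad_zyg):
        line = int(bad_zyg[0]) + 2
        raise ValueError(
            f"{path}, line {line}: zygosity {table.loc[bad_zyg[0], 'zygosity']!r} "
            "is not 'MZ' or 'DZ'"
        )
    for col in _NUMERIC:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna()]
        if len(bad):
            line = int(bad[0]) + 2
            raise ValueError(
                f"{path}, line {line}: non-numeric value {table.loc[bad[0], col]!r} "
                f"in column {col}"
            )
        table[col] = values.astype(float)
    return table[list(TWIN_COLUMNS)]


def write_twin_csv(table: pd.DataFrame, path) -> None:
    """Write a twin table at full float precision (lossless round-trip)."""
    table.to_csv(path, index=False, float_format="%.17g")


def moments_from_table(table: pd.DataFrame) -> MomentData:
    """Per-zygosity sample covariance, mean and pair counts.

    Sample covariances use the n-1 divisor.  A zygosity group with no rows
    is dropped with a warning (a one-group analysis is possible but weakly
    informative).
    """
    groups = {}
    for label in ("MZ", "DZ"):
        rows = table[table["zygosity"] == label]
        if len(rows) == 0:
            warnings.warn(f"no {label} pairs in table; group dropped", stacklevel=2)
            groups[label] = None
            continue
        data = rows[list(_NUMERIC)].to_numpy(dtype=float)
        if len(rows) < 2:
            raise ValueError(f"{label} group needs at least 2 pairs for a covariance")
        groups[label] = GroupMoments(
            covariance=np.cov(data, rowvar=False, ddof=1),
            mean=data.mean(axis=0),
            n_pairs=len(rows),
        )
    return MomentData(mz=groups["MZ"], dz=groups["DZ"])


_KNOWN_SECTIONS = {"model", "pattern", "design", "study", "output", "verbosity",
                   "reliability", "grid", "scenario"}


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(
            f"{path}: unknown config section(s) {sorted(unknown)}; "
            f"known sections are {sorted(_KNOWN_SECTIONS)}"
        )
    return config


def echo_config(config: dict, outdir) -> None:
    """Write the resolved configuration next to a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
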