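"""Readers and writers for the pipeline's tabular artifacts.

Cohort CSV conventions: UTF-8, "." decimal separator, empty cell =
missing, one row per subject with an ``id`` column followed by
covariates and raw test scores.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["read_cohort", "write_cohort", "write_manifest"]

COVARIATE_COLUMNS = [
    "age", "age_group", "gender", "education_ge13",
    "apoe4_count", "amyloid", "cognitive_status",
]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (indexed by ``id``); empty cells become NaN."""
    df = pd.read_csv(path, index_col="id")
    if "age_group" not in df.columns and "age" in df.columns:
        from .cohort import assign_age_group

        df["age_group"] = df["age"].map(assign_age_group)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table losslessly (missing -> empty cell)."""
    df.to_csv(path, index=True, index_label="id")


def write_manifest(path, *, seeds: dict, settings: dict) -> None:
    """Record everything needed to reproduce a run byte-identically."""
    from . import __version__

    manifest = {
        "package": "cogposet",
        "version": __version__,
        "seeds": seeds,
        "settings": settings,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
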