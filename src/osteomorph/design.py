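"""Specimen design table: factors and covariates driving the statistics.

Each specimen carries its species, sex, reproductive strategy (pelvic
vs. transfer brooding), standard length (mm) and which body side the
analysed bone comes from.  One bone per specimen enters the analyses;
the side is data, not a hard-coded choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["DesignTable", "read_design"]

REQUIRED_COLUMNS = ["specimen_id", "species", "sex", "strategy", "standard_length"]
SEX_LEVELS = {"female", "male"}
STRATEGY_LEVELS = {"pelvic", "transfer"}


@dataclass
class DesignTable:
    """Validated specimen table (wraps a pandas DataFrame)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if "side" not in df.columns:
            df = df.assign(side="right")
        dup = df["specimen_id"][df["specimen_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate specimen_id: {sorted(dup.unique())}")
        bad_sex = set(df["sex"]) - SEX_LEVELS
        if bad_sex:
            raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
        bad_strat = set(df["strategy"]) - STRATEGY_LEVELS
        if bad_strat:
            raise ValueError(f"unknown strategy levels: {sorted(bad_strat)}")
        bad_len = df.loc[df["standard_length"] <= 0, "specimen_id"]
        if not bad_len.empty:
            raise ValueError(
                f"non-positive standard_length for specimens: {list(bad_len)}")
        # strategy is a species-level attribute; it may not vary within species
        per_species = df.groupby("species")["strategy"].nunique()
        mixed = per_species[per_species > 1]
        if not mixed.empty:
            raise ValueError(
                f"strategy varies within species: {list(mixed.index)}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.frame["specimen_id"])

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def group_key(self) -> pd.Series:
        """(strategy, sex) label per specimen, the generator's group unit."""
        return self.frame["strategy"] + ":" + self.frame["sex"]


def read_design(path: str | Path) -> DesignTable:
    """Read and validate a design CSV (header row required)."""
    df = pd.read_csv(path)
    return DesignTable(df)
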