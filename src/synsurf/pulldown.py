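"""Ecto-Fc pull-down spectral-count hit filters.

Two filter modes mirror the two affinity-chromatography experiments:

* whole-brain mode — keep proteins absent from every Fc-control column
  (strictly zero counts) and carrying >=2 spectral counts in every
  bait-ectodomain experiment;
* sorted-synaptosome (MF) mode — keep proteins with <=1 spectral count in
  every Fc control and >=2 spectral counts in every bait experiment.

Hits are ranked by summed bait spectral counts, descending, ties broken by
protein identifier.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["bait_columns", "control_columns", "read_pulldown_tsv",
           "filter_whole_brain", "filter_mf"]


def bait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("spc_bait_")]


def control_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("spc_ctrl_")]


def _validate(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    if "protein_id" not in table.columns:
        raise ValueError("pull-down table needs a 'protein_id' column")
    baits = bait_columns(table)
    ctrls = control_columns(table)
    if not baits:
        raise ValueError("pull-down table needs >=1 spc_bait_* column")
    if (table[baits + ctrls].to_numpy() < 0).any():
        raise ValueError("spectral counts must be non-negative")
    return baits, ctrls


def read_pulldown_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def _rank(table: pd.DataFrame, baits: list[str]) -> pd.DataFrame:
    out = table.copy()
    out["_total"] = out[baits].sum(axis=1)
    out = out.sort_values(["_total", "protein_id"],
                          ascending=[False, True], kind="mergesort")
    return out.drop(columns="_total").reset_index(drop=True)


def _filter(table: pd.DataFrame, max_control: int, min_bait: int) -> pd.DataFrame:
    baits, ctrls = _validate(table)
    keep = (table[baits] >= min_bait).all(axis=1)
    if ctrls:
        keep &= (table[ctrls] <= max_control).all(axis=1)
    return _rank(table.loc[keep], baits)


def filter_whole_brain(table: pd.DataFrame, min_bait: int = 2) -> pd.DataFrame:
    """Absent in Fc controls (0 counts) and >=min_bait per bait experiment."""
    return _filter(table, max_control=0, min_bait=min_bait)


def filter_mf(table: pd.DataFrame, max_control: int = 1,
              min_bait: int = 2) -> pd.DataFrame:
    """<=max_control counts per Fc control and >=min_bait per bait experiment."""
    return _filter(table, max_control=max_control, min_bait=min_bait)
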