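"""Shared in-memory containers for expression matrices.

A single :class:`IntensityMatrix` serves both the proteomics LFQ table and
the miRNA array: features on rows, samples on columns, ``NaN`` marking
missing observations, and a mapping from group name to its sample columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a parameter set is internally inconsistent or infeasible."""


@dataclass
class IntensityMatrix:
    """Features x samples numeric table with group labels.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with one column per sample.
        Missing observations are ``NaN`` (zeros in raw input files are
        converted to ``NaN`` by the readers).
    groups:
        Mapping from group name to the list of sample columns belonging
        to that group. Columns must partition into the named groups.
    log2_scale:
        Whether ``data`` holds log2 intensities (``True``) or raw-scale
        intensities (``False``).
    """

    data: pd.DataFrame
    groups: Dict[str, List[str]] = field(default_factory=dict)
    log2_scale: bool = False

    def __post_init__(self) -> None:
        for g, cols in self.groups.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"group {g!r} references unknown samples {missing}")
        all_cols = [c for cols in self.groups.values() for c in cols]
        if len(set(all_cols)) != len(all_cols):
            raise ValueError("a sample column is assigned to more than one group")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def group_names(self) -> List[str]:
        return list(self.groups)

    def group_data(self, name: str) -> pd.DataFrame:
        return self.data[self.groups[name]]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "IntensityMatrix":
        return replace(self, data=self.data.copy(),
                       groups={g: list(c) for g, c in self.groups.items()})

    # -- scale conversions -----------------------------------------------
    def to_log2(self) -> "IntensityMatrix":
        if self.log2_scale:
            return self.copy()
        with np.errstate(divide="ignore"):
            out = np.log2(self.data.where(self.data > 0))
        return replace(self, data=out, log2_scale=True)

    def to_raw(self) -> "IntensityMatrix":
        if not self.log2_scale:
            return self.copy()
        return replace(self, data=np.power(2.0, self.data), log2_scale=False)
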