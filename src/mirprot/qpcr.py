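"""Relative qPCR quantification by the 2^-ddCT (Livak) method.

Each sample's target CT is normalized to a reference gene measured in
the same sample (dCT = CT_target - CT_reference), group dCTs are
averaged arithmetically, and the treated group is referred to a
calibrator group: ddCT = mean dCT(treated) - mean dCT(calibrator),
fold = 2^-ddCT. Amplification efficiency is fixed at exactly 2 per
cycle, as the method assumes.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .containers import ConfigurationError

__all__ = ["ddct_fold_change", "percent_change", "DEFAULT_REFERENCE"]

DEFAULT_REFERENCE = "RNU6B"


def _delta_ct(table: pd.DataFrame, target: str, reference: str,
              group: str) -> pd.Series:
    sub = table[table["group"] == group]
    tgt = sub[sub["target"] == target].set_index("sample_id")["ct"]
    ref = sub[sub["target"] == reference].set_index("sample_id")["ct"]
    if tgt.empty:
        raise ConfigurationError(
            f"no {target!r} CT values in group {group!r}")
    missing_ref = sorted(set(tgt.index) - set(ref.index))
    if missing_ref:
        raise ConfigurationError(
            f"missing reference {reference!r} CT for sample(s) {missing_ref}")
    return tgt - ref.loc[tgt.index]


def ddct_fold_change(table: pd.DataFrame, target: str, treated_group: str,
                     calibrator_group: str,
                     reference: str = DEFAULT_REFERENCE
                     ) -> Tuple[float, Dict[str, pd.Series]]:
    """Fold change of ``target`` in ``treated_group`` vs the calibrator.

    Returns the 2^-ddCT fold change and the per-sample dCT values of
    both groups. Raises a configuration error naming the sample if any
    included sample lacks a reference CT.
    """
    d_treat = _delta_ct(table, target, reference, treated_group)
    d_cal = _delta_ct(table, target, reference, calibrator_group)
    ddct = d_treat.mean() - d_cal.mean()
    fold = float(np.power(2.0, -ddct))
    return fold, {treated_group: d_treat, calibrator_group: d_cal}


def percent_change(fold: float) -> Tuple[float, str]:
    """Report a fold change as a signed percent with a direction label.

    fold < 1 -> ((1 - fold) * 100, "reduction"); fold >= 1 ->
    ((fold - 1) * 100, "increase"). A fold of 0.001 is a 99.9% reduction.
    """
    if fold <= 0:
        raise ConfigurationError("fold change must be positive")
    if fold < 1.0:
        return (1.0 - fold) * 100.0, "reduction"
    return (fold - 1.0) * 100.0, "increase"
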