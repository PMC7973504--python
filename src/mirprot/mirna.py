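"""miRNA differential expression, signed folds, and locus annotation.

The array analysis selects miRNAs with more than a twofold change and a
two-sample t-test p below 0.05 (raw p by default, BH-FDR reported
alongside and usable for selection via ``use_fdr``), with a fourfold
"top hit" tier. Fold changes follow the signed convention common in
array reports: ratios below 1 are reported as -1/ratio, so a 1/16 ratio
prints as -16.

Locus annotation attaches a cytoband (e.g. "14q32.31") and the nearest
common fragile site to each miRNA from a lookup built out of the
packaged tables; prefix matching on the cytoband ("14q32" matches both
14q32.2 and 14q32.31) supports cluster-level summaries such as the
fraction of hits at the 14q32 cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, IntensityMatrix
from . import fixtures as _fixtures

__all__ = [
    "LocusMap",
    "normalize_mirna_id",
    "dedupe_probes",
    "mirna_de_test",
    "signed_fold",
    "signed_to_ratio",
    "annotate_loci",
    "locus_fraction",
    "overlap_sets",
]


def normalize_mirna_id(mirna_id: str) -> str:
    """Case-insensitive miRNA id with any 'hsa-' prefix stripped."""
    s = str(mirna_id).strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


@dataclass
class LocusMap:
    """miRNA -> cytoband and cytoband -> nearest common fragile site."""

    mirna_to_cytoband: Dict[str, str] = field(default_factory=dict)
    cytoband_to_fragile: Dict[str, Optional[str]] = field(default_factory=dict)

    @classmethod
    def from_frames(cls, *frames: pd.DataFrame) -> "LocusMap":
        m2c: Dict[str, str] = {}
        c2f: Dict[str, Optional[str]] = {}
        for df in frames:
            for row in df.itertuples(index=False):
                key = normalize_mirna_id(row.mirna_id)
                m2c.setdefault(key, row.cytoband)
                fragile = getattr(row, "fragile_site", None)
                if isinstance(fragile, float) and np.isnan(fragile):
                    fragile = None
                c2f.setdefault(row.cytoband, fragile)
        return cls(m2c, c2f)

    @classmethod
    def from_fixtures(cls) -> "LocusMap":
        return cls.from_frames(
            _fixtures.load_fixture("table1_fac_vs_unt.tsv"),
            _fixtures.load_fixture("table2_ocv_vs_cv.tsv"),
        )

    def cytoband(self, mirna_id: str) -> Optional[str]:
        return self.mirna_to_cytoband.get(normalize_mirna_id(mirna_id))

    def fragile_site(self, mirna_id: str) -> Optional[str]:
        band = self.cytoband(mirna_id)
        return self.cytoband_to_fragile.get(band) if band else None


def dedupe_probes(matrix: IntensityMatrix) -> Tuple[IntensityMatrix, int]:
    """Collapse duplicate feature ids by per-sample median.

    Returns the collapsed matrix and the number of ids that had
    duplicates (arrays can carry the same snoRNA/miRNA on several
    probes).
    """
    dup_ids = matrix.data.index[matrix.data.index.duplicated()].unique()
    if len(dup_ids) == 0:
        return matrix.copy(), 0
    out = matrix.copy()
    out.data = out.data.groupby(level=0, sort=False).median()
    return out, int(len(dup_ids))


def signed_fold(ratio: float) -> float:
    """Signed fold-change convention: ratio >= 1 -> +ratio, else -1/ratio."""
    if ratio <= 0:
        raise ConfigurationError("ratio must be positive")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def signed_to_ratio(fold: float) -> float:
    """Inverse of :func:`signed_fold` (bijective on |fold| >= 1)."""
    if abs(fold) < 1.0:
        raise ConfigurationError("signed folds have magnitude >= 1")
    return float(fold) if fold >= 1.0 else float(-1.0 / fold)


def mirna_de_test(matrix: IntensityMatrix, control: str, treatment: str,
                  equal_var: bool = True, use_fdr: bool = False) -> pd.DataFrame:
    """Per-miRNA two-sided t-test with fold-change tiers.

    Equal-variance t by default (the usual choice at n=3 arrays); pass
    ``equal_var=False`` for Welch. The ratio is geometric,
    2^(mean log2 treatment - mean log2 control). Tier "twofold" requires
    ratio >= 2 or <= 0.5 plus p < 0.05 (raw p unless ``use_fdr``);
    "fourfold" analogously at 4 / 0.25.
    """
    for g in (control, treatment):
        if g not in matrix.groups:
            raise ConfigurationError(f"group {g!r} not present in matrix")
        if len(matrix.groups[g]) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 samples")
    log2m = matrix.to_log2()
    a = log2m.data[log2m.groups[control]].to_numpy()
    b = log2m.data[log2m.groups[treatment]].to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise ConfigurationError("miRNA matrix must be complete (no missing)")

    res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    ratio = np.power(2.0, log2fc)
    p_raw = np.asarray(res.pvalue)
    fdr = multipletests(p_raw, method="fdr_bh")[1]

    p_sel = fdr if use_fdr else p_raw
    two = ((ratio >= 2.0) | (ratio <= 0.5)) & (p_sel < 0.05)
    four = ((ratio >= 4.0) | (ratio <= 0.25)) & (p_sel < 0.05)
    tier = np.where(four, "fourfold", np.where(two, "twofold", "none"))

    return pd.DataFrame({
        "mirna_id": matrix.data.index,
        "log2fc": log2fc,
        "ratio": ratio,
        "fold_change_signed": [signed_fold(r) for r in ratio],
        "t": res.statistic,
        "p_raw": p_raw,
        "fdr_bh": fdr,
        "tier": tier,
    }).set_index("mirna_id")


def annotate_loci(records: pd.DataFrame, locus_map: LocusMap) -> pd.DataFrame:
    """Attach cytoband and nearest fragile site columns (unknown ids -> None)."""
    out = records.copy()
    ids = out.index if out.index.name == "mirna_id" else out["mirna_id"]
    out["cytoband"] = [locus_map.cytoband(i) for i in ids]
    out["nearest_fragile_site"] = [locus_map.fragile_site(i) for i in ids]
    return out


def locus_fraction(records: pd.DataFrame, cytoband_prefix: str
                   ) -> Tuple[int, int, Optional[float]]:
    """Count records whose cytoband starts with the prefix.

    Returns (count at locus, total, percent rounded to 2 decimals);
    percent is None for an empty record list.
    """
    total = len(records)
    if total == 0:
        return 0, 0, None
    bands = records["cytoband"].astype(str)
    count = int(bands.str.startswith(cytoband_prefix).sum())
    return count, total, round(100.0 * count / total, 2)


def overlap_sets(ids_a: Iterable[str], ids_b: Iterable[str]
                 ) -> Tuple[Set[str], Set[str], Set[str]]:
    """Partition two id collections into (only_a, shared, only_b).

    Ids are normalized (case, 'hsa-' prefix) before comparison.
    """
    a = {normalize_mirna_id(i) for i in ids_a}
    b = {normalize_mirna_id(i) for i in ids_b}
    return a - b, a & b, b - a
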