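"""Packaged reference fixtures.

Three tables of differentially expressed features from the chronic-iron
FTSEC comparisons (FAC vs Untreated, OCV vs CV), transcribed from the
printed summary tables, plus a miRNA->gene target map.

The target map (``target_map_fig5_synthetic.tsv``) is a SYNTHETIC
reconstruction: the displayed network contains 7 targets of miR-432-5p,
3 of miR-127-3p and 7 of miR-138-5p with PAX8 common to all three and
ALDH1A2 among the miR-138-5p targets; the remaining gene symbols are
filled from the 28-protein table and do not reproduce the commercial
knowledge base edge-for-edge.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["fixture_path", "load_fixture", "list_fixtures", "FIXTURES"]

#: registry: file name -> (expected row count, description)
FIXTURES = {
    "table1_fac_vs_unt.tsv": (
        35,
        "Top 35 miRNAs, FAC-treated vs Untreated FTSECs (signed fold change, "
        "BH-FDR p, cytoband, nearest common fragile site)",
    ),
    "table2_ocv_vs_cv.tsv": (
        45,
        "Top 45 miRNAs, oncogenic-cocktail (OCV) vs control virus (CV) FTSECs",
    ),
    "table3_fac_protein_targets.tsv": (
        28,
        "Top 28 protein targets (>4-fold) associated with gynecological "
        "cancers, FAC vs Untreated (raw LFQ intensity ratio)",
    ),
    "target_map_fig5_synthetic.tsv": (
        17,
        "SYNTHETIC miRNA->gene target map for miR-432-5p/miR-127-3p/miR-138-5p "
        "(PAX8 common to all three; ALDH1A2 under miR-138-5p)",
    ),
}


def fixture_path(name: str):
    """Return a traversable path to a packaged fixture file."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return resources.files(__name__).joinpath(name)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture TSV into a DataFrame ('N/A' -> NaN)."""
    with resources.as_file(fixture_path(name)) as p:
        return pd.read_csv(p, sep="\t", na_values=["N/A"])


def list_fixtures() -> pd.DataFrame:
    """Registry of packaged fixtures with realized row counts.

    Row counts are recomputed from the files so a corrupted install is
    visible immediately.
    """
    rows = []
    for name, (expected, desc) in FIXTURES.items():
        n = len(load_fixture(name))
        rows.append(
            {"file": name, "rows": n, "expected_rows": expected, "description": desc}
        )
    return pd.DataFrame(rows)
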