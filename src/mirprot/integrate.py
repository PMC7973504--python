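"""Inverse-expression pairing of miRNAs with protein targets.

A user-supplied miRNA->gene target map (a TSV stand-in for a commercial
target knowledge base) is joined against the two differential-expression
results; an edge survives only when both features pass their fold
cutoffs and move in opposite directions (miRNA up with protein down, or
miRNA down with protein up), the established heuristic for candidate
miRNA regulation. Gene-symbol matching is case-insensitive exact match
(no alias resolution).
"""

from __future__ import annotations

from typing import Iterable, Set

import pandas as pd

from .containers import ConfigurationError
from .mirna import LocusMap, normalize_mirna_id

__all__ = ["pair_inverse", "common_targets", "summarize_by_locus"]


def _mirna_folds(records: pd.DataFrame) -> pd.Series:
    df = records.reset_index() if records.index.name == "mirna_id" else records
    if "fold_change_signed" in df.columns:
        col = "fold_change_signed"
    elif "fold_change" in df.columns:
        col = "fold_change"
    else:
        raise ConfigurationError(
            "miRNA records need a 'fold_change_signed' or 'fold_change' column")
    s = pd.Series(df[col].to_numpy(dtype=float),
                  index=[normalize_mirna_id(i) for i in df["mirna_id"]])
    return s[~s.index.duplicated()]


def _protein_ratios(records: pd.DataFrame) -> pd.Series:
    df = records.reset_index()
    if "gene_symbol" in df.columns:
        col = "gene_symbol"
    elif "gene_name" in df.columns:
        col = "gene_name"
    else:
        raise ConfigurationError(
            "protein records need a 'gene_symbol' or 'gene_name' column")
    if "ratio" not in df.columns:
        raise ConfigurationError("protein records need a 'ratio' column")
    s = pd.Series(df["ratio"].to_numpy(dtype=float),
                  index=[str(g).upper() for g in df[col]])
    return s[~s.index.duplicated()]


def pair_inverse(mirna_records: pd.DataFrame, protein_records: pd.DataFrame,
                 target_map: pd.DataFrame, mirna_min_fold: float = 4.0,
                 protein_min_fold: float = 4.0) -> pd.DataFrame:
    """Emit map edges whose miRNA and protein changed in opposite directions.

    An edge is kept iff it is in the map, the miRNA's |signed fold| meets
    ``mirna_min_fold``, the protein's ratio meets ``protein_min_fold``
    (ratio >= f or <= 1/f), and the two directions are opposite. Output
    is sorted by (mirna_id, gene_symbol); it is always a subset of the
    map's edges.
    """
    mf = _mirna_folds(mirna_records)
    pr = _protein_ratios(protein_records)

    hits = []
    for edge in target_map.itertuples(index=False):
        mid = normalize_mirna_id(edge.mirna_id)
        gene = str(edge.gene_symbol).upper()
        if mid not in mf.index or gene not in pr.index:
            continue
        fold = float(mf.loc[mid])
        ratio = float(pr.loc[gene])
        if abs(fold) < mirna_min_fold:
            continue
        if not (ratio >= protein_min_fold or ratio <= 1.0 / protein_min_fold):
            continue
        mirna_up = fold > 0
        protein_up = ratio > 1.0
        if mirna_up == protein_up:
            continue  # concordant: not a candidate regulation
        hits.append({
            "mirna_id": edge.mirna_id,
            "mirna_signed_fold": fold,
            "gene_symbol": gene,
            "protein_ratio": ratio,
            "direction": ("mirna_up_protein_down" if mirna_up
                          else "mirna_down_protein_up"),
            "evidence": edge.evidence,
        })
    out = pd.DataFrame(hits, columns=["mirna_id", "mirna_signed_fold",
                                      "gene_symbol", "protein_ratio",
                                      "direction", "evidence"])
    return out.sort_values(["mirna_id", "gene_symbol"],
                           key=lambda s: s.str.lower()).reset_index(drop=True)


def common_targets(edges: pd.DataFrame, mirna_subset: Iterable[str]) -> Set[str]:
    """Genes targeted by ALL miRNAs in the subset.

    ``edges`` is any frame with ``mirna_id`` and ``gene_symbol`` columns
    (paired hits or a raw target map). Returns the intersection of the
    per-miRNA target sets (uppercased gene symbols).
    """
    subset = [normalize_mirna_id(m) for m in mirna_subset]
    if not subset:
        return set()
    keys = [normalize_mirna_id(m) for m in edges["mirna_id"]]
    genes = [str(g).upper() for g in edges["gene_symbol"]]
    per_mirna = {}
    for k, g in zip(keys, genes):
        per_mirna.setdefault(k, set()).add(g)
    result = per_mirna.get(subset[0], set()).copy()
    for m in subset[1:]:
        result &= per_mirna.get(m, set())
    return result


def summarize_by_locus(paired_hits: pd.DataFrame, locus_map: LocusMap
                       ) -> pd.DataFrame:
    """Per-cytoband counts of distinct miRNAs and distinct target genes.

    miRNAs without a known cytoband are pooled under "unknown"; counts
    partition the distinct id sets (each miRNA counted once, at its own
    band).
    """
    rows = {}
    seen_mirnas = set()
    for edge in paired_hits.itertuples(index=False):
        band = locus_map.cytoband(edge.mirna_id) or "unknown"
        entry = rows.setdefault(band, {"mirnas": set(), "genes": set()})
        entry["genes"].add(str(edge.gene_symbol).upper())
        key = normalize_mirna_id(edge.mirna_id)
        entry["mirnas"].add(key)
        seen_mirnas.add(key)
    out = pd.DataFrame(
        [{"cytoband": band, "n_mirnas": len(v["mirnas"]),
          "n_genes": len(v["genes"])} for band, v in sorted(rows.items())])
    return out
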