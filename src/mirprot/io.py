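"""Tabular and sequence I/O.

All tabular interchange is TSV with a header row. The protein-groups
dialect follows the MaxQuant proteinGroups.txt conventions used by this
pipeline: flag columns hold ``+`` when set, LFQ intensity columns are
named ``LFQ intensity <sample>``, and zero intensity means "not
quantified" (converted to NaN on read). Writers and readers round-trip
bit-exactly on the values they carry.
"""

from __future__ import annotations

from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import IntensityMatrix

__all__ = [
    "LFQ_PREFIX",
    "PROTEIN_GROUPS_FLAGS",
    "FormatError",
    "read_protein_groups",
    "write_protein_groups",
    "lfq_sample_columns",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_target_map",
    "write_target_map",
    "read_ct_table",
    "write_ct_table",
    "read_fasta",
    "write_fasta",
]

LFQ_PREFIX = "LFQ intensity "
PROTEIN_GROUPS_FLAGS = ["Reverse", "Potential contaminant", "Only identified by site"]
_REQUIRED = ["Protein IDs", "Gene names"] + PROTEIN_GROUPS_FLAGS


class FormatError(ValueError):
    """Raised when an input file is missing required structure."""


def read_protein_groups(path) -> pd.DataFrame:
    """Read a MaxQuant-style protein-groups TSV.

    Zero LFQ intensities are converted to NaN (not quantified). Raises
    :class:`FormatError` naming the first missing required column.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={f: str for f in PROTEIN_GROUPS_FLAGS})
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"protein-groups file lacks required column {col!r}")
    lfq = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq:
        raise FormatError(f"protein-groups file has no {LFQ_PREFIX!r}* columns")
    df[lfq] = df[lfq].astype(float).replace(0.0, np.nan)
    for f in PROTEIN_GROUPS_FLAGS:
        df[f] = df[f].fillna("")
    return df


def write_protein_groups(df: pd.DataFrame, path) -> None:
    out = df.copy()
    lfq = [c for c in out.columns if c.startswith(LFQ_PREFIX)]
    # NaN is serialized as 0 in the MaxQuant dialect
    out[lfq] = out[lfq].fillna(0.0)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def lfq_sample_columns(df: pd.DataFrame) -> Dict[str, str]:
    """Map sample name -> full LFQ column name."""
    return {c[len(LFQ_PREFIX):]: c for c in df.columns if c.startswith(LFQ_PREFIX)}


# -- generic feature x sample matrices ------------------------------------

def write_matrix_tsv(matrix: IntensityMatrix, path) -> None:
    """Write an intensity matrix; a header comment row encodes the groups."""
    group_spec = ";".join(f"{g}:{','.join(cols)}" for g, cols in matrix.groups.items())
    with open(path, "w") as fh:
        fh.write(f"#groups={group_spec}\n")
        fh.write(f"#log2_scale={int(matrix.log2_scale)}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id",
                           float_format="%.17g")


def read_matrix_tsv(path) -> IntensityMatrix:
    groups: Dict[str, List[str]] = {}
    log2_scale = False
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key == "groups" and val:
                for part in val.split(";"):
                    g, _, cols = part.partition(":")
                    groups[g] = cols.split(",") if cols else []
            elif key == "log2_scale":
                log2_scale = bool(int(val))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh, sep="\t", index_col="feature_id",
                           float_precision="round_trip")
    return IntensityMatrix(data=data, groups=groups, log2_scale=log2_scale)


# -- target maps, CT tables ------------------------------------------------

_EVIDENCE = {"experimental", "high", "moderate"}


def read_target_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "gene_symbol", "evidence"):
        if col not in df.columns:
            raise FormatError(f"target map lacks required column {col!r}")
    bad = set(df["evidence"]) - _EVIDENCE
    if bad:
        raise FormatError(f"target map has unknown evidence levels {sorted(bad)}")
    if df.duplicated(["mirna_id", "gene_symbol"]).any():
        raise FormatError("target map has duplicate (mirna, gene) edges")
    return df


def write_target_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["mirna_id", "gene_symbol", "evidence"])


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("sample_id", "group", "target", "ct"):
        if col not in df.columns:
            raise FormatError(f"CT table lacks required column {col!r}")
    if df.duplicated(["sample_id", "target"]).any():
        raise FormatError("CT table has duplicate (sample, target) rows")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g",
              columns=["sample_id", "group", "target", "ct"])


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
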