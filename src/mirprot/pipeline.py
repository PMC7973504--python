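"""End-to-end orchestration of the integrated analysis.

Runs the stages in fixed order — clean / filter / impute / test / tier on
the proteomics side, dedupe / test / tier on the miRNA side, then
inverse-expression pairing and locus summaries — and writes the results
of each stage to a run directory. Every tabular output carries the
config hash and master seed in header comments, and re-running with an
identical config reproduces byte-identical outputs.

Inputs may be files (protein-groups TSV, miRNA matrix TSV, target-map
TSV) or, when a file is not given, synthetic data generated from the
config's simulation parameters, so a demo run needs no external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import io as mio
from . import synthetic
from .containers import ConfigurationError
from .fixtures import list_fixtures  # re-exported; part of the public surface
from .integrate import pair_inverse, summarize_by_locus
from .mirna import LocusMap, annotate_loci, dedupe_probes, locus_fraction, \
    mirna_de_test
from .proteomics import ImputationParams, load_and_clean, \
    protein_table_to_matrix, run_protein_de

__all__ = ["RunConfig", "run_pipeline", "list_fixtures",
           "DOWNSHIFT_BY_COMPARISON"]

#: imputation downshift defaults per comparison
DOWNSHIFT_BY_COMPARISON = {"FAC_vs_UNT": 1.8, "OCV_vs_CV": 1.75}


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    Unknown keys are rejected on load; the effective config (with all
    defaults resolved) is always dumped into the run directory.
    """

    comparison: str = "FAC_vs_UNT"
    seed: int = 0
    out_dir: str = "runs/demo"
    control: str = "UNT"
    treatment: str = "FAC"
    # file inputs; None -> synthetic
    protein_groups_file: Optional[str] = None
    protein_groups: Optional[Dict[str, List[str]]] = None
    mirna_matrix_file: Optional[str] = None
    target_map_file: Optional[str] = None
    # proteomics stage
    min_valid: int = 3
    valid_rule: str = "any"
    width: float = 0.3
    downshift: Optional[float] = None
    # miRNA stage
    use_fdr: bool = False
    # integration stage
    mirna_min_fold: float = 2.0
    protein_min_fold: float = 4.0
    # synthetic-data parameters (used only for inputs not given as files)
    n_features: int = 2000
    de_fraction: float = 0.1
    cv: float = 0.22
    mnar_censor_quantile: float = 0.1

    def __post_init__(self) -> None:
        if self.comparison not in DOWNSHIFT_BY_COMPARISON:
            raise ConfigurationError(
                f"comparison must be one of {sorted(DOWNSHIFT_BY_COMPARISON)}")
        if self.downshift is None:
            self.downshift = DOWNSHIFT_BY_COMPARISON[self.comparison]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sha256(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, seed: int,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"#config_sha256={config_hash}\n#seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _protein_inputs(config: RunConfig):
    if config.protein_groups_file:
        if not config.protein_groups:
            raise ConfigurationError(
                "protein_groups (group -> sample names) is required with "
                "protein_groups_file")
        table, log = load_and_clean(config.protein_groups_file)
        matrix, meta = protein_table_to_matrix(table, config.protein_groups)
        return matrix, meta, None, log
    sim = synthetic.SimConfig(
        n_features=config.n_features, n_per_group=5,
        group_names=(config.control, config.treatment), cv=config.cv,
        de_fraction=config.de_fraction,
        mnar_censor_quantile=config.mnar_censor_quantile,
        seed=config.seed)
    matrix, truth = synthetic.simulate_lfq(sim)
    return matrix, None, truth, {"n_input": config.n_features,
                                 "n_retained": config.n_features}


def _mirna_inputs(config: RunConfig):
    if config.mirna_matrix_file:
        return mio.read_matrix_tsv(config.mirna_matrix_file), None
    sim = synthetic.SimConfig(
        n_features=max(200, config.n_features // 10), n_per_group=3,
        group_names=(config.control, config.treatment), cv=config.cv,
        de_fraction=config.de_fraction, seed=config.seed + 1)
    return synthetic.simulate_mirna(sim)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage errors propagate with the stage name prepended. Outputs:
    protein_de.tsv, mirna_de.tsv, paired_hits.tsv, locus_summary.tsv,
    run.log, plus the effective config dump.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.sha256()
    log_lines = [f"config_sha256={chash}", f"seed={config.seed}",
                 f"comparison={config.comparison}"]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # proteomics -----------------------------------------------------------
    prot_matrix, meta, prot_truth, clean_log = stage(
        "load_and_clean", _protein_inputs, config)
    log_lines.append(f"proteins_in={clean_log['n_input']} "
                     f"proteins_clean={clean_log['n_retained']}")
    params = ImputationParams(width=config.width, downshift=config.downshift,
                              seed=config.seed + 2)
    prot_de = stage("protein_de", run_protein_de, prot_matrix,
                    control=config.control, treatment=config.treatment,
                    params=params, min_valid=config.min_valid,
                    valid_rule=config.valid_rule, meta=meta)
    log_lines.append(f"proteins_tested={len(prot_de)} "
                     f"significant={(prot_de['tier'] != 'not_significant').sum()} "
                     f"differential={prot_de['tier'].isin(['differential', 'top']).sum()} "
                     f"top={(prot_de['tier'] == 'top').sum()}")
    _write_tsv(prot_de, out / "protein_de.tsv", chash, config.seed)

    # miRNA ------------------------------------------------------------------
    mirna_matrix, mirna_truth = stage("mirna_inputs", _mirna_inputs, config)
    mirna_matrix, n_dup = stage("dedupe_probes", dedupe_probes, mirna_matrix)
    log_lines.append(f"mirna_features={len(mirna_matrix.data)} "
                     f"duplicate_ids_collapsed={n_dup}")
    mirna_de = stage("mirna_de", mirna_de_test, mirna_matrix,
                     control=config.control, treatment=config.treatment,
                     use_fdr=config.use_fdr)
    locus_map = LocusMap.from_fixtures()
    mirna_de = annotate_loci(mirna_de, locus_map)
    log_lines.append(f"mirna_twofold={(mirna_de['tier'] != 'none').sum()} "
                     f"mirna_fourfold={(mirna_de['tier'] == 'fourfold').sum()}")
    _write_tsv(mirna_de, out / "mirna_de.tsv", chash, config.seed)

    # integration --------------------------------------------------------------
    if config.target_map_file:
        target_map = mio.read_target_map(config.target_map_file)
    elif prot_truth is not None and mirna_truth is not None:
        feasible = min(
            20,
            (mirna_truth["true_log2fc"] > 0).sum() * (prot_truth["true_log2fc"] < 0).sum()
            + (mirna_truth["true_log2fc"] < 0).sum() * (prot_truth["true_log2fc"] > 0).sum())
        target_map = synthetic.simulate_target_map(
            mirna_truth, prot_truth, planted_pairs=int(feasible),
            decoy_pairs=50, seed=config.seed + 3)
    else:
        raise ConfigurationError("target_map_file is required with file inputs")

    prot_for_pairing = prot_de.reset_index().rename(
        columns={"protein_id": "gene_name"} if meta is None else {})
    selected_mirnas = mirna_de[mirna_de["tier"] != "none"].reset_index()
    hits = stage("pair_inverse", pair_inverse, selected_mirnas,
                 prot_for_pairing, target_map,
                 mirna_min_fold=config.mirna_min_fold,
                 protein_min_fold=config.protein_min_fold)
    log_lines.append(f"paired_hits={len(hits)}")
    _write_tsv(hits, out / "paired_hits.tsv", chash, config.seed, index=False)

    # locus summary -------------------------------------------------------------
    summary = summarize_by_locus(hits, locus_map)
    n_at, n_tot, pct = locus_fraction(selected_mirnas, "14q32")
    log_lines.append(f"mirnas_at_14q32={n_at}/{n_tot} percent={pct}")
    _write_tsv(summary, out / "locus_summary.tsv", chash, config.seed,
               index=False)

    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
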