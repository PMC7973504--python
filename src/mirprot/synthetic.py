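"""Synthetic data generators with ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so the whole workflow is
exercisable without any external download:

* log-normal LFQ intensity matrices (two groups, default 5 replicates,
  ~20-25% within-group CV) with intensity-dependent (MNAR) missingness,
* miRNA array matrices (default 3 replicates, no missingness),
* miRNA->gene target maps with planted inverse-regulation pairs,
* qPCR CT tables following the reference-normalized doubling model,
* promoter sequences with a motif planted at a known offset.

Each generator also returns (or accepts) ground-truth labels so that
parameter-recovery tests can score the downstream analysis.

Randomness: one master seed per config; independent per-stage substreams
are spawned from it with :class:`numpy.random.SeedSequence`, so the same
config is bit-reproducible and stages can be re-run independently.

The within-group log2 sd is derived from the coefficient of variation by
the exact log-normal relation ``sd_log2 = sqrt(ln(1 + cv^2)) / ln 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ConfigurationError, IntensityMatrix

__all__ = [
    "SimConfig",
    "log2_sd_from_cv",
    "simulate_lfq",
    "simulate_mirna",
    "simulate_target_map",
    "simulate_ct_table",
    "simulate_promoter",
    "mnar_missing_probability",
]

_DNA = np.array(list("ACGT"))


def log2_sd_from_cv(cv: float) -> float:
    """Within-group log2 sd implied by a log-normal CV (exact relation)."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


@dataclass
class SimConfig:
    """Parameters of a two-group expression simulation.

    ``n_per_group`` defaults to the proteomics design (5 replicates per
    group); use 3 for the array design. ``cv`` is the within-group
    coefficient of variation on the raw scale (fraction). A fraction
    ``de_fraction`` of features receives a true log2 effect drawn
    uniformly in magnitude from ``log2fc_range`` with random sign.
    Missingness risk is logistic in the true log2 intensity, anchored at
    the ``mnar_censor_quantile`` of the intensity distribution with slope
    ``mnar_steepness``; a quantile of 0 disables missingness.
    """

    n_features: int = 2000
    n_per_group: int = 5
    group_names: Tuple[str, str] = ("UNT", "FAC")
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    cv: float = 0.22
    de_fraction: float = 0.0
    log2fc_range: Tuple[float, float] = (1.0, 7.0)
    mnar_censor_quantile: float = 0.0
    mnar_steepness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ConfigurationError("cv must be positive")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.mnar_censor_quantile < 1.0:
            raise ConfigurationError("mnar_censor_quantile must lie in [0, 1)")
        if len(self.group_names) != 2:
            raise ConfigurationError("exactly two group names are required")

    @property
    def sd_log2(self) -> float:
        return log2_sd_from_cv(self.cv)


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def mnar_missing_probability(log2_intensity, anchor: float, steepness: float):
    """Logistic probability of a value being missing, decreasing in intensity."""
    return expit(-(np.asarray(log2_intensity, dtype=float) - anchor) * steepness)


def _simulate_matrix(config: SimConfig, prefix: str, with_missing: bool
                     ) -> Tuple[IntensityMatrix, pd.DataFrame]:
    rng_base, rng_fx, rng_noise, rng_miss = _spawn(config.seed, 4)
    n, k = config.n_features, config.n_per_group
    g1, g2 = config.group_names

    feature_ids = [f"{prefix}{i:05d}" for i in range(n)]
    mu = rng_base.normal(config.base_log2_mean, config.base_log2_sd, size=n)

    n_changed = int(round(config.de_fraction * n))
    changed_idx = rng_fx.choice(n, size=n_changed, replace=False)
    true_fc = np.zeros(n)
    lo, hi = config.log2fc_range
    mag = rng_fx.uniform(lo, hi, size=n_changed)
    sign = rng_fx.choice([-1.0, 1.0], size=n_changed)
    true_fc[changed_idx] = mag * sign

    sd = config.sd_log2
    a = mu[:, None] + rng_noise.normal(0.0, sd, size=(n, k))
    b = (mu + true_fc)[:, None] + rng_noise.normal(0.0, sd, size=(n, k))
    log2x = np.hstack([a, b])

    if with_missing and config.mnar_censor_quantile > 0:
        anchor = np.quantile(log2x, config.mnar_censor_quantile)
        p_miss = mnar_missing_probability(log2x, anchor, config.mnar_steepness)
        miss = rng_miss.random(log2x.shape) < p_miss
    else:
        miss = np.zeros_like(log2x, dtype=bool)

    raw = np.power(2.0, log2x)
    raw[miss] = np.nan

    cols = [f"{g1}_{i + 1}" for i in range(k)] + [f"{g2}_{i + 1}" for i in range(k)]
    data = pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"),
                        columns=cols)
    groups = {g1: cols[:k], g2: cols[k:]}
    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "is_changed": true_fc != 0.0,
        "true_log2fc": true_fc,
    })
    return IntensityMatrix(data=data, groups=groups), truth


def simulate_lfq(config: SimConfig) -> Tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate a raw-scale LFQ protein matrix with MNAR missingness.

    Returns the intensity matrix and a ground-truth table with one row
    per feature (``feature_id``, ``is_changed``, ``true_log2fc``; the
    effect applies to the second group relative to the first).
    """
    return _simulate_matrix(config, "PROT", with_missing=True)


def simulate_mirna(config: SimConfig) -> Tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate a complete (no missingness) miRNA array matrix.

    The array design uses 3 replicates per group; pass a config with
    ``n_per_group=3`` to emulate it (the default config carries the
    proteomics 5).
    """
    return _simulate_matrix(config, "MIR", with_missing=False)


def simulate_target_map(mirna_truth: pd.DataFrame, prot_truth: pd.DataFrame,
                        planted_pairs: int, decoy_pairs: int, seed: int = 0
                        ) -> pd.DataFrame:
    """Build a miRNA->gene target map with planted inverse pairs.

    Planted edges connect a truly changed miRNA and a truly changed
    protein of opposite direction (the signal the inverse-expression
    pairing should recover); decoys are uniform random other edges.
    Returns a DataFrame with columns ``mirna_id``, ``gene_symbol``,
    ``evidence`` plus a boolean ``planted`` column for recovery tests.
    """
    rng = np.random.default_rng(seed)
    m_up = mirna_truth.loc[mirna_truth["true_log2fc"] > 0, "feature_id"].to_numpy()
    m_dn = mirna_truth.loc[mirna_truth["true_log2fc"] < 0, "feature_id"].to_numpy()
    p_up = prot_truth.loc[prot_truth["true_log2fc"] > 0, "feature_id"].to_numpy()
    p_dn = prot_truth.loc[prot_truth["true_log2fc"] < 0, "feature_id"].to_numpy()

    inverse = [(m, p) for m in m_up for p in p_dn] + \
              [(m, p) for m in m_dn for p in p_up]
    if planted_pairs > len(inverse):
        raise ConfigurationError(
            f"requested {planted_pairs} planted pairs but only "
            f"{len(inverse)} opposite-direction combinations exist")
    idx = rng.choice(len(inverse), size=planted_pairs, replace=False) \
        if planted_pairs else np.array([], dtype=int)
    planted = [inverse[i] for i in idx]

    all_m = mirna_truth["feature_id"].to_numpy()
    all_p = prot_truth["feature_id"].to_numpy()
    taken = set(planted)
    decoys = []
    while len(decoys) < decoy_pairs:
        edge = (rng.choice(all_m), rng.choice(all_p))
        if edge not in taken:
            taken.add(edge)
            decoys.append(edge)

    levels = np.array(["experimental", "high", "moderate"])
    edges = planted + decoys
    return pd.DataFrame({
        "mirna_id": [e[0] for e in edges],
        "gene_symbol": [e[1] for e in edges],
        "evidence": rng.choice(levels, size=len(edges)),
        "planted": [True] * len(planted) + [False] * len(decoys),
    })


def simulate_ct_table(groups: Mapping[str, int],
                      true_fold_changes: Mapping[str, Mapping[str, float]],
                      reference_ct: float = 20.0, noise_sd: float = 0.0,
                      seed: int = 0, reference_name: str = "RNU6B",
                      base_delta_ct: float = 5.0) -> pd.DataFrame:
    """Simulate a qPCR CT table under the doubling-per-cycle model.

    ``groups`` maps group name to replicate count; ``true_fold_changes``
    maps target name to ``{group: fold}`` relative to whichever group is
    used as the calibrator downstream (a group absent from the inner
    mapping has fold 1). Target CT for a sample is its reference CT plus
    a fixed assay offset minus log2(fold), plus Gaussian cycle noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in groups.items():
        for i in range(n):
            sample = f"{group}_{i + 1}"
            ref = reference_ct + rng.normal(0.0, noise_sd) if noise_sd else reference_ct
            rows.append({"sample_id": sample, "group": group,
                         "target": reference_name, "ct": ref})
            for target, folds in true_fold_changes.items():
                fold = folds.get(group, 1.0)
                if fold <= 0:
                    raise ConfigurationError("fold changes must be positive")
                noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                ct = ref + base_delta_ct - math.log2(fold) + noise
                rows.append({"sample_id": sample, "group": group,
                             "target": target, "ct": ct})
    return pd.DataFrame(rows)


def simulate_promoter(length: int, motif: str, plant_position: int,
                      n_mismatches: int = 0, seed: int = 0) -> str:
    """Uniform-random promoter sequence with a (mutated) motif planted.

    Exactly ``n_mismatches`` distinct motif positions are mutated to a
    different base before planting at ``plant_position`` (0-based).
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ConfigurationError("motif must be over the ACGT alphabet")
    if length < len(motif):
        raise ConfigurationError("sequence length is shorter than the motif")
    if not 0 <= plant_position <= length - len(motif):
        raise ConfigurationError("plant_position does not fit in the sequence")
    if not 0 <= n_mismatches <= len(motif):
        raise ConfigurationError("n_mismatches must lie in [0, motif length]")

    rng = np.random.default_rng(seed)
    seq = rng.choice(_DNA, size=length)
    planted = np.array(list(motif))
    mut_pos = rng.choice(len(motif), size=n_mismatches, replace=False)
    for j in mut_pos:
        choices = [b for b in "ACGT" if b != planted[j]]
        planted[j] = rng.choice(choices)
    seq[plant_position:plant_position + len(motif)] = planted
    return "".join(seq)
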