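import numpy as np
import pandas as pd
import pytest

from mirprot.containers import IntensityMatrix


@pytest.fixture
def toy_protein_groups(tmp_path):
    """10-row protein-groups TSV: 2 reverse, 1 contaminant, 1 site-only."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(10):
        rows.append({
            "Protein IDs": f"P{i:03d}",
            "Gene names": f"GENE{i}",
            "Reverse": "+" if i in (0, 1) else "",
            "Potential contaminant": "+" if i == 2 else "",
            "Only identified by site": "+" if i == 3 else "",
            **{f"LFQ intensity {g}_{j}": float(rng.uniform(1e6, 1e8))
               for g in ("UNT", "FAC") for j in range(1, 6)},
        })
    path = tmp_path / "proteinGroups.txt"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def make_matrix(values, group_sizes=(5, 5), names=("UNT", "FAC"),
                log2_scale=False):
    """Small IntensityMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    cols = [f"{names[0]}_{i+1}" for i in range(group_sizes[0])] + \
           [f"{names[1]}_{i+1}" for i in range(group_sizes[1])]
    data = pd.DataFrame(values, columns=cols,
                        index=pd.Index([f"F{i}" for i in range(len(values))],
                                       name="feature_id"))
    groups = {names[0]: cols[:group_sizes[0]], names[1]: cols[group_sizes[0]:]}
    return IntensityMatrix(data=data, groups=groups, log2_scale=log2_scale)
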