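"""Alpha diversity per sample and non-parametric between-state tests.

Richness is observed taxa on (rarefied) counts; Shannon is -sum p ln p in
nats; "Simpson" is the Gini-Simpson index 1 - sum p^2 (bounded [0, 1];
an inverse-Simpson variant is available via ``simpson="inverse"``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CommunityMatrix, TaxonTable


def alpha_diversity(data: TaxonTable | CommunityMatrix,
                    simpson: str = "gini") -> pd.DataFrame:
    """Per-sample richness, Shannon and Simpson indices.

    Accepts a (preferably rarefied) count table, in which case richness is the
    number of taxa with a nonzero count, or a closed relative-abundance
    matrix, where richness counts taxa with p > 0.
    """
    if isinstance(data, TaxonTable):
        counts = data.counts.to_numpy(dtype=float)
        p = counts / counts.sum(axis=1, keepdims=True)
        richness = (counts > 0).sum(axis=1)
        index = data.counts.index
    else:
        p = data.rel.to_numpy(dtype=float)
        if not data.closed:
            p = p / p.sum(axis=1, keepdims=True)
        richness = (p > 0).sum(axis=1)
        index = data.rel.index
    if p.size == 0:
        raise ValueError("empty community matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    sum_p2 = (p**2).sum(axis=1)
    if simpson == "gini":
        simp = 1.0 - sum_p2
    elif simpson == "inverse":
        simp = 1.0 / sum_p2
    else:
        raise ValueError("simpson must be 'gini' or 'inverse'")
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon, "simpson": simp},
        index=index,
    )


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected midranks) and chi-square p-value.

    Returns (0, 1) when all observations are identical (zero rank variance).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def compare_states(alpha: pd.DataFrame, labels) -> pd.DataFrame:
    """Kruskal-Wallis test of each alpha index between state labels."""
    rows = []
    for col in alpha.columns:
        h, p = kruskal_wallis(alpha[col].to_numpy(), labels)
        rows.append({"index": col, "H": h, "p": p})
    return pd.DataFrame(rows).set_index("index")
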