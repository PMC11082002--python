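"""Community tables and chronologies: I/O, rarefaction, collapsing, selection.

The central containers are :class:`TaxonTable` (integer counts per taxon per
stratigraphically ordered sample, plus a calibrated age per sample) and
:class:`CommunityMatrix` (relative abundances).  Samples are kept oldest-first
internally so that sample order and calendar age ascend together.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import write_tsv

#: Rank-prefixed, semicolon-delimited taxonomy dialect (QIIME/greengenes style).
RANK_PREFIXES = {
    "kingdom": "k__", "phylum": "p__", "class": "c__", "order": "o__",
    "family": "f__", "genus": "g__", "species": "s__",
}
UNCLASSIFIED = "unclassified"


@dataclass
class TaxonTable:
    """Counts per taxon per sample with a calibrated chronology.

    Parameters
    ----------
    counts:
        samples x taxa integer DataFrame; index = sample ids (stratigraphic
        order, oldest first), columns = taxon ids.
    ages:
        Calibrated calendar age (years CE) per sample, aligned to
        ``counts.index`` and strictly increasing.
    taxonomy:
        Optional rank-delimited taxonomy string per taxon.
    depths:
        Optional core depth (cm) per sample.
    """

    counts: pd.DataFrame
    ages: pd.Series
    taxonomy: pd.Series | None = None
    depths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[bad[0]]!r}, "
                f"taxon {self.counts.columns[bad[1]]!r}"
            )
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate taxon ids")
        missing = self.counts.index.difference(self.ages.index)
        if len(missing):
            raise ValueError(f"missing age for sample(s): {list(missing)}")
        self.ages = self.ages.loc[self.counts.index].astype(float)
        age = self.ages.to_numpy()
        if not np.all(np.diff(age) > 0):
            order = np.argsort(age, kind="stable")
            if not np.all(np.diff(age[order]) > 0):
                raise ValueError("chronology is not strictly monotonic (tied ages)")
            warnings.warn("sample order disagrees with age order; re-sorting by age")
            self.counts = self.counts.iloc[order]
            self.ages = self.ages.iloc[order]
            if self.depths is not None:
                self.depths = self.depths.loc[self.counts.index]
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class CommunityMatrix:
    """Relative-abundance matrix (samples x taxa) with chronology.

    ``closed=True`` means rows were normalized to sum to 1 over these taxa;
    ``closed=False`` means abundances are relative to the full sample total
    (rows sum to <= 1), which is what the gLV fit consumes.
    """

    rel: pd.DataFrame
    ages: pd.Series
    closed: bool = True
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.rel.to_numpy(dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-9).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        rows = arr.sum(axis=1)
        if self.closed and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("closed matrix rows must sum to 1")
        if not self.closed and (rows > 1 + 1e-9).any():
            raise ValueError("row sums exceed 1 in an unclosed matrix")
        self.ages = self.ages.loc[self.rel.index].astype(float)

    @property
    def S(self) -> int:
        return self.rel.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel.columns)


# ---------------------------------------------------------------------------
# I/O


def read_chronology(path) -> pd.DataFrame:
    """Read a 3-column TSV (sample_id, depth_cm, age_year_ce)."""
    chron = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                        float_precision="round_trip")
    chron.columns = [c.strip().lower() for c in chron.columns]
    required = {"sample_id", "age_year_ce"}
    if not required.issubset(chron.columns):
        raise ValueError(f"chronology must have columns {sorted(required)}")
    return chron.set_index("sample_id")


def read_taxon_table(path, chronology_path) -> TaxonTable:
    """Read a taxon table (TSV, taxa as rows; or BIOM-style sparse JSON) plus chronology.

    TSV layout: first column taxon id, one column per sample, optional final
    ``taxonomy`` column.  Counts must be non-negative integers; every sample
    must have a calibrated age in the chronology file.
    """
    with open(path, encoding="utf-8") as fh:
        head = fh.read(1)
    if head == "{":
        counts, taxonomy = _read_biom_json(path)
    else:
        counts, taxonomy = _read_tsv_table(path)
    chron = read_chronology(chronology_path)
    missing = counts.index.difference(chron.index)
    if len(missing):
        raise ValueError(f"missing age for sample(s): {list(missing)}")
    ages = chron.loc[counts.index, "age_year_ce"].astype(float)
    depths = (chron.loc[counts.index, "depth_cm"].astype(float)
              if "depth_cm" in chron.columns else None)
    return TaxonTable(counts=counts, ages=ages, taxonomy=taxonomy, depths=depths)


def _read_tsv_table(path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy")
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    arr = numeric.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        bad = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"invalid count at taxon {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    counts = numeric.astype(np.int64).T  # -> samples x taxa
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns.name = None
    return counts, taxonomy


def _read_biom_json(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Minimal BIOM 1.0 (sparse or dense JSON) reader."""
    with open(path, encoding="utf-8") as fh:
        biom = json.load(fh)
    taxa = [row["id"] for row in biom["rows"]]
    samples = [col["id"] for col in biom["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if biom.get("matrix_type", "sparse") == "sparse":
        for i, j, v in biom["data"]:
            mat[i, j] = v
    else:
        mat = np.asarray(biom["data"], dtype=float)
    taxonomy = None
    if biom["rows"] and (biom["rows"][0].get("metadata") or {}).get("taxonomy"):
        taxonomy = pd.Series(
            {row["id"]: ";".join(row["metadata"]["taxonomy"]) for row in biom["rows"]}
        )
    counts = pd.DataFrame(mat, index=taxa, columns=samples)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative count in BIOM table")
    return counts.astype(np.int64).T, taxonomy


def write_taxon_table(table: TaxonTable, path, chronology_path=None,
                      command: str = "write_taxon_table", seed: int | None = None) -> None:
    """Write a TaxonTable as TSV (taxa as rows) with a provenance header."""
    out = table.counts.T.copy()
    out.index.name = "taxon_id"
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    write_tsv(out, path, command, seed)
    if chronology_path is not None:
        chron = pd.DataFrame({
            "sample_id": table.sample_ids,
            "depth_cm": (table.depths.to_numpy() if table.depths is not None
                         else np.arange(table.n_samples, dtype=float)),
            "age_year_ce": table.ages.to_numpy(),
        })
        write_tsv(chron, chronology_path, command, seed, index=False)


# ---------------------------------------------------------------------------
# Transformations


def rarefy(table: TaxonTable, depth: int | None = None, seed: int = 0) -> TaxonTable:
    """Subsample each sample to equal depth without replacement.

    Draws are multivariate hypergeometric per sample, the variance-correct
    reading of "rarefied to the minimum number of reads".  ``depth`` defaults
    to the minimum sample total.
    """
    totals = table.totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(f"depth {depth} exceeds totals of samples: {list(shallow.index)}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for k, row in enumerate(table.counts.to_numpy()):
        out[k] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return replace(table, counts=counts)


def to_relative(table: TaxonTable) -> CommunityMatrix:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    totals = table.totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    rel = table.counts.div(totals, axis=0)
    return CommunityMatrix(rel=rel, ages=table.ages.copy(), closed=True)


def _rank_label(tax_string: str | float, rank: str) -> str:
    prefix = RANK_PREFIXES[rank]
    if not isinstance(tax_string, str):
        return UNCLASSIFIED
    for part in tax_string.split(";"):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return name if name else UNCLASSIFIED
    return UNCLASSIFIED


def collapse_taxonomy(table: TaxonTable, rank: str = "class") -> TaxonTable:
    """Sum taxa sharing the same label at ``rank``; pool unlabeled taxa as 'unclassified'.

    Per-sample totals are conserved exactly.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}; choose from {sorted(RANK_PREFIXES)}")
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy strings")
    labels = table.taxonomy.map(lambda s: _rank_label(s, rank))
    if (labels == UNCLASSIFIED).all():
        raise ValueError(f"no taxon is classified at rank {rank!r}")
    collapsed = table.counts.T.groupby(labels, sort=False).sum().T
    # keep unclassified as the last column
    if UNCLASSIFIED in collapsed.columns:
        cols = [c for c in collapsed.columns if c != UNCLASSIFIED] + [UNCLASSIFIED]
        collapsed = collapsed[cols]
    return replace(table, counts=collapsed, taxonomy=None)


def select_modeled_taxa(matrix: CommunityMatrix, min_mean_abund: float = 0.01,
                        max_taxa: int = 12, renormalize: bool = True,
                        exclude: tuple[str, ...] = (UNCLASSIFIED,)) -> CommunityMatrix:
    """Retain abundant taxa for modeling.

    Keeps taxa whose mean relative abundance is >= ``min_mean_abund``, capped
    at the ``max_taxa`` most abundant.  With ``renormalize=True`` rows are
    re-closed to sum to 1 over the retained set (for ordination); with
    ``renormalize=False`` abundances stay relative to the full sample total,
    which keeps the gLV regression identifiable (the retained columns no
    longer sum to a constant).
    """
    if not 0 <= min_mean_abund < 1:
        raise ValueError("min_mean_abund must be in [0, 1)")
    rel = matrix.rel.drop(columns=[c for c in exclude if c in matrix.rel.columns])
    means = rel.mean(axis=0)
    kept = means[means >= min_mean_abund].sort_values(ascending=False).index[:max_taxa]
    kept = [c for c in rel.columns if c in set(kept)]  # preserve original order
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} taxa pass selection; gLV needs at least 2")
    sub = rel[kept]
    if renormalize:
        sub = sub.div(sub.sum(axis=1), axis=0)
    prov = matrix.provenance + [
        f"select_modeled_taxa: min_mean_abund={min_mean_abund}, max_taxa={max_taxa}, "
        f"renormalize={renormalize}, kept={len(kept)}/{matrix.S}"
    ]
    return CommunityMatrix(rel=sub, ages=matrix.ages.copy(), closed=renormalize,
                           provenance=prov)
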