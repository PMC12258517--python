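"""Reading, validating, filtering, merging and classifying DE tables.

The central container is :class:`DETable`, a thin validated wrapper around a
pandas DataFrame with one row per gene and columns ``gene``, ``log2fc``,
``padj`` and (optionally) ``base_mean``.  Fold changes are always oriented
wild-type over knockout, so a positive ``log2fc`` means the perturbed factor
upregulates the gene.  Missing ``padj`` marks a gene as never significant but
keeps it available for rank statistics as long as ``log2fc`` is present;
rows missing ``log2fc`` too are excluded from every downstream statistic.

Gene-id matching throughout is exact and case-sensitive: these analyses merge
symbol tables drawn from a single annotation, and silent case-folding risks
false joins.  ``normalize_gene_ids`` is the opt-in hook for callers who do
need folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: default column names expected in a DE-table TSV
DEFAULT_DE_COLUMNS: Mapping[str, str] = {
    "gene": "gene",
    "log2fc": "log2fc",
    "padj": "padj",
    "base_mean": "base_mean",
}


@dataclass(frozen=True)
class DETable:
    """One differential-expression result table (one row per gene)."""

    data: pd.DataFrame
    label: str = "DE"

    def __post_init__(self) -> None:
        df = self.data
        required = {"gene", "log2fc", "padj"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"DE table missing required column(s): {sorted(missing)}")
        if df["gene"].isna().any() or (df["gene"].astype(str).str.len() == 0).any():
            raise DataError("DE table contains empty gene ids")
        dup = df["gene"][df["gene"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate gene ids in DE table: {sorted(set(dup))[:10]}")
        padj = df["padj"].to_numpy(dtype=float)
        bad = padj[~np.isnan(padj)]
        if ((bad < 0) | (bad > 1)).any():
            raise DataError("padj values outside [0, 1]")
        if "base_mean" in df.columns:
            bm = df["base_mean"].to_numpy(dtype=float)
            if (bm[~np.isnan(bm)] < 0).any():
                raise DataError("base_mean values must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene"])

    def usable(self) -> pd.DataFrame:
        """Rows with a finite log2fc — the universe for rank statistics."""
        return self.data[np.isfinite(self.data["log2fc"].to_numpy(dtype=float))]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of TPM values."""

    tpm: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        arr = self.tpm.to_numpy(dtype=float)
        if (arr < 0).any():
            raise DataError("TPM matrix contains negative entries")
        if self.tpm.index.duplicated().any():
            raise DataError("TPM matrix contains duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass(frozen=True)
class MergedTable:
    """Inner join of two DE tables on exact gene id.

    Columns: ``gene``, ``log2fc_<A>``, ``padj_<A>``, ``log2fc_<B>``,
    ``padj_<B>`` where A and B are the dataset labels.
    """

    data: pd.DataFrame
    label_a: str
    label_b: str

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene"])

    def log2fc(self, label: str) -> pd.Series:
        if label not in (self.label_a, self.label_b):
            raise ParameterError(f"unknown dataset label {label!r}")
        return self.data.set_index("gene")[f"log2fc_{label}"]

    def padj(self, label: str) -> pd.Series:
        if label not in (self.label_a, self.label_b):
            raise ParameterError(f"unknown dataset label {label!r}")
        return self.data.set_index("gene")[f"padj_{label}"]


@dataclass
class GeneSetCollection:
    """Named gene sets (cell-cycle phases, curated regulators, annotations)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise DataError("gene set with empty name")
            if any((not isinstance(g, str)) or not g for g in members):
                raise DataError(f"gene set {name!r} has empty member ids")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Read GMT: name <tab> description <tab> member1 <tab> member2 ..."""
        sets: dict[str, set[str]] = {}
        meta: dict[str, dict] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {parts[0]!r}")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise DataError(f"duplicate gene-set name {name!r}")
            sets[name] = set(members)
            meta[name] = {"description": desc}
        return cls(sets, meta)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneSetCollection":
        """Read two-column TSV: set_name <tab> gene (one membership per line)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"], dtype=str)
        sets = {name: set(sub["gene"]) for name, sub in df.groupby("set", sort=False)}
        return cls(sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.metadata.get(name, {}).get("description", "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {name: members & uni for name, members in self.sets.items()},
            dict(self.metadata),
        )


def normalize_gene_ids(table: DETable, how: str = "upper") -> DETable:
    """Opt-in id normalization hook (off by default everywhere).

    ``how`` is ``upper``, ``lower`` or ``capitalize``; collisions created by
    folding raise :class:`DataError` rather than merging silently.
    """
    folders = {"upper": str.upper, "lower": str.lower, "capitalize": str.capitalize}
    if how not in folders:
        raise ParameterError(f"unknown normalization {how!r}")
    df = table.data.copy()
    df["gene"] = df["gene"].map(folders[how])
    return DETable(df.reset_index(drop=True), label=table.label)


def read_de_table(
    path: str | Path,
    label: str | None = None,
    columns: Mapping[str, str] | None = None,
    orientation: str = "wt_over_ko",
    sep: str = "\t",
) -> DETable:
    """Read a DE-result TSV into a validated :class:`DETable`.

    Parameters
    ----------
    columns
        Maps canonical names (``gene``, ``log2fc``, ``padj``, ``base_mean``)
        to the file's header names.
    orientation
        ``wt_over_ko`` (native) or ``ko_over_wt`` (log2fc negated on load so
        the in-memory convention is always WT/KO).
    """
    if orientation not in ("wt_over_ko", "ko_over_wt"):
        raise ParameterError(f"orientation must be wt_over_ko or ko_over_wt, got {orientation!r}")
    colmap = dict(DEFAULT_DE_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep=sep)
    for canon in ("gene", "log2fc", "padj"):
        if colmap[canon] not in raw.columns:
            raise FormatError(f"missing required column {colmap[canon]!r} (for {canon})")
    out = pd.DataFrame({"gene": raw[colmap["gene"]].astype(str)})
    out["log2fc"] = pd.to_numeric(raw[colmap["log2fc"]], errors="coerce")
    out["padj"] = pd.to_numeric(raw[colmap["padj"]], errors="coerce")
    if colmap["base_mean"] in raw.columns:
        out["base_mean"] = pd.to_numeric(raw[colmap["base_mean"]], errors="coerce")
    if orientation == "ko_over_wt":
        out["log2fc"] = -out["log2fc"]
    n_missing = int(out["log2fc"].isna().sum())
    logger.info(
        "read_de_table %s: %d rows, %d with missing log2fc (kept, excluded from stats)",
        path, len(out), n_missing,
    )
    return DETable(out, label=label or Path(path).stem)


def write_de_table(table: DETable, path: str | Path) -> None:
    cols = [c for c in ("gene", "log2fc", "padj", "base_mean") if c in table.data.columns]
    table.data[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tpm_matrix(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples TPM TSV; first column is the gene id."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    logger.info("read_tpm_matrix %s: %d genes x %d samples", path, *df.shape)
    return ExpressionMatrix(df)


def filter_expressed(
    matrix: ExpressionMatrix, min_tpm: float = 1.0, min_samples: int = 3
) -> set[str]:
    """Genes with TPM >= ``min_tpm`` in at least ``min_samples`` samples.

    The thresholds are inclusive (a gene at exactly ``min_tpm`` in exactly
    ``min_samples`` samples is retained).
    """
    n_samples = len(matrix.samples)
    if min_samples > n_samples:
        raise ParameterError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    if min_samples < 0:
        raise ParameterError("min_samples must be non-negative")
    counts = (matrix.tpm.to_numpy(dtype=float) >= min_tpm).sum(axis=1)
    kept = {g for g, c in zip(matrix.genes, counts) if c >= min_samples}
    logger.info(
        "filter_expressed: %d of %d genes pass TPM>=%g in >=%d samples",
        len(kept), len(matrix.genes), min_tpm, min_samples,
    )
    return kept


def merge_by_gene(
    table_a: DETable, table_b: DETable, labels: tuple[str, str] | None = None
) -> MergedTable:
    """Inner-join two DE tables on exact gene-id equality.

    Genes present in only one table are dropped; the count is logged because
    silent attrition here is the main reproducibility hazard of the pipeline.
    """
    label_a, label_b = labels or (table_a.label, table_b.label)
    if label_a == label_b:
        raise ParameterError("dataset labels must differ for merging")
    a = table_a.data[["gene", "log2fc", "padj"]].rename(
        columns={"log2fc": f"log2fc_{label_a}", "padj": f"padj_{label_a}"}
    )
    b = table_b.data[["gene", "log2fc", "padj"]].rename(
        columns={"log2fc": f"log2fc_{label_b}", "padj": f"padj_{label_b}"}
    )
    merged = a.merge(b, on="gene", how="inner", validate="one_to_one")
    dropped = (len(table_a) - len(merged)) + (len(table_b) - len(merged))
    if merged.empty:
        raise DataError(
            f"merge of {label_a!r} and {label_b!r}: zero genes in common"
        )
    logger.info(
        "merge_by_gene %s/%s: %d shared genes, %d table rows dropped",
        label_a, label_b, len(merged), dropped,
    )
    return MergedTable(merged.reset_index(drop=True), label_a, label_b)


def classify_regulated(
    table: DETable,
    direction: str,
    alpha: float = 0.05,
    lfc_threshold: float = 0.0,
) -> set[str]:
    """Genes significantly up- or down-regulated by the perturbed factor.

    ``up``:   log2fc > lfc_threshold  and padj < alpha
    ``down``: log2fc < -lfc_threshold and padj < alpha

    All comparisons are strict, matching the definitions these analyses use
    (a gene at padj exactly alpha, or log2fc exactly at the threshold, is
    excluded).  Genes with missing padj are never significant.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if lfc_threshold < 0:
        raise ParameterError(f"lfc_threshold must be >= 0, got {lfc_threshold}")
    df = table.data
    lfc = df["log2fc"].to_numpy(dtype=float)
    padj = df["padj"].to_numpy(dtype=float)
    sig = np.isfinite(padj) & (padj < alpha) & np.isfinite(lfc)
    if direction == "up":
        mask = sig & (lfc > lfc_threshold)
    else:
        mask = sig & (lfc < -lfc_threshold)
    return set(df.loc[mask, "gene"])
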