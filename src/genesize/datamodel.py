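"""Core tables, SNP-to-gene assignment, and TSV exchange formats.

Tables are plain pandas DataFrames validated on read:

* SNP table: columns ``snp_id, chrom, pos, pvalue`` (``NA`` = missing p).
* Gene table: columns ``gene_id, chrom, start, end, sets`` where ``sets`` is
  a comma-separated list of set labels (e.g. GO ids), possibly empty.

Coordinates are 1-based closed intervals, the dbSNP/annotation convention;
a BED3+1 reader (0-based half-open) converts on input.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "pvalue"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "sets"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GeneSnpMap:
    """Per-gene ordered lists of SNP row indices.

    ``mapping`` maps gene_id -> integer indices into the SNP table the map
    was built from, sorted by SNP position.  Genes with no assigned SNP are
    retained with an empty list; :meth:`tested_genes` excludes them.
    """

    mapping: dict[str, np.ndarray]
    flank_bp: int = 0

    def counts(self) -> pd.Series:
        """Number of SNPs per gene (the gene 'size' M used throughout)."""
        return pd.Series(
            {g: len(idx) for g, idx in self.mapping.items()}, dtype=int, name="M"
        )

    def tested_genes(self) -> list[str]:
        return [g for g, idx in self.mapping.items() if len(idx) > 0]

    def empty_genes(self) -> list[str]:
        return [g for g, idx in self.mapping.items() if len(idx) == 0]

    def write(self, path, snp_ids=None) -> None:
        """Dump as TSV ``gene_id  M  snp_ids`` (comma-separated ids or indices)."""
        with open(path, "w") as fh:
            fh.write("gene_id\tM\tsnp_ids\n")
            for g, idx in self.mapping.items():
                labels = (
                    [str(snp_ids[i]) for i in idx] if snp_ids is not None
                    else [str(i) for i in idx]
                )
                fh.write(f"{g}\t{len(idx)}\t{','.join(labels)}\n")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP association table (TSV with header).

    Requires columns ``snp_id, chrom, pos``; ``pvalue`` is optional and
    missing values are kept as NaN.  Raises :class:`DataError` naming the
    offending line for malformed rows, duplicate ids, or p-values outside
    [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["snp_id", "chrom", "pos"], path)
    if "pvalue" not in df.columns:
        df["pvalue"] = "NA"

    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 0) | (pos != pos.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = line 1
        raise DataError(f"{path}: line {line}: invalid pos {df['pos'].iloc[line - 2]!r}")
    pval_str = df["pvalue"].replace({"NA": None, "": None})
    pval = pd.to_numeric(pval_str, errors="coerce")
    bad = (pval_str.notna()) & (pval.isna() | (pval < 0) | (pval > 1))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DataError(
            f"{path}: line {line}: pvalue {df['pvalue'].iloc[line - 2]!r} not in [0, 1]"
        )
    dup = df["snp_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise DataError(f"{path}: line {line}: duplicate snp_id {df['snp_id'].iloc[line - 2]!r}")

    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": pos.astype(np.int64),
            "pvalue": pval.astype(float),
        }
    )
    return out


def write_snp_table(df: pd.DataFrame, path) -> None:
    """Write a SNP table as TSV, missing p-values as ``NA``."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", columns=SNP_COLUMNS)


def read_gene_table(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a gene annotation table.

    ``fmt='tsv'``: header ``gene_id chrom start end sets``, 1-based closed.
    ``fmt='bed'``: headerless BED3+1 (chrom, start, end, name), 0-based
    half-open, converted to 1-based closed.
    """
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, keep_default_na=False
        )
        if df.shape[1] < 4:
            raise DataError(f"{path}: BED3+1 requires 4 columns (chrom,start,end,name)")
        df = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 3],
                "chrom": df.iloc[:, 0],
                "start": pd.to_numeric(df.iloc[:, 1], errors="coerce") + 1,
                "end": pd.to_numeric(df.iloc[:, 2], errors="coerce"),
                "sets": "",
            }
        )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(df, ["gene_id", "chrom", "start", "end"], path)
        if "sets" not in df.columns:
            df["sets"] = ""
        df = df[GENE_COLUMNS].copy()
        df["start"] = pd.to_numeric(df["start"], errors="coerce")
        df["end"] = pd.to_numeric(df["end"], errors="coerce")
    else:
        raise ValueError(f"unknown gene table format {fmt!r}")

    if df["start"].isna().any() or df["end"].isna().any():
        line = int(np.flatnonzero((df["start"].isna() | df["end"].isna()).to_numpy())[0]) + 2
        raise DataError(f"{path}: line {line}: non-numeric start/end")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DataError(f"{path}: line {line}: start >= end")
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise DataError(f"{path}: line {line}: duplicate gene_id")
    return df.reset_index(drop=True)


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 0
) -> GeneSnpMap:
    """Assign each SNP to every gene whose flanked interval contains it.

    A SNP at position ``pos`` on the gene's chromosome is assigned iff
    ``start - flank_bp <= pos <= end + flank_bp`` (1-based, inclusive).
    SNPs inside overlapping genes appear in every overlapping gene's list.
    Per-gene lists are sorted by position, so the result is invariant to the
    SNP table's row order.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    mapping: dict[str, np.ndarray] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        order = np.argsort(p, kind="stable")
        by_chrom[chrom] = (p[order], sub.index.to_numpy()[order])
    for row in genes.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            mapping[row.gene_id] = np.empty(0, dtype=np.int64)
            continue
        sorted_pos, orig_idx = entry
        lo = np.searchsorted(sorted_pos, row.start - flank_bp, side="left")
        hi = np.searchsorted(sorted_pos, row.end + flank_bp, side="right")
        mapping[row.gene_id] = orig_idx[lo:hi].astype(np.int64)
    return GeneSnpMap(mapping=mapping, flank_bp=int(flank_bp))


def snp_counts_per_gene(gene_map: GeneSnpMap) -> pd.Series:
    """Vector of per-gene SNP counts M, keyed by gene_id."""
    return gene_map.counts()


def log_skipped_genes(gene_map: GeneSnpMap, stream=sys.stderr) -> None:
    empty = gene_map.empty_genes()
    if empty:
        print(
            f"genesize: {len(empty)} gene(s) with no assigned SNPs excluded "
            f"from testing: {', '.join(empty[:20])}"
            + ("..." if len(empty) > 20 else ""),
            file=stream,
        )
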