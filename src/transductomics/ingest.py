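"""Alignment ingest: loading, filtering, read assignment and taxon rollup.

Long reads of encapsidated DNA are mapped to metagenomic scaffolds; this
module turns raw alignments into one unambiguous read-to-scaffold
assignment each, drops short reads and marginal alignments, classifies
scaffolds into six broad categories, and rolls reads up to taxonomic units
(MAG bins, solitary scaffolds, viral genomes) while removing rare entities.

Alignments live in a DataFrame with columns
``read_id, read_len, scaffold_id, start, end, strand, aln_len``
(coordinates 0-based half-open on the scaffold). Two input dialects are
supported: minimap2-style PAF (target coordinates) and a plain interval
TSV with exactly those columns.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ALIGNMENT_COLUMNS",
    "CATEGORIES",
    "load_alignments",
    "load_scaffold_metadata",
    "load_prophage_bed",
    "filter_alignments",
    "assign_reads",
    "categorize_scaffolds",
    "taxon_label",
    "rollup_taxa",
]

ALIGNMENT_COLUMNS = ["read_id", "read_len", "scaffold_id", "start", "end", "strand", "aln_len"]

CATEGORIES = (
    "Viruses",
    "MAG bacteria",
    "MAG bacteria with prophages",
    "Bacteria unbinned",
    "Bacteria with prophages",
    "Archaea",
)

_INT_COLS = {"read_len": np.int64, "start": np.int64, "end": np.int64, "aln_len": np.int64}


class AlignmentParseError(ValueError):
    pass


def _parse_paf_line(line: str, lineno: int) -> dict:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AlignmentParseError(f"line {lineno}: expected >=12 PAF columns, got {len(f)}")
    try:
        return {
            "read_id": f[0],
            "read_len": int(f[1]),
            "scaffold_id": f[5],
            "start": int(f[7]),
            "end": int(f[8]),
            "strand": f[4],
            "aln_len": int(f[8]) - int(f[7]),
        }
    except ValueError as exc:
        raise AlignmentParseError(f"line {lineno}: {exc}") from None


def load_alignments(path, dialect: str = "paf") -> pd.DataFrame:
    """Load read-to-scaffold alignments from PAF or an interval TSV.

    Coordinates are normalised to 0-based half-open target intervals; for
    PAF the aligned length is the target span. The first malformed line is
    reported with its line number.
    """
    if dialect not in ("paf", "tsv"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "scaffold_id": str})
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
        missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
        if missing:
            raise AlignmentParseError(f"{path}: missing columns {missing}")
        df = df[ALIGNMENT_COLUMNS].astype(_INT_COLS)
    else:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rows.append(_parse_paf_line(line, lineno))
        df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
        if len(df):
            df = df.astype(_INT_COLS)
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise AlignmentParseError(
            f"{path}: invalid interval for read {bad.iloc[0]['read_id']!r}"
        )
    return df.reset_index(drop=True)


def load_scaffold_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str}, keep_default_na=False)
    required = ["scaffold_id", "length", "bin_id", "domain", "taxonomy", "is_viral"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing scaffold metadata columns {missing}")
    df["is_viral"] = df["is_viral"].astype(str).str.lower().isin(("true", "1", "yes"))
    df["length"] = df["length"].astype(np.int64)
    return df


def load_prophage_bed(path) -> pd.DataFrame:
    """Prophage / viral-fragment intervals from BED (0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["scaffold_id", "start", "end", "prophage_id"])
    df = df.iloc[:, :4]
    df.columns = ["scaffold_id", "start", "end", "prophage_id"][: df.shape[1]]
    if "prophage_id" not in df.columns:
        df["prophage_id"] = [f"pp{i}" for i in range(len(df))]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def filter_alignments(
    alignments: pd.DataFrame, min_read_len: int = 3000, min_aln_len: int = 1000
) -> pd.DataFrame:
    """Keep alignments of reads >= min_read_len with aligned span >= min_aln_len.

    Defaults follow the standard practice for this assay: only reads of at
    least 3 kb are informative about packaging, and sub-kilobase alignments
    are discarded as noise. Order is preserved and the filter is idempotent.
    """
    if min_read_len < 0 or min_aln_len < 0:
        raise ValueError("filter thresholds must be >= 0")
    keep = (alignments["read_len"] >= min_read_len) & (alignments["aln_len"] >= min_aln_len)
    return alignments[keep].reset_index(drop=True)


def assign_reads(alignments: pd.DataFrame) -> pd.DataFrame:
    """Resolve ambiguous placements: one scaffold per read, greatest-sum rule.

    Each read goes to the scaffold with the greatest total aligned length
    across all of that read's alignments to it; ties break to the
    lexicographically smallest scaffold_id. Returns columns
    ``read_id, read_len, scaffold_id, aln_sum``.
    """
    if len(alignments) == 0:
        return pd.DataFrame(columns=["read_id", "read_len", "scaffold_id", "aln_sum"])
    sums = (
        alignments.groupby(["read_id", "scaffold_id"], as_index=False)
        .agg(read_len=("read_len", "first"), aln_sum=("aln_len", "sum"))
        .sort_values(["read_id", "aln_sum", "scaffold_id"], ascending=[True, False, True])
    )
    best = sums.drop_duplicates("read_id", keep="first").reset_index(drop=True)
    return best[["read_id", "read_len", "scaffold_id", "aln_sum"]]


def categorize_scaffolds(
    records: pd.DataFrame, prophages: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Attach one of the six broad scaffold categories.

    Viruses; Archaea (binned or not); otherwise binned/unbinned bacteria
    crossed with presence of viral-origin fragments (prophages).
    """
    if "domain" not in records.columns or records["domain"].isna().any() or (
        records["domain"].astype(str).str.len() == 0
    ).any():
        raise ValueError("scaffold records must carry a non-empty domain")
    rec = records.copy()
    with_pp = set()
    if prophages is not None and len(prophages):
        with_pp = set(prophages["scaffold_id"].astype(str))
    has_pp = rec["scaffold_id"].astype(str).isin(with_pp)
    binned = rec["bin_id"].astype(str).str.len() > 0
    viral = rec["is_viral"].astype(bool) | (rec["domain"] == "virus")

    cat = np.where(
        viral,
        "Viruses",
        np.where(
            rec["domain"] == "archaea",
            "Archaea",
            np.where(
                binned,
                np.where(has_pp, "MAG bacteria with prophages", "MAG bacteria"),
                np.where(has_pp, "Bacteria with prophages", "Bacteria unbinned"),
            ),
        ),
    )
    rec["category"] = cat
    return rec


def taxon_label(row) -> str:
    """MAG bin id, else lowest non-empty taxonomy rank, else scaffold id."""
    bin_id = str(row["bin_id"]) if row["bin_id"] is not None else ""
    if bin_id:
        return bin_id
    tax = str(row["taxonomy"]) if row["taxonomy"] is not None else ""
    ranks = [t.strip() for t in tax.split(";") if t.strip()]
    for rank in reversed(ranks):
        name = rank.split("__", 1)[-1] if "__" in rank else rank
        if name:
            return rank
    return str(row["scaffold_id"])


def rollup_taxa(
    assignments: pd.DataFrame,
    records: pd.DataFrame,
    min_reads_mag: int = 50,
    min_reads_unbinned: int = 50,
    min_reads_viral: int = 200,
) -> pd.DataFrame:
    """Label assigned reads with taxon and category; drop rare entities.

    A taxon is retained only when its read count strictly exceeds the
    applicable minimum (viral scaffolds have a higher bar than bacterial
    MAGs and solitary scaffolds). Returns the assignment table with
    ``taxon`` and ``category`` columns, restricted to retained taxa.
    """
    if len(assignments) == 0:
        return assignments.assign(taxon=pd.Series(dtype=str), category=pd.Series(dtype=str))
    rec = records if "category" in records.columns else categorize_scaffolds(records)
    rec = rec.copy()
    rec["taxon"] = rec.apply(taxon_label, axis=1)
    merged = assignments.merge(
        rec[["scaffold_id", "taxon", "category"]], on="scaffold_id", how="left"
    )
    unknown = merged["taxon"].isna()
    if unknown.any():
        bad = merged.loc[unknown, "scaffold_id"].iloc[0]
        raise ValueError(f"assignment references unknown scaffold {bad!r}")
    counts = merged.groupby("taxon")["read_id"].nunique()
    cat_by_taxon = merged.groupby("taxon")["category"].first()
    minimum = pd.Series(
        np.where(cat_by_taxon == "Viruses", min_reads_viral,
                 np.where(cat_by_taxon.isin(["MAG bacteria", "MAG bacteria with prophages"]),
                          min_reads_mag, min_reads_unbinned)),
        index=cat_by_taxon.index,
    )
    keep = counts.index[counts > minimum.loc[counts.index]]
    return merged[merged["taxon"].isin(keep)].reset_index(drop=True)
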