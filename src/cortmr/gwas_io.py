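"""Readers and writers for the tabular formats the pipeline touches.

Summary statistics are plain delimited text (TSV by default) with ten
canonical columns; pairwise LD is a three-column table of r² values; gene
annotations come in BED (0-based half-open) and gene sets in GMT.  All
readers validate records and drop (with a logged count) or reject rows
according to each format's contract.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)

#: Canonical summary-statistic column order.
SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_VALID_ALLELES = frozenset("ACGT")


def read_summary_stats(path, delimiter: str = "\t",
                       rename: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistic table.

    Parameters
    ----------
    path
        Delimited text file with a header row naming the ten canonical
        columns (``variant_id chrom pos effect_allele other_allele eaf
        beta se pval n``).
    delimiter
        Field separator, tab by default.
    rename
        Optional mapping from column names as they appear in the file to
        the canonical names.

    Returns
    -------
    pandas.DataFrame
        One row per valid variant, alleles uppercased, ``eaf`` may be NaN
        (encoded ``NA`` on disk).  Rows violating the record invariants
        (equal alleles, non-positive se, p outside (0, 1], position < 1,
        eaf outside (0, 1)) are dropped and the count is logged.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"chrom": str},
                         na_values=["NA"], keep_default_na=True)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"empty summary-statistic file: {path}")
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"summary-statistic file {path} is missing mandatory "
            f"column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise InputFormatError(f"summary-statistic file has no rows: {path}")
    df = df[SUMSTAT_COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    return validate_summary_stats(df, source=str(path))


def validate_summary_stats(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Drop rows violating the summary-statistic invariants; log the count."""
    ok = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["pos"] >= 1)
        & (df["n"] >= 2)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d invalid row(s)", source, n_bad)
    return df.loc[ok].reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a summary-statistic table; missing eaf is encoded as ``NA``."""
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")


class LDTable:
    """Symmetric pairwise r² lookup.

    Absent pairs have r² = 0 by contract; a variant with itself has
    r² = 1.  Construction rejects r² outside [0, 1].
    """

    def __init__(self, pairs=None):
        self._r2: dict[tuple[str, str], float] = {}
        self._partners: dict[str, set[str]] = {}
        if pairs is not None:
            for a, b, r2 in pairs:
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputFormatError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
        if a == b:
            return
        self._r2[self._key(a, b)] = float(r2)
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, a: str) -> set[str]:
        """Variants with a recorded (nonzero) r² to ``a``."""
        return self._partners.get(a, set())

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])


def read_ld_table(path, delimiter: str = "\t") -> LDTable:
    """Read a three-column (id_a, id_b, r2) LD table into a symmetric lookup."""
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"empty LD file: {path}")
    missing = [c for c in ("id_a", "id_b", "r2") if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"LD file {path} is missing column(s): {', '.join(missing)}")
    return LDTable(zip(df["id_a"].astype(str), df["id_b"].astype(str),
                       df["r2"].astype(float)))


def write_ld_table(ld: LDTable, path, delimiter: str = "\t") -> None:
    ld.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT record); members are unique, order-preserving."""
    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise InputFormatError(f"gene set {self.set_id} has no members")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: id, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}")
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+1 gene annotation into a (gene_id, chrom, start, end) table.

    BED coordinates are 0-based half-open ``[start, end)``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputFormatError(
                    f"BED line {lineno}: expected >= 4 fields, got {len(fields)}")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise InputFormatError(
                    f"BED line {lineno}: start {start} >= end {end}")
            rows.append((name, chrom, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_annotation(path, delimiter: str = "\t") -> dict[str, list[str]]:
    """Read a variant -> secondary-trait annotation table.

    Two columns (``variant_id``, ``trait``); a variant may appear on
    multiple rows.  Stands in for an online secondary-phenotype lookup.
    """
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        return {}
    missing = [c for c in ("variant_id", "trait") if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"annotation file {path} is missing column(s): {', '.join(missing)}")
    out: dict[str, list[str]] = {}
    for vid, trait in zip(df["variant_id"].astype(str), df["trait"].astype(str)):
        out.setdefault(vid, []).append(trait)
    return out
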