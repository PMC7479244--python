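"""Readers and writers for the text formats the pipeline consumes and emits.

Coordinate conventions
----------------------
All in-memory positions in this package are **0-based**; interval objects are
half-open ``[start, end)``.  The bisulfite *coverage* dialect on disk is
1-based inclusive (``chrom  start  end=start  meth%  count_M  count_U``), BED
tracks are 0-based half-open, GTF is 1-based inclusive.  Conversions happen
here and nowhere else.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = ["chrom", "pos", "count_m", "count_u"]


class CoverageParseError(ValueError):
    """Raised when a bisulfite coverage file contains a malformed line."""


def read_coverage_file(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a 6-column bisulfite coverage file.

    Returns a DataFrame with columns ``chrom, pos, count_m, count_u`` where
    ``pos`` is the 0-based position of the cytosine.  The methylation-percentage
    column of the file is ignored and always recomputed downstream from the
    counts.  Malformed lines raise :class:`CoverageParseError` naming the line.
    """
    path = Path(path)
    try:  # fast vectorised path; falls back to a line-by-line scan on failure
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "cm", "cu"],
            dtype={"chrom": str, "start": np.int64, "cm": np.int64, "cu": np.int64},
        )
        if raw.shape[1] != 6:
            raise ValueError("column count")
    except pd.errors.EmptyDataError:
        warnings.warn(f"coverage file {path} is empty", stacklevel=2)
        df = pd.DataFrame(columns=COVERAGE_COLUMNS).astype(
            {"pos": int, "count_m": int, "count_u": int}
        )
        if sample_id is not None:
            df.attrs["sample_id"] = sample_id
        return df
    except (ValueError, TypeError):
        _scan_coverage_for_error(path)
        raise  # pragma: no cover - scan always raises first
    if len(raw) == 0:
        warnings.warn(f"coverage file {path} is empty", stacklevel=2)
    if (raw["cm"] < 0).any() or (raw["cu"] < 0).any():
        _scan_coverage_for_error(path)
    df = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": raw["start"] - 1,
            "count_m": raw["cm"],
            "count_u": raw["cu"],
        }
    )
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def _scan_coverage_for_error(path) -> None:
    """Re-read a coverage file line by line to report the offending line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            start, _end, cm, cu = fields[1], fields[2], fields[4], fields[5]
            try:
                start_i, cm_i, cu_i = int(start), int(cm), int(cu)
            except ValueError as exc:
                raise CoverageParseError(
                    f"{path}:{lineno}: non-integer coordinate or count field ({exc})"
                ) from None
            if cm_i < 0 or cu_i < 0 or start_i < 1:
                raise CoverageParseError(f"{path}:{lineno}: negative count or coordinate")
    raise CoverageParseError(f"{path}: malformed coverage file")


def write_coverage_file(df: pd.DataFrame, path) -> None:
    """Write ``chrom,pos,count_m,count_u`` records in the coverage dialect.

    ``pos`` is 0-based in memory and written 1-based; the percentage column is
    recomputed from the counts.
    """
    total = (df["count_m"] + df["count_u"]).to_numpy()
    pct = np.where(total > 0, 100.0 * df["count_m"].to_numpy() / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["pos"].to_numpy() + 1,
            "end": df["pos"].to_numpy() + 1,
            "pct": np.round(pct, 4),
            "count_m": df["count_m"].to_numpy(),
            "count_u": df["count_u"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, bull_id, group (HM/MM), age (15/16)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "bull_id": str, "group": str})
    required = {"sample_id", "bull_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    bad = ~df["group"].isin(["HM", "MM"])
    if bad.any():
        raise ValueError(f"sample sheet {path}: unknown group labels {df.loc[bad, 'group'].unique()}")
    df["age"] = df["age"].astype(int)
    df["group_label"] = df["group"] + df["age"].astype(str)
    if df.duplicated(["bull_id", "age"]).any():
        raise ValueError(f"sample sheet {path}: duplicate (bull_id, age)")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[["sample_id", "bull_id", "group", "age"]].to_csv(path, index=False)


def read_bed(path, names: tuple[str, ...] = ("chrom", "start", "end")) -> pd.DataFrame:
    """Read a BED3/BED4 track (0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names))
    ncol = min(df.shape[1], 4)
    cols = list(names) + ["name"] * (ncol - len(names))
    df = df.iloc[:, :ncol]
    df.columns = (list(names) + ["name"])[:ncol]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), build_index=False)
    return {name: str(rec[:]).upper() for name, rec in fa.items()}


def write_gtf(records: list[dict], path) -> None:
    """Write GTF rows from dicts with keys
    chrom, source, feature, start, end (0-based half-open), strand, gene_id,
    transcript_id.  Coordinates are converted to GTF's 1-based inclusive."""
    with open(path, "w") as fh:
        for r in records:
            attrs = f'gene_id "{r["gene_id"]}"; transcript_id "{r.get("transcript_id", r["gene_id"] + ".t1")}";'
            fh.write(
                "\t".join(
                    [
                        r["chrom"],
                        r.get("source", "rrbsdiff"),
                        r["feature"],
                        str(r["start"] + 1),
                        str(r["end"]),
                        ".",
                        r["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_spikein_csv(path) -> pd.DataFrame:
    """Spike-in conversion-control CSV: sample_id, converted, total."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "converted", "total"):
        if col not in df.columns:
            raise ValueError(f"spike-in table {path} missing column {col}")
    return df


def read_pyro_csv(path) -> pd.DataFrame:
    """Pyrosequencing replicate table CSV:
    region, cpg_index, sample_id, replicate, percentage."""
    df = pd.read_csv(path, dtype={"region": str, "sample_id": str})
    required = {"region", "cpg_index", "sample_id", "replicate", "percentage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pyro table {path} missing columns: {sorted(missing)}")
    return df
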