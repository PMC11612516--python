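"""Tabular formats and provenance-stamped output files.

Every table the pipeline writes starts with ``#``-prefixed header comments
recording the tool version, a short hash of the configuration that produced
it, and the random seed, so a result file can always be traced back to the
exact run that made it.  Readers simply skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__version__ = "0.1.0"

#: column order for the normalised per-position read-count table
COUNT_COLUMNS = ["lg", "pos", "ref", "population", "replicate", "A", "C", "G", "T"]

#: column order for the biallelic SNP table
SNP_COLUMNS = [
    "lg", "pos", "ref", "alt",
    "population", "ref_count", "alt_count", "depth", "alt_freq",
]

BASES = ("A", "C", "G", "T")


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _header_lines(meta: Mapping[str, Any] | None) -> list[str]:
    lines = [f"# poolscan v{__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_tsv(df: pd.DataFrame, path: str | Path,
              meta: Mapping[str, Any] | None = None) -> None:
    """Write a TSV with provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(df: pd.DataFrame, path: str | Path,
                 meta: Mapping[str, Any] | None = None) -> None:
    write_tsv(df[COUNT_COLUMNS] if "replicate" in df.columns
              else df[[c for c in COUNT_COLUMNS if c != "replicate"]],
              path, meta)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"lg": str, "ref": str})
    missing = {"lg", "pos", "ref", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} missing columns: {sorted(missing)}")
    return df


def read_bam_readcount(path: str | Path, population: str,
                       replicate: str | int = 1) -> pd.DataFrame:
    """Parse a bam-readcount style TSV into the normalised count table.

    Expected layout: ``chrom  pos  ref  depth  base:count[:...] ...`` with one
    colon-joined field per observed base; fields for bases other than A/C/G/T
    (N, indels) are ignored.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{line_no}: expected >=4 tab-separated fields")
            chrom, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            counts = dict.fromkeys(BASES, 0)
            for token in fields[4:]:
                parts = token.split(":")
                base = parts[0].upper()
                if base in counts and len(parts) > 1:
                    counts[base] = int(parts[1])
            records.append((chrom, pos, ref, population, replicate,
                            counts["A"], counts["C"], counts["G"], counts["T"]))
    return pd.DataFrame(records, columns=COUNT_COLUMNS)


def write_sync(snps: pd.DataFrame, path: str | Path,
               meta: Mapping[str, Any] | None = None) -> None:
    """Write a SNP table in PoPoolation2 sync format.

    One row per site: ``chrom  pos  ref`` followed by one ``A:T:C:G:N:del``
    colon-separated count column per population (populations in sorted order).
    """
    populations = sorted(snps["population"].unique())
    wide_ref = snps.pivot_table(index=["lg", "pos", "ref", "alt"],
                                columns="population", values="ref_count",
                                aggfunc="first")
    wide_alt = snps.pivot_table(index=["lg", "pos", "ref", "alt"],
                                columns="population", values="alt_count",
                                aggfunc="first")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for (lg, pos, ref, alt), ref_row in wide_ref.iterrows():
            alt_row = wide_alt.loc[(lg, pos, ref, alt)]
            cols = []
            for p in populations:
                base_counts = dict.fromkeys(BASES, 0)
                base_counts[ref] = int(ref_row[p])
                base_counts[alt] = int(alt_row[p])
                cols.append(":".join(str(base_counts[b])
                                     for b in ("A", "T", "C", "G")) + ":0:0")
            fh.write("\t".join([str(lg), str(pos), ref, *cols]) + "\n")


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column population→group table (``population``, ``group``)."""
    df = read_tsv(path, dtype=str)
    if not {"population", "group"} <= set(df.columns):
        raise ValueError(f"design table {path} needs 'population' and 'group' columns")
    bad = sorted(set(df["group"]) - {"farmed", "wild"})
    if bad:
        raise ValueError(f"design table {path}: unknown group labels {bad}")
    return dict(zip(df["population"], df["group"]))


def write_design(design: Mapping[str, str], path: str | Path,
                 meta: Mapping[str, Any] | None = None) -> None:
    df = pd.DataFrame(sorted(design.items()), columns=["population", "group"])
    write_tsv(df, path, meta)
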