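"""Minimal GFF3 emit/ingest helpers shared by the calling modules.

Junction features are written ParTIES-style: a zero-width insertion point
at 0-based junction ``j`` becomes a 1-based feature with start == end ==
``j + 1`` (the first somatic-genome base after the junction).
"""

from __future__ import annotations

import os
import urllib.parse

import pandas as pd

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def escape_attr(value: str) -> str:
    return urllib.parse.quote(str(value), safe="ACGTNacgtn0-9_.:^*$@!+?|-")


def format_attributes(attrs: dict) -> str:
    return ";".join(f"{k}={escape_attr(v)}" for k, v in attrs.items())


def write_gff3(
    rows: list[tuple],
    path: str | os.PathLike,
    provenance: dict | None = None,
) -> None:
    """Write rows of (seqid, source, type, start, end, score, strand, phase,
    attrs-dict) as a GFF3 file with provenance comment lines."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for key, val in (provenance or {}).items():
            fh.write(f"#!{key} {val}\n")
        for seqid, source, ftype, start, end, score, strand, phase, attrs in rows:
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        ftype,
                        str(start),
                        str(end),
                        str(score),
                        strand,
                        phase,
                        format_attributes(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a GFF3 file into a DataFrame with an attribute dict column."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line[:80]!r}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    if not df.empty:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["attr"] = df["attributes"].map(parse_attributes)
    else:
        df["attr"] = pd.Series(dtype=object)
    return df


def parse_attributes(text: str) -> dict:
    attrs = {}
    for item in text.split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        attrs[key] = urllib.parse.unquote(val)
    return attrs


def read_junctions(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Junction annotation as (contig, 0-based junction) pairs.

    Accepts junction features with start == end; the 0-based junction is
    start - 1 (insertion point before that base).
    """
    df = read_gff3(path)
    out = []
    for _, row in df.iterrows():
        if row["end"] != row["start"]:
            raise ValueError(
                f"feature at {row['seqid']}:{row['start']}-{row['end']} is not a "
                "zero-width junction (start must equal end)"
            )
        out.append((row["seqid"], int(row["start"]) - 1))
    return out
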