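"""GFF3 export of annotated editing sites, with round-trip read-back.

One feature per site, type ``RNA_editing_site``, on the ORF sequence
(seqid = gene id), 1-based inclusive coordinates with
``start == end == position``.  All annotation fields travel in column 9
attributes, percent-encoded per the GFF3 attribute rules.
"""

from __future__ import annotations

import math
from pathlib import Path
from urllib.parse import quote, unquote

import pandas as pd

GFF_SOURCE = "mitoedit"
GFF_TYPE = "RNA_editing_site"

#: Annotation columns carried into attributes, in order.
_ATTR_COLUMNS = [
    "site_id",
    "sanger_level",
    "sanger_pass",
    "rnaseq_level",
    "rnaseq_depth",
    "category",
    "status",
    "evidence",
    "codon_index",
    "codon_pos",
    "ref_codon",
    "edited_codon",
    "ref_aa",
    "edited_aa",
    "effect",
    "aa_change",
    "hydropathy",
    "is_pseudogene",
]

_INT_ATTRS = {"sanger_pass", "rnaseq_depth", "codon_index", "codon_pos"}
_FLOAT_ATTRS = {"sanger_level", "rnaseq_level"}
_BOOL_ATTRS = {"is_pseudogene"}

# GFF3 reserves ; = & , and control characters inside attribute values
_SAFE = " :.->*+_()[]{}|/'\"!@^~"


def _encode(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        s = f"{value:.10g}"
    else:
        s = str(value)
    if s == "":
        return None
    return quote(s, safe=_SAFE)


def write_sites_gff3(annotated_sites: pd.DataFrame, path: str | Path) -> None:
    """Write one ``RNA_editing_site`` feature per annotated site."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##gff-version 3"]
    for r in annotated_sites.itertuples(index=False):
        d = r._asdict()
        attrs = []
        site_id = d.get("site_id") or f"{d['gene']}-{d['pos']}"
        attrs.append(f"ID={_encode(site_id)}")
        for col in _ATTR_COLUMNS:
            if col == "site_id" or col not in d:
                continue
            enc = _encode(d[col])
            if enc is not None:
                attrs.append(f"{col}={enc}")
        pos = int(d["pos"])
        lines.append(
            "\t".join(
                [
                    str(d["gene"]),
                    GFF_SOURCE,
                    GFF_TYPE,
                    str(pos),
                    str(pos),
                    ".",
                    "+",
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_sites_gff3(path: str | Path) -> pd.DataFrame:
    """Read back a site GFF3 into the annotated-sites table layout."""
    rows: list[dict] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
        seqid, source, ftype, start, end, _score, _strand, _phase, attr_col = fields
        if ftype != GFF_TYPE:
            continue
        if start != end:
            raise ValueError(f"{path}:{lineno}: editing site must have start == end")
        row: dict = {"gene": seqid, "pos": int(start)}
        for pair in attr_col.split(";"):
            if not pair:
                continue
            key, _, raw = pair.partition("=")
            value = unquote(raw)
            if key == "ID":
                row["site_id"] = value
            elif key in _INT_ATTRS:
                row[key] = int(value)
            elif key in _FLOAT_ATTRS:
                row[key] = float(value)
            elif key in _BOOL_ATTRS:
                row[key] = value == "true"
            else:
                row[key] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["gene", "pos"]).reset_index(drop=True)
    return df
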