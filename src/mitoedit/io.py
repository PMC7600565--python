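"""On-disk dialects: tab-separated tables, run configuration, reports.

All tables are plain TSV with a fixed header row.  Readers validate the
header and every field and report the first malformed line with its
line number and column name, deterministically.

Dialects
--------
counts:  ``sample_id  gene  pos  ref  a_count  c_count  g_count  t_count``
sanger:  ``gene  pos  replicate  peak_c  peak_t``
truth:   ``gene  pos  true_level  rnaseq_level  sanger_level  in_rnaseq
         in_sanger  site_class``
calls:   ``site_id  gene  pos  sanger_level  sanger_pass  rnaseq_level
         rnaseq_depth  category  status  evidence``
claims:  ``gene  pos  claimed_ref_aa  claimed_edited_aa``

Missing values in numeric columns are written as ``.``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
import yaml

MISSING = "."


class FormatError(ValueError):
    """Raised at the first malformed line of an input table."""


def _conv_int(s: str) -> int:
    return int(s)


def _conv_float(s: str) -> float:
    return float(s)


def _conv_optional_float(s: str):
    return None if s == MISSING else float(s)


def _conv_optional_int(s: str):
    return None if s == MISSING else int(s)


def _conv_str(s: str) -> str:
    return s


def _conv_bool(s: str) -> bool:
    if s in ("True", "true", "1"):
        return True
    if s in ("False", "false", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _conv_nonneg_int(s: str) -> int:
    v = int(s)
    if v < 0:
        raise ValueError(f"negative count {v}")
    return v


def _conv_nonneg_float(s: str) -> float:
    v = float(s)
    if v < 0 or math.isnan(v):
        raise ValueError(f"negative or NaN value {s}")
    return v


def _read_table(
    path: str | Path, schema: Sequence[tuple[str, Callable[[str], object]]]
) -> pd.DataFrame:
    """Read a TSV against a (column, converter) schema with line/column
    diagnostics on the first malformed entry."""
    path = Path(path)
    expected = [name for name, _ in schema]
    rows: list[list[object]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header != expected:
            raise FormatError(
                f"{path}:1: bad header {header!r}; expected {expected!r}"
            )
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and raw[0] == ""):
                continue
            if len(raw) != len(schema):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(schema)} columns, "
                    f"got {len(raw)}"
                )
            parsed: list[object] = []
            for (name, conv), value in zip(schema, raw):
                try:
                    parsed.append(conv(value))
                except (ValueError, TypeError) as exc:
                    raise FormatError(
                        f"{path}:{lineno}: column {name!r}: {exc}"
                    ) from None
            rows.append(parsed)
    return pd.DataFrame(rows, columns=expected)


COUNTS_SCHEMA = [
    ("sample_id", _conv_str),
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("ref", _conv_str),
    ("a_count", _conv_nonneg_int),
    ("c_count", _conv_nonneg_int),
    ("g_count", _conv_nonneg_int),
    ("t_count", _conv_nonneg_int),
]

SANGER_SCHEMA = [
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("replicate", _conv_int),
    ("peak_c", _conv_nonneg_float),
    ("peak_t", _conv_nonneg_float),
]

TRUTH_SCHEMA = [
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("true_level", _conv_float),
    ("rnaseq_level", _conv_float),
    ("sanger_level", _conv_float),
    ("in_rnaseq", _conv_bool),
    ("in_sanger", _conv_bool),
    ("site_class", _conv_str),
]

CALLS_SCHEMA = [
    ("site_id", _conv_str),
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("sanger_level", _conv_optional_float),
    ("sanger_pass", _conv_int),
    ("rnaseq_level", _conv_optional_float),
    ("rnaseq_depth", _conv_optional_int),
    ("category", _conv_str),
    ("status", _conv_str),
    ("evidence", _conv_str),
]

LEVELS_SCHEMA = [
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("rnaseq_level", _conv_float),
    ("rnaseq_depth", _conv_int),
]

SANGER_CALLS_SCHEMA = [
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("sanger_level", _conv_float),
    ("sanger_pass", _conv_int),
]

CLAIMS_SCHEMA = [
    ("gene", _conv_str),
    ("pos", _conv_int),
    ("claimed_ref_aa", _conv_str),
    ("claimed_edited_aa", _conv_str),
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, COUNTS_SCHEMA)


def read_sanger_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SANGER_SCHEMA)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, TRUTH_SCHEMA)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CALLS_SCHEMA)


def read_levels_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, LEVELS_SCHEMA)


def read_sanger_calls_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SANGER_CALLS_SCHEMA)


def read_claims_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CLAIMS_SCHEMA)


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        if math.isnan(value):
            return MISSING
        return f"{value:.10g}"
    return str(value)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with ``.`` for missing numeric values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(df.columns))
        for row in df.itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (also serialised for provenance).

    Thresholds follow the calling rules: ``threshold`` applies to both
    channels, ``rnaseq_tolerance`` is the borderline retention margin,
    ``min_pass_replicates`` the Sanger 2-of-3 rule, and
    ``category_bounds`` the L/M/H/EH bin edges.
    """

    panel_fasta: str = ""
    counts_tsv: list[str] = field(default_factory=list)
    sanger_tsv: str = ""
    output_dir: str = "mitoedit_out"
    flank_len: int = 100
    pseudogene_ids: list[str] = field(default_factory=list)
    threshold: float = 0.10
    rnaseq_tolerance: float = 0.02
    min_pass_replicates: int = 2
    min_depth: int = 1
    category_bounds: list[float] = field(
        default_factory=lambda: [0.10, 0.30, 0.60, 0.90]
    )
    hydrophobic_aa: str = "ACFILMV"
    random_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("threshold", "rnaseq_tolerance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.flank_len < 0:
            raise ValueError("flank_len must be non-negative")
        if self.min_depth < 0 or self.min_pass_replicates < 1:
            raise ValueError("min_depth >= 0 and min_pass_replicates >= 1 required")
        if len(self.category_bounds) != 4 or not all(
            0 <= b <= 1 for b in self.category_bounds
        ):
            raise ValueError("category_bounds must be four values in [0, 1]")
        if sorted(self.category_bounds) != list(self.category_bounds):
            raise ValueError("category_bounds must be increasing")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
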