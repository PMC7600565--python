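"""Dual-evidence C-to-U editing site calling and reconciliation.

Two detection rules are implemented:

* **RNA-seq**: at every C-containing reference position the editing
  level is the T fraction of the aligned-read base counts,
  ``T / (A + C + G + T)``; a site is called when the level is at or
  above the threshold (default 10%) with at least ``min_depth`` reads.
  Rows at flank coordinates (outside 1..CDS length) are discarded
  before calling.

* **Sanger**: the per-replicate editing level is the relative T peak
  height, ``T / (C + T)``; a site is called when at least
  ``min_pass_replicates`` of the replicates (default 2 of 3) reach the
  threshold.  The reported level is the mean across replicates.

Reconciliation treats Sanger as the primary evidence: Sanger-called
sites are accepted when the RNA-seq level is within a small tolerance
below the threshold (or when RNA-seq gives no coverage), which retains
genuine sites whose RNA-seq estimate lands around 9%; candidates seen
only in RNA-seq are reported but rejected.  Accepted sites carry an
editing-strength category: L [10-30%), M [30-60%), H [60-90%),
EH [90-100%].

Tables are pandas DataFrames with the documented column schemas (see
:mod:`mitoedit.io` for the on-disk dialects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ORFRecord

COUNT_COLUMNS = ["a_count", "c_count", "g_count", "t_count"]

CALL_COLUMNS = [
    "site_id",
    "gene",
    "pos",
    "sanger_level",
    "sanger_pass",
    "rnaseq_level",
    "rnaseq_depth",
    "category",
    "status",
    "evidence",
]

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_RNASEQ_ONLY = "rejected_rnaseq_only"
STATUS_REJECTED_BELOW_THRESHOLD = "rejected_below_threshold"

#: Lower edges of the L / M / H / EH editing-level categories.
DEFAULT_CATEGORY_BOUNDS = (0.10, 0.30, 0.60, 0.90)


class CallingError(ValueError):
    """Raised for malformed count/peak tables or inconsistent inputs."""


@dataclass(frozen=True)
class ReconcilePolicy:
    """Rules applied when merging the two evidence channels.

    ``rnaseq_tolerance`` is how far below ``threshold`` the RNA-seq
    level of a Sanger-called site may fall and still be accepted
    (default 0.02, i.e. levels of ~9% against a 10% threshold).
    ``require_sanger`` rejects RNA-seq-only candidates when True.
    """

    threshold: float = 0.10
    rnaseq_tolerance: float = 0.02
    require_sanger: bool = True


def rnaseq_level(row: Mapping) -> float:
    """Editing level of one count row: ``t_count / depth``.

    Only C reference positions are eligible; depth must be positive.
    """
    if str(row["ref"]).upper() != "C":
        raise CallingError(
            f"{row['gene']}:{row['pos']}: editing level is defined only at "
            f"C reference positions, got ref={row['ref']!r}"
        )
    depth = sum(int(row[c]) for c in COUNT_COLUMNS)
    if depth <= 0:
        raise CallingError(f"{row['gene']}:{row['pos']}: zero depth")
    return int(row["t_count"]) / depth


def sanger_level(peak_c: float, peak_t: float) -> float:
    """Editing level from chromatogram peaks: ``T / (C + T)``."""
    if peak_c < 0 or peak_t < 0:
        raise CallingError(f"negative peak height ({peak_c}, {peak_t})")
    total = peak_c + peak_t
    if total <= 0:
        raise CallingError("both C and T peaks are zero; level undefined")
    return peak_t / total


def merge_samples(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-position counts over samples (equivalent to merging
    alignments before counting).

    Positions present in any input appear in the output; conflicting
    reference bases at a position are fatal.
    """
    if not tables:
        raise CallingError("no count tables to merge")
    merged = pd.concat(tables, ignore_index=True)
    ref_check = merged.groupby(["gene", "pos"])["ref"].nunique()
    bad = ref_check[ref_check > 1]
    if not bad.empty:
        gene, pos = bad.index[0]
        raise CallingError(f"conflicting reference base at {gene}:{pos}")
    out = (
        merged.groupby(["gene", "pos"], as_index=False)
        .agg({"ref": "first", **{c: "sum" for c in COUNT_COLUMNS}})
        .sort_values(["gene", "pos"])
        .reset_index(drop=True)
    )
    return out


def categorize_level(
    level: float, bounds: Sequence[float] = DEFAULT_CATEGORY_BOUNDS
) -> str:
    """Editing-strength category of an accepted site.

    L = [bounds[0], bounds[1]), M = [bounds[1], bounds[2]),
    H = [bounds[2], bounds[3]), EH = [bounds[3], 1].  Levels below the
    calling threshold have no category and raise.
    """
    lo, m, h, eh = bounds
    if level < lo:
        raise CallingError(
            f"level {level:.4g} below {lo:.4g}; categories are defined only "
            "for accepted sites"
        )
    if level >= eh:
        return "EH"
    if level >= h:
        return "H"
    if level >= m:
        return "M"
    return "L"


def _category_for_accepted(
    level: float, bounds: Sequence[float] = DEFAULT_CATEGORY_BOUNDS
) -> str:
    """Category for an accepted site, tolerating borderline levels.

    A site can be accepted with a reported level slightly below the
    lowest bin edge (a passing 2-of-3 vote with one weak replicate, or
    the reconciliation tolerance); such sites fall in the lowest bin.
    """
    if level < bounds[0]:
        return "L"
    return categorize_level(level, bounds)


def _check_panel_rows(df: pd.DataFrame, panel: Mapping[str, ORFRecord]) -> None:
    unknown = set(df["gene"].unique()) - set(panel)
    if unknown:
        raise CallingError(f"rows reference unknown gene(s): {sorted(unknown)}")


def rnaseq_levels_table(
    counts: pd.DataFrame, panel: Mapping[str, ORFRecord]
) -> pd.DataFrame:
    """Per-position editing level and depth at every covered C position.

    Flank rows (coordinates outside 1..length) are discarded first.
    A reference-base mismatch against the panel is fatal (it indicates
    corrupted coordinates upstream).  Columns: ``gene, pos,
    rnaseq_level, rnaseq_depth``.
    """
    _check_panel_rows(counts, panel)
    df = counts.copy()
    lengths = df["gene"].map(lambda g: panel[g].length)
    df = df[(df["pos"] >= 1) & (df["pos"] <= lengths)]
    if not df.empty:
        panel_base = df.apply(lambda r: panel[r["gene"]].base_at(int(r["pos"])), axis=1)
        mismatch = df["ref"].str.upper() != panel_base
        if mismatch.any():
            r = df[mismatch].iloc[0]
            raise CallingError(
                f"reference base mismatch at {r['gene']}:{r['pos']}: counts say "
                f"{r['ref']!r}, panel says {panel_base[mismatch].iloc[0]!r}"
            )
    df = df[df["ref"].str.upper() == "C"].copy()
    depth = df[COUNT_COLUMNS].sum(axis=1)
    df = df[depth > 0]
    depth = depth[depth > 0]
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "pos": df["pos"].astype(int),
            "rnaseq_level": df["t_count"] / depth,
            "rnaseq_depth": depth.astype(int),
        }
    )
    return out.sort_values(["gene", "pos"]).reset_index(drop=True)


def call_rnaseq(
    counts: pd.DataFrame,
    panel: Mapping[str, ORFRecord],
    threshold: float = 0.10,
    min_depth: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call sites from merged RNA-seq counts.

    Returns ``(calls, levels)`` where ``levels`` is the full per-C-position
    table from :func:`rnaseq_levels_table` (the reconciler needs levels at
    every position, not only at called ones) and ``calls`` is its subset
    with ``rnaseq_level >= threshold`` and ``rnaseq_depth >= min_depth``.
    """
    levels = rnaseq_levels_table(counts, panel)
    calls = levels[
        (levels["rnaseq_level"] >= threshold) & (levels["rnaseq_depth"] >= min_depth)
    ].reset_index(drop=True)
    return calls, levels


def call_sanger(
    observations: pd.DataFrame,
    panel: Mapping[str, ORFRecord],
    threshold: float = 0.10,
    min_pass_replicates: int = 2,
) -> pd.DataFrame:
    """Call sites from replicate Sanger peak heights.

    A position is called when at least ``min_pass_replicates``
    replicates reach the threshold; the reported ``sanger_level`` is
    the mean over all replicates with data.  Duplicate replicate ids
    for one position are fatal.  Columns of the result: ``gene, pos,
    sanger_level, sanger_pass``.
    """
    _check_panel_rows(observations, panel)
    dup = observations.duplicated(["gene", "pos", "replicate"])
    if dup.any():
        r = observations[dup].iloc[0]
        raise CallingError(
            f"duplicate replicate id {r['replicate']} at {r['gene']}:{r['pos']}"
        )
    df = observations.copy()
    total = df["peak_c"] + df["peak_t"]
    if (total <= 0).any():
        r = df[total <= 0].iloc[0]
        raise CallingError(f"both peaks zero at {r['gene']}:{r['pos']} "
                           f"replicate {r['replicate']}")
    df["level"] = df["peak_t"] / total
    grouped = df.groupby(["gene", "pos"], as_index=False).agg(
        sanger_level=("level", "mean"),
        sanger_pass=("level", lambda v: int((v >= threshold).sum())),
        n_replicates=("level", "size"),
    )
    called = grouped[grouped["sanger_pass"] >= min_pass_replicates].copy()
    called["pos"] = called["pos"].astype(int)
    return (
        called[["gene", "pos", "sanger_level", "sanger_pass"]]
        .sort_values(["gene", "pos"])
        .reset_index(drop=True)
    )


def reconcile(
    sanger_calls: pd.DataFrame,
    rnaseq_levels: pd.DataFrame,
    policy: ReconcilePolicy = ReconcilePolicy(),
    category_bounds: Sequence[float] = DEFAULT_CATEGORY_BOUNDS,
) -> pd.DataFrame:
    """Merge the two evidence channels into the final site table.

    * Sanger-called sites are **accepted** when their RNA-seq level is at
      least ``threshold - rnaseq_tolerance`` or when RNA-seq gives no
      coverage at the position; otherwise they are marked
      ``rejected_below_threshold``.
    * Positions at or above the threshold in RNA-seq but not Sanger-called
      are emitted as ``rejected_rnaseq_only`` (or accepted, if
      ``require_sanger`` is False).

    Accepted sites carry a category computed from the Sanger level when
    present, else the RNA-seq level, and an ``evidence`` field naming
    the channels at or above threshold.
    """
    rl = rnaseq_levels.set_index(["gene", "pos"]) if not rnaseq_levels.empty else None
    rows: list[dict] = []
    sanger_keys = set()

    for r in sanger_calls.itertuples(index=False):
        sanger_keys.add((r.gene, r.pos))
        rna_level = rna_depth = None
        if rl is not None and (r.gene, r.pos) in rl.index:
            rec = rl.loc[(r.gene, r.pos)]
            rna_level = float(rec["rnaseq_level"])
            rna_depth = int(rec["rnaseq_depth"])
        if rna_level is None or rna_level >= policy.threshold - policy.rnaseq_tolerance:
            status = STATUS_ACCEPTED
        else:
            status = STATUS_REJECTED_BELOW_THRESHOLD
        evidence = ["sanger"]
        if rna_level is not None and rna_level >= policy.threshold:
            evidence.append("rnaseq")
        category = (
            _category_for_accepted(float(r.sanger_level), category_bounds)
            if status == STATUS_ACCEPTED
            else ""
        )
        rows.append(
            dict(
                site_id=f"{r.gene}-{r.pos}",
                gene=r.gene,
                pos=int(r.pos),
                sanger_level=float(r.sanger_level),
                sanger_pass=int(r.sanger_pass),
                rnaseq_level=rna_level,
                rnaseq_depth=rna_depth,
                category=category,
                status=status,
                evidence="+".join(evidence),
            )
        )

    if rl is not None:
        candidates = rnaseq_levels[rnaseq_levels["rnaseq_level"] >= policy.threshold]
        for r in candidates.itertuples(index=False):
            if (r.gene, r.pos) in sanger_keys:
                continue
            status = (
                STATUS_REJECTED_RNASEQ_ONLY
                if policy.require_sanger
                else STATUS_ACCEPTED
            )
            category = (
                _category_for_accepted(float(r.rnaseq_level), category_bounds)
                if status == STATUS_ACCEPTED
                else ""
            )
            rows.append(
                dict(
                    site_id=f"{r.gene}-{r.pos}",
                    gene=r.gene,
                    pos=int(r.pos),
                    sanger_level=None,
                    sanger_pass=0,
                    rnaseq_level=float(r.rnaseq_level),
                    rnaseq_depth=int(r.rnaseq_depth),
                    category=category,
                    status=status,
                    evidence="rnaseq",
                )
            )

    out = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return out.sort_values(["gene", "pos"]).reset_index(drop=True)


def accepted_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Subset of a reconciled call table with status ``accepted``."""
    return calls[calls["status"] == STATUS_ACCEPTED].reset_index(drop=True)
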