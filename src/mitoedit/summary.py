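"""Descriptive statistics over an annotated editing-site catalogue.

Covers the standard panels of an organellar editing survey: the
distribution of sites over codon positions, synonymous vs nonsynonymous
codon changes, how many codons carry one vs two sites, the most frequent
amino-acid changes and edited codons, start/stop gains, per-gene edited-C
percentages, and Pearson correlations of per-gene edited-C counts
against total Cs and gene length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .consequence import HYDROPHOBIC_AA
from .reference import ORFRecord, c_positions


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding (32.505 → 32.51), matching conventional reporting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    """All headline statistics of one annotated site set.

    Percentages are stored unrounded; :func:`render_report` applies
    half-up rounding to two decimals for display.
    """

    total_sites: int
    n_genes_with_sites: int
    per_gene: pd.DataFrame  # gene, n_sites, edited_Cs, total_Cs, pct_C_edited
    position_counts: tuple[int, int, int]
    position_percentages: tuple[float, float, float] | None
    total_codons: int
    codons_single: int
    codons_double: int
    n_synonymous: int
    n_nonsynonymous: int
    aa_change_tally: "pd.Series[int]"
    edited_codon_tally: "pd.Series[int]"
    top_k: int
    top_k_share_pct: float | None
    hydrophobic_gain_pct: float | None
    start_gains: list[str]
    stop_gains: list[str]
    corr_edited_vs_total_c: tuple[float, float] | None
    corr_edited_vs_length: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "total_sites": self.total_sites,
            "n_genes_with_sites": self.n_genes_with_sites,
            "position_counts": list(self.position_counts),
            "position_percentages": (
                list(self.position_percentages)
                if self.position_percentages
                else None
            ),
            "total_codons": self.total_codons,
            "codons_single": self.codons_single,
            "codons_double": self.codons_double,
            "n_synonymous": self.n_synonymous,
            "n_nonsynonymous": self.n_nonsynonymous,
            "aa_change_tally": self.aa_change_tally.to_dict(),
            "edited_codon_tally": self.edited_codon_tally.to_dict(),
            "top_k": self.top_k,
            "top_k_share_pct": self.top_k_share_pct,
            "hydrophobic_gain_pct": self.hydrophobic_gain_pct,
            "start_gains": self.start_gains,
            "stop_gains": self.stop_gains,
            "corr_edited_vs_total_c": (
                list(self.corr_edited_vs_total_c)
                if self.corr_edited_vs_total_c
                else None
            ),
            "corr_edited_vs_length": (
                list(self.corr_edited_vs_length)
                if self.corr_edited_vs_length
                else None
            ),
        }


def position_percentages(counts: Sequence[int]) -> tuple[float, float, float] | None:
    """Percentage of sites at codon positions 1/2/3; None for an empty set."""
    total = sum(counts)
    if total == 0:
        return None
    return tuple(100.0 * c / total for c in counts)  # type: ignore[return-value]


def codon_bookkeeping(n_single: int, n_double: int) -> tuple[int, int]:
    """(total codons, total sites) implied by single/double-site codon counts."""
    return n_single + n_double, n_single + 2 * n_double


def top_k_share(tally: Mapping[str, int] | pd.Series, k: int = 3) -> float | None:
    """Percentage of all edited codons accounted for by the top-k codons."""
    s = pd.Series(tally, dtype=float).sort_values(ascending=False)
    total = s.sum()
    if total == 0:
        return None
    return float(100.0 * s.iloc[:k].sum() / total)


def pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via the t transform.

    ``t = r * sqrt(n - 2) / sqrt(1 - r**2)`` with ``n - 2`` degrees of
    freedom.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    ``t = r * sqrt(n - 2) / sqrt(1 - r**2)`` against a t distribution
    with ``n - 2`` degrees of freedom.  Requires n >= 3 and non-zero
    variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.dot(dx, dy) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    return r, pvalue_from_r(r, n)


def per_gene_c_fraction(
    annotated_sites: pd.DataFrame, panel: Mapping[str, ORFRecord]
) -> pd.DataFrame:
    """Distinct edited C positions per gene against the gene's C content.

    Columns: ``gene, n_sites, edited_Cs, total_Cs, length,
    pct_C_edited`` (NaN when a gene has no Cs).  Every panel gene
    appears, including those without sites.
    """
    rows = []
    by_gene = (
        annotated_sites.groupby("gene")["pos"].nunique()
        if not annotated_sites.empty
        else pd.Series(dtype=int)
    )
    n_rows = (
        annotated_sites.groupby("gene")["pos"].size()
        if not annotated_sites.empty
        else pd.Series(dtype=int)
    )
    for gene, orf in panel.items():
        total_c = len(c_positions(orf))
        edited = int(by_gene.get(gene, 0))
        pct = 100.0 * edited / total_c if total_c > 0 else float("nan")
        rows.append(
            dict(
                gene=gene,
                n_sites=int(n_rows.get(gene, 0)),
                edited_Cs=edited,
                total_Cs=total_c,
                length=orf.length,
                pct_C_edited=pct,
            )
        )
    return pd.DataFrame(rows)


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def summarize(
    annotated_sites: pd.DataFrame,
    consequences: pd.DataFrame,
    panel: Mapping[str, ORFRecord],
    top_k: int = 3,
) -> SummaryReport:
    """Compute the full :class:`SummaryReport` for one annotated site set.

    Correlations are taken over genes carrying at least one site (the
    natural per-gene sample for an editing survey); they are omitted
    (None) when fewer than three such genes exist or a vector is
    constant.  An empty site set yields a valid all-zero report.
    """
    total_sites = len(annotated_sites)
    pos_counts = [0, 0, 0]
    if total_sites:
        vc = annotated_sites["codon_pos"].value_counts()
        for p in (1, 2, 3):
            pos_counts[p - 1] = int(vc.get(p, 0))

    if consequences.empty:
        n_single = n_double = 0
        n_syn = n_nonsyn = 0
        aa_tally = pd.Series(dtype=int)
        codon_tally = pd.Series(dtype=int)
        hydrophobic_pct = None
        start_gains: list[str] = []
        stop_gains: list[str] = []
    else:
        n_edits = consequences["positions_in_codon"].str.count(",") + 1
        n_single = int((n_edits == 1).sum())
        n_double = int((n_edits == 2).sum())
        n_nonsyn = int(consequences["is_nonsynonymous"].sum())
        n_syn = len(consequences) - n_nonsyn
        nonsyn = consequences[consequences["is_nonsynonymous"]]
        aa_tally = (
            nonsyn["aa_change"].value_counts().sort_values(ascending=False)
        )
        codon_tally = (
            consequences["edited_codon"].map(_to_rna).value_counts()
            .sort_values(ascending=False)
        )
        if len(nonsyn):
            gained_hydrophobic = nonsyn["edited_aa"].isin(HYDROPHOBIC_AA)
            hydrophobic_pct = float(100.0 * gained_hydrophobic.mean())
        else:
            hydrophobic_pct = None
        start_gains = [
            f"{r.gene}-codon{r.codon_index}"
            for r in consequences[consequences["effect"] == "start_gain"].itertuples()
        ]
        stop_gains = [
            f"{r.gene}-codon{r.codon_index}"
            for r in consequences[consequences["effect"] == "stop_gain"].itertuples()
        ]

    per_gene = per_gene_c_fraction(annotated_sites, panel)
    with_sites = per_gene[per_gene["edited_Cs"] > 0]

    corr_c = corr_len = None
    if len(with_sites) >= 3:
        try:
            corr_c = pearson(with_sites["total_Cs"], with_sites["edited_Cs"])
        except ValueError:
            corr_c = None
        try:
            corr_len = pearson(with_sites["length"], with_sites["edited_Cs"])
        except ValueError:
            corr_len = None

    return SummaryReport(
        total_sites=total_sites,
        n_genes_with_sites=len(with_sites),
        per_gene=per_gene,
        position_counts=tuple(pos_counts),  # type: ignore[arg-type]
        position_percentages=position_percentages(pos_counts),
        total_codons=n_single + n_double,
        codons_single=n_single,
        codons_double=n_double,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
        aa_change_tally=aa_tally,
        edited_codon_tally=codon_tally,
        top_k=top_k,
        top_k_share_pct=top_k_share(codon_tally, top_k) if len(codon_tally) else None,
        hydrophobic_gain_pct=hydrophobic_pct,
        start_gains=start_gains,
        stop_gains=stop_gains,
        corr_edited_vs_total_c=corr_c,
        corr_edited_vs_length=corr_len,
    )


def alignment_column_report(
    aligned_fasta: str | Path, reference_id: str, position: int
) -> tuple[dict[str, str], float]:
    """Residues of one alignment column, addressed by an ungapped
    position in a chosen reference row.

    Returns ``(column, identity_fraction)`` where ``column`` maps each
    sequence id to its residue (``-`` for a gap) and the identity
    fraction is the share of non-gap residues equal to the reference
    residue (gapped rows are excluded from the denominator).
    """
    rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(aligned_fasta), "fasta")}
    if reference_id not in rows:
        raise ValueError(f"reference row {reference_id!r} not in alignment")
    ref = rows[reference_id]
    seen = 0
    col_idx = None
    for i, ch in enumerate(ref):
        if ch != "-":
            seen += 1
            if seen == position:
                col_idx = i
                break
    if col_idx is None:
        raise ValueError(
            f"ungapped position {position} beyond reference length {seen}"
        )
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    column = {sid: seq[col_idx] for sid, seq in rows.items()}
    ref_res = column[reference_id]
    non_gap = [res for res in column.values() if res != "-"]
    fraction = sum(res == ref_res for res in non_gap) / len(non_gap)
    return column, fraction


def render_report(report: SummaryReport) -> str:
    """Plain-text rendering of a :class:`SummaryReport`."""
    lines: list[str] = []
    lines.append("== Editing-site summary ==")
    lines.append(f"total sites: {report.total_sites} "
                 f"in {report.n_genes_with_sites} genes")
    lines.append("")
    lines.append("-- Codon-position distribution --")
    if report.position_percentages:
        for p, (n, pct) in enumerate(
            zip(report.position_counts, report.position_percentages), start=1
        ):
            lines.append(f"position {p}: {n} ({round_half_up(pct):.2f}%)")
    else:
        lines.append("n/a (no sites)")
    lines.append("")
    lines.append("-- Codon bookkeeping --")
    lines.append(
        f"codons altered: {report.total_codons} "
        f"({report.codons_single} with one site, "
        f"{report.codons_double} with two)"
    )
    lines.append(
        f"synonymous: {report.n_synonymous}  "
        f"nonsynonymous: {report.n_nonsynonymous}"
    )
    lines.append("")
    lines.append("-- Top amino-acid changes --")
    for label, n in report.aa_change_tally.head(10).items():
        lines.append(f"{label}: {n}")
    lines.append("")
    lines.append("-- Top edited codons --")
    for codon, n in report.edited_codon_tally.head(10).items():
        lines.append(f"{codon}: {n}")
    if report.top_k_share_pct is not None:
        lines.append(
            f"top {report.top_k} codons account for "
            f"{round_half_up(report.top_k_share_pct):.2f}% of edited codons"
        )
    if report.hydrophobic_gain_pct is not None:
        lines.append(
            f"nonsynonymous changes producing a hydrophobic residue: "
            f"{round_half_up(report.hydrophobic_gain_pct):.2f}%"
        )
    lines.append("")
    lines.append("-- Recoding events --")
    lines.append("start gains: " + (", ".join(report.start_gains) or "none"))
    lines.append("stop gains: " + (", ".join(report.stop_gains) or "none"))
    lines.append("")
    lines.append("-- Per-gene correlations (genes with sites) --")
    for name, corr in (
        ("edited Cs vs total Cs", report.corr_edited_vs_total_c),
        ("edited Cs vs gene length", report.corr_edited_vs_length),
    ):
        if corr is None:
            lines.append(f"{name}: n/a")
        else:
            r, p = corr
            lines.append(f"{name}: r = {r:.3f}, p = {p:.3f}")
    return "\n".join(lines) + "\n"
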