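"""Codon-level consequences of accepted C-to-U editing sites.

Sites sharing a codon are annotated together: the edited codon applies
every C→T edit in that codon simultaneously, so a codon with two sites
yields one consequence record.  Effects are classified as synonymous,
nonsynonymous, stop gain (edited codon becomes a terminator) or start
gain (ACG recoded to AUG); start/stop gains take precedence in the
single ``effect`` field, while a separate ``is_nonsynonymous`` flag
records whether the encoded amino acid changed so that syn/nonsyn
tallies over codons remain straightforward.

Amino-acid changes are labelled with three-letter names ("Ser-to-Leu");
hydropathy transitions use a fixed hydrophobic set (positive
Kyte-Doolittle hydropathy: A, C, F, I, L, M, V), configurable via the
``hydrophobic`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Mapping

import pandas as pd

from .reference import ORFRecord, codon_context, translate_codon

#: Residues with positive Kyte-Doolittle hydropathy.
HYDROPHOBIC_AA: FrozenSet[str] = frozenset("ACFILMV")

AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stop",
}

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NONSYNONYMOUS = "nonsynonymous"
EFFECT_STOP_GAIN = "stop_gain"
EFFECT_START_GAIN = "start_gain"

CONSEQUENCE_COLUMNS = [
    "gene",
    "codon_index",
    "positions_in_codon",
    "ref_codon",
    "edited_codon",
    "ref_aa",
    "edited_aa",
    "effect",
    "is_nonsynonymous",
    "aa_change",
    "hydropathy",
]


class ConsequenceError(ValueError):
    """Raised when a site or codon pair is inconsistent with C→T editing."""


def classify_effect(ref_codon: str, edited_codon: str,
                    codon_index: int | None = None) -> str:
    """Effect label for a ref/edited codon pair.

    The edited codon must be reachable from the reference codon by C→T
    substitutions only.  ``codon_index`` is accepted for interface
    symmetry; a start gain is any ACG→ATG recoding (organellar editing
    can create initiation codons away from the annotated first codon).
    """
    ref = ref_codon.upper().replace("U", "T")
    edited = edited_codon.upper().replace("U", "T")
    diffs = [(a, b) for a, b in zip(ref, edited) if a != b]
    if not diffs or any((a, b) != ("C", "T") for a, b in diffs):
        raise ConsequenceError(
            f"{ref_codon}->{edited_codon} is not a pure C-to-T edit"
        )
    ref_aa = translate_codon(ref)
    edited_aa = translate_codon(edited)
    if ref == "ACG" and edited == "ATG":
        return EFFECT_START_GAIN
    if edited_aa == "*" and ref_aa != "*":
        return EFFECT_STOP_GAIN
    if ref_aa == edited_aa:
        return EFFECT_SYNONYMOUS
    return EFFECT_NONSYNONYMOUS


def hydropathy_transition(
    ref_aa: str, edited_aa: str, hydrophobic: FrozenSet[str] = HYDROPHOBIC_AA
) -> str:
    """Hydropathy class change of an amino-acid substitution.

    Returns one of ``hydrophilic->hydrophobic``,
    ``hydrophobic->hydrophilic``, ``unchanged-class`` or ``n/a`` (when
    either side is a stop).
    """
    if ref_aa == "*" or edited_aa == "*":
        return "n/a"
    ref_hydro = ref_aa in hydrophobic
    ed_hydro = edited_aa in hydrophobic
    if ref_hydro == ed_hydro:
        return "unchanged-class"
    return "hydrophilic->hydrophobic" if ed_hydro else "hydrophobic->hydrophilic"


def _aa_change_label(ref_aa: str, edited_aa: str, effect: str) -> str:
    if effect == EFFECT_SYNONYMOUS:
        return "syn"
    return f"{AA_THREE[ref_aa]}-to-{AA_THREE[edited_aa]}"


def annotate_sites(
    accepted: pd.DataFrame,
    panel: Mapping[str, ORFRecord],
    hydrophobic: FrozenSet[str] = HYDROPHOBIC_AA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate accepted sites with their codon consequences.

    Parameters
    ----------
    accepted:
        Site table with at least ``gene`` and ``pos`` columns (1-based
        CDS coordinates of C positions).
    panel:
        Gene id → :class:`~mitoedit.reference.ORFRecord`.

    Returns
    -------
    (consequences, annotated_sites):
        ``consequences`` has one row per distinct edited codon (columns
        :data:`CONSEQUENCE_COLUMNS`, with ``positions_in_codon`` a
        comma-joined string of codon offsets).  ``annotated_sites`` is
        the input with codon context and consequence fields joined back
        per site.
    """
    cons_rows: list[dict] = []
    site_rows: list[dict] = []

    if accepted.empty:
        cons = pd.DataFrame(columns=CONSEQUENCE_COLUMNS)
        annotated = accepted.copy()
        for col in ("codon_index", "codon_pos", "ref_codon", "edited_codon",
                    "ref_aa", "edited_aa", "effect", "aa_change", "hydropathy"):
            annotated[col] = pd.Series(dtype=object)
        return cons, annotated

    work = accepted.copy()
    ctx_cols = {"codon_index": [], "codon_pos": [], "ref_codon": []}
    for r in work.itertuples(index=False):
        if r.gene not in panel:
            raise ConsequenceError(f"unknown gene {r.gene!r}")
        orf = panel[r.gene]
        if orf.base_at(int(r.pos)) != "C":
            raise ConsequenceError(
                f"{r.gene}:{r.pos}: site at non-C reference base "
                f"{orf.base_at(int(r.pos))!r} (upstream corruption)"
            )
        ctx = codon_context(orf, int(r.pos))
        ctx_cols["codon_index"].append(ctx.codon_index)
        ctx_cols["codon_pos"].append(ctx.codon_position)
        ctx_cols["ref_codon"].append(ctx.ref_codon)
    for k, v in ctx_cols.items():
        work[k] = v

    for (gene, ci), grp in work.groupby(["gene", "codon_index"], sort=True):
        orf = panel[gene]
        ref_codon = grp["ref_codon"].iloc[0]
        offsets = sorted(int(cp) for cp in grp["codon_pos"])
        edited = list(ref_codon)
        for off in offsets:
            edited[off - 1] = "T"
        edited_codon = "".join(edited)
        ref_aa = translate_codon(ref_codon)
        edited_aa = translate_codon(edited_codon)
        effect = classify_effect(ref_codon, edited_codon, int(ci))
        label = _aa_change_label(ref_aa, edited_aa, effect)
        hydro = (
            hydropathy_transition(ref_aa, edited_aa, hydrophobic)
            if effect != EFFECT_SYNONYMOUS
            else "unchanged-class"
        )
        cons_rows.append(
            dict(
                gene=gene,
                codon_index=int(ci),
                positions_in_codon=",".join(str(o) for o in offsets),
                ref_codon=ref_codon,
                edited_codon=edited_codon,
                ref_aa=ref_aa,
                edited_aa=edited_aa,
                effect=effect,
                is_nonsynonymous=ref_aa != edited_aa,
                aa_change=label,
                hydropathy=hydro,
            )
        )
        for r in grp.itertuples(index=False):
            d = r._asdict()
            d.update(
                edited_codon=edited_codon,
                ref_aa=ref_aa,
                edited_aa=edited_aa,
                effect=effect,
                aa_change=label,
                hydropathy=hydro,
                is_pseudogene=orf.is_pseudogene,
            )
            site_rows.append(d)

    consequences = pd.DataFrame(cons_rows, columns=CONSEQUENCE_COLUMNS)
    annotated = pd.DataFrame(site_rows)
    annotated = annotated.sort_values(["gene", "pos"]).reset_index(drop=True)
    return consequences, annotated
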