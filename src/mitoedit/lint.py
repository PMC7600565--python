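"""Linting of externally claimed editing-site annotations.

Curated databases occasionally place an editing site one nucleotide away
from its true position, which changes the implied codon arithmetic (the
claimed amino-acid change then cannot be produced by a C→T edit at the
claimed position).  :func:`lint_annotations` checks each claim against
the reference panel: a claim is *confirmed* when a C→T edit at the
claimed position yields the claimed change; otherwise the neighbouring
positions and the other Cs of the claimed codon are tested and the
unique position that explains the claim is reported as a correction.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .consequence import AA_THREE
from .reference import ORFRecord, codon_context, translate_codon

_THREE_TO_ONE = {three.upper(): one for one, three in AA_THREE.items()}

STATUS_CONFIRMED = "confirmed"
STATUS_CORRECTED = "off_by_one"
STATUS_RELOCATED = "relocated"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNEXPLAINABLE = "unexplainable"

REPORT_COLUMNS = [
    "gene",
    "claimed_pos",
    "claimed_change",
    "status",
    "corrected_pos",
    "detail",
]


def normalize_aa(symbol: str) -> str:
    """Accept one-letter codes, three-letter names, or ``Stop``/``*``."""
    s = symbol.strip()
    if len(s) == 1 and (s.upper() in AA_THREE or s == "*"):
        return s if s == "*" else s.upper()
    if s.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[s.upper()]
    raise ValueError(f"unrecognised amino-acid symbol {symbol!r}")


def _explains(orf: ORFRecord, p: int, ref_aa: str, edited_aa: str) -> bool:
    """Does a C→T edit at CDS position ``p`` produce ref_aa → edited_aa?"""
    if not 1 <= p <= orf.length or orf.base_at(p) != "C":
        return False
    try:
        ctx = codon_context(orf, p)
    except Exception:
        return False
    if translate_codon(ctx.ref_codon) != ref_aa:
        return False
    edited = list(ctx.ref_codon)
    edited[ctx.codon_position - 1] = "T"
    return translate_codon("".join(edited)) == edited_aa


def lint_annotations(
    claims: pd.DataFrame, panel: Mapping[str, ORFRecord]
) -> pd.DataFrame:
    """Check claimed (gene, position, AA change) annotations.

    ``claims`` columns: ``gene, pos, claimed_ref_aa, claimed_edited_aa``
    (one- or three-letter amino-acid symbols).  Every claim produces a
    report row; nothing raises for a wrong claim.  Candidate corrections
    are the positions one nucleotide up/downstream of the claim plus the
    other C positions of the claimed codon.
    """
    rows: list[dict] = []
    for r in claims.itertuples(index=False):
        gene = r.gene
        p = int(r.pos)
        change = f"{r.claimed_ref_aa}-to-{r.claimed_edited_aa}"
        base = dict(gene=gene, claimed_pos=p, claimed_change=change)
        if gene not in panel:
            rows.append(dict(**base, status=STATUS_UNEXPLAINABLE,
                             corrected_pos=None, detail="unknown gene"))
            continue
        orf = panel[gene]
        if not 1 <= p <= orf.length:
            rows.append(dict(**base, status=STATUS_UNEXPLAINABLE,
                             corrected_pos=None,
                             detail=f"position outside CDS 1..{orf.length}"))
            continue
        try:
            ref_aa = normalize_aa(r.claimed_ref_aa)
            edited_aa = normalize_aa(r.claimed_edited_aa)
        except ValueError as exc:
            rows.append(dict(**base, status=STATUS_UNEXPLAINABLE,
                             corrected_pos=None, detail=str(exc)))
            continue

        if _explains(orf, p, ref_aa, edited_aa):
            rows.append(dict(**base, status=STATUS_CONFIRMED,
                             corrected_pos=p, detail="claim reproduced"))
            continue

        candidates: list[int] = []
        for q in (p - 1, p + 1):
            if 1 <= q <= orf.length:
                candidates.append(q)
        try:
            ctx = codon_context(orf, p)
            start = (ctx.codon_index - 1) * 3
            for off in range(3):
                q = start + off + 1
                if q != p and q not in candidates and orf.base_at(q) == "C":
                    candidates.append(q)
        except Exception:
            pass

        matches = [q for q in candidates if _explains(orf, q, ref_aa, edited_aa)]
        if len(matches) == 1:
            q = matches[0]
            status = STATUS_CORRECTED if abs(q - p) == 1 else STATUS_RELOCATED
            rows.append(dict(**base, status=status, corrected_pos=q,
                             detail=f"claim explained by C-to-T edit at {gene}-{q}"))
        elif len(matches) > 1:
            rows.append(dict(**base, status=STATUS_AMBIGUOUS, corrected_pos=None,
                             detail="multiple candidate positions: "
                             + ", ".join(str(q) for q in matches)))
        else:
            rows.append(dict(**base, status=STATUS_UNEXPLAINABLE,
                             corrected_pos=None,
                             detail="no nearby C-to-T edit produces the "
                             "claimed change"))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
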