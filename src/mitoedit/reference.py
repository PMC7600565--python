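"""ORF panels, the CDS coordinate frame, and codon arithmetic.

Everything downstream of this module speaks one coordinate system:
1-based nucleotide positions *within the CDS* of a sense-strand ORF.
This matches the conventional site naming for organellar editing events
(e.g. ``atp1-1292`` is the 1292nd nucleotide of the atp1 coding sequence).

ORF references may be stored with fixed-length flanking sequence on each
side (added to improve read coverage near the CDS ends during mapping);
:func:`load_orf_panel` trims the flanks so that the in-memory record
holds the bare CDS, and CDS position ``p`` corresponds to offset
``p + flank_len`` in the flanked FASTA entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

STOP_SYMBOL = "*"


class PanelError(ValueError):
    """Raised for malformed ORF panels or out-of-frame coordinate requests."""


@dataclass(frozen=True)
class ORFRecord:
    """One sense-strand coding sequence (or pseudogene in its nominal frame).

    Parameters
    ----------
    gene_id:
        Short identifier, e.g. ``"atp1"``.
    cds_seq:
        DNA string over ``{A, C, G, T}``; the CDS only, flanks removed.
    flank_len:
        Number of flanking nucleotides per side that were present in the
        source FASTA (kept for coordinate bookkeeping; the flanks
        themselves are not stored).
    is_pseudogene:
        Pseudogenes are carried through every stage and annotated in
        their nominal reading frame, but flagged in outputs.
    """

    gene_id: str
    cds_seq: str
    flank_len: int = 0
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise PanelError("empty gene id")
        if self.flank_len < 0:
            raise PanelError(f"{self.gene_id}: negative flank_len {self.flank_len}")
        if len(self.cds_seq) < 3:
            raise PanelError(
                f"{self.gene_id}: CDS must be at least one codon, got "
                f"{len(self.cds_seq)} nt"
            )
        for i, base in enumerate(self.cds_seq):
            if base not in VALID_BASES:
                raise PanelError(
                    f"{self.gene_id}: invalid base {base!r} at CDS position {i + 1} "
                    "(only A/C/G/T accepted; ambiguity codes are rejected)"
                )

    @property
    def length(self) -> int:
        """CDS length in nucleotides (flanks excluded)."""
        return len(self.cds_seq)

    @property
    def n_codons(self) -> int:
        """Number of complete codons in the CDS."""
        return self.length // 3

    def base_at(self, p: int) -> str:
        """Reference base at 1-based CDS position ``p``."""
        if not 1 <= p <= self.length:
            raise PanelError(
                f"{self.gene_id}: position {p} outside CDS 1..{self.length}"
            )
        return self.cds_seq[p - 1]


@dataclass(frozen=True)
class CodonContext:
    """Codon coordinates of a single CDS nucleotide position.

    ``codon_index`` is 1-based; ``codon_position`` is 1, 2 or 3 within
    the codon; ``ref_codon`` is the unedited codon as stored (DNA).
    """

    codon_index: int
    codon_position: int
    ref_codon: str


def codon_context(orf: ORFRecord, p: int) -> CodonContext:
    """Map a 1-based CDS position to its codon.

    ``codon_index = ceil(p / 3)`` and ``codon_position = ((p - 1) mod 3) + 1``.
    A position falling in a trailing partial codon (CDS length not a
    multiple of 3) is an error rather than a guess.
    """
    if not 1 <= p <= orf.length:
        raise PanelError(
            f"{orf.gene_id}: position {p} outside CDS 1..{orf.length}"
        )
    codon_index = (p - 1) // 3 + 1
    codon_position = (p - 1) % 3 + 1
    if codon_index * 3 > orf.length:
        raise PanelError(
            f"{orf.gene_id}: position {p} lies in a trailing partial codon "
            f"(CDS length {orf.length}, remainder {orf.length % 3} nt)"
        )
    start = (codon_index - 1) * 3
    return CodonContext(codon_index, codon_position, orf.cds_seq[start : start + 3])


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code.

    Plant mitochondria use the standard code, so C-to-U recoding effects
    (e.g. ACG→AUG start gain, CAA→UAA stop gain) follow directly from
    it.  ``U`` and ``T`` are treated identically; stop codons return
    ``"*"``.  IUPAC ambiguity codes are rejected.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    dna = codon.upper().replace("U", "T")
    if any(b not in VALID_BASES for b in dna):
        raise ValueError(f"codon {codon!r} contains non-ACGT/U characters")
    return str(Seq(dna).translate())


def c_positions(orf: ORFRecord) -> list[int]:
    """1-based CDS positions whose reference base is C, in increasing order.

    The length of this list is the per-gene denominator for the
    percentage of edited Cs.
    """
    return [i + 1 for i, base in enumerate(orf.cds_seq) if base == "C"]


def load_orf_panel(
    fasta_source: str | Path,
    flank_len: int = 0,
    pseudogene_ids: Iterable[str] = (),
) -> dict[str, ORFRecord]:
    """Load a multi-FASTA ORF panel, trimming ``flank_len`` nt from each end.

    The FASTA header token up to the first whitespace is the gene id.
    Sequences are upper-cased; each must be strictly longer than
    ``2 * flank_len`` so that a non-empty CDS remains.  Duplicate gene
    ids and non-ACGT characters are fatal.
    """
    if flank_len < 0:
        raise PanelError(f"negative flank_len {flank_len}")
    pseudo = set(pseudogene_ids)
    panel: dict[str, ORFRecord] = {}
    seen_at: dict[str, int] = {}
    for idx, rec in enumerate(SeqIO.parse(str(fasta_source), "fasta"), start=1):
        gene_id = rec.id
        if gene_id in panel:
            raise PanelError(
                f"duplicate gene id {gene_id!r}: FASTA records "
                f"{seen_at[gene_id]} and {idx}"
            )
        seq = str(rec.seq).upper()
        if len(seq) <= 2 * flank_len:
            raise PanelError(
                f"{gene_id}: sequence length {len(seq)} does not exceed "
                f"2 x flank_len ({2 * flank_len}); no CDS would remain"
            )
        for i, base in enumerate(seq):
            if base not in VALID_BASES:
                raise PanelError(
                    f"{gene_id}: invalid base {base!r} at sequence position {i + 1}"
                )
        cds = seq[flank_len : len(seq) - flank_len] if flank_len else seq
        panel[gene_id] = ORFRecord(
            gene_id=gene_id,
            cds_seq=cds,
            flank_len=flank_len,
            is_pseudogene=gene_id in pseudo,
        )
        seen_at[gene_id] = idx
    if not panel:
        raise PanelError(f"no FASTA records found in {fasta_source}")
    return panel
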