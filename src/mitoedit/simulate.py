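"""Synthetic ORF panels with planted C-to-U editing sites.

The generator emulates the data a plant-mitochondrial editing study
produces: ORF-like coding sequences (ATG start, stop-free interior,
realistic GC content), a truth table of planted C-to-U sites with
editing levels, and the two measurement channels used to detect them —

* per-position nucleotide counts as emitted by a base counter applied
  to aligned RNA-seq reads (binomial sampling around a target coverage,
  with a uniform per-base sequencing-error rate), including flanking
  positions outside the CDS so that flank trimming is exercised; and
* per-replicate Sanger chromatogram C/T peak-height pairs with
  multiplicative noise.

Planted sites fall into four classes so that both directions of
cross-method discordance are represented:

``real``
    level in ``level_range`` (default [0.10, 1.0]), visible to both
    channels — should be called and accepted.
``subthreshold``
    level in ``decoy_level_range`` (default [0.01, 0.09]) — should be
    rejected by both channels.
``rnaseq_only``
    level above threshold in RNA-seq but invisible to Sanger — should
    end up rejected for lack of Sanger support.
``borderline``
    Sanger level just above threshold but RNA-seq level just below it
    (around 9%) — should be retained by the reconciliation tolerance.

Every output is reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ORFRecord, translate_codon

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

TRUTH_COLUMNS = [
    "gene",
    "pos",
    "true_level",
    "rnaseq_level",
    "sanger_level",
    "in_rnaseq",
    "in_sanger",
    "site_class",
]

#: Peak height, in arbitrary fluorescence units, of a fully populated
#: chromatogram channel before noise.
BASE_PEAK_HEIGHT = 100.0


@dataclass
class SimulationConfig:
    """Knobs for one simulated dataset.

    Defaults describe a mid-sized organellar panel: ~10 ORFs of 0.3-1.5 kb
    at 44% GC, editing levels spanning the low/middle/high/extremely-high
    range, read coverage of a few hundred per position (real studies see
    tens to thousands), a 0.2% per-base sequencing-error rate, and three
    Sanger replicates with 5% relative peak noise.
    """

    n_orfs: int = 10
    length_range: tuple[int, int] = (300, 1500)  # nt, rounded to codons
    gc_fraction: float = 0.44
    #: exact number of "real" sites per ORF; None defers to ``site_rate``
    sites_per_orf: int | None = None
    #: probability that a C position carries a real site (gives the
    #: per-gene variability real panels show); used when sites_per_orf
    #: is None
    site_rate: float = 0.05
    level_range: tuple[float, float] = (0.10, 1.0)
    decoy_level_range: tuple[float, float] = (0.01, 0.09)
    decoys_per_orf: int = 2
    rnaseq_only_per_orf: int = 1
    borderline_per_orf: int = 1
    borderline_sanger_range: tuple[float, float] = (0.11, 0.15)
    borderline_rnaseq_range: tuple[float, float] = (0.085, 0.095)
    mean_coverage: float = 500.0
    coverage_dispersion: float = 0.1  # gamma-Poisson; 0 = pure Poisson
    sequencing_error_rate: float = 0.002
    sanger_noise_sd: float = 0.05
    n_replicates: int = 3
    n_samples: int = 2
    flank_len: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_orf is None and self.site_rate is None:
            raise ValueError("one of sites_per_orf or site_rate is required")
        if self.site_rate is not None and not 0.0 <= self.site_rate <= 1.0:
            raise ValueError(f"site_rate must be in [0, 1], got {self.site_rate}")
        for name in ("gc_fraction", "sequencing_error_rate", "sanger_noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("level_range", "decoy_level_range",
                     "borderline_sanger_range", "borderline_rnaseq_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered pair in [0, 1]")
        if self.mean_coverage < 1:
            raise ValueError("mean_coverage must be >= 1")
        if self.n_orfs < 1 or self.n_replicates < 1 or self.n_samples < 1:
            raise ValueError("n_orfs, n_replicates and n_samples must be >= 1")
        if self.length_range[0] < 9 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be an ordered pair with min >= 9")
        if self.random_seed is None:
            raise ValueError("random_seed is mandatory")


@dataclass
class SimulatedPanel:
    """A generated ORF panel plus its ground truth.

    ``records`` hold the bare CDS; ``flanked_seqs`` the same sequences
    with ``flank_len`` random nucleotides on each side, as written to
    FASTA; ``truth`` the planted-site table (one row per site).
    """

    records: dict[str, ORFRecord]
    flanked_seqs: dict[str, str]
    truth: pd.DataFrame
    config: SimulationConfig

    def fasta_text(self) -> str:
        lines = []
        for gene, seq in self.flanked_seqs.items():
            lines.append(f">{gene}")
            for i in range(0, len(seq), 70):
                lines.append(seq[i : i + 70])
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        """Write panel FASTA and truth TSV into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "panel.fasta").write_text(self.fasta_text())
        truth = self.truth.copy()
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                     float_format="%.6g")


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams so each op is deterministic in isolation
    return np.random.default_rng(np.random.SeedSequence([config.random_seed, stream]))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _gc_given_no_stop(gc: float) -> float:
    """Expected GC fraction of a random codon conditioned on not being a
    stop codon, for iid bases with GC fraction ``gc``."""
    w = (1.0 - gc) / 2.0  # P(A) = P(T)
    s = gc / 2.0          # P(C) = P(G)
    p_taa = w * w * w
    p_tag = w * w * s
    p_tga = w * s * w
    p_stop = p_taa + p_tag + p_tga
    # GC letters in the excluded codons: TAA has 0, TAG and TGA have 1
    return (3.0 * gc - (p_tag + p_tga)) / (3.0 * (1.0 - p_stop))


def _interior_gc(target: float) -> float:
    """Base-level GC that yields ``target`` GC after stop-codon exclusion
    (bisection; exclusion slightly enriches GC otherwise)."""
    if target <= 0.0 or target >= 1.0:
        return target
    lo, hi = 1e-6, 1.0 - 1e-6
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _gc_given_no_stop(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG start, stop-free interior, TAA terminator."""
    gc_adj = _interior_gc(gc)
    middle = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(_random_bases(rng, 3, gc_adj))
            if codon not in STOP_CODONS:
                break
        middle.append(codon)
    return "ATG" + "".join(middle) + "TAA"


def _edit_safe(cds: str, edited: dict[int, bool], pos: int) -> bool:
    """Would planting a C→T edit at ``pos`` keep the interior stop-free?

    Checks the codon containing ``pos`` with all currently planted edits
    in that codon plus the candidate applied.
    """
    ci = (pos - 1) // 3
    codon = list(cds[ci * 3 : ci * 3 + 3])
    for off in range(3):
        p = ci * 3 + off + 1
        if p == pos or edited.get(p):
            codon[off] = "T"
    if ci == len(cds) // 3 - 1:  # terminator codon carries no C anyway
        return True
    return "".join(codon) not in STOP_CODONS


def generate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate ORFs and plant editing sites with known levels.

    Raises ``ValueError`` when an ORF does not contain enough C
    positions for the requested number of sites.
    """
    rng = _rng_for(config, 0)
    records: dict[str, ORFRecord] = {}
    flanked: dict[str, str] = {}
    truth_rows: list[dict] = []

    lo_codons = config.length_range[0] // 3
    hi_codons = config.length_range[1] // 3

    for k in range(config.n_orfs):
        gene = f"orf{k + 1:02d}"
        n_codons = int(rng.integers(lo_codons, hi_codons + 1))
        cds = _random_cds(rng, n_codons, config.gc_fraction)

        # candidate C positions; the terminator codon (TAA) has none
        candidates = [i + 1 for i, b in enumerate(cds) if b == "C"]
        rng.shuffle(candidates)

        if config.sites_per_orf is not None:
            n_real = config.sites_per_orf
        else:
            n_real = int(rng.binomial(len(candidates), config.site_rate))
        wanted = (
            [("real",) for _ in range(n_real)]
            + [("subthreshold",) for _ in range(config.decoys_per_orf)]
            + [("rnaseq_only",) for _ in range(config.rnaseq_only_per_orf)]
            + [("borderline",) for _ in range(config.borderline_per_orf)]
        )
        n_wanted = len(wanted)
        if n_wanted > len(candidates):
            raise ValueError(
                f"{gene}: requested {n_wanted} sites but CDS has only "
                f"{len(candidates)} C positions"
            )

        edited: dict[int, bool] = {}
        placed = 0
        it = iter(candidates)
        while placed < n_wanted:
            try:
                pos = next(it)
            except StopIteration:
                raise ValueError(
                    f"{gene}: could not place {n_wanted} sites without "
                    "creating an in-frame stop; reduce sites_per_orf"
                ) from None
            if not _edit_safe(cds, edited, pos):
                continue
            (site_class,) = wanted[placed]
            if site_class == "real":
                level = float(rng.uniform(*config.level_range))
                row = dict(true_level=level, rnaseq_level=level,
                           sanger_level=level, in_rnaseq=True, in_sanger=True)
            elif site_class == "subthreshold":
                level = float(rng.uniform(*config.decoy_level_range))
                row = dict(true_level=level, rnaseq_level=level,
                           sanger_level=level, in_rnaseq=True, in_sanger=True)
            elif site_class == "rnaseq_only":
                level = float(rng.uniform(*config.level_range))
                row = dict(true_level=level, rnaseq_level=level,
                           sanger_level=0.0, in_rnaseq=True, in_sanger=False)
            else:  # borderline: Sanger-positive, RNA-seq just under threshold
                s = float(rng.uniform(*config.borderline_sanger_range))
                r = float(rng.uniform(*config.borderline_rnaseq_range))
                row = dict(true_level=s, rnaseq_level=r,
                           sanger_level=s, in_rnaseq=True, in_sanger=True)
            truth_rows.append(dict(gene=gene, pos=pos, site_class=site_class, **row))
            edited[pos] = True
            placed += 1

        left = "".join(_random_bases(rng, config.flank_len, config.gc_fraction))
        right = "".join(_random_bases(rng, config.flank_len, config.gc_fraction))
        records[gene] = ORFRecord(gene_id=gene, cds_seq=cds,
                                  flank_len=config.flank_len)
        flanked[gene] = left + cds + right

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if not truth.empty:
        truth = truth.sort_values(["gene", "pos"]).reset_index(drop=True)
    return SimulatedPanel(records=records, flanked_seqs=flanked,
                          truth=truth, config=config)


def _multinomial_columns(
    rng: np.random.Generator, depth: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Vectorised multinomial draws via sequential conditional binomials.

    ``probs`` has one row per position and 4 columns (A, C, G, T
    probabilities); returns an integer array of the same shape.
    """
    n = depth.astype(np.int64)
    out = np.zeros((len(n), 4), dtype=np.int64)
    remaining = n.copy()
    tail = probs.sum(axis=1)
    for j in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(tail > 0, probs[:, j] / tail, 0.0)
        cond = np.clip(cond, 0.0, 1.0)
        out[:, j] = rng.binomial(remaining, cond)
        remaining -= out[:, j]
        tail -= probs[:, j]
    out[:, 3] = remaining
    return out


def _base_probs(ref: np.ndarray, level: np.ndarray, error: float) -> np.ndarray:
    """Per-position A/C/G/T read probabilities under the error model.

    A fraction ``level`` of molecules carry T instead of the reference
    base (non-zero only at planted C sites); every molecule's base is
    read correctly with probability ``1 - error`` and as each of the
    other three bases with probability ``error / 3``.
    """
    bases = "ACGT"
    n = len(ref)
    probs = np.full((n, 4), error / 3.0)
    ref_idx = np.searchsorted(np.array(list(bases)), ref)
    t_idx = 3
    rows = np.arange(n)
    # unedited molecules
    probs[rows, ref_idx] += (1.0 - level) * (1.0 - error) - (1.0 - level) * (error / 3.0)
    # edited molecules (base T)
    probs[rows, t_idx] += level * (1.0 - error) - level * (error / 3.0)
    # the += above started from a uniform error/3 allocated per molecule class
    return probs


def simulate_rnaseq_counts(
    panel: SimulatedPanel, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Per-position nucleotide counts for each simulated RNA-seq sample.

    Output columns: ``sample_id, gene, pos, ref, a_count, c_count,
    g_count, t_count``.  Flank positions are emitted with coordinates
    ``<= 0`` (5' flank) or ``> length`` (3' flank) so that downstream
    trimming is exercised.  Positions that draw depth 0 are omitted.
    """
    config = config or panel.config
    rng = _rng_for(config, 1)
    truth = panel.truth
    per_sample_mean = config.mean_coverage / config.n_samples

    frames = []
    for gene, rec in panel.records.items():
        seq = panel.flanked_seqs[gene]
        flank = config.flank_len
        positions = np.arange(1 - flank, rec.length + flank + 1)
        ref = np.array(list(seq))
        level = np.zeros(len(positions))
        if not truth.empty:
            sub = truth[(truth["gene"] == gene) & truth["in_rnaseq"]]
            for pos, lvl in zip(sub["pos"], sub["rnaseq_level"]):
                level[pos - 1 + flank] = lvl
        probs = _base_probs(ref, level, config.sequencing_error_rate)
        for s in range(1, config.n_samples + 1):
            if config.coverage_dispersion > 0:
                shape = 1.0 / config.coverage_dispersion
                g = rng.gamma(shape, config.coverage_dispersion, size=len(positions))
                depth = rng.poisson(per_sample_mean * g)
            else:
                depth = rng.poisson(per_sample_mean, size=len(positions))
            counts = _multinomial_columns(rng, depth, probs)
            keep = depth > 0
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": f"S{s}",
                        "gene": gene,
                        "pos": positions[keep],
                        "ref": ref[keep],
                        "a_count": counts[keep, 0],
                        "c_count": counts[keep, 1],
                        "g_count": counts[keep, 2],
                        "t_count": counts[keep, 3],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_sanger_replicates(
    panel: SimulatedPanel, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """C/T peak-height pairs for every C position, per replicate.

    Ideal peaks are ``BASE_PEAK_HEIGHT * (1 - level)`` for C and
    ``BASE_PEAK_HEIGHT * level`` for T, each perturbed by an independent
    multiplicative factor ``max(0, 1 + N(0, sanger_noise_sd))``.  Sites
    invisible to the Sanger channel emit level 0.  Output columns:
    ``gene, pos, replicate, peak_c, peak_t``.
    """
    config = config or panel.config
    rng = _rng_for(config, 2)
    truth = panel.truth

    frames = []
    for gene, rec in panel.records.items():
        cpos = np.array([i + 1 for i, b in enumerate(rec.cds_seq) if b == "C"],
                        dtype=np.int64)
        if len(cpos) == 0:
            continue
        level = np.zeros(len(cpos))
        if not truth.empty:
            sub = truth[(truth["gene"] == gene) & truth["in_sanger"]]
            lookup = dict(zip(sub["pos"], sub["sanger_level"]))
            for i, p in enumerate(cpos):
                if int(p) in lookup:
                    level[i] = lookup[int(p)]
        for rep in range(1, config.n_replicates + 1):
            m_c = np.maximum(0.0, 1.0 + rng.normal(0.0, config.sanger_noise_sd,
                                                   size=len(cpos)))
            m_t = np.maximum(0.0, 1.0 + rng.normal(0.0, config.sanger_noise_sd,
                                                   size=len(cpos)))
            peak_c = BASE_PEAK_HEIGHT * (1.0 - level) * m_c
            peak_t = BASE_PEAK_HEIGHT * level * m_t
            # a truncated multiplier can zero out the only populated channel;
            # restore the ideal height there so peak_c + peak_t > 0 holds
            dead = (peak_c + peak_t) <= 0.0
            if dead.any():
                peak_c[dead] = BASE_PEAK_HEIGHT * (1.0 - level[dead])
                peak_t[dead] = BASE_PEAK_HEIGHT * level[dead]
            frames.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "pos": cpos,
                        "replicate": rep,
                        "peak_c": peak_c,
                        "peak_t": peak_t,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[SimulatedPanel, pd.DataFrame, pd.DataFrame]:
    """Generate a full dataset (panel + truth, counts, Sanger peaks).

    When ``outdir`` is given, writes ``panel.fasta``, ``truth.tsv``,
    ``counts.tsv`` and ``sanger.tsv`` there.
    """
    panel = generate_panel(config)
    counts = simulate_rnaseq_counts(panel, config)
    sanger = simulate_sanger_replicates(panel, config)
    if outdir is not None:
        outdir = Path(outdir)
        panel.write(outdir)
        counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        sanger.to_csv(outdir / "sanger.tsv", sep="\t", index=False,
                      float_format="%.6g")
    return panel, counts, sanger
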