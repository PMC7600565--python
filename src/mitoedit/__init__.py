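"""mitoedit: C-to-U RNA editing detection and annotation for plant
mitochondrial ORFs.

The pipeline stages are importable per module:

* :mod:`mitoedit.reference` — ORF panels, codon arithmetic, genetic code
* :mod:`mitoedit.simulate` — synthetic panels with planted editing sites
* :mod:`mitoedit.calling` — RNA-seq and Sanger site calling, reconciliation
* :mod:`mitoedit.consequence` — codon-level consequence annotation
* :mod:`mitoedit.summary` — catalogue statistics and correlations
* :mod:`mitoedit.io` / :mod:`mitoedit.gff` / :mod:`mitoedit.cli` — formats
  and the command-line interface
"""

from importlib import resources

import pandas as pd

from .calling import (
    ReconcilePolicy,
    accepted_sites,
    call_rnaseq,
    call_sanger,
    categorize_level,
    merge_samples,
    reconcile,
    rnaseq_level,
    sanger_level,
)
from .consequence import annotate_sites, classify_effect, hydropathy_transition
from .reference import (
    CodonContext,
    ORFRecord,
    c_positions,
    codon_context,
    load_orf_panel,
    translate_codon,
)
from .simulate import SimulationConfig, generate_panel, simulate_dataset
from .summary import SummaryReport, pearson, per_gene_c_fraction, summarize

__version__ = "0.1.0"

__all__ = [
    "CodonContext",
    "ORFRecord",
    "ReconcilePolicy",
    "SimulationConfig",
    "SummaryReport",
    "accepted_sites",
    "annotate_sites",
    "c_positions",
    "call_rnaseq",
    "call_sanger",
    "categorize_level",
    "classify_effect",
    "codon_context",
    "generate_panel",
    "hydropathy_transition",
    "load_orf_panel",
    "merge_samples",
    "pearson",
    "per_gene_c_fraction",
    "reconcile",
    "rice_mito_site_counts",
    "rnaseq_level",
    "sanger_level",
    "simulate_dataset",
    "summarize",
    "translate_codon",
]


def rice_mito_site_counts() -> pd.DataFrame:
    """Reported C-to-U editing-site counts per rice mitochondrial ORF.

    Bundled reference catalogue (Nipponbare; 37 edited ORFs) with
    columns ``gene`` and ``n_sites``.
    """
    with resources.files("mitoedit").joinpath(
        "data/rice_mito_site_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
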