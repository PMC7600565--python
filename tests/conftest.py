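"""Shared fixtures: simulated datasets run through the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from mitoedit import calling, consequence, summary
from mitoedit.calling import ReconcilePolicy
from mitoedit.simulate import SimulatedPanel, SimulationConfig, simulate_dataset


@dataclass
class PipelineRun:
    """One simulated dataset pushed through call → reconcile → annotate."""

    panel_sim: SimulatedPanel
    counts: pd.DataFrame
    sanger: pd.DataFrame
    levels: pd.DataFrame
    sanger_calls: pd.DataFrame
    final: pd.DataFrame
    accepted: pd.DataFrame
    consequences: pd.DataFrame
    annotated: pd.DataFrame
    report: summary.SummaryReport


def run_pipeline(
    config: SimulationConfig, policy: ReconcilePolicy = ReconcilePolicy()
) -> PipelineRun:
    panel_sim, counts, sanger = simulate_dataset(config)
    panel = panel_sim.records
    merged = calling.merge_samples(
        [g for _, g in counts.groupby("sample_id", sort=True)]
    )
    _, levels = calling.call_rnaseq(merged, panel, policy.threshold)
    sanger_calls = calling.call_sanger(sanger, panel, policy.threshold)
    final = calling.reconcile(sanger_calls, levels, policy)
    accepted = calling.accepted_sites(final)
    cons, annotated = consequence.annotate_sites(accepted, panel)
    report = summary.summarize(annotated, cons, panel)
    return PipelineRun(panel_sim, counts, sanger, levels, sanger_calls,
                       final, accepted, cons, annotated, report)


def noiseless_expected_keys(run: "PipelineRun") -> set[tuple[str, int]]:
    """Independent oracle for a noise-free run.

    Expected accepted sites are the planted Sanger-visible sites with
    level >= 0.10 whose RNA-seq T fraction — recomputed directly from
    the raw count table, independently of the calling module — is at
    least 0.08 (threshold minus the borderline tolerance) or absent.
    """
    truth = run.panel_sim.truth
    counts = run.counts
    pooled = counts.groupby(["gene", "pos"])[
        ["a_count", "c_count", "g_count", "t_count"]
    ].sum()
    expected = set()
    for r in truth.itertuples():
        if not (r.in_sanger and r.sanger_level >= 0.10):
            continue
        key = (r.gene, r.pos)
        if key in pooled.index:
            row = pooled.loc[key]
            frac = row["t_count"] / row.sum()
            if frac < 0.08:
                continue
        expected.add(key)
    return expected


NOISELESS_CONFIG = SimulationConfig(
    n_orfs=6,
    sequencing_error_rate=0.0,
    sanger_noise_sd=0.0,
    coverage_dispersion=0.0,
    mean_coverage=400.0,
    random_seed=11,
)

DEFAULT_CONFIG = SimulationConfig(random_seed=5)


@pytest.fixture(scope="session")
def noiseless_run() -> PipelineRun:
    """Noise-free simulation: calls must match the planted truth exactly."""
    return run_pipeline(NOISELESS_CONFIG)


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    """Simulation under default (noisy) study-like conditions."""
    return run_pipeline(DEFAULT_CONFIG)
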