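"""End-to-end simulation studies: generate a synthetic reference, build
the model, simulate mixtures of known composition, deconvolute, score.

These runners back both the test suite and ``scripts/acceptance.py``.
The default study uses a 50,000-CpG reference with 500 planted
differential CpGs per type/subtype, sample noise sd 0.02, 10 sorted
samples per population and 100 simulated mixtures — a scale at which the
whole study runs in well under a coffee break on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CellTypeHierarchy, ProportionSet, default_hierarchy
from .decon import DeconvolutionResult, build_model, deconvolute_full
from .evaluation import RecoveryReport, per_type_metrics
from .sim import (
    SyntheticReference,
    SyntheticTruth,
    compose_mixture,
    default_simulation_spec,
    generate_synthetic_reference,
    simulate_truth,
)

__all__ = ["StudyResult", "run_study", "default_study_model"]


@dataclass
class StudyResult:
    """One simulated data set deconvoluted and scored."""

    truth: SyntheticTruth
    result: DeconvolutionResult
    main_report: RecoveryReport | None
    subtype_report: RecoveryReport


def default_study_model(
    seed: int,
    n_cpgs: int = 50_000,
    n_diff_per_type: int = 500,
    noise_sd: float = 0.02,
    n_samples_per_type: int = 10,
    hierarchy: CellTypeHierarchy | None = None,
    **panel_sizes,
):
    """Synthetic reference plus fitted bases/panels; returns
    (reference, hierarchy, bases, panels)."""
    hierarchy = hierarchy or default_hierarchy()
    ref = generate_synthetic_reference(
        n_cpgs,
        hierarchy,
        n_diff_per_type=n_diff_per_type,
        n_samples_per_type=n_samples_per_type,
        noise_sd=noise_sd,
        seed=seed,
    )
    bases, panels = build_model(ref.samples, hierarchy, **panel_sizes)
    return ref, hierarchy, bases, panels


def run_study(
    reference: SyntheticReference,
    hierarchy: CellTypeHierarchy,
    bases,
    panels,
    seed: int,
    n_mixtures: int = 100,
    mode: str = "whole_blood",
) -> StudyResult:
    """Simulate ``n_mixtures`` samples in the given mode, deconvolute
    them with the given model, and score recovery per type/subtype."""
    rng = np.random.default_rng(seed)
    spec = default_simulation_spec(n_samples=n_mixtures, seed=seed, mode=mode)
    truth = simulate_truth(spec, rng, hierarchy)
    mixtures = compose_mixture(truth, reference.samples, rng, hierarchy)
    result = deconvolute_full(mixtures, bases, panels, hierarchy)
    est = result.table
    merged_truth = truth.merged_subtypes(hierarchy)
    if mode == "whole_blood":
        main_report = per_type_metrics(est, truth.main)
        subtype_report = per_type_metrics(est, merged_truth)
    else:
        parent = mode.split(":", 1)[1]
        cols = hierarchy.reported_subtypes(parent)
        main_report = None
        subtype_report = per_type_metrics(
            est, merged_truth.select_types(cols, check_sum=False)
        )
    return StudyResult(
        truth=truth,
        result=result,
        main_report=main_report,
        subtype_report=subtype_report,
    )
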