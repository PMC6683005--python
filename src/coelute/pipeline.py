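"""End-to-end orchestration: fits -> consensus -> clustering -> reports.

Thin glue over the stage modules, used by both the command-line interface
and programmatic callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coelute import classification, complex_clustering, evaluation
from coelute.complex_clustering import ClusteringResult, choose_cut
from coelute.io_profiles import AnnotationTable, KnownComplex, ProfileMatrix
from coelute.peak_fitting import FitResult, fit_matrix
from coelute.replicate_consensus import ReproducibleEntry, build_entries, concatenate_features
from coelute.sec_calibration import CalibrationModel, apparent_mass

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    entries: list[ReproducibleEntry]
    features: np.ndarray
    clustering: ClusteringResult
    diagnostics: dict
    chosen_k: int
    classifications: pd.DataFrame
    benchmark: pd.DataFrame | None = None
    m_app: dict[str, float] = field(default_factory=dict)


def default_cuts(n_entries: int, lo: int = 20, hi: int = 600, step: int = 10) -> list[int]:
    """The standard cut sweep (20..600 by 10), clipped to the entry count."""
    return [k for k in range(lo, hi + 1, step) if k <= n_entries - 1] or [
        max(2, n_entries // 2)
    ]


def run_pipeline(
    matrices: dict[tuple[str, int], ProfileMatrix],
    annotations: AnnotationTable,
    calibration: CalibrationModel,
    complexes: list[KnownComplex] | None = None,
    max_peaks: int = 4,
    min_separation: float = 4.0,
    sec_tolerance: float = 2.0,
    iex_tolerance: float = 4.0,
    linkage_method: str = "ward",
    cuts: list[int] | None = None,
    fixed_k: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> PipelineResult:
    """Run fitting, consensus, clustering and classification on four matrices.

    ``matrices`` must be keyed by ('SEC'|'IEX', 1|2).  The reporting cut is
    ``fixed_k`` when given, otherwise chosen from the within-cluster
    distance diagnostics over ``cuts``.
    """
    fits: dict[tuple[str, int], dict[str, FitResult]] = {}
    for key, m in matrices.items():
        logger.info("fitting %s replicate %d (%d proteins)", key[0], key[1], m.n_proteins)
        fits[key] = fit_matrix(
            m, max_peaks=max_peaks, min_separation=min_separation, n_starts=n_starts, seed=seed
        )

    entries = build_entries(
        (fits[("SEC", 1)], fits[("SEC", 2)]),
        (fits[("IEX", 1)], fits[("IEX", 2)]),
        n_sec_fractions=matrices[("SEC", 1)].n_fractions,
        n_iex_fractions=matrices[("IEX", 1)].n_fractions,
        sec_tolerance=sec_tolerance,
        iex_tolerance=iex_tolerance,
    )
    if len(entries) < 2:
        raise RuntimeError("fewer than 2 reproducible entries; nothing to cluster")
    for e in entries:
        e.sec_m_app_kda, _ = apparent_mass(e.sec_peak.mu, calibration)
    m_app = {e.entry_id: e.sec_m_app_kda for e in entries}

    features = concatenate_features(entries)
    clustering = complex_clustering.build_dendrogram(
        features, entry_ids=[e.entry_id for e in entries], linkage_method=linkage_method
    )
    if cuts is None:
        cuts = default_cuts(len(entries))
    diagnostics = complex_clustering.within_cluster_distance_sweep(
        features, clustering, cuts
    )
    chosen_k = fixed_k if fixed_k is not None else choose_cut(diagnostics)
    assignments = complex_clustering.cut_dendrogram(clustering, chosen_k)

    classifications = classification.classify_entries(
        assignments, m_app, annotations, multi_peak={e.entry_id: e.multi_peak for e in entries}
    )
    benchmark = None
    if complexes:
        benchmark = evaluation.benchmark_sweep(clustering, complexes, [chosen_k])
    return PipelineResult(
        entries=entries,
        features=features,
        clustering=clustering,
        diagnostics=diagnostics,
        chosen_k=chosen_k,
        classifications=classifications,
        benchmark=benchmark,
        m_app=m_app,
    )
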