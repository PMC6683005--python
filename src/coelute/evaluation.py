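"""Benchmarking and validation of clustering-based complex predictions.

Intactness of a known complex is the largest fraction of its detected
subunits that co-occupy a single cluster; purity is the fraction of that
best cluster occupied by subunits.  Chance co-elution is probed two ways:
the percentage of multi-protein clusters mixing compartments, and a
permutation test drawing uniform random cluster IDs for externally
reported interacting pairs.  Condition comparison (e.g. mutant vs wild
type) reports per-protein peak shifts and apparent-mass changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coelute.io_profiles import AnnotationTable, KnownComplex
from coelute.peak_fitting import FitResult
from coelute.replicate_consensus import match_peaks
from coelute.sec_calibration import CalibrationModel, apparent_mass


@dataclass
class ComplexBenchmark:
    name: str
    k: int
    n_detected: int
    intactness: float
    purity: float
    best_cluster: int


def _best_cluster(assignments: dict[str, int], complex_: KnownComplex):
    """(best cluster id, subunit count there, detected subunits, cluster sizes).

    The best cluster holds the maximum number of detected subunits; ties
    break toward the smaller cluster (higher purity), then the lower ID.
    Sub-entries ('_peakN') count via their base protein.
    """
    base = {e: e.rsplit("_peak", 1)[0] if "_peak" in e else e for e in assignments}
    cluster_sizes: dict[int, int] = {}
    subunit_counts: dict[int, set[str]] = {}
    detected: set[str] = set()
    for entry, cid in assignments.items():
        cluster_sizes[cid] = cluster_sizes.get(cid, 0) + 1
        if base[entry] in complex_.subunits:
            detected.add(base[entry])
            subunit_counts.setdefault(cid, set()).add(base[entry])
    if not detected:
        return None, 0, detected, cluster_sizes
    best = min(
        subunit_counts,
        key=lambda c: (-len(subunit_counts[c]), cluster_sizes[c], c),
    )
    return best, len(subunit_counts[best]), detected, cluster_sizes


def intactness(assignments: dict[str, int], complex_: KnownComplex) -> float:
    """Max subunits co-clustered / subunits detected in the clustering."""
    best, n_best, detected, _ = _best_cluster(assignments, complex_)
    if not detected:
        return float("nan")
    return n_best / len(detected)


def purity(assignments: dict[str, int], complex_: KnownComplex) -> float:
    """Subunits in the best cluster / total proteins in that cluster."""
    best, n_best, detected, sizes = _best_cluster(assignments, complex_)
    if not detected:
        return float("nan")
    return n_best / sizes[best]


def benchmark_sweep(
    result,
    complexes: list[KnownComplex],
    k_values: list[int],
) -> pd.DataFrame:
    """Intactness and purity for every complex at every cut."""
    from coelute.complex_clustering import cut_dendrogram

    rows = []
    for k in k_values:
        if not 1 <= k <= result.n_entries:
            continue
        assign = cut_dendrogram(result, k)
        for c in complexes:
            best, n_best, detected, sizes = _best_cluster(assign, c)
            rows.append(
                ComplexBenchmark(
                    name=c.name,
                    k=k,
                    n_detected=len(detected),
                    intactness=n_best / len(detected) if detected else float("nan"),
                    purity=n_best / sizes[best] if detected else float("nan"),
                    best_cluster=best if best is not None else -1,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def compartment_mixing_fdr(
    assignments: dict[str, int],
    annotations: AnnotationTable,
) -> float:
    """Percent of multi-protein clusters whose members share one compartment.

    Compartment mixing in a cluster flags chance co-elution, since
    proteins confined to distinct compartments cannot physically
    interact; the single-compartment percentage is therefore an empirical
    ceiling on the false-discovery rate of co-elution.
    """
    clusters: dict[int, set[str]] = {}
    for entry, cid in assignments.items():
        base = entry.rsplit("_peak", 1)[0] if "_peak" in entry else entry
        if base not in annotations:
            raise KeyError(f"entry {entry!r} has no compartment annotation")
        clusters.setdefault(cid, set()).add(annotations.compartment(base))
    multi = [labels for cid, labels in clusters.items() if _cluster_size(assignments, cid) >= 2]
    if not multi:
        return float("nan")
    single = sum(1 for labels in multi if len(labels) == 1)
    return 100.0 * single / len(multi)


def _cluster_size(assignments: dict[str, int], cid: int) -> int:
    return sum(1 for c in assignments.values() if c == cid)


def compartment_mixing_sweep(
    result, annotations: AnnotationTable, k_values: list[int]
) -> pd.DataFrame:
    from coelute.complex_clustering import cut_dendrogram

    rows = []
    for k in k_values:
        if not 1 <= k <= result.n_entries:
            continue
        rows.append(
            {"k": k, "single_compartment_pct": compartment_mixing_fdr(cut_dendrogram(result, k), annotations)}
        )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceTest:
    """Permutation test of external interacting pairs vs cluster IDs."""

    n_pairs: int
    observed_matches: int
    k: int
    tolerance: int
    n_sim: int
    seed: int
    fraction_zero: float  # fraction of null simulations with 0 matched pairs
    max_matches: int  # max matched pairs over all simulations
    p_value: float  # empirical P(null matches >= observed)

    @property
    def expected_fraction_zero(self) -> float:
        """Closed-form (1 - q)^P with q the per-pair match probability."""
        return (1.0 - _match_probability(self.k, self.tolerance)) ** self.n_pairs


def _match_probability(k: int, d: int) -> float:
    """P(|a - b| <= d) for independent uniform a, b on 1..k."""
    d = min(d, k - 1)
    favorable = k + 2 * sum(k - i for i in range(1, d + 1))
    return favorable / k**2


def pair_concordance_test(
    pairs: list[tuple[str, str]],
    assignments: dict[str, int],
    k: int,
    tolerance: int = 2,
    n_sim: int = 10_000,
    seed: int = 0,
) -> ConcordanceTest:
    """Test whether reported interactors land in nearby clusters.

    Observed matches = pairs whose cluster IDs differ by <= ``tolerance``.
    Null: each protein appearing in the pairs draws an independent uniform
    cluster ID in 1..k; the match count is recomputed per simulation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    proteins = sorted({p for pair in pairs for p in pair})
    for p in proteins:
        if p not in assignments:
            raise KeyError(f"protein {p!r} has no cluster assignment")
    observed = sum(
        1 for a, b in pairs if abs(assignments[a] - assignments[b]) <= tolerance
    )
    rng = np.random.default_rng(seed)
    if pairs:
        idx = {p: i for i, p in enumerate(proteins)}
        ia = np.array([idx[a] for a, _ in pairs])
        ib = np.array([idx[b] for _, b in pairs])
        draws = rng.integers(1, k + 1, size=(n_sim, len(proteins)))
        match_counts = (np.abs(draws[:, ia] - draws[:, ib]) <= tolerance).sum(axis=1)
    else:
        match_counts = np.zeros(n_sim, dtype=int)
    return ConcordanceTest(
        n_pairs=len(pairs),
        observed_matches=observed,
        k=k,
        tolerance=tolerance,
        n_sim=n_sim,
        seed=seed,
        fraction_zero=float(np.mean(match_counts == 0)),
        max_matches=int(match_counts.max()),
        p_value=float(np.mean(match_counts >= observed)),
    )


def _primary_consensus_peak(fit1: FitResult, fit2: FitResult, tolerance: float):
    """Earliest-eluting reproducible peak across two replicates, or None."""
    matched = [m for m in match_peaks(fit1.peaks, fit2.peaks, tolerance) if m.matched]
    if not matched:
        return None
    return min((m.consensus for m in matched), key=lambda p: p.mu)


def compare_conditions(
    fits_a: tuple[dict[str, FitResult], dict[str, FitResult]],
    fits_b: tuple[dict[str, FitResult], dict[str, FitResult]],
    calibration: CalibrationModel | None = None,
    tolerance: float = 2.0,
) -> pd.DataFrame:
    """Per-protein primary-peak shift between two conditions (e.g. WT vs mutant).

    Both conditions must share the fraction grid and calibration.  Proteins
    lacking a reproducible peak in one condition are flagged as not
    detected there; deltas are reported only when detected in both.
    """
    proteins = sorted(set(fits_a[0]) & set(fits_a[1]) | set(fits_b[0]) & set(fits_b[1]))
    rows = []
    for p in proteins:
        peak_a = (
            _primary_consensus_peak(fits_a[0][p], fits_a[1][p], tolerance)
            if p in fits_a[0] and p in fits_a[1]
            else None
        )
        peak_b = (
            _primary_consensus_peak(fits_b[0][p], fits_b[1][p], tolerance)
            if p in fits_b[0] and p in fits_b[1]
            else None
        )
        row: dict = {"protein": p}
        for label, peak in (("a", peak_a), ("b", peak_b)):
            row[f"peak_fraction_{label}"] = peak.mu if peak else float("nan")
            if calibration is not None and peak is not None:
                row[f"m_app_{label}"], _ = apparent_mass(peak.mu, calibration)
            else:
                row[f"m_app_{label}"] = float("nan")
        if peak_a is None and peak_b is None:
            row["status"] = "not detected"
        elif peak_a is None:
            row["status"] = "not detected in A"
        elif peak_b is None:
            row["status"] = "not detected in B"
        else:
            row["status"] = "detected in both"
        if peak_a is not None and peak_b is not None:
            row["delta_fraction"] = peak_b.mu - peak_a.mu
            row["delta_m_app"] = row["m_app_b"] - row["m_app_a"]
        else:
            row["delta_fraction"] = float("nan")
            row["delta_m_app"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def filter_coip_hits(
    detections: pd.DataFrame,
    control: pd.DataFrame | pd.Series,
    min_test_detections: int = 2,
) -> set[str]:
    """Accept co-IP hits detected in >= 2 test pulldowns and never in control.

    ``detections``: boolean protein x test-replicate table; ``control``:
    boolean protein x control-column table (or a single Series).
    """
    if detections.shape[1] < 1:
        raise ValueError("need >= 1 test pulldown column")
    if isinstance(control, pd.Series):
        control = control.to_frame()
    if control.shape[1] < 1:
        raise ValueError("need >= 1 control column")
    test_counts = detections.astype(bool).sum(axis=1)
    in_control = control.reindex(detections.index).fillna(False).astype(bool).any(axis=1)
    accepted = detections.index[(test_counts >= min_test_detections) & ~in_control]
    return set(accepted)
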