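"""Replicate reproducibility filtering and feature-vector construction.

Peaks fitted independently in two biological replicates are matched
greedily by center distance; a peak is reproducible when its replicate
counterpart lies within the column-specific tolerance (2 fractions for
SEC, 4 for IEX).  Proteins reproducible on both columns become entries;
proteins with several reproducible IEX peaks are deconvoluted into one
entry per peak ("_peakN" suffix).  Every entry carries a normalized
concatenated feature vector over the four blocks SEC r1, SEC r2, IEX r1,
IEX r2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from coelute.peak_fitting import FitResult, GaussianPeak

logger = logging.getLogger(__name__)

SEC_TOLERANCE = 2.0
IEX_TOLERANCE = 4.0


@dataclass(frozen=True)
class PeakMatch:
    """A candidate pairing of one replicate-1 and one replicate-2 peak."""

    peak1: GaussianPeak | None
    peak2: GaussianPeak | None
    delta_mu: float
    matched: bool

    @property
    def consensus(self) -> GaussianPeak:
        if not self.matched:
            raise ValueError("no consensus for an unmatched peak")
        return GaussianPeak(
            mu=(self.peak1.mu + self.peak2.mu) / 2.0,
            sigma=(self.peak1.sigma + self.peak2.sigma) / 2.0,
            amplitude=(self.peak1.amplitude + self.peak2.amplitude) / 2.0,
        )


@dataclass
class ReproducibleEntry:
    """One clustering entry: a protein or a '_peakN' sub-entry of one.

    ``feature`` concatenates the four 0-1 normalized blocks; ``blocks``
    keeps them separate (keys 'SEC1', 'SEC2', 'IEX1', 'IEX2').
    """

    entry_id: str
    base_protein: str
    sec_peak: GaussianPeak
    iex_peak: GaussianPeak
    blocks: dict[str, np.ndarray]
    sec_m_app_kda: float = float("nan")
    multi_peak: bool = False

    @property
    def feature(self) -> np.ndarray:
        return np.concatenate(
            [self.blocks[k] for k in ("SEC1", "SEC2", "IEX1", "IEX2")]
        )


def match_peaks(
    peaks_rep1: list[GaussianPeak],
    peaks_rep2: list[GaussianPeak],
    tolerance: float,
) -> list[PeakMatch]:
    """Greedy one-to-one matching of replicate peaks by ascending |delta mu|.

    Candidate pairs are ranked by center distance (ties toward the earlier
    fraction); a pair is matched when |delta mu| <= tolerance and neither
    peak is already taken.  Unmatched peaks are returned flagged.
    """
    pairs = [
        (abs(p1.mu - p2.mu), min(p1.mu, p2.mu), i, j)
        for i, p1 in enumerate(peaks_rep1)
        for j, p2 in enumerate(peaks_rep2)
    ]
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    matches: list[PeakMatch] = []
    for d, _, i, j in pairs:
        if d > tolerance or i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matches.append(PeakMatch(peaks_rep1[i], peaks_rep2[j], d, True))
    for i, p1 in enumerate(peaks_rep1):
        if i not in used1:
            matches.append(PeakMatch(p1, None, float("inf"), False))
    for j, p2 in enumerate(peaks_rep2):
        if j not in used2:
            matches.append(PeakMatch(None, p2, float("inf"), False))
    matches.sort(key=lambda m: (m.peak1 or m.peak2).mu)
    return matches


def replicate_correlation(matrix_rep1, matrix_rep2) -> np.ndarray:
    """Fraction x fraction Pearson correlation between two replicates.

    Computed over the shared proteins; entry (i, j) correlates fraction
    i+1 of replicate 1 with fraction j+1 of replicate 2.
    """
    shared = sorted(set(matrix_rep1.proteins) & set(matrix_rep2.proteins))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared proteins; need >= 3")
    a = matrix_rep1.subset(shared).values
    b = matrix_rep2.subset(shared).values
    # column-standardize, guarding constant columns
    def _std(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=0)
        s = c.std(axis=0)
        s[s == 0] = np.nan
        return c / s

    return _std(a).T @ _std(b) / len(shared)


def normalize_block(vector: np.ndarray) -> np.ndarray:
    """Min-max scale a nonnegative vector to [0, 1].

    A constant vector maps to all zeros so that concatenated distances
    stay finite.
    """
    v = np.asarray(vector, dtype=float)
    if (v < 0).any():
        raise ValueError("normalize_block expects nonnegative input")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _reproducible_peaks(
    fit1: FitResult, fit2: FitResult, tolerance: float
) -> list[PeakMatch]:
    return [m for m in match_peaks(fit1.peaks, fit2.peaks, tolerance) if m.matched]


def _component_block(fit: FitResult, peak: GaussianPeak | None, n_fractions: int) -> np.ndarray:
    """A replicate's feature block for one entry.

    Gaussian fits contribute only the entry's own component evaluated on
    the fraction grid (sibling peaks zeroed); fallback fits contribute the
    raw profile.
    """
    if fit.fallback:
        return normalize_block(fit.fitted_curve)
    x = np.arange(1, n_fractions + 1, dtype=float)
    return normalize_block(peak(x))


def build_entries(
    sec_fits: tuple[dict[str, FitResult], dict[str, FitResult]],
    iex_fits: tuple[dict[str, FitResult], dict[str, FitResult]],
    n_sec_fractions: int,
    n_iex_fractions: int,
    sec_tolerance: float = SEC_TOLERANCE,
    iex_tolerance: float = IEX_TOLERANCE,
) -> list[ReproducibleEntry]:
    """Build reproducible clustering entries from per-replicate fits.

    A protein is retained only with >= 1 reproducible peak on BOTH columns.
    The SEC peak used for all of a protein's entries is its earliest
    eluting (largest apparent mass) reproducible SEC peak, duplicated
    across entries.  Each reproducible IEX peak yields one entry; when a
    protein has several, entries are suffixed '_peak1', '_peak2', ... in
    IEX elution order.
    """
    sec1, sec2 = sec_fits
    iex1, iex2 = iex_fits
    entries: list[ReproducibleEntry] = []
    dropped: dict[str, str] = {}
    proteins = sorted(set(sec1) & set(sec2) & set(iex1) & set(iex2))
    for protein in proteins:
        sec_matches = _reproducible_peaks(sec1[protein], sec2[protein], sec_tolerance)
        if not sec_matches:
            dropped[protein] = "no reproducible SEC peak"
            continue
        iex_matches = _reproducible_peaks(iex1[protein], iex2[protein], iex_tolerance)
        if not iex_matches:
            dropped[protein] = "no reproducible IEX peak"
            continue
        # earliest-eluting SEC consensus peak = largest apparent mass
        sec_match = min(sec_matches, key=lambda m: m.consensus.mu)
        sec_b1 = _component_block(sec1[protein], sec_match.peak1, n_sec_fractions)
        sec_b2 = _component_block(sec2[protein], sec_match.peak2, n_sec_fractions)
        iex_matches.sort(key=lambda m: m.consensus.mu)
        multi = len(iex_matches) > 1
        for n, im in enumerate(iex_matches, start=1):
            entry_id = f"{protein}_peak{n}" if multi else protein
            entries.append(
                ReproducibleEntry(
                    entry_id=entry_id,
                    base_protein=protein,
                    sec_peak=sec_match.consensus,
                    iex_peak=im.consensus,
                    blocks={
                        "SEC1": sec_b1,
                        "SEC2": sec_b2,
                        "IEX1": _component_block(iex1[protein], im.peak1, n_iex_fractions),
                        "IEX2": _component_block(iex2[protein], im.peak2, n_iex_fractions),
                    },
                    multi_peak=multi,
                )
            )
    for protein, reason in dropped.items():
        logger.debug("dropped %s: %s", protein, reason)
    if dropped:
        logger.info("reproducibility filter dropped %d proteins", len(dropped))
    return entries


def concatenate_features(
    entries: list[ReproducibleEntry],
    block_order: tuple[str, ...] = ("SEC1", "SEC2", "IEX1", "IEX2"),
) -> np.ndarray:
    """Stack entry feature vectors into an (entries x features) matrix."""
    if not entries:
        return np.empty((0, 0))
    lengths = {b: len(entries[0].blocks[b]) for b in block_order}
    for e in entries:
        for b in block_order:
            if len(e.blocks[b]) != lengths[b]:
                raise ValueError(
                    f"block {b!r} length mismatch for entry {e.entry_id!r}"
                )
    return np.vstack([np.concatenate([e.blocks[b] for b in block_order]) for e in entries])
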