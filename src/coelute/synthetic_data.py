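"""Synthetic replicated SEC+IEX experiments with planted complexes.

The generator emulates the statistical structure of a two-column,
two-replicate co-fractionation experiment: members of a planted complex
co-elute at a shared SEC fraction (derived from the complex's summed
monomer mass through the inverse mass calibration) and a shared IEX
fraction; per-replicate peak-location jitter, lognormal protein
abundances, multiplicative measurement noise, detection dropout,
non-reproducible contaminants and a configurable fraction of proteins
with a second IEX peak are all planted.  Full ground truth is emitted so
every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coelute.io_profiles import (
    AnnotationTable,
    CalibrationStandard,
    KnownComplex,
    ProfileMatrix,
    Separation,
)
from coelute.sec_calibration import CalibrationModel, fit_calibration, inverse_fraction

#: default SEC standards: 669-29 kDa spanning the column's usable range
DEFAULT_STANDARDS = (
    CalibrationStandard(669.0, 6.0),
    CalibrationStandard(440.0, 10.0),
    CalibrationStandard(158.0, 18.0),
    CalibrationStandard(66.0, 25.0),
    CalibrationStandard(29.0, 32.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the profiled experiment: 38 SEC and 65 IEX fractions,
    two biological replicates, Gaussian peaks ~1-2 fractions wide,
    sub-fraction replicate jitter (well inside the 2/4-fraction
    reproducibility tolerances), and 14% of proteins carrying a second
    IEX peak.
    """

    n_proteins: int = 200
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (2, 16)
    complex_size_mean: float = 4.0  # truncated-geometric mean; real complexes skew small
    n_sec_fractions: int = 38
    n_iex_fractions: int = 65
    sigma_range: tuple[float, float] = (0.8, 2.0)
    jitter_sd: float = 0.5
    sec_tolerance: float = 2.0
    iex_tolerance: float = 4.0
    multi_iex_peak_fraction: float = 0.14
    contaminant_fraction: float = 0.05
    dropout_rate: float = 0.02
    noise_cv: float = 0.1
    amplitude_scale: float = 1e6
    monomer_mass_logmean: float = np.log(45.0)  # kDa; typical soluble proteome
    monomer_mass_logsd: float = 0.45
    compartment_mix: dict = field(default_factory=lambda: {"cytosol": 0.65, "chloroplast": 0.35})
    iex_last_third_bias: float = 0.5  # downweight for late (high-salt) IEX fractions
    standards: tuple[CalibrationStandard, ...] = DEFAULT_STANDARDS
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.multi_iex_peak_fraction,
            self.contaminant_fraction,
            self.dropout_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_proteins < 1 or self.n_complexes < 0:
            raise ValueError("sizes must be positive")


@dataclass
class GroundTruth:
    """Planted truth: membership, peak centers per replicate, masses."""

    table: pd.DataFrame  # one row per protein
    complexes: list[KnownComplex]
    calibration: CalibrationModel


def _truncated_geometric_sizes(
    n: int, rng: np.random.Generator, lo: int, hi: int, mean: float
) -> np.ndarray:
    p = 1.0 / max(mean - lo + 1, 1.001)
    sizes = lo + rng.geometric(p, size=4 * n) - 1
    sizes = sizes[sizes <= hi][:n]
    while len(sizes) < n:  # pragma: no cover - extremely unlikely
        sizes = np.append(sizes, lo)
    return sizes


def _draw_iex_center(rng: np.random.Generator, n_frac: int, bias: float) -> float:
    """Uniform IEX center, downweighting the high-salt last third."""
    edge = 2.0
    while True:
        c = rng.uniform(edge, n_frac - edge)
        if c < 2 * n_frac / 3 or rng.uniform() < bias:
            return float(c)


def _profile(
    center: float,
    sigma: float,
    amplitude: float,
    n_frac: int,
    rng: np.random.Generator,
    noise_cv: float,
) -> np.ndarray:
    x = np.arange(1, n_frac + 1, dtype=float)
    curve = amplitude * np.exp(-((x - center) ** 2) / (2 * sigma**2))
    noisy = curve * np.exp(rng.normal(0.0, noise_cv, size=n_frac))
    # detection floor: label-free quantification misses faint tails
    noisy[noisy < 1e-3 * amplitude] = 0.0
    return np.clip(noisy, 0.0, None)


def generate_experiment(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, int], ProfileMatrix], AnnotationTable, list[KnownComplex], GroundTruth]:
    """Generate four profile matrices (SEC x2, IEX x2) with planted truth.

    Returns ``(matrices, annotations, complexes, truth)`` where
    ``matrices`` is keyed by ('SEC'|'IEX', replicate).  Deterministic for
    a fixed config (including its seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    calibration = fit_calibration(list(cfg.standards))
    frac_lo, frac_hi = calibration.fraction_range

    proteins = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    monomer_mass = np.exp(
        rng.normal(cfg.monomer_mass_logmean, cfg.monomer_mass_logsd, cfg.n_proteins)
    )

    # --- complex membership -------------------------------------------------
    sizes = _truncated_geometric_sizes(
        cfg.n_complexes, rng, *cfg.complex_size_range, cfg.complex_size_mean
    )
    membership = np.full(cfg.n_proteins, -1)
    cursor = 0
    for ci, size in enumerate(sizes):
        size = int(min(size, cfg.n_proteins - cursor))
        if size < 2:
            break
        membership[cursor : cursor + size] = ci
        cursor += size
    # remaining proteins are monomers; a slice of them are contaminants
    free = np.where(membership == -1)[0]
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_proteins))
    contaminant = np.zeros(cfg.n_proteins, dtype=bool)
    contaminant[free[:n_contam]] = True

    # --- compartments: whole complexes share one ----------------------------
    comp_labels = list(cfg.compartment_mix)
    comp_probs = np.array(list(cfg.compartment_mix.values()), dtype=float)
    comp_probs = comp_probs / comp_probs.sum()
    complex_comp = rng.choice(comp_labels, size=max(cfg.n_complexes, 1), p=comp_probs)
    compartment = np.array(
        [
            complex_comp[membership[i]] if membership[i] >= 0 else rng.choice(comp_labels, p=comp_probs)
            for i in range(cfg.n_proteins)
        ]
    )

    # --- true peak centers ---------------------------------------------------
    sec_center = np.empty(cfg.n_proteins)
    iex_center = np.empty(cfg.n_proteins)
    true_m_app = np.empty(cfg.n_proteins)
    for ci in range(len(sizes)):
        members = np.where(membership == ci)[0]
        if members.size == 0:
            continue
        mass = float(monomer_mass[members].sum())
        frac = inverse_fraction(mass, calibration)
        while not (frac_lo <= frac <= frac_hi):
            # complex mass outside the calibrated window: redraw the IEX/SEC
            # placement from the usable range rather than planting an
            # unobservable species
            frac = float(rng.uniform(frac_lo, frac_hi))
        sec_center[members] = frac
        iex_center[members] = _draw_iex_center(rng, cfg.n_iex_fractions, cfg.iex_last_third_bias)
        true_m_app[members] = 10 ** (calibration.slope * frac + calibration.intercept)
    for i in np.where(membership == -1)[0]:
        mass = float(np.clip(monomer_mass[i], 29.0, 669.0))
        sec_center[i] = inverse_fraction(mass, calibration)
        iex_center[i] = _draw_iex_center(rng, cfg.n_iex_fractions, cfg.iex_last_third_bias)
        true_m_app[i] = mass

    # second IEX peak for a configured fraction of non-contaminant proteins
    second_iex = np.full(cfg.n_proteins, np.nan)
    eligible = np.where(~contaminant)[0]
    n_multi = int(round(cfg.multi_iex_peak_fraction * cfg.n_proteins))
    multi_idx = rng.choice(eligible, size=min(n_multi, eligible.size), replace=False)
    for i in multi_idx:
        while True:
            c = _draw_iex_center(rng, cfg.n_iex_fractions, cfg.iex_last_third_bias)
            if abs(c - iex_center[i]) >= 8.0:  # resolvable second oligomeric state
                second_iex[i] = c
                break

    # --- per-replicate matrices ----------------------------------------------
    amplitude = cfg.amplitude_scale * rng.lognormal(0.0, 1.0, cfg.n_proteins)

    # each co-eluting species (a complex, or a monomeric protein) shifts as a
    # unit between runs: jitter is drawn per species per replicate, with only
    # small per-protein peak-measurement noise on top
    n_species = len(sizes) + cfg.n_proteins  # complex species + monomer species
    species_of = np.array(
        [membership[i] if membership[i] >= 0 else len(sizes) + i for i in range(cfg.n_proteins)]
    )
    peak_noise_sd = 0.15  # fraction units; residual peak-position error per protein
    # peak width is a species property, with mild per-protein variation
    sig_lo, sig_hi = cfg.sigma_range
    species_sigma_sec = rng.uniform(sig_lo, sig_hi, n_species)
    species_sigma_iex = rng.uniform(sig_lo, sig_hi, n_species)
    sigma_sec = np.clip(
        species_sigma_sec[species_of] + rng.normal(0.0, 0.08, cfg.n_proteins), sig_lo, sig_hi
    )
    sigma_iex = np.clip(
        species_sigma_iex[species_of] + rng.normal(0.0, 0.08, cfg.n_proteins), sig_lo, sig_hi
    )

    def jitter(tol: float) -> np.ndarray:
        # truncate per-replicate jitter so |rep1 - rep2| stays within the
        # reproducibility tolerance for genuine (non-contaminant) proteins
        j = np.clip(rng.normal(0.0, cfg.jitter_sd, n_species), -tol / 2, tol / 2)
        noise = np.clip(rng.normal(0.0, peak_noise_sd, cfg.n_proteins), -0.4, 0.4)
        return j[species_of] + noise

    matrices: dict[tuple[str, int], ProfileMatrix] = {}
    truth_centers: dict[str, np.ndarray] = {}
    dropout_mask = rng.uniform(size=(cfg.n_proteins, 4)) < cfg.dropout_rate

    for block_idx, (sep, rep, n_frac, centers, sigmas, tol) in enumerate(
        [
            ("SEC", 1, cfg.n_sec_fractions, sec_center, sigma_sec, cfg.sec_tolerance),
            ("SEC", 2, cfg.n_sec_fractions, sec_center, sigma_sec, cfg.sec_tolerance),
            ("IEX", 1, cfg.n_iex_fractions, iex_center, sigma_iex, cfg.iex_tolerance),
            ("IEX", 2, cfg.n_iex_fractions, iex_center, sigma_iex, cfg.iex_tolerance),
        ]
    ):
        jit = jitter(tol)
        rep_centers = centers + jit
        # contaminants elute irreproducibly: independent centers per replicate
        for i in np.where(contaminant)[0]:
            rep_centers[i] = rng.uniform(2.0, n_frac - 1.0)
        rep_centers = np.clip(rep_centers, 1.5, n_frac - 0.5)
        values = np.zeros((cfg.n_proteins, n_frac))
        for i in range(cfg.n_proteins):
            if dropout_mask[i, block_idx]:
                continue
            values[i] = _profile(
                rep_centers[i], sigmas[i], amplitude[i], n_frac, rng, cfg.noise_cv
            )
            if sep == "IEX" and not np.isnan(second_iex[i]):
                c2 = np.clip(second_iex[i] + jit[i], 1.5, n_frac - 0.5)
                values[i] += _profile(
                    c2, sigmas[i], 0.6 * amplitude[i], n_frac, rng, cfg.noise_cv
                )
        matrices[(sep, rep)] = ProfileMatrix(
            separation=Separation(sep), replicate=rep, proteins=list(proteins), values=values
        )
        truth_centers[f"{sep.lower()}_center_rep{rep}"] = rep_centers.copy()

    # --- annotations, complexes, truth ----------------------------------------
    ann = AnnotationTable(
        pd.DataFrame(
            {
                "compartment": compartment,
                "monomer_mass_kda": monomer_mass,
                "exclude_tm": np.zeros(cfg.n_proteins, dtype=bool),
            },
            index=pd.Index(proteins, name="protein_id"),
        )
    )
    complexes = [
        KnownComplex(
            f"complex{ci + 1:02d}",
            frozenset(proteins[i] for i in np.where(membership == ci)[0]),
        )
        for ci in range(len(sizes))
        if (membership == ci).sum() >= 2
    ]
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "protein_id": proteins,
                "complex": [
                    f"complex{m + 1:02d}" if m >= 0 else "" for m in membership
                ],
                "contaminant": contaminant,
                "compartment": compartment,
                "monomer_mass_kda": monomer_mass,
                "true_m_app_kda": true_m_app,
                "sec_center": sec_center,
                "iex_center": iex_center,
                "second_iex_center": second_iex,
                **truth_centers,
            }
        ),
        complexes=complexes,
        calibration=calibration,
    )
    return matrices, ann, complexes, truth
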