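"""Tabular I/O for co-fractionation profiling artifacts.

All on-disk formats are plain CSV/TSV.  A :class:`ProfileMatrix` holds the
protein x fraction abundance table for one separation x replicate; the
remaining types carry annotations (compartment, monomer mass,
transmembrane flag), known-complex membership, and SEC calibration
standards.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Separation(str, Enum):
    """Chromatographic separation type."""

    SEC = "SEC"
    IEX = "IEX"


class ProfileFormatError(ValueError):
    """Raised when an input table violates the expected layout."""


class ProfileParseError(ValueError):
    """Raised when a cell cannot be interpreted as a valid abundance."""


@dataclass
class ProfileMatrix:
    """Protein x fraction abundance matrix for one separation x replicate.

    Fractions are 1-based and contiguous; missing/not-detected values are
    stored as 0.  Abundances must be nonnegative.
    """

    separation: Separation
    replicate: int
    proteins: list[str]
    values: np.ndarray  # shape (n_proteins, n_fractions)
    fraction_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.separation = Separation(self.separation)
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_prot, n_frac = self.values.shape
        if len(self.proteins) != n_prot:
            raise ValueError("protein list length does not match values")
        if not self.fraction_ids:
            self.fraction_ids = list(range(1, n_frac + 1))
        if self.fraction_ids != list(range(1, n_frac + 1)):
            raise ValueError("fraction ids must be contiguous from 1")
        if len(set(self.proteins)) != len(self.proteins):
            dupes = pd.Series(self.proteins)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ProfileFormatError(f"duplicate protein IDs: {dupes[:5]}")
        if np.isnan(self.values).any():
            self.values = np.nan_to_num(self.values, nan=0.0)
        if (self.values < 0).any():
            r, c = np.argwhere(self.values < 0)[0]
            raise ProfileParseError(
                f"negative abundance for protein {self.proteins[r]!r} "
                f"in fraction {c + 1}"
            )

    @property
    def n_fractions(self) -> int:
        return self.values.shape[1]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def profile(self, protein: str) -> np.ndarray:
        """Elution profile (abundance per fraction) of one protein."""
        return self.values[self.proteins.index(protein)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.proteins, name="protein_id"),
            columns=[str(f) for f in self.fraction_ids],
        )

    def subset(self, proteins: Sequence[str]) -> "ProfileMatrix":
        idx = [self.proteins.index(p) for p in proteins]
        return ProfileMatrix(
            separation=self.separation,
            replicate=self.replicate,
            proteins=list(proteins),
            values=self.values[idx],
        )

    def write(self, path: str | Path, sep: str | None = None) -> None:
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class AnnotationTable:
    """Per-protein annotations: compartment, monomer mass, TM exclusion flag."""

    table: pd.DataFrame  # index protein_id; columns compartment, monomer_mass_kda, exclude_tm

    COMPARTMENTS = ("cytosol", "chloroplast", "other")

    def __post_init__(self) -> None:
        required = {"compartment", "monomer_mass_kda", "exclude_tm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ProfileFormatError(f"annotation table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ProfileFormatError("duplicate protein IDs in annotation table")
        bad = ~self.table["compartment"].isin(self.COMPARTMENTS)
        if bad.any():
            raise ProfileFormatError(
                f"unknown compartment labels: {sorted(self.table.loc[bad, 'compartment'].unique())}"
            )
        mass = self.table["monomer_mass_kda"]
        if ((mass <= 0) & mass.notna()).any():
            raise ProfileFormatError("monomer_mass_kda must be positive where present")
        self.table["exclude_tm"] = self.table["exclude_tm"].astype(bool)

    def __contains__(self, protein: str) -> bool:
        return protein in self.table.index

    def compartment(self, protein: str) -> str:
        return str(self.table.at[protein, "compartment"])

    def monomer_mass(self, protein: str) -> float:
        m = self.table.at[protein, "monomer_mass_kda"]
        return float(m) if pd.notna(m) else float("nan")

    def write(self, path: str | Path) -> None:
        self.table.rename_axis("protein_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class KnownComplex:
    """A reference complex: a name and >= 2 unique subunit protein IDs."""

    name: str
    subunits: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.subunits) < 2:
            raise ValueError(f"complex {self.name!r} needs >= 2 subunits")


@dataclass(frozen=True)
class CalibrationStandard:
    """One SEC calibration standard: known mass and observed peak fraction."""

    mass_kda: float
    peak_fraction: float

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError("mass_kda must be positive")
        if self.peak_fraction < 1:
            raise ValueError("peak_fraction must be >= 1")


# ---------------------------------------------------------------------------
# readers

#: default column-name pattern for MaxQuant-style per-fraction intensities
MAXQUANT_INTENSITY_PATTERN = r"Intensity\s+F(\d+)$"
MAXQUANT_ID_CANDIDATES = ("Majority protein IDs", "Protein IDs", "Protein ID")
MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_profile_matrix(
    path: str | Path,
    format: str = "generic_csv",
    separation: Separation | str = Separation.SEC,
    replicate: int = 1,
    intensity_pattern: str = MAXQUANT_INTENSITY_PATTERN,
) -> ProfileMatrix:
    """Read an abundance matrix from a generic CSV/TSV or MaxQuant-style table.

    Generic format: first column = protein ID, remaining columns = fractions
    in elution order.  MaxQuant format: protein ID column plus per-fraction
    intensity columns matched by ``intensity_pattern`` (one capturing group
    holding the fraction number); reverse/contaminant-flagged rows are
    dropped.  Rows with all-zero abundance are retained.
    """
    df = _read_table(path)
    if format == "generic_csv":
        id_col = df.columns[0]
        frac_cols = list(df.columns[1:])
    elif format == "maxquant":
        id_col = next((c for c in MAXQUANT_ID_CANDIDATES if c in df.columns), None)
        if id_col is None:
            raise ProfileFormatError(
                f"no protein ID column found (expected one of {MAXQUANT_ID_CANDIDATES})"
            )
        pat = re.compile(intensity_pattern)
        matched = [(c, pat.search(c)) for c in df.columns]
        frac_cols_idx = sorted(
            ((int(m.group(1)), c) for c, m in matched if m), key=lambda t: t[0]
        )
        if not frac_cols_idx:
            raise ProfileFormatError(
                f"no intensity columns match pattern {intensity_pattern!r}"
            )
        expected = list(range(1, len(frac_cols_idx) + 1))
        if [i for i, _ in frac_cols_idx] != expected:
            raise ProfileFormatError("fraction numbers not contiguous from 1")
        frac_cols = [c for _, c in frac_cols_idx]
        for flag in MAXQUANT_FLAG_COLUMNS:
            if flag in df.columns:
                df = df[df[flag].fillna("") != "+"]
    else:
        raise ValueError(f"unknown format {format!r}")

    if df[id_col].duplicated().any():
        raise ProfileFormatError("duplicate protein IDs in input table")
    values = np.empty((len(df), len(frac_cols)), dtype=float)
    for j, col in enumerate(frac_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            row = df.index[bad][0]
            raise ProfileParseError(
                f"non-numeric abundance at row {row}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        values[:, j] = converted.fillna(0.0).to_numpy()
    return ProfileMatrix(
        separation=Separation(separation),
        replicate=replicate,
        proteins=[str(p) for p in df[id_col]],
        values=values,
    )


def read_annotations(path: str | Path) -> AnnotationTable:
    df = _read_table(path)
    if "protein_id" not in df.columns:
        raise ProfileFormatError("annotation table needs a protein_id column")
    df = df.set_index("protein_id")
    df.index = df.index.astype(str)
    if df["exclude_tm"].dtype == object:
        df["exclude_tm"] = (
            df["exclude_tm"].astype(str).str.lower().isin({"true", "1", "yes", "+"})
        )
    return AnnotationTable(df)


def read_known_complexes(path: str | Path) -> list[KnownComplex]:
    """Read a long-format complex membership table (complex_name, protein_id)."""
    df = _read_table(path)
    for col in ("complex_name", "protein_id"):
        if col not in df.columns:
            raise ProfileFormatError(f"known-complex table needs a {col} column")
    out = []
    for name, grp in df.groupby("complex_name", sort=True):
        out.append(KnownComplex(str(name), frozenset(grp["protein_id"].astype(str))))
    return out


def read_calibration_standards(path: str | Path) -> list[CalibrationStandard]:
    df = _read_table(path)
    for col in ("mass_kda", "peak_fraction"):
        if col not in df.columns:
            raise ProfileFormatError(f"calibration table needs a {col} column")
    return [
        CalibrationStandard(float(r.mass_kda), float(r.peak_fraction))
        for r in df.itertuples()
    ]


def write_known_complexes(complexes: Iterable[KnownComplex], path: str | Path) -> None:
    rows = [
        {"complex_name": c.name, "protein_id": p}
        for c in complexes
        for p in sorted(c.subunits)
    ]
    pd.DataFrame(rows, columns=["complex_name", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# filtering


def filter_proteins(
    matrix: ProfileMatrix,
    annotations: AnnotationTable,
    compartment: str,
) -> ProfileMatrix:
    """Restrict a matrix to one compartment, dropping TM-flagged proteins.

    Proteins with transmembrane domains are excluded because their SEC
    behaviour typically reflects detergent micelles or proteolytic
    fragments rather than soluble complexes.  Unannotated proteins are
    dropped with a logged count.
    """
    if compartment not in AnnotationTable.COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    keep: list[str] = []
    n_unannotated = 0
    for p in matrix.proteins:
        if p not in annotations:
            n_unannotated += 1
            continue
        if annotations.table.at[p, "exclude_tm"]:
            continue
        if annotations.compartment(p) == compartment:
            keep.append(p)
    if n_unannotated:
        logger.info("dropped %d unannotated proteins", n_unannotated)
    if not keep:
        logger.warning(
            "no proteins retained for compartment %r (rep %d %s)",
            compartment,
            matrix.replicate,
            matrix.separation.value,
        )
    return matrix.subset(keep)


# ---------------------------------------------------------------------------
# reports


def write_cluster_report(
    result,
    classifications: pd.DataFrame,
    path: str | Path,
    multi_cut_path: str | Path | None = None,
) -> None:
    """Write the per-entry cluster report and an optional multi-cut table.

    ``classifications`` must carry one row per entry of ``result`` with
    columns entry_id, base_protein, cluster_id, m_app_kda, m_calc_kda,
    r_app, category.  The companion multi-cut table holds the cluster ID
    of every entry at each cut stored in ``result``.
    """
    required = [
        "entry_id",
        "base_protein",
        "cluster_id",
        "m_app_kda",
        "m_calc_kda",
        "r_app",
        "category",
    ]
    missing = [c for c in required if c not in classifications.columns]
    if missing:
        raise ValueError(f"classification table missing columns: {missing}")
    got = set(classifications["entry_id"])
    expected = set(result.entry_ids)
    if got != expected:
        raise ValueError("classifications do not cover every entry in the result")
    classifications[required].to_csv(path, sep="\t", index=False)
    if multi_cut_path is not None and result.assignments:
        table = pd.DataFrame(
            {f"k{k}": pd.Series(result.assignments[k]) for k in sorted(result.assignments)}
        )
        table.rename_axis("entry_id").to_csv(multi_cut_path, sep="\t")
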