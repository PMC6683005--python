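"""Reliability / oligomerization categories for predicted complexes.

Each cluster's calculated mass M_calc (sum of member monomer masses,
assuming 1:1 stoichiometry) is compared with the members' SEC apparent
masses M_app.  Categories are assigned per entry by a first-match rule
cascade ordered from most specific to most general:

1. singleton clusters: R_app < 0.5 -> degraded; 0.5 <= R_app < 1.6 ->
   monomeric; R_app >= 1.6 -> homooligomer
2. clusters of 2-3 members whose entry has M_app >= 4 * M_calc ->
   possible homo-/hetero-oligomer with high subunit stoichiometry
3. multi-peak proteins: a subset of IEX-peak entries with
   M_app >= 4 * M_calc -> subcomplex / high stoichiometry; ALL peak
   entries with M_app > 1.4 * M_calc -> partial complex / false negative
4. clusters of >= 2 with |M_calc - mean M_app| <= 40% of mean M_app ->
   putative intact complex
5. clusters with M_calc > 1.4 * mean M_app: entries with R_app >= 1.6 ->
   putative complex clustered with false positives; R_app < 1.6 ->
   likely false positive (monomer)
6. otherwise unclassified (reported explicitly)

All rules an entry matches are additionally recorded as secondary flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from coelute.io_profiles import AnnotationTable

logger = logging.getLogger(__name__)


class Category(str, Enum):
    DEGRADED = "degraded"
    MONOMERIC = "monomeric"
    HOMOOLIGOMER = "homooligomer"
    POSSIBLE_OLIGOMER_HIGH_STOICHIOMETRY = (
        "possible_homo_or_hetero_oligomer_high_stoichiometry"
    )
    PUTATIVE_INTACT_COMPLEX = "putative_intact_complex"
    SUBCOMPLEX_OR_HIGH_STOICHIOMETRY = "subcomplex_or_high_stoichiometry"
    PARTIAL_COMPLEX_FALSE_NEGATIVE = "partial_complex_false_negative"
    PUTATIVE_COMPLEX_WITH_FALSE_POSITIVES = "putative_complex_with_false_positives"
    LIKELY_FALSE_POSITIVE_MONOMER = "likely_false_positive_monomer"
    UNCLASSIFIED = "unclassified"


def m_calc(members: list[str], annotations: AnnotationTable) -> tuple[float, bool]:
    """Summed monomer mass (kDa) of a cluster's members, 1:1 stoichiometry.

    Sub-entries count their base protein's monomer mass.  Members with an
    unknown mass are excluded from the sum and flagged; all-unknown yields
    NaN.  Returns (mass, flag_missing).
    """
    masses = []
    missing = False
    for entry in members:
        base = entry.rsplit("_peak", 1)[0] if "_peak" in entry else entry
        m = annotations.monomer_mass(base) if base in annotations else float("nan")
        if np.isnan(m):
            missing = True
            logger.debug("no monomer mass for %s; excluded from M_calc", entry)
        else:
            masses.append(m)
    if not masses:
        return float("nan"), True
    return float(sum(masses)), missing


@dataclass
class EntryClassification:
    entry_id: str
    base_protein: str
    cluster_id: int
    m_app_kda: float
    r_app: float
    m_calc_kda: float
    m_app_avg_kda: float
    category: Category
    secondary_flags: tuple[str, ...] = ()
    reason: str = ""


def _singleton_category(r: float) -> Category | None:
    if np.isnan(r):
        return None
    if r < 0.5:
        return Category.DEGRADED
    if r < 1.6:
        return Category.MONOMERIC
    return Category.HOMOOLIGOMER


def classify_entries(
    assignments: dict[str, int],
    m_app: dict[str, float],
    annotations: AnnotationTable,
    multi_peak: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Classify every entry at one dendrogram cut.

    ``assignments`` maps entry ID -> cluster ID, ``m_app`` maps entry ID ->
    SEC apparent mass (kDa); ``multi_peak`` marks entries that are one of
    several IEX peaks of the same protein (inferred from '_peak' suffixes
    when omitted).
    """
    entries = sorted(assignments)
    if multi_peak is None:
        multi_peak = {e: "_peak" in e for e in entries}
    base = {e: e.rsplit("_peak", 1)[0] if "_peak" in e else e for e in entries}

    clusters: dict[int, list[str]] = {}
    for e in entries:
        clusters.setdefault(assignments[e], []).append(e)
    cluster_mcalc = {cid: m_calc(members, annotations) for cid, members in clusters.items()}
    cluster_mapp_avg = {
        cid: float(np.nanmean([m_app[e] for e in members]))
        for cid, members in clusters.items()
    }
    # sibling entries of each multi-peak protein, for rules evaluated per protein
    siblings: dict[str, list[str]] = {}
    for e in entries:
        siblings.setdefault(base[e], []).append(e)

    rows: list[EntryClassification] = []
    for e in entries:
        cid = assignments[e]
        members = clusters[cid]
        mc, mc_missing = cluster_mcalc[cid]
        ma = m_app.get(e, float("nan"))
        mono = annotations.monomer_mass(base[e]) if base[e] in annotations else float("nan")
        r = ma / mono if mono and not np.isnan(mono) and not np.isnan(ma) else float("nan")
        mavg = cluster_mapp_avg[cid]
        flags: list[str] = []
        category: Category | None = None
        reason = ""

        singleton = len(members) == 1
        if singleton:
            category = _singleton_category(r)
            if category is None:
                category = Category.UNCLASSIFIED
                reason = "singleton with unknown monomer mass"
        if not np.isnan(ma) and not np.isnan(mc):
            if 2 <= len(members) <= 3 and ma >= 4.0 * mc:
                flags.append("m_app>=4*m_calc_small_cluster")
                if category is None:
                    category = Category.POSSIBLE_OLIGOMER_HIGH_STOICHIOMETRY
            if multi_peak.get(e, False):
                sibs = siblings[base[e]]
                ratios = []
                for s in sibs:
                    smc = cluster_mcalc[assignments[s]][0]
                    sma = m_app.get(s, float("nan"))
                    ratios.append(sma / smc if smc and not np.isnan(smc) else float("nan"))
                own_ratio = ma / mc if mc else float("nan")
                if own_ratio >= 4.0:
                    flags.append("iex_peak_in_high_stoichiometry_quadrant")
                    if category is None:
                        category = Category.SUBCOMPLEX_OR_HIGH_STOICHIOMETRY
                elif all(rt > 1.4 for rt in ratios if not np.isnan(rt)) and ratios:
                    flags.append("all_peaks_m_app>1.4*m_calc")
                    if category is None:
                        category = Category.PARTIAL_COMPLEX_FALSE_NEGATIVE
        if not singleton and not np.isnan(mc) and not np.isnan(mavg):
            if abs(mc - mavg) <= 0.4 * mavg:
                flags.append("m_calc_within_40pct_of_m_app_avg")
                if category is None:
                    category = Category.PUTATIVE_INTACT_COMPLEX
            if mc > 1.4 * mavg:
                flags.append("m_calc>1.4*m_app_avg")
                if category is None:
                    if np.isnan(r):
                        category = Category.UNCLASSIFIED
                        reason = "false-positive cluster but unknown monomer mass"
                    elif r >= 1.6:
                        category = Category.PUTATIVE_COMPLEX_WITH_FALSE_POSITIVES
                    else:
                        category = Category.LIKELY_FALSE_POSITIVE_MONOMER
        if category is None:
            category = Category.UNCLASSIFIED
            if not reason:
                reason = "no rule matched"
        rows.append(
            EntryClassification(
                entry_id=e,
                base_protein=base[e],
                cluster_id=cid,
                m_app_kda=ma,
                r_app=r,
                m_calc_kda=mc,
                m_app_avg_kda=mavg,
                category=category,
                secondary_flags=tuple(flags),
                reason=reason,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["category"] = df["category"].map(lambda c: c.value)
    return df


def summarize_categories(classifications: pd.DataFrame) -> pd.DataFrame:
    """Entry- and cluster-level category counts and percentages.

    A cluster's category is the most common category among its entries
    (ties toward the rarer category overall, then alphabetical).
    """
    if classifications.empty:
        return pd.DataFrame(columns=["category", "level", "count", "percent"])
    rows = []
    ecounts = classifications["category"].value_counts()
    for cat, n in ecounts.items():
        rows.append(
            {"category": cat, "level": "entry", "count": int(n),
             "percent": 100.0 * n / len(classifications)}
        )
    cluster_cat = (
        classifications.groupby("cluster_id")["category"]
        .agg(lambda s: s.value_counts().idxmax())
    )
    ccounts = cluster_cat.value_counts()
    for cat, n in ccounts.items():
        rows.append(
            {"category": cat, "level": "cluster", "count": int(n),
             "percent": 100.0 * n / len(cluster_cat)}
        )
    return pd.DataFrame(rows)
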