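"""Target counting and promiscuity statistics.

The central quantities: per-compound distinct-target counts; the average
number of targets per compound over all compounds (``avg_all``) and over
promiscuous compounds only (``avg_promiscuous``, compounds with at least
``threshold`` targets, default 2); the probability of promiscuity
(``p_ge2`` = fraction of compounds with >= 2 targets, ``p_gt5`` = fraction
with > 5, strict); the family scope of each compound's activity (single
target / multiple targets within one family / targets across families); and
the assay-coverage fraction for screening data.

Because a non-promiscuous compound has exactly one target, the overall and
promiscuous-only averages are tied by an exact mixture identity::

    avg_all = p_ge2 * avg_promiscuous + (1 - p_ge2) * 1

which holds to floating-point precision for every summary computed at
threshold 2 and doubles as an internal consistency oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("promiscuity")


@dataclass(frozen=True)
class PromiscuitySummary:
    """Promiscuity statistics for one compound set.

    ``avg_promiscuous`` and the promiscuity probabilities are computed at
    ``promiscuity_threshold`` (default 2); ``median_promiscuous`` at
    ``median_threshold``, which may be stricter for drug and screening
    categories.  When no compound reaches the threshold the promiscuous
    fields are NaN (undefined), never zero.
    """

    n_compounds: int
    avg_all: float
    avg_promiscuous: float
    median_promiscuous: float
    p_ge2: float
    p_gt5: float
    promiscuity_threshold: int = 2
    median_threshold: int = 2
    n_promiscuous: int = 0

    @classmethod
    def empty(cls, threshold: int = 2, median_threshold: int | None = None) -> "PromiscuitySummary":
        mt = threshold if median_threshold is None else median_threshold
        return cls(0, math.nan, math.nan, math.nan, math.nan, math.nan, threshold, mt, 0)

    @property
    def is_empty(self) -> bool:
        return self.n_compounds == 0

    def as_dict(self) -> dict:
        def _clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v
        return {k: _clean(v) for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class FamilyScopeBreakdown:
    """Fractions of compounds with single-target, intra-family and cross-family activity."""

    frac_single: float
    frac_intra_family: float
    frac_cross_family: float

    def __post_init__(self):
        total = self.frac_single + self.frac_intra_family + self.frac_cross_family
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"family-scope fractions sum to {total}, not 1")


def count_targets(pairs: pd.DataFrame) -> pd.DataFrame:
    """Count distinct targets per compound.

    Returns one row per compound with ``n_targets`` (distinct target_ids)
    and ``families`` (frozenset of the targets' family labels; missing
    labels appear as NaN members and are rejected downstream by the
    family-scope classification).
    """
    if pairs.empty:
        return pd.DataFrame(columns=["compound_id", "n_targets", "families"])
    grouped = (
        pairs.groupby("compound_id", sort=False)
        .agg(n_targets=("target_id", "nunique"),
             families=("target_family", lambda s: frozenset(s)))
        .reset_index()
    )
    return grouped


def promiscuity_summary(counts: pd.DataFrame | np.ndarray, threshold: int = 2,
                        median_threshold: int | None = None) -> PromiscuitySummary:
    """Summarise a set of per-compound target counts.

    ``counts`` is either the frame from :func:`count_targets` or a bare
    array of counts.  The median of an even-sized set is the mean of the two
    middle values.  Empty input yields :meth:`PromiscuitySummary.empty`.
    """
    if threshold < 2:
        raise ValueError("promiscuity threshold must be >= 2")
    if isinstance(counts, pd.DataFrame):
        n = counts["n_targets"].to_numpy() if len(counts) else np.array([], dtype=int)
    else:
        n = np.asarray(counts, dtype=int)
    mt = threshold if median_threshold is None else median_threshold
    if n.size == 0:
        return PromiscuitySummary.empty(threshold, mt)
    if (n < 1).any():
        raise ValueError("every compound present must have at least one target")
    prom = n[n >= threshold]
    med_set = n[n >= mt]
    return PromiscuitySummary(
        n_compounds=int(n.size),
        avg_all=float(n.mean()),
        avg_promiscuous=float(prom.mean()) if prom.size else math.nan,
        median_promiscuous=float(np.median(med_set)) if med_set.size else math.nan,
        p_ge2=float((n >= 2).mean()),
        p_gt5=float((n > 5).mean()),
        promiscuity_threshold=threshold,
        median_threshold=mt,
        n_promiscuous=int(prom.size),
    )


def mixture_identity(p_ge2: float, avg_promiscuous: float) -> float:
    """Overall average reconstructed from the promiscuity probability and
    the promiscuous-only average.

    Non-promiscuous compounds have exactly one target, so
    ``avg_all = p_ge2 * avg_promiscuous + (1 - p_ge2) * 1`` exactly.  With
    ``p_ge2 == 0`` the promiscuous average is irrelevant and the result
    is 1.
    """
    if not 0.0 <= p_ge2 <= 1.0:
        raise ValueError(f"p_ge2 must be a probability, got {p_ge2}")
    if p_ge2 == 0.0:
        return 1.0
    if not avg_promiscuous >= 2.0:
        raise ValueError(
            f"avg_promiscuous must be >= 2 when p_ge2 > 0, got {avg_promiscuous}")
    return p_ge2 * avg_promiscuous + (1.0 - p_ge2) * 1.0


def classify_family_scope(counts: pd.DataFrame) -> tuple[pd.Series, FamilyScopeBreakdown]:
    """Label each compound single / intra_family / cross_family.

    A compound is ``single`` with one target, ``intra_family`` with two or
    more targets all in one family, ``cross_family`` when its targets span
    families.  Raises if any compound carries an unlabeled target family.
    """
    if counts.empty:
        raise ValueError("classify_family_scope: no compounds")
    labels = []
    for row in counts.itertuples(index=False):
        fams = {f for f in row.families}
        if any(f is None or (isinstance(f, float) and math.isnan(f)) for f in fams):
            raise ValueError(
                f"compound {row.compound_id!r} has a target with no family label")
        if row.n_targets == 1:
            labels.append("single")
        elif len(fams) == 1:
            labels.append("intra_family")
        else:
            labels.append("cross_family")
    s = pd.Series(labels, index=counts["compound_id"].to_numpy(), name="family_scope")
    n = len(s)
    breakdown = FamilyScopeBreakdown(
        frac_single=float((s == "single").sum()) / n,
        frac_intra_family=float((s == "intra_family").sum()) / n,
        frac_cross_family=float((s == "cross_family").sum()) / n,
    )
    return s, breakdown


#: default median thresholds per compound category: approved drugs counted as
#: promiscuous for the median at > 4 targets (i.e. >= 5), experimental at
#: >= 2, screening actives at >= 3, bioactive (ChEMBL-like) at >= 2
CATEGORY_MEDIAN_THRESHOLDS = {
    "approved": 5,
    "experimental": 2,
    "screen_active": 3,
    "chembl": 2,
}


def drug_target_counts(annotations: pd.DataFrame, status: str) -> pd.DataFrame:
    """Distinct-target counts per drug for one approval status; no
    confidence filtering is applied to drug annotations."""
    sub = annotations.loc[annotations["drug_status"] == status]
    if sub.empty:
        return pd.DataFrame(columns=["compound_id", "n_targets"])
    grouped = (
        sub.groupby("drug_id", sort=False)["target_id"].nunique()
        .rename("n_targets").reset_index()
        .rename(columns={"drug_id": "compound_id"})
    )
    return grouped


def screen_target_counts(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Distinct active-target counts per confirmed-active screening compound."""
    active = outcomes.loc[outcomes["outcome"] == "active"]
    if active.empty:
        return pd.DataFrame(columns=["compound_id", "n_targets"])
    grouped = (
        active.groupby("compound_id", sort=False)["target_id"].nunique()
        .rename("n_targets").reset_index()
    )
    return grouped


def category_summary(data: pd.DataFrame, category: str,
                     median_threshold: int | None = None) -> PromiscuitySummary:
    """Promiscuity summary for a drug or screening category.

    ``approved`` / ``experimental`` expect a drug-annotation table and count
    all annotated targets; ``screen_active`` expects an assay-outcome table
    and counts distinct targets of active outcomes.  The promiscuous average
    and probabilities use the standard >= 2 threshold; the median uses the
    category-specific threshold.
    """
    if category in ("approved", "experimental"):
        counts = drug_target_counts(data, category)
    elif category == "screen_active":
        counts = screen_target_counts(data)
    else:
        raise ValueError(f"unknown category: {category!r}")
    mt = CATEGORY_MEDIAN_THRESHOLDS[category] if median_threshold is None else median_threshold
    if counts.empty:
        return PromiscuitySummary.empty(2, mt)
    return promiscuity_summary(counts["n_targets"].to_numpy(), threshold=2, median_threshold=mt)


def assay_coverage(outcomes: pd.DataFrame, min_assays: int = 50) -> float:
    """Fraction of confirmed-active compounds tested in more than
    ``min_assays`` distinct assays (strict >).

    The denominator is every compound with at least one active outcome; the
    numerator counts those among them whose total number of distinct tested
    assays (active or inactive) exceeds ``min_assays``.
    """
    active_compounds = outcomes.loc[outcomes["outcome"] == "active", "compound_id"].unique()
    if active_compounds.size == 0:
        return math.nan
    tested = outcomes.groupby("compound_id")["assay_id"].nunique()
    covered = tested.loc[active_compounds] > min_assays
    return float(covered.mean())
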