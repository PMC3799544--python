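"""Classification of promiscuous compounds against the prevalent promiscuity
profile and the rare selectivity-outlier pattern.

The prevalent profile of a promiscuous bioactive compound: sub-micromolar
potency against two to five targets from the same family, with potency
differences across those targets within one or two orders of magnitude.
The opposite pattern -- very potent against one (primary) target and weak
against all others -- is rare, and is flagged separately.

All assessments work on aggregated compound-target pairs of a single
measurement type (Ki or IC50, never mixed) carrying pPotencies; the potency
spread is max minus min pPotency in log10 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import p_potency_from_nM


@dataclass(frozen=True)
class ProfileRule:
    """Thresholds defining the prevalent promiscuity profile.

    ``sub_uM_threshold`` is in nM and strict: a pair qualifies as sub-µM
    when its aggregated potency is better than (below) the threshold,
    equivalently pPotency > 6 at the 1000 nM default.  ``max_spread_log``
    is the tolerated max-minus-min pPotency difference (two orders of
    magnitude by default; the one-order case is reported separately).
    """

    min_targets: int = 2
    max_targets: int = 5
    sub_uM_threshold: float = 1000.0
    require_same_family: bool = True
    max_spread_log: float = 2.0

    def __post_init__(self):
        if self.min_targets > self.max_targets:
            raise ValueError("min_targets must be <= max_targets")
        if self.min_targets < 2:
            raise ValueError("the profile is defined for promiscuous compounds (min_targets >= 2)")
        if not self.sub_uM_threshold > 0 or not self.max_spread_log > 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ProfileAssessment:
    """Per-compound evaluation against the profile rules."""

    compound_id: str
    n_targets: int
    all_sub_uM: bool
    same_family: bool
    spread_log: float
    matches_prevalent: bool
    within_one_log: bool
    selectivity_outlier: bool


def detect_selectivity_outlier(p_potencies: np.ndarray,
                               potent_threshold: float = 100.0,
                               weak_threshold: float = 10000.0) -> bool:
    """True iff the best pair is at or below ``potent_threshold`` nM and
    every other pair is at or above ``weak_threshold`` nM.

    Raises on fewer than two pairs (pattern defined only for promiscuous
    compounds).
    """
    p = np.asarray(p_potencies, dtype=float)
    if p.size < 2:
        raise ValueError("selectivity-outlier detection needs >= 2 pairs")
    p_potent = p_potency_from_nM(potent_threshold)  # higher p = more potent
    p_weak = p_potency_from_nM(weak_threshold)
    best = p.max()
    others = np.delete(p, p.argmax())
    return bool(best >= p_potent and (others <= p_weak).all())


def assess_profile(pairs: pd.DataFrame, rule: ProfileRule | None = None,
                   potent_threshold: float = 100.0,
                   weak_threshold: float = 10000.0) -> ProfileAssessment | None:
    """Assess one compound's aggregated pairs against the profile rule.

    ``pairs`` holds one compound's rows (single measurement type) with
    ``p_potency`` and ``target_family``.  Returns None for fewer than two
    pairs: the profile is defined only for promiscuous compounds.
    """
    rule = rule or ProfileRule()
    if len(pairs) < 2:
        return None
    cids = pairs["compound_id"].unique()
    if len(cids) != 1:
        raise ValueError("assess_profile expects the pairs of a single compound")
    p = pairs["p_potency"].to_numpy(dtype=float)
    spread = float(p.max() - p.min())
    sub_uM_p = p_potency_from_nM(rule.sub_uM_threshold)
    all_sub = bool((p > sub_uM_p).all())
    fams = set(pairs["target_family"])
    same_family = len(fams) == 1 and not any(
        f is None or (isinstance(f, float) and math.isnan(f)) for f in fams)
    n = int(pairs["target_id"].nunique())
    matches = (
        rule.min_targets <= n <= rule.max_targets
        and all_sub
        and (same_family or not rule.require_same_family)
        and spread <= rule.max_spread_log
    )
    return ProfileAssessment(
        compound_id=str(cids[0]),
        n_targets=n,
        all_sub_uM=all_sub,
        same_family=same_family,
        spread_log=spread,
        matches_prevalent=bool(matches),
        within_one_log=bool(spread <= 1.0),
        selectivity_outlier=detect_selectivity_outlier(p, potent_threshold, weak_threshold),
    )


@dataclass(frozen=True)
class ProfilePrevalence:
    """Fractions of promiscuous compounds matching each pattern."""

    n_assessed: int
    frac_matches_prevalent: float
    frac_within_one_log: float
    frac_selectivity_outlier: float


def profile_prevalence(assessments) -> ProfilePrevalence:
    """Prevalence fractions over assessed (promiscuous) compounds; None
    entries (non-assessable compounds) are ignored."""
    kept = [a for a in assessments if a is not None]
    n = len(kept)
    if n == 0:
        return ProfilePrevalence(0, math.nan, math.nan, math.nan)
    return ProfilePrevalence(
        n_assessed=n,
        frac_matches_prevalent=sum(a.matches_prevalent for a in kept) / n,
        frac_within_one_log=sum(a.within_one_log for a in kept) / n,
        frac_selectivity_outlier=sum(a.selectivity_outlier for a in kept) / n,
    )


def assess_all(pairs: pd.DataFrame, rule: ProfileRule | None = None,
               potent_threshold: float = 100.0,
               weak_threshold: float = 10000.0) -> list[ProfileAssessment]:
    """Assess every promiscuous compound in an aggregated-pair table."""
    out = []
    for _, grp in pairs.groupby("compound_id", sort=False):
        a = assess_profile(grp, rule, potent_threshold, weak_threshold)
        if a is not None:
            out.append(a)
    return out
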