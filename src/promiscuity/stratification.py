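"""Family-restricted and molecular-weight-binned promiscuity summaries.

Family stratification restricts a compound's target count to targets inside
one family: a compound hitting two GPCRs and a kinase contributes a count of
2 to the GPCR summary and 1 to the kinase summary.  Compounds active in
several families appear in each family's summary independently.

MW stratification partitions compounds into seven weight ranges.  Bins are
lower-open / upper-closed so every weight maps to exactly one bin: the first
bin is "<= 200" inclusive, then (200, 300], ..., (600, 700], and "> 700".
Compounds without a known molecular weight are excluded with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import PromiscuitySummary, count_targets, promiscuity_summary

logger = logging.getLogger("promiscuity")


@dataclass(frozen=True)
class MWBin:
    """One molecular-weight range; half-open (lower, upper] by default."""

    label: str
    lower: float  # -inf for the first bin
    upper: float  # +inf for the last bin

    def contains(self, mw: float) -> bool:
        return self.lower < mw <= self.upper


def default_mw_bins() -> tuple[MWBin, ...]:
    """The seven standard weight ranges, in Daltons."""
    edges = [200.0, 300.0, 400.0, 500.0, 600.0, 700.0]
    bins = [MWBin("≤ 200", -math.inf, 200.0)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        bins.append(MWBin(f"({lo:.0f}, {hi:.0f})", lo, hi))
    bins.append(MWBin("> 700", 700.0, math.inf))
    return tuple(bins)


def validate_bins(bins) -> tuple[MWBin, ...]:
    """Check that the bins partition (0, +inf)."""
    bins = tuple(bins)
    if not bins:
        raise ValueError("no MW bins")
    if bins[0].lower > 0:
        raise ValueError("first bin must start at or below 0")
    for a, b in zip(bins[:-1], bins[1:]):
        if a.upper != b.lower:
            raise ValueError(f"bins {a.label!r} and {b.label!r} do not abut")
    if bins[-1].upper != math.inf:
        raise ValueError("last bin must be unbounded above")
    return bins


def assign_mw_bin(mw: float, bins=None) -> str:
    """Label of the unique bin containing ``mw``; boundary weights fall in
    the lower-labelled bin (e.g. 200 in "<= 200", 700 in "(600, 700]")."""
    if not mw > 0:
        raise ValueError(f"mw must be positive, got {mw}")
    bins = validate_bins(bins or default_mw_bins())
    for b in bins:
        if b.contains(mw):
            return b.label
    raise AssertionError("unreachable: bins partition (0, inf)")


@dataclass(frozen=True)
class FamilySummary:
    """Within-family promiscuity summary for one target family."""

    family: str
    n_targets_in_family: int
    n_compounds: int
    summary: PromiscuitySummary


def stratify_by_family(pairs: pd.DataFrame, family: str) -> FamilySummary:
    """Promiscuity summary over compounds with activity in one family,
    counting only their within-family targets."""
    sub = pairs.loc[pairs["target_family"] == family]
    if sub.empty:
        return FamilySummary(family, 0, 0, PromiscuitySummary.empty())
    counts = count_targets(sub)
    return FamilySummary(
        family=family,
        n_targets_in_family=int(sub["target_id"].nunique()),
        n_compounds=len(counts),
        summary=promiscuity_summary(counts),
    )


def stratify_by_mw(counts: pd.DataFrame, meta: pd.DataFrame,
                   bins=None) -> dict[str, PromiscuitySummary]:
    """Per-MW-bin promiscuity summaries.

    ``counts`` is the per-compound target-count frame; ``meta`` supplies
    molecular weights joined on ``compound_id``.  Each compound with a known
    weight lands in exactly one bin; the per-bin compound totals sum to the
    number of compounds with known MW.
    """
    bins = validate_bins(bins or default_mw_bins())
    joined = counts.merge(meta[["compound_id", "mw"]], on="compound_id", how="left")
    known = joined.loc[joined["mw"].notna()]
    n_missing = len(joined) - len(known)
    if n_missing:
        logger.warning("stratify_by_mw: %d compound(s) without MW excluded", n_missing)
    if known.empty and len(joined):
        logger.warning("stratify_by_mw: no compound has a known MW; all bins empty")
    out: dict[str, PromiscuitySummary] = {}
    for b in bins:
        in_bin = known.loc[(known["mw"] > b.lower) & (known["mw"] <= b.upper)]
        out[b.label] = (promiscuity_summary(in_bin["n_targets"].to_numpy())
                        if len(in_bin) else PromiscuitySummary.empty())
    total = sum(s.n_compounds for s in out.values())
    assert total == len(known), "MW bins must partition compounds with known MW"
    return out
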