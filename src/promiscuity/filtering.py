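"""Confidence filtering, Ki/IC50 splitting and replicate aggregation.

Promiscuity statistics are only meaningful on high-confidence data: an
explicit (unqualified) activity measurement asserting a direct ligand-target
interaction at the highest curation confidence level.  Records passing the
filter are split by measurement type -- Ki and IC50 values are never pooled,
a compound measured with both enters both subsets -- and replicate
measurements for one compound-target pair are collapsed to a single pair by
geometric-mean averaging on the concentration scale (arithmetic mean of
pPotencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import p_potency_from_nM

logger = logging.getLogger("promiscuity")


@dataclass(frozen=True)
class FilterCriteria:
    """Data-confidence criteria for activity records.

    Defaults keep only unqualified (relation ``eq``) measurements at
    confidence level 9 flagged as direct interactions -- the strictest
    reading of "high-confidence activity annotation" on a ChEMBL-like 0-9
    confidence scale.
    """

    min_confidence: int = 9
    require_direct: bool = True
    allowed_relations: frozenset[str] = field(default_factory=lambda: frozenset({"eq"}))

    def __post_init__(self):
        if not 0 <= self.min_confidence <= 9:
            raise ValueError(f"min_confidence must be in [0, 9], got {self.min_confidence}")
        bad = set(self.allowed_relations) - {"eq", "lt", "gt"}
        if bad:
            raise ValueError(f"unknown relation(s): {sorted(bad)}")
        object.__setattr__(self, "allowed_relations", frozenset(self.allowed_relations))


def filter_high_confidence(records: pd.DataFrame,
                           criteria: FilterCriteria | None = None) -> pd.DataFrame:
    """Keep records meeting the confidence criteria; empty output is permitted."""
    criteria = criteria or FilterCriteria()
    keep = (records["confidence_level"] >= criteria.min_confidence) \
        & (records["relation"].isin(criteria.allowed_relations))
    if criteria.require_direct:
        keep &= records["direct_interaction"]
    out = records.loc[keep].reset_index(drop=True)
    logger.info("filter_high_confidence: %d of %d records kept", len(out), len(records))
    return out


def split_by_measurement(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split records into Ki and IC50 subsets.

    A compound with both measurement types appears in both subsets; records
    with ``measurement_type`` 'other' appear in neither.
    """
    return {
        mt: records.loc[records["measurement_type"] == mt].reset_index(drop=True)
        for mt in ("Ki", "IC50")
    }


def aggregate_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate measurements into unique compound-target pairs.

    Expects records of a single measurement type.  Replicates for one
    (compound, target) are combined by the arithmetic mean of their
    pPotencies, i.e. the geometric mean of the nanomolar values.  Returns a
    DataFrame with columns ``compound_id, target_id, target_family,
    measurement_type, p_potency, n_replicates``.
    """
    types = records["measurement_type"].unique()
    if len(types) > 1:
        raise ValueError(f"aggregate_pairs expects a single measurement type, got {sorted(types)}")
    if records.empty:
        return pd.DataFrame(columns=["compound_id", "target_id", "target_family",
                                     "measurement_type", "p_potency", "n_replicates"])
    if "value_nM" in records.columns:
        work = records.assign(
            p_potency=p_potency_from_nM(records["value_nM"].to_numpy()),
            n_replicates=1,
        )
    else:  # already-aggregated pairs: re-aggregation is the identity
        work = records
    grouped = (
        work.groupby(["compound_id", "target_id"], sort=False)
        .agg(target_family=("target_family", "first"),
             measurement_type=("measurement_type", "first"),
             p_potency=("p_potency", "mean"),
             n_replicates=("n_replicates", "sum"))
        .reset_index()
    )
    if not np.isfinite(grouped["p_potency"]).all():
        raise ValueError("non-finite aggregated pPotency")
    logger.info("aggregate_pairs: %d records -> %d unique pairs", len(records), len(grouped))
    return grouped
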