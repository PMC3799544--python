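"""Table schemas, readers and writers for activity, drug, assay and compound-metadata tables.

The pipeline consumes flat TSV/CSV tables in three dialects modelled on the
public bioactivity databases:

``chembl_like``
    one row per measured compound-target activity (Ki or IC50), with a
    curation confidence level (0-9) and a direct-interaction flag;
``drugbank_like``
    one row per drug-target annotation, with the drug's approval status;
``pubchem_like``
    one row per compound-assay outcome from confirmatory screening.

Potencies are normalised to nanomolar on input and carried internally on the
pPotency scale, ``p = -log10(value in mol/L) = 9 - log10(value_nM)``, so that
replicate aggregation and potency-spread computations work on a single
logarithmic scale.
"""

from __future__ import annotations

import json
import logging
import math
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("promiscuity")

FAMILIES = ("GPCR_A", "kinase", "ion_channel", "protease", "nuclear_receptor", "other")
MEASUREMENT_TYPES = ("Ki", "IC50", "other")
RELATIONS = ("eq", "lt", "gt")
SOURCES = ("chembl_like", "pubchem_like", "drugbank_like")
CATEGORIES = ("bioactive", "approved_drug", "experimental_drug", "screen_active")

#: unit label -> factor converting a value in that unit to nanomolar
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "um": 1e3, "mM": 1e6, "M": 1e9}

ACTIVITY_COLUMNS = (
    "compound_id", "target_id", "target_family", "measurement_type",
    "value", "unit", "relation", "confidence_level", "direct_interaction",
)
DRUG_COLUMNS = ("drug_id", "drug_status", "target_id")
ASSAY_COLUMNS = ("compound_id", "assay_id", "target_id", "outcome")
META_COLUMNS = ("compound_id", "mw", "category")


class SchemaError(ValueError):
    """The file header does not match the declared table schema."""


class RowError(ValueError):
    """A data row holds an unparsable or out-of-range value; cites the line number."""


def p_potency_from_nM(value_nM):
    """pPotency (-log10 molar) from a nanomolar concentration."""
    return 9.0 - np.log10(value_nM)


def nM_from_p_potency(p):
    """Nanomolar concentration from a pPotency."""
    return np.power(10.0, 9.0 - np.asarray(p, dtype=float))


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _parse_bool(raw: str, line: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes", "t"):
        return True
    if low in ("false", "0", "no", "f"):
        return False
    raise RowError(f"line {line}: column {column!r}: cannot parse boolean from {raw!r}")


def read_activity_table(path, dialect: str = "chembl_like") -> pd.DataFrame:
    """Read an activity table and normalise potencies to nM.

    Returns a DataFrame with columns ``compound_id, target_id, target_family,
    measurement_type, value_nM, relation, confidence_level,
    direct_interaction, source``, one row per measurement, input row order
    preserved.  Exactly duplicated rows are collapsed silently; rows that
    share keys but disagree in value are kept as replicates for the
    aggregation stage.

    Raises :class:`SchemaError` for a bad header and :class:`RowError`
    (citing the 1-based file line) for non-numeric or non-positive potencies,
    unknown units, relations, or out-of-range confidence levels.
    """
    if dialect != "chembl_like":
        raise ValueError(f"unknown activity dialect: {dialect!r}")
    raw = _read_table(path, ACTIVITY_COLUMNS)
    n_in = len(raw)
    values = np.empty(n_in, dtype=float)
    direct = np.empty(n_in, dtype=bool)
    conf = np.empty(n_in, dtype=int)
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            v = float(row.value)
        except ValueError:
            raise RowError(f"line {line}: non-numeric potency value {row.value!r}") from None
        if not math.isfinite(v) or v <= 0:
            raise RowError(f"line {line}: potency must be a positive finite number, got {row.value!r}")
        unit = row.unit.strip()
        if unit not in UNIT_TO_NM:
            raise RowError(f"line {line}: unknown unit {unit!r} (accepted: nM, uM/µM, mM, M)")
        values[i] = v * UNIT_TO_NM[unit]
        if row.measurement_type not in MEASUREMENT_TYPES:
            raise RowError(f"line {line}: unknown measurement_type {row.measurement_type!r}")
        if row.relation not in RELATIONS:
            raise RowError(f"line {line}: unknown relation {row.relation!r}")
        try:
            c = int(row.confidence_level)
        except ValueError:
            raise RowError(f"line {line}: non-integer confidence_level {row.confidence_level!r}") from None
        if not 0 <= c <= 9:
            raise RowError(f"line {line}: confidence_level {c} outside [0, 9]")
        conf[i] = c
        direct[i] = _parse_bool(row.direct_interaction, line, "direct_interaction")
    out = pd.DataFrame({
        "compound_id": raw["compound_id"].to_numpy(),
        "target_id": raw["target_id"].to_numpy(),
        "target_family": raw["target_family"].replace("", np.nan).to_numpy(),
        "measurement_type": raw["measurement_type"].to_numpy(),
        "value_nM": values,
        "relation": raw["relation"].to_numpy(),
        "confidence_level": conf,
        "direct_interaction": direct,
        "source": dialect,
    })
    out = out.drop_duplicates(ignore_index=True)
    logger.info("read_activity_table: %s: %d rows read, %d kept", path, n_in, len(out))
    return out


def read_drug_annotations(path) -> pd.DataFrame:
    """Read drug-target annotations; (drug_id, target_id) made unique with a warning."""
    raw = _read_table(path, DRUG_COLUMNS)
    n_in = len(raw)
    bad = ~raw["drug_status"].isin(("approved", "experimental"))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise RowError(f"line {line}: unknown drug_status {raw.loc[bad, 'drug_status'].iloc[0]!r}")
    out = raw.drop_duplicates(subset=["drug_id", "target_id"], ignore_index=True)
    if len(out) < n_in:
        logger.warning("read_drug_annotations: %s: collapsed %d duplicate (drug, target) rows",
                       path, n_in - len(out))
    logger.info("read_drug_annotations: %s: %d rows read, %d kept", path, n_in, len(out))
    return out[list(DRUG_COLUMNS)]


def read_assay_outcomes(path) -> pd.DataFrame:
    """Read confirmatory-assay outcomes; (compound_id, assay_id) made unique with a warning."""
    raw = _read_table(path, ASSAY_COLUMNS)
    n_in = len(raw)
    bad = ~raw["outcome"].isin(("active", "inactive"))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise RowError(f"line {line}: unknown outcome {raw.loc[bad, 'outcome'].iloc[0]!r}")
    out = raw.drop_duplicates(subset=["compound_id", "assay_id"], ignore_index=True)
    if len(out) < n_in:
        logger.warning("read_assay_outcomes: %s: collapsed %d duplicate (compound, assay) rows",
                       path, n_in - len(out))
    logger.info("read_assay_outcomes: %s: %d rows read, %d kept", path, n_in, len(out))
    return out[list(ASSAY_COLUMNS)]


def read_compound_meta(path) -> pd.DataFrame:
    """Read compound metadata (molecular weight in Daltons, category)."""
    raw = _read_table(path, META_COLUMNS)
    mw = pd.to_numeric(raw["mw"].replace("", np.nan), errors="coerce")
    stated = raw["mw"].replace("", np.nan).notna()
    bad = stated & mw.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise RowError(f"line {line}: non-numeric mw {raw.loc[bad, 'mw'].iloc[0]!r}")
    if (mw <= 0).any():
        line = int(np.flatnonzero((mw <= 0).to_numpy())[0]) + 2
        raise RowError(f"line {line}: mw must be positive")
    bad_cat = ~raw["category"].isin(CATEGORIES)
    if bad_cat.any():
        line = int(np.flatnonzero(bad_cat.to_numpy())[0]) + 2
        raise RowError(f"line {line}: unknown category {raw.loc[bad_cat, 'category'].iloc[0]!r}")
    out = pd.DataFrame({"compound_id": raw["compound_id"], "mw": mw, "category": raw["category"]})
    return out.drop_duplicates(subset=["compound_id"], ignore_index=True)


def write_activity_table(df: pd.DataFrame, path) -> None:
    """Write activity records back to the external schema (values in nM)."""
    out = pd.DataFrame({
        "compound_id": df["compound_id"],
        "target_id": df["target_id"],
        "target_family": df["target_family"].fillna(""),
        "measurement_type": df["measurement_type"],
        "value": df["value_nM"].map(lambda v: format(v, ".17g")),
        "unit": "nM",
        "relation": df["relation"],
        "confidence_level": df["confidence_level"],
        "direct_interaction": df["direct_interaction"].map({True: "true", False: "false"}),
    })
    sep = "\t" if str(path).endswith(".tsv") else ","
    out.to_csv(path, sep=sep, index=False)


def write_simple_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)


def round_average(x) -> str:
    """Rounding contract for report averages: one decimal."""
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.1f}"


def round_percent(p) -> str:
    """Rounding contract for report probabilities: one-decimal percent."""
    return "" if p is None or (isinstance(p, float) and math.isnan(p)) else f"{100.0 * p:.1f}"


def write_report_tables(frames: Mapping[str, pd.DataFrame], full_precision: Mapping,
                        out_dir) -> list[str]:
    """Write one TSV per report table plus a JSON carrying full-precision values.

    ``frames`` maps a table name to its already-rounded display DataFrame
    (the rounding contract is applied by the caller via :func:`round_average`
    / :func:`round_percent`); ``full_precision`` is a JSON-serialisable
    object with the unrounded numbers.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, frame in frames.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(full_precision, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    written.append(json_path)
    return written
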