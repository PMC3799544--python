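"""Model / results interface over the promiscuity pipeline.

:class:`PromiscuityAnalysis` is built from the input tables (activity
records, compound metadata, drug annotations, assay outcomes) together with
the analysis settings; :meth:`PromiscuityAnalysis.fit` runs the fixed stage
order -- filter, split by measurement type, aggregate replicates, count
targets, summarise, stratify by family and molecular weight, classify
profiles -- and returns a :class:`PromiscuityResults` holding every summary,
a ``summary()`` text report, TSV/JSON writers, and the mixture-identity
consistency check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .filtering import FilterCriteria, aggregate_pairs, filter_high_confidence, split_by_measurement
from .io_model import (read_activity_table, read_assay_outcomes, read_compound_meta,
                       read_drug_annotations, round_average, round_percent,
                       write_report_tables)
from .profiles import ProfilePrevalence, ProfileRule, assess_all, profile_prevalence
from .stats import (CATEGORY_MEDIAN_THRESHOLDS, FamilyScopeBreakdown, PromiscuitySummary,
                    assay_coverage, category_summary, classify_family_scope, count_targets,
                    mixture_identity, promiscuity_summary)
from .stratification import FamilySummary, default_mw_bins, stratify_by_family, stratify_by_mw

logger = logging.getLogger("promiscuity")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _summary_row(label: str, s: PromiscuitySummary, extra: Mapping | None = None) -> dict:
    row = {"subset": label, **(extra or {})}
    row.update({
        "n_compounds": s.n_compounds,
        "avg_all": s.avg_all,
        "avg_promiscuous": s.avg_promiscuous,
        "median_promiscuous": s.median_promiscuous,
        "p_ge2": s.p_ge2,
        "p_gt5": s.p_gt5,
    })
    return row


class PromiscuityAnalysis:
    """Compound-promiscuity analysis over one set of input tables.

    Parameters
    ----------
    activities : DataFrame, optional
        Activity records in the internal schema (see ``io_model``).
    meta : DataFrame, optional
        Compound metadata (molecular weight, category).
    drugs : DataFrame, optional
        Drug-target annotations with approval status.
    assays : DataFrame, optional
        Confirmatory-assay outcomes.
    criteria : FilterCriteria
        Data-confidence filter applied to activity records.
    mw_bins : sequence of MWBin
        Molecular-weight ranges for stratification.
    profile_rule : ProfileRule
        Thresholds for the prevalent-profile classification.
    """

    def __init__(self, activities: pd.DataFrame | None = None, *,
                 meta: pd.DataFrame | None = None,
                 drugs: pd.DataFrame | None = None,
                 assays: pd.DataFrame | None = None,
                 criteria: FilterCriteria | None = None,
                 mw_bins=None,
                 profile_rule: ProfileRule | None = None,
                 min_assays: int = 50,
                 provenance: dict | None = None):
        self.activities = activities
        self.meta = meta
        self.drugs = drugs
        self.assays = assays
        self.criteria = criteria or FilterCriteria()
        self.mw_bins = tuple(mw_bins) if mw_bins else default_mw_bins()
        self.profile_rule = profile_rule or ProfileRule()
        self.min_assays = min_assays
        self.provenance = dict(provenance or {})

    @classmethod
    def from_files(cls, activities=None, meta=None, drugs=None, assays=None, **kwargs):
        """Build an analysis from TSV/CSV table paths (any subset may be given)."""
        prov = {"inputs": {k: str(v) for k, v in
                           (("activities", activities), ("meta", meta),
                            ("drugs", drugs), ("assays", assays)) if v is not None}}
        prov.update(kwargs.pop("provenance", {}))
        return cls(
            activities=read_activity_table(activities) if activities else None,
            meta=read_compound_meta(meta) if meta else None,
            drugs=read_drug_annotations(drugs) if drugs else None,
            assays=read_assay_outcomes(assays) if assays else None,
            provenance=prov, **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, seed: int | None = None, **kwargs):
        """Build an analysis from a freshly generated synthetic dataset."""
        from .synthetic import SyntheticConfig, generate_dataset
        config = config or SyntheticConfig()
        ds = generate_dataset(config, seed=seed)
        model = cls(activities=ds.activities, meta=ds.meta, drugs=ds.drugs,
                    assays=ds.assays,
                    provenance={"synthetic_seed": config.seed if seed is None else seed},
                    **kwargs)
        model.synthetic = ds
        return model

    def fit(self) -> "PromiscuityResults":
        """Run the full pipeline and return the results bundle."""
        stage = "setup"
        try:
            summaries: dict[str, PromiscuitySummary] = {}
            family_summaries: dict[str, dict[str, FamilySummary]] = {}
            mw_summaries: dict[str, dict[str, PromiscuitySummary]] = {}
            scopes: dict[str, FamilyScopeBreakdown] = {}
            prevalences: dict[str, ProfilePrevalence] = {}
            assessments: dict[str, list] = {}
            pairs_by_subset: dict[str, pd.DataFrame] = {}
            counts_by_subset: dict[str, pd.DataFrame] = {}
            coverage = math.nan

            if self.activities is not None and len(self.activities):
                stage = "filter"
                kept = filter_high_confidence(self.activities, self.criteria)
                stage = "split"
                subsets = split_by_measurement(kept)
                for mt, records in subsets.items():
                    stage = f"aggregate[{mt}]"
                    pairs = aggregate_pairs(records)
                    pairs_by_subset[mt] = pairs
                    stage = f"count[{mt}]"
                    counts = count_targets(pairs)
                    counts_by_subset[mt] = counts
                    stage = f"summarize[{mt}]"
                    summaries[mt] = (promiscuity_summary(counts) if len(counts)
                                     else PromiscuitySummary.empty())
                    stage = f"stratify[{mt}]"
                    fams = sorted(pairs["target_family"].dropna().unique()) if len(pairs) else []
                    family_summaries[mt] = {f: stratify_by_family(pairs, f) for f in fams}
                    if self.meta is not None and len(counts):
                        mw_summaries[mt] = stratify_by_mw(counts, self.meta, self.mw_bins)
                    if len(counts):
                        stage = f"family_scope[{mt}]"
                        missing = pairs.loc[pairs["target_family"].isna(), "target_id"]
                        if len(missing):
                            raise ValueError(
                                f"target {missing.iloc[0]!r} has no family label")
                        _, scopes[mt] = classify_family_scope(counts)
                    stage = f"profile[{mt}]"
                    asmts = assess_all(pairs, self.profile_rule)
                    assessments[mt] = asmts
                    prevalences[mt] = profile_prevalence(asmts)

            if self.drugs is not None and len(self.drugs):
                stage = "summarize[drugs]"
                for status in ("approved", "experimental"):
                    summaries[status] = category_summary(self.drugs, status)
            if self.assays is not None and len(self.assays):
                stage = "summarize[screen]"
                summaries["screen_active"] = category_summary(self.assays, "screen_active")
                stage = "assay_coverage"
                coverage = assay_coverage(self.assays, self.min_assays)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

        provenance = {
            "tool_version": __version__,
            "filter_criteria": {
                "min_confidence": self.criteria.min_confidence,
                "require_direct": self.criteria.require_direct,
                "allowed_relations": sorted(self.criteria.allowed_relations),
            },
            "mw_bins": [b.label for b in self.mw_bins],
            "min_assays": self.min_assays,
            **self.provenance,
        }
        return PromiscuityResults(
            summaries=summaries, family_summaries=family_summaries,
            mw_summaries=mw_summaries, scopes=scopes, prevalences=prevalences,
            assessments=assessments, assay_coverage=coverage,
            pairs=pairs_by_subset, counts=counts_by_subset, provenance=provenance)


@dataclass
class PromiscuityResults:
    """Results bundle from one fitted promiscuity analysis.

    Mirrors the standard report layout: overall category summaries and
    probabilities, per-family and per-MW-bin summaries, the family-scope
    breakdown, profile prevalences, and the assay-coverage fraction.
    """

    summaries: dict[str, PromiscuitySummary]
    family_summaries: dict[str, dict[str, FamilySummary]]
    mw_summaries: dict[str, dict[str, PromiscuitySummary]]
    scopes: dict[str, FamilyScopeBreakdown]
    prevalences: dict[str, ProfilePrevalence]
    assessments: dict[str, list] = field(default_factory=dict)
    assay_coverage: float = math.nan
    pairs: dict[str, pd.DataFrame] = field(default_factory=dict)
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- reporting ---------------------------------------------------------

    def _iter_summaries(self):
        """Yield (name, summary) over every summary in the bundle."""
        for name, s in self.summaries.items():
            yield name, s
        for mt, fams in self.family_summaries.items():
            for f, fs in fams.items():
                yield f"{mt}/{f}", fs.summary
        for mt, bins in self.mw_summaries.items():
            for label, s in bins.items():
                yield f"{mt}/MW {label}", s

    def verify_consistency(self, tol: float = 1e-9) -> list[tuple[str, float]]:
        """Mixture-identity gap |avg_all - (p_ge2 * avg_prom + (1 - p_ge2))|
        for every non-empty summary; all gaps must be below ``tol``."""
        gaps = []
        for name, s in self._iter_summaries():
            if s.is_empty or s.promiscuity_threshold != 2:
                continue
            expect = mixture_identity(s.p_ge2, s.avg_promiscuous if s.p_ge2 > 0 else math.nan)
            gaps.append((name, abs(s.avg_all - expect)))
        bad = [(n, g) for n, g in gaps if not g < tol]
        if bad:
            logger.warning("verify_consistency: %d summary(ies) violate the mixture identity: %s",
                           len(bad), bad[:5])
        return gaps

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Display tables with the report rounding contract applied
        (averages to one decimal, probabilities to one-decimal percent)."""
        t1 = []
        t2 = []
        for name, s in self.summaries.items():
            t1.append({"category": name, "n_compounds": s.n_compounds,
                       "avg_targets_all": round_average(s.avg_all),
                       "avg_targets_promiscuous": round_average(s.avg_promiscuous),
                       "median_targets_promiscuous": round_average(s.median_promiscuous),
                       "median_threshold": s.median_threshold})
            t2.append({"category": name,
                       "p_ge2_targets_pct": round_percent(s.p_ge2),
                       "p_gt5_targets_pct": round_percent(s.p_gt5)})
        t3, t4 = [], []
        for mt, fams in self.family_summaries.items():
            for f, fs in fams.items():
                t3.append({"subset": mt, "family": f,
                           "n_targets": fs.n_targets_in_family,
                           "n_compounds": fs.n_compounds,
                           "avg_targets_all": round_average(fs.summary.avg_all),
                           "avg_targets_promiscuous": round_average(fs.summary.avg_promiscuous)})
                t4.append({"subset": mt, "family": f,
                           "p_ge2_targets_pct": round_percent(fs.summary.p_ge2),
                           "p_gt5_targets_pct": round_percent(fs.summary.p_gt5)})
        t5, t6 = [], []
        for mt, bins in self.mw_summaries.items():
            for label, s in bins.items():
                t5.append({"subset": mt, "mw_range": label, "n_compounds": s.n_compounds,
                           "avg_targets_all": round_average(s.avg_all),
                           "avg_targets_promiscuous": round_average(s.avg_promiscuous)})
                t6.append({"subset": mt, "mw_range": label,
                           "p_ge2_targets_pct": round_percent(s.p_ge2),
                           "p_gt5_targets_pct": round_percent(s.p_gt5)})
        prof = []
        for mt, pv in self.prevalences.items():
            prof.append({"subset": mt, "n_promiscuous_assessed": pv.n_assessed,
                         "matches_prevalent_pct": round_percent(pv.frac_matches_prevalent),
                         "within_one_log_pct": round_percent(pv.frac_within_one_log),
                         "selectivity_outlier_pct": round_percent(pv.frac_selectivity_outlier)})
        scope = []
        for mt, b in self.scopes.items():
            scope.append({"subset": mt,
                          "single_pct": round_percent(b.frac_single),
                          "intra_family_pct": round_percent(b.frac_intra_family),
                          "cross_family_pct": round_percent(b.frac_cross_family)})
        cols = {
            "table1_average_promiscuity": (t1, ["category", "n_compounds", "avg_targets_all",
                                                "avg_targets_promiscuous",
                                                "median_targets_promiscuous", "median_threshold"]),
            "table2_probability": (t2, ["category", "p_ge2_targets_pct", "p_gt5_targets_pct"]),
            "table3_family_averages": (t3, ["subset", "family", "n_targets", "n_compounds",
                                            "avg_targets_all", "avg_targets_promiscuous"]),
            "table4_family_probability": (t4, ["subset", "family", "p_ge2_targets_pct",
                                               "p_gt5_targets_pct"]),
            "table5_mw_averages": (t5, ["subset", "mw_range", "n_compounds",
                                        "avg_targets_all", "avg_targets_promiscuous"]),
            "table6_mw_probability": (t6, ["subset", "mw_range", "p_ge2_targets_pct",
                                           "p_gt5_targets_pct"]),
            "profile_prevalence": (prof, ["subset", "n_promiscuous_assessed",
                                          "matches_prevalent_pct", "within_one_log_pct",
                                          "selectivity_outlier_pct"]),
            "family_scope": (scope, ["subset", "single_pct", "intra_family_pct",
                                     "cross_family_pct"]),
        }
        return {name: pd.DataFrame(rows, columns=columns)
                for name, (rows, columns) in cols.items()}

    def to_dict(self) -> dict:
        """Full-precision JSON-serialisable report."""
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x
        out = {
            "summaries": {k: v.as_dict() for k, v in self.summaries.items()},
            "family_summaries": {
                mt: {f: {"family": fs.family,
                         "n_targets_in_family": fs.n_targets_in_family,
                         "n_compounds": fs.n_compounds,
                         "summary": fs.summary.as_dict()}
                     for f, fs in fams.items()}
                for mt, fams in self.family_summaries.items()},
            "mw_summaries": {mt: {label: s.as_dict() for label, s in bins.items()}
                             for mt, bins in self.mw_summaries.items()},
            "family_scope": {mt: {"single": b.frac_single,
                                  "intra_family": b.frac_intra_family,
                                  "cross_family": b.frac_cross_family}
                             for mt, b in self.scopes.items()},
            "profile_prevalence": {mt: {k: clean(v) for k, v in asdict(pv).items()}
                                   for mt, pv in self.prevalences.items()},
            "assay_coverage": clean(self.assay_coverage),
            "provenance": self.provenance,
        }
        return out

    def save(self, out_dir) -> list[str]:
        """Write the TSV report tables and the full-precision JSON report."""
        return write_report_tables(self.to_frames(), self.to_dict(), out_dir)

    def summary(self) -> str:
        """Human-readable report of the main tables."""
        lines = ["Promiscuity analysis", "=" * 52]
        frames = self.to_frames()
        for name in ("table1_average_promiscuity", "table2_probability",
                     "family_scope", "profile_prevalence"):
            frame = frames[name]
            if frame.empty:
                continue
            lines.append("")
            lines.append(name.replace("_", " "))
            lines.append("-" * 52)
            lines.append(frame.to_string(index=False))
        if not math.isnan(self.assay_coverage):
            lines.append("")
            lines.append(f"assay coverage (> {self.provenance.get('min_assays', 50)} assays): "
                         f"{100 * self.assay_coverage:.1f}% of confirmed actives")
        gaps = self.verify_consistency()
        if gaps:
            worst = max(g for _, g in gaps)
            lines.append("")
            lines.append(f"mixture-identity check: {len(gaps)} summaries, max gap {worst:.2e}")
        return "\n".join(lines)

    def plot_target_distribution(self, subset: str = "Ki", ax=None, max_count: int = 10):
        """Bar plot of the per-compound distinct-target-count distribution."""
        import matplotlib.pyplot as plt
        counts = self.counts.get(subset)
        if counts is None or not len(counts):
            raise ValueError(f"no counts available for subset {subset!r}")
        n = counts["n_targets"].clip(upper=max_count)
        if ax is None:
            _, ax = plt.subplots()
        vals = n.value_counts(normalize=True).sort_index()
        ax.bar(vals.index, vals.to_numpy(), color="#4477aa")
        ax.set_xlabel("distinct targets per compound")
        ax.set_ylabel("fraction of compounds")
        ax.set_title(f"{subset} subset (n={len(counts)})")
        return ax
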