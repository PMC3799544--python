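"""Seeded generator of synthetic activity, drug-annotation and assay-outcome
tables with the statistical structure the promiscuity analysis assumes.

No public accession backs the analysed extracts, so every pipeline stage is
exercised against synthetic data emulating their empirical shape:

* per-compound distinct-target counts following a truncated geometric law
  concentrated at 1-3 targets with a thin tail past 5;
* same-family clustering of multi-target activity (each additional target
  stays in the compound's first family with a configurable bias);
* log-normally distributed potencies, i.e. normal on the pPotency scale,
  centred near-sub-µM;
* normal molecular weights truncated at zero;
* drug-target annotation counts with heavier tails for approved drugs than
  experimental ones, and confirmatory-assay outcome tables in which most
  active compounds have been tested in dozens of assays.

Generation is fully deterministic for a fixed master seed: every stream is
spawned from one ``numpy.random.SeedSequence``, and the emitted tables are
byte-identical across runs.  A ``ground_truth`` table carries each
compound's true target count, family scope and profile flags for recovery
tests; the profile flags are exact whenever replicate noise is disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io_model import FAMILIES, nM_from_p_potency


@dataclass(frozen=True)
class TargetCountLaw:
    """Distribution of per-compound distinct-target counts.

    Either a geometric law with success probability ``q`` truncated to
    ``1..k_max`` -- P(N = k) proportional to q(1-q)^(k-1) -- or an explicit
    probability vector ``probs`` over support ``values``.
    """

    kind: str = "geometric_truncated"
    q: float = 0.62
    k_max: int = 10
    values: tuple[int, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind == "geometric_truncated":
            if not 0.0 < self.q < 1.0:
                raise ValueError(f"q must be in (0, 1), got {self.q}")
            if self.k_max < 1:
                raise ValueError("k_max must be >= 1")
        elif self.kind == "explicit":
            if self.values is None or self.probs is None:
                raise ValueError("explicit law needs values and probs")
            v = np.asarray(self.values)
            p = np.asarray(self.probs, dtype=float)
            if len(v) != len(p) or (v < 1).any():
                raise ValueError("values must be >= 1 and match probs in length")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("probs must be non-negative and sum to 1")
        else:
            raise ValueError(f"unknown target_count_law kind: {self.kind!r}")

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, probabilities) of the law, normalised."""
        if self.kind == "explicit":
            v = np.asarray(self.values, dtype=int)
            p = np.asarray(self.probs, dtype=float)
            return v, p / p.sum()
        k = np.arange(1, self.k_max + 1)
        raw = self.q * (1.0 - self.q) ** (k - 1)
        return k, raw / raw.sum()


@dataclass(frozen=True)
class ExpectedStatistics:
    """Closed-form moments of a target-count law."""

    mean: float
    var: float
    p_ge2: float
    p_gt5: float


def expected_statistics(law: "TargetCountLaw | SyntheticConfig") -> ExpectedStatistics:
    """Exact E[N], Var[N], P(N >= 2) and P(N > 5) under a count law."""
    if isinstance(law, SyntheticConfig):
        law = law.target_count_law
    v, p = law.support()
    mean = float((v * p).sum())
    return ExpectedStatistics(
        mean=mean,
        var=float((v.astype(float) ** 2 * p).sum() - mean ** 2),
        p_ge2=float(p[v >= 2].sum()),
        p_gt5=float(p[v > 5].sum()),
    )


def _default_family_sizes() -> dict[str, int]:
    return {"GPCR_A": 40, "kinase": 30, "ion_channel": 15,
            "protease": 25, "nuclear_receptor": 10, "other": 30}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic dataset.

    Defaults emulate a medicinal-chemistry-like corpus: ~38% of compounds
    promiscuous with counts concentrated at 1-3 targets, strong same-family
    clustering, potencies centred just below 1 µM (mean pPotency 6.5, sd
    1.0), molecular weights near 400 Da, and approved drugs far more
    promiscuous than experimental ones.
    """

    n_compounds: int = 2000
    n_targets_per_family: dict = field(default_factory=_default_family_sizes)
    target_count_law: TargetCountLaw = field(default_factory=TargetCountLaw)
    intra_family_bias: float = 0.95
    mean_p: float = 6.5
    sd_p: float = 1.0
    mw_mean: float = 400.0
    mw_sd: float = 100.0
    p_ki: float = 0.45
    p_ic50: float = 0.45
    p_both: float = 0.10
    replicate_prob: float = 0.2
    replicate_noise_sd: float = 0.2
    confidence9_fraction: float = 0.9
    qualified_fraction: float = 0.05
    n_approved_drugs: int = 150
    n_experimental_drugs: int = 300
    approved_count_law: TargetCountLaw = field(
        default_factory=lambda: TargetCountLaw(q=0.17, k_max=30))
    experimental_count_law: TargetCountLaw = field(
        default_factory=lambda: TargetCountLaw(q=0.76, k_max=15))
    n_screen_compounds: int = 500
    n_screen_targets: int = 40
    n_assays: int = 120
    assays_tested_mean: float = 56.0
    screen_count_law: TargetCountLaw = field(
        default_factory=lambda: TargetCountLaw(q=0.49, k_max=15))
    seed: int = 0

    def __post_init__(self):
        for name in ("intra_family_bias", "replicate_prob", "confidence9_fraction",
                     "qualified_fraction", "p_ki", "p_ic50", "p_both"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_ki + self.p_ic50 + self.p_both - 1.0) > 1e-9:
            raise ValueError("measurement mix p_ki + p_ic50 + p_both must sum to 1")
        for name in ("n_compounds", "n_approved_drugs", "n_experimental_drugs",
                     "n_screen_compounds", "n_screen_targets", "n_assays"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sd_p < 0 or self.replicate_noise_sd < 0 or self.mw_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mw_mean <= 0:
            raise ValueError("mw_mean must be positive")
        sizes = self.n_targets_per_family
        if not sizes or any(s < 1 for s in sizes.values()):
            raise ValueError("n_targets_per_family must map families to positive counts")
        vmax = int(self.target_count_law.support()[0].max())
        if vmax > min(sizes.values()):
            raise ValueError(
                f"max target count {vmax} exceeds the smallest family size "
                f"{min(sizes.values())}: within-family counts could not stay distinct")


@dataclass
class SyntheticDataset:
    """Generated tables plus the generative ground truth."""

    activities: pd.DataFrame
    meta: pd.DataFrame
    drugs: pd.DataFrame
    assays: pd.DataFrame
    ground_truth: pd.DataFrame
    profile_truth: pd.DataFrame
    config: SyntheticConfig


def _sample_counts(law: TargetCountLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    v, p = law.support()
    return v[rng.choice(len(v), size=n, p=p)]


def _profile_flags(p_vals: np.ndarray, fams: list[str]) -> dict:
    """Prevalent-profile and selectivity-outlier flags from true potencies.

    Independent inline arithmetic (not the profiles module) so recovery
    tests compare two separate code paths.  Thresholds are the standard
    defaults: sub-µM strict at 1000 nM, spread <= 2 log units, 2-5 targets,
    outlier at best <= 100 nM with all others >= 10 µM.
    """
    spread = float(p_vals.max() - p_vals.min())
    all_sub = bool((p_vals > 6.0).all())
    same_fam = len(set(fams)) == 1
    n = len(p_vals)
    best_idx = int(np.argmax(p_vals))
    others = np.delete(p_vals, best_idx)
    return {
        "n_targets": n,
        "all_sub_uM": all_sub,
        "same_family": same_fam,
        "spread_log": spread,
        "matches_prevalent": bool(2 <= n <= 5 and all_sub and same_fam and spread <= 2.0),
        "within_one_log": bool(spread <= 1.0),
        "selectivity_outlier": bool(p_vals[best_idx] >= 7.0 and (others <= 5.0).all()),
    }


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate one complete synthetic dataset.

    ``seed`` overrides ``config.seed`` when given.  Deterministic: the same
    configuration and seed always produce identical tables.
    """
    config = config or SyntheticConfig()
    master = config.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(6)
    rng_struct, rng_pot, rng_mw, rng_rec, rng_drug, rng_assay = \
        (np.random.default_rng(s) for s in streams)

    families = sorted(config.n_targets_per_family)
    fam_sizes = np.array([config.n_targets_per_family[f] for f in families], dtype=float)
    fam_weights = fam_sizes / fam_sizes.sum()
    target_ids = {f: [f"{f}_T{i:03d}" for i in range(config.n_targets_per_family[f])]
                  for f in families}

    n = config.n_compounds
    counts = _sample_counts(config.target_count_law, n, rng_struct)
    first_fam_idx = rng_struct.choice(len(families), size=n, p=fam_weights)
    mtype_draw = rng_struct.choice(3, size=n, p=[config.p_ki, config.p_ic50, config.p_both])
    mtypes_per_compound = [("Ki",), ("IC50",), ("Ki", "IC50")]

    pair_compound, pair_target, pair_family = [], [], []
    scope_labels = np.empty(n, dtype=object)
    compound_ids = np.array([f"CPD{i:06d}" for i in range(n)])
    for i in range(n):
        k = int(counts[i])
        first = families[first_fam_idx[i]]
        stay = rng_struct.random(k - 1) < config.intra_family_bias if k > 1 else np.array([])
        n_home = 1 + int(stay.sum())
        home_targets = rng_struct.choice(len(target_ids[first]), size=n_home, replace=False)
        fams_i = [first] * n_home
        tids_i = [target_ids[first][t] for t in home_targets]
        used: dict[str, set] = {}
        for _ in range(k - n_home):
            other = families[rng_struct.choice(len(families))]
            while other == first:
                other = families[rng_struct.choice(len(families))]
            taken = used.setdefault(other, set())
            t = int(rng_struct.choice(len(target_ids[other])))
            while t in taken:
                t = int(rng_struct.choice(len(target_ids[other])))
            taken.add(t)
            fams_i.append(other)
            tids_i.append(target_ids[other][t])
        pair_compound.extend([compound_ids[i]] * k)
        pair_target.extend(tids_i)
        pair_family.extend(fams_i)
        scope_labels[i] = ("single" if k == 1
                           else "intra_family" if len(set(fams_i)) == 1
                           else "cross_family")

    pairs = pd.DataFrame({
        "compound_id": pair_compound,
        "target_id": pair_target,
        "target_family": pair_family,
    })
    comp_order = pd.Series(np.arange(n), index=compound_ids)

    # one true pPotency per (compound, target, measurement type)
    rec_rows = []
    profile_rows = []
    for mt_idx, mt in ((0, "Ki"), (1, "IC50")):
        has = np.isin(mtype_draw[comp_order[pairs["compound_id"]].to_numpy()], [mt_idx, 2])
        sub = pairs.loc[has].reset_index(drop=True)
        base_p = rng_pot.normal(config.mean_p, config.sd_p, size=len(sub))
        sub = sub.assign(measurement_type=mt, p_true=base_p)
        rec_rows.append(sub)
        for cid, grp in sub.groupby("compound_id", sort=False):
            if len(grp) >= 2:
                flags = _profile_flags(grp["p_true"].to_numpy(),
                                       list(grp["target_family"]))
                profile_rows.append({"compound_id": cid, "measurement_type": mt, **flags})
    true_pairs = pd.concat(rec_rows, ignore_index=True)

    # expand to measurement records: first replicate exact, optional second noisy
    dup = rng_rec.random(len(true_pairs)) < config.replicate_prob
    firsts = true_pairs.assign(p_meas=true_pairs["p_true"])
    seconds = true_pairs.loc[dup].assign(
        p_meas=lambda d: d["p_true"] + rng_rec.normal(0.0, config.replicate_noise_sd,
                                                      size=dup.sum()))
    records = pd.concat([firsts, seconds], ignore_index=True)
    m = len(records)
    high_conf = rng_rec.random(m) < config.confidence9_fraction
    qualified = rng_rec.random(m) < config.qualified_fraction
    qual_dir = rng_rec.random(m) < 0.5
    activities = pd.DataFrame({
        "compound_id": records["compound_id"],
        "target_id": records["target_id"],
        "target_family": records["target_family"],
        "measurement_type": records["measurement_type"],
        "value_nM": nM_from_p_potency(records["p_meas"].to_numpy()),
        "relation": np.where(qualified, np.where(qual_dir, "lt", "gt"), "eq"),
        "confidence_level": np.where(high_conf, 9, 4 + rng_rec.integers(0, 5, size=m)),
        "direct_interaction": high_conf,
        "source": "chembl_like",
    }).sort_values(["compound_id", "measurement_type", "target_id"],
                   kind="stable").reset_index(drop=True)

    mw = rng_mw.normal(config.mw_mean, config.mw_sd, size=n)
    while (mw <= 0).any():  # truncation at zero; essentially never loops at default scale
        bad = mw <= 0
        mw[bad] = rng_mw.normal(config.mw_mean, config.mw_sd, size=int(bad.sum()))
    meta = pd.DataFrame({"compound_id": compound_ids, "mw": mw, "category": "bioactive"})

    ground_truth = pd.DataFrame({
        "compound_id": compound_ids,
        "n_targets_true": counts,
        "family_scope_true": scope_labels,
        "measurement_types": [" + ".join(mtypes_per_compound[d]) for d in mtype_draw],
    })
    profile_truth = pd.DataFrame(
        profile_rows,
        columns=["compound_id", "measurement_type", "n_targets", "all_sub_uM",
                 "same_family", "spread_log", "matches_prevalent", "within_one_log",
                 "selectivity_outlier"])

    drugs = _generate_drugs(config, target_ids, families, fam_weights, rng_drug)
    assays = _generate_assays(config, rng_assay)

    return SyntheticDataset(activities=activities, meta=meta, drugs=drugs,
                            assays=assays, ground_truth=ground_truth,
                            profile_truth=profile_truth, config=config)


def _generate_drugs(config, target_ids, families, fam_weights, rng) -> pd.DataFrame:
    pool = [t for f in families for t in target_ids[f]]
    rows = []
    for status, n_drugs, law, prefix in (
            ("approved", config.n_approved_drugs, config.approved_count_law, "DAP"),
            ("experimental", config.n_experimental_drugs, config.experimental_count_law, "DEX")):
        if n_drugs == 0:
            continue
        counts = _sample_counts(law, n_drugs, rng)
        for i in range(n_drugs):
            k = min(int(counts[i]), len(pool))
            chosen = rng.choice(len(pool), size=k, replace=False)
            for t in chosen:
                rows.append((f"{prefix}{i:05d}", status, pool[t]))
    return pd.DataFrame(rows, columns=["drug_id", "drug_status", "target_id"])


def _generate_assays(config, rng) -> pd.DataFrame:
    if config.n_screen_compounds == 0 or config.n_assays == 0:
        return pd.DataFrame(columns=["compound_id", "assay_id", "target_id", "outcome"])
    screen_targets = [f"SCRN_T{i:03d}" for i in range(config.n_screen_targets)]
    assay_target = rng.choice(config.n_screen_targets, size=config.n_assays)
    rows = []
    for i in range(config.n_screen_compounds):
        cid = f"SCR{i:06d}"
        n_tested = int(min(rng.poisson(config.assays_tested_mean), config.n_assays))
        if n_tested == 0:
            continue
        tested = rng.choice(config.n_assays, size=n_tested, replace=False)
        tested_targets = np.unique(assay_target[tested])
        n_act = min(int(_sample_counts(config.screen_count_law, 1, rng)[0]),
                    len(tested_targets))
        active_set = set(rng.choice(tested_targets, size=n_act, replace=False).tolist())
        for a in sorted(tested):
            rows.append((cid, f"AID{a:04d}", screen_targets[assay_target[a]],
                         "active" if int(assay_target[a]) in active_set else "inactive"))
    return pd.DataFrame(rows, columns=["compound_id", "assay_id", "target_id", "outcome"])


def config_to_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("target_count_law", "approved_count_law",
                "experimental_count_law", "screen_count_law"):
        if key in raw and isinstance(raw[key], dict):
            law = dict(raw[key])
            for seq in ("values", "probs"):
                if law.get(seq) is not None:
                    law[seq] = tuple(law[seq])
            raw[key] = TargetCountLaw(**law)
    return SyntheticConfig(**raw)
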