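"""Independent brute-force reimplementations used as oracles.

Deliberately naive: plain dicts, lists and loops, no pandas, no shared code
with the package under test.
"""

import math


def naive_counts(pair_rows):
    """pair_rows: iterable of (compound_id, target_id) -> {compound: n_distinct}."""
    seen = {}
    for cid, tid in pair_rows:
        seen.setdefault(cid, set()).add(tid)
    return {cid: len(tids) for cid, tids in seen.items()}


def naive_summary(counts, threshold=2, median_threshold=None):
    """Summary statistics from a list of per-compound counts, by enumeration."""
    counts = list(counts)
    mt = threshold if median_threshold is None else median_threshold
    n = len(counts)
    if n == 0:
        return None
    prom = [c for c in counts if c >= threshold]
    med_set = sorted(c for c in counts if c >= mt)

    def median(xs):
        k = len(xs)
        if k == 0:
            return math.nan
        return xs[k // 2] if k % 2 else (xs[k // 2 - 1] + xs[k // 2]) / 2.0

    return {
        "n_compounds": n,
        "avg_all": sum(counts) / n,
        "avg_promiscuous": sum(prom) / len(prom) if prom else math.nan,
        "median_promiscuous": median(med_set),
        "p_ge2": sum(1 for c in counts if c >= 2) / n,
        "p_gt5": sum(1 for c in counts if c > 5) / n,
        "n_promiscuous": len(prom),
    }


def naive_scope(compound_families):
    """{compound: [family per target]} -> (labels dict, fractions tuple)."""
    labels = {}
    for cid, fams in compound_families.items():
        if len(fams) == 1:
            labels[cid] = "single"
        elif len(set(fams)) == 1:
            labels[cid] = "intra_family"
        else:
            labels[cid] = "cross_family"
    n = len(labels)
    fr = tuple(sum(1 for v in labels.values() if v == k) / n
               for k in ("single", "intra_family", "cross_family"))
    return labels, fr


def naive_assay_coverage(outcome_rows, min_assays=50):
    """outcome_rows: (compound, assay, outcome) -> coverage fraction."""
    tested = {}
    active = set()
    for cid, aid, out in outcome_rows:
        tested.setdefault(cid, set()).add(aid)
        if out == "active":
            active.add(cid)
    if not active:
        return math.nan
    return sum(1 for cid in active if len(tested[cid]) > min_assays) / len(active)


def naive_geometric_truncated(q, k_max):
    """(mean, p_ge2, p_gt5) of a truncated geometric by direct summation."""
    raw = [q * (1 - q) ** (k - 1) for k in range(1, k_max + 1)]
    z = sum(raw)
    probs = [r / z for r in raw]
    ks = list(range(1, k_max + 1))
    mean = sum(k * p for k, p in zip(ks, probs))
    p_ge2 = sum(p for k, p in zip(ks, probs) if k >= 2)
    p_gt5 = sum(p for k, p in zip(ks, probs) if k > 5)
    return mean, p_ge2, p_gt5
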