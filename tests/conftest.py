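import numpy as np
import pandas as pd
import pytest


def make_activities(rows):
    """Internal-schema activity frame from compact tuples:
    (compound, target, family, mtype, value_nM[, relation, conf, direct])."""
    full = []
    for r in rows:
        r = tuple(r) + ("eq", 9, True)[len(r) - 5:]
        full.append(r)
    df = pd.DataFrame(full, columns=["compound_id", "target_id", "target_family",
                                     "measurement_type", "value_nM", "relation",
                                     "confidence_level", "direct_interaction"])
    df["source"] = "chembl_like"
    return df


def write_activity_tsv(path, rows, header=None):
    """Write an external-schema activity TSV from raw string rows."""
    header = header or ("compound_id\ttarget_id\ttarget_family\tmeasurement_type\t"
                        "value\tunit\trelation\tconfidence_level\tdirect_interaction")
    path.write_text("\n".join([header] + list(rows)) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_activities():
    """Three compounds: one selective, one intra-family promiscuous, one cross-family."""
    return make_activities([
        ("c1", "GPCR_A_T1", "GPCR_A", "Ki", 100.0),
        ("c2", "GPCR_A_T1", "GPCR_A", "Ki", 300.0),
        ("c2", "GPCR_A_T2", "GPCR_A", "Ki", 500.0),
        ("c3", "GPCR_A_T1", "GPCR_A", "IC50", 50.0),
        ("c3", "kinase_T1", "kinase", "IC50", 2000.0),
    ])
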