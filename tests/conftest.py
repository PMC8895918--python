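import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_clone_table(rows, sample_id="M01_blood", isotype="IgM", **meta):
    """Small canonical clone table from (v, j, cdr3_nt, cdr3_aa, count) tuples."""
    base = {
        "sample_id": sample_id,
        "mouse_id": meta.get("mouse_id", sample_id.split("_")[0]),
        "strain": meta.get("strain", "BAL"),
        "tissue": meta.get("tissue", sample_id.split("_")[-1]),
        "batch": meta.get("batch", "round1"),
        "isotype": isotype,
    }
    records = []
    for v, j, nt, aa, count in rows:
        records.append({**base, "v_gene": v, "d_gene": meta.get("d_gene", "IGHD1"),
                        "j_gene": j, "cdr3_nt": nt, "cdr3_aa": aa, "count": count})
    columns = list(base) + ["v_gene", "d_gene", "j_gene", "cdr3_nt", "cdr3_aa", "count"]
    return pd.DataFrame(records, columns=columns)


# 21-nt CDR3s (7 aa): one mismatch is 20/21 = 95.24% identity, over threshold
CDR3_A = "TGTGCAAGAGATTATTGGTAC"   # CARDYW-like ancestor
CDR3_A1 = "TGTGCAAGAGATTATTGGTAA"[:-1] + "G"  # 1 mismatch from CDR3_A
CDR3_B = "ACCCGTTACCATGGCCATACC"   # unrelated, same length
CDR3_C = "TGTACTCGTGCATTCGGATGC"   # unrelated, other V/J group


@pytest.fixture
def toy_clones():
    """Two V/J groups: one >=95%-identity pair plus unrelated sequences."""
    return make_clone_table([
        ("IGHV1", "IGHJ1", CDR3_A, "CARDYWY", 5),
        ("IGHV1", "IGHJ1", CDR3_A1, "CARDYWC", 2),
        ("IGHV1", "IGHJ1", CDR3_B, "TRYHGHT", 1),
        ("IGHV2", "IGHJ2", CDR3_C, "CTRAFGC", 3),
    ])


def random_profile(rng, max_clonotypes=1000):
    n = int(rng.integers(1, max_clonotypes + 1))
    counts = rng.integers(1, 50, size=n)
    return {f"c{i}": int(c) for i, c in enumerate(counts)}


def random_nt(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
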