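"""Shared fixtures: tiny hand-built repertoires and random-record factories."""

from __future__ import annotations

import numpy as np
import pytest

from tcroverlap import ClonotypeRecord, KeyMode, aggregate

#: a few sense codons with their translations, for building valid CDR3s
CODONS = {"TGT": "C", "GCA": "A", "AAA": "K", "TTC": "F", "GGG": "G", "AGC": "S"}
V_SEGS = ("TRBV1", "TRBV2", "TRBV3", "TRBV19")
J_SEGS = ("TRBJ1-1", "TRBJ2-5", "TRBJ2-7")


def make_records(counts, productive=True, v_call="TRBV3", j_call="TRBJ2-5"):
    """Records keyed by clonotype label; ``productive`` may be a per-label dict."""
    recs = []
    for name, count in counts.items():
        prod = productive[name] if isinstance(productive, dict) else productive
        recs.append(ClonotypeRecord(cdr3_nt=name, cdr3_aa="", v_call=v_call,
                                    j_call=j_call, read_count=count, productive=prod))
    return recs


def rep_from_counts(counts, key_mode=KeyMode.NT_VJ, **kw):
    return aggregate(make_records(counts, **kw), key_mode=key_mode)


def random_rep(rng: np.random.Generator, n: int, label_pool: int | None = None,
               max_count: int = 1000):
    """A random repertoire over integer-labelled clonotypes (for oracles)."""
    pool = label_pool or 2 * n
    labels = rng.choice(pool, size=n, replace=False)
    counts = {f"c{l}": int(c) for l, c in zip(labels, rng.integers(1, max_count, size=n))}
    return rep_from_counts(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
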