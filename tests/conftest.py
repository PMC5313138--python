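"""Shared fixtures: planted-motif sets, synthetic family, tiny DBs."""

import numpy as np
import pytest

from relkit._align import AA_ORDER
from relkit.core_seq import ProteinSeq, SequenceSet
from relkit.synthetic_data import (FamilySpec, SignatureSpec, gen_decoys,
                                   gen_family, make_pwm)


def planted_literal_set(n=50, length=100, literal="HIHEKHTH", seed=5):
    """Sequences of i.i.d. uniform residues with one literal planted."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        codes = rng.integers(0, 20, size=length)
        s = "".join(AA_ORDER[c] for c in codes)
        pos = int(rng.integers(0, length - len(literal) + 1))
        s = s[:pos] + literal + s[pos + len(literal):]
        records.append(ProteinSeq(f"s{i:03d}", s))
    return SequenceSet(records)


def uniform_random_set(n=50, length=100, seed=0, prefix="r"):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        codes = rng.integers(0, 20, size=length)
        records.append(ProteinSeq(f"{prefix}{i:03d}",
                                  "".join(AA_ORDER[c] for c in codes)))
    return SequenceSet(records)


@pytest.fixture(scope="session")
def two_clade_family():
    """60-member two-clade family with one universal signature."""
    spec = FamilySpec(
        30, 30,
        [SignatureSpec("sigU", make_pwm("HIHEKHTHGWID"), {1: 1.0, 2: 1.0}),
         SignatureSpec("sigB", make_pwm("WQDNFYRAPL"), {1: 1.0, 2: 0.0})],
        member_length=120)
    return gen_family(spec, 7)


@pytest.fixture(scope="session")
def search_db(two_clade_family):
    """60 family members + 500 decoys, family seed first."""
    family, truth = two_clade_family
    decoys = gen_decoys(500, (100, 140), seed=8)
    db = SequenceSet(list(family) + list(decoys), source="fixture")
    return family, decoys, db, truth
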