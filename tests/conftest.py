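"""Shared fixtures: a hand-annotated canonical tRNA, tRNAscan-SE fixtures
generated programmatically, and a cached default simulation run."""

from __future__ import annotations

import pytest

from trnamod.annotation import TRNACluster
from trnamod.simulate import SimConfig, simulate_experiment


def _revcomp_rna(s: str) -> str:
    return s.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def make_cloverleaf(
    dloop: str = "AGACUGAA",
    var: str = "AGGUC",
    acc5: str = "GCGGAUU",
    dstem5: str = "GCUC",
    acstem5: str = "CAGAC",
    anticodon: str = "GAA",
    tstem5: str = "CGGAG",
    tloop: str = "UUCGAUC",
) -> TRNACluster:
    """A well-formed cloverleaf tRNA; defaults give the canonical 76-nt
    layout (7-bp acceptor, 2-nt 8/9 linker, 4-bp D-stem, 8-nt D-loop,
    5-bp anticodon stem, 7-nt loops, 5-nt variable loop, NCCA tail)."""
    seq = (
        acc5 + "UA" + dstem5 + dloop + _revcomp_rna(dstem5) + "A"
        + acstem5 + "UU" + anticodon + "AU" + _revcomp_rna(acstem5)
        + var + tstem5 + tloop + _revcomp_rna(tstem5)
        + _revcomp_rna(acc5) + "ACCA"
    )
    struct = (
        "(" * 7 + ".." + "(" * 4 + "." * len(dloop) + ")" * 4 + "."
        + "(" * 5 + "." * 7 + ")" * 5 + "." * len(var)
        + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + "...."
    )
    return TRNACluster(
        cluster_id=f"Phe-{anticodon.replace('U', 'T')}-1",
        member_ids=["fix.trna1"],
        sequence=seq,
        isotype="Phe",
        anticodon=anticodon,
        structure=struct,
    )


# Hand-annotated Sprinzl oracle for the canonical 76-nt layout above.
CANONICAL_LABELS = (
    [str(i) for i in range(1, 10)]                      # acceptor 1-7, linker 8-9
    + [str(i) for i in range(10, 14)]                   # D-stem 5'
    + [str(i) for i in range(14, 22)]                   # D-loop (8 nt)
    + [str(i) for i in range(22, 26)]                   # D-stem 3'
    + ["26"]
    + [str(i) for i in range(27, 32)]                   # anticodon stem 5'
    + [str(i) for i in range(32, 39)]                   # anticodon loop
    + [str(i) for i in range(39, 44)]                   # anticodon stem 3'
    + [str(i) for i in range(44, 49)]                   # variable loop (5 nt)
    + [str(i) for i in range(49, 54)]                   # T-stem 5'
    + [str(i) for i in range(54, 61)]                   # T-loop
    + [str(i) for i in range(61, 66)]                   # T-stem 3'
    + [str(i) for i in range(66, 73)]                   # acceptor 3'
    + ["73", "74", "75", "76"]                          # discriminator + CCA
)


@pytest.fixture
def canonical_cluster() -> TRNACluster:
    return make_cloverleaf()


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation: 20 clusters, depth 2000, background
    0.002, stop probability 0.2, 3 replicates, seed 1."""
    return simulate_experiment(SimConfig(seed=1))


def pooled_by_treatment(res):
    from trnamod.pileup import pool

    out = {}
    for tr in res.config.treatments:
        out[tr] = pool(
            res.pileups[s.sample_id] for s in res.samples if s.treatment == tr
        )
    return out
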