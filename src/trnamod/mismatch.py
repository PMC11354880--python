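"""Misincorporation-signature detection in untreated libraries.

Some modifications need no chemical treatment to be seen: they change base
pairing during cDNA synthesis and surface as position-specific mismatch
accumulations.  Three signatures are recognized here: inosine at position 34
(A read almost exclusively as G), m¹A at position 22 (A read as G or T) and
m¹G at position 37 (elevated mismatch over a genomic G).  Low-coverage
positions and mismatch fractions explainable by sequencing error are
suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from trnamod.annotation import TRNACluster
from trnamod.pileup import BASES, PileupMatrix

SEQ_ERROR_RATE = 0.01  # per-base miscall rate assumed for the noise test


@dataclass
class MismatchRecord:
    cluster_id: str
    index0: int
    sprinzl_label: str
    ref_base: str
    coverage: int
    fractions: dict[str, float]  # per observed base, of bases called at the position
    mismatch_fraction: float
    binom_pvalue: float  # P(mismatches >= observed | sequencing error alone)
    signature: str = "unassigned"  # inosine_A34 | m1A22 | m1G37 | unassigned


def profile_mismatches(
    p: PileupMatrix,
    cluster: TRNACluster | None = None,
    min_coverage: int = 10,
    min_mismatch_fraction: float = 0.10,
) -> list[MismatchRecord]:
    """Emit one record per position with coverage ≥ *min_coverage* and
    mismatch fraction ≥ *min_mismatch_fraction*, with signatures assigned
    when a Sprinzl map is available."""
    out: list[MismatchRecord] = []
    ref = cluster.sequence if cluster is not None else p.ref_seq
    for i in range(p.L):
        counts = p.base_counts[i]
        n = int(counts.sum())
        cov = int(p.coverage[i])
        if cov < min_coverage or n == 0:
            continue
        rb = ref[i].upper().replace("U", "T") if ref else "N"
        if rb not in BASES:
            continue
        n_ref = int(counts[BASES.index(rb)])
        mm = 1.0 - n_ref / n
        if mm < min_mismatch_fraction:
            continue
        rec = MismatchRecord(
            cluster_id=p.cluster_id,
            index0=i,
            sprinzl_label=(
                cluster.sprinzl.label_at(i)
                if cluster is not None and cluster.sprinzl is not None
                else "-"
            ),
            ref_base=rb,
            coverage=cov,
            fractions={b: int(counts[j]) / n for j, b in enumerate(BASES)},
            mismatch_fraction=mm,
            binom_pvalue=float(stats.binomtest(n - n_ref, n, SEQ_ERROR_RATE,
                                               alternative="greater").pvalue),
        )
        out.append(assign_signature(rec, min_mismatch_fraction))
    return out


def assign_signature(
    r: MismatchRecord, min_mismatch_fraction: float = 0.10
) -> MismatchRecord:
    """Attach a modification signature based on Sprinzl label, genomic base
    and the mismatch base pattern."""
    label, rb, f = r.sprinzl_label, r.ref_base, r.fractions
    if label == "34" and rb == "A" and f.get("G", 0.0) > 0.99:
        r.signature = "inosine_A34"
    elif label == "22" and rb == "A":
        mm_total = r.mismatch_fraction
        gt = f.get("G", 0.0) + f.get("T", 0.0)
        # G/T must dominate the mismatch portion of the reads
        if mm_total > 0 and gt / mm_total > 0.5 and mm_total >= min_mismatch_fraction:
            r.signature = "m1A22"
    elif label == "37" and rb == "G" and r.mismatch_fraction >= min_mismatch_fraction:
        r.signature = "m1G37"
    return r


def records_to_frame(records: Sequence[MismatchRecord]):
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "cluster_id": r.cluster_id,
            "index0": r.index0,
            "sprinzl_label": r.sprinzl_label,
            "ref_base": r.ref_base,
            "coverage": r.coverage,
            "mismatch_fraction": r.mismatch_fraction,
            "binom_pvalue": r.binom_pvalue,
            "signature": r.signature,
        }
        for b in BASES:
            row[f"frac_{b}"] = r.fractions.get(b, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
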