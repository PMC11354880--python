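"""Treated-vs-control RT-stop enrichment: γ scaling, fold change, Poisson
test, BH-FDR and the three noise filters.

For each cluster position the stop count of the treated library is compared
with the untreated (or buffer) control.  The control is put on the treated
library's scale by the per-cluster ratio γ of assigned reads; effect size is
a pseudocounted fold change FC = (Stop⁺ + α) / (γ·Stop⁻ + α) with α = 1;
significance is the upper tail P(X ≥ k) of a Poisson with background rate
λ = γ·Stop⁻, BH-adjusted over all tested positions jointly.  A site passes
when q < fdr, log₂FC > min_log2fc, Stop⁺ ≥ min_stops and the percentage of
stopped reads at the position ≥ min_stop_percent.  Because the reverse
transcriptase terminates one position before the modified nucleotide
(3'→5' synthesis), the reported modification index is stop_index − 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from trnamod.annotation import TRNACluster
from trnamod.pileup import PileupMatrix

logger = logging.getLogger(__name__)

LAMBDA_FLOOR = 1e-9  # avoids a degenerate zero-rate Poisson when Stop⁻ = 0


@dataclass
class CallParams:
    """Thresholds of the enrichment caller (defaults = operative cutoffs:
    FDR < 0.01, log2 FC > 1, total stops ≥ 20, percent stops ≥ 2, α = 1)."""

    fdr: float = 0.01
    min_log2fc: float = 1.0
    min_stops: int = 20
    min_stop_percent: float = 2.0
    alpha: float = 1.0
    literal_tail: bool = False  # debug: 1 - pmf(k) instead of P(X >= k)


@dataclass
class EnrichmentRecord:
    """One tested cluster position (stop index n+1 / modification index n)."""

    cluster_id: str
    stop_index: int
    mod_index: int
    sprinzl_label: str
    ref_base: str
    stop_plus: int
    stop_minus: int
    gamma: float
    lam: float
    fc: float
    log2fc: float
    pvalue: float
    qvalue: float = math.nan
    stop_percent: float = 0.0
    n_stops_total: int = 0
    pass_fdr: bool = False
    pass_fc: bool = False
    pass_count: bool = False
    pass_percent: bool = False

    @property
    def passed(self) -> bool:
        return self.pass_fdr and self.pass_fc and self.pass_count and self.pass_percent

    def apply_filters(self, params: "CallParams") -> "EnrichmentRecord":
        """Set the four pass flags from qvalue / log2fc / counts / percent."""
        self.pass_fdr = self.qvalue < params.fdr
        self.pass_fc = self.log2fc > params.min_log2fc
        self.pass_count = self.stop_plus >= params.min_stops
        self.pass_percent = self.stop_percent >= params.min_stop_percent
        return self


class EnrichmentError(ValueError):
    pass


def cluster_gamma(treated: PileupMatrix, control: PileupMatrix) -> float:
    """γ = reads assigned to the cluster in treated / in control; puts
    control stop counts on the treated library's scale."""
    if treated.cluster_id != control.cluster_id:
        raise EnrichmentError("gamma requires matching clusters")
    denom = control.reads_assigned
    if denom == 0:
        raise ZeroDivisionError(
            f"{control.cluster_id}: control cluster has zero assigned reads"
        )
    return treated.reads_assigned / denom


def fold_change(
    stop_plus: float, stop_minus: float, gamma: float, alpha: float = 1.0
) -> float:
    """Pseudocounted fold change FC = (Stop⁺ + α) / (γ·Stop⁻ + α)."""
    if stop_plus < 0 or stop_minus < 0:
        raise EnrichmentError("stop counts must be non-negative")
    if gamma <= 0 or alpha <= 0:
        raise EnrichmentError("gamma and alpha must be positive")
    return (stop_plus + alpha) / (gamma * stop_minus + alpha)


def poisson_sf_pvalue(k: int, lam: float, literal: bool = False) -> float:
    """Upper-tail Poisson p-value P(X ≥ k) for X ~ Poisson(λ).

    With *literal* the alternative reading 1 − pmf(k; λ) is returned for
    comparison; it is not a tail probability and exists only for debugging.
    """
    if lam < 0:
        raise EnrichmentError("lambda must be non-negative")
    if k < 0:
        raise EnrichmentError("k must be non-negative")
    if literal:
        return float(1.0 - stats.poisson.pmf(k, lam))
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1,
    order-preserving with respect to the input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# Control library paired with each treatment.
CONTROL_OF = {"NaBH4": "untreated", "CMCT": "CMCT_control"}


def call_sites(
    treated: Mapping[str, PileupMatrix],
    control: Mapping[str, PileupMatrix],
    clusters: Mapping[str, TRNACluster] | None = None,
    params: CallParams | None = None,
    all_sites: bool = False,
) -> list[EnrichmentRecord]:
    """Run the enrichment chain over every cluster position covered in both
    conditions and return passing records (or all tested records with
    *all_sites*), sorted by cluster and position.

    Counts are expected to be raw, pooled over replicates.  Stop index 0 is
    the full-length bin and yields no call (no upstream base).  Clusters
    present in only one condition, or with zero control reads, are skipped
    with a warning.
    """
    params = params or CallParams()
    records: list[EnrichmentRecord] = []
    for cid in sorted(treated):
        if cid not in control:
            logger.warning("%s: missing from control condition; skipped", cid)
            continue
        t, c = treated[cid], control[cid]
        if t.L != c.L:
            raise EnrichmentError(f"{cid}: length mismatch between conditions")
        try:
            gamma = cluster_gamma(t, c)
        except ZeroDivisionError:
            logger.warning("%s: zero control reads; gamma undefined, skipped", cid)
            continue
        clu = clusters.get(cid) if clusters else None
        for s in range(1, t.L):
            if t.coverage[s] == 0 or c.coverage[s] == 0:
                continue
            k = int(t.stop5[s])
            sm = int(c.stop5[s])
            lam = max(gamma * sm, LAMBDA_FLOOR)
            fc = fold_change(k, sm, gamma, params.alpha)
            n = s - 1
            label = "-"
            if clu is not None and clu.sprinzl is not None:
                label = clu.sprinzl.label_at(n)
            ref = clu.ref_base(n) if clu is not None else (t.ref_seq[n] if t.ref_seq else "N")
            records.append(
                EnrichmentRecord(
                    cluster_id=cid,
                    stop_index=s,
                    mod_index=n,
                    sprinzl_label=label,
                    ref_base=ref,
                    stop_plus=k,
                    stop_minus=sm,
                    gamma=gamma,
                    lam=lam,
                    fc=fc,
                    log2fc=math.log2(fc),
                    pvalue=poisson_sf_pvalue(k, lam, literal=params.literal_tail),
                    stop_percent=100.0 * k / int(t.coverage[s]),
                    n_stops_total=k,
                )
            )
    if records:
        q = bh_adjust([r.pvalue for r in records])
        for r, qv in zip(records, q):
            r.qvalue = float(qv)
            r.apply_filters(params)
    if all_sites:
        return records
    return [r for r in records if r.passed]


_REC_COLS = [
    "cluster_id", "stop_index", "mod_index", "sprinzl_label", "ref_base",
    "stop_plus", "stop_minus", "gamma", "lam", "fc", "log2fc", "pvalue",
    "qvalue", "stop_percent", "n_stops_total",
    "pass_fdr", "pass_fc", "pass_count", "pass_percent", "passed",
]


def records_to_frame(records: Sequence[EnrichmentRecord]):
    import pandas as pd

    return pd.DataFrame(
        [{c: getattr(r, c) for c in _REC_COLS} for r in records], columns=_REC_COLS
    )
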