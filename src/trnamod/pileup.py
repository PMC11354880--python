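"""Per-cluster pileups: coverage, 5'-end (RT-stop) counts, base composition.

The RT-stop signal of this protocol lives in read 5' ends: reverse
transcription runs 3'→5' along the tRNA template, so a premature termination
leaves a cDNA whose genomic 5'-most aligned base marks the stop.  This module
turns single-end alignments against the cluster references (or pre-computed
pileup tables) into integer matrices of coverage, 5'-end counts and aligned
base composition, and provides the library-/replicate-wise scaling used for
QC profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

TREATMENTS = ("untreated", "NaBH4", "CMCT", "CMCT_control")


class PileupError(ValueError):
    pass


@dataclass(frozen=True)
class LibrarySample:
    """One sequencing library: organism, growth temperature, chemical
    treatment (untreated / NaBH4 / CMCT / CMCT_control) and replicate."""

    sample_id: str
    organism: str
    temperature: int
    treatment: str
    replicate: int
    path: str = ""

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise PileupError(
                f"{self.sample_id}: unknown treatment {self.treatment!r} "
                f"(expected one of {TREATMENTS})"
            )

    @property
    def group(self) -> tuple[str, int]:
        return (self.organism, self.temperature)


@dataclass
class PileupMatrix:
    """Position-wise counts for one cluster in one library.

    ``stop5[i]`` counts reads whose 5'-most aligned reference index is *i*
    (full-length reads land at index 0); ``coverage[i]`` counts reads whose
    alignment spans *i*; ``base_counts[i, b]`` counts aligned read bases.
    """

    cluster_id: str
    ref_seq: str = ""  # DNA alphabet; may be "" when unknown
    coverage: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    stop5: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    base_counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    total_mapped_reads: int = 0  # per-sample total across all clusters

    @classmethod
    def zeros(cls, cluster_id: str, length: int, ref_seq: str = "") -> "PileupMatrix":
        return cls(
            cluster_id=cluster_id,
            ref_seq=ref_seq,
            coverage=np.zeros(length, dtype=np.int64),
            stop5=np.zeros(length, dtype=np.int64),
            base_counts=np.zeros((length, 4), dtype=np.int64),
        )

    @property
    def L(self) -> int:
        return len(self.coverage)

    @property
    def reads_assigned(self) -> int:
        """Number of reads assigned to this cluster (sum of 5'-end counts)."""
        return int(self.stop5.sum())

    def validate(self) -> None:
        if np.any(self.stop5 < 0) or np.any(self.coverage < 0) or np.any(self.base_counts < 0):
            raise PileupError(f"{self.cluster_id}: negative counts")
        if np.any(self.stop5 > self.coverage):
            raise PileupError(f"{self.cluster_id}: stop5 exceeds coverage")
        if np.any(self.base_counts.sum(axis=1) > self.coverage):
            raise PileupError(f"{self.cluster_id}: base counts exceed coverage")

    def __add__(self, other: "PileupMatrix") -> "PileupMatrix":
        if other.cluster_id != self.cluster_id or other.L != self.L:
            raise PileupError("cannot pool pileups of different clusters")
        return PileupMatrix(
            cluster_id=self.cluster_id,
            ref_seq=self.ref_seq or other.ref_seq,
            coverage=self.coverage + other.coverage,
            stop5=self.stop5 + other.stop5,
            base_counts=self.base_counts + other.base_counts,
            total_mapped_reads=self.total_mapped_reads + other.total_mapped_reads,
        )


def pool(pileups: Iterable[Mapping[str, PileupMatrix]]) -> dict[str, PileupMatrix]:
    """Sum raw counts across replicates, cluster by cluster."""
    out: dict[str, PileupMatrix] = {}
    for pm in pileups:
        for cid, p in pm.items():
            out[cid] = out[cid] + p if cid in out else p
    return out


@dataclass
class NormalizedProfile:
    """Real-valued per-position stop/coverage tracks after library scaling."""

    cluster_id: str
    stop5: np.ndarray
    coverage: np.ndarray

    @property
    def L(self) -> int:
        return len(self.stop5)


# ---------------------------------------------------------------------------
# Counting from alignments
# ---------------------------------------------------------------------------

def count_from_alignments(
    path: str | Path,
    clusters: Mapping[str, str],
    min_mapq: int = 0,
    min_base_quality: int = 20,
) -> dict[str, PileupMatrix]:
    """Count stops/coverage/base composition from a SAM/BAM of single-end
    reads aligned to the cluster references.

    Only primary, non-supplementary alignments with MAPQ >= *min_mapq* are
    counted.  The RT-stop position is the reference-leftmost aligned index
    (soft-clipped bases are unaligned and do not move it).  Bases below
    *min_base_quality* are excluded from the base composition (mirroring a
    variant caller's confidence gate) but still count toward coverage.

    *clusters* maps cluster_id → reference sequence (DNA).
    """
    result = {cid: PileupMatrix.zeros(cid, len(seq), seq) for cid, seq in clusters.items()}
    n_reads = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        unknown = [r for r in (af.references or []) if r not in clusters]
        if unknown:
            raise PileupError(f"unknown reference(s) in {path}: {sorted(unknown)}")
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            p = result[aln.reference_name]
            p.stop5[aln.reference_start] += 1
            n_reads += 1
            quals = aln.query_qualities
            seq = aln.query_sequence
            for qpos, rpos in aln.get_aligned_pairs():
                if rpos is None:  # insertion in read
                    continue
                p.coverage[rpos] += 1
                if qpos is None:  # deletion: covered, no base observed
                    continue
                b = seq[qpos].upper()
                if b in _BASE_IDX and (quals is None or quals[qpos] >= min_base_quality):
                    p.base_counts[rpos, _BASE_IDX[b]] += 1
    if n_reads == 0:
        logger.warning("no usable alignments in %s", path)
    for p in result.values():
        p.total_mapped_reads = n_reads
        p.validate()
    return result


# ---------------------------------------------------------------------------
# Pileup TSV round trip
# ---------------------------------------------------------------------------

_COLS = ["cluster_id", "index0", "ref_base", "coverage", "stop5", "nA", "nC", "nG", "nT"]


def write_pileup_tsv(
    pileups: Mapping[str, PileupMatrix], path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        total = max((p.total_mapped_reads for p in pileups.values()), default=0)
        fh.write(f"# total_mapped_reads={total}\n")
        fh.write("\t".join(_COLS) + "\n")
        for cid in sorted(pileups):
            p = pileups[cid]
            for i in range(p.L):
                rb = p.ref_seq[i] if p.ref_seq else "N"
                fh.write(
                    f"{cid}\t{i}\t{rb}\t{p.coverage[i]}\t{p.stop5[i]}\t"
                    f"{p.base_counts[i, 0]}\t{p.base_counts[i, 1]}\t"
                    f"{p.base_counts[i, 2]}\t{p.base_counts[i, 3]}\n"
                )


def read_pileup_tsv(path: str | Path) -> dict[str, PileupMatrix]:
    total = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "total_mapped_reads=" in line:
                    total = int(line.rsplit("=", 1)[1])
                continue
            rows.append(line)
    if not rows:
        return {}
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t")
    missing = set(_COLS) - set(df.columns)
    if missing:
        raise PileupError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, PileupMatrix] = {}
    for cid, sub in df.groupby("cluster_id", sort=False):
        sub = sub.sort_values("index0")
        if list(sub["index0"]) != list(range(len(sub))):
            raise PileupError(f"{path}: non-contiguous indices for {cid}")
        p = PileupMatrix(
            cluster_id=str(cid),
            ref_seq="".join(sub["ref_base"].astype(str)),
            coverage=sub["coverage"].to_numpy(dtype=np.int64),
            stop5=sub["stop5"].to_numpy(dtype=np.int64),
            base_counts=sub[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64),
            total_mapped_reads=total,
        )
        p.validate()
        out[str(cid)] = p
    return out


# ---------------------------------------------------------------------------
# Normalization (QC tracks)
# ---------------------------------------------------------------------------

def normalize_library(p: PileupMatrix, scale_to: float = 1e6) -> NormalizedProfile:
    """Scale a pileup to *scale_to* total mapped reads (library-wise)."""
    if p.total_mapped_reads <= 0:
        raise PileupError(f"{p.cluster_id}: total_mapped_reads must be positive")
    f = scale_to / p.total_mapped_reads
    return NormalizedProfile(
        cluster_id=p.cluster_id,
        stop5=p.stop5.astype(float) * f,
        coverage=p.coverage.astype(float) * f,
    )


def replicate_mean(profiles: Sequence[NormalizedProfile]) -> NormalizedProfile:
    """Position-wise mean across replicate profiles (replica-wise scaling)."""
    if not profiles:
        raise PileupError("replicate_mean requires at least one profile")
    cid = profiles[0].cluster_id
    L = profiles[0].L
    for q in profiles[1:]:
        if q.cluster_id != cid or q.L != L:
            raise PileupError("replicate profiles must share cluster and length")
    return NormalizedProfile(
        cluster_id=cid,
        stop5=np.mean([q.stop5 for q in profiles], axis=0),
        coverage=np.mean([q.coverage for q in profiles], axis=0),
    )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[LibrarySample]:
    """TSV with columns sample_id, organism, temperature, treatment,
    replicate, path."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"sample_id", "organism", "temperature", "treatment", "replicate", "path"}
    missing = needed - set(df.columns)
    if missing:
        raise PileupError(f"{path}: sample sheet missing columns {sorted(missing)}")
    samples = [
        LibrarySample(
            sample_id=str(r.sample_id),
            organism=str(r.organism),
            temperature=int(r.temperature),
            treatment=str(r.treatment),
            replicate=int(r.replicate),
            path=str(r.path),
        )
        for r in df.itertuples()
    ]
    keys = [(s.organism, s.temperature, s.treatment, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise PileupError(f"{path}: duplicate (organism, temperature, treatment, replicate)")
    return samples
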