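"""Synthetic treated/control tRNA-seq experiments with planted modifications.

The generator emulates the study design the statistics are built for: three
biological replicates of four libraries (untreated, borohydride-treated,
carbodiimide-treated and its buffer control) over a set of tRNA clusters.
Reads start at the tRNA 3' end (the adapter-ligation/RT protocol) and walk
5'-ward, surviving each position independently; a planted modification raises
the termination probability at the position one nucleotide 3' of the modified
base, exactly the offset the caller must undo.  A linear 3'-biased background
termination rate mimics the reverse transcriptase's tendency to fall off
early in the 3' half.  Base-miscall sites emulate mismatch-signature
modifications (inosine 34, m¹A22).

Counts are drawn analytically: the per-read sequential-survival process
induces a multinomial over stop positions, so pileups are sampled directly
from it — byte-identical output under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from trnamod.annotation import (
    SprinzlMap,
    TRNACluster,
    assign_sprinzl,
    to_dna,
    write_cluster_fasta,
    write_sprinzl_tsv,
)
from trnamod.classify import ModificationCall
from trnamod.pileup import BASES, LibrarySample, PileupMatrix, write_pileup_tsv

RNA_COMP = str.maketrans("ACGU", "UGCA")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSite:
    cluster_id: str
    label: str  # Sprinzl label of the modified base
    modification: str  # D | s4U | m7G | Psi
    treatment: str  # library in which the stop is enhanced
    stop_prob: float = 0.2


@dataclass(frozen=True)
class MiscallSite:
    cluster_id: str
    label: str
    target_base: str  # base read instead of the genomic one
    fraction: float


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults mirror the real design: 3 replicates x 4 treatments, mean
    per-cluster depth 2000 reads (Poisson), background termination 0.002 per
    position rising linearly toward the 3' end, planted stop probability 0.2.
    With ``planted=None`` two sites per cluster are planted automatically
    (one borohydride-track, one carbodiimide-track) at cataloged positions.
    """

    n_clusters: int = 20
    depth: float = 2000.0
    background_stop: float = 0.002
    bias_3prime: float = 1.0  # background multiplied by (1 + bias * i/(L-1))
    replicates: int = 3
    treatments: tuple[str, ...] = ("untreated", "NaBH4", "CMCT", "CMCT_control")
    planted: list[PlantedSite] | None = None
    miscalls: list[MiscallSite] | None = None
    organism: str = "SimOrg"
    temperature: int = 37
    seed: int = 1


@dataclass
class SimTruth:
    sites: list[PlantedSite]
    indices: dict[tuple[str, str], int]  # (cluster_id, label) -> index0

    def index0(self, s: PlantedSite) -> int:
        return self.indices[(s.cluster_id, s.label)]


@dataclass
class SimResult:
    clusters: list[TRNACluster]
    samples: list[LibrarySample]
    pileups: dict[str, dict[str, PileupMatrix]]  # sample_id -> cluster -> pileup
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Cluster generation
# ---------------------------------------------------------------------------

_ISOACCEPTORS = [
    ("Ala", "AGC"), ("Arg", "ACG"), ("Arg", "CCU"), ("Asn", "GUU"),
    ("Asp", "GUC"), ("Cys", "GCA"), ("Gln", "UUG"), ("Glu", "UUC"),
    ("Gly", "GCC"), ("Gly", "UCC"), ("His", "GUG"), ("Ile", "GAU"),
    ("Leu", "UAA"), ("Leu", "GAG"), ("Lys", "UUU"), ("Met", "CAU"),
    ("Phe", "GAA"), ("Pro", "UGG"), ("Ser", "GCU"), ("Thr", "UGU"),
    ("Trp", "CCA"), ("Tyr", "GUA"), ("Val", "UAC"), ("Ser", "UGA"),
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def _revcomp_rna(s: str) -> str:
    return s.translate(RNA_COMP)[::-1]


def _make_cluster(
    rng: np.random.Generator, isotype: str, anticodon: str, serial: int
) -> TRNACluster:
    """One cloverleaf tRNA with U at the cataloged treatment-target positions
    (8, D-loop, 39 partner, T-loop) so sites can be planted there."""
    acc5 = _rand_seq(rng, 7)
    linker1 = "U" + rng.choice(list("AG"))  # U8 (s4U target), purine 9
    dstem5 = _rand_seq(rng, 3) + "U"  # U13 -> A22 partner (m1A22 target)
    dloop_len = int(rng.choice([8, 9, 10]))
    dloop = "U" * dloop_len  # D-loops are U-rich; makes D sites plantable
    linker2 = rng.choice(list("AG"))  # 26
    acstem5 = _rand_seq(rng, 3) + rng.choice(list("CG")) + "A"  # A31 -> U39
    acloop = "U" + rng.choice(list("CU")) + anticodon + rng.choice(list("AG")) + "U"
    # variable loop: G at label 46 (m7G target); U at 47 when present (5 nt)
    var_len = int(rng.choice([4, 5]))
    if var_len == 5:  # labels 44 45 46 47 48
        var = _rand_seq(rng, 2) + "GU" + _rand_seq(rng, 1)
    else:  # labels 44 45 46 48 (47 absent)
        var = _rand_seq(rng, 2) + "G" + _rand_seq(rng, 1)
    tstem5 = _rand_seq(rng, 5)
    tloop = "UUCGAAU"  # 54U 55U(Psi) 56C 57G 58A 59A 60U(Psi)
    seq = (
        acc5 + linker1 + dstem5 + dloop + _revcomp_rna(dstem5) + linker2
        + acstem5 + acloop + _revcomp_rna(acstem5)
        + var + tstem5 + tloop + _revcomp_rna(tstem5)
        + _revcomp_rna(acc5) + rng.choice(list("ACGU")) + "CCA"
    )
    struct = (
        "(" * 7 + "." * 2 + "(" * 4 + "." * dloop_len + ")" * 4 + "."
        + "(" * 5 + "." * 7 + ")" * 5 + "." * var_len
        + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + "." * 4
    )
    c = TRNACluster(
        cluster_id=f"{isotype}-{to_dna(anticodon)}-{serial}",
        member_ids=[f"sim.trna{serial}"],
        sequence=seq,
        isotype=isotype,
        anticodon=anticodon,
        structure=struct,
    )
    assign_sprinzl(c)
    return c


def _auto_plant(clusters: Sequence[TRNACluster], rng: np.random.Generator,
                stop_prob: float = 0.2) -> list[PlantedSite]:
    """Two sites per cluster at cataloged positions: one borohydride-track
    (s4U8 / D / m7G46), one carbodiimide-track (Psi)."""
    nabh4_mods = [("8", "s4U"), ("16", "D"), ("17", "D"), ("20", "D"),
                  ("20a", "D"), ("21", "D"), ("47", "D"), ("46", "m7G")]
    psi_labels = ["13", "32", "38", "39", "55", "60"]
    sites = []
    for c in clusters:
        have = set(c.sprinzl.labels)
        cands = [(l, m) for l, m in nabh4_mods if l in have]
        lab, mod = cands[int(rng.integers(len(cands)))]
        sites.append(PlantedSite(c.cluster_id, lab, mod, "NaBH4", stop_prob))
        lab = psi_labels[int(rng.integers(len(psi_labels)))]
        sites.append(PlantedSite(c.cluster_id, lab, "Psi", "CMCT", stop_prob))
    return sites


def _auto_miscalls(clusters: Sequence[TRNACluster]) -> list[MiscallSite]:
    sites = []
    for c in clusters:
        if c.anticodon.startswith("A"):
            sites.append(MiscallSite(c.cluster_id, "34", "G", 0.995))
        elif int(c.cluster_id[-1]) % 3 == 0:
            sites.append(MiscallSite(c.cluster_id, "22", "G", 0.45))
            sites.append(MiscallSite(c.cluster_id, "22", "T", 0.35))
    return sites


def default_config(seed: int = 1, **overrides) -> SimConfig:
    return dataclasses.replace(SimConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _stop_probs(L: int, cfg: SimConfig) -> np.ndarray:
    """Background termination probability per stop index (index 0 = full
    length, never a termination site itself)."""
    p = np.zeros(L)
    i = np.arange(1, L)
    p[1:] = cfg.background_stop * (1.0 + cfg.bias_3prime * i / (L - 1))
    return p


def _stop_distribution(p_stop: np.ndarray) -> np.ndarray:
    """P(read 5'-most index = i) for the sequential-survival walk from the
    3' end: stop at i with prob p[i] after surviving all j > i."""
    L = len(p_stop)
    probs = np.zeros(L)
    surv = 1.0
    for i in range(L - 1, 0, -1):
        probs[i] = surv * p_stop[i]
        surv *= 1.0 - p_stop[i]
    probs[0] = surv  # full-length reads
    return probs


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Generate clusters, samples, truth and per-sample pileups."""
    rng = np.random.default_rng(cfg.seed)
    clusters = []
    for k in range(cfg.n_clusters):
        iso, ac = _ISOACCEPTORS[k % len(_ISOACCEPTORS)]
        clusters.append(_make_cluster(rng, iso, ac, k + 1))
    by_id = {c.cluster_id: c for c in clusters}

    planted = cfg.planted if cfg.planted is not None else _auto_plant(clusters, rng)
    miscalls = cfg.miscalls if cfg.miscalls is not None else _auto_miscalls(clusters)

    indices: dict[tuple[str, str], int] = {}
    for s in planted:
        if s.cluster_id not in by_id:
            raise SimulationError(f"planted site references unknown cluster {s.cluster_id}")
        c = by_id[s.cluster_id]
        try:
            idx = c.sprinzl.index_of(s.label)
        except KeyError:
            raise SimulationError(
                f"planted label {s.label!r} absent from cluster {s.cluster_id}"
            ) from None
        if idx + 1 >= len(c.sequence):
            raise SimulationError(f"planted site at 3' terminus of {s.cluster_id}")
        indices[(s.cluster_id, s.label)] = idx
    truth = SimTruth(sites=list(planted), indices=indices)

    mis_resolved: dict[str, list[tuple[int, str, float]]] = {}
    for m in miscalls:
        c = by_id[m.cluster_id]
        idx = c.sprinzl.index_of(m.label)
        mis_resolved.setdefault(m.cluster_id, []).append((idx, m.target_base, m.fraction))

    samples = []
    for tr in cfg.treatments:
        for rep in range(1, cfg.replicates + 1):
            samples.append(
                LibrarySample(
                    sample_id=f"{cfg.organism}_{cfg.temperature}C_{tr}_r{rep}",
                    organism=cfg.organism,
                    temperature=cfg.temperature,
                    treatment=tr,
                    replicate=rep,
                )
            )

    planted_by_cluster: dict[str, list[PlantedSite]] = {}
    for s in planted:
        planted_by_cluster.setdefault(s.cluster_id, []).append(s)

    pileups: dict[str, dict[str, PileupMatrix]] = {}
    for sample in samples:
        per_cluster: dict[str, PileupMatrix] = {}
        total = 0
        for c in clusters:
            L = len(c.sequence)
            p_stop = _stop_probs(L, cfg)
            for s in planted_by_cluster.get(c.cluster_id, []):
                if s.treatment == sample.treatment:
                    p_stop[truth.index0(s) + 1] = s.stop_prob
            probs = _stop_distribution(p_stop)
            n_reads = int(rng.poisson(cfg.depth))
            stop5 = rng.multinomial(n_reads, probs)
            coverage = np.cumsum(stop5)
            pm = PileupMatrix(
                cluster_id=c.cluster_id,
                ref_seq=to_dna(c.sequence),
                coverage=coverage.astype(np.int64),
                stop5=stop5.astype(np.int64),
                base_counts=np.zeros((L, 4), dtype=np.int64),
                total_mapped_reads=0,
            )
            ref_idx = np.array([BASES.index(b) for b in pm.ref_seq])
            pm.base_counts[np.arange(L), ref_idx] = coverage
            # miscall sites: split coverage multinomially among target bases
            # and the remaining reference-base reads
            by_index: dict[int, list[tuple[str, float]]] = {}
            for idx, tb, frac in mis_resolved.get(c.cluster_id, []):
                by_index.setdefault(idx, []).append((tb, frac))
            for idx, targets in by_index.items():
                fr = [f for _, f in targets]
                if sum(fr) > 1.0:
                    raise SimulationError(
                        f"miscall fractions at {c.cluster_id} index {idx} exceed 1"
                    )
                draws = rng.multinomial(int(coverage[idx]), fr + [1.0 - sum(fr)])
                pm.base_counts[idx, ref_idx[idx]] = draws[-1]
                for (tb, _), n_mis in zip(targets, draws[:-1]):
                    pm.base_counts[idx, BASES.index(tb)] += n_mis
            per_cluster[c.cluster_id] = pm
            total += n_reads
        for pm in per_cluster.values():
            pm.total_mapped_reads = total
            pm.validate()
        pileups[sample.sample_id] = per_cluster
    return SimResult(clusters=clusters, samples=samples, pileups=pileups,
                     truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# File emission / truth round trip
# ---------------------------------------------------------------------------

def write_experiment(res: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Emit the exact file formats the rest of the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "clusters.fasta",
        "sprinzl": outdir / "sprinzl.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_cluster_fasta(res.clusters, paths["fasta"])
    write_sprinzl_tsv(res.clusters, paths["sprinzl"])
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\torganism\ttemperature\ttreatment\treplicate\tpath\n")
        for s in res.samples:
            p = outdir / f"pileup_{s.sample_id}.tsv"
            write_pileup_tsv(res.pileups[s.sample_id], p,
                             header_comment=f"sample={s.sample_id} seed={res.config.seed}")
            # paths relative to the sheet keep the output relocatable and
            # byte-identical across output directories
            fh.write(f"{s.sample_id}\t{s.organism}\t{s.temperature}\t"
                     f"{s.treatment}\t{s.replicate}\t{p.name}\n")
    write_truth_tsv(res.truth, paths["truth"])
    return paths


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tindex0\tsprinzl_label\tmodification\ttreatment\tstop_prob\n")
        for s in truth.sites:
            fh.write(f"{s.cluster_id}\t{truth.index0(s)}\t{s.label}\t"
                     f"{s.modification}\t{s.treatment}\t{s.stop_prob}\n")


def read_truth_tsv(path: str | Path) -> SimTruth:
    sites, indices = [], {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            cid, idx, lab, mod, tr, sp = line.rstrip("\n").split("\t")
            sites.append(PlantedSite(cid, lab, mod, tr, float(sp)))
            indices[(cid, lab)] = int(idx)
    return SimTruth(sites=sites, indices=indices)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(
    calls: Sequence[ModificationCall], truth: SimTruth
) -> dict:
    """Confusion summary of a classified passing callset against the planted
    truth: sensitivity (planted sites recovered as TP at the planted index),
    observed FDR (passing sites not planted / all passing), per-modification
    breakdown.  With no calls at all, FDR is reported as 0 with a flag."""
    call_keys = {(c.cluster_id, c.record.mod_index, c.treatment) for c in calls}
    tp_keys = {
        (c.cluster_id, c.record.mod_index, c.treatment)
        for c in calls
        if c.status == "TP_known"
    }
    per_mod: dict[str, dict[str, int]] = {}
    n_recovered = 0
    planted_keys = set()
    for s in truth.sites:
        key = (s.cluster_id, truth.index0(s), s.treatment)
        planted_keys.add(key)
        d = per_mod.setdefault(s.modification, {"planted": 0, "recovered": 0})
        d["planted"] += 1
        if key in tp_keys:
            d["recovered"] += 1
            n_recovered += 1
    n_calls = len(call_keys)
    n_false = len(call_keys - planted_keys)
    return {
        "n_planted": len(planted_keys),
        "n_recovered": n_recovered,
        "n_calls": n_calls,
        "n_false": n_false,
        "sensitivity": n_recovered / len(planted_keys) if planted_keys else 0.0,
        "observed_fdr": n_false / n_calls if n_calls else 0.0,
        "no_calls": n_calls == 0,
        "per_modification": per_mod,
    }
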