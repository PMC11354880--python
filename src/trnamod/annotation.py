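"""tRNA gene annotation, identical-sequence clustering and Sprinzl coordinates.

Consumes tRNAscan-SE v2.0 tabular output (optionally with its ``-f`` secondary
structure companion file and/or a genome FASTA), groups genes with identical
mature sequence into clusters — the mapping references used downstream, which
sidestep the multi-copy nature of tRNA genes — and assigns standard (Sprinzl)
position labels to every cluster index by decomposing the dot-bracket
secondary structure into the four-arm cloverleaf.

Sprinzl labels are the field's canonical tRNA coordinates: 1–76 for the core,
insertion labels ``17a``, ``20a``, ``20b`` in the D-loop and ``e1``… for long
variable arms.  They let a position such as "G46" be compared across tRNAs of
different lengths.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_RNA = str.maketrans("Tt", "Uu")
_DNA = str.maketrans("Uu", "Tt")


class AnnotationError(ValueError):
    """Malformed annotation input."""


class SprinzlError(ValueError):
    """Structure cannot be decomposed into a cloverleaf; a user-supplied
    coordinate map (``--sprinzl-map``) may be needed for this tRNA."""


def to_rna(seq: str) -> str:
    return seq.upper().translate(_RNA)


def to_dna(seq: str) -> str:
    return seq.upper().translate(_DNA)


@dataclass
class TRNAGene:
    """A single annotated tRNA gene with its mature (sense, intron-free) RNA."""

    gene_id: str
    isotype: str
    anticodon: str
    mature_sequence: str  # RNA alphabet ACGU
    structure: str  # dot-bracket, same length as mature_sequence ("" if unknown)
    locus: tuple[str, int, int, str]  # contig, start, end (0-based half-open), strand

    def __post_init__(self) -> None:
        self.mature_sequence = to_rna(self.mature_sequence)
        self.anticodon = to_rna(self.anticodon)
        if self.structure and len(self.structure) != len(self.mature_sequence):
            raise AnnotationError(
                f"{self.gene_id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.mature_sequence)}"
            )
        if not 55 <= len(self.mature_sequence) <= 120:
            raise AnnotationError(
                f"{self.gene_id}: mature length {len(self.mature_sequence)} "
                "outside the plausible tRNA range 55-120"
            )
        if self.anticodon and self.anticodon not in self.mature_sequence:
            raise AnnotationError(
                f"{self.gene_id}: anticodon {self.anticodon} not found in mature sequence"
            )


@dataclass
class SprinzlMap:
    """One Sprinzl label per 0-based cluster sequence index ("-" = unlabeled)."""

    labels: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        """0-based sequence index carrying *label* (raises if absent)."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"Sprinzl label {label!r} not present") from None

    def label_at(self, index0: int) -> str:
        return self.labels[index0]


@dataclass
class TRNACluster:
    """Identical-sequence tRNA gene cluster used as one mapping reference."""

    cluster_id: str
    member_ids: list[str]
    sequence: str  # RNA alphabet, shared by all members
    isotype: str = ""
    anticodon: str = ""
    structure: str = ""
    sprinzl: SprinzlMap | None = None

    def ref_base(self, index0: int, dna: bool = True) -> str:
        b = self.sequence[index0]
        return to_dna(b) if dna else b


# ---------------------------------------------------------------------------
# tRNAscan-SE parsing
# ---------------------------------------------------------------------------

def _parse_structure_file(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse tRNAscan-SE ``-f`` output into {gene_id: (sequence, dot-bracket)}.

    Intron spans reported as ``Possible intron: i-j`` (1-based, relative to
    the listed sequence) are excised so the stored sequence is mature.
    """
    out: dict[str, tuple[str, str]] = {}
    gid = None
    seq = struct = ""
    intron: tuple[int, int] | None = None

    def flush() -> None:
        nonlocal gid, seq, struct, intron
        if gid and seq:
            s, st = seq, struct
            if intron is not None:
                i, j = intron
                s = s[: i - 1] + s[j:]
                st = st[: i - 1] + st[j:]
            out[gid] = (to_rna(s), st.replace(">", "(").replace("<", ")"))
        gid, seq, struct, intron = None, "", "", None

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = re.match(r"^(\S+)\s+\(\d+-\d+\)\s+Length", line)
            if m:
                flush()
                gid = m.group(1)
            elif line.startswith("Seq:"):
                seq = line.split(":", 1)[1].strip()
            elif line.startswith("Str:"):
                struct = line.split(":", 1)[1].strip()
            else:
                m = re.search(r"[Ii]ntron:\s*(\d+)-(\d+)", line)
                if m:
                    intron = (int(m.group(1)), int(m.group(2)))
    flush()
    return out


def parse_trnascan(
    path: str | Path,
    genome: str | Path | dict | None = None,
    structure_path: str | Path | None = None,
) -> list[TRNAGene]:
    """Parse tRNAscan-SE v2.0 tabular output into :class:`TRNAGene` records.

    Pseudogene records are dropped.  Coordinates in the file are 1-based
    inclusive with begin > end marking the minus strand; minus-strand genes
    are reverse-complemented to the sense tRNA.  Intron spans are excised.
    Sequences come from *structure_path* (``-f`` output) when given, else
    from the *genome* FASTA (path, or a mapping of contig → sequence).
    """
    structures = _parse_structure_file(structure_path) if structure_path else {}

    contigs: dict[str, str] = {}
    if genome is not None:
        if isinstance(genome, dict):
            contigs = {k: str(v) for k, v in genome.items()}
        else:
            contigs = {r.id: str(r.seq) for r in SeqIO.parse(str(genome), "fasta")}

    genes: list[TRNAGene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            first = line.split()[0]
            if first in ("Sequence", "Name") or set(first) == {"-"}:
                continue  # header block
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields]
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: malformed row ({len(fields)} fields)")
            try:
                contig = fields[0]
                num = int(fields[1])
                begin, end = int(fields[2]), int(fields[3])
                isotype = fields[4]
                anticodon = to_rna(fields[5])
                ib, ie = int(fields[6]), int(fields[7])
                float(fields[8])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed row: {exc}") from None
            note = " ".join(fields[9:]).lower()
            if "pseudo" in note or isotype.lower() in ("pseudo", "undet"):
                continue

            gene_id = f"{contig}.trna{num}"
            strand = "+" if begin <= end else "-"
            lo, hi = (begin, end) if strand == "+" else (end, begin)
            start0, end0 = lo - 1, hi  # 0-based half-open

            if gene_id in structures:
                seq, struct = structures[gene_id]
            else:
                if contig not in contigs:
                    raise AnnotationError(
                        f"{path}:{lineno}: no sequence source for {gene_id} "
                        f"(contig {contig!r} absent from genome FASTA)"
                    )
                csec = contigs[contig]
                if end0 > len(csec):
                    raise AnnotationError(
                        f"{path}:{lineno}: {gene_id} coordinates exceed contig "
                        f"length {len(csec)}"
                    )
                seq = csec[start0:end0]
                if strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                if ib and ie:
                    # intron bounds are genomic, 1-based inclusive, sense-strand order
                    if strand == "+":
                        ri, rj = ib - lo, ie - lo + 1
                    else:
                        ri, rj = hi - ie, hi - ib + 1
                    seq = seq[:ri] + seq[rj:]
                seq = to_rna(seq)
                struct = ""
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    isotype=isotype,
                    anticodon=anticodon,
                    mature_sequence=seq,
                    structure=struct,
                    locus=(contig, start0, end0, strand),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Identical-sequence clustering
# ---------------------------------------------------------------------------

def build_clusters(genes: Sequence[TRNAGene]) -> list[TRNACluster]:
    """Partition genes into clusters of exactly identical mature sequence.

    Cluster ids are ``{isotype}-{anticodon}-{serial}``, deterministic under
    permutation of the input (sorted by isotype, anticodon, sequence).  If
    members of one cluster disagree on isotype the majority wins and a
    warning is logged.
    """
    if not genes:
        raise AnnotationError("build_clusters requires at least one gene")
    by_seq: dict[str, list[TRNAGene]] = {}
    for g in genes:
        by_seq.setdefault(g.mature_sequence, []).append(g)

    prelim = []
    for seq, members in by_seq.items():
        isotypes = Counter(m.isotype for m in members)
        isotype = isotypes.most_common(1)[0][0]
        if len(isotypes) > 1:
            logger.warning(
                "cluster with sequence %s...: isotype conflict %s; keeping %s",
                seq[:12], dict(isotypes), isotype,
            )
        anticodons = Counter(m.anticodon for m in members)
        anticodon = anticodons.most_common(1)[0][0]
        struct = next((m.structure for m in members if m.structure), "")
        prelim.append((isotype, anticodon, seq, members, struct))

    prelim.sort(key=lambda t: (t[0], t[1], t[2]))
    clusters: list[TRNACluster] = []
    serial: Counter = Counter()
    for isotype, anticodon, seq, members, struct in prelim:
        serial[(isotype, anticodon)] += 1
        clusters.append(
            TRNACluster(
                cluster_id=f"{isotype}-{anticodon}-{serial[(isotype, anticodon)]}",
                member_ids=sorted(m.gene_id for m in members),
                sequence=seq,
                isotype=isotype,
                anticodon=anticodon,
                structure=struct,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Sprinzl coordinate assignment
# ---------------------------------------------------------------------------

def _pair_table(structure: str) -> list[int]:
    pairs = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c in "(<":
            stack.append(i)
        elif c in ")>":
            if not stack:
                raise SprinzlError(f"unbalanced structure at index {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c not in ".-:,_":
            raise SprinzlError(f"unexpected structure character {c!r} at index {i}")
    if stack:
        raise SprinzlError("unbalanced structure (unclosed pairs)")
    return pairs


def _hairpins(pairs: list[int], lo: int, hi: int) -> list[tuple[int, int, int, int]]:
    """Hairpin arms in [lo, hi], as (outer5, inner5, inner3, outer3) indices."""
    arms = []
    for i in range(lo, hi + 1):
        j = pairs[i]
        if j <= i:
            continue
        if all(pairs[k] == -1 for k in range(i + 1, j)):  # loop-closing pair
            oi, oj = i, j
            while oi - 1 >= lo and pairs[oi - 1] == oj + 1:
                oi -= 1
                oj += 1
            arms.append((oi, i, j, oj))
    arms.sort()
    return arms


# D-loop base labels (8 canonical slots) and the insertion slots used for
# longer loops; fill order 20a, then 20b, then 17a matches the observed
# frequency of these insertions in bacterial tRNAs.
_DLOOP_BASE = ["14", "15", "16", "17", "18", "19", "20", "21"]
_DLOOP_DROP_ORDER = ["17", "20", "16", "21", "15"]


def _dloop_labels(n: int, dstem_len: int) -> list[str]:
    base = list(_DLOOP_BASE)
    if dstem_len == 3:  # 3-bp D-stem frees label 13 into the loop
        base = ["13"] + base
    extra = n - len(base)
    if extra > 3:
        raise SprinzlError(f"D-loop of {n} nt exceeds the 17a/20a/20b insertion slots")
    if extra < 0:
        drops = _DLOOP_DROP_ORDER[: -extra]
        if len(drops) < -extra:
            raise SprinzlError(f"D-loop of {n} nt is too short to label")
        base = [b for b in base if b not in drops]
    labels = []
    for b in base:
        labels.append(b)
        if b == "17" and extra >= 3:
            labels.append("17a")
        if b == "20":
            if extra >= 1:
                labels.append("20a")
            if extra >= 2:
                labels.append("20b")
    return labels


def _variable_labels(n: int) -> list[str]:
    if n <= 5:
        base = ["44", "45", "46", "47", "48"]
        for drop in ["47", "44", "48", "45"][: 5 - n]:
            base.remove(drop)
        return base
    n_e = n - 5
    if n_e > 27:
        raise SprinzlError(f"variable arm of {n} nt exceeds the e-label vocabulary")
    return ["44", "45"] + [f"e{k}" for k in range(1, n_e + 1)] + ["46", "47", "48"]


def assign_sprinzl(
    cluster: TRNACluster, override: Sequence[str] | None = None
) -> SprinzlMap:
    """Assign Sprinzl labels to every cluster index, structure-guided.

    The dot-bracket structure is segmented into acceptor stem, D-arm,
    anticodon arm, (optional long variable arm) and T-arm; each segment gets
    its canonical label range (acceptor 1–7/66–72, linker 8–9, D-stem 10–13 /
    22–25, D-loop 14–21 with 17a/20a/20b insertions, anticodon stem 27–31 /
    39–43, anticodon loop 32–38, variable region 44–48 (+ e-labels), T-stem
    49–53 / 61–65, T-loop 54–60, discriminator 73 and CCA 74–76).

    A user-supplied *override* of the right length is returned unchanged,
    which is the escape hatch for structures that do not segment cleanly.
    """
    L = len(cluster.sequence)
    if override is not None:
        if len(override) != L:
            raise SprinzlError(
                f"{cluster.cluster_id}: override map length {len(override)} != {L}"
            )
        m = SprinzlMap(labels=list(override))
        cluster.sprinzl = m
        return m
    if L < 55:
        raise SprinzlError(f"{cluster.cluster_id}: length {L} < 55")
    if not cluster.structure:
        raise SprinzlError(
            f"{cluster.cluster_id}: no dot-bracket structure; supply a coordinate map"
        )
    pairs = _pair_table(cluster.structure)

    # acceptor stem: maximal stacked run from the 5' end
    a = 0
    while a < L and pairs[a] > a and (a == 0 or pairs[a] == pairs[a - 1] - 1):
        a += 1
    if a == 0 or a > 7:
        raise SprinzlError(
            f"{cluster.cluster_id}: no acceptor stem at the 5' end (run {a})"
        )
    acc3_start = pairs[a - 1]

    arms = _hairpins(pairs, a, acc3_start - 1)
    if len(arms) not in (3, 4):
        raise SprinzlError(
            f"{cluster.cluster_id}: expected 3 hairpin arms (4 with a long "
            f"variable arm), found {len(arms)}; not a cloverleaf"
        )
    d_arm, ac_arm = arms[0], arms[1]
    t_arm = arms[-1]

    labels: list[str] = ["-"] * L
    for k in range(a):  # acceptor 5' arm
        labels[k] = str(k + 1)

    # linker between acceptor stem and D-stem: positions 8 (and 9)
    l1 = d_arm[0] - a
    if l1 not in (1, 2):
        raise SprinzlError(f"{cluster.cluster_id}: 8/9 linker of {l1} nt")
    for k in range(l1):
        labels[a + k] = str(8 + k)

    oi, i5, i3, oj = d_arm
    dl = i5 - oi + 1
    if not 3 <= dl <= 4:
        raise SprinzlError(f"{cluster.cluster_id}: D-stem of {dl} bp")
    for k in range(dl):
        labels[oi + k] = str(10 + k)
        labels[oj - k] = str(25 - k)
    for idx, lab in zip(range(i5 + 1, i3), _dloop_labels(i3 - i5 - 1, dl)):
        labels[idx] = lab

    l2 = ac_arm[0] - (d_arm[3] + 1)
    if l2 > 1:
        raise SprinzlError(f"{cluster.cluster_id}: 26 linker of {l2} nt")
    if l2 == 1:
        labels[d_arm[3] + 1] = "26"

    oi, i5, i3, oj = ac_arm
    al = i5 - oi + 1
    if not 3 <= al <= 5:
        raise SprinzlError(f"{cluster.cluster_id}: anticodon stem of {al} bp")
    if i3 - i5 - 1 != 7:
        raise SprinzlError(
            f"{cluster.cluster_id}: anticodon loop of {i3 - i5 - 1} nt (expected 7)"
        )
    for k in range(al):
        labels[oi + k] = str(27 + k)
        labels[oj - k] = str(43 - k)
    for k in range(7):
        labels[i5 + 1 + k] = str(32 + k)
    if cluster.anticodon:
        observed = cluster.sequence[i5 + 3 : i5 + 6]
        if observed != cluster.anticodon:
            logger.warning(
                "%s: annotated anticodon %s != bases at Sprinzl 34-36 (%s)",
                cluster.cluster_id, cluster.anticodon, observed,
            )

    # variable region spans everything between the anticodon and T arms,
    # including a long variable arm when present
    var_lo, var_hi = ac_arm[3] + 1, t_arm[0] - 1
    v = var_hi - var_lo + 1
    for idx, lab in zip(range(var_lo, var_hi + 1), _variable_labels(v)):
        labels[idx] = lab

    oi, i5, i3, oj = t_arm
    tl = i5 - oi + 1
    if not 3 <= tl <= 5:
        raise SprinzlError(f"{cluster.cluster_id}: T-stem of {tl} bp")
    if i3 - i5 - 1 != 7:
        raise SprinzlError(
            f"{cluster.cluster_id}: T-loop of {i3 - i5 - 1} nt (expected 7)"
        )
    for k in range(tl):
        labels[oi + k] = str(49 + k)
        labels[oj - k] = str(65 - k)
    for k in range(7):
        labels[i5 + 1 + k] = str(54 + k)

    if acc3_start - (t_arm[3] + 1) != 0:
        raise SprinzlError(
            f"{cluster.cluster_id}: gap between T-stem and acceptor 3' arm"
        )
    for k in range(a):  # acceptor 3' arm: label 73 - (5' partner label)
        labels[pairs[k]] = str(73 - (k + 1))

    tail = L - (pairs[0] + 1)
    if tail > 4:
        raise SprinzlError(f"{cluster.cluster_id}: {tail} nt after the acceptor stem")
    for k in range(tail):  # discriminator 73 + CCA 74-76
        labels[pairs[0] + 1 + k] = str(73 + k)

    m = SprinzlMap(labels=labels)
    cluster.sprinzl = m
    return m


# ---------------------------------------------------------------------------
# Cluster FASTA + Sprinzl map TSV I/O
# ---------------------------------------------------------------------------

def write_cluster_fasta(clusters: Iterable[TRNACluster], path: str | Path) -> None:
    """Write cluster reference FASTA (DNA alphabet; the mapping reference)."""
    with open(path, "w") as fh:
        for c in clusters:
            desc = (
                f"isotype={c.isotype} anticodon={to_dna(c.anticodon)} "
                f"members={','.join(c.member_ids)}"
            )
            if c.structure:
                desc += f" structure={c.structure}"
            fh.write(f">{c.cluster_id} {desc}\n{to_dna(c.sequence)}\n")


def read_cluster_fasta(path: str | Path) -> list[TRNACluster]:
    clusters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(
            item.split("=", 1) for item in rec.description.split()[1:] if "=" in item
        )
        clusters.append(
            TRNACluster(
                cluster_id=rec.id,
                member_ids=kv.get("members", "").split(",") if kv.get("members") else [],
                sequence=to_rna(str(rec.seq)),
                isotype=kv.get("isotype", ""),
                anticodon=to_rna(kv.get("anticodon", "")),
                structure=kv.get("structure", ""),
            )
        )
    return clusters


def write_sprinzl_tsv(clusters: Iterable[TRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tindex0\tlabel\tbase\n")
        for c in clusters:
            if c.sprinzl is None:
                continue
            for i, lab in enumerate(c.sprinzl.labels):
                fh.write(f"{c.cluster_id}\t{i}\t{lab}\t{c.ref_base(i)}\n")


def read_sprinzl_tsv(path: str | Path) -> dict[str, SprinzlMap]:
    maps: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("cluster_id"):
            raise AnnotationError(f"{path}: missing sprinzl map header")
        for line in fh:
            if not line.strip():
                continue
            cid, idx, lab, _base = line.rstrip("\n").split("\t")
            maps.setdefault(cid, []).append((int(idx), lab))
    out = {}
    for cid, items in maps.items():
        items.sort()
        if [i for i, _ in items] != list(range(len(items))):
            raise AnnotationError(f"{path}: non-contiguous indices for {cid}")
        out[cid] = SprinzlMap(labels=[lab for _, lab in items])
    return out


def load_clusters(
    fasta: str | Path, sprinzl_tsv: str | Path | None = None
) -> list[TRNACluster]:
    """Read clusters back from their file form (FASTA + optional map TSV)."""
    clusters = read_cluster_fasta(fasta)
    if sprinzl_tsv is not None:
        maps = read_sprinzl_tsv(sprinzl_tsv)
        for c in clusters:
            if c.cluster_id in maps:
                c.sprinzl = maps[c.cluster_id]
    return clusters
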