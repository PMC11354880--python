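"""Classification of enrichment calls against a catalog of known sites.

A passing RT-stop call is classified per treatment:

* **TP_known** — the (Sprinzl label, genomic base) pair matches a cataloged
  modification for that treatment: borohydride-track D at U 16/17/20/20a/20b/
  21/47, m⁷G at G46 and s⁴U at U8; carbodiimide-track Ψ at U 13/31/32/38/39/
  40/55/60/65.
* **ambiguous_m5U** — carbodiimide-track call at U54, where only
  ribothymidine (m⁵U) is documented in bacteria, so Ψ cannot be assigned.
* **type1_FP** — the base is a valid target of the treatment (U; G also for
  the borohydride track, which detects m⁷G) but the position is not in the
  catalog: a plausible but unknown site.
* **type2_FP** — a base the treatment cannot target (C/A; G too on the
  carbodiimide track).
* **shadow** — a call at position 45 co-occurring with a TP m⁷G46 in the same
  cluster; these stops are artifacts of the neighboring m⁷G and are tallied
  separately.

The catalog is an editable file so that newly validated sites (the U8 → s⁴U
and U60 → Ψ cases were promoted exactly this way after mass-spectrometry
confirmation) can move from type1_FP to TP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from trnamod.enrichment import EnrichmentRecord


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogEntry:
    treatment: str
    modification: str
    labels: frozenset[str]
    ref_base: str  # U or G


# Bases on which each treatment can create an RT block (type-I candidates).
TARGET_BASES = {"NaBH4": {"U"}, "CMCT": {"U"}}
TARGET_BASES["NaBH4"] = {"U", "G"}  # m7G makes G a valid borohydride target

# CMCT positions where only m5U is documented in bacteria.
AMBIGUOUS = {("CMCT", "54", "U")}


@dataclass
class KnownSiteCatalog:
    entries: list[CatalogEntry]

    def lookup(self, treatment: str, label: str, base: str) -> str | None:
        """Modification name for a (treatment, label, base) hit, else None."""
        for e in self.entries:
            if e.treatment == treatment and label in e.labels and base == e.ref_base:
                return e.modification
        return None

    @classmethod
    def default(cls) -> "KnownSiteCatalog":
        return cls(
            entries=[
                CatalogEntry("NaBH4", "D", frozenset(
                    {"16", "17", "20", "20a", "20b", "21", "47"}), "U"),
                CatalogEntry("NaBH4", "m7G", frozenset({"46"}), "G"),
                CatalogEntry("NaBH4", "s4U", frozenset({"8"}), "U"),
                CatalogEntry("CMCT", "Psi", frozenset(
                    {"13", "31", "32", "38", "39", "40", "55", "60", "65"}), "U"),
            ]
        )

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "treatment": e.treatment,
                "modification": e.modification,
                "labels": sorted(e.labels),
                "ref_base": e.ref_base,
            }
            for e in self.entries
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KnownSiteCatalog":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            entries=[
                CatalogEntry(
                    d["treatment"], d["modification"],
                    frozenset(str(x) for x in d["labels"]), d["ref_base"],
                )
                for d in data
            ]
        )


@dataclass
class ModificationCall:
    record: EnrichmentRecord
    treatment: str
    modification: str | None
    status: str  # TP_known | type1_FP | type2_FP | ambiguous_m5U | shadow
    organism: str = ""
    temperature: int = 0

    @property
    def cluster_id(self) -> str:
        return self.record.cluster_id

    @property
    def sprinzl_label(self) -> str:
        return self.record.sprinzl_label


def _base_as_rna(b: str) -> str:
    return b.upper().replace("T", "U")


def classify_call(
    r: EnrichmentRecord,
    treatment: str,
    catalog: KnownSiteCatalog | None = None,
) -> ModificationCall:
    """Classify one passing enrichment record (without shadow resolution,
    which needs the whole per-cluster callset; see :func:`classify_calls`)."""
    catalog = catalog or KnownSiteCatalog.default()
    if treatment not in TARGET_BASES:
        raise ClassificationError(f"treatment {treatment!r} has no classification rules")
    label = r.sprinzl_label
    if label in ("-", "", None):
        raise ClassificationError(
            f"{r.cluster_id} index {r.mod_index}: Sprinzl label unassigned"
        )
    base = _base_as_rna(r.ref_base)
    mod = catalog.lookup(treatment, label, base)
    if mod is not None:
        status, modification = "TP_known", mod
    elif (treatment, label, base) in AMBIGUOUS:
        status, modification = "ambiguous_m5U", None
    elif base in TARGET_BASES[treatment]:
        status, modification = "type1_FP", None
    else:
        status, modification = "type2_FP", None
    return ModificationCall(record=r, treatment=treatment,
                            modification=modification, status=status)


def classify_calls(
    records: Sequence[EnrichmentRecord],
    treatment: str,
    catalog: KnownSiteCatalog | None = None,
) -> list[ModificationCall]:
    """Classify a callset and flag position-45 shadows of m⁷G46."""
    calls = [classify_call(r, treatment, catalog) for r in records]
    m7g46_clusters = {
        c.cluster_id
        for c in calls
        if c.status == "TP_known" and c.modification == "m7G" and c.sprinzl_label == "46"
    }
    for c in calls:
        if (
            c.sprinzl_label == "45"
            and c.status in ("type1_FP", "type2_FP")
            and c.cluster_id in m7g46_clusters
        ):
            c.status = "shadow"
    return calls


def summarize_counts(calls: Iterable[ModificationCall]) -> pd.DataFrame:
    """Per-site summary: rows are modification+label (e.g. ``D17``, ``Psi55``),
    columns are (organism, temperature), cells count distinct tRNA clusters
    with a TP call.  Duplicated calls (replicates) count once."""
    seen: dict[tuple[str, tuple[str, int]], set[str]] = {}
    for c in calls:
        if c.status != "TP_known":
            continue
        row = f"{c.modification}{c.sprinzl_label}"
        seen.setdefault((row, (c.organism, c.temperature)), set()).add(c.cluster_id)
    if not seen:
        return pd.DataFrame()
    rows = sorted({k[0] for k in seen})
    cols = sorted({k[1] for k in seen})
    df = pd.DataFrame(0, index=rows, columns=pd.MultiIndex.from_tuples(
        cols, names=["organism", "temperature"]))
    for (row, col), clusters in seen.items():
        df.loc[row, col] = len(clusters)
    return df


def render_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Render zero cells as "-" for the report table."""
    return df.map(lambda v: "-" if v == 0 else v)


def compare_callsets(
    a: set[tuple], b: set[tuple]
) -> dict:
    """Overlap summary of two callsets keyed the same way (typically
    (isoacceptor family, Sprinzl label, modification)): sizes and membership
    lists of a∩b, a\\b, b\\a, upset-style."""
    inter, only_a, only_b = a & b, a - b, b - a
    return {
        "n_both": len(inter),
        "n_only_a": len(only_a),
        "n_only_b": len(only_b),
        "both": sorted(inter),
        "only_a": sorted(only_a),
        "only_b": sorted(only_b),
    }


def calls_to_frame(calls: Sequence[ModificationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        r = c.record
        rows.append(
            {
                "cluster_id": r.cluster_id,
                "mod_index": r.mod_index,
                "stop_index": r.stop_index,
                "sprinzl_label": r.sprinzl_label,
                "ref_base": r.ref_base,
                "treatment": c.treatment,
                "modification": c.modification or "",
                "status": c.status,
                "organism": c.organism,
                "temperature": c.temperature,
                "fc": r.fc,
                "log2fc": r.log2fc,
                "qvalue": r.qvalue,
                "stop_percent": r.stop_percent,
            }
        )
    return pd.DataFrame(rows)
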