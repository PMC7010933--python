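"""Per-gene aggregation of HSE matches.

A gene carrying exactly one typical / gapped / varied HSE is a TTG /
TGG / TVG respectively; two or more HSEs -> ``multi``; none -> ``none``.
Downstream architecture statistics use only the single-HSE classes, so
the position and subunit number of "the" HSE are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from hsescan.genome_io import GeneModel
from hsescan.hse_scanner import HSEMatch

GENE_CLASSES = ("TTG", "TGG", "TVG", "multi", "none")

_SINGLE = {"typical": "TTG", "gapped": "TGG", "varied": "TVG"}


@dataclass(frozen=True)
class GeneHSERecord:
    gene_id: str
    hse_count: int
    gene_class: str
    hse: Optional[HSEMatch] = None  # present iff hse_count == 1
    subgenome_key: Optional[str] = None


def classify_genes(
    matches: Iterable[HSEMatch], genes: Iterable[GeneModel]
) -> list[GeneHSERecord]:
    """One record per gene, including genes with no HSE at all."""
    by_gene: dict[str, list[HSEMatch]] = {}
    gene_list = list(genes)
    known = {g.gene_id for g in gene_list}
    for m in matches:
        if m.gene_id not in known:
            raise KeyError(f"HSE match references unknown gene {m.gene_id!r}")
        by_gene.setdefault(m.gene_id, []).append(m)
    records = []
    for g in sorted(gene_list, key=lambda g: g.gene_id):
        hits = by_gene.get(g.gene_id, [])
        if not hits:
            cls, single = "none", None
        elif len(hits) == 1:
            cls, single = _SINGLE[hits[0].hse_class], hits[0]
        else:
            cls, single = "multi", None
        records.append(
            GeneHSERecord(
                gene_id=g.gene_id,
                hse_count=len(hits),
                gene_class=cls,
                hse=single,
                subgenome_key=g.subgenome_key,
            )
        )
    return records


def summarize_classes(
    records: Iterable[GeneHSERecord], group_by: Optional[str] = None
) -> pd.DataFrame:
    """Count genes per class, optionally stratified by ``subgenome_key``.

    Row sums always equal the number of genes in each stratum.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no gene records to summarize")
    df = pd.DataFrame(
        {
            "gene_class": [r.gene_class for r in recs],
            "subgenome_key": [r.subgenome_key for r in recs],
        }
    )
    if group_by is None:
        counts = df["gene_class"].value_counts()
        table = pd.DataFrame(
            [[int(counts.get(c, 0)) for c in GENE_CLASSES]],
            columns=list(GENE_CLASSES),
            index=["all"],
        )
    else:
        if group_by != "subgenome_key":
            raise ValueError(f"unsupported grouping key {group_by!r}")
        table = (
            df.groupby("subgenome_key", dropna=False)["gene_class"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=list(GENE_CLASSES), fill_value=0)
        )
        table.columns.name = None
    return table


def hse_class_composition(class_counts: dict[str, int]) -> pd.DataFrame:
    """Composition of an HSE count table {typical, gapped, varied}.

    Returns counts, percentages, and the pooled non-canonical (gapped +
    varied) percentage in the ``percent`` column of row ``noncanonical``.
    """
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("empty class count table")
    rows = []
    for cls in ("typical", "gapped", "varied"):
        n = class_counts.get(cls, 0)
        rows.append({"hse_class": cls, "count": n, "percent": 100.0 * n / total})
    noncanon = class_counts.get("gapped", 0) + class_counts.get("varied", 0)
    rows.append(
        {
            "hse_class": "noncanonical",
            "count": noncanon,
            "percent": 100.0 * noncanon / total,
        }
    )
    return pd.DataFrame(rows).set_index("hse_class")


def records_to_frame(records: Iterable[GeneHSERecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "hse_count": r.hse_count,
                "gene_class": r.gene_class,
                "subgenome_key": r.subgenome_key,
                "distance_to_atg": r.hse.distance_to_atg if r.hse else pd.NA,
                "subunit_count": r.hse.subunit_count if r.hse else pd.NA,
                "hse_class": r.hse.hse_class if r.hse else pd.NA,
                "first_orientation": r.hse.first_orientation if r.hse else pd.NA,
                "mismatch_subunit": (
                    r.hse.mismatch.subunit_index
                    if r.hse and r.hse.mismatch
                    else pd.NA
                ),
                "mismatch_position": (
                    r.hse.mismatch.position_in_subunit
                    if r.hse and r.hse.mismatch
                    else pd.NA
                ),
                "mismatch_base": (
                    r.hse.mismatch.observed_base
                    if r.hse and r.hse.mismatch
                    else pd.NA
                ),
            }
        )
    return pd.DataFrame(rows)
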