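"""Transcript grouping by transcription start site (TSS) or by gene.

Isoform-level allelic estimates are noisy because reads rarely distinguish
both allele and isoform.  Summing isoforms that share a promoter (exactly,
or within a small basepair window — "fuzzy" TSS groups) strengthens the
signal of promoter-driven cis-regulation while keeping sub-gene resolution.

The TSS of a transcript is its 5' end: the minimum exon start on the +
strand, the maximum exon end on the - strand (1-based, GTF convention).
Fuzzy grouping chains TSS positions within one gene and strand by
single-linkage: consecutive sorted TSS at most ``window`` bp apart join the
same group.  Groups never span genes or strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "TranscriptAnnotation",
    "GroupMap",
    "parse_gtf",
    "make_tx2tss",
    "make_tx2gene",
]


@dataclass(frozen=True)
class TranscriptAnnotation:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int  # 1-based genomic coordinate of the 5' end

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.tx_id}: undefined strand {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"{self.tx_id}: TSS must be >= 1")


@dataclass(frozen=True)
class GroupInfo:
    group_id: str
    gene_id: str
    tx_ids: tuple
    tss_min: Optional[int] = None
    tss_max: Optional[int] = None


@dataclass
class GroupMap:
    """Total map transcript -> group at TSS or gene level."""

    tx2group: dict
    groups: dict = field(repr=False)
    level: str = "tss"

    def __post_init__(self):
        if self.level not in ("tss", "gene"):
            raise ValueError("level must be 'tss' or 'gene'")
        covered = {t for g in self.groups.values() for t in g.tx_ids}
        if covered != set(self.tx2group):
            raise ValueError("groups do not partition the transcript set")

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, tx_id: str) -> str:
        return self.tx2group[tx_id]

    def members(self, group_id: str) -> tuple:
        return self.groups[group_id].tx_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.tx2group.items()), columns=["tx_id", "group_id"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def parse_gtf(path) -> list:
    """Extract one :class:`TranscriptAnnotation` per transcript from a GTF.

    The TSS is computed strand-aware from exon extremes.  Transcripts
    without exons or with undefined strand are skipped (one summary warning
    reports how many).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans: dict = {}
    for exon in db.features_of_type("exon"):
        tx = exon.attributes.get("transcript_id", [None])[0]
        gene = exon.attributes.get("gene_id", [None])[0]
        if tx is None or gene is None:
            continue
        key = (tx, gene, exon.seqid, exon.strand)
        lo, hi = spans.get(key, (exon.start, exon.end))
        spans[key] = (min(lo, exon.start), max(hi, exon.end))
    records = []
    skipped = 0
    for (tx, gene, chrom, strand), (lo, hi) in spans.items():
        if strand not in ("+", "-"):
            skipped += 1
            continue
        records.append(
            TranscriptAnnotation(
                tx_id=tx,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                tss=lo if strand == "+" else hi,
            )
        )
    if skipped:
        warnings.warn(f"skipped {skipped} transcripts with undefined strand")
    return records


def make_tx2tss(
    annotation: Iterable[TranscriptAnnotation], window: int = 50
) -> GroupMap:
    """Build TSS groups with a basepair tolerance window.

    ``window=0`` gives exact-position groups.  Within each (gene, strand),
    distinct TSS are sorted and chained while consecutive positions differ
    by at most ``window`` (single-linkage).  Group ids are
    ``<gene_id>-<k>`` with k numbered 1..G by ascending minimum TSS.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_gene: dict = {}
    for rec in annotation:
        by_gene.setdefault((rec.gene_id, rec.strand), []).append(rec)
    # collect per-gene clusters first so numbering spans strands consistently
    per_gene_clusters: dict = {}
    for (gene, _strand), recs in by_gene.items():
        positions = sorted({r.tss for r in recs})
        clusters = [[positions[0]]] if positions else []
        for p in positions[1:]:
            if p - clusters[-1][-1] <= window:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            members = tuple(
                sorted(r.tx_id for r in recs if cl[0] <= r.tss <= cl[-1])
            )
            per_gene_clusters.setdefault(gene, []).append(
                (cl[0], cl[-1], members)
            )
    tx2group: dict = {}
    groups: dict = {}
    for gene, clusters in per_gene_clusters.items():
        for k, (lo, hi, members) in enumerate(sorted(clusters), start=1):
            gid = f"{gene}-{k}"
            groups[gid] = GroupInfo(gid, gene, members, lo, hi)
            for t in members:
                tx2group[t] = gid
    return GroupMap(tx2group, groups, level="tss")


def make_tx2gene(annotation: Iterable[TranscriptAnnotation]) -> GroupMap:
    """One group per gene containing all of its transcripts."""
    by_gene: dict = {}
    for rec in annotation:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    tx2group = {}
    groups = {}
    for gene, recs in by_gene.items():
        members = tuple(sorted(r.tx_id for r in recs))
        tsss = [r.tss for r in recs]
        groups[gene] = GroupInfo(gene, gene, members, min(tsss), max(tsss))
        for t in members:
            tx2group[t] = gene
    return GroupMap(tx2group, groups, level="gene")
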