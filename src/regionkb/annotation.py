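"""Nearest-gene annotation with strand-aware signed TSS/TES distances.

Gene coordinates follow the UCSC flat-table convention: ``txStart < txEnd``
are the numerically lower and higher chromosomal coordinates on either
strand, so the strand decides which end is the transcription start site.
Distances are measured from the region centre and carry a sign: negative
means the region lies upstream of the site *in gene orientation*, so a
region inside a plus-strand gene has bpTSS > 0 (downstream of the TSS) and
bpTES < 0 (upstream of the TES).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import GenomicInterval, RegionSet

__all__ = [
    "GeneModel",
    "AnnotationHit",
    "tss_tes",
    "signed_tss_tes_distances",
    "annotate_regions",
    "load_gene_definitions",
    "load_refgene_table",
    "search_genes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene model (UCSC refGene-style coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    cdsStart: int = -1
    cdsEnd: int = -1
    accession: str = ""
    exonStarts: tuple[int, ...] = field(default_factory=tuple)
    exonEnds: tuple[int, ...] = field(default_factory=tuple)
    assembly: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.txStart < self.txEnd:
            raise ValueError(f"gene {self.gene_id!r}: txStart must be < txEnd")
        if self.cdsStart < 0:  # default CDS to the transcript span
            object.__setattr__(self, "cdsStart", self.txStart)
            object.__setattr__(self, "cdsEnd", self.txEnd)
        if len(self.exonStarts) != len(self.exonEnds):
            raise ValueError(f"gene {self.gene_id!r}: exon list lengths differ")


@dataclass(frozen=True)
class AnnotationHit:
    """One (region, gene) association with signed centre-to-site distances."""

    region: GenomicInterval
    gene: GeneModel
    bpTSS: int
    bpTES: int

    @property
    def min_distance(self) -> int:
        return min(abs(self.bpTSS), abs(self.bpTES))


def tss_tes(gene: GeneModel) -> tuple[int, int]:
    """(TSS, TES) coordinates; on the minus strand the TSS is txEnd."""
    if gene.strand == "+":
        return gene.txStart, gene.txEnd
    return gene.txEnd, gene.txStart


def signed_tss_tes_distances(region: GenomicInterval, gene: GeneModel) -> tuple[int, int]:
    """Signed (bpTSS, bpTES) from the region centre, in gene orientation.

    Negative always means upstream of the site; for an intragenic region the
    two values therefore have opposite signs on either strand.
    """
    if region.chrom != gene.chrom:
        raise ValueError("region and gene are on different chromosomes")
    c = region.centre
    if gene.strand == "+":
        return c - gene.txStart, c - gene.txEnd
    return gene.txEnd - c, gene.txStart - c


def annotate_regions(
    regions: RegionSet | Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    max_tss: int,
    max_tes: int,
    mode: str = "nearest",
) -> list[AnnotationHit]:
    """Attach nearby genes to each region.

    A gene qualifies when ``|bpTSS| <= max_tss`` or ``|bpTES| <= max_tes``.
    ``mode="all"`` reports every qualifying pair; ``mode="nearest"`` keeps,
    per region, the gene minimising ``min(|bpTSS|, |bpTES|)`` (ties broken by
    gene symbol). Regions with no qualifying gene produce no row; their count
    is logged.
    """
    if not genes:
        raise ValueError("empty gene table")
    if mode not in ("nearest", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    hits: list[AnnotationHit] = []
    n_unannotated = 0
    for region in regions:
        candidates: list[AnnotationHit] = []
        for g in by_chrom.get(region.chrom, ()):
            bptss, bptes = signed_tss_tes_distances(region, g)
            if abs(bptss) <= max_tss or abs(bptes) <= max_tes:
                candidates.append(AnnotationHit(region, g, bptss, bptes))
        if not candidates:
            n_unannotated += 1
            continue
        if mode == "all":
            candidates.sort(key=lambda h: h.gene.gene_id)
            hits.extend(candidates)
        else:
            hits.append(min(candidates, key=lambda h: (h.min_distance, h.gene.gene_id)))
    if n_unannotated:
        log.info("%d region(s) had no gene within the distance limits", n_unannotated)
    return hits


def hits_to_table(hits: Iterable[AnnotationHit]) -> pd.DataFrame:
    rows = [
        {
            "chrom": h.region.chrom, "start": h.region.start, "end": h.region.end,
            "gene_id": h.gene.gene_id, "accession": h.gene.accession,
            "strand": h.gene.strand,
            "txStart": h.gene.txStart, "txEnd": h.gene.txEnd,
            "cdsStart": h.gene.cdsStart, "cdsEnd": h.gene.cdsEnd,
            "bpTSS": h.bpTSS, "bpTES": h.bpTES,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene_id", "accession", "strand",
                 "txStart", "txEnd", "cdsStart", "cdsEnd", "bpTSS", "bpTES"],
    )


def load_gene_definitions(
    source: str | os.PathLike,
    column_map: dict[str, int],
    assembly: str,
    delimiter: str = "\t",
    has_header: bool = True,
) -> list[GeneModel]:
    """Load a custom gene table given a column map.

    ``column_map`` gives 0-based column indices for the required keys
    ``chromosome``, ``strand``, ``lower``, ``upper`` and optionally ``id``.
    CDS coordinates default to the transcript span.
    """
    required = {"chromosome", "strand", "lower", "upper"}
    missing = required - set(column_map)
    if missing:
        raise ValueError(f"column map missing required columns: {sorted(missing)}")
    df = pd.read_csv(source, sep=delimiter, header=0 if has_header else None, dtype=str)
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = tuple(row)
        gid = vals[column_map["id"]] if "id" in column_map else f"gene_{i + 1}"
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(vals[column_map["chromosome"]]),
                strand=str(vals[column_map["strand"]]),
                txStart=int(vals[column_map["lower"]]),
                txEnd=int(vals[column_map["upper"]]),
                assembly=assembly,
            )
        )
    return genes


#: column order of a UCSC refFlat/refGene-style flat gene table
_REFGENE_COLS = [
    "gene_id", "accession", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
]


def _coord_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(text).strip(",").split(",") if x)


def load_refgene_table(source: str | os.PathLike, assembly: str) -> list[GeneModel]:
    """Load a UCSC refGene-style flat file (refFlat column order, no header)."""
    df = pd.read_csv(source, sep="\t", header=None, names=_REFGENE_COLS, dtype=str)
    return [
        GeneModel(
            gene_id=r.gene_id, accession=r.accession, chrom=r.chrom, strand=r.strand,
            txStart=int(r.txStart), txEnd=int(r.txEnd),
            cdsStart=int(r.cdsStart), cdsEnd=int(r.cdsEnd),
            exonStarts=_coord_list(r.exonStarts), exonEnds=_coord_list(r.exonEnds),
            assembly=assembly,
        )
        for r in df.itertuples(index=False)
    ]


def search_genes(pattern: str, genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Case-insensitive prefix match on the gene symbol, exact matches first."""
    out = [g for g in genes if g.gene_id.lower().startswith(pattern.lower())]
    out.sort(key=lambda g: (g.gene_id.lower() != pattern.lower(), g.gene_id))
    return out
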