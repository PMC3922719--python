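"""Proximal-feature queries: archived regions near a locus or a gene.

Distance is measured from the centre of each archived region to the anchor
point. The anchor is either an explicit (chromosome, position) locus or a
gene site — the strand-aware TSS, or the strand-aware translation start
(cdsStart on the plus strand, cdsEnd on the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import tss_tes
from .core import GenomicInterval
from .knowledgebase import DatasetRecord, KBError, KnowledgeBase

__all__ = ["ProximalSummaryRow", "features_near_point", "features_near_gene", "gene_anchor"]


@dataclass(frozen=True)
class ProximalSummaryRow:
    kbid: int
    cell_line: str
    factor: str
    n_regions: int


def _scope_records(
    kb: KnowledgeBase, kbids: list[int] | None
) -> list[DatasetRecord]:
    if kbids is None:
        records = kb.active_datasets()
        if not records:
            raise KBError("no active datasets to search")
    else:
        records = [kb.get_dataset(k) for k in kbids]
    builds = {r.genome_build for r in records}
    if len(builds) > 1:
        raise KBError(f"scope datasets span multiple builds: {sorted(builds)}")
    return records


def features_near_point(
    kb: KnowledgeBase,
    chrom: str,
    pos: int,
    distance: int,
    kbids: list[int] | None = None,
    mode: str = "summary",
) -> list[ProximalSummaryRow] | list[tuple[DatasetRecord, GenomicInterval]]:
    """Archived regions whose centre lies within ``distance`` of a locus.

    ``kbids=None`` searches all active datasets. Summary mode tallies
    qualifying regions per dataset (cell line, factor, count); detail mode,
    allowed only for a single dataset, returns the full region rows.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if mode not in ("summary", "detail"):
        raise ValueError(f"unknown mode {mode!r}")
    records = _scope_records(kb, kbids)
    if mode == "detail" and len(records) != 1:
        raise KBError("detail mode requires exactly one dataset")

    def qualifying(rec: DatasetRecord) -> list[GenomicInterval]:
        regions = kb.fetch_regions(rec.kbid)
        return [iv for iv in regions.on(chrom) if abs(iv.centre - pos) <= distance]

    if mode == "summary":
        return [
            ProximalSummaryRow(r.kbid, r.cell_line, r.factor, len(qualifying(r)))
            for r in records
        ]
    rec = records[0]
    return [(rec, iv) for iv in qualifying(rec)]


def gene_anchor(gene, anchor_site: str) -> tuple[str, int]:
    """Resolve a gene to an anchor point: strand-aware TSS or CDS start."""
    if anchor_site.lower() == "tss":
        tss, _ = tss_tes(gene)
        return gene.chrom, tss
    if anchor_site.lower() == "cds":
        pos = gene.cdsStart if gene.strand == "+" else gene.cdsEnd
        return gene.chrom, pos
    raise ValueError(f"unknown anchor site {anchor_site!r}; expected 'tss' or 'cds'")


def features_near_gene(
    kb: KnowledgeBase,
    gene_pattern: str,
    assembly: str,
    anchor_site: str = "tss",
    distance: int = 100_000,
    kbids: list[int] | None = None,
    mode: str = "summary",
):
    """Archived regions near a gene's TSS or CDS start.

    The gene must resolve uniquely: an exact symbol match wins; otherwise a
    unique prefix match is accepted, and an ambiguous prefix raises with the
    candidate list.
    """
    matches = kb.search_genes(gene_pattern, assembly)
    if not matches:
        raise KBError(f"no gene matching {gene_pattern!r} in assembly {assembly!r}")
    exact = [g for g in matches if g.gene_id.lower() == gene_pattern.lower()]
    if exact:
        gene = exact[0]
    elif len(matches) == 1:
        gene = matches[0]
    else:
        raise KBError(
            f"ambiguous gene {gene_pattern!r}: candidates "
            + ", ".join(g.gene_id for g in matches[:10])
        )
    chrom, pos = gene_anchor(gene, anchor_site)
    return features_near_point(kb, chrom, pos, distance, kbids=kbids, mode=mode)
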