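"""Embedded knowledge base of region datasets and gene annotation tables.

A single SQLite file replaces the original client/server archive. Dataset
metadata live in ``kbdetails``, regions in ``kbsites`` keyed by the dataset
identity, and gene models in ``annotation`` keyed by assembly. Only datasets
of one genome build may be active at a time, which is what makes every
downstream comparison coherent.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import GeneModel
from .core import GenomicInterval, RegionSet

__all__ = ["DatasetRecord", "SizeHistogram", "KnowledgeBase", "KBError"]


class KBError(ValueError):
    """Domain-rule violation in the knowledge base (not an I/O failure)."""


@dataclass
class DatasetRecord:
    """Metadata row for one archived dataset."""

    kbid: int
    label: str = ""
    organism: str = ""
    cell_line: str = ""
    factor: str = ""
    condition: str = ""
    genome_build: str = ""
    peak_caller: str = ""
    source_link: str = ""
    notes: str = ""
    active: bool = False

    _META_FIELDS = (
        "label", "organism", "cell_line", "factor", "condition",
        "genome_build", "peak_caller", "source_link", "notes",
    )


@dataclass
class SizeHistogram:
    """Region-size distribution of one dataset: bins of fixed width plus mean."""

    bin_size: int
    bins: dict[int, int] = field(default_factory=dict)
    mean_size: float = 0.0

    @property
    def n_regions(self) -> int:
        return sum(self.bins.values())


_SCHEMA = """
CREATE TABLE IF NOT EXISTS kbdetails (
    kbid INTEGER PRIMARY KEY AUTOINCREMENT,
    label TEXT, organism TEXT, cell_line TEXT, factor TEXT, condition TEXT,
    genome_build TEXT NOT NULL, peak_caller TEXT, source_link TEXT,
    notes TEXT, active INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS kbsites (
    kbid INTEGER NOT NULL REFERENCES kbdetails(kbid),
    chr TEXT NOT NULL, start INTEGER NOT NULL, end INTEGER NOT NULL,
    name TEXT, score REAL, strand TEXT
);
CREATE INDEX IF NOT EXISTS kbsites_idx ON kbsites(kbid, chr, start);
CREATE TABLE IF NOT EXISTS annotation (
    assembly TEXT NOT NULL, gene_id TEXT NOT NULL, accession TEXT,
    chr TEXT NOT NULL, strand TEXT NOT NULL,
    txStart INTEGER NOT NULL, txEnd INTEGER NOT NULL,
    cdsStart INTEGER NOT NULL, cdsEnd INTEGER NOT NULL,
    exonStarts TEXT, exonEnds TEXT, custom INTEGER NOT NULL DEFAULT 0
);
CREATE INDEX IF NOT EXISTS annotation_idx ON annotation(assembly, gene_id);
"""


class KnowledgeBase:
    """Persistent archive of region datasets, metadata and gene tables.

    Parameters
    ----------
    path : str
        SQLite file path, or ``":memory:"`` for an ephemeral store.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- datasets ----------------------------------------------------------

    def register_dataset(
        self, meta: dict | DatasetRecord, intervals: Iterable[GenomicInterval]
    ) -> int:
        """Store a new dataset; returns its fresh kbid.

        Requires a non-empty ``genome_build`` and at least one validated
        interval. Newly registered datasets start inactive.
        """
        if isinstance(meta, DatasetRecord):
            meta = {f: getattr(meta, f) for f in DatasetRecord._META_FIELDS}
        meta = dict(meta)
        build = str(meta.get("genome_build") or "").strip()
        if not build:
            raise KBError("genome_build must be specified when registering a dataset")
        ivs = list(intervals)
        if not ivs:
            raise KBError("refusing to register a dataset with no regions")
        for iv in ivs:
            if not iv.is_valid():
                raise KBError(f"invalid interval {iv!r}; validate before registering")
        cols = DatasetRecord._META_FIELDS
        cur = self._conn.execute(
            f"INSERT INTO kbdetails ({', '.join(cols)}, active) "
            f"VALUES ({', '.join('?' * len(cols))}, 0)",
            [str(meta.get(c, "") or "") for c in cols],
        )
        kbid = int(cur.lastrowid)
        self._conn.executemany(
            "INSERT INTO kbsites (kbid, chr, start, end, name, score, strand) "
            "VALUES (?, ?, ?, ?, ?, ?, ?)",
            [(kbid, i.chrom, i.start, i.end, i.name, i.score, i.strand) for i in ivs],
        )
        self._conn.commit()
        return kbid

    def save_result_set(
        self, label: str, intervals: Iterable[GenomicInterval], parent_kbids: Sequence[int]
    ) -> int:
        """Archive an analysis result as an ordinary dataset.

        The result inherits the parents' genome build and records its
        derivation in the notes field, so it can enter downstream analyses
        and be annotated independently.
        """
        parents = [self.get_dataset(k) for k in parent_kbids]
        builds = {p.genome_build for p in parents}
        if len(builds) != 1:
            raise KBError(f"parents span multiple builds: {sorted(builds)}")
        meta = {
            "label": label,
            "genome_build": builds.pop(),
            "notes": "derived from kbids " + json.dumps(sorted(int(k) for k in parent_kbids)),
        }
        return self.register_dataset(meta, intervals)

    def get_dataset(self, kbid: int) -> DatasetRecord:
        row = self._conn.execute(
            "SELECT kbid, label, organism, cell_line, factor, condition, genome_build,"
            " peak_caller, source_link, notes, active FROM kbdetails WHERE kbid = ?",
            (kbid,),
        ).fetchone()
        if row is None:
            raise KBError(f"no dataset with kbid {kbid}")
        return DatasetRecord(*row[:10], active=bool(row[10]))

    def fetch_regions(self, kbid: int) -> RegionSet:
        rec = self.get_dataset(kbid)
        rows = self._conn.execute(
            "SELECT chr, start, end, name, score, strand FROM kbsites WHERE kbid = ?",
            (kbid,),
        ).fetchall()
        return RegionSet(
            (GenomicInterval(*r) for r in rows),
            genome_build=rec.genome_build,
            label=rec.label or f"kb:{kbid}",
        )

    def search_datasets(
        self,
        organism: str | None = None,
        cell_line: str | None = None,
        factor: str | None = None,
        genome_build: str | None = None,
        peak_caller: str | None = None,
        active_only: bool = False,
    ) -> list[DatasetRecord]:
        """Case-insensitive substring search over the metadata fields."""
        clauses, args = [], []
        for col, val in (
            ("organism", organism), ("cell_line", cell_line), ("factor", factor),
            ("genome_build", genome_build), ("peak_caller", peak_caller),
        ):
            if val is not None:
                clauses.append(f"lower({col}) LIKE ?")
                args.append(f"%{val.lower()}%")
        if active_only:
            clauses.append("active = 1")
        where = ("WHERE " + " AND ".join(clauses)) if clauses else ""
        rows = self._conn.execute(
            "SELECT kbid, label, organism, cell_line, factor, condition, genome_build,"
            f" peak_caller, source_link, notes, active FROM kbdetails {where} ORDER BY kbid",
            args,
        ).fetchall()
        return [DatasetRecord(*r[:10], active=bool(r[10])) for r in rows]

    def set_active_datasets(self, kbids: Sequence[int], state: bool) -> list[DatasetRecord]:
        """Toggle activation; activation must leave the active set single-build."""
        records = [self.get_dataset(k) for k in kbids]
        if state:
            active = [r for r in self.search_datasets(active_only=True)
                      if r.kbid not in set(kbids)]
            builds = {r.genome_build for r in active} | {r.genome_build for r in records}
            if len(builds) > 1:
                raise KBError(
                    "cannot activate: active datasets would span builds "
                    + ", ".join(sorted(builds))
                    + "; deactivate all datasets first"
                )
        self._conn.executemany(
            "UPDATE kbdetails SET active = ? WHERE kbid = ?",
            [(1 if state else 0, k) for k in kbids],
        )
        self._conn.commit()
        return [self.get_dataset(k) for k in kbids]

    def deactivate_all(self) -> None:
        self._conn.execute("UPDATE kbdetails SET active = 0")
        self._conn.commit()

    def active_datasets(self) -> list[DatasetRecord]:
        return self.search_datasets(active_only=True)

    def delete_dataset(self, kbid: int) -> None:
        """Remove a dataset and all its regions; kbids are never reused."""
        self.get_dataset(kbid)  # existence check
        self._conn.execute("DELETE FROM kbsites WHERE kbid = ?", (kbid,))
        self._conn.execute("DELETE FROM kbdetails WHERE kbid = ?", (kbid,))
        self._conn.commit()

    # -- summaries and queries --------------------------------------------

    def region_size_summary(self, kbid: int, bin_size: int = 100) -> SizeHistogram:
        """Mean region size and a fixed-width size histogram for one dataset."""
        if bin_size < 1:
            raise KBError("bin_size must be >= 1")
        sizes = [
            e - s for s, e in self._conn.execute(
                "SELECT start, end FROM kbsites WHERE kbid = ?", (kbid,)
            )
        ]
        if not sizes:
            self.get_dataset(kbid)
            raise KBError(f"dataset {kbid} has no regions")
        hist = SizeHistogram(bin_size=bin_size, mean_size=sum(sizes) / len(sizes))
        for s in sizes:
            b = (s // bin_size) * bin_size
            hist.bins[b] = hist.bins.get(b, 0) + 1
        return hist

    def query_window(
        self, kbids: Sequence[int] | None, chrom: str, lo: int, hi: int
    ) -> list[tuple[DatasetRecord, GenomicInterval]]:
        """Regions whose start lies in [lo, hi] on ``chrom``.

        This is a start-coordinate window (the archive-query idiom), not an
        overlap query; ``kbids=None`` searches the whole store.
        """
        if lo > hi:
            raise KBError("window lower bound exceeds upper bound")
        sql = ("SELECT kbid, chr, start, end, name, score, strand FROM kbsites "
               "WHERE chr = ? AND start >= ? AND start <= ?")
        args: list = [chrom, lo, hi]
        if kbids is not None:
            sql += f" AND kbid IN ({', '.join('?' * len(kbids))})"
            args.extend(kbids)
        out = []
        records: dict[int, DatasetRecord] = {}
        for kbid, *rest in self._conn.execute(sql + " ORDER BY kbid, start", args):
            if kbid not in records:
                records[kbid] = self.get_dataset(kbid)
            out.append((records[kbid], GenomicInterval(*rest)))
        return out

    # -- gene annotation tables -------------------------------------------

    def load_genes(self, genes: Iterable[GeneModel], assembly: str, custom: bool = False) -> int:
        genes = list(genes)
        self._conn.executemany(
            "INSERT INTO annotation (assembly, gene_id, accession, chr, strand,"
            " txStart, txEnd, cdsStart, cdsEnd, exonStarts, exonEnds, custom)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    assembly, g.gene_id, g.accession, g.chrom, g.strand,
                    g.txStart, g.txEnd, g.cdsStart, g.cdsEnd,
                    json.dumps(list(g.exonStarts)), json.dumps(list(g.exonEnds)),
                    1 if custom else 0,
                )
                for g in genes
            ],
        )
        self._conn.commit()
        return len(genes)

    def get_genes(self, assembly: str) -> list[GeneModel]:
        rows = self._conn.execute(
            "SELECT gene_id, accession, chr, strand, txStart, txEnd, cdsStart, cdsEnd,"
            " exonStarts, exonEnds FROM annotation WHERE assembly = ? ORDER BY gene_id",
            (assembly,),
        ).fetchall()
        return [
            GeneModel(
                gene_id=r[0], accession=r[1] or "", chrom=r[2], strand=r[3],
                txStart=r[4], txEnd=r[5], cdsStart=r[6], cdsEnd=r[7],
                exonStarts=tuple(json.loads(r[8] or "[]")),
                exonEnds=tuple(json.loads(r[9] or "[]")),
                assembly=assembly,
            )
            for r in rows
        ]

    def delete_custom_genes(self, assembly: str) -> int:
        cur = self._conn.execute(
            "DELETE FROM annotation WHERE assembly = ? AND custom = 1", (assembly,)
        )
        self._conn.commit()
        return cur.rowcount

    def search_genes(self, pattern: str, assembly: str) -> list[GeneModel]:
        """Case-insensitive prefix search on gene symbol; exact matches first."""
        genes = [
            g for g in self.get_genes(assembly)
            if g.gene_id.lower().startswith(pattern.lower())
        ]
        genes.sort(key=lambda g: (g.gene_id.lower() != pattern.lower(), g.gene_id))
        return genes

    def vacuum(self) -> None:
        """Housekeeping hook; compacts the store file."""
        self._conn.execute("VACUUM")
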