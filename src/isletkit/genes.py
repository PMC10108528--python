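"""Gene models and GTF I/O.

One canonical transcript per gene. GTF is 1-based inclusive on disk and is
converted to the package-wide 0-based half-open convention on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .intervals import GenomicInterval, RegionSet


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene must have at least one exon")

    @property
    def tss(self) -> int:
        """Transcription start site (a single base position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (3' terminal base position)."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (0-based half-open), 5'->3' order agnostic."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


def write_gtf(genes: list[Gene], path: str | Path, source: str = "isletkit") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (s, e) in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    return path


def _attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    raise ValueError(f"GTF attribute {key!r} not found in: {attrs!r}")


def read_gtf(path: str | Path) -> list[Gene]:
    """Read gene models from GTF (1-based inclusive -> 0-based half-open).

    Exon records are grouped by gene_id; the gene span is the exon hull when
    no explicit gene record exists.
    """
    path = Path(path)
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: GTF line with fewer than 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = cols[:9]
            start, end = int(start1) - 1, int(end1)
            gid = _attr(attrs, "gene_id")
            if gid not in exons:
                exons[gid] = []
                order.append(gid)
            if feature == "gene":
                spans[gid] = (chrom, start, end, strand)
            elif feature == "exon":
                exons[gid].append((start, end))
                if gid not in spans:
                    spans[gid] = (chrom, start, end, strand)
                else:
                    c, s, e, st = spans[gid]
                    spans[gid] = (c, min(s, start), max(e, end), st)
    genes = []
    for gid in order:
        chrom, start, end, strand = spans[gid]
        ex = tuple(sorted(exons[gid])) or ((start, end),)
        genes.append(Gene(gid, chrom, start, end, strand, ex))
    return genes


def tss_regions(genes: list[Gene]) -> RegionSet:
    """One-bp TSS intervals, strand-annotated, for profile computations."""
    return RegionSet(
        [GenomicInterval(g.chrom, g.tss, g.tss + 1, name=g.gene_id, strand=g.strand) for g in genes],
        meta={"track_kind": "other", "label": "tss"},
    )
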