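"""Genomic intervals and gene models.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversion
to/from 1-based closed GTF coordinates happens only at the GTF boundary
(:mod:`clipscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an input violates a contract of the pipeline."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) pairs into a disjoint sorted set."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def subtract_intervals(
    span: tuple[int, int], blocks: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference span − blocks, as disjoint sorted intervals."""
    out = []
    cur = span[0]
    for s, e in merge_intervals(blocks):
        s, e = max(s, span[0]), min(e, span[1])
        if s >= e:
            continue
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


def intersect_interval_sets(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in merge_intervals(a):
        for s2, e2 in merge_intervals(b):
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return merge_intervals(out)


@dataclass
class GeneModel:
    """One gene: exon/CDS/UTR structure plus derived introns.

    ``exons`` is the exonic union over transcripts; ``constitutive_exons``
    the intersection (regions present in every transcript), used as the
    gene-length denominator for rpkm.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: end <= start")
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        for tid in self.transcripts:
            self.transcripts[tid] = sorted(self.transcripts[tid])

    @property
    def exons(self) -> list[tuple[int, int]]:
        all_ex = [iv for ivs in self.transcripts.values() for iv in ivs]
        return merge_intervals(all_ex)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return subtract_intervals((self.start, self.end), self.exons)

    @property
    def constitutive_exons(self) -> list[tuple[int, int]]:
        txs = list(self.transcripts.values())
        if not txs:
            return []
        out = merge_intervals(txs[0])
        for ivs in txs[1:]:
            out = intersect_interval_sets(out, ivs)
        return out

    @property
    def constitutive_exon_length(self) -> int:
        return sum(e - s for s, e in self.constitutive_exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def noncoding_exons(self) -> list[tuple[int, int]]:
        """Exonic regions that are neither CDS nor annotated UTR."""
        blocks = self.cds + self.utr5 + self.utr3
        out = []
        for s, e in self.exons:
            out.extend(subtract_intervals((s, e), blocks))
        return merge_intervals(out)


@dataclass
class AnnotationBundle:
    """A deterministic, sorted collection of gene models."""

    genes: list[GeneModel]

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        for g in self.genes:
            if g.transcripts and g.constitutive_exon_length <= 0:
                raise ValidationError(
                    f"gene {g.gene_id}: constitutive exon length is 0"
                )
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValidationError("duplicate gene_id in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id
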