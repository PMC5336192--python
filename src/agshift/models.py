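"""Gene/isoform models shared by the simulator, annotation lookup and NMD code.

Coordinates are 0-based half-open genomic intervals throughout the package;
conversion to/from the 1-based closed conventions of GTF and STAR ``SJ.out.tab``
happens only at the I/O boundary (:mod:`agshift.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from ._seq import revcomp


@dataclass(frozen=True)
class IsoformModel:
    """One transcript isoform: ordered exons plus an implicit CDS.

    ``exons`` are genomic ``(start, end)`` intervals sorted in ascending genomic
    order regardless of strand. ``cds_start``/``cds_end`` are *transcript*
    coordinates (0-based half-open); by default the CDS spans the whole
    transcript, which is how the synthetic generator emits genes.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0
    cds_end: int | None = None  # None -> transcript end

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e

    # -- basic geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals, ascending order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in transcription (5'->3') order."""
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def acceptor_boundaries(self) -> list[int]:
        """Genomic coordinate of each intron's 3' splice-site boundary.

        For a plus-strand intron ``[s, e)`` the acceptor boundary is ``e`` (the
        downstream exon starts there); for minus strand it is ``s``.
        """
        if self.strand == "+":
            return [e for _, e in self.introns()]
        return [s for s, _ in self.introns()]

    def last_junction_tpos(self) -> int | None:
        """Transcript coordinate of the last exon-exon junction (None if single-exon)."""
        if len(self.exons) < 2:
            return None
        exons = self.exons_tx_order()
        return sum(e - s for s, e in exons[:-1])

    # -- sequence ---------------------------------------------------------

    def transcript_sequence(self, genome: Mapping[str, str]) -> str:
        chrom = genome[self.chrom]
        parts = [str(chrom[s:e]) for s, e in self.exons]
        seq = "".join(parts).upper()
        return seq if self.strand == "+" else revcomp(seq)

    def with_exons(self, exons: Sequence[tuple[int, int]]) -> "IsoformModel":
        return replace(self, exons=tuple(exons))


def gene_bounds(isoforms: Sequence[IsoformModel]) -> dict[str, tuple[str, int, int, str]]:
    """gene_id -> (chrom, start, end, strand) span over all isoforms."""
    out: dict[str, tuple[str, int, int, str]] = {}
    for iso in isoforms:
        cur = out.get(iso.gene_id)
        if cur is None:
            out[iso.gene_id] = (iso.chrom, iso.start, iso.end, iso.strand)
        else:
            chrom, s, e, strand = cur
            out[iso.gene_id] = (chrom, min(s, iso.start), max(e, iso.end), strand)
    return out
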