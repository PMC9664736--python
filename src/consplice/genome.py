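"""Genome configuration, gene models, and positional annotation.

Coordinates are 0-based half-open everywhere inside the package; 1-based
formats (VCF, GTF, per-position TSVs) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

REF_ALLELES = "ACGT"
REF_INDEX = {b: i for i, b in enumerate(REF_ALLELES)}

AUTOSOME = "autosome"
X_CLASS = "X"

# Relative exonic/intronic position labels, strand-aware, measured from the
# nearest splice junction. Canonical sites are the two intronic bases on each
# side of an internal exon boundary.
CANONICAL_LABELS = ("A-1", "A-2", "D+1", "D+2")
POSITION_LABELS = CANONICAL_LABELS + (
    "splice_region_intronic",
    "splice_region_exonic",
    "intronic",
    "exonic",
    "deep_intronic",
    "deep_exonic",
)

SPLICE_REGION_INTRONIC_BP = 8
SPLICE_REGION_EXONIC_BP = 3
NEAR_JUNCTION_BP = 10


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    ivals = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class GenomeConfig:
    """Chromosome inventory with autosome/X designation and PAR intervals.

    Parameters
    ----------
    chrom_lengths : mapping chrom -> length (bp)
    x_chromosomes : chromosomes modeled as X (separate constraint model)
    par_intervals : pseudoautosomal intervals on X, excluded from the X model
    build : free-text genome build label carried into output manifests
    """

    chrom_lengths: dict[str, int]
    x_chromosomes: frozenset[str] = frozenset({"chrX", "X"})
    par_intervals: tuple[tuple[str, int, int], ...] = ()
    build: str = "synthetic"

    def __post_init__(self) -> None:
        seen: list[tuple[str, int, int]] = []
        for chrom, start, end in self.par_intervals:
            if chrom not in self.x_chromosomes:
                raise ValueError(f"PAR interval on non-X chromosome {chrom!r}")
            length = self.chrom_lengths.get(chrom)
            if length is None or not (0 <= start < end <= length):
                raise ValueError(f"PAR interval {chrom}:{start}-{end} outside chromosome")
            for pc, ps, pe in seen:
                if pc == chrom and interval_overlap((start, end), (ps, pe)):
                    raise ValueError("overlapping PAR intervals")
            seen.append((chrom, start, end))

    def chromosome_class(self, chrom: str) -> str | None:
        """'autosome', 'X', or None for chromosomes excluded from modeling (Y)."""
        if chrom not in self.chrom_lengths:
            return None
        if chrom in self.x_chromosomes:
            return X_CLASS
        if chrom.lstrip("chr") in ("Y",):
            return None
        return AUTOSOME

    def pars_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.par_intervals if c == chrom]


# GRCh38 pseudoautosomal intervals (1-based inclusive in the reference
# literature; stored half-open 0-based).
GRCH38_PAR = (("chrX", 9_999, 2_781_479), ("chrX", 155_701_381, 156_030_895))


@dataclass
class GeneModel:
    """A protein-coding gene as a strand-separated union of its transcripts.

    ``merged_intervals`` is the union of all transcript spans on the gene's
    strand (sorted, non-overlapping); ``exons`` the union of exon intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    merged_intervals: list[tuple[int, int]]
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.merged_intervals = merge_intervals(self.merged_intervals)
        self.exons = merge_intervals(self.exons)
        self.cds = merge_intervals(self.cds)
        span = self.span
        for s, e in self.exons:
            if not (span[0] <= s and e <= span[1]):
                raise ValueError(f"exon outside merged span in {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.merged_intervals[0][0], self.merged_intervals[-1][1]

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e


def _exon_index(exons: Sequence[tuple[int, int]], pos: int) -> int | None:
    for k, (s, e) in enumerate(exons):
        if s <= pos < e:
            return k
    return None


def annotate_relative_position(pos: int, gene: GeneModel) -> str:
    """Label a genic position relative to the nearest splice junction.

    Labels follow clinical convention: A-1/A-2 and D+1/D+2 are the canonical
    intronic acceptor/donor bases of internal junctions; the splice region is
    8 intronic / 3 exonic bases; positions within 10 bp are intronic/exonic
    and beyond that deep intronic/exonic. The transcription-first exon has no
    acceptor and the transcription-last exon no donor. Strand determines which
    genomic edge of an exon is the acceptor.

    Raises ``ValueError`` for positions outside the gene span. Ties between
    acceptor and donor distance resolve to the acceptor side.
    """
    if not gene.contains(pos):
        raise ValueError(f"position {pos} outside span of {gene.gene_id}")
    exons = gene.exons
    n = len(exons)
    plus = gene.strand == "+"
    k = _exon_index(exons, pos)

    if k is None:
        if pos < exons[0][0] or pos >= exons[-1][1]:
            # Inside the merged span but outside the exon span: not adjacent
            # to any internal splice junction, so never a splice-region base.
            return "deep_intronic"
        # Intronic: find flanking exons.
        left = max(i for i, (_, e) in enumerate(exons) if e <= pos)
        s_next = exons[left + 1][0]
        e_prev = exons[left][1]
        if plus:
            d_donor = pos - e_prev + 1       # D+1 at first intronic base
            d_acceptor = s_next - pos        # A-1 adjacent to next exon
        else:
            d_donor = s_next - pos
            d_acceptor = pos - e_prev + 1
        if d_acceptor <= d_donor:
            d, side = d_acceptor, "A"
        else:
            d, side = d_donor, "D"
        if d <= 2:
            return f"{side}-{d}" if side == "A" else f"{side}+{d}"
        if d <= SPLICE_REGION_INTRONIC_BP:
            return "splice_region_intronic"
        if d <= NEAR_JUNCTION_BP:
            return "intronic"
        return "deep_intronic"

    # Exonic: distances to this exon's real splice junctions only. The
    # transcriptionally first exon lacks an acceptor junction, the last a
    # donor junction (those edges do not participate in splicing).
    s, e = exons[k]
    dists = []
    if plus:
        if k > 0:  # acceptor at genomic left edge
            dists.append(pos - s + 1)
        if k < n - 1:  # donor at genomic right edge
            dists.append(e - pos)
    else:
        if k < n - 1:  # acceptor at genomic right edge
            dists.append(e - pos)
        if k > 0:  # donor at genomic left edge
            dists.append(pos - s + 1)
    if not dists:
        return "deep_exonic"
    d = min(dists)
    if d <= SPLICE_REGION_EXONIC_BP:
        return "splice_region_exonic"
    if d <= NEAR_JUNCTION_BP:
        return "exonic"
    return "deep_exonic"
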