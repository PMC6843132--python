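"""ChIP-Seq peak preprocessing: summit windows, promoters, overlaps.

Reads narrowPeak (BED6+4) peak calls, builds fixed-width windows centered
on peak summits for motif analysis, defines promoters as the 500 bp
strand-aware upstream of annotated TSSs, intersects interval sets with a
sorted sweep line, and extracts window sequences from an indexed genome.
All coordinates are 0-based half-open internally; GFF3 input (1-based) is
converted at the parser boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "Annotation",
    "VennCounts",
    "read_narrowpeak",
    "summit_window",
    "promoter_intervals",
    "intersect",
    "venn_counts",
    "classify_promoter_peaks",
    "extract_sequences",
    "read_gff3_tss",
    "write_bed6",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit_offset: int = -1  # narrowPeak column 10; -1 = unknown
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset >= 0 and (
            self.interval.start + self.summit_offset >= self.interval.end
        ):
            raise ValueError("summit offset falls outside the peak interval")

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when the offset is unknown."""
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass
class PeakSet:
    label: str
    peaks: list[Peak] = field(default_factory=list)
    n_malformed: int = 0

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass(frozen=True)
class Annotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("annotation strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError("TSS must be >= 0")


def read_narrowpeak(source, label: str = "peaks") -> PeakSet:
    """Parse a narrowPeak (BED6+4) file or open stream into a PeakSet.

    Track/comment lines are tolerated; lines with fewer than 10 columns are
    skipped and counted.  A summit column of -1 is replaced by the interval
    midpoint with a warning.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh = source
    peaks: list[Peak] = []
    n_malformed = 0
    n_midpoint = 0
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                n_malformed += 1
                log.warning("narrowPeak line %d: %d column(s), expected 10; skipped",
                            lineno, len(fields))
                continue
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4]) if fields[4] != "." else 0.0
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
                summit = int(fields[9])
                interval = GenomicInterval(chrom, start, end, strand)
                if summit < 0:
                    summit = (end - start) // 2
                    n_midpoint += 1
                peaks.append(Peak(interval, summit_offset=summit,
                                  score=score, name=name))
            except (ValueError, IndexError) as exc:
                n_malformed += 1
                log.warning("narrowPeak line %d unparsable (%s); skipped", lineno, exc)
    finally:
        if close:
            fh.close()
    if n_midpoint:
        warnings.warn(
            f"{n_midpoint} peak(s) had summit -1; replaced by interval midpoint",
            stacklevel=2,
        )
    return PeakSet(label=label, peaks=peaks, n_malformed=n_malformed)


def summit_window(
    peak: Peak, flank: int = 25, chrom_size: int | None = None
) -> GenomicInterval:
    """Fixed-width window [summit - flank, summit + flank) around the summit.

    The default flank of 25 bp gives a 50 bp window.  Windows are clipped at
    position 0 and, when the chromosome length is known, at its end.
    """
    if flank <= 0:
        raise ValueError("flank must be a positive number of bases")
    summit = peak.summit
    start = summit - flank
    end = summit + flank
    if start < 0:
        warnings.warn(f"window at summit {summit} clipped at chromosome start",
                      stacklevel=2)
        start = 0
    if chrom_size is not None and end > chrom_size:
        warnings.warn(f"window at summit {summit} clipped at chromosome end",
                      stacklevel=2)
        end = chrom_size
    return GenomicInterval(peak.interval.chrom, start, end, ".")


def promoter_intervals(
    annotations: Sequence[Annotation], upstream: int = 500
) -> list[GenomicInterval]:
    """Strand-aware promoters: the ``upstream`` bp 5' of each annotated TSS.

    Plus-strand gene -> [tss - upstream, tss); minus-strand gene ->
    [tss + 1, tss + 1 + upstream); clipped at 0.
    """
    out: list[GenomicInterval] = []
    for ann in annotations:
        if ann.strand == "+":
            start, end = max(0, ann.tss - upstream), ann.tss
        else:
            start, end = ann.tss + 1, ann.tss + 1 + upstream
        if start >= end:
            warnings.warn(f"gene {ann.gene_id!r}: promoter fully clipped; skipped",
                          stacklevel=2)
            continue
        out.append(GenomicInterval(ann.chrom, start, end, ann.strand))
    return out


class _Event(NamedTuple):
    pos: int
    kind: int    # 0 = start before end at equal pos? see sweep ordering
    which: int   # 0 = set a, 1 = set b
    index: int


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[list[tuple[int, int]], list[bool], list[bool]]:
    """All >= 1 bp overlapping pairs between two interval lists (sweep line).

    Strand is ignored; only same-chromosome intervals can overlap.  Returns
    ``(pairs, flags_a, flags_b)`` where pairs holds (index in a, index in b)
    and the flag lists mark which inputs overlap anything in the other set.
    """
    flags_a = [False] * len(a)
    flags_b = [False] * len(b)
    pairs: list[tuple[int, int]] = []
    # sweep per chromosome: ends (kind 0) processed before starts (kind 1)
    # at equal coordinate, so half-open abutting intervals do not pair
    events: dict[str, list[tuple[int, int, int, int]]] = {}
    for which, intervals in enumerate((a, b)):
        for idx, iv in enumerate(intervals):
            events.setdefault(iv.chrom, []).append((iv.start, 1, which, idx))
            events.setdefault(iv.chrom, []).append((iv.end, 0, which, idx))
    for chrom_events in events.values():
        chrom_events.sort()
        active: tuple[set[int], set[int]] = (set(), set())
        for _pos, kind, which, idx in chrom_events:
            if kind == 0:
                active[which].discard(idx)
            else:
                other = 1 - which
                for jdx in active[other]:
                    ai, bi = (idx, jdx) if which == 0 else (jdx, idx)
                    pairs.append((ai, bi))
                    flags_a[ai] = True
                    flags_b[bi] = True
                active[which].add(idx)
    pairs.sort()
    return pairs, flags_a, flags_b


class VennCounts(NamedTuple):
    only_a: int
    shared_a: int
    only_b: int
    shared_b: int


def venn_counts(
    a: PeakSet, b: PeakSet, overlap_mode: str = "peak", flank: int = 25
) -> VennCounts:
    """Per-set shared/exclusive peak counts for a two-set Venn diagram.

    ``shared_a`` counts a's peaks overlapping >= 1 peak of b (and vice
    versa); because peak overlap is many-to-many the two shared counts can
    differ, so both are reported.  ``overlap_mode="peak"`` overlaps the
    original peak intervals; ``"window"`` overlaps fixed summit windows of
    half-width ``flank`` instead.
    """
    if overlap_mode not in ("peak", "window"):
        raise ValueError("overlap_mode must be 'peak' or 'window'")
    if overlap_mode == "peak":
        ia, ib = a.intervals(), b.intervals()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ia = [summit_window(p, flank) for p in a.peaks]
            ib = [summit_window(p, flank) for p in b.peaks]
    _, flags_a, flags_b = intersect(ia, ib)
    shared_a, shared_b = sum(flags_a), sum(flags_b)
    return VennCounts(
        only_a=len(a) - shared_a,
        shared_a=shared_a,
        only_b=len(b) - shared_b,
        shared_b=shared_b,
    )


def classify_promoter_peaks(
    peaks: PeakSet, promoters: Sequence[GenomicInterval]
) -> PeakSet:
    """Subset of peaks whose interval overlaps >= 1 promoter interval."""
    _, flags, _ = intersect(peaks.intervals(), list(promoters))
    return PeakSet(
        label=f"{peaks.label}|promoter",
        peaks=[p for p, f in zip(peaks.peaks, flags) if f],
    )


def extract_sequences(
    intervals: Sequence[GenomicInterval], genome_fasta
) -> list[tuple[str, str]]:
    """Top-strand, uppercased sequences of intervals from an indexed FASTA.

    ``genome_fasta`` is a path or an open :class:`pyfaidx.Fasta`.  Intervals
    on missing chromosomes are logged and skipped; intervals running past
    the chromosome end are clipped with a warning.  Ids encode
    ``chrom:start-end``.
    """
    import pyfaidx

    fasta = (
        genome_fasta
        if isinstance(genome_fasta, pyfaidx.Fasta)
        else pyfaidx.Fasta(str(genome_fasta))
    )
    out: list[tuple[str, str]] = []
    for iv in intervals:
        if iv.chrom not in fasta:
            log.warning("chromosome %r absent from genome; interval skipped", iv.chrom)
            continue
        size = len(fasta[iv.chrom])
        end = iv.end
        if end > size:
            warnings.warn(
                f"interval {iv.chrom}:{iv.start}-{iv.end} clipped at chromosome "
                f"end {size}",
                stacklevel=2,
            )
            end = size
        if iv.start >= end:
            log.warning("interval %s:%d-%d empty after clipping; skipped",
                        iv.chrom, iv.start, iv.end)
            continue
        seq = str(fasta[iv.chrom][iv.start:end]).upper()
        out.append((f"{iv.chrom}:{iv.start}-{end}", seq))
    return out


def read_gff3_tss(path, feature: str = "gene") -> list[Annotation]:
    """Extract strand-aware TSS records from GFF3 gene features.

    The TSS is the 5' end of the feature: the (1-based) start converted to
    0-based on '+', the end converted to 0-based on '-'.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[Annotation] = []
    for gene in db.features_of_type(feature):
        if gene.strand not in ("+", "-"):
            log.warning("gene %s has strand %r; skipped", gene.id, gene.strand)
            continue
        tss = gene.start - 1 if gene.strand == "+" else gene.end - 1
        out.append(Annotation(gene_id=gene.id, chrom=gene.seqid,
                              strand=gene.strand, tss=tss))
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path, name: str = ".") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
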