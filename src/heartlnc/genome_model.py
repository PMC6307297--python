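"""Genomic domain model: intervals, transcripts, genes and an indexed annotation.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive file convention at the boundary.  The transcription start
site (TSS) of a transcript is ``span.start`` on the ``+`` strand and
``span.end`` on the ``-`` strand.

Distances from a point to a gene span are measured as the coordinate gap to
the nearest base contained in the span (0 if the point falls inside), so a
point at 5,000 is 3,000 bp from a span starting at 8,000, symmetrically on
either flank.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

BIOTYPES = frozenset(
    {"protein_coding", "lncRNA_candidate", "snoRNA", "tRNA", "other_nc"}
)

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """A record violates a structural invariant of the domain model."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def point_to_span_distance(pos: int, start: int, end: int) -> int:
    """Gap in bp from a point to the nearest base of [start, end); 0 inside."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced transcript: strand, exon structure and optional CDS."""

    transcript_id: str
    gene_id: str
    biotype: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_length: int = 0
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exon chrom/strand differs from span"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{ex.start},{ex.end}) outside "
                    f"declared span [{self.span.start},{self.span.end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if self.cds:
            cds_sum = sum(len(c) for c in self.cds)
            if self.cds_length == 0:
                object.__setattr__(self, "cds_length", cds_sum)
            elif self.cds_length != cds_sum:
                raise ValidationError(
                    f"{self.transcript_id}: cds_length {self.cds_length} != "
                    f"sum of CDS records {cds_sum}"
                )
        if self.cds_length < 0 or self.cds_length > self.transcript_length:
            raise ValidationError(
                f"{self.transcript_id}: cds_length {self.cds_length} exceeds "
                f"transcript length {self.transcript_length}"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def tss(self) -> int:
        """TSS position: span.start on '+', span.end on '-'."""
        return self.span.start if self.span.strand == "+" else self.span.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    def reverse_strand(self) -> "TranscriptModel":
        flip = {"+": "-", "-": "+"}
        new_strand = flip[self.strand]
        return replace(
            self,
            span=replace(self.span, strand=new_strand),
            exons=tuple(replace(ex, strand=new_strand) for ex in self.exons),
            cds=tuple(replace(c, strand=new_strand) for c in self.cds),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing gene_id, chrom and strand."""

    gene_id: str
    biotype: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene without transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.gene_id}: transcripts disagree on chrom/strand"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValidationError(
                    f"{self.gene_id}: transcript {t.transcript_id} carries "
                    f"gene_id {t.gene_id}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Union envelope of the transcripts' spans."""
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    @property
    def tss_set(self) -> tuple[tuple[str, int, str], ...]:
        """Distinct (chrom, position, strand) per transcript start."""
        seen = sorted({(t.chrom, t.tss, t.strand) for t in self.transcripts})
        return tuple(seen)


@dataclass(frozen=True)
class NearestHit:
    gene_id: str
    distance: int


class SpanIndex:
    """Per-chromosome index over gene spans for overlap and nearest queries.

    Overlap hits come from an interval tree; flanking candidates from
    bisection on span boundaries sorted by (coordinate, gene_id), so ties are
    resolved by smaller distance then lexicographic gene_id — identical to an
    exhaustive scan.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        # per chrom: boundaries sorted ascending, ends by (end, id), starts by (start, id)
        self._ends: dict[str, list[tuple[int, str]]] = {}
        self._starts: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            sp = g.span
            self._trees.setdefault(sp.chrom, IntervalTree())[
                sp.start : sp.end
            ] = g.gene_id
            self._ends.setdefault(sp.chrom, []).append((sp.end, g.gene_id))
            self._starts.setdefault(sp.chrom, []).append((sp.start, g.gene_id))
        for chrom in self._ends:
            self._ends[chrom].sort()
            self._starts[chrom].sort()

    def overlapping(
        self, chrom: str, start: int, end: int, exclude: Optional[str] = None
    ) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [g for g in hits if g != exclude]

    def nearest(
        self, chrom: str, pos: int, exclude: Optional[str] = None
    ) -> Optional[NearestHit]:
        """Nearest gene span to a point; None when the pool is empty."""
        candidates: list[tuple[int, str]] = []
        tree = self._trees.get(chrom)
        if tree is not None:
            for iv in tree[pos]:
                if iv.data != exclude:
                    candidates.append((0, iv.data))
        ends = self._ends.get(chrom, [])
        idx = bisect.bisect_right(ends, (pos, "￿")) - 1
        while idx >= 0:
            e = ends[idx][0]
            group = []
            j = idx
            while j >= 0 and ends[j][0] == e:
                if ends[j][1] != exclude:
                    group.append(ends[j][1])
                j -= 1
            if group:
                candidates.append((pos - (e - 1), min(group)))
                break
            idx = j
        starts = self._starts.get(chrom, [])
        idx = bisect.bisect_left(starts, (pos, ""))
        n = len(starts)
        while idx < n:
            s = starts[idx][0]
            group = []
            j = idx
            while j < n and starts[j][0] == s:
                if starts[j][1] != exclude:
                    group.append(starts[j][1])
                j += 1
            if group:
                candidates.append((s - pos, min(group)))
                break
            idx = j
        # flanking candidates can be negative-gap when the point sits inside
        # another gene's envelope; containment hits already cover distance 0
        candidates = [(max(d, 0), g) for d, g in candidates]
        if not candidates:
            return None
        d, g = min(candidates)
        return NearestHit(g, d)


class TssIndex:
    """Sorted TSS positions, optionally split by strand."""

    def __init__(self, genes: Iterable[GeneModel]):
        raw: dict[tuple[str, str], list[tuple[int, str]]] = {}
        allraw: dict[str, list[tuple[int, str, str]]] = {}
        for g in genes:
            for chrom, pos, strand in g.tss_set:
                raw.setdefault((chrom, strand), []).append((pos, g.gene_id))
                allraw.setdefault(chrom, []).append((pos, strand, g.gene_id))
        self._by_strand = {k: sorted(v) for k, v in raw.items()}
        self._all = {k: sorted(v) for k, v in allraw.items()}

    def within(
        self, chrom: str, pos: int, window: int, strand: Optional[str] = None
    ) -> list[tuple[int, str]]:
        """All (tss, gene_id) with |tss - pos| <= window, optionally on one strand."""
        if strand is not None:
            arr = self._by_strand.get((chrom, strand), [])
            lo = bisect.bisect_left(arr, (pos - window, ""))
            hi = bisect.bisect_right(arr, (pos + window, "￿"))
            return arr[lo:hi]
        arr = self._all.get(chrom, [])
        lo = bisect.bisect_left(arr, (pos - window, "", ""))
        hi = bisect.bisect_right(arr, (pos + window, "￿", "￿"))
        return [(p, g) for p, _, g in arr[lo:hi]]

    def nearest(
        self, chrom: str, pos: int, exclude: Optional[str] = None
    ) -> Optional[NearestHit]:
        arr = self._all.get(chrom, [])
        if not arr:
            return None
        idx = bisect.bisect_left(arr, (pos, "", ""))
        best: Optional[tuple[int, str]] = None
        for j in range(idx - 1, -1, -1):
            p, _, g = arr[j]
            if g == exclude:
                continue
            d = abs(pos - p)
            if best is not None and d > best[0]:
                break
            if best is None or (d, g) < best:
                best = (d, g)
        for j in range(idx, len(arr)):
            p, _, g = arr[j]
            if g == exclude:
                continue
            d = abs(pos - p)
            if best is not None and d > best[0]:
                break
            if best is None or (d, g) < best:
                best = (d, g)
        if best is None:
            return None
        return NearestHit(best[1], best[0])


class GenomeAnnotation:
    """Indexed collection of genes supporting nearest/overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        ordered = sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id))
        self.genes: dict[str, GeneModel] = {}
        for g in ordered:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._span_indexes: dict[Optional[str], SpanIndex] = {}
        self._tss_indexes: dict[Optional[str], TssIndex] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.genes == other.genes

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes.values():
            yield from g.transcripts

    def genes_of_biotype(self, biotype: Optional[str]) -> list[GeneModel]:
        if biotype is None:
            return list(self.genes.values())
        return [g for g in self.genes.values() if g.biotype == biotype]

    def span_index(self, biotype: Optional[str] = None) -> SpanIndex:
        if biotype not in self._span_indexes:
            self._span_indexes[biotype] = SpanIndex(self.genes_of_biotype(biotype))
        return self._span_indexes[biotype]

    def tss_index(self, biotype: Optional[str] = None) -> TssIndex:
        if biotype not in self._tss_indexes:
            self._tss_indexes[biotype] = TssIndex(self.genes_of_biotype(biotype))
        return self._tss_indexes[biotype]

    def reverse_strands(self) -> "GenomeAnnotation":
        """Annotation with every strand flipped (used by symmetry checks)."""
        genes = [
            GeneModel(
                g.gene_id,
                g.biotype,
                tuple(t.reverse_strand() for t in g.transcripts),
            )
            for g in self.genes.values()
        ]
        return GenomeAnnotation(genes)

    def mirror(self) -> "GenomeAnnotation":
        """Mirror image: per-chromosome coordinate reflection + strand flip.

        This is the exact symmetry of all distance/orientation computations:
        every TSS maps to the same genomic point, gaps and overlaps are
        preserved, and divergent pairs stay divergent.
        """
        flip = {"+": "-", "-": "+"}
        chrom_len: dict[str, int] = {}
        for g in self.genes.values():
            chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.span.end + 1000)

        def refl(iv: GenomicInterval) -> GenomicInterval:
            L = chrom_len[iv.chrom]
            return GenomicInterval(iv.chrom, L - iv.end, L - iv.start, flip[iv.strand])

        genes = []
        for g in self.genes.values():
            ts = []
            for t in g.transcripts:
                ts.append(
                    TranscriptModel(
                        t.transcript_id,
                        t.gene_id,
                        t.biotype,
                        refl(t.span),
                        tuple(refl(e) for e in reversed(t.exons)),
                        cds=tuple(refl(c) for c in reversed(t.cds)),
                    )
                )
            genes.append(GeneModel(g.gene_id, g.biotype, tuple(ts)))
        return GenomeAnnotation(genes)


def nearest_gene_query(
    annotation: GenomeAnnotation,
    chrom: str,
    pos: int,
    biotype_filter: Optional[str] = None,
    exclude_gene: Optional[str] = None,
) -> Optional[NearestHit]:
    """Nearest qualifying gene span to a point; None when no neighbor exists."""
    return annotation.span_index(biotype_filter).nearest(chrom, pos, exclude_gene)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect; 1-based inclusive coordinates in files)
# ---------------------------------------------------------------------------

_GTF_HEADER = "#!heartlnc GTF (gene_id/transcript_id/biotype attributes)"


def read_gtf(path) -> GenomeAnnotation:
    """Read exon/CDS records grouped into transcripts and genes.

    Raises GtfParseError naming the offending line; ValidationError for
    structurally inconsistent records (unknown strand, exon outside a
    declared transcript span, ...).
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    declared_span: dict[str, GenomicInterval] = {}
    meta: dict[str, tuple[str, str]] = {}  # transcript_id -> (gene_id, biotype)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated GTF columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - reported with line number
                raise GtfParseError(f"line {lineno}: cannot parse GTF record ({exc})")
            if feat.featuretype not in ("exon", "CDS", "transcript"):
                continue
            if feat.strand not in STRANDS:
                raise ValidationError(
                    f"line {lineno}: unknown strand symbol {feat.strand!r}"
                )
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing attribute {exc}")
            biotype = (feat.attributes.get("biotype") or ["other_nc"])[0]
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise GtfParseError(f"line {lineno}: invalid coordinates")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            prev = meta.setdefault(tid, (gid, biotype))
            if prev != (gid, biotype):
                raise ValidationError(
                    f"line {lineno}: transcript {tid} redefines gene/biotype"
                )
            if feat.featuretype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feat.featuretype == "CDS":
                cds.setdefault(tid, []).append(iv)
            else:
                declared_span[tid] = iv
    transcripts = []
    for tid, (gid, biotype) in meta.items():
        exs = sorted(exons.get(tid, []), key=lambda e: e.start)
        if not exs:
            raise ValidationError(f"transcript {tid} has no exon records")
        span = declared_span.get(tid)
        if span is None:
            span = GenomicInterval(
                exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
            )
        cds_ivs = tuple(sorted(cds.get(tid, []), key=lambda c: c.start))
        transcripts.append(
            TranscriptModel(tid, gid, biotype, span, tuple(exs), cds=cds_ivs)
        )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid, ts in by_gene.items():
        ts.sort(key=lambda t: (t.span.start, t.transcript_id))
        biotypes = {t.biotype for t in ts}
        gene_biotype = (
            "protein_coding" if "protein_coding" in biotypes else ts[0].biotype
        )
        genes.append(GeneModel(gid, gene_biotype, tuple(ts)))
    return GenomeAnnotation(genes)


def _format_line(
    chrom: str, feature: str, start0: int, end0: int, strand: str, attrs: str
) -> str:
    return (
        f"{chrom}\theartlnc\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
    )


def _synthesized_cds(t: TranscriptModel) -> tuple[GenomicInterval, ...]:
    """Greedy CDS placement over exons when only cds_length is known."""
    remaining = t.cds_length
    out = []
    for ex in t.exons:
        if remaining <= 0:
            break
        take = min(remaining, len(ex))
        out.append(GenomicInterval(ex.chrom, ex.start, ex.start + take, ex.strand))
        remaining -= take
    return tuple(out)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Emit GTF with 1-based inclusive coordinates; inverse of read_gtf."""
    with open(path, "w") as fh:
        fh.write(_GTF_HEADER + "\n")
        for gene in annotation.genes.values():
            for t in gene.transcripts:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    _format_line(
                        t.chrom, "transcript", t.span.start, t.span.end, t.strand, attrs
                    )
                    + "\n"
                )
                for ex in t.exons:
                    fh.write(
                        _format_line(t.chrom, "exon", ex.start, ex.end, t.strand, attrs)
                        + "\n"
                    )
                cds_ivs = t.cds if t.cds else _synthesized_cds(t)
                for c in cds_ivs:
                    fh.write(
                        _format_line(t.chrom, "CDS", c.start, c.end, t.strand, attrs)
                        + "\n"
                    )
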