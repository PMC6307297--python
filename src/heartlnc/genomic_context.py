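"""Genomic-context classification of lncRNA candidates.

A candidate is *bidirectional* when some protein-coding TSS lies on the
opposite strand within the promoter window (default 3,000 bp) with the two
transcripts pointing away from each other (head-to-head divergence);
*antisense* when its span overlaps a protein-coding gene span on the
opposite strand by at least 1 bp (gene-span overlap, so purely intronic
overlap counts); *both* when the two co-occur; otherwise *intergenic*.
Same-strand TSS proximity is recorded as a diagnostic flag but never counts
as bidirectional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .candidate_filter import ExpressionMatrix, FilterConfig, LncCandidate
from .genome_model import GenomeAnnotation, SpanIndex, TssIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContextConfig:
    bidirectional_window: int = 3_000
    proximity_window: int = 10_000
    require_divergent: bool = True
    expressed_neighbors_only: bool = True
    distance_mode: str = "gene_body"  # or "tss"

    def __post_init__(self) -> None:
        if self.bidirectional_window <= 0 or self.proximity_window <= 0:
            raise ValueError("windows must be positive")
        if self.distance_mode not in ("gene_body", "tss"):
            raise ValueError("distance_mode must be 'gene_body' or 'tss'")


def expressed_coding_genes(
    annotation: GenomeAnnotation,
    matrix: Optional[ExpressionMatrix],
    filter_config: FilterConfig = FilterConfig(),
) -> list:
    """Protein-coding genes expressed in >= 1 heart (ventricle) stage."""
    coding = annotation.genes_of_biotype("protein_coding")
    if matrix is None:
        return coding
    heart = matrix.tissue_samples(filter_config.heart_tissue)
    out = []
    for g in coding:
        for t in g.transcripts:
            if max(matrix.get(t.transcript_id, heart), default=0) >= filter_config.min_fpkm:
                out.append(g)
                break
    return out


def compute_nearest_distances(
    candidates: Sequence[LncCandidate],
    annotation: GenomeAnnotation,
    matrix: Optional[ExpressionMatrix] = None,
    config: ContextConfig = ContextConfig(),
    filter_config: FilterConfig = FilterConfig(),
) -> list[LncCandidate]:
    """Fill nearest_gene/nearest_distance from each candidate's TSS.

    The neighbor pool is protein-coding genes, restricted to those expressed
    in at least one ventricle stage when expressed_neighbors_only is set.
    Distance is the gap from the TSS to the gene span (distance_mode
    'gene_body', default) or to the nearest coding TSS ('tss'). Candidates
    with an empty pool on their chromosome keep the None sentinel.
    """
    pool = (
        expressed_coding_genes(annotation, matrix, filter_config)
        if config.expressed_neighbors_only
        else annotation.genes_of_biotype("protein_coding")
    )
    index = SpanIndex(pool) if config.distance_mode == "gene_body" else TssIndex(pool)
    for c in candidates:
        t = c.transcript
        hit = index.nearest(t.chrom, t.tss, exclude=t.gene_id)
        if hit is None:
            c.nearest_gene, c.nearest_distance = None, None
        else:
            c.nearest_gene, c.nearest_distance = hit.gene_id, hit.distance
    return list(candidates)


def _divergent(
    lnc_strand: str, lnc_tss: int, coding_strand: str, coding_tss: int
) -> bool:
    """Head-to-head orientation: the + partner lies at or right of the - one."""
    plus_pos = coding_tss if coding_strand == "+" else lnc_tss
    minus_pos = lnc_tss if coding_strand == "+" else coding_tss
    return plus_pos >= minus_pos


def classify_genomic_context(
    candidates: Sequence[LncCandidate],
    annotation: GenomeAnnotation,
    config: ContextConfig = ContextConfig(),
) -> list[LncCandidate]:
    """Label each candidate bidirectional / antisense / both / intergenic."""
    tss_index = annotation.tss_index("protein_coding")
    span_index = annotation.span_index("protein_coding")
    coding_strand = {
        g.gene_id: g.strand for g in annotation.genes_of_biotype("protein_coding")
    }
    for c in candidates:
        t = c.transcript
        opp = "-" if t.strand == "+" else "+"
        bid = set()
        for pos, gid in tss_index.within(
            t.chrom, t.tss, config.bidirectional_window, strand=opp
        ):
            if gid == t.gene_id:
                continue
            if config.require_divergent and not _divergent(
                t.strand, t.tss, opp, pos
            ):
                continue
            bid.add(gid)
        same = [
            gid
            for _, gid in tss_index.within(
                t.chrom, t.tss, config.bidirectional_window, strand=t.strand
            )
            if gid != t.gene_id
        ]
        anti = {
            gid
            for gid in span_index.overlapping(
                t.chrom, t.span.start, t.span.end, exclude=t.gene_id
            )
            if coding_strand[gid] == opp
        }
        c.bidirectional_partners = tuple(sorted(bid))
        c.antisense_partners = tuple(sorted(anti))
        c.same_strand_proximal = bool(same)
        if bid and anti:
            c.context = "both"
        elif bid:
            c.context = "bidirectional"
        elif anti:
            c.context = "antisense"
        else:
            c.context = "intergenic"
    counts: dict[str, int] = {}
    for c in candidates:
        counts[c.context] = counts.get(c.context, 0) + 1
    logger.info("context classes: %s", counts)
    return list(candidates)


def orientation_census(
    candidates: Sequence[LncCandidate],
    annotation: GenomeAnnotation,
    config: ContextConfig = ContextConfig(),
    mode: str = "nearest",
) -> tuple[int, int]:
    """(opposite, same) strand counts vs known genes within proximity_window.

    'Known genes' are every annotated gene that is not itself a lncRNA
    candidate. mode='nearest' compares each candidate with its single nearest
    known gene (default); mode='any' counts a candidate as opposite if any
    known gene within the window is on the opposite strand.
    """
    known = [
        g for g in annotation.genes.values() if g.biotype != "lncRNA_candidate"
    ]
    index = SpanIndex(known)
    strand_of = {g.gene_id: g.strand for g in known}
    opposite = same = 0
    for c in candidates:
        t = c.transcript
        if mode == "nearest":
            hit = index.nearest(t.chrom, t.tss, exclude=t.gene_id)
            if hit is None or hit.distance > config.proximity_window:
                continue
            if strand_of[hit.gene_id] == t.strand:
                same += 1
            else:
                opposite += 1
        elif mode == "any":
            lo = t.tss - config.proximity_window
            hi = t.tss + config.proximity_window
            hits = index.overlapping(t.chrom, max(lo, 0), hi, exclude=t.gene_id)
            if not hits:
                continue
            if any(strand_of[g] != t.strand for g in hits):
                opposite += 1
            else:
                same += 1
        else:
            raise ValueError("mode must be 'nearest' or 'any'")
    return opposite, same
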