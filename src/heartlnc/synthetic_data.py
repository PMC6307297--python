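"""Synthetic annotations, expression matrices and gene labels with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: multi-exon protein-coding genes with CDS; spliced lncRNA loci planted
as bidirectional (divergent TSS within the promoter window), antisense
(opposite-strand span overlap) or intergenic; fpkm across heart development
(E10.5, E13.5, adult) plus brain/kidney/liver with planted heart selectivity;
signed log-expression coupling for divergent pairs; and an excess of
bidirectional partners among haploinsufficient-labeled genes.

Planted loci keep a >=10% margin from every class-decision boundary
(3,000 bp bidirectional window, 10,000 bp proximity window) so that
classification recovers the planted labels deterministically.

Randomness: a master seed spawns one independent stream per sub-generator
(placement, selectivity, expression, labels), so enlarging one stage never
reshuffles the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)


class ConfigurationError(ValueError):
    """The simulation request cannot be satisfied (geometry or odds)."""


# sample grid: heart across three developmental stages, plus three reference
# tissues with a single (adult) sample each
DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("heart", "E10.5"),
    ("heart", "E13.5"),
    ("heart", "adult"),
    ("brain", "adult"),
    ("kidney", "adult"),
    ("liver", "adult"),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome/expression/label generator.

    Distances are bp; expression is fpkm; coupling acts on log2(fpkm).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000_000
    n_coding_genes: int = 200
    n_bidirectional: int = 20
    n_antisense: int = 20
    n_intergenic: int = 20
    # divergent TSS gap; kept <=2700 so planted loci sit >=10% away from the
    # 3000 bp decision boundary
    bidirectional_offset_range: tuple[int, int] = (100, 2700)
    antisense_overlap_fraction: float = 0.5
    intergenic_min_distance: int = 20_000
    locus_spacing: int = 80_000
    samples: tuple[tuple[str, str], ...] = DEFAULT_SAMPLES
    selectivity_fraction: float = 2 / 3
    pair_coupling_strength: float = 0.9
    pair_coupling_noise_sd: float = 0.2
    hi_fraction: float = 0.1
    hi_bidirectional_odds: float = 3.0
    housekeeping_fraction: float = 0.3
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms,
            self.n_coding_genes,
            self.n_bidirectional,
            self.n_antisense,
            self.n_intergenic,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be >= 0")
        lo, hi = self.bidirectional_offset_range
        if not (0 < lo <= hi):
            raise ConfigurationError("bidirectional offset range must be positive")
        for frac in (
            self.antisense_overlap_fraction,
            self.selectivity_fraction,
            self.hi_fraction,
            self.housekeeping_fraction,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.n_bidirectional + self.n_antisense > self.n_coding_genes:
            raise ConfigurationError(
                "more partnered lncRNAs requested than coding genes available"
            )

    @property
    def n_lnc(self) -> int:
        return self.n_bidirectional + self.n_antisense + self.n_intergenic


@dataclass
class TruthLabels:
    """Planted ground truth keyed by transcript/gene identifiers."""

    lnc_class: dict[str, str] = field(default_factory=dict)
    lnc_partner: dict[str, Optional[str]] = field(default_factory=dict)
    lnc_selective: dict[str, bool] = field(default_factory=dict)
    pair_sign: dict[str, int] = field(default_factory=dict)
    haploinsufficient: dict[str, bool] = field(default_factory=dict)
    housekeeping: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLabels":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("placement", "selectivity", "expression", "labels")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _make_exons(
    chrom: str, start: int, length: int, strand: str, n_exons: int
) -> tuple[GenomicInterval, ...]:
    """Evenly spaced exons covering [start, start+length) deterministically."""
    # alternate exon/intron blocks of equal size; guarantees sorted,
    # non-overlapping exons spanning the full transcript
    n_blocks = 2 * n_exons - 1
    bounds = np.linspace(start, start + length, n_blocks + 1).astype(int)
    exons = []
    for i in range(0, n_blocks, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e <= s:
            e = s + 1
        exons.append(GenomicInterval(chrom, s, e, strand))
    return tuple(exons)


def _coding_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str, n_exons: int
) -> GeneModel:
    exons = _make_exons(chrom, start, length, strand, n_exons)
    # CDS = interior of each exon, roughly a quarter of exonic length,
    # comfortably below the 1/3 coding-fraction threshold for lncRNAs but
    # marked protein_coding anyway
    total = sum(len(e) for e in exons)
    cds = []
    budget = total // 4
    for ex in exons:
        if budget <= 0:
            break
        take = min(budget, max(1, len(ex) // 2))
        cds.append(GenomicInterval(chrom, ex.start, ex.start + take, strand))
        budget -= take
    t = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        biotype="protein_coding",
        span=GenomicInterval(chrom, start, start + length, strand),
        exons=exons,
        cds=tuple(cds),
    )
    return GeneModel(gene_id, "protein_coding", (t,))


def _lnc_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str, n_exons: int
) -> GeneModel:
    exons = _make_exons(chrom, start, length, strand, n_exons)
    t = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        biotype="lncRNA_candidate",
        span=GenomicInterval(chrom, start, start + length, strand),
        exons=exons,
    )
    return GeneModel(gene_id, "lncRNA_candidate", (t,))


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, TruthLabels]:
    """Place coding genes and planted lncRNA loci; deterministic given seed."""
    rng = _streams(config.seed)["placement"]
    sel_rng = _streams(config.seed)["selectivity"]
    spacing = config.locus_spacing
    per_chrom = -(-config.n_coding_genes // config.n_chroms)  # ceil
    needed = (per_chrom + 1) * spacing + 2 * config.intergenic_min_distance
    if needed > config.chrom_length:
        raise ConfigurationError(
            f"chromosome length {config.chrom_length} too short for "
            f"{config.n_coding_genes} genes at spacing {spacing}"
        )
    genes: list[GeneModel] = []
    coding_meta: list[GeneModel] = []
    # round-robin loci: gene i sits on chrom i%n at slot i//n
    for i in range(config.n_coding_genes):
        chrom = f"chr{i % config.n_chroms + 1}"
        slot = i // config.n_chroms
        anchor = config.intergenic_min_distance + slot * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(12_000, 18_000))
        n_exons = int(rng.integers(4, 10))
        g = _coding_gene(f"pc{i:04d}", chrom, anchor, length, strand, n_exons)
        genes.append(g)
        coding_meta.append(g)
    truth = TruthLabels()
    # partner assignment: first n_bidirectional coding genes host divergent
    # lncRNAs, the following n_antisense host intronic antisense lncRNAs
    order = rng.permutation(config.n_coding_genes)
    bid_hosts = [coding_meta[j] for j in order[: config.n_bidirectional]]
    as_hosts = [
        coding_meta[j]
        for j in order[
            config.n_bidirectional : config.n_bidirectional + config.n_antisense
        ]
    ]
    lo, hi = config.bidirectional_offset_range
    k = 0
    for host in bid_hosts:
        lnc_id = f"lnc{k:04d}"
        k += 1
        offset = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(1_000, 3_000))
        n_exons = int(rng.integers(2, 5))
        hspan = host.span
        if host.strand == "+":
            # host TSS at hspan.start; divergent partner on '-' to the left
            tss = hspan.start - offset
            g = _lnc_gene(lnc_id, host.chrom, tss - length, length, "-", n_exons)
        else:
            tss = hspan.end + offset
            g = _lnc_gene(lnc_id, host.chrom, tss, length, "+", n_exons)
        genes.append(g)
        truth.lnc_class[g.transcripts[0].transcript_id] = "bidirectional"
        truth.lnc_partner[g.transcripts[0].transcript_id] = host.gene_id
    for host in as_hosts:
        lnc_id = f"lnc{k:04d}"
        k += 1
        hspan = host.span
        length = int(
            max(800, config.antisense_overlap_fraction * 4_000)
        )
        n_exons = int(rng.integers(2, 5))
        anti = "-" if host.strand == "+" else "+"
        # TSS placed 6 kb into the gene body: overlap is certain, and the
        # lncRNA TSS stays >3,300 bp (10% margin) from the host promoter
        if host.strand == "+":
            tss = hspan.start + 6_000
            g = _lnc_gene(lnc_id, host.chrom, tss - length, length, anti, n_exons)
        else:
            tss = hspan.end - 6_000
            g = _lnc_gene(lnc_id, host.chrom, tss, length, anti, n_exons)
        genes.append(g)
        truth.lnc_class[g.transcripts[0].transcript_id] = "antisense"
        truth.lnc_partner[g.transcripts[0].transcript_id] = host.gene_id
    # intergenic lncRNAs go into the inter-locus gaps on chrom 1, placed so
    # both flanks clear intergenic_min_distance (gene bodies end <=18 kb past
    # their anchor; divergent lncRNAs reach at most ~6 kb around an anchor)
    gap_slots = []
    off = 18_000 + int(1.1 * config.intergenic_min_distance)
    right_clear = spacing - off - 3_000 - 6_000
    if config.n_intergenic > 0 and right_clear < 1.1 * config.intergenic_min_distance:
        raise ConfigurationError(
            "locus_spacing too small to place intergenic lncRNAs with the "
            "required clearance on both flanks"
        )
    max_slot = (config.n_coding_genes - 1) // config.n_chroms
    for slot in range(max_slot):
        anchor = config.intergenic_min_distance + slot * spacing
        gap_slots.append(("chr1", anchor + off))
    if config.n_intergenic > len(gap_slots):
        raise ConfigurationError(
            "not enough inter-locus gaps for the requested intergenic lncRNAs"
        )
    for chrom, mid in gap_slots[: config.n_intergenic]:
        lnc_id = f"lnc{k:04d}"
        k += 1
        length = int(rng.integers(1_000, 3_000))
        n_exons = int(rng.integers(2, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        g = _lnc_gene(lnc_id, chrom, mid, length, strand, n_exons)
        genes.append(g)
        truth.lnc_class[g.transcripts[0].transcript_id] = "intergenic"
        truth.lnc_partner[g.transcripts[0].transcript_id] = None
    annotation = GenomeAnnotation(genes)
    # planted heart selectivity, drawn from its own stream
    lnc_tids = sorted(truth.lnc_class)
    n_sel = int(round(config.selectivity_fraction * len(lnc_tids)))
    sel = set(np.array(lnc_tids)[sel_rng.permutation(len(lnc_tids))[:n_sel]])
    for tid in lnc_tids:
        truth.lnc_selective[tid] = tid in sel
    # signed coupling for divergent pairs
    for tid in lnc_tids:
        if truth.lnc_class[tid] == "bidirectional":
            truth.pair_sign[tid] = 1 if sel_rng.random() < 0.5 else -1
    return annotation, truth


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: TruthLabels,
    config: SimulationConfig,
):
    """fpkm per transcript across the sample grid; coupling on log2 scale.

    lncRNA fpkm is drawn at a lower scale than coding fpkm; heart-selective
    lncRNAs exceed the 1-fpkm floor in at least one heart stage yet stay
    below it in every brain sample and rarely exceed 10 fpkm; divergent
    partner genes follow sign * strength * log2(lnc fpkm) plus lognormal
    noise across the three heart stages.
    """
    from .candidate_filter import ExpressionMatrix  # local import: no cycle at load

    rng = _streams(config.seed)["expression"]
    samples = [f"{t}_{s}" for t, s in config.samples]
    heart_idx = [i for i, (t, _) in enumerate(config.samples) if t == "heart"]
    brain_idx = [i for i, (t, _) in enumerate(config.samples) if t == "brain"]
    other_idx = [
        i
        for i, (t, _) in enumerate(config.samples)
        if t not in ("heart", "brain")
    ]
    tids, rows = [], []
    partner_gene_to_lnc = {
        g: t for t, g in truth.lnc_partner.items()
        if g is not None and truth.lnc_class[t] == "bidirectional"
    }
    lnc_heart_log2: dict[str, np.ndarray] = {}
    # lncRNA rows first so coupled coding rows can reuse the same draws
    lnc_rows: dict[str, np.ndarray] = {}
    for t in annotation.transcripts():
        if t.biotype != "lncRNA_candidate":
            continue
        vals = np.zeros(len(samples))
        heart_log2 = rng.uniform(0.3, 3.0, size=len(heart_idx))
        lnc_heart_log2[t.transcript_id] = heart_log2
        vals[heart_idx] = 2.0 ** heart_log2
        selective = truth.lnc_selective.get(t.transcript_id, False)
        if selective:
            vals[brain_idx] = rng.uniform(0.0, 0.5, size=len(brain_idx))
        else:
            vals[brain_idx] = rng.uniform(1.0, 5.0, size=len(brain_idx))
        for i in other_idx:
            vals[i] = (
                rng.uniform(1.0, 5.0) if rng.random() < 0.4 else rng.uniform(0.0, 0.5)
            )
        lnc_rows[t.transcript_id] = vals
    for t in annotation.transcripts():
        if t.biotype == "lncRNA_candidate":
            tids.append(t.transcript_id)
            rows.append(lnc_rows[t.transcript_id])
            continue
        vals = np.zeros(len(samples))
        base = rng.normal(np.log2(20.0), 1.0)
        vals[:] = 2.0 ** (base + rng.normal(0.0, config.noise_sd, size=len(samples)))
        lnc_tid = partner_gene_to_lnc.get(t.gene_id)
        if lnc_tid is not None and lnc_tid in lnc_heart_log2:
            sign = truth.pair_sign.get(lnc_tid, 1)
            x = lnc_heart_log2[lnc_tid]
            intercept = rng.normal(3.5, 0.5)
            y = (
                intercept
                + sign * config.pair_coupling_strength * x
                + rng.normal(0.0, config.pair_coupling_noise_sd, size=len(x))
            )
            vals[heart_idx] = 2.0 ** y
        tids.append(t.transcript_id)
        rows.append(vals)
    values = pd.DataFrame(np.array(rows), index=tids, columns=samples)
    values = values.round(6).sort_index()
    return ExpressionMatrix.from_dataframe(values)


def _solve_baseline_odds(
    bid_fraction: float, hi_fraction: float, odds_multiplier: float
) -> float:
    """Baseline odds o s.t. f_b*mo/(1+mo) + (1-f_b)*o/(1+o) == hi_fraction."""
    if hi_fraction <= 0.0:
        return 0.0

    def marginal(o: float) -> float:
        mo = odds_multiplier * o
        return bid_fraction * mo / (1 + mo) + (1 - bid_fraction) * o / (1 + o)

    lo, hi = 1e-12, 1e12
    if marginal(hi) < hi_fraction:
        raise ConfigurationError(
            f"requested hi_fraction {hi_fraction} unattainable with odds "
            f"multiplier {odds_multiplier}"
        )
    return brentq(lambda o: marginal(o) - hi_fraction, lo, hi)


def simulate_label_table(
    n_genes: int,
    bid_fraction: float,
    hi_fraction: float,
    hi_bidirectional_odds: float,
    housekeeping_fraction: float,
    rng: np.random.Generator,
    gene_ids: Optional[Sequence[str]] = None,
    has_bidirectional: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Per-gene flag table with planted HI/bidirectional association.

    has_bidirectional may be supplied (from planted geometry) or is drawn
    Bernoulli(bid_fraction). Haploinsufficiency odds are multiplied by
    hi_bidirectional_odds for bidirectional carriers, with the baseline odds
    solved so the marginal HI fraction equals hi_fraction. Housekeeping flags
    are independent of everything else.
    """
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    if has_bidirectional is None:
        has_bid = rng.random(n_genes) < bid_fraction
    else:
        has_bid = np.asarray(has_bidirectional, dtype=bool)
    f_b = float(has_bid.mean()) if n_genes else 0.0
    o = _solve_baseline_odds(f_b, hi_fraction, hi_bidirectional_odds)
    p0 = o / (1 + o)
    mo = hi_bidirectional_odds * o
    p1 = mo / (1 + mo)
    p = np.where(has_bid, p1, p0)
    hi = rng.random(n_genes) < p
    hk = rng.random(n_genes) < housekeeping_fraction
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "has_bidirectional": has_bid,
            "haploinsufficient": hi,
            "housekeeping": hk,
        }
    )


def simulate_gene_labels(
    truth: TruthLabels, config: SimulationConfig, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Flags for the coding genes of a simulated annotation.

    Uses the planted bidirectional partners as the has_bidirectional flag and
    writes the haploinsufficient/housekeeping draws back into truth.
    """
    rng = _streams(config.seed)["labels"]
    coding = [g.gene_id for g in annotation.genes_of_biotype("protein_coding")]
    bid_partners = {
        g
        for t, g in truth.lnc_partner.items()
        if g is not None and truth.lnc_class[t] == "bidirectional"
    }
    has_bid = [g in bid_partners for g in coding]
    table = simulate_label_table(
        len(coding),
        bid_fraction=float(np.mean(has_bid)) if coding else 0.0,
        hi_fraction=config.hi_fraction,
        hi_bidirectional_odds=config.hi_bidirectional_odds,
        housekeeping_fraction=config.housekeeping_fraction,
        rng=rng,
        gene_ids=coding,
        has_bidirectional=has_bid,
    )
    for _, row in table.iterrows():
        truth.haploinsufficient[row.gene_id] = bool(row.haploinsufficient)
        truth.housekeeping[row.gene_id] = bool(row.housekeeping)
    return table


def simulate_exon_truncation(
    reference: GenomeAnnotation,
    gene_fpkm: Mapping[str, float],
    a: float,
    b: float,
    rng: np.random.Generator,
) -> GenomeAnnotation:
    """Assembly emulation: drop terminal exons at a rate decaying with fpkm.

    Per gene the number of missing exons is Poisson with mean
    a * exp(-b * fpkm), truncated so at least one exon survives. Used to
    exercise the assembly-fidelity QC fit with known generating parameters.
    """
    genes = []
    for g in reference.genes.values():
        fpkm = float(gene_fpkm.get(g.gene_id, 0.0))
        lam = a * np.exp(-b * fpkm)
        new_ts = []
        for t in g.transcripts:
            drop = min(int(rng.poisson(lam)), t.exon_count - 1)
            exons = t.exons[: t.exon_count - drop] if drop else t.exons
            span = GenomicInterval(t.chrom, exons[0].start, exons[-1].end, t.strand)
            new_ts.append(
                TranscriptModel(
                    t.transcript_id, t.gene_id, t.biotype, span, exons
                )
            )
        genes.append(GeneModel(g.gene_id, g.biotype, tuple(new_ts)))
    return GenomeAnnotation(genes)
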