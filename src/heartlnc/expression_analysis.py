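"""Divergent-pair expression correlation, RNA localization ratio, and the
assembly-fidelity QC fit.

Pair correlations are Pearson r on log2(fpkm + pseudocount) across the heart
developmental stages (replicates averaged per stage first). The localization
ratio is log10((intact + pc) / (nuclear + pc)): positive means
cytoplasm-skewed, negative nucleus-skewed, near zero not clearly localized.
The QC fit regresses the per-gene |assembled - reference| exon-number
difference on expression with a decaying exponential a*exp(-b*fpkm) — the
difference shrinks as coverage rises — and reports the fpkm at which the
expected difference drops below 0.5 exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .candidate_filter import ExpressionMatrix
from .genome_model import GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCorrelation:
    lnc_id: str
    partner_gene_id: str
    r: float  # NaN when undefined
    n_points: int
    defined: bool


def _gene_stage_series(
    gene_id: str,
    annotation: GenomeAnnotation,
    matrix: ExpressionMatrix,
    tissue: str,
) -> pd.Series:
    """Gene-level per-stage fpkm: max over isoforms of stage-mean fpkm."""
    gene = annotation.genes[gene_id]
    series = [
        matrix.stage_means(t.transcript_id, tissue) for t in gene.transcripts
    ]
    return pd.concat(series, axis=1).max(axis=1)


def pair_correlation(
    pairs: Sequence[tuple[str, str]],
    matrix: ExpressionMatrix,
    annotation: GenomeAnnotation,
    pseudocount: float = 1.0,
    tissue: str = "heart",
    bins: int = 20,
) -> tuple[list[PairCorrelation], dict]:
    """Pearson r per (lnc transcript, partner gene) across heart stages.

    Pairs with fewer than 3 stages or zero variance in either log-series are
    flagged undefined and excluded from the histogram summary.
    """
    results = []
    for lnc_id, gene_id in pairs:
        x = matrix.stage_means(lnc_id, tissue)
        y = _gene_stage_series(gene_id, annotation, matrix, tissue)
        stages = x.index.intersection(y.index)
        lx = np.log2(x.loc[stages].to_numpy() + pseudocount)
        ly = np.log2(y.loc[stages].to_numpy() + pseudocount)
        if len(stages) < 3 or np.std(lx) == 0 or np.std(ly) == 0:
            results.append(PairCorrelation(lnc_id, gene_id, float("nan"), len(stages), False))
            continue
        r = float(np.corrcoef(lx, ly)[0, 1])
        results.append(PairCorrelation(lnc_id, gene_id, r, len(stages), True))
    defined = [p.r for p in results if p.defined]
    counts, edges = np.histogram(defined, bins=bins, range=(-1.0, 1.0))
    histogram = {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "n_defined": len(defined),
        "n_undefined": len(results) - len(defined),
    }
    return results, histogram


def localization_ratio(
    intact: Union[pd.Series, Mapping[str, float]],
    nuclear: Union[pd.Series, Mapping[str, float]],
    pseudocount: float = 1.0,
) -> pd.Series:
    """log10((intact + pc)/(nuclear + pc)) per transcript."""
    intact = pd.Series(intact, dtype=float)
    nuclear = pd.Series(nuclear, dtype=float)
    if (intact < 0).any() or (nuclear < 0).any():
        raise ValueError("abundances must be non-negative")
    ids = intact.index.intersection(nuclear.index)
    return np.log10((intact.loc[ids] + pseudocount) / (nuclear.loc[ids] + pseudocount))


@dataclass
class QcFitResult:
    table: pd.DataFrame  # gene_id, ref_exons, assembled_exons, difference, fpkm
    a: Optional[float]
    b: Optional[float]
    fpkm_at_half_exon: Optional[float]
    fit_failed: bool


def _gene_exon_numbers(annotation: GenomeAnnotation) -> dict[str, int]:
    """Exon number per gene: maximum over alternative transcripts."""
    return {
        gid: max(t.exon_count for t in g.transcripts)
        for gid, g in annotation.genes.items()
    }


def _gene_max_fpkm(
    gene_id: str,
    annotation: GenomeAnnotation,
    expression: Union[ExpressionMatrix, Mapping[str, float]],
    tissue: str,
) -> float:
    if isinstance(expression, ExpressionMatrix):
        cols = expression.tissue_samples(tissue)
        gene = annotation.genes[gene_id]
        return float(
            max(np.max(expression.get(t.transcript_id, cols)) for t in gene.transcripts)
        )
    return float(expression.get(gene_id, 0.0))


def exon_fidelity_qc(
    assembled: GenomeAnnotation,
    reference: GenomeAnnotation,
    expression: Union[ExpressionMatrix, Mapping[str, float]],
    max_ref_exons: int = 12,
    tissue: str = "heart",
) -> QcFitResult:
    """Assembly fidelity: exon-number difference vs expression, with fit.

    Genes are matched by shared gene_id; only genes whose reference exon
    number is max_ref_exons or fewer enter the comparison. The difference
    |assembled - reference| is fit with a*exp(-b*fpkm) by least squares on
    the gene-level stage-max fpkm. Degenerate data (constant differences or
    optimizer failure) is flagged with the raw table still returned.
    """
    ref_exons = _gene_exon_numbers(reference)
    asm_exons = _gene_exon_numbers(assembled)
    shared = sorted(set(ref_exons) & set(asm_exons))
    if not shared:
        raise ValueError("assembled and reference annotations share no gene ids")
    rows = []
    for gid in shared:
        if ref_exons[gid] > max_ref_exons:
            continue
        fpkm = _gene_max_fpkm(gid, reference, expression, tissue)
        rows.append(
            {
                "gene_id": gid,
                "ref_exons": ref_exons[gid],
                "assembled_exons": asm_exons[gid],
                "difference": abs(asm_exons[gid] - ref_exons[gid]),
                "fpkm": fpkm,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no genes with reference exon number within the cutoff")
    x = table["fpkm"].to_numpy(float)
    y = table["difference"].to_numpy(float)
    a = b = fpkm_half = None
    fit_failed = False
    if np.all(y == y[0]):
        fit_failed = True  # constant difference: exponential decay unidentifiable
    else:
        try:
            (a, b), _ = curve_fit(
                lambda t, a_, b_: a_ * np.exp(-b_ * t),
                x,
                y,
                p0=(max(y.max(), 0.5), 0.1),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10_000,
            )
            a, b = float(a), float(b)
            if a > 0.5 and b > 0:
                fpkm_half = float(np.log(a / 0.5) / b)
            else:
                fpkm_half = 0.0
        except (RuntimeError, ValueError) as exc:
            logger.warning("exponential QC fit failed: %s", exc)
            fit_failed = True
    return QcFitResult(table=table, a=a, b=b, fpkm_at_half_exon=fpkm_half, fit_failed=fit_failed)
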