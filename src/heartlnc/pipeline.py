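"""End-to-end orchestration: filter -> selectivity -> context -> distances ->
correlations -> enrichments, with TSV/JSON report outputs and a manifest.

Every run is deterministic given its configuration; the manifest records the
package version, dependency versions, the config hash and the seed, so two
runs with the same config produce byte-identical payloads.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidate_filter import (
    ExpressionMatrix,
    FilterConfig,
    LncCandidate,
    census_categories,
    identify_candidates,
)
from .enrichment_stats import (
    bidirectional_hi_enrichment,
    gene_set_enrichment,
    mann_whitney,
    proportion_control,
)
from .expression_analysis import exon_fidelity_qc, pair_correlation
from .genome_model import GenomeAnnotation, read_gtf, write_gtf
from .genomic_context import (
    ContextConfig,
    classify_genomic_context,
    compute_nearest_distances,
    expressed_coding_genes,
    orientation_census,
)
from .synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_gene_labels,
)
from .genome_model import SpanIndex

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Inputs are structurally valid but a stage cannot proceed (exit 3)."""


@dataclass
class RunConfig:
    annotation_gtf: str
    expression_tsv: str
    gene_labels_tsv: Optional[str] = None
    gene_sets_tsv: Optional[str] = None
    reference_gtf: Optional[str] = None
    output_dir: str = "heartlnc_out"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    context: ContextConfig = field(default_factory=ContextConfig)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            filt = FilterConfig(**{
                **d.get("filter", {}),
                "extra_tissues": tuple(d.get("filter", {}).get("extra_tissues", ("kidney", "liver"))),
            })
            ctx = ContextConfig(**d.get("context", {}))
            return cls(
                annotation_gtf=d["annotation_gtf"],
                expression_tsv=d["expression_tsv"],
                gene_labels_tsv=d.get("gene_labels_tsv"),
                gene_sets_tsv=d.get("gene_sets_tsv"),
                reference_gtf=d.get("reference_gtf"),
                output_dir=d.get("output_dir", "heartlnc_out"),
                seed=int(d.get("seed", 0)),
                filter=filt,
                context=ctx,
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid run config: {exc}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        required = {"annotation_gtf": self.annotation_gtf, "expression_tsv": self.expression_tsv}
        optional = {
            "gene_labels_tsv": self.gene_labels_tsv,
            "gene_sets_tsv": self.gene_sets_tsv,
            "reference_gtf": self.reference_gtf,
        }
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise ConfigError(f"missing required input {name}: {path}")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise ConfigError(f"configured input {name} does not exist: {path}")


def _write_tsv(df: pd.DataFrame, path: Path, schema_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {schema_note}\n")
        df.to_csv(fh, sep="\t", index=False)


def candidates_frame(candidates: Sequence[LncCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        t = c.transcript
        row = {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "start": t.span.start,
            "end": t.span.end,
            "strand": t.strand,
            "exon_count": t.exon_count,
            "length": t.transcript_length,
            "max_heart_fpkm": c.max_heart_fpkm,
            "selective": c.selective,
            "context": c.context,
            "bidirectional_partners": ",".join(c.bidirectional_partners),
            "antisense_partners": ",".join(c.antisense_partners),
            "same_strand_proximal": c.same_strand_proximal,
            "nearest_gene": c.nearest_gene if c.nearest_gene else "",
            "nearest_distance": c.nearest_distance if c.nearest_distance is not None else "",
        }
        for tissue, flag in sorted(c.tissue_census.items()):
            row[f"expressed_{tissue}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def _mrna_distances(
    annotation: GenomeAnnotation,
    matrix: ExpressionMatrix,
    filter_config: FilterConfig,
    context_config: ContextConfig,
) -> list[int]:
    """Per expressed coding gene: min TSS distance to the nearest other gene
    in the same expressed pool (the mRNA arm of the distance comparison)."""
    pool = (
        expressed_coding_genes(annotation, matrix, filter_config)
        if context_config.expressed_neighbors_only
        else annotation.genes_of_biotype("protein_coding")
    )
    index = SpanIndex(pool)
    out = []
    for g in pool:
        best = None
        for chrom, pos, _ in g.tss_set:
            hit = index.nearest(chrom, pos, exclude=g.gene_id)
            if hit is not None and (best is None or hit.distance < best):
                best = hit.distance
        if best is not None:
            out.append(best)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict and writes files."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        annotation = read_gtf(config.annotation_gtf)
        matrix = ExpressionMatrix.from_tsv(config.expression_tsv)
    except (OSError, ValueError) as exc:
        raise DataError(f"stage=load: {exc}")

    logger.info("loaded %d genes, %d expression rows", len(annotation), len(matrix.values))
    candidates = identify_candidates(annotation.transcripts(), matrix, config.filter)
    compute_nearest_distances(candidates, annotation, matrix, config.context, config.filter)
    classify_genomic_context(candidates, annotation, config.context)
    opposite, same = orientation_census(candidates, annotation, config.context)

    # distance-distribution comparison (mRNA vs all lnc vs heart-selective lnc)
    mrna_d = _mrna_distances(annotation, matrix, config.filter, config.context)
    all_d = [c.nearest_distance for c in candidates if c.nearest_distance is not None]
    sel_d = [
        c.nearest_distance
        for c in candidates
        if c.selective and c.nearest_distance is not None
    ]
    distance_summary = {
        "median_mrna": float(np.median(mrna_d)) if mrna_d else None,
        "median_all_lnc": float(np.median(all_d)) if all_d else None,
        "median_selective_lnc": float(np.median(sel_d)) if sel_d else None,
        "n_mrna": len(mrna_d),
        "n_all_lnc": len(all_d),
        "n_selective_lnc": len(sel_d),
    }
    if mrna_d and all_d:
        distance_summary["p_all_vs_mrna"] = mann_whitney(all_d, mrna_d).two_sided_p
    if mrna_d and sel_d:
        distance_summary["p_selective_vs_mrna"] = mann_whitney(sel_d, mrna_d).two_sided_p

    # divergent-pair correlation across heart development
    pairs = sorted(
        {
            (c.transcript_id, gid)
            for c in candidates
            if c.context in ("bidirectional", "both")
            for gid in c.bidirectional_partners
        }
    )
    pair_results, histogram = pair_correlation(pairs, matrix, annotation)
    corr_df = pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "partner_gene_id": p.partner_gene_id,
                "r": p.r,
                "n_points": p.n_points,
                "defined": p.defined,
            }
            for p in pair_results
        ]
    )

    # class counts and tissue census
    class_counts: dict[str, int] = {}
    for c in candidates:
        class_counts[c.context] = class_counts.get(c.context, 0) + 1
    census = census_categories(candidates)

    # enrichment among haploinsufficient genes (+ housekeeping control)
    enrichment = {}
    if config.gene_labels_tsv:
        labels = pd.read_csv(config.gene_labels_tsv, sep="\t", comment="#")
        bid_genes = {
            gid for c in candidates for gid in c.bidirectional_partners
        }
        labels["has_bidirectional"] = labels["gene_id"].isin(bid_genes)
        hi_res = bidirectional_hi_enrichment(labels)
        enrichment["hi_enrichment"] = hi_res.as_dict()
        if "housekeeping" in labels.columns:
            enrichment["housekeeping_control_p"] = proportion_control(labels)

    # gene-set over-representation of nearest genes (Tables 1-2 shape)
    gs_df = None
    if config.gene_sets_tsv:
        sets_df = pd.read_csv(config.gene_sets_tsv, sep="\t", comment="#")
        gene_sets = {
            term: set(sub["gene_id"]) for term, sub in sets_df.groupby("term")
        }
        universe = {g.gene_id for g in annotation.genes_of_biotype("protein_coding")}
        query = {c.nearest_gene for c in candidates if c.nearest_gene} & universe
        gs_df = gene_set_enrichment(query, gene_sets, universe)

    # optional assembly-fidelity QC against a reference annotation
    qc_summary = None
    if config.reference_gtf:
        reference = read_gtf(config.reference_gtf)
        qc = exon_fidelity_qc(annotation, reference, matrix)
        qc_summary = {
            "a": qc.a,
            "b": qc.b,
            "fpkm_at_half_exon": qc.fpkm_at_half_exon,
            "fit_failed": qc.fit_failed,
            "n_genes": len(qc.table),
        }
        _write_tsv(
            qc.table,
            outdir / "qc_exon_fidelity.tsv",
            "gene_id ref_exons assembled_exons difference fpkm",
        )

    cand_df = candidates_frame(candidates)
    _write_tsv(
        cand_df,
        outdir / "candidates.tsv",
        "one row per spliced lncRNA candidate; coordinates 0-based half-open",
    )
    if not corr_df.empty:
        _write_tsv(
            corr_df,
            outdir / "pair_correlations.tsv",
            "Pearson r of log2(fpkm+1) across heart stages per divergent pair",
        )
    if gs_df is not None:
        _write_tsv(
            gs_df,
            outdir / "gene_set_enrichment.tsv",
            "term count pct p q odds_ratio (BH across terms)",
        )

    report = {
        "n_input_transcripts": sum(1 for _ in annotation.transcripts()),
        "n_candidates": len(candidates),
        "n_heart_selective": int(sum(c.selective for c in candidates)),
        "class_counts": class_counts,
        "tissue_census": census,
        "orientation_census": {"opposite": opposite, "same": same},
        "distance_summary": distance_summary,
        "correlation_histogram": histogram,
        "enrichment": enrichment,
        "qc": qc_summary,
    }
    manifest = {
        "tool": "heartlnc",
        "version": __version__,
        "dependency_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "report": report,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def simulate_bundle(config: SimulationConfig, outdir) -> RunConfig:
    """Write a synthetic input bundle and a ready-to-run RunConfig YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = simulate_annotation(config)
    matrix = simulate_expression(annotation, truth, config)
    labels = simulate_gene_labels(truth, config, annotation)
    write_gtf(annotation, outdir / "annotation.gtf")
    matrix.to_tsv(outdir / "expression.tsv")
    _write_tsv(
        labels,
        outdir / "gene_labels.tsv",
        "gene_id has_bidirectional haploinsufficient housekeeping",
    )
    truth.to_json(outdir / "truth.json")
    # small planted gene-set file: one term per block of coding genes plus a
    # term concentrated on bidirectional partner genes
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    coding = sorted(g.gene_id for g in annotation.genes_of_biotype("protein_coding"))
    records = []
    bid_partners = sorted(
        {g for g in truth.lnc_partner.values() if g is not None}
    )
    for gid in bid_partners:
        records.append({"term": "planted_partner_set", "gene_id": gid})
    for term_i in range(3):
        size = min(40, len(coding))
        for gid in rng.choice(coding, size=size, replace=False):
            records.append({"term": f"random_set_{term_i}", "gene_id": gid})
    _write_tsv(
        pd.DataFrame(records), outdir / "gene_sets.tsv", "term gene_id"
    )
    run_config = RunConfig(
        annotation_gtf=str(outdir / "annotation.gtf"),
        expression_tsv=str(outdir / "expression.tsv"),
        gene_labels_tsv=str(outdir / "gene_labels.tsv"),
        gene_sets_tsv=str(outdir / "gene_sets.tsv"),
        output_dir=str(outdir / "results"),
        seed=config.seed,
    )
    run_config.to_yaml(outdir / "run_config.yaml")
    return run_config
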