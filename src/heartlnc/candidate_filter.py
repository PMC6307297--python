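"""Filtering cascade: assembled transcripts -> spliced lncRNA candidates.

The cascade keeps spliced transcripts (>= 2 exons), drops annotated mRNAs and
small functional RNAs plus anything whose CDS covers more than a third of the
transcript, requires fpkm >= 1 in at least one heart stage, and finally calls
heart selectivity against a reference tissue (brain): selective transcripts
are expressed in the heart yet stay below threshold in every brain sample.
All filters are pure set intersections, so application order is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import TranscriptModel

logger = logging.getLogger(__name__)

#: biotypes excluded from lncRNA candidacy (known mRNAs / small RNAs)
EXCLUDED_BIOTYPES = frozenset({"protein_coding", "snoRNA", "tRNA", "other_nc"})


class ConfigError(ValueError):
    """Filter configuration inconsistent with the supplied matrix."""


@dataclass(frozen=True)
class FilterConfig:
    min_fpkm: float = 1.0
    cds_fraction_max: float = 1.0 / 3.0
    min_exons: int = 2
    heart_tissue: str = "heart"
    reference_tissue: str = "brain"
    extra_tissues: tuple[str, ...] = ("kidney", "liver")

    def __post_init__(self) -> None:
        if self.min_fpkm <= 0:
            raise ConfigError("min_fpkm must be positive")
        if not (0 < self.cds_fraction_max <= 1):
            raise ConfigError("cds_fraction_max must lie in (0, 1]")


class ExpressionMatrix:
    """Transcript x sample fpkm table with tissue/stage sample metadata.

    Sample names follow the ``tissue_stage`` convention (``heart_E10.5``);
    metadata is parsed from the name on load.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if (values.values < 0).any():
            raise ValueError("fpkm values must be non-negative")
        self.values = values
        self.samples = samples
        self._warned_missing: set[str] = set()

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame) -> "ExpressionMatrix":
        meta = []
        for name in values.columns:
            tissue, _, stage = name.partition("_")
            meta.append({"sample": name, "tissue": tissue, "stage": stage or "NA"})
        samples = pd.DataFrame(meta).set_index("sample")
        return cls(values.astype(float), samples)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls.from_dataframe(df)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# transcript_id followed by fpkm per tissue_stage sample\n")
            self.values.to_csv(fh, sep="\t", index_label="transcript_id")

    def tissue_samples(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    def get(self, transcript_id: str, sample_names: Sequence[str]) -> np.ndarray:
        """fpkm vector; transcripts absent from the matrix count as 0 fpkm."""
        if transcript_id not in self.values.index:
            if transcript_id not in self._warned_missing:
                logger.warning(
                    "transcript %s absent from expression matrix; treating as 0 fpkm",
                    transcript_id,
                )
                self._warned_missing.add(transcript_id)
            return np.zeros(len(sample_names))
        return self.values.loc[transcript_id, list(sample_names)].to_numpy(float)

    def stage_means(self, transcript_id: str, tissue: str) -> pd.Series:
        """Per-stage mean fpkm within one tissue (replicates averaged)."""
        cols = self.tissue_samples(tissue)
        vals = self.get(transcript_id, cols)
        stages = self.samples.loc[cols, "stage"]
        return pd.Series(vals, index=stages).groupby(level=0).mean()


@dataclass
class LncCandidate:
    """A transcript surviving the cascade, with selectivity and context."""

    transcript: TranscriptModel
    max_heart_fpkm: float = 0.0
    selective: bool = False
    tissue_census: dict[str, bool] = field(default_factory=dict)
    context: Optional[str] = None
    bidirectional_partners: tuple[str, ...] = ()
    antisense_partners: tuple[str, ...] = ()
    same_strand_proximal: bool = False
    nearest_gene: Optional[str] = None
    nearest_distance: Optional[int] = None

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def filter_spliced(
    transcripts: Iterable[TranscriptModel], config: FilterConfig = FilterConfig()
) -> list[TranscriptModel]:
    """Keep spliced transcripts (exon_count >= min_exons)."""
    return [t for t in transcripts if t.exon_count >= config.min_exons]


def filter_coding_potential(
    transcripts: Iterable[TranscriptModel], config: FilterConfig = FilterConfig()
) -> list[TranscriptModel]:
    """Drop known mRNA/small-RNA biotypes and transcripts whose CDS exceeds
    cds_fraction_max of the transcript length (strictly greater removes)."""
    out = []
    for t in transcripts:
        if t.biotype in EXCLUDED_BIOTYPES:
            continue
        if t.cds_length > config.cds_fraction_max * t.transcript_length:
            continue
        out.append(t)
    return out


def filter_expression(
    transcripts: Iterable[TranscriptModel],
    matrix: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
) -> list[TranscriptModel]:
    """Keep transcripts with fpkm >= min_fpkm in at least one heart sample."""
    heart = matrix.tissue_samples(config.heart_tissue)
    if not heart:
        raise ConfigError(
            f"matrix has no samples for tissue {config.heart_tissue!r}"
        )
    out = []
    for t in transcripts:
        if np.max(matrix.get(t.transcript_id, heart)) >= config.min_fpkm:
            out.append(t)
    return out


def classify_tissue_selectivity(
    transcripts: Iterable[TranscriptModel],
    matrix: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
) -> list[LncCandidate]:
    """Attach max heart fpkm, the selective flag and the per-tissue census.

    selective <=> expressed (>= min_fpkm) in >= 1 heart sample AND below
    min_fpkm in every reference-tissue sample.
    """
    heart = matrix.tissue_samples(config.heart_tissue)
    ref = matrix.tissue_samples(config.reference_tissue)
    if not ref:
        raise ConfigError(
            f"matrix has no samples for reference tissue {config.reference_tissue!r}"
        )
    out = []
    for t in transcripts:
        heart_vals = matrix.get(t.transcript_id, heart)
        ref_vals = matrix.get(t.transcript_id, ref)
        census = {}
        for tissue in config.extra_tissues:
            cols = matrix.tissue_samples(tissue)
            census[tissue] = bool(
                cols and np.max(matrix.get(t.transcript_id, cols)) >= config.min_fpkm
            )
        expressed_heart = bool(np.max(heart_vals) >= config.min_fpkm)
        out.append(
            LncCandidate(
                transcript=t,
                max_heart_fpkm=float(np.max(heart_vals)),
                selective=expressed_heart and bool(np.max(ref_vals) < config.min_fpkm),
                tissue_census=census,
            )
        )
    return out


def census_categories(candidates: Sequence[LncCandidate]) -> dict[str, int]:
    """Counts of heart-selective candidates by extra-tissue expression.

    heart_only: expressed in no extra tissue; both_extra: expressed in every
    extra tissue; some_extra: the remainder.
    """
    sel = [c for c in candidates if c.selective]
    heart_only = sum(1 for c in sel if not any(c.tissue_census.values()))
    both = sum(
        1 for c in sel if c.tissue_census and all(c.tissue_census.values())
    )
    return {
        "selective": len(sel),
        "heart_only": heart_only,
        "both_extra": both,
        "some_extra": len(sel) - heart_only - both,
    }


def identify_candidates(
    transcripts: Iterable[TranscriptModel],
    matrix: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
) -> list[LncCandidate]:
    """Full cascade: spliced -> non-coding -> expressed -> selectivity."""
    ts = list(transcripts)
    n0 = len(ts)
    ts = filter_spliced(ts, config)
    logger.info("spliced filter: %d -> %d", n0, len(ts))
    n1 = len(ts)
    ts = filter_coding_potential(ts, config)
    logger.info("coding-potential filter: %d -> %d", n1, len(ts))
    n2 = len(ts)
    ts = filter_expression(ts, matrix, config)
    logger.info("expression filter (fpkm >= %g): %d -> %d", config.min_fpkm, n2, len(ts))
    cands = classify_tissue_selectivity(ts, matrix, config)
    logger.info(
        "selectivity: %d candidates, %d heart-selective",
        len(cands),
        sum(c.selective for c in cands),
    )
    return cands
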