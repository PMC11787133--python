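"""Molecular subtyping of endometrial cancer: the four-rule cascade.

Subtypes are assigned deterministically, first rule wins:

1. **POLE** — any POLE missense mutation in the exonuclease domain
   (residues 268–471, both ends included);
2. **MSI-H** — at least two frameshift indels located in repetitive
   sequence context (a tandem repeat of ≥4 consecutive copies, unit length
   1–6, overlapping the variant position);
3. **CNV-H** — copy-number alterations affecting strictly more than 20% of
   the assayed genome territory;
4. **CNV-L** — everything else (the default sink).

Inputs are simplified variant tables (gene, protein_position, consequence,
ref_context, context_offset) and CNV segment tables (chrom, start, end,
altered_flag; 1-based inclusive coordinates).  The denominator for the CNA
fraction is the explicit ``genome_length`` in the configuration (panel
territory), never an implied whole genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import FormatError, TlsQuantError

log = logging.getLogger("tlsquant")

SUBTYPES = ("POLE", "MSI-H", "CNV-H", "CNV-L")


@dataclass
class VariantRecord:
    gene: str
    consequence: str  # missense | frameshift_indel | other
    protein_position: Optional[int] = None
    variant_class: str = ""
    ref_context: Optional[str] = None
    context_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_context is not None and self.context_offset is not None:
            if not 0 <= self.context_offset < len(self.ref_context):
                raise FormatError(
                    f"context_offset {self.context_offset} outside ref_context "
                    f"of length {len(self.ref_context)}"
                )


@dataclass
class CNVSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    altered_flag: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SubtypeCall:
    subtype: str
    rule: str  # which rule fired
    pole_variant: Optional[VariantRecord] = None
    msi_indel_count: int = 0
    cna_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "rule": self.rule,
            "pole_position": self.pole_variant.protein_position if self.pole_variant else None,
            "msi_indel_count": self.msi_indel_count,
            "cna_fraction": self.cna_fraction,
        }


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    recs = []
    for row in df.itertuples(index=False):
        pos = getattr(row, "protein_position", None)
        pos = None if pos is None or (isinstance(pos, float) and np.isnan(pos)) else int(pos)
        ctx = getattr(row, "ref_context", None)
        ctx = None if ctx is None or (isinstance(ctx, float) and np.isnan(ctx)) else str(ctx)
        off = getattr(row, "context_offset", None)
        off = None if off is None or (isinstance(off, float) and np.isnan(off)) else int(off)
        recs.append(
            VariantRecord(
                gene=str(row.gene),
                consequence=str(row.consequence),
                protein_position=pos,
                variant_class=str(getattr(row, "variant_class", "")),
                ref_context=ctx,
                context_offset=off,
            )
        )
    return recs


def segments_from_frame(df: pd.DataFrame) -> list[CNVSegment]:
    return [
        CNVSegment(str(r.chrom), int(r.start), int(r.end), bool(r.altered_flag))
        for r in df.itertuples(index=False)
    ]


def is_pole_exo_missense(
    v: VariantRecord, config: PipelineConfig = DEFAULT_CONFIG
) -> bool:
    """True iff a POLE missense falls within the exonuclease domain (268–471 inclusive)."""
    if v.gene != "POLE" or v.consequence != "missense":
        return False
    if v.protein_position is None:
        log.warning("POLE missense without protein_position treated as non-domain")
        return False
    return config.pole_domain_start <= v.protein_position <= config.pole_domain_end


def in_repeat_context(
    v: VariantRecord,
    min_copies: Optional[int] = None,
    max_unit: Optional[int] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> bool:
    """True iff a tandem repeat (unit 1..max_unit, ≥min_copies consecutive copies)
    overlaps the variant position within its reference context."""
    min_copies = config.repeat_min_copies if min_copies is None else min_copies
    max_unit = config.repeat_max_unit if max_unit is None else max_unit
    if v.ref_context is None or v.context_offset is None:
        log.warning("variant in %s lacks ref_context; repeat check false", v.gene)
        return False
    s = v.ref_context
    off = v.context_offset
    n = len(s)
    for unit in range(1, max_unit + 1):
        start = 0
        while start + unit <= n:
            # count consecutive copies of s[start:start+unit]
            copies = 1
            while (
                start + (copies + 1) * unit <= n
                and s[start + copies * unit : start + (copies + 1) * unit]
                == s[start : start + unit]
            ):
                copies += 1
            if copies >= min_copies and start <= off < start + copies * unit:
                return True
            start += 1
    return False


def cna_fraction(
    segments: list[CNVSegment],
    genome_length: Optional[int] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of the assayed territory covered by altered segments."""
    genome_length = config.genome_length if genome_length is None else genome_length
    if genome_length <= 0:
        raise TlsQuantError("genome_length must be > 0")
    altered = sum(seg.length for seg in segments if seg.altered_flag)
    if altered > genome_length:
        raise TlsQuantError(
            f"altered length {altered} exceeds genome length {genome_length}"
        )
    return altered / genome_length


def classify_subtype(
    variants: list[VariantRecord] | pd.DataFrame,
    segments: list[CNVSegment] | pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SubtypeCall:
    """Apply the cascade in order; the first rule that fires determines the subtype."""
    if isinstance(variants, pd.DataFrame):
        variants = variants_from_frame(variants)
    if isinstance(segments, pd.DataFrame):
        segments = segments_from_frame(segments)

    pole_hits = [v for v in variants if is_pole_exo_missense(v, config)]
    msi_count = sum(
        1
        for v in variants
        if v.consequence == "frameshift_indel" and in_repeat_context(v, config=config)
    )
    frac = cna_fraction(segments, config=config)

    if pole_hits:
        return SubtypeCall("POLE", rule="pole_exonuclease_missense",
                           pole_variant=pole_hits[0], msi_indel_count=msi_count,
                           cna_fraction=frac)
    if msi_count >= config.msi_min_frameshift_indels:
        return SubtypeCall("MSI-H", rule="frameshift_indels_in_repeats",
                           msi_indel_count=msi_count, cna_fraction=frac)
    if frac > config.cnv_high_fraction:  # strict: "more than 20%"
        return SubtypeCall("CNV-H", rule="cna_fraction_gt_threshold",
                           msi_indel_count=msi_count, cna_fraction=frac)
    return SubtypeCall("CNV-L", rule="default_sink",
                       msi_indel_count=msi_count, cna_fraction=frac)
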