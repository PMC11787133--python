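"""BCR clone-overlap statistics between microdissected TLS and TIL samples.

For each TLS sample, the top-N clones by read count (default N = 30) are
intersected with the paired intratumoral TIL sample's top-N clones.  Clone
identity defaults to the CDR3 amino-acid sequence alone; a stricter
CDR3+V+J key is available.  Reported statistics per TLS sample:

* ``common_clone_reads`` — TLS-side reads of the shared clones,
* ``common_clone_percent`` — 100 × common reads / total in-frame reads of
  the TLS sample, reported to one decimal,
* ``unique_common_clones`` — number of distinct shared clone keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AnalysisError, FormatError

log = logging.getLogger("tlsquant")

Clone = tuple  # (cdr3_aa, v_call, j_call, read_count)


@dataclass
class RepertoireSample:
    """A clonotype table for one microdissected sample."""

    sample_id: str
    role: str  # "TLS" | "TIL"
    clones: list[Clone] = field(default_factory=list)
    total_inframe_reads: Optional[int] = None

    def __post_init__(self) -> None:
        for cdr3, _v, _j, reads in self.clones:
            if not cdr3:
                raise FormatError(f"{self.sample_id}: empty CDR3 sequence")
            if reads < 1:
                raise FormatError(f"{self.sample_id}: read_count {reads} < 1")
        listed = sum(c[3] for c in self.clones)
        if self.total_inframe_reads is None:
            self.total_inframe_reads = listed
        elif self.total_inframe_reads < listed:
            raise FormatError(
                f"{self.sample_id}: total_inframe_reads {self.total_inframe_reads} "
                f"< sum of listed reads {listed}"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str, role: str = "TLS",
                   total_inframe_reads: Optional[int] = None) -> "RepertoireSample":
        """Build from an AIRR-like table (sample_id, cdr3_aa, v_call, j_call,
        duplicate_count, productive); unproductive rows are dropped."""
        sub = df[df["sample_id"] == sample_id]
        if "productive" in sub.columns:
            sub = sub[sub["productive"].astype(bool)]
        clones = [
            (str(r.cdr3_aa), str(getattr(r, "v_call", "")), str(getattr(r, "j_call", "")),
             int(r.duplicate_count))
            for r in sub.itertuples(index=False)
        ]
        return cls(sample_id=sample_id, role=role, clones=clones,
                   total_inframe_reads=total_inframe_reads)


@dataclass
class OverlapStats:
    common_clone_reads: int
    common_clone_percent: float  # 1-decimal reporting convention
    unique_common_clones: int

    def as_dict(self) -> dict:
        return {
            "common_clone_reads": self.common_clone_reads,
            "common_clone_percent": self.common_clone_percent,
            "unique_common_clones": self.unique_common_clones,
        }


def clone_key(clone: Clone, key_mode: str) -> tuple:
    if key_mode == "cdr3_aa":
        return (clone[0],)
    if key_mode == "cdr3_vj":
        return (clone[0], clone[1], clone[2])
    raise FormatError(f"unknown clone key mode {key_mode!r}")


def top_clones(sample: RepertoireSample, n: Optional[int] = None,
               config: PipelineConfig = DEFAULT_CONFIG) -> list[Clone]:
    """Top-n clones by read count; ties broken by CDR3 lexicographic order."""
    n = config.top_n_clones if n is None else n
    if n < 1:
        raise AnalysisError("top_clones requires n >= 1")
    if not sample.clones:
        log.warning("sample %s has no clones", sample.sample_id)
        return []
    ordered = sorted(sample.clones, key=lambda c: (-c[3], c[0]))
    return ordered[:n]


def shared_clone_keys(tls_top: list[Clone], til_top: list[Clone],
                      key_mode: str = "cdr3_aa") -> set:
    """Intersection of clone keys between two top-N lists."""
    return {clone_key(c, key_mode) for c in tls_top} & {
        clone_key(c, key_mode) for c in til_top
    }


def common_clone_percent(common_reads: int, total_inframe_reads: int) -> float:
    """Percentage of a TLS sample's in-frame reads in shared clones (1 decimal)."""
    if total_inframe_reads <= 0:
        raise AnalysisError("total_inframe_reads must be positive")
    return round(100.0 * common_reads / total_inframe_reads, 1)


def overlap_stats(tls_sample: RepertoireSample, til_sample: RepertoireSample,
                  config: PipelineConfig = DEFAULT_CONFIG) -> OverlapStats:
    """Clone-overlap statistics for one TLS/TIL pair.

    Shared keys are computed over the two top-N lists; reads are counted on
    the TLS side; the percentage denominator is the TLS sample's total
    in-frame reads (not the top-N subtotal).
    """
    if not tls_sample.total_inframe_reads:
        raise AnalysisError(f"{tls_sample.sample_id}: zero total in-frame reads")
    tls_top = top_clones(tls_sample, config=config)
    til_top = top_clones(til_sample, config=config)
    shared = shared_clone_keys(tls_top, til_top, config.clone_key)
    common_reads = sum(
        c[3] for c in tls_top if clone_key(c, config.clone_key) in shared
    )
    return OverlapStats(
        common_clone_reads=int(common_reads),
        common_clone_percent=common_clone_percent(
            common_reads, tls_sample.total_inframe_reads
        ),
        unique_common_clones=len(shared),
    )
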