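"""Expression scoring: single-sample gene-set enrichment, CYT, and GEP.

The ssGSEA statistic scores a gene set's coordinate up-regulation within a
single sample.  Genes are ranked by expression (highest expression → rank N,
ties by average rank); walking the ranked list from top to bottom, the score
is the running sum of the difference between the weighted in-set empirical
CDF (weights rank^α, α = 0.25 by default) and the uniform out-of-set CDF.
The CYT score is the geometric mean of GZMA and PRF1 expression (with a
small offset guarding zeros), and the GEP score is a user-weighted sum of
per-gene normalized (z-scored) expression — the 18-gene weights must be
supplied by the user and are never invented here.

Expression matrices are genes × samples DataFrames with unique gene rows.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AnalysisError, FormatError

log = logging.getLogger("tlsquant")


def _validate_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise FormatError("expression matrix has duplicate gene rows")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise FormatError("expression matrix contains non-finite values")


def _ranked_order(x: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Ranks (ties = average, highest expression = N) and a deterministic
    descending walk order (by expression, then gene identifier)."""
    ranks = x.rank(method="average").to_numpy()
    order = np.lexsort((x.index.to_numpy(), -x.to_numpy(dtype=float)))
    return ranks, order


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: Sequence[str],
    sample: str,
    exponent: Optional[float] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """Single-sample enrichment score of ``gene_set`` in ``sample``."""
    alpha = config.ssgsea_exponent if exponent is None else exponent
    _validate_matrix(expr)
    x = expr[sample].astype(float)
    in_set = expr.index.isin(set(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        missing = sorted(set(gene_set))
        raise AnalysisError(
            f"no overlap between gene set and matrix genes; set genes {missing[:10]}"
        )
    n_out = len(x) - n_in
    if n_out == 0:
        raise AnalysisError(
            "gene set covers every matrix gene; out-of-set CDF undefined"
        )
    ranks, order = _ranked_order(x)
    in_sorted = in_set[order]
    w = np.where(in_sorted, np.abs(ranks[order]) ** alpha, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(cdf_in - cdf_out))


def minmax_normalize(scores: pd.Series | np.ndarray) -> pd.Series:
    """Scale one score column over samples to [0, 1]; constant → all zeros."""
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if len(s) < 2:
        raise AnalysisError("min-max normalization needs >= 2 samples")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        log.warning("constant score column; min-max normalization returns zeros")
        return pd.Series(np.zeros(len(s)), index=s.index)
    return (s - lo) / (hi - lo)


def cyt_score(
    expr: pd.DataFrame,
    sample: str,
    offset: Optional[float] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 expression."""
    offset = config.cyt_offset if offset is None else offset
    for gene in ("GZMA", "PRF1"):
        if gene not in expr.index:
            raise AnalysisError(f"CYT score requires gene {gene}, absent from matrix")
    gzma = float(expr.at["GZMA", sample])
    prf1 = float(expr.at["PRF1", sample])
    return float(np.sqrt((gzma + offset) * (prf1 + offset)))


def gep_score(
    expr: pd.DataFrame,
    sample: str,
    weights: Mapping[str, float],
    missing_policy: str = "strict",
) -> float:
    """T cell-inflamed gene expression profile: weighted sum of z-scored genes.

    ``weights`` maps gene → weight (the published 18-gene table, supplied by
    the user).  Normalization is a per-gene z-score across the matrix's
    samples.  ``missing_policy``: "strict" errors on an absent gene; "skip"
    drops it with a warning.
    """
    total = 0.0
    for gene, w in weights.items():
        if gene not in expr.index:
            if missing_policy == "strict":
                raise AnalysisError(f"GEP gene {gene} absent from matrix")
            log.warning("GEP gene %s absent; skipped", gene)
            continue
        row = expr.loc[gene].astype(float)
        sd = float(row.std(ddof=0))
        z = 0.0 if sd == 0 else (float(row[sample]) - float(row.mean())) / sd
        total += w * z
    return float(total)


def score_cohort(
    expr: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    config: PipelineConfig = DEFAULT_CONFIG,
    gep_weights: Optional[Mapping[str, float]] = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Samples × signatures score table (one ssGSEA column per gene set,
    plus CYT, plus GEP when weights are supplied).

    With ``normalize=True`` every column is min-max scaled to [0, 1] across
    the cohort (per-signature, cohort-wide).
    """
    _validate_matrix(expr)
    samples = list(expr.columns)
    out = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for name, genes in gene_sets.items():
        out[name] = [
            ssgsea_score(expr, genes, s, config=config) for s in samples
        ]
    if "GZMA" in expr.index and "PRF1" in expr.index:
        out["CYT"] = [cyt_score(expr, s, config=config) for s in samples]
    if gep_weights:
        out["GEP"] = [gep_score(expr, s, gep_weights) for s in samples]
    if normalize:
        for col in out.columns:
            out[col] = minmax_normalize(out[col])
    out.attrs["normalization"] = "minmax" if normalize else "raw"
    return out
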