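"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here with a controlled
truth record, so each analysis stage can be validated end to end:

* label maps with a central tumor (disk or wavy blob), a stromal band, and
  TLS disks planted at requested margin distances and areas;
* per-tile TIL calls with a known intratumoral positivity rate;
* variant/CNV profiles constructed to classify to a requested molecular
  subtype under the rule cascade;
* expression matrices where signature genes are up-shifted (log scale) in
  dTLS-positive samples;
* paired TLS/TIL clonotype tables with a controlled number of shared CDR3
  clones and power-law (Zipf) read counts;
* survival cohorts with exponential event times whose true dTLS hazard
  ratio equals the Cox estimand, uniform censoring calibrated to a target
  fraction, and administrative censoring at the configured horizon.

All generators are deterministic given (seed, parameters), and each one
verifies its own truth against the corresponding analysis operation before
returning (self-consistency gate).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AnalysisError, GenerationError
from .labelmap import STROMA, TLS, TUMOR, LabelMap
from . import spatial, subtype as subtype_mod
from .repertoire import RepertoireSample, overlap_stats
from .spatial import build_tile_grid, classify_tls, summarize_case

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# label maps


@dataclass
class PlantedTLS:
    distance_um: float
    area_um2: float
    expected_category: str


@dataclass
class SpatialTruth:
    case_id: str
    planted: list[PlantedTLS]
    n_ptls: int
    n_dtls: int
    tls_positive: bool
    ptls_positive: bool
    dtls_positive: bool


def _disk_mask(shape: tuple[int, int], center_um: np.ndarray, radius_um: float,
               mpp: float) -> np.ndarray:
    """Pixels whose centers lie within radius_um of center_um (physical µm)."""
    nrows, ncols = shape
    r_px = radius_um / mpp
    cx, cy = center_um / mpp - 0.5  # pixel-index coordinates of the center
    r0 = max(0, int(math.floor(cy - r_px)))
    r1 = min(nrows, int(math.ceil(cy + r_px)) + 1)
    c0 = max(0, int(math.floor(cx - r_px)))
    c1 = min(ncols, int(math.ceil(cx + r_px)) + 1)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask[r0:r1, c0:c1] = (rr - cy) ** 2 + (cc - cx) ** 2 <= r_px**2
    return mask


def _blob_mask(shape, center_um, radius_um, mpp, rng, wobble=0.12, n_harmonics=4):
    """Tumor blob: disk with a smooth angular perturbation of the radius."""
    nrows, ncols = shape
    amps = rng.uniform(-wobble, wobble, n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    x = (cc + 0.5) * mpp - center_um[0]
    y = (rr + 0.5) * mpp - center_um[1]
    theta = np.arctan2(y, x)
    r_theta = radius_um * (
        1.0 + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return x**2 + y**2 <= r_theta**2


def gen_labelmap(
    tls_specs: Sequence[tuple[float, float]],
    tumor_shape: str = "disk",
    mpp: float = 4.0,
    seed: int = 0,
    tumor_radius_um: float = 400.0,
    canvas_um: Optional[float] = None,
    case_id: str = "sim",
    config: PipelineConfig = DEFAULT_CONFIG,
    verify: bool = True,
) -> tuple[LabelMap, SpatialTruth]:
    """Plant TLS disks at requested (distance µm, area µm²) around a tumor.

    Each TLS is an approximately circular component whose centroid's true
    nearest-tumor-pixel distance is within one pixel diagonal of the
    request and whose pixel area is within 5% of the request.  Stroma fills
    a band around the tumor out to the farthest planted TLS.  Raises
    :class:`GenerationError` when the canvas cannot hold the requested
    geometry or the disks cannot be placed without touching.
    """
    rng = np.random.default_rng(seed)
    specs = [(float(d), float(a)) for d, a in tls_specs]
    for d, a in specs:
        if d < 0 or a <= 0:
            raise GenerationError(f"invalid TLS spec (distance {d}, area {a})")
    radii = [math.sqrt(a / math.pi) for _, a in specs]
    reach = max((d + 2 * r for (d, _), r in zip(specs, radii)), default=0.0)
    pad = 20 * mpp
    needed = 2 * (tumor_radius_um * 1.2 + reach + pad)
    if canvas_um is None:
        canvas_um = needed
    elif canvas_um < needed:
        raise GenerationError(
            f"canvas {canvas_um} µm too small; need >= {needed:.0f} µm"
        )
    n = int(round(canvas_um / mpp))
    shape = (n, n)
    center = np.array([canvas_um / 2, canvas_um / 2])

    pixels = np.zeros(shape, dtype=np.uint8)
    if tumor_shape == "disk":
        tumor = _disk_mask(shape, center, tumor_radius_um, mpp)
    elif tumor_shape == "blob":
        tumor = _blob_mask(shape, center, tumor_radius_um, mpp, rng)
    else:
        raise GenerationError(f"unknown tumor_shape {tumor_shape!r}")
    if not tumor.any():
        raise GenerationError("tumor mask empty; enlarge tumor_radius_um or shrink mpp")

    # stromal band: everything within (max distance + 2 max radius + pad) of the tumor
    from scipy import ndimage

    rows, cols = np.nonzero(tumor)
    tumor_centers = np.column_stack([(cols + 0.5) * mpp, (rows + 0.5) * mpp])
    tree = cKDTree(tumor_centers)
    dist_field = ndimage.distance_transform_edt(~tumor, sampling=mpp)
    band_um = reach + pad
    pixels[(dist_field <= band_um) & ~tumor] = STROMA
    pixels[tumor] = TUMOR

    # plant TLS disks, farthest first, spreading angles
    order = sorted(range(len(specs)), key=lambda i: -specs[i][0])
    placed_masks: list[np.ndarray] = []
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    base_angle = rng.uniform(0, 2 * np.pi)
    planted: list[Optional[PlantedTLS]] = [None] * len(specs)
    gap_um = 2 * mpp
    for slot, i in enumerate(order):
        d_req, a_req = specs[i]
        r_tls = radii[i]
        placed = False
        for attempt in range(72):
            theta = base_angle + 2 * np.pi * (slot / max(1, len(specs))) + attempt * (2 * np.pi / 72)
            u = np.array([math.cos(theta), math.sin(theta)])
            p = center + u * (tumor_radius_um + max(d_req, r_tls + gap_um))
            # Newton-style correction: move along the ray until the exact
            # nearest-tumor-pixel distance matches the request
            for _ in range(6):
                actual = tree.query(p)[0]
                p = p + u * (d_req - actual)
            actual = tree.query(p)[0]
            if abs(actual - d_req) > mpp * math.sqrt(2.0) / 2:
                continue
            if np.any(p - r_tls < pad) or np.any(p + r_tls > canvas_um - pad):
                continue
            disk = _disk_mask(shape, p, r_tls, mpp)
            if not disk.any():
                continue
            if d_req > 0 and (disk & tumor).any():
                continue
            if any((disk & m).any() for m in placed_masks):
                continue
            if placed_centers and any(
                np.linalg.norm(p - q) < r_tls + rq + gap_um
                for q, rq in zip(placed_centers, placed_radii)
            ):
                continue
            # re-center on the rasterized centroid so the component centroid
            # (mean of pixel centers) sits at the requested distance
            drows, dcols = np.nonzero(disk)
            centroid = np.array([(dcols.mean() + 0.5) * mpp, (drows.mean() + 0.5) * mpp])
            shift = tree.query(centroid)[0] - d_req
            if abs(shift) > mpp / 4:
                p2 = p - u * shift
                disk2 = _disk_mask(shape, p2, r_tls, mpp)
                if disk2.any() and not (d_req > 0 and (disk2 & tumor).any()) and not any(
                    (disk2 & m).any() for m in placed_masks
                ):
                    disk, p = disk2, p2
            area_px_um2 = disk.sum() * mpp**2
            if abs(area_px_um2 - a_req) > 0.05 * a_req:
                continue
            pixels[disk & ~tumor] = TLS
            placed_masks.append(disk)
            placed_centers.append(p)
            placed_radii.append(r_tls)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place TLS (distance {d_req} µm, area {a_req} µm²); "
                "canvas too crowded or too small"
            )
        if a_req < config.min_tls_area_um2:
            cat = "excluded_small"
        else:
            cat = classify_tls(d_req, config)
        planted[i] = PlantedTLS(d_req, a_req, cat)

    lmap = LabelMap(pixels, mpp=mpp, case_id=case_id)
    cats = [p.expected_category for p in planted]
    truth = SpatialTruth(
        case_id=case_id,
        planted=list(planted),
        n_ptls=cats.count("proximal"),
        n_dtls=cats.count("distal"),
        tls_positive=("proximal" in cats) or ("distal" in cats),
        ptls_positive="proximal" in cats,
        dtls_positive="distal" in cats,
    )
    if verify:
        summary, _ = summarize_case(lmap, config)
        if (summary.n_ptls, summary.n_dtls) != (truth.n_ptls, truth.n_dtls):
            raise GenerationError(
                "self-consistency gate failed: planted "
                f"({truth.n_ptls} pTLS, {truth.n_dtls} dTLS) but analysis found "
                f"({summary.n_ptls}, {summary.n_dtls})"
            )
    return lmap, truth


def gen_til_calls(
    lmap: LabelMap,
    intratumoral_density: float,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-tile TIL calls: every non-background tile is TIL-positive
    independently with probability ``intratumoral_density``.

    The expected iTIL score equals the density, since tumor tiles are
    flagged i.i.d. Bernoulli(p)."""
    p = float(intratumoral_density)
    if not 0.0 <= p <= 1.0:
        raise GenerationError(f"intratumoral_density must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    grid = build_tile_grid(lmap, config)
    rows = []
    for tr in range(grid.shape[0]):
        for tc in range(grid.shape[1]):
            cls = int(grid.dominant_class[tr, tc])
            if cls < 0:
                continue
            pos = bool(rng.random() < p) if cls != 0 else False
            rows.append({"tile_row": tr, "tile_col": tc, "til_positive": int(pos)})
    return pd.DataFrame(rows, columns=["tile_row", "tile_col", "til_positive"])


# ---------------------------------------------------------------------------
# molecular subtype profiles


def _random_context(rng, length=15) -> tuple[str, int]:
    """Sequence context with no tandem repeat of >=4 copies (unit 1-6)."""
    while True:
        ctx = "".join(rng.choice(list("ACGT"), size=length))
        off = int(rng.integers(0, length))
        probe = subtype_mod.VariantRecord("X", "other", ref_context=ctx, context_offset=off)
        if not subtype_mod.in_repeat_context(probe):
            return ctx, off


def _repeat_context(rng) -> tuple[str, int]:
    """Homopolymer run of >= 4 copies embedded in random flanks, offset inside."""
    base = rng.choice(list("ACGT"))
    run_len = int(rng.integers(4, 9))
    run = base * run_len
    others = [b for b in "ACGT" if b != base]
    left = "".join(rng.choice(others, size=int(rng.integers(2, 5))))
    right = "".join(rng.choice(others, size=int(rng.integers(2, 5))))
    ctx = left + run + right
    off = len(left) + int(rng.integers(0, run_len))
    return ctx, off


def _make_segments(rng, fraction: float, genome_length: int) -> pd.DataFrame:
    """Non-overlapping segments on one chromosome with the requested altered fraction."""
    altered_total = int(round(fraction * genome_length))
    segs = []
    pos = 1
    remaining = altered_total
    k = int(rng.integers(3, 8)) if altered_total else 0
    for i in range(k):
        seg_len = remaining // (k - i) if i < k - 1 else remaining
        if seg_len <= 0:
            continue
        gap = int(rng.integers(100, 1000))
        neutral_end = pos + gap - 1
        segs.append({"chrom": "chr1", "start": pos, "end": neutral_end, "altered_flag": 0})
        pos = neutral_end + 1
        segs.append({"chrom": "chr1", "start": pos, "end": pos + seg_len - 1, "altered_flag": 1})
        pos += seg_len
        remaining -= seg_len
    if pos <= genome_length:
        segs.append({"chrom": "chr1", "start": pos, "end": genome_length, "altered_flag": 0})
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "altered_flag"])


def gen_variant_profile(
    requested: str,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant and CNV tables that classify to ``requested`` under the cascade.

    POLE profiles carry an exonuclease-domain missense (position uniform in
    the domain) and may also carry MSI- and CNV-level features (the cascade
    order must still resolve them to POLE).  MSI-H profiles carry >= 2
    frameshift indels in repeat context and no POLE-domain missense; CNV-H
    profiles have altered fraction drawn in (0.2, 0.6]; CNV-L profiles fire
    no rule.  Self-checked against :func:`tlsquant.subtype.classify_subtype`.
    """
    if requested not in subtype_mod.SUBTYPES:
        raise GenerationError(f"unknown subtype {requested!r}")
    rng = np.random.default_rng(seed)
    variants: list[dict] = []

    def add_variant(gene, consequence, position=None, ctx_off=None):
        ctx, off = ctx_off if ctx_off else (None, None)
        variants.append(
            {
                "gene": gene,
                "protein_position": position,
                "consequence": consequence,
                "variant_class": "SNV" if consequence == "missense" else "indel",
                "ref_context": ctx,
                "context_offset": off,
            }
        )

    # benign background noise shared by all profiles
    for _ in range(int(rng.integers(1, 4))):
        add_variant(
            rng.choice(["TP53", "PTEN", "PIK3CA", "ARID1A"]),
            "missense",
            int(rng.integers(1, 1000)),
            _random_context(rng),
        )

    def add_msi_indels(count):
        for _ in range(count):
            add_variant(
                rng.choice(["RPL22", "KMT2B", "JAK1"]),
                "frameshift_indel",
                int(rng.integers(1, 500)),
                _repeat_context(rng),
            )

    if requested == "POLE":
        add_variant("POLE", "missense",
                    int(rng.integers(config.pole_domain_start, config.pole_domain_end + 1)),
                    _random_context(rng))
        if rng.random() < 0.5:  # distractors: cascade order must still say POLE
            add_msi_indels(int(rng.integers(2, 5)))
        frac = float(rng.uniform(0.0, 0.6))
    elif requested == "MSI-H":
        add_msi_indels(int(rng.integers(config.msi_min_frameshift_indels, 6)))
        # POLE missense OUTSIDE the domain is allowed noise
        if rng.random() < 0.3:
            add_variant("POLE", "missense", int(rng.integers(1, config.pole_domain_start - 1)),
                        _random_context(rng))
        frac = float(rng.uniform(0.0, 0.6))
    elif requested == "CNV-H":
        if rng.random() < 0.5:  # a single repeat indel must not trip the MSI rule
            add_msi_indels(config.msi_min_frameshift_indels - 1)
        frac = float(rng.uniform(config.cnv_high_fraction + 0.01, 0.6))
    else:  # CNV-L
        if rng.random() < 0.5:
            add_msi_indels(config.msi_min_frameshift_indels - 1)
        frac = float(rng.uniform(0.0, config.cnv_high_fraction))

    rng.shuffle(variants)
    vdf = pd.DataFrame(
        variants,
        columns=["gene", "protein_position", "consequence", "variant_class",
                 "ref_context", "context_offset"],
    )
    sdf = _make_segments(rng, frac, config.genome_length)
    call = subtype_mod.classify_subtype(vdf, sdf, config)
    if call.subtype != requested:
        raise GenerationError(
            f"self-consistency gate failed: requested {requested}, classified {call.subtype}"
        )
    return vdf, sdf


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    n_samples: int,
    dtls_status: Sequence[bool],
    effect_size: float,
    gene_sets: dict[str, Sequence[str]],
    seed: int = 0,
    n_background: int = 200,
    base_log_mean: float = 1.0,
    log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression matrix with signature genes up-shifted in
    dTLS-positive samples.

    Signature genes (union of the supplied sets) are drawn with log-mean
    shifted by ``effect_size`` (in log-SD units) in dTLS-positive samples;
    background genes are exchangeable.  Returns (genes × samples matrix,
    per-sample dTLS status).
    """
    if not gene_sets or all(len(g) == 0 for g in gene_sets.values()):
        raise GenerationError("gene sets empty; nothing to plant a signal in")
    if len(dtls_status) != n_samples:
        raise GenerationError("dtls_status length must equal n_samples")
    rng = np.random.default_rng(seed)
    sig_genes: list[str] = []
    for genes in gene_sets.values():
        sig_genes.extend(genes)
    bg_genes = [f"BG{i:04d}" for i in range(n_background)]
    all_genes = sig_genes + bg_genes
    if len(set(all_genes)) != len(all_genes):
        raise GenerationError("gene identifiers must be unique across sets and background")
    samples = [f"S{i:03d}" for i in range(n_samples)]
    status = pd.Series(list(map(bool, dtls_status)), index=samples, name="dtls_positive")

    mu = np.full((len(all_genes), n_samples), base_log_mean)
    shift = effect_size * log_sd
    sig_rows = np.arange(len(sig_genes))
    pos_cols = np.nonzero(status.to_numpy())[0]
    mu[np.ix_(sig_rows, pos_cols)] += shift
    values = np.exp(rng.normal(mu, log_sd))
    expr = pd.DataFrame(values, index=pd.Index(all_genes, name="gene"), columns=samples)
    return expr, status


# ---------------------------------------------------------------------------
# clonotype tables


def _random_cdr3(rng, used: set) -> str:
    while True:
        cdr3 = "C" + "".join(rng.choice(list(AA), size=int(rng.integers(8, 18)))) + "W"
        if cdr3 not in used:
            used.add(cdr3)
            return cdr3


def _zipf_reads(rng, n: int, exponent: float, scale: int = 10_000) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    reads = np.maximum(1, np.round(scale * ranks**-exponent)).astype(int)
    return reads


def gen_clone_tables(
    n_shared: int,
    n_private_each: int,
    seed: int = 0,
    zipf_exponent: float = 1.5,
    shared_at_top: bool = True,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[RepertoireSample, RepertoireSample, dict]:
    """Paired TLS/TIL clonotype tables with exactly ``n_shared`` common CDR3s.

    Read counts follow a Zipf power law (default exponent 1.5).  With
    ``shared_at_top`` the shared clones take the highest read ranks in both
    samples, so all of them land in the top-N; otherwise ranks are shuffled
    and the truth reflects which shared clones actually fall inside both
    top-N lists.  Truth records expected common reads (TLS side) and the
    number of unique common clones, computed by direct set intersection.
    """
    rng = np.random.default_rng(seed)
    used: set = set()
    shared = [_random_cdr3(rng, used) for _ in range(n_shared)]
    tls_priv = [_random_cdr3(rng, used) for _ in range(n_private_each)]
    til_priv = [_random_cdr3(rng, used) for _ in range(n_private_each)]
    v_genes = [f"IGHV{i}-{j}" for i in range(1, 8) for j in (2, 18, 23, 30, 34, 69)]
    j_genes = [f"IGHJ{i}" for i in range(1, 7)]

    def build(sample_id, role, cdr3s):
        m = len(cdr3s)
        reads = _zipf_reads(rng, m, zipf_exponent)
        if shared_at_top:
            order = np.arange(m)  # shared first (they lead the list) -> top reads
        else:
            order = rng.permutation(m)
        clone_reads = np.empty(m, dtype=int)
        clone_reads[order] = reads  # position in `cdr3s` -> a read rank
        clones = [
            (c, str(rng.choice(v_genes)), str(rng.choice(j_genes)), int(r))
            for c, r in zip(cdr3s, clone_reads)
        ]
        return RepertoireSample(sample_id=sample_id, role=role, clones=clones)

    tls_sample = build("TLS_1", "TLS", shared + tls_priv)
    til_sample = build("TIL_1", "TIL", shared + til_priv)

    # truth by direct set intersection of the two top-N lists
    n = config.top_n_clones
    def topn_keys(s):
        ordered = sorted(s.clones, key=lambda c: (-c[3], c[0]))[:n]
        return {c[0] for c in ordered}, {c[0]: c[3] for c in ordered}

    tls_keys, tls_reads = topn_keys(tls_sample)
    til_keys, _ = topn_keys(til_sample)
    common = tls_keys & til_keys & set(shared)
    truth = {
        "n_shared_planted": n_shared,
        "unique_common_clones": len(common),
        "common_clone_reads": int(sum(tls_reads[c] for c in common)),
        "total_inframe_reads_tls": int(tls_sample.total_inframe_reads),
    }
    stats = overlap_stats(tls_sample, til_sample, config)
    if (stats.unique_common_clones, stats.common_clone_reads) != (
        truth["unique_common_clones"], truth["common_clone_reads"]
    ):
        raise GenerationError("self-consistency gate failed for clone tables")
    return tls_sample, til_sample, truth


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass
class CohortTruth:
    hr_dtls: float
    baseline_rate: float
    censor_frac: float
    dtls_status: pd.Series  # per-case true dTLS flag


def _uniform_censor_bound(rates: np.ndarray, censor_frac: float) -> float:
    """Upper bound b of U(0, b) censoring so that P(C < T) ~= censor_frac."""
    def frac(b):
        lb = rates * b
        return float(np.mean((1.0 - np.exp(-lb)) / lb)) - censor_frac

    # frac(b) -> 1 - cf as b -> 0+, -> -cf as b -> inf
    return brentq(frac, 1e-9, 1e9)


def gen_survival_cohort(
    n: int = 559,
    hr_dtls: float = 0.56,
    dtls_prevalence: float = 0.45,
    baseline_rate: float = 0.04,
    censor_frac: float = 0.3,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
    stage_log_hr: float = 0.0,
    age_log_hr: float = 0.0,
    histology_log_hr: float = 0.0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Clinical table with exponential event times and a true dTLS hazard ratio.

    Event times ~ Exp(rate = baseline_rate × hr_dtls^dTLS × optional
    stage/age/histology multipliers); censoring is independent U(0, b) with b
    calibrated so the pre-administrative censoring fraction is
    ``censor_frac``, followed by administrative censoring at
    ``config.censor_years``.  Under exponential baselines the Cox estimand
    equals the generative HR.  Stage/age/histology marginals mirror a large
    endometrial-carcinoma cohort (stage I-IV ≈ 64/9/22/5%, endometrioid ≈ 76%).
    """
    if hr_dtls <= 0 or baseline_rate <= 0:
        raise GenerationError("hazard ratio and baseline rate must be > 0")
    if not 0 <= censor_frac < 1:
        raise GenerationError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dtls = rng.random(n) < dtls_prevalence
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.637, 0.093, 0.220, 0.050])
    age = np.clip(rng.normal(63, 10, n), 25, 95).round(1)
    histology = np.where(rng.random(n) < 0.76, "endometrioid", "other")

    log_rate = (
        np.log(baseline_rate)
        + np.log(hr_dtls) * dtls
        + stage_log_hr * (stage - 1)
        + age_log_hr * (age >= config.age_cutoff)
        + histology_log_hr * (histology != "endometrioid")
    )
    rates = np.exp(log_rate)

    def endpoint(rates_ep):
        t_event = rng.exponential(1.0 / rates_ep)
        if censor_frac > 0:
            b = _uniform_censor_bound(rates_ep, censor_frac)
            c = rng.uniform(0, b, n)
        else:
            c = np.full(n, np.inf)
        t_obs = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
        horizon = config.censor_years
        over = t_obs > horizon
        t_obs = np.where(over, horizon, t_obs)
        event = np.where(over, 0, event)
        return t_obs, event

    os_t, os_e = endpoint(rates)
    pfs_t, pfs_e = endpoint(rates * 1.3)  # progression precedes death on average

    df = pd.DataFrame(
        {
            "case_id": [f"C{i:04d}" for i in range(n)],
            "stage": stage,
            "age": age,
            "histology": histology,
            "dtls_positive": dtls.astype(int),
            "os_years": os_t,
            "os_event": os_e,
            "pfs_years": pfs_t,
            "pfs_event": pfs_e,
        }
    )
    if int(df["os_event"].sum()) == 0:
        raise GenerationError("generated cohort has zero events; raise baseline_rate")
    truth = CohortTruth(
        hr_dtls=hr_dtls,
        baseline_rate=baseline_rate,
        censor_frac=censor_frac,
        dtls_status=pd.Series(dtls, index=df["case_id"].to_numpy()),
    )
    return df, truth
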