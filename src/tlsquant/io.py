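"""Tabular and gene-set I/O.

Every table the pipeline touches is tab-separated with a header row:
variants (MAF-like), CNV segments (SEG-like), clonotypes (AIRR-like),
expression (genes × samples), TIL tile calls, and clinical tables.  Floats
are written at 6 significant digits; percentages are reported at 1 decimal
elsewhere in the package.

Gene sets use the GMT dialect: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import FormatError

log = logging.getLogger("tlsquant")

FLOAT_FORMAT = "%.6g"

VARIANT_COLUMNS = ["gene", "protein_position", "consequence", "variant_class",
                   "ref_context", "context_offset"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "altered_flag"]
CLONE_COLUMNS = ["sample_id", "cdr3_aa", "v_call", "j_call", "duplicate_count",
                 "productive"]
CLINICAL_COLUMNS = ["case_id", "stage", "age", "histology",
                    "os_years", "os_event", "pfs_years", "pfs_event"]
TIL_CALL_COLUMNS = ["tile_row", "tile_col", "til_positive"]


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref_context": "string"})
    _require_columns(df, ["gene", "consequence"], "variant table")
    return df


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SEGMENT_COLUMNS, "CNV segment table")
    return df


def read_clones(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "cdr3_aa", "duplicate_count"], "clonotype table")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["case_id", "os_years", "os_event"], "clinical table")
    return df


def read_til_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TIL_CALL_COLUMNS, "TIL call table")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples matrix; first column holds gene identifiers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"expression matrix: duplicate gene row(s) {dupes[:5]}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered {name: [genes]} mapping.

    Duplicate genes within a set are dropped (order preserved) with a logged
    warning; a duplicated set name is a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen: set[str] = set()
            uniq: list[str] = []
            for g in genes:
                if g in seen:
                    log.warning("gene set %s: duplicate gene %s dropped", name, g)
                    continue
                seen.add(g)
                uniq.append(g)
            sets[name] = uniq
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path,
                    descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def bundled_signature_gmt() -> Path:
    """Path of the editable default TLS-signature GMT shipped with the package.

    The lists are reconstructions of commonly used TLS-related signatures
    (12-chemokine, CXCL13, plasma cell, Tfh, Th1, Th1/B cell, TLS imprint);
    they are configuration, not ground truth, and users should replace them
    with their preferred curated versions.
    """
    return Path(__file__).parent / "data" / "tls_signatures.gmt"
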