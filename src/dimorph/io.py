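"""Readers and writers for the pipeline's external tab-separated formats.

Formats: expression TSV (genes × samples, header = sample ids), sample
sheet TSV (sample_id, sex, stage), gene metadata TSV (gene_id, chromosome),
annotation tables (two-column TSV or GAF 2.x), and result TSVs.  Readers
validate and reject malformed input instead of coercing it; output tables
have a deterministic column order and sort so runs diff byte-stably.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .model import AnnotationSet, ExpressionMatrix, GeneMeta, SampleMeta

GO_ID_RE = re.compile(r"^GO:\d{7}$")


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "stage"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    sheet = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in sheet:
            raise ParseError(f"{path}: duplicated sample id {sid!r}")
        sheet[sid] = SampleMeta(sample_id=sid, sex=row["sex"], stage=row["stage"])
    return sheet


def read_gene_metadata(path: str | Path) -> dict[str, GeneMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "chromosome"}.issubset(df.columns):
        raise ParseError(f"{path}: gene metadata needs columns gene_id, chromosome")
    meta = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if gid in meta:
            raise ParseError(f"{path}: duplicated gene id {gid!r}")
        meta[gid] = GeneMeta(gene_id=gid, chromosome_class=row["chromosome"])
    return meta


def read_expression_tsv(
    path: str | Path,
    sample_sheet: str | Path | dict[str, SampleMeta],
    gene_metadata: str | Path | dict[str, GeneMeta] | None = None,
) -> ExpressionMatrix:
    """Read a gene × sample FPKM table.

    The first column holds gene ids, the header row sample ids; every
    sample id must appear in the sample sheet.  Missing, negative or
    non-numeric values raise :class:`ParseError` naming the cell.
    """
    if not isinstance(sample_sheet, dict):
        sample_sheet = read_sample_sheet(sample_sheet)
    if gene_metadata is not None and not isinstance(gene_metadata, dict):
        gene_metadata = read_gene_metadata(gene_metadata)

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene id {dup!r}")
    for col in df.columns:
        if col not in sample_sheet:
            raise ParseError(f"{path}: sample {col!r} absent from sample sheet")
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing value at gene {bad[0]!r}, sample {col!r}"
            )
        neg = series.index[series < 0]
        if len(neg):
            raise ParseError(
                f"{path}: negative value at gene {neg[0]!r}, sample {col!r}"
            )
        df[col] = series

    samples = [sample_sheet[c] for c in df.columns]
    if gene_metadata is None:
        genes = [GeneMeta(gene_id=g) for g in df.index]
    else:
        genes = [
            gene_metadata.get(g, GeneMeta(gene_id=g, chromosome_class="unknown"))
            for g in df.index
        ]
    return ExpressionMatrix(values=df, samples=samples, genes=genes)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def write_sample_sheet(samples: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.sex, s.stage) for s in samples],
        columns=["sample_id", "sex", "stage"],
    ).to_csv(path, sep="\t", index=False)


def write_gene_metadata(genes: list[GeneMeta], path: str | Path) -> None:
    pd.DataFrame(
        sorted((g.gene_id, g.chromosome_class) for g in genes),
        columns=["gene_id", "chromosome"],
    ).to_csv(path, sep="\t", index=False)


def read_annotations(
    path: str | Path,
    dialect: str = "two-column-tsv",
    population_size: int | None = None,
) -> AnnotationSet:
    """Read gene → GO annotations from a two-column TSV or a GAF 2.x file.

    GAF columns follow the standard layout: the object id is column 2 and
    the GO id column 5 (1-based).  Term sets are deduplicated per gene.
    """
    gene_to_terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "two-column-tsv":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
                gene, term = fields[0], fields[1]
            elif dialect == "gaf":
                if len(fields) < 5:
                    raise ParseError(f"{path}:{lineno}: GAF line has fewer than 5 columns")
                gene, term = fields[2], fields[4]
            else:
                raise ValueError(f"unknown annotation dialect {dialect!r}")
            if gene == "gene_id" and lineno == 1:
                continue  # header row of the TSV dialect
            if not GO_ID_RE.match(term):
                raise ParseError(f"{path}:{lineno}: malformed GO id {term!r}")
            gene_to_terms.setdefault(gene, set()).add(term)
    return AnnotationSet(gene_to_terms=gene_to_terms, population_size=population_size)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    rows = sorted(
        (gene, term)
        for gene, terms in annotations.gene_to_terms.items()
        for term in terms
    )
    pd.DataFrame(rows, columns=["gene_id", "go_id"]).to_csv(path, sep="\t", index=False)


def write_results_tsv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with a fixed column order and stable row sort.

    Rows are sorted by every identifier-like column present (gene_id, sex,
    stage, term id) so repeated runs produce byte-identical files.
    """
    if records is None:
        raise ValueError("records must not be None")
    df = records.copy()
    sort_cols = [c for c in ("gene_id", "sex", "stage", "go_id", "term_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
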