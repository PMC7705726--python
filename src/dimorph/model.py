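"""Shared data model for the gonad expression-profiling pipeline.

The pipeline works on an FPKM matrix of embryonic/adult gonad samples from
both sexes at four developmental time points (Hamburger–Hamilton stages
HH27, HH31, HH38, plus adult).  Genes carry a chromosome class so that
autosomal and Z-linked expression can be summarised separately — birds have
a ZZ male / ZW female system with incomplete dosage compensation, so the
Z chromosome is analysed on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEXES = ("male", "female")
STAGES = ("HH27", "HH31", "HH38", "adult")
EMBRYONIC_STAGES = ("HH27", "HH31", "HH38")
CHROMOSOME_CLASSES = ("autosome", "Z", "W", "unknown")


@dataclass(frozen=True)
class SampleMeta:
    """One gonad sample: a (sex, stage) combination."""

    sample_id: str
    sex: str
    stage: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id!r}")
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class GeneMeta:
    """Gene identifier plus chromosome class (autosome / Z / W / unknown)."""

    gene_id: str
    chromosome_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValueError(
                f"unknown chromosome class {self.chromosome_class!r} "
                f"for gene {self.gene_id!r}"
            )


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix on the FPKM scale.

    ``values`` is a DataFrame indexed by gene id with one column per sample
    id; ``samples`` and ``genes`` carry the metadata in matching order.
    Values must be finite and non-negative.  ``normalized`` records whether
    between-sample (TMM) scaling has been applied.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    genes: list[GeneMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("matrix columns do not match sample metadata order")
        if list(self.values.index) != [g.gene_id for g in self.genes]:
            raise ValueError("matrix rows do not match gene metadata order")
        if len(set(self.values.index)) != len(self.values.index):
            raise ValueError("duplicated gene ids")
        pairs = [(s.sex, s.stage) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicated (sex, stage) sample combinations")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (missing values are an error)")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_id_for(self, sex: str, stage: str) -> str:
        for s in self.samples:
            if s.sex == sex and s.stage == stage:
                return s.sample_id
        raise KeyError(f"no sample for sex={sex!r}, stage={stage!r}")

    def has_sample(self, sex: str, stage: str) -> bool:
        return any(s.sex == sex and s.stage == stage for s in self.samples)

    def embryonic_sample_ids(self) -> list[str]:
        """The six embryonic columns (both sexes × HH27/HH31/HH38), if present."""
        ids = []
        for sex in SEXES:
            for stage in EMBRYONIC_STAGES:
                if not self.has_sample(sex, stage):
                    raise KeyError(f"missing embryonic sample sex={sex}, stage={stage}")
                ids.append(self.sample_id_for(sex, stage))
        return ids

    def chromosome_class_series(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.chromosome_class for g in self.genes}, name="chromosome_class"
        ).loc[self.gene_ids]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        keep = set(gene_ids)
        genes = [g for g in self.genes if g.gene_id in keep]
        order = [g.gene_id for g in genes]
        return ExpressionMatrix(
            values=self.values.loc[order].copy(),
            samples=list(self.samples),
            genes=genes,
            normalized=self.normalized,
        )

    def with_values(self, values: pd.DataFrame, *, normalized: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            samples=list(self.samples),
            genes=list(self.genes),
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class AnnotationSet:
    """Gene → set-of-GO-term map plus the enrichment population size.

    ``population_size`` defaults to the number of annotated genes but can be
    supplied by the caller when the background population is defined
    externally (e.g. a merged cross-species annotation set).
    """

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    population_size: int | None = None

    def __post_init__(self) -> None:
        if self.population_size is None:
            self.population_size = len(self.gene_to_terms)
        if self.population_size < len(self.gene_to_terms):
            raise ValueError(
                "population_size must be at least the number of annotated genes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_terms)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out


def copy_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return replace(matrix, values=matrix.values.copy())
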