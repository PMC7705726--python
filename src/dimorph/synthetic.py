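"""Truth-labelled synthetic data with the structure the pipeline assumes.

The generator emulates a gonad mRNA-seq experiment — two sexes at HH27,
HH31, HH38 and adult — by planting known structure and emitting an FPKM
matrix plus a truth table, so every pipeline stage can be scored against
ground truth without any sequencing data:

* **Stage patterns.**  Each patterned gene is assigned one of the nine
  up/flat/down × up/flat/down trajectory clusters.  Its log2 trajectory is
  the cumulative sum of per-transition effects (±``transition_effect`` for
  up/down, 0 for flat) plus Gaussian per-transition noise of sd
  ``noise_sd``, on top of a gene-specific baseline.  FPKM = 2**log2.
* **Sex structure.**  Stage-level noise is shared between the sexes, so
  between-sex fold changes equal the planted offsets: a Z-linked male
  dosage excess (×``z_male_dosage``, emulating incomplete avian dosage
  compensation), fold-class bias genes planted in the middle of the
  ×1.5–2 / ×2–3 / ×3+ bins, and cluster-2 dimorphic candidate genes at
  ×``dimorphic_fold``.  The candidate genes sit exactly on the up–flat
  archetype (no trajectory noise) so that candidate recovery measures the
  pipeline, not a noise realisation.
* **GO structure.**  A small biological-process ontology (25 terms, known
  depths, one alt_id, a diamond) plus per-gene annotations in which one
  designated term is enriched among the planted candidate genes
  (``enriched_term_fraction`` vs ``background_term_rate`` elsewhere).

All randomness flows from one seed through named substreams, so changing
one structural parameter leaves the other substreams' draws untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .go_enrichment import OntologyDAG, parse_obo
from .model import (
    SEXES,
    STAGES,
    AnnotationSet,
    ExpressionMatrix,
    GeneMeta,
    SampleMeta,
)

#: planted GO term enriched among the dimorphic candidate genes (depth 3)
ENRICHED_TERM = "GO:1000010"

# ---------------------------------------------------------------------------
# toy biological-process ontology: 25 terms, depths fixed by construction
# (term, name, is_a parents).  GO:1000010 sits under a diamond; GO:1000017
# has an extra-hop path making its longest-path depth exceed its level.
_ONTOLOGY = [
    ("GO:0008150", "biological_process", []),
    ("GO:1000001", "cellular process", ["GO:0008150"]),
    ("GO:1000002", "metabolic process", ["GO:0008150"]),
    ("GO:1000003", "developmental process", ["GO:0008150"]),
    ("GO:1000004", "reproduction", ["GO:0008150"]),
    ("GO:1000005", "anatomical structure development", ["GO:1000003"]),
    ("GO:1000006", "reproductive process", ["GO:1000004"]),
    ("GO:1000007", "cellular developmental process", ["GO:1000001", "GO:1000003"]),
    ("GO:1000008", "primary metabolic process", ["GO:1000002"]),
    ("GO:1000009", "biosynthetic process", ["GO:1000002"]),
    ("GO:1000010", "reproductive structure development", ["GO:1000005", "GO:1000006"]),
    ("GO:1000011", "gonad development", ["GO:1000010"]),
    ("GO:1000012", "cell differentiation", ["GO:1000007"]),
    ("GO:1000013", "protein metabolic process", ["GO:1000008"]),
    ("GO:1000014", "lipid metabolic process", ["GO:1000008"]),
    ("GO:1000015", "small molecule biosynthesis", ["GO:1000009"]),
    ("GO:1000016", "signaling", ["GO:0008150"]),
    ("GO:1000017", "cell communication", ["GO:1000016", "GO:1000012"]),
    ("GO:1000018", "transport", ["GO:1000001"]),
    ("GO:1000019", "ion transport", ["GO:1000018"]),
    ("GO:1000020", "RNA metabolic process", ["GO:1000008"]),
    ("GO:1000021", "translation", ["GO:1000013"]),
    ("GO:1000022", "proteolysis", ["GO:1000013"]),
    ("GO:1000023", "developmental process involved in reproduction", ["GO:1000003", "GO:1000006"]),
    ("GO:1000024", "germ cell development", ["GO:1000012", "GO:1000023"]),
]
_ALT_IDS = {"GO:1000099": "GO:1000010"}

#: longest-is_a-path depth of every toy term, fixed by the structure above
ONTOLOGY_DEPTHS = {
    "GO:0008150": 0,
    "GO:1000001": 1, "GO:1000002": 1, "GO:1000003": 1, "GO:1000004": 1,
    "GO:1000016": 1,
    "GO:1000005": 2, "GO:1000006": 2, "GO:1000007": 2, "GO:1000008": 2,
    "GO:1000009": 2, "GO:1000018": 2,
    "GO:1000010": 3, "GO:1000012": 3, "GO:1000013": 3, "GO:1000014": 3,
    "GO:1000015": 3, "GO:1000019": 3, "GO:1000020": 3, "GO:1000023": 3,
    "GO:1000011": 4, "GO:1000021": 4, "GO:1000022": 4,
    "GO:1000017": 4,  # via cell differentiation, longer than its level-2 path
    "GO:1000024": 4,
}

#: terms genes are annotated to at random (background), all depth ≤ 4
_BACKGROUND_TERMS = [
    "GO:1000011", "GO:1000012", "GO:1000013", "GO:1000014", "GO:1000015",
    "GO:1000017", "GO:1000019", "GO:1000020", "GO:1000021", "GO:1000022",
    "GO:1000024",
]


def ontology_obo_text() -> str:
    """The toy ontology as an OBO 1.2 document."""
    lines = ["format-version: 1.2", "ontology: toy-bp", ""]
    for term, name, parents in _ONTOLOGY:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {name}")
        lines.append("namespace: biological_process")
        for alt, primary in _ALT_IDS.items():
            if primary == term:
                lines.append(f"alt_id: {alt}")
        for p in parents:
            pname = next(n for t, n, _ in _ONTOLOGY if t == p)
            lines.append(f"is_a: {p} ! {pname}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class SyntheticSpec:
    """Planting parameters; the defaults are the generator's study conditions."""

    n_genes_per_cluster: int = 100
    n_background_genes: int = 1000  # stable genes, as in real filtered transcriptomes
    baseline_log2_fpkm: float = 8.0
    baseline_spread: float = 2.5  # half-width of the uniform log2 baseline band
    transition_effect: float = 1.5
    noise_sd: float = 0.3
    frac_z_linked: float = 0.08
    z_male_dosage: float = 1.6
    dimorphic_counts: dict[str, int] = field(
        default_factory=lambda: {"male": 52, "female": 40}
    )
    dimorphic_fold: float = 3.0
    n_bias_genes_per_class: int = 25
    below_threshold_genes: int = 100
    enriched_term_fraction: float = 0.15
    background_term_rate: float = 0.005
    background_annotation_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "enriched_term_fraction", "background_term_rate",
            "background_annotation_rate", "frac_z_linked",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_genes_per_cluster", "below_threshold_genes", "n_bias_genes_per_class"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.dimorphic_counts.values()):
            raise ValueError("dimorphic counts must be non-negative")
        for name in ("transition_effect", "noise_sd", "z_male_dosage", "dimorphic_fold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SyntheticData:
    matrix: ExpressionMatrix
    truth: pd.DataFrame
    annotations: AnnotationSet
    ontology: OntologyDAG
    obo_text: str


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _cluster_effects(cluster: int, e: float) -> tuple[float, float]:
    """(transition-1, transition-2) effects for a 1–9 grid cluster."""
    row, col = divmod(cluster - 1, 3)
    step = (e, 0.0, -e)
    return step[row], step[col]


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate the full truth-labelled bundle for one seed."""
    rng_traj = _substream(spec.seed, "trajectories")
    rng_noise = _substream(spec.seed, "noise")
    rng_chrom = _substream(spec.seed, "chromosomes")
    rng_adult = _substream(spec.seed, "adult")

    gene_rows = []  # gene_id, role, cluster, bias_direction, bias_class, planted_fold

    for cluster in range(1, 10):
        for i in range(spec.n_genes_per_cluster):
            gene_rows.append(
                (f"pat_c{cluster}_{i:04d}", "patterned", cluster, "unbiased", "unbiased", 1.0)
            )
    for sex in SEXES:
        tag = "m" if sex == "male" else "f"
        direction = f"{sex}-biased"
        for i in range(spec.dimorphic_counts.get(sex, 0)):
            gene_rows.append(
                (f"dim_{tag}_{i:03d}", "dimorphic", 2, direction, "fc3plus", spec.dimorphic_fold)
            )
        for cls, fold in (("fc1.5_2", 1.7), ("fc2_3", 2.4), ("fc3plus", 4.0)):
            for i in range(spec.n_bias_genes_per_class):
                gene_rows.append(
                    (f"bias_{tag}_{cls}_{i:03d}", "bias", 5, direction, cls, fold)
                )
    # stable background genes: most of a real filtered transcriptome does not
    # change between stages; without this mass the per-column distributions
    # would be dominated by the planted shifts and quantile normalization
    # would distort rather than correct
    for i in range(spec.n_background_genes):
        gene_rows.append((f"bg_{i:05d}", "background", 5, "unbiased", "unbiased", 1.0))
    for i in range(spec.below_threshold_genes):
        gene_rows.append((f"low_{i:04d}", "below_threshold", 5, "unbiased", "unbiased", 1.0))

    truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "role", "planted_cluster", "bias_direction", "bias_class", "planted_fold"],
    )
    n = len(truth)

    # chromosome classes: Z assigned at random among patterned genes only, so
    # the planted dosage excess never interferes with the planted fold classes
    # or the candidate folds
    is_z = rng_chrom.random(n) < spec.frac_z_linked
    is_z &= truth.role.isin(["patterned", "background"]).to_numpy()
    truth["chromosome_class"] = np.where(is_z, "Z", "autosome")
    truth["above_filter"] = (truth.role != "below_threshold").to_numpy()

    # baselines: filter-passing genes high, below-threshold genes low, with
    # margin on both sides of the FPKM-30 line so TMM scaling cannot flip them
    lo = max(spec.baseline_log2_fpkm - spec.baseline_spread, 5.5)
    hi = max(spec.baseline_log2_fpkm + spec.baseline_spread, lo + 0.5)
    baseline = rng_traj.uniform(lo, hi, n)
    low_mask = ~truth.above_filter.to_numpy()
    baseline[low_mask] = rng_traj.uniform(2.0, 4.0, int(low_mask.sum()))

    # per-transition noise, shared between the sexes; the planted candidate
    # and fold-class genes sit exactly on their archetypal trajectory
    eta = rng_noise.normal(0.0, spec.noise_sd, size=(n, 2)) if spec.noise_sd > 0 else np.zeros((n, 2))
    eta[truth.role.isin(["dimorphic", "bias"]).to_numpy()] = 0.0

    e1 = np.empty(n)
    e2 = np.empty(n)
    for idx, cl in enumerate(truth.planted_cluster):
        e1[idx], e2[idx] = _cluster_effects(int(cl), spec.transition_effect)
    d1, d2 = e1 + eta[:, 0], e2 + eta[:, 1]
    # embryonic log2 trajectory, mean-centred around the baseline so every
    # stage column carries the same spread of planted offsets (keeps the
    # per-column distributions comparable, as in real data, so quantile
    # normalization is a small correction rather than a distortion)
    traj = np.stack([np.zeros(n), d1, d1 + d2], axis=1)
    traj = traj - traj.mean(axis=1, keepdims=True)
    adult_level = rng_adult.normal(0.0, 1.0, n)

    # sex offsets in log2 units
    log_fold = np.log2(truth.planted_fold.to_numpy(dtype=float))
    male_off = np.where(truth.bias_direction == "male-biased", log_fold, 0.0)
    female_off = np.where(truth.bias_direction == "female-biased", log_fold, 0.0)
    male_off = male_off + np.where(is_z, np.log2(spec.z_male_dosage), 0.0)

    columns = {}
    sample_meta = []
    for sex in SEXES:
        off = male_off if sex == "male" else female_off
        for si, stage in enumerate(STAGES):
            sid = f"{'M' if sex == 'male' else 'F'}_{stage}"
            level = adult_level if stage == "adult" else traj[:, si]
            columns[sid] = 2.0 ** (baseline + level + off)
            sample_meta.append(SampleMeta(sample_id=sid, sex=sex, stage=stage))

    values = pd.DataFrame(columns, index=truth.gene_id.to_numpy())
    genes = [
        GeneMeta(gene_id=g, chromosome_class=c)
        for g, c in zip(truth.gene_id, truth.chromosome_class)
    ]
    matrix = ExpressionMatrix(values=values, samples=sample_meta, genes=genes)

    # candidate truth: dimorphic genes are cluster-2 members of their sex
    truth["is_candidate"] = (truth.role == "dimorphic").to_numpy()
    truth["candidate_sex"] = np.where(
        truth.is_candidate, truth.bias_direction.str.replace("-biased", "", regex=False), ""
    )

    annotations, planted = _draw_annotations(spec, truth)
    truth["planted_go"] = truth.gene_id.isin(planted).to_numpy()

    obo_text = ontology_obo_text()
    dag = _parse_obo_text(obo_text)
    return SyntheticData(
        matrix=matrix, truth=truth, annotations=annotations, ontology=dag, obo_text=obo_text
    )


def _draw_annotations(
    spec: SyntheticSpec, truth: pd.DataFrame
) -> tuple[AnnotationSet, set[str]]:
    """Direct (unpropagated) gene → term annotations.

    Every gene gets one deterministic broad annotation (so the population is
    the full gene set), random background terms, and the planted term with
    probability ``enriched_term_fraction`` for candidate genes versus
    ``background_term_rate`` for the rest.
    """
    rng = _substream(spec.seed, "annotations")
    gene_ids = truth.gene_id.to_numpy()
    is_candidate = truth.is_candidate.to_numpy()
    gene_to_terms: dict[str, set[str]] = {}
    planted: set[str] = set()
    anchors = ("GO:1000018", "GO:1000020")  # transport / RNA metabolic process
    for i, gid in enumerate(gene_ids):
        terms = {anchors[i % 2]}
        for t in _BACKGROUND_TERMS:
            if rng.random() < spec.background_annotation_rate:
                terms.add(t)
        p = spec.enriched_term_fraction if is_candidate[i] else spec.background_term_rate
        if rng.random() < p:
            terms.add(ENRICHED_TERM)
            planted.add(gid)
        gene_to_terms[gid] = terms
    return AnnotationSet(gene_to_terms=gene_to_terms), planted


def _parse_obo_text(text: str) -> OntologyDAG:
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".obo", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return parse_obo(path)
    finally:
        Path(path).unlink(missing_ok=True)


def score_cluster_recovery(
    truth: pd.DataFrame, assignments: pd.DataFrame, roles: tuple[str, ...] = ("patterned",)
) -> float:
    """Fraction of planted genes (both sexes) assigned their planted cluster."""
    t = truth[truth.role.isin(roles)].set_index("gene_id")
    a = assignments.set_index(["gene_id", "sex"]).cluster
    hits = total = 0
    for sex in SEXES:
        got = a.xs(sex, level="sex").reindex(t.index)
        hits += int((got == t.planted_cluster).sum())
        total += len(t)
    return hits / total


def write_fixture_bundle(data: SyntheticData, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files readable by the io module."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
        "genes": directory / "genes.tsv",
        "annotations": directory / "annotations.tsv",
        "ontology": directory / "ontology.obo",
        "truth": directory / "truth.tsv",
    }
    dio.write_expression_tsv(data.matrix, paths["expression"])
    dio.write_sample_sheet(data.matrix.samples, paths["samples"])
    dio.write_gene_metadata(data.matrix.genes, paths["genes"])
    dio.write_annotations(data.annotations, paths["annotations"])
    paths["ontology"].write_text(data.obo_text, encoding="utf-8")
    data.truth.sort_values("gene_id", kind="mergesort").to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.10g"
    )
    return paths
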