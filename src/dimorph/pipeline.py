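"""End-to-end orchestration: normalize → bias tables → clusters → candidates → GO.

A run is driven by a plain YAML config (see :data:`DEFAULT_CONFIG` for every
key and default).  All outputs are TSV with deterministic ordering, plus a
JSON manifest recording the config, package version and input checksums, so
two runs from the same config and inputs are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from . import clustering, dimorphism, go_enrichment, io as dio, normalization

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "inputs": {
        "expression": None,   # gene × sample FPKM TSV
        "samples": None,      # sample sheet TSV
        "genes": None,        # gene metadata TSV (optional)
        "annotations": None,  # gene → GO table (optional unless go.enabled)
        "annotation_dialect": "two-column-tsv",
        "ontology": None,     # OBO file (optional unless go.enabled)
    },
    "out": None,
    "seed": 0,
    "tmm": {"trim_m": 0.30, "trim_a": 0.05, "embryonic_only": False},
    "zscore": {"scope": "per-sex", "pseudocount": 1.0, "sd_floor": normalization.SD_FLOOR},
    "bias": {"top_n": 5000, "pseudocount": 1.0},
    "cluster": {
        "threshold_fpkm": 30.0,
        "backend": "exact",
        "seed": 0,
        "restarts": 10,
        "flat_band": clustering.FLAT_BAND,
    },
    "candidate": {"cluster": 2, "stage": "HH31", "min_fold": 2.0},
    "go": {
        "enabled": True,
        "namespace": "BP",
        "max_fdr": 0.05,
        "max_depth": 3,
        "population_size": None,
    },
}


class ConfigError(ValueError):
    """One or more config violations; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _merge_checked(defaults: dict, given: dict, prefix: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        path = f"{prefix}{key}"
        if key not in defaults:
            errors.append(f"unknown config key {path!r}")
            continue
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            errors.append(f"{path!r} must be a mapping")
        elif isinstance(defaults[key], dict):
            out[key] = _merge_checked(defaults[key], value, path + ".", errors)
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict) -> dict:
    """Parse and validate a config, reporting every violation at once."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            given = yaml.safe_load(fh) or {}
    else:
        given = source
    errors: list[str] = []
    cfg = _merge_checked(DEFAULT_CONFIG, given, "", errors)

    for name in ("trim_m", "trim_a"):
        frac = cfg["tmm"][name]
        if not 0 < frac < 0.5:
            errors.append(f"tmm.{name}: fraction must be > 0 and < 0.5 (got {frac})")
    if cfg["zscore"]["scope"] not in ("per-sex", "across-sexes"):
        errors.append(f"zscore.scope: unknown scope {cfg['zscore']['scope']!r}")
    if cfg["zscore"]["pseudocount"] <= 0:
        errors.append("zscore.pseudocount: must be positive")
    if cfg["bias"]["top_n"] <= 0:
        errors.append("bias.top_n: must be positive")
    if cfg["cluster"]["backend"] not in ("exact", "lloyd"):
        errors.append(f"cluster.backend: unknown backend {cfg['cluster']['backend']!r}")
    if cfg["candidate"]["min_fold"] < 1:
        errors.append("candidate.min_fold: must be ≥ 1")
    if not 0 < cfg["go"]["max_fdr"] <= 1:
        errors.append("go.max_fdr: must be in (0, 1]")
    for key in ("expression", "samples"):
        path = cfg["inputs"][key]
        if path is None:
            errors.append(f"inputs.{key}: required")
        elif not Path(path).exists():
            errors.append(f"inputs.{key}: file not found: {path}")
    for key in ("genes", "annotations", "ontology"):
        path = cfg["inputs"][key]
        if path is not None and not Path(path).exists():
            errors.append(f"inputs.{key}: file not found: {path}")
    if cfg["go"]["enabled"]:
        for key in ("annotations", "ontology"):
            if cfg["inputs"][key] is None:
                errors.append(f"inputs.{key}: required when go.enabled is true")
    if cfg["out"] is None:
        errors.append("out: required")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path) -> dict[str, Path]:
    """Run every enabled stage; returns the map of output names to paths.

    Any stage failure removes the partial output bundle and re-raises with
    the stage named.
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Path] = {}

    def emit(name: str, filename: str, writer) -> None:
        path = out_dir / filename
        writer(path)
        written.append(path)
        outputs[name] = path

    stage = "read inputs"
    try:
        matrix = dio.read_expression_tsv(
            cfg["inputs"]["expression"],
            cfg["inputs"]["samples"],
            cfg["inputs"]["genes"],
        )

        stage = "tmm normalization"
        normalized, factors = normalization.normalize_tmm(
            matrix,
            trim_m=cfg["tmm"]["trim_m"],
            trim_a=cfg["tmm"]["trim_a"],
            embryonic_only=cfg["tmm"]["embryonic_only"],
        )
        logger.info(
            "TMM reference sample %s; trim_m=%g trim_a=%g",
            factors.reference_sample, factors.trim_m, factors.trim_a,
        )
        emit("factors", "factors.tsv", lambda p: dio.write_results_tsv(factors.as_frame(), p))

        stage = "sex-bias tables"
        gene_tables = []
        for st in ("HH27", "HH31", "HH38", "adult"):
            if normalized.has_sample("male", st) and normalized.has_sample("female", st):
                gene_tables.append(
                    dimorphism.classify_stage(
                        normalized, st,
                        n=cfg["bias"]["top_n"],
                        pseudocount=cfg["bias"]["pseudocount"],
                    )
                )
        import pandas as pd

        bias_genes = pd.concat(gene_tables, ignore_index=True)
        emit("bias_genes", "bias_genes.tsv", lambda p: dio.write_results_tsv(bias_genes, p))
        proportions = dimorphism.bias_proportion_table(
            normalized, n=cfg["bias"]["top_n"], pseudocount=cfg["bias"]["pseudocount"]
        )
        emit("bias_proportions", "bias_proportions.tsv",
             lambda p: proportions.to_csv(p, sep="\t", index=False, float_format="%.10g"))

        stage = "pattern clustering"
        logger.info(
            "clustering: threshold=%g backend=%s scope=%s pseudocount=%g sd_floor=%g flat_band=%g seed=%d",
            cfg["cluster"]["threshold_fpkm"], cfg["cluster"]["backend"],
            cfg["zscore"]["scope"], cfg["zscore"]["pseudocount"],
            cfg["zscore"]["sd_floor"], cfg["cluster"]["flat_band"], cfg["cluster"]["seed"],
        )
        patterns = clustering.cluster_patterns(
            normalized,
            threshold=cfg["cluster"]["threshold_fpkm"],
            scope=cfg["zscore"]["scope"],
            pseudocount=cfg["zscore"]["pseudocount"],
            backend=cfg["cluster"]["backend"],
            seed=cfg["cluster"]["seed"],
            restarts=cfg["cluster"]["restarts"],
            sd_floor=cfg["zscore"]["sd_floor"],
            flat_band=cfg["cluster"]["flat_band"],
        )
        emit("clusters", "clusters.tsv",
             lambda p: dio.write_results_tsv(patterns.assignments, p))

        stage = "candidate selection"
        candidates = clustering.select_candidates(
            patterns.assignments,
            normalized,
            cluster=cfg["candidate"]["cluster"],
            stage=cfg["candidate"]["stage"],
            min_fold=cfg["candidate"]["min_fold"],
            pseudocount=cfg["bias"]["pseudocount"],
        )
        emit("candidates", "candidates.tsv", lambda p: dio.write_results_tsv(candidates, p))

        if cfg["go"]["enabled"]:
            stage = "go enrichment"
            annotations = dio.read_annotations(
                cfg["inputs"]["annotations"],
                dialect=cfg["inputs"]["annotation_dialect"],
                population_size=cfg["go"]["population_size"],
            )
            dag = go_enrichment.parse_obo(cfg["inputs"]["ontology"])
            propagated = go_enrichment.propagate_annotations(annotations, dag)
            study = set(candidates.gene_id)
            results = go_enrichment.hypergeom_enrich(
                study, propagated, dag, namespace=cfg["go"]["namespace"]
            )
            emit("enrichment", "enrichment.tsv",
                 lambda p: results.to_csv(p, sep="\t", index=False, float_format="%.10g"))
            significant = go_enrichment.filter_significant(
                results, max_fdr=cfg["go"]["max_fdr"], max_depth=cfg["go"]["max_depth"]
            )
            emit("enrichment_significant", "enrichment_significant.tsv",
                 lambda p: significant.to_csv(p, sep="\t", index=False, float_format="%.10g"))

        stage = "manifest"
        manifest = {
            "config": cfg,
            "version": __version__,
            "input_checksums": {
                k: _sha256(v) for k, v in cfg["inputs"].items()
                if v is not None and k != "annotation_dialect"
            },
        }
        emit("manifest", "manifest.json",
             lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                    encoding="utf-8"))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return outputs
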