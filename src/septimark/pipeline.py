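"""End-to-end orchestration of the marker-discovery stages.

One :class:`RunConfig` drives the whole chain: (optional) cohort simulation,
variant susceptibility screening, miRNA fold-change screening with optional
consensus-target enrichment, per-day protein differential testing, PCA,
cross-day common-feature intersection, trend-profile analysis, and candidate
marker validation.  Every stage writes its outputs before the next starts
and the machine-readable run report echoes the configuration, the seed, and
per-stage feature counts (timings go to the log only, so two identical runs
produce byte-identical files).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import abundance, enrich, trends, validation, variants as variants_mod
from .errors import ConfigError, SeptimarkError
from .matrix import AbundanceMatrix, load_samples, samples_in_group
from .synth import CohortConfig, SimulatedCohort, default_cohort_config, generate_cohort

log = logging.getLogger("septimark")

_THRESHOLD_DOMAINS = {
    "min_category": ("one of {3, 4}", lambda v: v in (3, 4)),
    "delta_threshold": ("in (0, 1)", lambda v: 0 < v < 1),
    "mirna_fc": ("a ratio > 1", lambda v: v > 1),
    "protein_fc": ("a ratio > 1", lambda v: v > 1),
    "p_threshold": ("in (0, 1)", lambda v: 0 < v < 1),
    "min_nonnull_frac": ("in (0, 1]", lambda v: 0 < v <= 1),
    "step_fc_threshold": ("a ratio > 1", lambda v: v > 1),
    "top_k": (">= 1", lambda v: v >= 1),
}


@dataclass
class RunConfig:
    """Paths or a simulation recipe, plus every stage threshold.

    Exactly one of ``cohort`` (simulate) and ``inputs`` (load tables) must be
    set.  ``inputs`` maps: ``variants``, ``samples``, ``mirna``,
    ``protein_days`` (day -> path), and optionally ``target_gmts``
    (db -> path) and ``annotation_gmt``.
    """

    cohort: CohortConfig | None = None
    inputs: dict[str, Any] | None = None
    min_category: int = 3
    delta_threshold: float = 0.18
    mirna_fc: float = 2.0
    protein_fc: float = 1.2
    p_threshold: float = 0.05
    min_nonnull_frac: float = 0.25
    step_fc_threshold: float = 1.5
    class_map: str = "results-text"
    top_k: int = 10
    min_dbs: int | None = None
    use_adjusted_p: bool = False
    panel: tuple[str, ...] | None = None
    out_dir: str = "septimark_out"
    seed: int = 0
    log_level: str = "INFO"


_CONFIG_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def validate_config(doc: Mapping[str, Any]) -> RunConfig:
    """Normalize a flat config mapping: fill defaults, check every range."""
    unknown = sorted(set(doc) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    kwargs = dict(doc)
    cohort = kwargs.pop("cohort", None)
    if isinstance(cohort, Mapping):
        unknown = sorted(set(cohort) - {f for f in CohortConfig.__dataclass_fields__})  # type: ignore[attr-defined]
        if unknown:
            raise ConfigError(f"unknown cohort keys: {unknown}")
        cohort = dict(cohort)
        for key in ("days",):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        for key in ("planted_susceptibility", "planted_mirna", "planted_trend",
                    "planted_marker"):
            if key in cohort:
                cohort[key] = tuple(tuple(item) for item in cohort[key])
        cohort = CohortConfig(**cohort)
    inputs = kwargs.pop("inputs", None)
    if (cohort is None) == (inputs is None):
        raise ConfigError("exactly one of 'cohort' and 'inputs' must be provided")
    if inputs is not None:
        required = {"variants", "samples", "mirna", "protein_days"}
        missing = sorted(required - set(inputs))
        if missing:
            raise ConfigError(f"inputs lacks required entries: {missing}")
        stray = sorted(set(inputs) - required - {"target_gmts", "annotation_gmt"})
        if stray:
            raise ConfigError(f"unknown input entries: {stray}")
        inputs = dict(inputs)
        inputs["protein_days"] = {int(d): p for d, p in inputs["protein_days"].items()}
    if "panel" in kwargs and kwargs["panel"] is not None:
        kwargs["panel"] = tuple(str(f) for f in kwargs["panel"])
    config = RunConfig(cohort=cohort, inputs=inputs, **kwargs)
    for name, (domain, ok) in _THRESHOLD_DOMAINS.items():
        value = getattr(config, name)
        if not ok(value):
            raise ConfigError(f"{name} = {value!r} is out of range; must be {domain}")
    if config.class_map not in trends.CLASS_MAPS:
        raise ConfigError(
            f"class_map = {config.class_map!r}; must be one of {sorted(trends.CLASS_MAPS)}")
    if cohort is not None:
        cohort.validate()
    return config


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON, a YAML subset) configuration file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    return validate_config(doc)


# ---------------------------------------------------------------------------
# stage runner
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, (set, frozenset)) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(doc, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(doc), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, AbundanceMatrix,
                                             dict[int, AbundanceMatrix], pd.DataFrame]:
    paths = config.inputs
    variants = variants_mod.load_variants(paths["variants"])
    samples = load_samples(paths["samples"])
    mirna = AbundanceMatrix.from_tsv(paths["mirna"], state="raw")
    protein = {day: AbundanceMatrix.from_tsv(p, state="raw")
               for day, p in sorted(paths["protein_days"].items())}
    return variants, mirna, protein, samples


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run report (also written)."""
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run starting: seed=%d out=%s", config.seed, out)

    report: dict[str, Any] = {"seed": config.seed, "stages": [], "config": _config_echo(config)}
    stages: list[dict[str, Any]] = report["stages"]

    def stage(name: str, **counts):
        entry = {"name": name, **_jsonable(counts)}
        stages.append(entry)
        log.info("stage %-16s %s (%.2fs elapsed)", name,
                 " ".join(f"{k}={v}" for k, v in counts.items()),
                 time.perf_counter() - t_start)

    truth = None
    try:
        # 1. simulate or load ------------------------------------------------
        if config.cohort is not None:
            cohort: SimulatedCohort = generate_cohort(replace(config.cohort, seed=config.seed))
            cohort.write(out)
            variants, mirna, protein, samples = (cohort.variants, cohort.mirna,
                                                 cohort.protein, cohort.samples)
            truth = cohort.truth
            stage("simulate", n_samples=len(samples), n_variant_records=len(variants),
                  n_mirna=mirna.shape[0], n_protein=next(iter(protein.values())).shape[0])
        else:
            variants, mirna, protein, samples = _load_inputs(config)
            stage("load", n_samples=len(samples), n_variant_records=len(variants))

        # 2. variant susceptibility screen ----------------------------------
        susceptibility = variants_mod.susceptibility_screen(
            variants, samples, min_category=config.min_category,
            delta_threshold=config.delta_threshold)
        susceptibility.to_csv(out / "susceptibility.tsv", sep="\t", index=False)
        stage("variant_screen", n_genes=len(susceptibility),
              n_selected=int(susceptibility["selected"].sum()))

        # 3. miRNA fold-change screen ---------------------------------------
        mirna_proc = abundance.process(mirna, config.min_nonnull_frac)
        subject_of = {"C": samples_in_group(samples, "C", 0),
                      "NS": [s for s in samples_in_group(samples, "NS", 0)],
                      "S": [s for s in samples_in_group(samples, "S", 0)]}
        mirna_de: dict[str, pd.DataFrame] = {}
        for contrast, (a, b) in (("NSvsC", ("NS", "C")), ("SvsC", ("S", "C")),
                                 ("SvsNS", ("S", "NS"))):
            ga = [s for s in subject_of[a] if s in mirna_proc.values.columns]
            gb = [s for s in subject_of[b] if s in mirna_proc.values.columns]
            de = abundance.fold_change_screen(mirna_proc, ga, gb, config.mirna_fc)
            de.to_csv(out / f"de_results_mirna_{contrast}.tsv", sep="\t", index=False)
            mirna_de[contrast] = de
        stage("mirna_screen",
              **{f"n_called_{c}": int(d["called"].sum()) for c, d in mirna_de.items()})

        # 4. consensus-target enrichment (needs GMT inputs) ------------------
        gmt_paths = (config.inputs or {}).get("target_gmts")
        annot_path = (config.inputs or {}).get("annotation_gmt")
        if gmt_paths and annot_path:
            collection = enrich.collection_from_gmt(annot_path)
            enriched_terms = {}
            for contrast in ("NSvsC", "SvsC"):
                top = enrich.top_k_by_fold(
                    mirna_de[contrast].loc[mirna_de[contrast]["called"]]
                    if mirna_de[contrast]["called"].any() else mirna_de[contrast],
                    config.top_k)
                per_db = {}
                for db, path in sorted(gmt_paths.items()):
                    sets = enrich.read_gmt(path)
                    per_db[db] = frozenset().union(
                        *(sets[m][1] for m in top if m in sets)) if sets else frozenset()
                query = enrich.target_consensus(per_db, config.min_dbs) & collection.background
                if query:
                    result = enrich.fisher_enrichment(query, collection)
                    result.to_csv(out / f"enrichment_{contrast}.tsv", sep="\t", index=False)
                    enriched_terms[contrast] = int(
                        (result["p_adjusted"] < config.p_threshold).sum())
                else:
                    enriched_terms[contrast] = 0
            stage("enrichment", **{f"n_terms_{c}": n for c, n in enriched_terms.items()})
        else:
            stage("enrichment", skipped="no annotation/target GMT inputs supplied")

        # 5. protein differential per day ------------------------------------
        from .matrix import hstack
        patient_days = [d for d in sorted(protein) if d != 0]
        if 0 not in protein:
            raise SeptimarkError("protein matrices must include day 0 (healthy controls)")
        pooled_raw = hstack([protein[d] for d in sorted(protein)])
        pooled = abundance.process(pooled_raw, config.min_nonnull_frac)
        called_sets: dict[str, set] = {}
        de_counts = {}
        for day in patient_days:
            cols_c = [s for s in samples_in_group(samples, "C", 0)
                      if s in pooled.values.columns]
            cols_burn = [s for s in pooled.values.columns
                         if s in set(samples.loc[samples["day"] == day, "sample_id"])]
            de = abundance.moderated_de(pooled, cols_burn, cols_c,
                                        fc_threshold=config.protein_fc,
                                        p_threshold=config.p_threshold,
                                        use_adjusted=config.use_adjusted_p)
            de.to_csv(out / f"de_results_protein_D{day}vsC.tsv", sep="\t", index=False)
            called_sets[f"D{day}"] = set(de.loc[de["called"], "feature"])
            cols_ns = [s for s in samples_in_group(samples, "NS", day)
                       if s in pooled.values.columns]
            cols_s = [s for s in samples_in_group(samples, "S", day)
                      if s in pooled.values.columns]
            de_ns_s = abundance.moderated_de(pooled, cols_s, cols_ns,
                                             fc_threshold=config.protein_fc,
                                             p_threshold=config.p_threshold,
                                             use_adjusted=config.use_adjusted_p)
            de_ns_s.to_csv(out / f"de_results_protein_SvsNS_D{day}.tsv", sep="\t", index=False)
            de_counts[f"n_called_D{day}vsC"] = int(de["called"].sum())
            de_counts[f"n_called_SvsNS_D{day}"] = int(de_ns_s["called"].sum())
        stage("protein_de", **de_counts)

        # 6. PCA --------------------------------------------------------------
        n_comp = min(5, pooled.shape[1] - 1, pooled.shape[0])
        scores, var_frac = abundance.pca_scores(pooled, n_comp)
        annotated = scores.join(samples.set_index("sample_id")[["group", "day"]])
        annotated.to_csv(out / "pca_scores.tsv", sep="\t")
        stage("pca", n_components=n_comp,
              pc1_var_frac=round(float(var_frac[0]), 4))

        # 7. common differential features across days ------------------------
        if len(called_sets) >= 2:
            common = abundance.common_features(called_sets)
            _write_json({"intersection": sorted(common.intersection),
                         "regions": dict(common.regions)}, out / "venn_regions.json")
            stage("common_features", n_common=len(common.intersection))
        else:
            stage("common_features", skipped="fewer than 2 patient days")

        # 8. trend analysis over (C, day 1, day 3) ----------------------------
        # steps use observed-value means (log2, no imputation): constant-min
        # fills would swamp the step threshold for low-abundance features
        if {1, 3} <= set(patient_days):
            pooled_log2 = abundance.log2_transform(abundance.quantile_normalize(
                abundance.missingness_filter(pooled_raw, config.min_nonnull_frac)))
            trend_calls = trends.trend_analysis_matrix(
                pooled_log2, samples, step_fc_threshold=config.step_fc_threshold,
                class_map=trends.CLASS_MAPS[config.class_map])
            trend_calls.to_csv(out / "trend_calls.tsv", sep="\t", index=False)
            stage("trend", n_features=len(trend_calls),
                  n_differential=int(trend_calls["is_differential"].sum()))
        else:
            trend_calls = None
            stage("trend", skipped="days 1 and 3 not both present")

        # 9. marker panel validation ------------------------------------------
        panel = list(config.panel) if config.panel else (
            sorted(truth.marker) if truth is not None else [])
        if panel:
            eval_days = {d: protein[d] for d in (1, 3) if d in protein}
            marker_report = validation.evaluate_panel(panel, eval_days, samples)
            marker_report.to_json(out / "marker_report.json")
            for (feat, day), pts in sorted(marker_report.roc.items()):
                pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                    out / f"roc_{feat}_D{day}.tsv", sep="\t", index=False)
            stage("marker_validation", n_panel=len(panel),
                  n_rows=len(marker_report.table))
        else:
            marker_report = None
            stage("marker_validation", skipped="no panel supplied or planted")

        # planted-truth confusion tables --------------------------------------
        if truth is not None:
            report["confusion"] = _confusion_tables(
                truth, susceptibility, mirna_de, trend_calls, marker_report)
    except SeptimarkError as exc:
        failed = stages[-1]["name"] if stages else "startup"
        raise SeptimarkError(f"stage after {failed!r} failed: {exc}") from exc

    _write_json(report, out / "run_report.json")
    log.info("run complete: %d stages, %.2fs", len(stages), time.perf_counter() - t_start)
    return report


def _config_echo(config: RunConfig) -> dict:
    doc = asdict(config)
    doc.pop("out_dir")  # implied by the report's own location
    if config.cohort is not None:
        doc["cohort"] = asdict(config.cohort)
    return _jsonable(doc)


def _confusion(planted: set, called: set, universe: set) -> dict:
    tp = len(planted & called)
    fp = len(called - planted)
    fn = len(planted - called)
    tn = len(universe - planted - called)
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _confusion_tables(truth, susceptibility, mirna_de, trend_calls, marker_report) -> dict:
    out: dict[str, Any] = {}
    genes = set(susceptibility["gene"])
    out["susceptibility"] = _confusion(
        set(truth.susceptibility), set(susceptibility.loc[susceptibility["selected"], "gene"]),
        genes)
    mirna_conf = {}
    for contrast, de in mirna_de.items():
        planted = {f for f, (_, c) in truth.mirna.items() if c == contrast}
        mirna_conf[contrast] = _confusion(planted, set(de.loc[de["called"], "feature"]),
                                          set(de["feature"]))
    out["mirna"] = mirna_conf
    if trend_calls is not None:
        planted = set(truth.trend_differential_features())
        called = set(trend_calls.loc[trend_calls["is_differential"], "feature"])
        out["trend"] = _confusion(planted, called, set(trend_calls["feature"]))
    if marker_report is not None:
        day1 = marker_report.table.loc[marker_report.table["day"] == 1]
        out["marker"] = {
            "planted": sorted(truth.marker),
            "significant_day1": sorted(day1.loc[day1["significant"], "feature"]),
            "auc_day1": {r["feature"]: round(float(r["auc"]), 4)
                         for _, r in day1.iterrows()},
        }
    return out


def default_run_config(seed: int = 0, out_dir: str = "septimark_out") -> RunConfig:
    """The default synthetic end-to-end configuration."""
    return validate_config({"cohort": asdict(default_cohort_config(seed)),
                            "out_dir": out_dir, "seed": seed})


def hash_outputs(out_dir) -> dict[str, str]:
    """SHA-256 of every file in a run directory (for determinism checks)."""
    out = Path(out_dir)
    digests = {}
    for path in sorted(out.rglob("*")):
        if path.is_file():
            digests[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return digests
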