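"""End-to-end pipeline over on-disk artifacts (OME-TIFF + CSV + YAML).

Stages run in order synthgen/ingest → imgproc → segment → measure → stats;
every stage communicates through documented files (TIFF stacks, CSV tables),
every output CSV carries a header comment with the config hash and seed, and
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, measure, segment, stats, synthgen
from .core import CHANNELS, ConfigError, StackGeometry
from .imgproc import EnhancementParams
from .measure import FilterParams, LayerScheme
from .segment import SegmentationParams

log = logging.getLogger("cb1rquant.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; constructed from a YAML mapping."""

    out_dir: str
    seed: int = 0
    #: directory with an existing cohort (manifest.csv + stacks); if None the
    #: synthetic generator runs first using ``cohort``/``geometry``/shape keys
    input_dir: str | None = None
    geometry: StackGeometry = field(default_factory=StackGeometry)
    cohort: synthgen.CohortSimParams = field(default_factory=synthgen.CohortSimParams)
    sites_per_layer: int = 2
    layers: tuple = ("III", "V")
    enhancement: EnhancementParams = field(default_factory=EnhancementParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    filters: FilterParams | None = None
    layer_scheme: LayerScheme = field(default_factory=LayerScheme)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        # hash the scientific settings only; output location is not part of
        # the result's identity
        raw = {k: v for k, v in self.raw.items() if k not in ("out_dir",)}
        canon = json.dumps(raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    try:
        params, geometry, shape = synthgen.params_from_dict(raw)
        seed = int(raw.get("seed", params.seed))
        if seed != params.seed:
            from dataclasses import replace

            params = replace(params, seed=seed)
        enh = EnhancementParams(**raw.get("enhancement", {}))
        seg_cfg = dict(raw.get("segmentation", {}))
        seg = SegmentationParams(**seg_cfg)
        filt = FilterParams(**raw["filters"]) if "filters" in raw else None
        cfg = PipelineConfig(
            out_dir=raw.get("out_dir", "pipeline_out"),
            seed=seed,
            input_dir=raw.get("input_dir"),
            geometry=geometry,
            cohort=params,
            sites_per_layer=shape["sites_per_layer"],
            layers=tuple(shape["layers"]),
            enhancement=enh,
            segmentation=seg,
            filters=filt,
            raw=raw,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def validate_config(raw: dict) -> list[str]:
    """Check every type invariant; returns all violations, not just the first."""
    violations = []

    def check(factory, label):
        try:
            factory()
        except (ConfigError, ValueError, TypeError) as exc:
            violations.append(f"{label}: {exc}")

    gcfg = dict(raw.get("geometry", {}))
    if "exposure_times_ms" in gcfg:
        gcfg["exposure_times_ms"] = tuple(gcfg["exposure_times_ms"])
    check(lambda: StackGeometry(**gcfg), "StackGeometry")
    check(lambda: synthgen.params_from_dict(raw), "CohortSimParams")
    check(lambda: EnhancementParams(**raw.get("enhancement", {})), "EnhancementParams")
    check(lambda: SegmentationParams(**raw.get("segmentation", {})), "SegmentationParams")
    if "filters" in raw:
        check(lambda: FilterParams(**raw["filters"]), "FilterParams")
    if "layer_scheme" in raw:
        check(
            lambda: LayerScheme(
                boundaries=tuple(tuple(b) for b in raw["layer_scheme"])
            ),
            "LayerScheme",
        )
    if "input_dir" in raw and raw["input_dir"] is not None:
        p = Path(raw["input_dir"])
        if not (p / "manifest.csv").exists():
            violations.append(f"input_dir: no manifest.csv under {p}")
    return violations


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = f"# cb1rquant config_sha={cfg.config_hash} seed={cfg.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


@dataclass
class PipelineResult:
    out_dir: str
    bouton_table: str
    site_summaries: str
    layer_summaries: str
    anova_report: str
    median_split_adu: float


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; abort on failure naming the stage and site."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import tifffile

    # ---- stage 1: synthesize or ingest -----------------------------------
    if config.input_dir is None:
        log.info("stage synthgen: rendering cohort to %s", out)
        cohort = synthgen.generate_cohort(
            config.cohort,
            sites_per_layer=config.sites_per_layer,
            layers=config.layers,
            geometry=config.geometry,
        )
        try:
            synthgen.write_cohort(cohort, out / "cohort")
        except Exception as exc:  # pragma: no cover - disk errors
            raise RuntimeError(f"stage synthgen failed: {exc}") from exc
        cohort_dir = out / "cohort"
    else:
        cohort_dir = Path(config.input_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    truth_path = cohort_dir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None

    filters = config.filters
    if filters is None:
        filters = FilterParams.scaled_frame(config.geometry)
    reference = config.cohort.reference_exposure_ms

    # ---- stages 2-4: per-site imgproc -> segment -> measure --------------
    all_records = []
    site_rows = []
    attrition_rows = []
    for _, row in manifest.iterrows():
        site_id = row["site_id"]
        try:
            data = tifffile.imread(row["stack_path"])
            stack = np.moveaxis(data, 1, 0)  # ZCYX on disk -> CZYX
            exposures = tuple(float(row[f"exposure_{c}_ms"]) for c in CHANNELS)
            from dataclasses import replace

            geometry = replace(
                config.geometry,
                measured_thickness=float(row["measured_thickness_um"]),
                exposure_times_ms=exposures,
            )
            meta = {
                k: row[k]
                for k in ("subject_id", "pair_id", "group", "layer", "site_id")
            }
            records, plane_sum, plane, seg_objects, attrition = (
                evaluate.process_site(
                    stack, geometry, meta, config.enhancement,
                    config.segmentation, filters, reference,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"stage segment/measure failed at site {site_id}: {exc}") from exc
        all_records.append(records)
        site_rows.append((meta, plane_sum, plane))
        for channel, att in attrition.items():
            attrition_rows.append({"site_id": site_id, "channel": channel, **att})
        log.info(
            "site %s: %d boutons accepted (%s)",
            site_id, len(records),
            ", ".join(f"{c}:{a.get('n_in', 0)}→{a.get('n_out', 0)}"
                      for c, a in attrition.items()),
        )

    non_empty = [r for r in all_records if not r.empty]
    if not non_empty:
        raise RuntimeError("stage measure failed: no boutons accepted in any site")
    records = pd.concat(non_empty, ignore_index=True)
    records, median = measure.split_expressor_class(records)
    summaries = [
        measure.site_summary_from_records(
            records[records["site_id"] == meta["site_id"]], plane_sum, plane, meta
        )
        for meta, plane_sum, plane in site_rows
    ]
    site_summaries = pd.DataFrame(summaries)
    layer_summaries = measure.summarize_layer(site_summaries)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        long_table = measure.layer_table_long(layer_summaries)

    # ---- stage 5: stats ---------------------------------------------------
    try:
        report, model_tables = _stats_stage(
            long_table, layer_summaries, manifest, median
        )
    except Exception as exc:
        raise RuntimeError(f"stage stats failed: {exc}") from exc

    _write_csv(records, out / "bouton_records.csv", config)
    _write_csv(site_summaries, out / "site_summaries.csv", config)
    _write_csv(layer_summaries, out / "layer_summaries.csv", config)
    _write_csv(pd.DataFrame(attrition_rows), out / "attrition.csv", config)
    _write_csv(model_tables, out / "anova_tables.csv", config)
    report_path = out / "stats_report.txt"
    with open(report_path, "w") as fh:
        fh.write(f"# cb1rquant config_sha={config.config_hash} seed={config.seed}\n")
        fh.write(report)
    return PipelineResult(
        out_dir=str(out),
        bouton_table=str(out / "bouton_records.csv"),
        site_summaries=str(out / "site_summaries.csv"),
        layer_summaries=str(out / "layer_summaries.csv"),
        anova_report=str(report_path),
        median_split_adu=median,
    )


def _stats_stage(long_table, layer_summaries, manifest, median):
    """Fit the model suite and render tables + a human-readable report."""
    subjects = manifest.drop_duplicates("subject_id")
    covs = [c for c in stats.DEFAULT_COVARIATES if c in subjects.columns]
    long_cov = long_table.merge(
        subjects[["subject_id", *covs]], on="subject_id", how="left"
    )
    sum_cov = layer_summaries.merge(
        subjects[["subject_id", *covs]], on="subject_id", how="left"
    )
    frames = []
    lines = [f"expressor split median: {median:.1f} ADU", ""]
    single_layer = long_table["layer"].nunique() < 2

    def fit(label, data, spec):
        try:
            results, fitres = stats.fit_ancova(data, spec)
        except ValueError as exc:
            lines.append(f"{label}: not estimable ({exc})")
            return None
        tab = stats.anova_table(results)
        tab.insert(0, "model", label)
        frames.append(tab)
        lines.append(label)
        for r in results:
            lines.append(
                f"  {r.term:28s} F({r.df_num},{r.df_den}) = {r.F:8.3f}  p = {r.p:.4g}"
            )
        lines.append("")
        return fitres

    def drop_layer_terms(spec):
        from dataclasses import replace

        fixed = tuple(t for t in spec.fixed_effects if "layer" not in t)
        return replace(spec, fixed_effects=fixed)

    tt_paired = stats.terminal_type_spec(paired=True)
    tt_unpaired = stats.terminal_type_spec(paired=False)
    sum_paired = stats.sum_intensity_spec(paired=True)
    sum_unpaired = stats.sum_intensity_spec(paired=False)
    if single_layer:
        tt_paired = drop_layer_terms(tt_paired)
        tt_unpaired = drop_layer_terms(tt_unpaired)
        sum_paired = drop_layer_terms(sum_paired)
        sum_unpaired = drop_layer_terms(sum_unpaired)
    fit_tt = fit("terminal-type model (paired)", long_cov, tt_paired)
    fit("terminal-type model (unpaired)", long_cov, tt_unpaired)
    fit("sum-intensity model (paired)", sum_cov, sum_paired)
    fit("sum-intensity model (unpaired)", sum_cov, sum_unpaired)

    if fit_tt is not None:
        ph = stats.posthoc_bonferroni(long_cov, fit=fit_tt)
        lines.append("post hoc group contrasts (Bonferroni)")
        for _, r in ph.iterrows():
            lines.append(
                f"  {r['terminal_class']:12s} {r['contrast']}: diff = {r['difference']:9.2f}"
                f"  t({r['df']}) = {r['t']:7.3f}  p = {r['p']:.4g}  adj p = {r['adjusted_p']:.4g}"
            )
        lines.append("")
        ph.insert(0, "model", "posthoc_bonferroni")
        ph = ph.rename(columns={"terminal_class": "term", "p": "p", "adjusted_p": "adjusted_p"})
        frames.append(
            ph[["model", "term", "t", "df", "p", "adjusted_p"]].rename(
                columns={"t": "F"}
            )
        )

    # percent group differences of the estimated cell means
    cells = (
        long_table.groupby(["group", "terminal_class", "subject_id"])["response"]
        .mean()
        .groupby(["group", "terminal_class"])
        .mean()
        .unstack(0)
    )
    lines.append("estimated group percent differences (SZ vs Ctrl)")
    for cls, r in cells.iterrows():
        if r.get("Ctrl", np.nan) > 0:
            pct = stats.group_percent_difference(r["SZ"], r["Ctrl"])
            lines.append(f"  {cls:12s} {pct:+.1f}%")
    lines.append("")

    # exposure-history ratio tests on the sum measure
    subj_sum = layer_summaries.groupby(["subject_id", "pair_id", "group"], as_index=False)[
        "sum_cb1r"
    ].mean()
    wide = subj_sum.pivot(index="pair_id", columns="group", values="sum_cb1r")
    if {"Ctrl", "SZ"} <= set(wide.columns) and (wide["SZ"] > 0).all():
        ratios = (wide["Ctrl"] / wide["SZ"]).rename("ratio").reset_index()
        lines.append("within-pair Ctrl/SZ sum ratio vs exposure history")
        for exposure in (
            "cannabis_history", "antipsychotic_history", "antidepressant_history",
            "benzodiazepine_history", "valproate_history",
        ):
            if exposure not in subjects.columns:
                continue
            flags = (
                subjects[subjects["group"] == "SZ"]
                .set_index("pair_id")[exposure]
                .reindex(ratios["pair_id"])
                .astype(bool)
            )
            if flags.nunique() < 2:
                lines.append(f"  {exposure}: one exposure group empty; skipped")
                continue
            t, p = stats.within_pair_ratio_test(ratios["ratio"], flags.to_numpy())
            lines.append(f"  {exposure:24s} t = {t:7.3f}  p = {p:.4g}")
        lines.append("")

    demo = stats.demographic_tests(manifest)
    lines.append("demographic comparisons")
    for _, r in demo.iterrows():
        lines.append(f"  {r['variable']:24s} {r['test']:12s} p = {r['p']:.4g}")
    lines.append("")

    tables = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return "\n".join(lines), tables
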