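"""End-to-end orchestration: simulate -> crop/extract -> reliability -> survival -> stats.

Every stage writes its artifacts (CSV/JSON) into the run directory together
with a manifest recording the config hash and per-stage seeds, so a run is
reproducible from its config alone and later stages can be rerun against
cached earlier artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, reliability, survival, stats, synthgen
from .config import RunConfig, STAGES
from .features import FeatureConfig
from .features.extract import extract_all, write_feature_table, read_feature_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are retained."""


@dataclass
class RunContext:
    config: RunConfig
    outdir: Path
    cohort: synthgen.Cohort | None = None
    features: pd.DataFrame | None = None  # patient-indexed wide table
    icc_auto: pd.DataFrame | None = None
    icc_manual: pd.DataFrame | None = None
    signatures: reliability.SignatureSet | None = None
    distributions: dict[str, survival.CIndexDistribution] = field(default_factory=dict)


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    return json.loads(p.read_text()) if p.exists() else {"completed": []}


def _update_manifest(ctx: RunContext, stage: str) -> None:
    m = _load_manifest(ctx.outdir)
    m["config_hash"] = ctx.config.config_hash()
    m["seeds"] = {s: ctx.config.stage_seed(s) for s in STAGES}
    if stage not in m["completed"]:
        m["completed"].append(stage)
    _manifest_path(ctx.outdir).write_text(json.dumps(m, indent=2))


def _cached(ctx: RunContext, stage: str) -> bool:
    m = _load_manifest(ctx.outdir)
    return (m.get("config_hash") == ctx.config.config_hash()
            and stage in m.get("completed", []))


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_simulate(ctx: RunContext) -> None:
    cfg = ctx.config
    spec = synthgen.CohortSpec(
        n_patients=cfg.cohort.n_patients,
        modality=cfg.cohort.modality,
        image_size=cfg.cohort.image_size,
        pixel_spacing=cfg.cohort.pixel_spacing,
        semi_axis_range_mm=tuple(cfg.cohort.semi_axis_range_mm),
        irregularity_range=tuple(cfg.cohort.irregularity_range),
        texture_corr_range_mm=tuple(cfg.cohort.texture_corr_range_mm),
        sharpness_range_mm=tuple(cfg.cohort.sharpness_range_mm),
        k_manual=cfg.cohort.k_manual,
        manual_amplitude_mm=cfg.cohort.manual_amplitude_mm,
        perturbation=synthgen.PerturbationSpec(
            n_variants=cfg.perturbation.n_variants,
            amplitude_mm=cfg.perturbation.amplitude_mm,
            noise_corr_mm=cfg.perturbation.noise_corr_mm,
            gradient_modulation=cfg.perturbation.gradient_modulation,
            min_dice=cfg.perturbation.min_dice,
        ),
        survival=synthgen.SurvivalGenSpec(
            beta=dict(cfg.survival_gen.beta),
            baseline_rate=cfg.survival_gen.baseline_rate,
            censor_rate=cfg.survival_gen.censor_rate,
            admin_censor_time=cfg.survival_gen.admin_censor_time,
        ),
    )
    ctx.cohort = synthgen.make_cohort(spec, master_seed=cfg.stage_seed("simulate"))
    synthgen.save_cohort(ctx.cohort, ctx.outdir / "cohort")


def _require_cohort(ctx: RunContext) -> synthgen.Cohort:
    if ctx.cohort is None:
        cohort_dir = ctx.outdir / "cohort"
        if not cohort_dir.exists():
            raise StageError("simulate stage has not produced a cohort")
        ctx.cohort = synthgen.load_cohort(cohort_dir)
    return ctx.cohort


def _stage_extract(ctx: RunContext) -> None:
    cfg = ctx.config
    cohort = _require_cohort(ctx)
    if cfg.crop.box_size is None:
        diameters = [synthgen_case_diameter(c) for c in cohort.cases]
        box = preprocess.size_boxes(diameters, cohort.cases[0].spacing)
        box = min(box, cfg.cohort.image_size)
    else:
        box = cfg.crop.box_size
    rule = preprocess.CropRule(box_size=box, min_volume_mm3=cfg.crop.min_volume_mm3,
                               slice_thickness_mm=cfg.crop.slice_thickness_mm)
    kept, logdf = preprocess.crop_cohort(cohort.cases, rule)
    preprocess.write_exclusion_log(logdf, ctx.outdir / "exclusion_log.csv")
    if not kept:
        raise StageError("all lesions excluded by the crop rules")
    fc = FeatureConfig(n_bins=cfg.features.n_bins,
                       discretization=cfg.features.discretization,
                       bin_width=cfg.features.bin_width,
                       wavelets=cfg.features.wavelets,
                       wavelet=cfg.features.wavelet)
    table = extract_all(kept, fc)
    # one lesion per patient: index features by patient for the survival stage
    lesion_to_patient = {c.lesion_id: c.patient_id for c in cohort.cases}
    table.index = pd.MultiIndex.from_tuples(
        [(lesion_to_patient[l], s) for l, s in table.index],
        names=["patient_id", "segmentation_id"])
    ctx.features = table.sort_index()
    out = table.copy()
    out.index.names = ["lesion_id", "segmentation_id"]  # long CSV schema
    write_feature_table(out, ctx.outdir / "features.csv")


def _require_features(ctx: RunContext) -> pd.DataFrame:
    if ctx.features is None:
        path = ctx.outdir / "features.csv"
        if not path.exists():
            raise StageError("extract stage has not produced features.csv")
        t = read_feature_table(path)
        t.index.names = ["patient_id", "segmentation_id"]
        ctx.features = t
    return ctx.features


def _stage_reliability(ctx: RunContext) -> None:
    cfg = ctx.config
    table = _require_features(ctx)
    modality = cfg.cohort.modality
    icc_auto = reliability.icc_table(table, "auto", dataset="synthetic",
                                     modality=modality)
    icc_auto = reliability.signature_flags(reliability.quartile_groups(icc_auto))
    icc_auto.to_csv(ctx.outdir / "icc_auto.csv", index=False)
    ctx.icc_auto = icc_auto
    if (icc_auto["icc"] >= 1.0 - 1e-12).all():
        log.warning("all features have ICC 1 (zero perturbation?): "
                    "the low-ICC signature will be empty")

    if cfg.cohort.k_manual >= 2:
        icc_manual = reliability.icc_table(table, "manual", dataset="synthetic",
                                           modality=modality)
        icc_manual = reliability.signature_flags(reliability.quartile_groups(icc_manual))
        icc_manual.to_csv(ctx.outdir / "icc_manual.csv", index=False)
        ctx.icc_manual = icc_manual
        comp = reliability.compare_manual_auto(icc_manual, icc_auto)
        comp.to_csv(ctx.outdir / "icc_manual_vs_auto.csv", index=False)

    sigs = reliability.threshold_signatures(ctx.icc_auto)
    ctx.signatures = sigs
    (ctx.outdir / "signatures.json").write_text(json.dumps(
        {"high": sigs.high, "low": sigs.low, "all": sigs.all}, indent=2))


def _require_signatures(ctx: RunContext) -> reliability.SignatureSet:
    if ctx.signatures is None:
        path = ctx.outdir / "signatures.json"
        if not path.exists():
            raise StageError("reliability stage has not produced signatures.json")
        d = json.loads(path.read_text())
        ctx.signatures = reliability.SignatureSet(**d)
    return ctx.signatures


def _stage_survival(ctx: RunContext) -> None:
    cfg = ctx.config
    table = _require_features(ctx)
    cohort = _require_cohort(ctx)
    sigs = _require_signatures(ctx)
    cv = survival.stratified_folds(cohort.survival, n_folds=cfg.survival_eval.n_folds,
                                   seed=cfg.stage_seed("survival"))
    rows = []
    for name in ("high", "all", "low"):
        feats = sigs.get(name)
        if not feats:
            log.warning("signature %r is empty: skipped", name)
            continue
        dist = survival.evaluate_signature(
            table, cohort.survival, feats, cv, signature_name=name,
            max_k=cfg.survival_eval.max_k, penalty=cfg.survival_eval.penalty,
            refit_per_variant=cfg.survival_eval.refit_per_variant)
        if dist.values.empty:
            log.warning("signature %r: no fold produced a usable model", name)
            continue
        ctx.distributions[name] = dist
        rows.append({"signature": name, "mean": dist.mean, "sd": dist.sd,
                     "n_values": len(dist.values), "incomplete": dist.incomplete})
        dist.values.assign(signature=name).to_csv(
            ctx.outdir / f"cindex_{name}.csv", index=False)
    pd.DataFrame(rows).to_csv(ctx.outdir / "cindex_summary.csv", index=False)

    # risk stratification with the all-signature model on the full cohort
    manual = table.xs("manual-00", level="segmentation_id")
    recs = cohort.survival.set_index("patient_id").loc[manual.index].reset_index()
    try:
        feats = survival.forward_select(
            manual[sigs.all], recs["time_years"], recs["event"],
            max_k=cfg.survival_eval.max_k, penalty=cfg.survival_eval.penalty)
        model = survival.CoxPHModel(penalty=cfg.survival_eval.penalty).fit(
            manual[feats], time=recs["time_years"], event=recs["event"])
        groups, km = survival.risk_stratify(model, manual[feats], recs)
        groups.to_csv(ctx.outdir / "risk_groups.csv", index=False)
        for g, sf in km.items():
            sf.to_csv(ctx.outdir / f"km_{g}.csv", index=False)
    except (survival.ConvergenceError, ValueError) as exc:
        log.warning("risk stratification skipped: %s", exc)


def _require_distributions(ctx: RunContext) -> dict[str, np.ndarray]:
    """Per-signature C-index values, matched on (fold, segmentation_id).

    Signatures whose model failed in some fold are missing those values; the
    paired tests require matched samples, so only the intersection of
    (fold, segmentation) keys present in every signature is kept.
    """
    frames = {}
    for name in ("high", "all", "low"):
        if name in ctx.distributions:
            frames[name] = ctx.distributions[name].values
        else:
            path = ctx.outdir / f"cindex_{name}.csv"
            if path.exists():
                frames[name] = pd.read_csv(path)
    if not frames:
        raise StageError("survival stage has not produced C-index distributions")
    series = {name: df.set_index(["fold", "segmentation_id"])["c_index"]
              for name, df in frames.items()}
    common = None
    for s in series.values():
        common = s.index if common is None else common.intersection(s.index)
    if len(common) < len(next(iter(series.values()))):
        log.warning("matching C-index values on %d common (fold, segmentation) "
                    "keys", len(common))
    return {name: s.loc[common].to_numpy() for name, s in series.items()}


def _stage_stats(ctx: RunContext) -> None:
    cfg = ctx.config
    dists = _require_distributions(ctx)
    report = stats.compare_signatures(dists, alpha=cfg.stats.alpha,
                                      n_comparisons=cfg.stats.n_comparisons)
    report.to_frame().to_csv(ctx.outdir / "stats_report.csv", index=False)
    (ctx.outdir / "stats_report.txt").write_text(report.to_text() + "\n")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "reliability": _stage_reliability,
    "survival": _stage_survival,
    "stats": _stage_stats,
}


def synthgen_case_diameter(case: synthgen.LesionCase) -> float:
    """Maximum diameter (mm) of a lesion's reference mask."""
    from .features import shape2d
    return shape2d(case.manual_masks[0], case.spacing)["MaximumDiameter"]


def run_pipeline(config: RunConfig, outdir: str | Path,
                 stages: list[str] | None = None, force: bool = False) -> Path:
    """Execute the pipeline (or a subset of stages) into ``outdir``.

    Stages whose outputs already exist under the same config hash are reused
    unless ``force`` is set.  A stage failure raises :class:`StageError`;
    artifacts of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    ctx = RunContext(config=config, outdir=outdir)
    wanted = stages or list(STAGES)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage not in wanted:
            continue
        if not force and _cached(ctx, stage):
            log.info("stage %s: cached, skipping", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            _STAGE_FNS[stage](ctx)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        _update_manifest(ctx, stage)
    return outdir


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def make_report(run_dir: str | Path, plots: bool = False) -> Path:
    """Assemble per-figure data tables (and optional plots) from a run.

    Emits: ICC by quartile manual vs automatic; ICC by feature family and
    filter; C-index distribution by signature.  Missing stage outputs are
    listed in the raised error.
    """
    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    missing = []

    comp_path = run_dir / "icc_manual_vs_auto.csv"
    if comp_path.exists():
        pd.read_csv(comp_path).to_csv(report_dir / "icc_quartiles_manual_vs_auto.csv",
                                      index=False)

    icc_path = run_dir / "icc_auto.csv"
    if icc_path.exists():
        icc = pd.read_csv(icc_path)
        parts = icc["feature_name"].str.split(".", expand=True)
        icc["filter"], icc["family"] = parts[0], parts[1]
        fam = (icc.groupby(["modality", "family"])["icc"]
               .agg(["median", "count",
                     lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)]))
        fam.columns = ["median_icc", "n_features", "q1_icc", "q3_icc"]
        fam.reset_index().to_csv(report_dir / "icc_by_family.csv", index=False)
    else:
        missing.append("icc_auto.csv (rerun: reliability)")

    dists = []
    for name in ("high", "all", "low"):
        p = run_dir / f"cindex_{name}.csv"
        if p.exists():
            dists.append(pd.read_csv(p))
    if dists:
        allc = pd.concat(dists, ignore_index=True)
        allc.to_csv(report_dir / "cindex_by_signature.csv", index=False)
        if len(dists) < 3:
            log.warning("only %d signature distribution(s) present", len(dists))
        if plots:
            _violin_plot(allc, report_dir / "cindex_violin.png")
    else:
        missing.append("cindex_*.csv (rerun: survival)")

    if missing:
        raise StageError("missing artifacts: " + "; ".join(missing))
    return report_dir


def _violin_plot(cindex: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [s for s in ("high", "all", "low") if s in set(cindex["signature"])]
    data = [cindex.loc[cindex["signature"] == s, "c_index"] for s in order]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(order) + 1), [f"{s} ICC" for s in order])
    ax.set_ylabel("Concordance index")
    ax.axhline(0.5, ls=":", c="gray", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
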