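"""End-to-end experiment: simulate, preprocess, train, synthesize, evaluate.

Reproduces the study comparison at desk scale: a seeded phantom cohort is
split into train/validation/test, each translation variant is trained on
the preprocessed axial slices, synthetic CTs are generated for the test
cases, and image quality (ME/MAE/PSNR), structure agreement (DSC,
Hausdorff, subsite mean HU), DVH conservation and gamma pass rates are
aggregated into one report.  All randomness flows from a single master
seed through a documented per-stage derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dosimetry import (
    DVH_METRICS,
    GammaCriteria,
    PlanSpec,
    compute_arc_dose,
    dvh_curve,
    dvh_metric,
    gamma_evaluate,
)
from .grid import HU_MIN, VolumeGrid
from .metrics import dice, hausdorff, intensity_metrics, mean_hu, segment_subsites
from .models import (
    LossWeights,
    ModelBundle,
    TrainConfig,
    Variant,
    build_models,
    desk_train_config,
    generate_sct,
    train,
)
from .phantom import (
    PROSTATE,
    PairedCase,
    PhantomSpec,
    apply_misregistration,
    generate_phantom,
)
from .preprocess import PreprocessConfig, PreprocessedCase, preprocess_case

STAGE_NAMES = ("phantom", "misregistration", "split", "training", "evaluation")


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGE_NAMES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGE_NAMES, children)
    }


@dataclass
class ExperimentConfig:
    """Everything one run needs; defaults are the desk-scale preset."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_train: int = 8
    n_val: int = 2
    n_test: int = 4
    variants: tuple[Variant, ...] = (Variant.GAN, Variant.CYCGAN, Variant.RGGAN)
    train_config: TrainConfig = field(default_factory=lambda: desk_train_config(crop=(84, 84)))
    loss_weights: LossWeights = field(default_factory=LossWeights)
    model_scale: float = 0.15
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    plan: PlanSpec = field(default_factory=PlanSpec)
    gamma_criteria: tuple[GammaCriteria, ...] = (
        GammaCriteria(3.0, 2.0),
        GammaCriteria(2.0, 2.0),
    )
    ptv_margin_mm: float = 6.0
    misregister: bool = True
    compute_dose: bool = True
    # False: each dose is normalized to the prescription on its own volume
    # (the engine's contract); True: the sCT dose reuses the CT plan's scale
    # factor, emulating fixed monitor units
    fixed_plan_scale: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("split counts must be positive")
        self.variants = tuple(Variant(v) for v in self.variants)


@dataclass
class MetricsReport:
    image_quality: pd.DataFrame
    structures: pd.DataFrame
    dvh: pd.DataFrame
    gamma: pd.DataFrame
    statistics: pd.DataFrame
    loss_history: pd.DataFrame
    config_summary: dict
    flags: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd of the headline metrics per variant."""
        rows = []
        for variant, grp in self.image_quality.groupby("variant"):
            row = {"variant": variant}
            for col in ("me_hu", "mae_hu", "psnr_db"):
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


def make_cohort(config: ExperimentConfig) -> tuple[list[PairedCase], dict[str, list[int]]]:
    """Generate and (optionally) misalign the cohort, then split it."""
    seeds = derive_stage_seeds(config.master_seed)
    n = config.n_train + config.n_val + config.n_test
    rng_gen = np.random.default_rng(seeds["phantom"])
    rng_mis = np.random.default_rng(seeds["misregistration"])
    cases = []
    for _ in range(n):
        case = generate_phantom(config.phantom, int(rng_gen.integers(0, 2**31)))
        if config.misregister and not config.phantom.misregistration.is_identity():
            case = apply_misregistration(case, int(rng_mis.integers(0, 2**31)))
        cases.append(case)
    perm = np.random.default_rng(seeds["split"]).permutation(n)
    split = {
        "train": sorted(perm[: config.n_train].tolist()),
        "val": sorted(perm[config.n_train : config.n_train + config.n_val].tolist()),
        "test": sorted(perm[config.n_train + config.n_val :].tolist()),
    }
    return cases, split


def _ptv_mask(prep: PreprocessedCase, margin_mm: float) -> np.ndarray:
    """PTV = prostate label (CTV surrogate) expanded by an isotropic margin."""
    ctv = prep.labels == PROSTATE
    if not ctv.any():
        return ctv
    dt = ndimage.distance_transform_edt(~ctv, sampling=prep.ct.spacing)
    return dt <= margin_mm


def evaluate_case(
    prep: PreprocessedCase,
    sct: VolumeGrid,
    config: ExperimentConfig,
    ref_cache: dict | None = None,
) -> dict:
    """All evaluation metrics of one synthetic CT against its reference CT."""
    out: dict = {}
    fill = config.phantom.balloon_fill
    iq = intensity_metrics(prep.ct, sct, prep.body)
    out["image_quality"] = {"me_hu": iq.me_hu, "mae_hu": iq.mae_hu, "psnr_db": iq.psnr_db}

    ref_ss = ref_cache.get("structures") if ref_cache else None
    if ref_ss is None:
        ref_ss = segment_subsites(prep.ct, balloon_fill=fill)
        if ref_cache is not None:
            ref_cache["structures"] = ref_ss
    test_ss = segment_subsites(sct, balloon_fill=fill)
    rows = []
    for name in ("body", "bone", "rectal_balloon", "soft_tissue"):
        a, b = ref_ss[name], test_ss[name]
        row = {"structure": name, "dsc": dice(a, b)}
        row["hd_mm"] = hausdorff(a, b, prep.ct.spacing) if a.any() and b.any() else np.nan
        row["mean_hu_ref"] = mean_hu(prep.ct, a) if a.any() else np.nan
        row["mean_hu_test"] = mean_hu(sct, b) if b.any() else np.nan
        rows.append(row)
    out["structures"] = rows

    if config.compute_dose:
        ptv = _ptv_mask(prep, config.ptv_margin_mm)
        structures = ref_ss
        structures.masks["ptv"] = ptv
        ref_dose = ref_cache.get("dose") if ref_cache else None
        scale = ref_cache.get("dose_scale") if ref_cache else None
        if ref_dose is None:
            ref_dose, scale = compute_arc_dose(prep.ct, structures, config.plan, return_scale=True)
            if ref_cache is not None:
                ref_cache["dose"] = ref_dose
                ref_cache["dose_scale"] = scale
        eval_dose = compute_arc_dose(
            sct, structures, config.plan, scale=scale if config.fixed_plan_scale else None
        )
        ref_curve = dvh_curve(ref_dose, ptv, "ptv")
        ev_curve = dvh_curve(eval_dose, ptv, "ptv")
        dvh_rows = []
        for x in DVH_METRICS:
            r, e = dvh_metric(ref_curve, x), dvh_metric(ev_curve, x)
            dvh_rows.append(
                {
                    "structure": "ptv",
                    "metric": f"D{x:g}%",
                    "ref_gy": r,
                    "test_gy": e,
                    "rel_diff_pct": 100.0 * (e - r) / r if r != 0 else np.nan,
                }
            )
        out["dvh"] = dvh_rows
        out["gamma"] = [
            {
                "criterion": crit.label,
                "pass_rate_percent": gamma_evaluate(ref_dose, eval_dose, crit).pass_rate_percent,
            }
            for crit in config.gamma_criteria
        ]
    return out


def relative_dvh_difference(ref_metrics: dict[str, float], test_metrics: dict[str, float]) -> dict[str, float]:
    """Per-metric 100*(test-ref)/ref; NaN flags an undefined (zero-reference) entry."""
    if set(ref_metrics) != set(test_metrics):
        raise ValueError("metric sets differ")
    out = {}
    for k, r in ref_metrics.items():
        out[k] = np.nan if r == 0 else 100.0 * (test_metrics[k] - r) / r
    return out


def anova_bonferroni(groups: dict[str, list[float]]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise two-sample t-tests.

    Returns (F, p_anova, pairwise table).  Degenerate all-equal input
    reports p = 1 by convention.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[k]) < 2 for k in names):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        pairs = [
            {"group_a": a, "group_b": b, "p_adj": 1.0, "significant": False}
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        return 0.0, 1.0, pd.DataFrame(pairs)
    f_stat, p_anova = stats.f_oneway(*arrays)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
                p = 1.0
            else:
                _, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
            p_adj = min(1.0, float(p) * m)
            rows.append(
                {"group_a": a, "group_b": b, "p_adj": p_adj, "significant": p_adj < 0.05}
            )
    return float(f_stat), float(p_anova), pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> MetricsReport:
    """Execute the full comparison; deterministic given the master seed."""
    seeds = derive_stage_seeds(config.master_seed)
    cases, split = make_cohort(config)
    preps = {i: preprocess_case(cases[i], config.preprocess) for i in range(len(cases))}
    dataset = [p for i in split["train"] for p in preps[i].paired_slices()]

    flags: list[str] = []
    iq_rows, st_rows, dvh_rows, gm_rows, loss_rows = [], [], [], [], []
    ref_caches: dict[int, dict] = {i: {} for i in split["test"]}
    for vi, variant in enumerate(config.variants):
        bundle = build_models(variant, config.model_scale, seed=seeds["training"] + vi)
        tcfg = replace(config.train_config, seed=seeds["training"] + 1000 + vi)
        try:
            bundle, history = train(bundle, dataset, tcfg, config.loss_weights)
        except Exception as exc:  # noqa: BLE001 - flagged, report continues
            flags.append(f"training failed for {variant.value}: {exc}")
            continue
        for rec in history:
            loss_rows.append(
                {
                    "variant": variant.value,
                    "iteration": rec.iteration,
                    "adv_dis": rec.adv_dis,
                    "adv_gen": rec.adv_gen,
                    "cycle": rec.cycle,
                    "reference_mae": rec.reference_mae,
                    "total": rec.total,
                }
            )
        for i in split["test"]:
            prep = preps[i]
            sct = generate_sct(
                bundle, prep.mr_norm, prep.ct, crop_rows_cols=tcfg.crop_rows_cols
            )
            # body-mask the sCT (as the reference CT is): the zero-padded
            # inference border would otherwise read as ~1023 HU and distort
            # both auto-contours and the dose calculation
            sct = sct.with_values(np.where(prep.body, sct.values, HU_MIN))
            try:
                res = evaluate_case(prep, sct, config, ref_caches[i])
            except Exception as exc:  # noqa: BLE001
                flags.append(f"evaluation failed for {variant.value} on case {i}: {exc}")
                continue
            base = {"case": i, "variant": variant.value}
            iq_rows.append({**base, **res["image_quality"]})
            st_rows += [{**base, **r} for r in res["structures"]]
            dvh_rows += [{**base, **r} for r in res.get("dvh", [])]
            gm_rows += [{**base, **r} for r in res.get("gamma", [])]

    iq = pd.DataFrame(iq_rows)
    stats_rows = []
    if not iq.empty and iq["variant"].nunique() >= 2 and iq.groupby("variant").size().min() >= 2:
        for col in ("me_hu", "mae_hu", "psnr_db"):
            groups = {v: g[col].tolist() for v, g in iq.groupby("variant")}
            f_stat, p_anova, pairs = anova_bonferroni(groups)
            for _, row in pairs.iterrows():
                stats_rows.append(
                    {
                        "metric": col,
                        "F": f_stat,
                        "p_anova": p_anova,
                        "group_a": row["group_a"],
                        "group_b": row["group_b"],
                        "p_adj": row["p_adj"],
                    }
                )

    report = MetricsReport(
        image_quality=iq,
        structures=pd.DataFrame(st_rows),
        dvh=pd.DataFrame(dvh_rows),
        gamma=pd.DataFrame(gm_rows),
        statistics=pd.DataFrame(stats_rows),
        loss_history=pd.DataFrame(loss_rows),
        config_summary={
            "master_seed": config.master_seed,
            "stage_seeds": seeds,
            "split": split,
            "variants": [v.value for v in config.variants],
            "model_scale": config.model_scale,
            "grid_shape": list(config.phantom.shape),
            "spacing_mm": list(config.phantom.spacing),
        },
        flags=flags,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: MetricsReport, out_dir: str | Path, plots: bool = True) -> list[Path]:
    """CSV tables, JSON summary and overview plots; idempotent."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "image_quality": report.image_quality,
        "structures": report.structures,
        "dvh": report.dvh,
        "gamma": report.gamma,
        "statistics": report.statistics,
        "loss_history": report.loss_history,
    }
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    summary = {
        "config": report.config_summary,
        "flags": report.flags,
        "per_variant": report.summary().to_dict("records") if not report.image_quality.empty else [],
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, default=float))
    written.append(path)

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if not report.image_quality.empty:
            fig, axes = plt.subplots(1, 3, figsize=(12, 4))
            for ax, col in zip(axes, ("me_hu", "mae_hu", "psnr_db")):
                data = [
                    g[col].dropna().values for _, g in report.image_quality.groupby("variant")
                ]
                ax.boxplot(data, tick_labels=sorted(report.image_quality["variant"].unique()))
                ax.set_title(col)
            fig.tight_layout()
            p = out / "image_quality.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
        if not report.gamma.empty:
            fig, ax = plt.subplots(figsize=(6, 4))
            piv = report.gamma.pivot_table(
                index="criterion", columns="variant", values="pass_rate_percent"
            )
            piv.plot.bar(ax=ax)
            ax.set_ylabel("gamma pass rate (%)")
            fig.tight_layout()
            p = out / "gamma.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
        if not report.loss_history.empty:
            fig, ax = plt.subplots(figsize=(6, 4))
            for variant, g in report.loss_history.groupby("variant"):
                ax.plot(g["iteration"], g["total"], label=variant)
            ax.set_xlabel("iteration")
            ax.set_ylabel("weighted total loss")
            ax.legend()
            fig.tight_layout()
            p = out / "losses.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
    return written
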