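"""Pipeline orchestration, the summary metrics table, and dashboard figures.

``run_pipeline`` chains ingest -> selectivity -> mixing model ->
deviation/reliable-range -> ROC/AUC -> deconvolution for one dataset and
returns a :class:`DashboardResult` holding the metrics row (detection
counts per class, reliable-range limits, AUC over all and within-range
labels, deviation median and IQR, proportion segment-length sum) plus
the intermediate artifacts the figure panels need.

Three analysis modes follow the protocol variants: ``full`` (pures +
mixtures, replicated), ``baseline`` (banked pure profile + current
mixtures only) and ``single_replicate`` (first replicate of each sample;
ROC ranked by ordered ratios instead of paired-t p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .deconvolution import (
    ProportionEstimate,
    ProportionUncertainty,
    TargetGeometry,
    estimate_proportions,
    proportion_uncertainty,
    target_geometry,
)
from .design import MixtureDesign
from .discrimination import RocResult, paired_pvalues, roc_auc, unreplicated_scores
from .ingest import ExpressionTable, Log2Table, cq_to_log2, detect_filter, normalize_median_total, to_log2
from .mixture_model import observed_ratios, predict_mixture_signals, predicted_ratios
from .performance import (
    DEFAULT_TOLERANCE_LOG2,
    ReliableRange,
    bias_precision,
    deviation_table,
    reliable_range,
)
from .selectivity import (
    NON_SELECTIVE,
    ONE_TO_ONE,
    PureProfile,
    SelectivityClassification,
    class_counts,
    classify_selectivity,
    pure_profile,
)

__all__ = ["PipelineConfig", "DashboardResult", "run_pipeline", "render_dashboard", "metrics_to_table"]

Mode = Literal["full", "baseline", "single_replicate"]

# panel colors follow the reference-figure convention
_CLASS_COLORS = {
    "placenta_selective": "tab:red",
    "brain_selective": "tab:blue",
    ONE_TO_ONE: "gold",
    NON_SELECTIVE: "0.6",
}


@dataclass
class PipelineConfig:
    """Tunable analysis parameters with the conventional defaults."""

    pseudocount: float = 1.0
    detect_threshold: float = 1.0
    fold: float = 10.0
    equality_tol_log2: float = 0.5
    tolerance: float = DEFAULT_TOLERANCE_LOG2
    coverage: float = 0.95
    window_size: Optional[int] = None
    assess_upper: Optional[bool] = None  # default: only for intensity platforms
    min_range_records: int = 100  # below this the range is reported ND (e.g. PCR panels)
    n_boot: int = 300
    seed: int = 0


@dataclass
class DashboardResult:
    """One dataset's complete metrics row plus plot-ready artifacts.

    Every metric is either populated or None with the reason recorded in
    ``nd_reasons`` (rendered literally as "ND" in the summary table).
    """

    mode: Mode
    counts: dict[str, int]
    reliable: Optional[ReliableRange]
    auc_all: Optional[float]
    auc_within: Optional[float]
    deviation_median: float
    deviation_iqr: float
    proportion_sum: Optional[float]
    nd_reasons: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    @property
    def lower_limit(self) -> Optional[float]:
        return self.reliable.lower_limit if self.reliable and self.reliable.defined else None

    @property
    def upper_limit(self) -> Optional[float]:
        return self.reliable.upper_limit if self.reliable and self.reliable.defined else None

    @property
    def range_span(self) -> Optional[float]:
        return self.reliable.range_span if self.reliable and self.reliable.defined else None


def _preprocess(
    table: ExpressionTable, config: PipelineConfig
) -> tuple[ExpressionTable, Log2Table]:
    """Filter/normalize/log2 for genome-scale tables; negate Cq for PCR."""
    if table.platform_kind == "cq":
        return table, cq_to_log2(table)
    filtered = detect_filter(table, config.detect_threshold)
    normalized = normalize_median_total(filtered)
    return normalized, to_log2(normalized, config.pseudocount)


def run_pipeline(
    table: ExpressionTable,
    design: MixtureDesign,
    config: Optional[PipelineConfig] = None,
    mode: Mode = "full",
    baseline_profile: Optional[PureProfile] = None,
    round_id: Optional[str] = None,
) -> DashboardResult:
    """Execute the full analysis for one dataset and assemble its metrics.

    ``full`` requires pure and mixture samples in the table's manifest;
    ``baseline`` requires ``baseline_profile`` (a banked pure-component
    profile) and at least the mixtures; ``single_replicate`` restricts the
    table to replicate index 1 and ranks the ROC by ordered |log2 ratio|.
    """
    config = config or PipelineConfig()
    table.manifest.validate_against(design)
    nd: dict[str, str] = {}

    if mode == "single_replicate":
        rep1 = table.manifest.replicate(1)
        if not rep1.entries:
            raise ValueError("no replicate-index-1 samples for single_replicate mode")
        table = table.subset_samples(rep1.sample_ids)
    elif mode not in ("full", "baseline"):
        raise ValueError(f"unknown mode {mode!r}")

    manifest = table.manifest
    missing_mixes = [m for m in design.mixture_ids if not manifest.samples_for_role(f"mix:{m}")]
    if missing_mixes:
        raise ValueError(f"table lacks samples for mixtures: {missing_mixes}")
    if mode == "baseline":
        if baseline_profile is None:
            raise ValueError("baseline mode requires a baseline_profile")
    else:
        missing_pures = [
            c for c in design.component_ids if not manifest.samples_for_role(f"pure:{c}")
        ]
        if missing_pures:
            raise ValueError(f"table lacks samples for pure components: {missing_pures}")

    linear, log2_table = _preprocess(table, config)

    profile = baseline_profile if mode == "baseline" else pure_profile(linear)
    classification = classify_selectivity(
        profile, config.fold, config.equality_tol_log2, design=design
    )
    counts = class_counts(classification)

    pred = predict_mixture_signals(profile, design)
    pc = config.pseudocount if table.platform_kind != "cq" else 0.0
    ratios_pred = predicted_ratios(pred, pc)
    ratios_obs = observed_ratios(log2_table)
    devs = deviation_table(ratios_pred, ratios_obs, classification)
    bp = bias_precision(devs, by_class=True)

    assess_upper = config.assess_upper
    if assess_upper is None:
        assess_upper = table.platform_kind == "intensity"
    if len(devs) < config.min_range_records:
        reliable = None
        nd["reliable_range"] = (
            f"only {len(devs)} deviation records (< {config.min_range_records}); "
            "range not assessed"
        )
    else:
        reliable = reliable_range(
            devs, config.tolerance, config.coverage, config.window_size, assess_upper
        )
        if not reliable.defined:
            nd["reliable_range"] = reliable.reason or "not determined"

    n_reps = {
        m: len(manifest.samples_for_role(f"mix:{m}")) for m in design.mixture_ids
    }
    replicated = min(n_reps.values()) >= 2 and mode != "single_replicate"
    if replicated:
        ranking = paired_pvalues(log2_table)["pvalue"]
        kind = "pvalue"
    else:
        ranking = unreplicated_scores(ratios_obs)
        kind = "score"
    roc_all = roc_auc(ranking, classification, kind)
    if not roc_all.defined:
        nd["auc_all"] = roc_all.reason or "ND"
    if reliable is not None and reliable.defined:
        roc_within = roc_auc(
            ranking, classification, kind, range_filter=reliable, A_values=ratios_obs["A"]
        )
        if not roc_within.defined:
            nd["auc_within"] = roc_within.reason or "ND"
    else:
        roc_within = RocResult(None, None, 0, 0, True, False, reason="reliable range ND")
        nd["auc_within"] = "reliable range not determined"

    proportion_sum: Optional[float] = None
    estimate: Optional[ProportionEstimate] = None
    uncertainty: Optional[ProportionUncertainty] = None
    geometry: Optional[TargetGeometry] = None
    try:
        mixes_linear = linear if table.platform_kind != "cq" else None
        if mixes_linear is None:
            raise ValueError("deconvolution needs linear-scale signals (not Cq)")
        estimate = estimate_proportions(profile, mixes_linear, design)
        geometry = target_geometry(design, estimate)
        proportion_sum = estimate.length_sum
        uncertainty = proportion_uncertainty(
            profile, mixes_linear, design, n_boot=config.n_boot, seed=config.seed
        )
    except (ValueError, RuntimeError) as exc:
        nd["proportion_sum"] = str(exc)

    return DashboardResult(
        mode=mode,
        counts=counts,
        reliable=reliable,
        auc_all=roc_all.auc,
        auc_within=roc_within.auc,
        deviation_median=bp.median,
        deviation_iqr=bp.iqr,
        proportion_sum=proportion_sum,
        nd_reasons=nd,
        provenance={
            "mode": mode,
            "round_id": round_id,
            "platform_kind": table.platform_kind,
            "pseudocount": config.pseudocount,
            "detect_threshold": config.detect_threshold,
            "fold": config.fold,
            "equality_tol_log2": config.equality_tol_log2,
            "tolerance": config.tolerance,
            "coverage": config.coverage,
            "assess_upper": assess_upper,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "ranking": kind,
            "table_provenance": dict(table.provenance),
        },
        artifacts={
            "classification": classification,
            "ratios_pred": ratios_pred,
            "ratios_obs": ratios_obs,
            "deviations": devs,
            "bias_precision": bp,
            "roc_all": roc_all,
            "roc_within": roc_within,
            "estimate": estimate,
            "uncertainty": uncertainty,
            "geometry": geometry,
            "profile": profile,
        },
    )


def _fmt(v: Optional[float], digits: int = 3) -> str:
    return "ND" if v is None else f"{v:.{digits}f}"


def _ma_panel(ax, ratios, classification, title):
    cls = classification.class_of.reindex(ratios.index).fillna(NON_SELECTIVE)
    for label, color in _CLASS_COLORS.items():
        sub = ratios[cls == label]
        if not len(sub):
            continue
        filled = label != NON_SELECTIVE
        ax.scatter(
            sub["A"], sub["M"], s=6,
            c=color if filled else "none",
            edgecolors=color, linewidths=0.5, label=label, alpha=0.7,
        )
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("A (mean log2 signal)")
    ax.set_ylabel("M (log2 ratio)")
    ax.set_title(title)


def render_dashboard(
    result: DashboardResult,
    output_path: str | Path,
    formats: Sequence[str] = ("png",),
) -> list[Path]:
    """Render the multi-panel dashboard figure and its metrics table.

    Panels: predicted MA, observed MA, deviation vs signal with the
    reliable-range margins, per-class deviation box plot, ROC (solid =
    all labels, dashed = within range), and the proportion target plot
    with bootstrap ellipses.  Missing inputs leave an annotated empty
    panel.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    art = result.artifacts
    fig, axes = plt.subplots(2, 3, figsize=(15, 9))
    (ax_pred, ax_obs, ax_dev), (ax_box, ax_roc, ax_tgt) = axes
    classification: SelectivityClassification = art["classification"]

    _ma_panel(ax_pred, art["ratios_pred"], classification, "Predicted log2 ratios")
    _ma_panel(ax_obs, art["ratios_obs"], classification, "Observed log2 ratios")
    ax_pred.legend(fontsize=6, loc="upper left")

    devs = art["deviations"]
    cls = devs["class"] if "class" in devs else pd.Series(NON_SELECTIVE, index=devs.index)
    for label, color in _CLASS_COLORS.items():
        sub = devs[cls == label]
        if len(sub):
            ax_dev.scatter(sub["A_avg"], sub["D"], s=6, c=color, alpha=0.7)
    ax_dev.axhline(result.deviation_median, color="k", lw=1)
    for sign in (1, -1):
        ax_dev.axhline(
            result.deviation_median + sign * result.deviation_iqr / 2,
            color="k", lw=0.8, ls="--",
        )
    if result.reliable is not None and result.reliable.defined:
        ax_dev.axvspan(
            devs["A_avg"].min(), result.reliable.lower_limit, color="0.8", alpha=0.5
        )
        if result.reliable.upper_limit < devs["A_avg"].max():
            ax_dev.axvspan(
                result.reliable.upper_limit, devs["A_avg"].max(), color="0.8", alpha=0.5
            )
    else:
        ax_dev.annotate("margins not assessed", xy=(0.05, 0.92), xycoords="axes fraction",
                        fontsize=8)
    ax_dev.set_xlabel("average log2 signal")
    ax_dev.set_ylabel("D (observed - predicted M)")
    ax_dev.set_title("Deviation from predicted")

    order = [ONE_TO_ONE, "brain_selective", "placenta_selective", NON_SELECTIVE]
    groups = [devs.loc[cls == g, "D"].dropna() for g in order]
    present = [(g, v) for g, v in zip(order, groups) if len(v)]
    if present:
        bp = ax_box.boxplot(
            [v for _, v in present], tick_labels=[g for g, _ in present],
            patch_artist=True, whis=1.5, sym="k|",
        )
        for patch, (g, _) in zip(bp["boxes"], present):
            patch.set_facecolor(_CLASS_COLORS.get(g, "0.6"))
        ax_box.tick_params(axis="x", labelsize=6, rotation=20)
    ax_box.axhline(result.deviation_median, color="k", lw=1)
    ax_box.set_ylabel("D")
    ax_box.set_title("Deviation by class")

    for roc, style in ((art["roc_all"], "-"), (art["roc_within"], "--")):
        if roc is not None and roc.defined:
            ax_roc.plot(roc.points[:, 0], roc.points[:, 1], style, color="k",
                        label=f"AUC={roc.auc:.3f}" + (" (within)" if roc.restricted_to_range else ""))
    if not (art["roc_all"] is not None and art["roc_all"].defined):
        ax_roc.annotate("ND", xy=(0.45, 0.5), xycoords="axes fraction", fontsize=14)
    ax_roc.plot([0, 1], [0, 1], color="0.8", lw=0.5)
    ax_roc.set_xlabel("false positive rate")
    ax_roc.set_ylabel("true positive rate")
    ax_roc.set_title("Discrimination (designed truth)")
    ax_roc.legend(fontsize=7, loc="lower right")

    geometry = art["geometry"]
    if geometry is not None:
        comp_colors = {"liver": "gold", "brain": "tab:blue", "placenta": "tab:red"}
        for comp in geometry.centers.index:
            c = geometry.centers.loc[comp]
            e = geometry.endpoints.loc[comp]
            color = comp_colors.get(comp, "k")
            for r in (0.02, 0.04):
                ax_tgt.add_patch(
                    plt.Circle((c["x"], c["y"]), r, fill=False, color=color, lw=0.8)
                )
            ax_tgt.plot([c["x"], e["x"]], [c["y"], e["y"]], color=color, lw=1.5)
            ax_tgt.plot([e["x"]], [e["y"]], "o", color=color, ms=4)
            unc = art["uncertainty"]
            if unc is not None and comp in unc.ellipses and not unc.ellipses[comp].degenerate:
                ell = unc.ellipses[comp]
                evals, evecs = np.linalg.eigh(ell.cov)
                angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
                axes_len = 2 * np.sqrt(ell.chi2_quantile * np.clip(evals, 0, None))
                ax_tgt.add_patch(
                    MplEllipse(ell.center, width=axes_len[-1], height=axes_len[0],
                               angle=angle, fill=False, color=color, ls=":")
                )
        ax_tgt.set_xlim(0, 0.7)
        ax_tgt.set_ylim(0, 0.7)
        ax_tgt.set_xlabel("fraction in Mix1")
        ax_tgt.set_ylabel("fraction in Mix2")
    else:
        ax_tgt.annotate("deconvolution not available", xy=(0.1, 0.5),
                        xycoords="axes fraction", fontsize=9)
    ax_tgt.set_title(f"Deconvolved proportions (sum={_fmt(result.proportion_sum)})")

    metrics = metrics_to_table([result])
    fig.suptitle(
        "  ".join(f"{k}={v}" for k, v in metrics.iloc[0].items()), fontsize=7
    )
    fig.tight_layout(rect=(0, 0, 1, 0.96))

    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        p = output_path.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written


_TABLE_COLUMNS = [
    "round", "mode", "non_selective", "one_to_one", "brain", "placenta",
    "lower_limit", "upper_limit", "range", "auc_all", "auc_within",
    "median", "iqr", "proportion_sum",
]


def metrics_to_table(results: Sequence[DashboardResult]) -> pd.DataFrame:
    """One summary row per dataset/round; ND rendered literally.

    Column order is stable so rounds can be tracked longitudinally by
    appending rows.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "round": r.provenance.get("round_id") or "",
                "mode": r.mode,
                "non_selective": r.counts.get(NON_SELECTIVE, 0),
                "one_to_one": r.counts.get(ONE_TO_ONE, 0),
                "brain": r.counts.get("brain_selective", 0),
                "placenta": r.counts.get("placenta_selective", 0),
                "lower_limit": _fmt(r.lower_limit, 2),
                "upper_limit": _fmt(r.upper_limit, 2),
                "range": _fmt(r.range_span, 2),
                "auc_all": _fmt(r.auc_all),
                "auc_within": _fmt(r.auc_within),
                "median": _fmt(r.deviation_median),
                "iqr": _fmt(r.deviation_iqr),
                "proportion_sum": _fmt(r.proportion_sum),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
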