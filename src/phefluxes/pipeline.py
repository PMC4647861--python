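"""End-to-end pipeline: tables in, flux trajectories and comparisons out.

Stages: read/validate → fixed-intercept trend fits → consumption rate
(fitted for the control genotype, rescaled by emission fractions for
perturbed lines) → flux trajectories on the 6-min grid → delta-method
variances → genotype summaries (t₀/t₆ fluxes, v₂/v₁ ratios, percent changes
vs control) → between-genotype tests.  Deterministic given dataset, config
and seed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    GenotypeComparison,
    compare_absolute_fluxes,
    compare_flux_trends,
    scale_consumption_rate,
)
from .datamodel import (
    AnalysisConfig,
    LabelingDataset,
    extract_series,
    format_dataset,
    read_dataset,
)
from .fluxmodel import FluxSummary, FluxTrajectory, compute_fluxes, percent_change
from .trends import (
    estimate_consumption_rate,
    fit_fixed_intercept_slope,
    mean_tyrosine_labelling,
)


class PipelineStageError(RuntimeError):
    """An analysis stage failed; names the stage and the offending series."""

    def __init__(self, stage: str, series, cause: Exception):
        super().__init__(f"stage {stage!r} failed for series {series}: {cause}")
        self.stage = stage
        self.series = series


@dataclass
class PipelineResult:
    trajectories: pd.DataFrame  # genotype replicate time_h v1 v1_var v2 v2_var vc vc_var
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: dict
    warnings: list[str] = field(default_factory=list)
    replicate_trajectories: dict[str, list[FluxTrajectory]] = field(
        default_factory=dict
    )
    mean_trajectories: dict[str, FluxTrajectory] = field(default_factory=dict)


def _fit_replicate(
    dataset: LabelingDataset,
    genotype: str,
    replicate: str,
    config: AnalysisConfig,
    vc: float,
    vc_variance: float,
) -> FluxTrajectory:
    from .uncertainty import flux_variances

    stage, series = "trend_fit", (genotype, replicate)
    try:
        t, y, c0 = extract_series(dataset, genotype, replicate, "pool_phe")
        pool_trend = fit_fixed_intercept_slope(t, y, c0)
        t, y, f0 = extract_series(dataset, genotype, replicate, "frac_phe")
        frac_trend = fit_fixed_intercept_slope(t, y, f0)
        _, fty, _ = extract_series(dataset, genotype, replicate, "frac_tyr")
        f_tyr, f_tyr_var = mean_tyrosine_labelling(fty)
        stage = "flux_computation"
        traj = compute_fluxes(
            pool_trend,
            frac_trend,
            f_tyr,
            vc,
            config.grid,
            balance=config.enrichment_balance,
            genotype=genotype,
            replicate=replicate,
        )
        stage = "error_propagation"
        traj.v1_variance, traj.v2_variance = flux_variances(
            pool_trend,
            frac_trend,
            f_tyr,
            f_tyr_var,
            vc,
            vc_variance,
            config.grid,
            balance=config.enrichment_balance,
            include_f_tyr_variance=config.include_f_tyr_variance,
        )
        traj.vc_variance = vc_variance
        traj.meta.update(
            {
                "pool_slope": pool_trend.slope,
                "pool_slope_variance": pool_trend.slope_variance,
                "frac_slope": frac_trend.slope,
                "frac_slope_variance": frac_trend.slope_variance,
                "f_tyr_variance": f_tyr_var,
            }
        )
        return traj
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, series, exc) from exc


def _pooled_dataset(dataset: LabelingDataset, config: AnalysisConfig) -> LabelingDataset:
    """Collapse replicates into one pseudo-replicate per genotype.

    All post-feeding points of a genotype enter one fit; the intercept is
    the mean of the replicate t₀ measurements.
    """
    frame = dataset.frame
    rows = []
    for (genotype, variable), sub in frame.groupby(["genotype", "variable"], sort=False):
        at0 = sub[sub["time_h"] == 0.0]
        rows.append((genotype, "pooled", 0.0, variable, float(at0["value"].mean())))
        later = sub[sub["time_h"] > 0.0]
        for r in later.itertuples(index=False):
            rows.append((genotype, "pooled", r.time_h, variable, r.value))
    pooled = pd.DataFrame(rows, columns=list(dataset.frame.columns))
    # replicates share harvest times, which the schema forbids within one
    # series; collapsing ties to their mean keeps the identical least-squares
    # slope (equal time leverage) while satisfying the uniqueness invariant

    pooled = (
        pooled.groupby(["genotype", "replicate", "variable", "time_h"], sort=False)[
            "value"
        ]
        .mean()
        .reset_index()[list(dataset.frame.columns)]
    )
    return LabelingDataset.from_frame(pooled, dict(dataset.metadata))


def _consumption_rates(
    dataset: LabelingDataset, config: AnalysisConfig
) -> dict[str, dict[str, tuple[float, float]]]:
    """(vc, vc_variance) per genotype/replicate.

    Control replicates get their own emission-slope fit.  Genotypes listed in
    ``rnai_emission_fractions`` get the mean control v_c scaled by the mean
    emission fraction, with the variance of the mean control v_c scaled by
    the squared fraction.
    """
    out: dict[str, dict[str, tuple[float, float]]] = {}
    control = config.control_genotype
    control_vcs: list[tuple[float, float]] = []
    if control in dataset.genotypes:
        out[control] = {}
        for rep in dataset.replicates(control):
            t, y, _ = extract_series(dataset, control, rep, "emission_total")
            trend = estimate_consumption_rate(t, y, strict=config.strict_emission)
            out[control][rep] = (trend.slope, trend.slope_variance)
            control_vcs.append((trend.slope, trend.slope_variance))
    for genotype in dataset.genotypes:
        if genotype == control:
            continue
        out[genotype] = {}
        fractions = config.rnai_emission_fractions.get(genotype)
        if fractions is not None:
            if not control_vcs:
                raise PipelineStageError(
                    "consumption_rate",
                    genotype,
                    ValueError("no control genotype to rescale v_c from"),
                )
            mean_vc = float(np.mean([v for v, _ in control_vcs]))
            var_mean_vc = float(
                np.sum([s for _, s in control_vcs]) / len(control_vcs) ** 2
            )
            frac = float(np.mean(np.atleast_1d(fractions)))
            vc = scale_consumption_rate(mean_vc, np.atleast_1d(fractions))
            vc_var = frac**2 * var_mean_vc
            for rep in dataset.replicates(genotype):
                out[genotype][rep] = (vc, vc_var)
        else:
            for rep in dataset.replicates(genotype):
                t, y, _ = extract_series(dataset, genotype, rep, "emission_total")
                trend = estimate_consumption_rate(t, y, strict=config.strict_emission)
                out[genotype][rep] = (trend.slope, trend.slope_variance)
    return out


def _mean_trajectory(trajs: list[FluxTrajectory], genotype: str) -> FluxTrajectory:
    """Across-replicate mean trajectory; variances are of the mean."""
    n = len(trajs)
    grid = trajs[0].grid
    return FluxTrajectory(
        grid=grid,
        v1=np.mean([t.v1 for t in trajs], axis=0),
        v2=np.mean([t.v2 for t in trajs], axis=0),
        vc=float(np.mean([t.vc for t in trajs])),
        v1_variance=np.sum([t.v1_variance for t in trajs], axis=0) / n**2,
        v2_variance=np.sum([t.v2_variance for t in trajs], axis=0) / n**2,
        vc_variance=float(np.sum([t.vc_variance for t in trajs]) / n**2),
        genotype=genotype,
        replicate="mean",
    )


def fit_fluxes(
    dataset: LabelingDataset, config: AnalysisConfig
) -> dict[str, list[FluxTrajectory]]:
    """Per-genotype replicate flux trajectories (the pipeline's core fit)."""
    working = dataset if config.pooling == "replicate" else _pooled_dataset(
        dataset, config
    )
    vc_map = _consumption_rates(working, config)
    out: dict[str, list[FluxTrajectory]] = {}
    for genotype in working.genotypes:
        out[genotype] = [
            _fit_replicate(working, genotype, rep, config, *vc_map[genotype][rep])
            for rep in working.replicates(genotype)
        ]
    return out


def _summaries(
    fits: dict[str, list[FluxTrajectory]],
    means: dict[str, FluxTrajectory],
    config: AnalysisConfig,
) -> pd.DataFrame:
    control = config.control_genotype
    i0, i6 = 0, -1
    rows = []
    for genotype, mean in means.items():
        n = len(fits[genotype])
        summary = FluxSummary(
            genotype=genotype,
            v1_t0=float(mean.v1[i0]),
            v1_t6=float(mean.v1[i6]),
            v2_t0=float(mean.v2[i0]),
            v2_t6=float(mean.v2[i6]),
            ratio_t6=float(mean.v2[i6] / mean.v1[i6])
            if mean.v1[i6] != 0
            else float("nan"),
            v1_t0_se=float(np.sqrt(mean.v1_variance[i0])),
            v1_t6_se=float(np.sqrt(mean.v1_variance[i6])),
            v2_t0_se=float(np.sqrt(mean.v2_variance[i0])),
            v2_t6_se=float(np.sqrt(mean.v2_variance[i6])),
            n_replicates=n,
        )
        row = summary.__dict__.copy()
        row["vc"] = mean.vc
        row["vc_se"] = float(np.sqrt(mean.vc_variance))
        if control in means and genotype != control:
            ref = means[control]
            row["v1_t0_pct_change_vs_control"] = percent_change(
                float(ref.v1[i0]), summary.v1_t0
            )
            row["v1_t6_pct_change_vs_control"] = percent_change(
                float(ref.v1[i6]), summary.v1_t6
            )
        else:
            row["v1_t0_pct_change_vs_control"] = float("nan")
            row["v1_t6_pct_change_vs_control"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _comparisons(
    fits: dict[str, list[FluxTrajectory]],
    means: dict[str, FluxTrajectory],
    config: AnalysisConfig,
) -> list[GenotypeComparison]:
    control = config.control_genotype
    if control not in fits:
        return []
    others = [g for g in fits if g != control]
    if not others:
        return []
    grid = means[control].grid
    t0, t6 = float(grid[0]), float(grid[-1])
    # family of absolute-flux tests: v1 and v2 at t0 and t6 per genotype pair
    m = config.bonferroni_m or 4 * len(others)
    results: list[GenotypeComparison] = []
    for genotype in others:
        a, b = fits[control], fits[genotype]
        for which, t, idx in (
            ("v1", t0, 0),
            ("v1", t6, -1),
            ("v2", t0, 0),
            ("v2", t6, -1),
        ):
            if config.pooling == "replicate":
                results.append(
                    compare_absolute_fluxes(
                        [getattr(tr, which)[idx] for tr in a],
                        [getattr(tr, which)[idx] for tr in b],
                        m=m,
                        pair=(control, genotype),
                        quantity=which,
                        time_h=t,
                    )
                )
            else:
                ta, tb = means[control], means[genotype]
                results.append(
                    compare_absolute_fluxes(
                        [getattr(ta, which)[idx]],
                        [getattr(tb, which)[idx]],
                        m=m,
                        pair=(control, genotype),
                        quantity=which,
                        time_h=t,
                        variances_a=[getattr(ta, f"{which}_variance")[idx]],
                        variances_b=[getattr(tb, f"{which}_variance")[idx]],
                        mode="pooled",
                    )
                )
        trend_mode = "slopes" if config.pooling == "replicate" else "paired_times"
        trend_args = (a, b) if trend_mode == "slopes" else ([means[control]], [means[genotype]])
        results.append(
            compare_flux_trends(
                *trend_args,
                m=1,
                pair=(control, genotype),
                which="v2",
                mode=trend_mode,
            )
        )
    return results


def _trajectory_table(fits: dict[str, list[FluxTrajectory]]) -> pd.DataFrame:
    frames = []
    for genotype, trajs in fits.items():
        for traj in trajs:
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": genotype,
                        "replicate": traj.replicate,
                        "time_h": traj.grid,
                        "v1": traj.v1,
                        "v1_var": traj.v1_variance,
                        "v2": traj.v2,
                        "v2_var": traj.v2_variance,
                        "vc": traj.vc,
                        "vc_var": traj.vc_variance,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    dataset: LabelingDataset | str | Path,
    config: AnalysisConfig | str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a dataset and collect tables plus provenance."""
    if isinstance(config, (str, Path)):
        config = AnalysisConfig.from_yaml(config)
    config = config or AnalysisConfig()
    if isinstance(dataset, (str, Path)):
        dataset = read_dataset(dataset, config)

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fits = fit_fluxes(dataset, config)
        means = {g: _mean_trajectory(t, g) for g, t in fits.items()}
        summaries = _summaries(fits, means, config)
        comparisons = _comparisons(fits, means, config)
        collected = [str(w.message) for w in caught]
    if dataset.metadata.get("clipped_fractions"):
        collected.append(
            f"{dataset.metadata['clipped_fractions']} fraction observation(s) "
            "clipped to [0, 1] during generation"
        )

    comp_df = pd.DataFrame(
        [
            {
                "comparison": f"{c.pair[0]}_vs_{c.pair[1]}",
                "quantity": c.quantity,
                "time_h": c.time_h,
                "estimate_a": c.estimate_a,
                "estimate_b": c.estimate_b,
                "stat": c.stat,
                "p_raw": c.p_raw,
                "p_corrected": c.p_corrected,
                "mode": c.mode,
                "n_a": c.n_a,
                "n_b": c.n_b,
            }
            for c in comparisons
        ]
    )
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            repr(sorted(config.__dict__.items())).encode()
        ).hexdigest()[:16],
        "input_digest": hashlib.sha256(format_dataset(dataset).encode()).hexdigest()[
            :16
        ],
        "pooling": config.pooling,
        "enrichment_balance": config.enrichment_balance,
    }
    return PipelineResult(
        trajectories=_trajectory_table(fits),
        summaries=summaries,
        comparisons=comp_df,
        provenance=provenance,
        warnings=collected,
        replicate_trajectories=fits,
        mean_trajectories=means,
    )


def report_summary(result: PipelineResult) -> str:
    """Fixed-template text report of the pipeline outcome."""
    lines = [
        "Phenylalanine pathway flux partitioning",
        "=" * 39,
        f"version {result.provenance['version']}  "
        f"config {result.provenance['config_hash']}  "
        f"input {result.provenance['input_digest']}",
        "",
        "Fluxes at window endpoints (nmol/gFW/h, mean +/- s.e.)",
    ]
    for row in result.summaries.itertuples(index=False):
        lines.append(
            f"  {row.genotype} (n={row.n_replicates}): "
            f"v1(t0)={row.v1_t0:.3f}+/-{row.v1_t0_se:.3f}  "
            f"v1(t6)={row.v1_t6:.3f}+/-{row.v1_t6_se:.3f}  "
            f"v2(t0)={row.v2_t0:.3f}+/-{row.v2_t0_se:.3f}  "
            f"v2(t6)={row.v2_t6:.3f}+/-{row.v2_t6_se:.3f}  "
            f"vc={row.vc:.3f}  v2/v1(t6)={row.ratio_t6:.3f}"
        )
        if np.isfinite(row.v1_t0_pct_change_vs_control):
            lines.append(
                f"    v1 vs control: {row.v1_t0_pct_change_vs_control:.1f}% lower "
                f"at t0, {row.v1_t6_pct_change_vs_control:.1f}% lower at t6"
            )
    if len(result.comparisons):
        lines += ["", "Genotype comparisons"]
        for row in result.comparisons.itertuples(index=False):
            when = f"t={row.time_h:g} h" if np.isfinite(row.time_h) else "trend"
            lines.append(
                f"  {row.comparison} {row.quantity} ({when}, {row.mode}): "
                f"{row.estimate_a:.3f} vs {row.estimate_b:.3f}, "
                f"p_raw={row.p_raw:.4g}, p_corrected={row.p_corrected:.4g}"
            )
    if result.warnings:
        lines += ["", "Warnings"]
        lines += [f"  - {w}" for w in result.warnings]
    return "\n".join(lines) + "\n"


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the flux, summary and comparison TSVs plus report and log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fluxes": outdir / "fluxes.tsv",
        "summary": outdir / "summary.tsv",
        "comparisons": outdir / "comparisons.tsv",
        "report": outdir / "report.txt",
        "log": outdir / "run.log",
    }
    result.trajectories.to_csv(
        paths["fluxes"], sep="\t", index=False, float_format="%.10g"
    )
    result.summaries.to_csv(
        paths["summary"], sep="\t", index=False, float_format="%.10g"
    )
    result.comparisons.to_csv(
        paths["comparisons"], sep="\t", index=False, float_format="%.10g"
    )
    paths["report"].write_text(report_summary(result))
    log_lines = [f"provenance: {result.provenance}"] + [
        f"warning: {w}" for w in result.warnings
    ]
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
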