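"""Fit the flux model to the synthetic study and plot the trajectories.

Runs the full pipeline (fixed-intercept trends → v_c → flux inversion →
delta-method variances) on results/synthetic/data.tsv and writes the flux,
summary and comparison tables plus a trajectory figure to results/fluxes/.

Run analysis/01_simulate_labeling.py first.
"""

from pathlib import Path

from phefluxes import run_pipeline, write_outputs

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "synthetic" / "data.tsv"
    if not data.exists():
        raise SystemExit("run analysis/01_simulate_labeling.py first")
    result = run_pipeline(data, ROOT / "synthetic" / "config.yaml")
    outdir = ROOT / "fluxes"
    write_outputs(result, outdir)
    _plot(result, outdir / "flux_trajectories.png")
    print((outdir / "report.txt").read_text())


def _plot(result, path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping figure")
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    colors = {"control": "tab:blue", "rnai": "tab:red"}
    for genotype, mean in result.mean_trajectories.items():
        for ax, which in zip(axes, ("v1", "v2")):
            y = getattr(mean, which)
            se = getattr(mean, f"{which}_variance") ** 0.5
            ax.plot(mean.grid, y, label=genotype, color=colors.get(genotype))
            ax.fill_between(
                mean.grid, y - se, y + se, alpha=0.25, color=colors.get(genotype)
            )
    axes[0].set_ylabel("flux (nmol gFW$^{-1}$ h$^{-1}$)")
    axes[0].set_title("plastidial arogenate pathway $v_1$")
    axes[1].set_title("cytosolic phenylpyruvate pathway $v_2$")
    for ax in axes:
        ax.set_xlabel("time after feeding (h)")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
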