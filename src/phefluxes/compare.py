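"""Statistical comparison of fluxes between genotypes.

Absolute fluxes at a given time are compared by a two-tailed two-sample
t-test (Welch by default — safer than the pooled-variance form for the
unbalanced n = 3 control vs n = 6 RNAi design) with Bonferroni correction
over the family of comparisons.  The rate of change of the cytosolic flux is
compared either on per-replicate v₂ slopes (independent two-sample test,
default) or by pairing genotype-mean v₂ values at matched grid times
(paired t-test); which mode produced a result is recorded in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fluxmodel import FluxTrajectory


class InsufficientReplicatesError(ValueError):
    """A t-test was requested with fewer than two values in a group."""


class GridMismatchError(ValueError):
    """Trajectories to be compared do not share a time grid."""


@dataclass(frozen=True)
class GenotypeComparison:
    """Outcome of one genotype-vs-genotype test."""

    pair: tuple[str, str]
    quantity: str
    time_h: float  # NaN for whole-window quantities such as slopes
    estimate_a: float
    estimate_b: float
    stat: float
    p_raw: float
    p_corrected: float
    mode: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1 or not 0 <= self.p_corrected <= 1:
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_corrected < self.p_raw - 1e-12:
            raise ValueError("corrected p cannot be below raw p")


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p-value, min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def scale_consumption_rate(vc_control: float, emission_fractions) -> float:
    """Consumption rate of a perturbed genotype.

    The RNAi lines' v_c is not re-measured; it is the control v_c times the
    mean fractional total emission of the lines relative to control.
    """
    fractions = np.asarray(emission_fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty emission fraction list")
    if np.any(fractions <= 0):
        raise ValueError("emission fractions must be > 0")
    if vc_control < 0:
        raise ValueError("vc_control must be >= 0")
    return float(vc_control * fractions.mean())


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t-test robust to the zero-variance corner cases."""
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def compare_absolute_fluxes(
    group_a,
    group_b,
    m: int = 1,
    pair: tuple[str, str] = ("a", "b"),
    quantity: str = "flux",
    time_h: float = float("nan"),
    variances_a=None,
    variances_b=None,
    mode: str = "welch",
) -> GenotypeComparison:
    """Compare flux values between two genotypes at one time point.

    ``mode='welch'`` (default) treats per-replicate flux estimates as the
    samples.  ``mode='pooled'`` compares two pooled point estimates with
    delta-method variances by a z-style statistic; ``group_a``/``group_b``
    are then length-1 and ``variances_a``/``variances_b`` required.
    """
    a = np.atleast_1d(np.asarray(group_a, dtype=float))
    b = np.atleast_1d(np.asarray(group_b, dtype=float))
    if mode == "welch":
        if a.size < 2 or b.size < 2:
            raise InsufficientReplicatesError(
                "Welch mode needs >=2 replicate values per group"
            )
        stat, p_raw = _welch(a, b)
    elif mode == "pooled":
        if variances_a is None or variances_b is None:
            raise ValueError("pooled mode requires propagated variances")
        va = float(np.sum(np.atleast_1d(variances_a)))
        vb = float(np.sum(np.atleast_1d(variances_b)))
        se = np.sqrt(va + vb)
        if se == 0.0:
            stat = 0.0 if a.mean() == b.mean() else float(np.inf)
        else:
            stat = float((a.mean() - b.mean()) / se)
        p_raw = float(2.0 * stats.norm.sf(abs(stat))) if np.isfinite(stat) else 0.0
        if stat == 0.0:
            p_raw = 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GenotypeComparison(
        pair=pair,
        quantity=quantity,
        time_h=time_h,
        estimate_a=float(a.mean()),
        estimate_b=float(b.mean()),
        stat=stat,
        p_raw=p_raw,
        p_corrected=bonferroni(p_raw, m),
        mode=mode,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def trajectory_slope(traj: FluxTrajectory, which: str = "v2") -> float:
    """Ordinary least-squares slope of a flux trajectory over its grid."""
    y = getattr(traj, which)
    return float(np.polyfit(traj.grid, y, 1)[0])


def compare_flux_trends(
    trajs_a,
    trajs_b,
    m: int = 1,
    pair: tuple[str, str] = ("a", "b"),
    which: str = "v2",
    mode: str = "slopes",
) -> GenotypeComparison:
    """Test whether the rate of change of a flux differs between genotypes.

    ``mode='slopes'`` (default): per-replicate trajectory slopes compared as
    independent samples (Welch).  The genotypes are unpaired, so a literally
    paired test of slopes is not possible; ``mode='paired_times'`` instead
    pairs the genotype-mean flux values at matched grid times and applies a
    paired two-tailed t-test.  The mode used is recorded in the result.
    """
    trajs_a = list(trajs_a)
    trajs_b = list(trajs_b)
    grids = [t.grid for t in trajs_a + trajs_b]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise GridMismatchError("trajectories are not on a common grid")

    if mode == "slopes":
        slopes_a = np.array([trajectory_slope(t, which) for t in trajs_a])
        slopes_b = np.array([trajectory_slope(t, which) for t in trajs_b])
        if slopes_a.size < 2 or slopes_b.size < 2:
            raise InsufficientReplicatesError(
                "slope mode needs >=2 replicate trajectories per group"
            )
        stat, p_raw = _welch(slopes_a, slopes_b)
        est_a, est_b = float(slopes_a.mean()), float(slopes_b.mean())
        n_a, n_b = slopes_a.size, slopes_b.size
    elif mode == "paired_times":
        mean_a = np.mean([getattr(t, which) for t in trajs_a], axis=0)
        mean_b = np.mean([getattr(t, which) for t in trajs_b], axis=0)
        diff = mean_a - mean_b
        if np.allclose(diff, diff[0]) and diff.std(ddof=1) == 0.0:
            # identical (or uniformly offset) mean trajectories: no evidence
            # of differing values at matched times beyond a constant
            stat, p_raw = (0.0, 1.0) if diff[0] == 0.0 else (float(np.inf), 0.0)
        else:
            stat, p_raw = stats.ttest_rel(mean_a, mean_b)
            stat, p_raw = float(stat), float(p_raw)
        est_a, est_b = float(mean_a.mean()), float(mean_b.mean())
        n_a, n_b = len(trajs_a), len(trajs_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return GenotypeComparison(
        pair=pair,
        quantity=f"{which}_trend",
        time_h=float("nan"),
        estimate_a=est_a,
        estimate_b=est_b,
        stat=stat,
        p_raw=p_raw,
        p_corrected=bonferroni(p_raw, m),
        mode=mode,
        n_a=n_a,
        n_b=n_b,
    )
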