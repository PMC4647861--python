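"""First-order (delta-method) error propagation for the flux estimates.

For y = f(x₁, …, xₙ) with independent inputs,

    Var(y) ≈ Σᵢ (∂f/∂xᵢ)² · Var(xᵢ).

The random inputs of the flux model are the two fitted slopes (dC/dt, df/dt),
the consumption rate v_c, and optionally the mean tyrosine labelling f_Tyr;
the measured t = 0 intercepts are treated as constants and contribute no
variance.  A seeded Monte-Carlo resampler serves as the independent check on
the analytic propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluxmodel import ZeroTyrosineLabellingError, labelled_pool_rate
from .trends import LinearTrend, evaluate_trend


@dataclass(frozen=True)
class VarianceBudget:
    """Per-input contributions to one output variance."""

    names: tuple[str, ...]
    variances: tuple[float, ...]
    partials: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.names) == len(self.variances) == len(self.partials):
            raise ValueError("names, variances and partials must align")
        if any(v < 0 for v in self.variances):
            raise ValueError("input variances must be >= 0")

    @property
    def output_variance(self) -> float:
        return float(
            sum(p * p * v for p, v in zip(self.partials, self.variances))
        )


def propagate_variance(partials, variances) -> float:
    """Delta-method output variance Σ (∂f/∂xᵢ)²·Var(xᵢ), inputs independent."""
    p = np.asarray(partials, dtype=float)
    v = np.asarray(variances, dtype=float)
    if p.shape != v.shape:
        raise ValueError("partials and variances must have equal length")
    if np.any(v < 0):
        raise ValueError("variances must be >= 0")
    return float(np.sum(p * p * v))


def _flux_partials(
    pool_trend: LinearTrend,
    frac_trend: LinearTrend,
    f_tyr: float,
    vc: float,
    grid: np.ndarray,
    balance: str,
):
    """Analytic partials of v₁, v₂ w.r.t. (dC/dt, df/dt, v_c, f_Tyr).

    With C(t) = C₀ + b_C t and f(t) = f₀ + b_f t (intercepts constant), the
    labelled-pool rate N(t) = f·b_C + C·b_f + v_c·f (product rule) or
    C·b_f + v_c·f (enrichment-only), and v₂ = N/f_Tyr, v₁ = b_C − v₂ + v_c.
    """
    t = np.asarray(grid, dtype=float)
    C = evaluate_trend(pool_trend, t)
    f = evaluate_trend(frac_trend, t)
    b_C, b_f = pool_trend.slope, frac_trend.slope
    N = labelled_pool_rate(C, b_C, f, b_f, balance) + vc * f
    if balance == "product_rule":
        dv2_dbC = (f + t * b_f) / f_tyr
        dv2_dbf = (t * b_C + C + vc * t) / f_tyr
    else:  # enrichment_only: N = C*b_f + vc*f
        dv2_dbC = (t * b_f) / f_tyr
        dv2_dbf = (C + vc * t) / f_tyr
    dv2_dvc = f / f_tyr
    dv2_dft = -N / f_tyr**2
    v2_partials = (dv2_dbC, dv2_dbf, dv2_dvc, dv2_dft)
    v1_partials = (1.0 - dv2_dbC, -dv2_dbf, 1.0 - dv2_dvc, -dv2_dft)
    return v1_partials, v2_partials


def flux_variances(
    pool_trend: LinearTrend,
    frac_trend: LinearTrend,
    f_tyr: float,
    f_tyr_variance: float,
    vc: float,
    vc_variance: float,
    grid,
    balance: str = "product_rule",
    include_f_tyr_variance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-point delta-method variances of v₁ and v₂.

    Intercepts are constants (zero variance); whether f_Tyr uncertainty
    enters the budget is a configuration toggle (default: it does).
    """
    if f_tyr <= 0:
        raise ZeroTyrosineLabellingError("f_tyr must be positive")
    for name, value in (
        ("pool slope", pool_trend.slope_variance),
        ("fraction slope", frac_trend.slope_variance),
        ("f_tyr", f_tyr_variance),
        ("vc", vc_variance),
    ):
        if value < 0:
            raise ValueError(f"negative variance for {name}")
    grid = np.asarray(grid, dtype=float)
    v1_partials, v2_partials = _flux_partials(
        pool_trend, frac_trend, f_tyr, vc, grid, balance
    )
    ft_var = f_tyr_variance if include_f_tyr_variance else 0.0
    variances = (
        pool_trend.slope_variance,
        frac_trend.slope_variance,
        vc_variance,
        ft_var,
    )
    var_v1 = sum(p * p * v for p, v in zip(v1_partials, variances))
    var_v2 = sum(p * p * v for p, v in zip(v2_partials, variances))
    return np.broadcast_to(var_v1, grid.shape).astype(float), np.broadcast_to(
        var_v2, grid.shape
    ).astype(float)


def monte_carlo_flux_variance(
    pool_trend: LinearTrend,
    frac_trend: LinearTrend,
    f_tyr: float,
    f_tyr_variance: float,
    vc: float,
    vc_variance: float,
    grid,
    n_draws: int = 100_000,
    seed: int = 0,
    balance: str = "product_rule",
    include_f_tyr_variance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical flux variances from normal resampling of the inputs.

    Inputs are drawn independently around their point estimates; fractions
    drawn outside (0, 1] are rejected and redrawn so the v₂ equation stays
    well posed.  Deterministic for a given seed.  Used as the independent
    oracle for :func:`flux_variances`.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)

    b_C = rng.normal(pool_trend.slope, np.sqrt(pool_trend.slope_variance), n_draws)
    b_f = rng.normal(frac_trend.slope, np.sqrt(frac_trend.slope_variance), n_draws)
    vc_d = rng.normal(vc, np.sqrt(vc_variance), n_draws)
    if include_f_tyr_variance and f_tyr_variance > 0:
        ft = rng.normal(f_tyr, np.sqrt(f_tyr_variance), n_draws)
        bad = (ft <= 0) | (ft > 1)
        while bad.any():
            ft[bad] = rng.normal(f_tyr, np.sqrt(f_tyr_variance), int(bad.sum()))
            bad = (ft <= 0) | (ft > 1)
    else:
        ft = np.full(n_draws, f_tyr)

    t = grid[None, :]
    C = pool_trend.intercept + b_C[:, None] * t
    f = frac_trend.intercept + b_f[:, None] * t
    N = labelled_pool_rate(C, b_C[:, None], f, b_f[:, None], balance)
    v2 = (N + vc_d[:, None] * f) / ft[:, None]
    v1 = b_C[:, None] - v2 + vc_d[:, None]
    return v1.var(axis=0, ddof=1), v2.var(axis=0, ddof=1)
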