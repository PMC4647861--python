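"""Mass-balance flux partitioning between the two phenylalanine pathways.

Phenylalanine is made by two parallel routes: the plastidial arogenate
pathway (flux v₁, nmol·gFW⁻¹·h⁻¹) whose product is unlabelled in a
¹⁵N-tyrosine feeding experiment, and the cytosolic phenylpyruvate pathway
(flux v₂) which uses tyrosine as amino donor and is therefore the only entry
route for the ¹⁵N label.  Phenylalanine is consumed into volatiles at a
constant rate v_c.  The dynamic balances around the free phenylalanine pool
C(t) and its labelled sub-pool f(t)·C(t) are

    dC/dt          = v₁ + v₂ − v_c                      (total pool)
    d(f·C)/dt      = v₂·f_Tyr − v_c·f                   (labelled pool)

where f is the phenylalanine ¹⁵N fraction and f_Tyr the (pseudo-steady)
tyrosine ¹⁵N fraction.  Inverting for the unknown pathway fluxes:

    v₂(t) = [d(f·C)/dt + v_c·f(t)] / f_Tyr
    v₁(t) = dC/dt − v₂(t) + v_c

With C(t) and f(t) affine (fixed-intercept fits), d(f·C)/dt is the exact
product rule f·(dC/dt) + C·(df/dt), and v₁, v₂ are evaluated on a 6-min grid
over the feeding window.  An ``enrichment_only`` variant replaces the
labelled-pool rate by C·(df/dt), i.e. ignores dilution of the enrichment by
pool growth; the full product rule is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trends import LinearTrend, evaluate_trend

BALANCE_VARIANTS = ("product_rule", "enrichment_only")


class ZeroTyrosineLabellingError(ZeroDivisionError):
    """f_Tyr <= 0 makes the labelled-pool balance (the v₂ equation) singular."""


class UndefinedRatioError(ZeroDivisionError):
    """v₂/v₁ requested where v₁ = 0."""


@dataclass
class FluxTrajectory:
    """Pathway fluxes and their variances on a common time grid.

    ``vc`` is a scalar (constant consumption); v₁ + v₂ − v_c equals the
    fitted pool slope at every grid point by construction.
    """

    grid: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    vc: float
    v1_variance: np.ndarray
    v2_variance: np.ndarray
    vc_variance: float = 0.0
    genotype: str = ""
    replicate: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for name in ("v1", "v2", "v1_variance", "v2_variance"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} does not match the grid length")
            setattr(self, name, arr)
        if np.any(self.v1_variance < 0) or np.any(self.v2_variance < 0):
            raise ValueError("variances must be >= 0")
        if self.vc_variance < 0:
            raise ValueError("vc_variance must be >= 0")

    def at(self, t: float) -> int:
        """Index of grid time ``t`` (must lie on the grid)."""
        idx = np.flatnonzero(np.isclose(self.grid, t, rtol=0.0, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"t={t} is not on the grid")
        return int(idx[0])


@dataclass(frozen=True)
class FluxSummary:
    """Endpoint summaries of one genotype's mean flux trajectory."""

    genotype: str
    v1_t0: float
    v1_t6: float
    v2_t0: float
    v2_t6: float
    ratio_t6: float
    v1_t0_se: float = float("nan")
    v1_t6_se: float = float("nan")
    v2_t0_se: float = float("nan")
    v2_t6_se: float = float("nan")
    n_replicates: int = 1


def product_rate(C: float, dCdt: float, f: float, dfdt: float) -> float:
    """Rate of change of the labelled pool, d(f·C)/dt = f·dC/dt + C·df/dt."""
    if not np.all(np.isfinite([C, dCdt, f, dfdt])):
        raise ValueError("inputs must be finite")
    if np.any((np.asarray(f) < 0) | (np.asarray(f) > 1)):
        raise ValueError("f must lie in [0, 1]")
    return f * dCdt + C * dfdt


def labelled_pool_rate(
    C, dCdt: float, f, dfdt: float, balance: str = "product_rule"
):
    """Labelled-pool rate under the configured enrichment-balance variant."""
    if balance == "product_rule":
        return f * dCdt + C * dfdt
    if balance == "enrichment_only":
        return C * dfdt + 0.0 * np.asarray(f)
    raise ValueError(f"unknown balance variant {balance!r}")


def compute_fluxes(
    pool_trend: LinearTrend,
    frac_trend: LinearTrend,
    f_tyr: float,
    vc: float,
    grid,
    balance: str = "product_rule",
    genotype: str = "",
    replicate: str = "",
    warn_negative: bool = True,
) -> FluxTrajectory:
    """Evaluate v₁(t) and v₂(t) on the grid from fitted trends.

    Variances are initialised to zero; :func:`phefluxes.uncertainty.flux_variances`
    fills them in.  Negative flux estimates are reported with a warning and
    never clipped — clipping would silently break the conservation identity
    v₁ + v₂ − v_c = dC/dt.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid is empty")
    if f_tyr <= 0:
        raise ZeroTyrosineLabellingError(
            "f_Tyr <= 0: the labelled-pool balance cannot be inverted for v2"
        )
    C = evaluate_trend(pool_trend, grid)
    f = evaluate_trend(frac_trend, grid)
    rate = labelled_pool_rate(C, pool_trend.slope, f, frac_trend.slope, balance)
    v2 = (rate + vc * f) / f_tyr
    v1 = pool_trend.slope - v2 + vc
    if warn_negative and (np.any(v1 < 0) or np.any(v2 < 0)):
        warnings.warn(
            f"negative flux estimate for {genotype or '<genotype>'}/"
            f"{replicate or '<replicate>'}; values reported unclipped",
            stacklevel=2,
        )
    return FluxTrajectory(
        grid=grid,
        v1=v1,
        v2=v2,
        vc=float(vc),
        v1_variance=np.zeros_like(grid),
        v2_variance=np.zeros_like(grid),
        vc_variance=0.0,
        genotype=genotype,
        replicate=replicate,
        meta={"balance": balance, "f_tyr": float(f_tyr)},
    )


def flux_ratio(traj: FluxTrajectory, t: float) -> float:
    """v₂/v₁ at a grid time; the relative weight of the cytosolic route."""
    i = traj.at(t)
    if traj.v1[i] == 0.0:
        raise UndefinedRatioError(f"v1(t={t}) = 0; ratio undefined")
    return float(traj.v2[i] / traj.v1[i])


def percent_change(reference: float, test: float) -> float:
    """Percent by which ``test`` is lower than ``reference`` (printed scale).

    Positive values mean lower than reference: 32.0 means 32% lower.
    """
    if reference == 0.0:
        raise ZeroDivisionError("reference flux is zero")
    return 100.0 * (reference - test) / reference
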