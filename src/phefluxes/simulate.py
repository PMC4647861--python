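"""Synthetic ¹⁵N-tyrosine labelling datasets with known ground-truth fluxes.

Two generating modes:

``exact_linear``
    The estimator's assumptions are literally true: the phenylalanine pool
    and its labelled fraction are exactly affine in time, tyrosine labelling
    is a constant plateau, cumulative emission is exactly v_c·t.  The implied
    ground-truth fluxes are available in closed form, making this mode the
    pipeline's exact oracle.

``mechanistic``
    The pathway fluxes v₁(t), v₂(t) are prescribed affine functions and the
    pool/enrichment balances dC/dt = v₁+v₂−v_c, d(fC)/dt = v₂·f_Tyr(t) −
    v_c·f are integrated forward (fixed-step RK4), so the sampled
    observables are only approximately linear.  This mode probes the
    robustness of the linear approximation.

Defaults emulate the study conditions: harvests at 2, 4, 6 h plus measured
t = 0 intercepts; tyrosine labelling plateauing at 0.85 (reaching >0.8
within 2 h); pool and labelling of phenylalanine rising linearly over 6 h;
constant volatile emission rate; multiplicative noise (CV) on
concentration-like variables and additive noise (s.d.) on fractions, with
fraction values clipped to [0, 1] (clipping events counted).  Intercept rows
are emitted noise-free: the estimator treats them as known constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .datamodel import SCHEMA_COLUMNS, LabelingDataset
from .fluxmodel import FluxTrajectory, compute_fluxes
from .trends import LinearTrend

DEFAULT_GRID = 0.0 + 0.1 * np.arange(61)  # 6-min steps over the 6-h window


class InfeasibleScenarioError(ValueError):
    """The scenario drives f outside [0, 1] or the pool non-positive."""


@dataclass
class SyntheticScenario:
    """Ground truth, noise model and design of one synthetic genotype.

    Exact-linear ground truth is parameterised by the observable trends
    (pool_t0, pool_slope, frac_t0, frac_slope, f_tyr, v_c); mechanistic
    ground truth by affine pathway fluxes ``v1_coeffs``/``v2_coeffs`` =
    (value at t = 0, slope per hour).  Units: pools and emission nmol·gFW⁻¹,
    fluxes nmol·gFW⁻¹·h⁻¹, fractions dimensionless.
    """

    mode: str = "exact_linear"
    genotype: str = "control"
    # exact-linear observable trends
    pool_t0: float = 100.0
    pool_slope: float = 5.0
    frac_t0: float = 0.0
    frac_slope: float = 0.009
    f_tyr: float = 0.85
    v_c: float = 10.0
    # mechanistic ground truth (used when mode == "mechanistic")
    v1_coeffs: tuple[float, float] = (7.5, 0.0)
    v2_coeffs: tuple[float, float] = (2.5, 0.0)
    f_tyr_rise_h: float = 2.0  # linear rise to the plateau; 0 => constant
    ode_step_h: float = 0.005
    # noise model and design
    cv_pool: float = 0.05
    cv_emission: float = 0.05
    sd_fraction: float = 0.01
    replicates: int = 3
    times: tuple[float, ...] = (2.0, 4.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact_linear", "mechanistic"):
            raise ValueError("mode must be 'exact_linear' or 'mechanistic'")
        if not 0 < self.f_tyr <= 1:
            raise ValueError("f_tyr plateau must lie in (0, 1]")
        if min(self.cv_pool, self.cv_emission, self.sd_fraction) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.times) < 1 or min(self.times) <= 0:
            raise ValueError("sampling times must be positive (t0 is implicit)")

    @property
    def horizon(self) -> float:
        return float(max(self.times))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        for key in ("v1_coeffs", "v2_coeffs", "times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("v1_coeffs", "v2_coeffs", "times"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class Perturbation:
    """Fractional changes turning a control scenario into a perturbed one.

    ``v1_scale`` scales the initial plastidial flux v₁(0); ``v2_slope_scale``
    scales the labelling slope df/dt and hence the trend of the cytosolic
    flux; ``vc_fraction`` is the perturbed line's total emission as a
    fraction of control.  Identity perturbation = (1, 1, 1).
    """

    v1_scale: float = 1.0
    v2_slope_scale: float = 1.0
    vc_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.v1_scale, self.v2_slope_scale, self.vc_fraction) <= 0:
            raise ValueError("perturbation factors must be > 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.v1_scale == 1.0
            and self.v2_slope_scale == 1.0
            and self.vc_fraction == 1.0
        )


#: perturbation emulating the export-impaired (RNAi) genotype: v1(0) 32%
#: lower, steeper labelling trend, total emission at 70% of control
RNAI_PERTURBATION = Perturbation(v1_scale=0.68, v2_slope_scale=1.7, vc_fraction=0.7)


def ground_truth_trends(
    scenario: SyntheticScenario,
) -> tuple[LinearTrend, LinearTrend]:
    """Noise-free pool and fraction trends of an exact-linear scenario."""
    pool = LinearTrend(scenario.pool_slope, 0.0, scenario.pool_t0, 0.0, len(scenario.times))
    frac = LinearTrend(scenario.frac_slope, 0.0, scenario.frac_t0, 0.0, len(scenario.times))
    return pool, frac


def ground_truth_fluxes(
    scenario: SyntheticScenario, grid=DEFAULT_GRID, balance: str = "product_rule"
) -> FluxTrajectory:
    """Implied ground-truth v₁(t), v₂(t) of an exact-linear scenario."""
    pool, frac = ground_truth_trends(scenario)
    return compute_fluxes(
        pool,
        frac,
        scenario.f_tyr,
        scenario.v_c,
        grid,
        balance=balance,
        genotype=scenario.genotype,
        replicate="truth",
        warn_negative=False,
    )


def _check_exact_linear_feasible(scenario: SyntheticScenario) -> None:
    for t in (0.0, scenario.horizon):
        f = scenario.frac_t0 + scenario.frac_slope * t
        if not 0.0 <= f <= 1.0:
            raise InfeasibleScenarioError(
                f"f_Phe(t={t}) = {f:.4g} outside [0, 1]"
            )
        if scenario.pool_t0 + scenario.pool_slope * t <= 0:
            raise InfeasibleScenarioError(f"pool non-positive at t={t}")


def _noisy_rows(
    scenario: SyntheticScenario,
    sample,  # callable t -> (pool, frac_phe, frac_tyr, emission)
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    rows: list[tuple] = []
    clipped = 0
    g = scenario.genotype
    for r in range(1, scenario.replicates + 1):
        rep = f"r{r}"
        pool0, frac0, _, _ = sample(0.0)
        # intercepts: measured baselines, treated as exact constants
        rows += [
            (g, rep, 0.0, "pool_phe", pool0),
            (g, rep, 0.0, "frac_phe", frac0),
            (g, rep, 0.0, "frac_tyr", 0.0),
            (g, rep, 0.0, "emission_total", 0.0),
        ]
        for t in scenario.times:
            pool, frac_phe, frac_tyr, emission = sample(float(t))
            pool_obs = pool * (1.0 + rng.normal(0.0, scenario.cv_pool))
            emis_obs = emission * (1.0 + rng.normal(0.0, scenario.cv_emission))
            fp = frac_phe + rng.normal(0.0, scenario.sd_fraction)
            ft = frac_tyr + rng.normal(0.0, scenario.sd_fraction)
            for raw in (fp, ft):
                if raw < 0.0 or raw > 1.0:
                    clipped += 1
            fp = float(np.clip(fp, 0.0, 1.0))
            ft = float(np.clip(ft, 0.0, 1.0))
            rows += [
                (g, rep, t, "pool_phe", max(pool_obs, 0.0)),
                (g, rep, t, "frac_phe", fp),
                (g, rep, t, "frac_tyr", ft),
                (g, rep, t, "emission_total", max(emis_obs, 0.0)),
            ]
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)), clipped


def _f_tyr_profile(scenario: SyntheticScenario, t: float) -> float:
    if scenario.f_tyr_rise_h <= 0 or t >= scenario.f_tyr_rise_h:
        return scenario.f_tyr
    return scenario.f_tyr * t / scenario.f_tyr_rise_h


def simulate_exact_linear(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[LabelingDataset, FluxTrajectory]:
    """Generate one genotype's dataset from exactly affine observables.

    Returns the dataset and the implied ground-truth flux trajectory on the
    6-min grid.  Identical scenario and seed give identical datasets.
    """
    if scenario.mode != "exact_linear":
        raise ValueError("scenario mode must be 'exact_linear'")
    _check_exact_linear_feasible(scenario)
    rng = np.random.default_rng(scenario.seed) if rng is None else rng

    def sample(t: float):
        return (
            scenario.pool_t0 + scenario.pool_slope * t,
            scenario.frac_t0 + scenario.frac_slope * t,
            scenario.f_tyr if t > 0 else 0.0,
            scenario.v_c * t,
        )

    frame, clipped = _noisy_rows(scenario, sample, rng)
    dataset = LabelingDataset.from_frame(
        frame, {"mode": "exact_linear", "clipped_fractions": clipped}
    )
    return dataset, ground_truth_fluxes(scenario)


def integrate_balances(
    scenario: SyntheticScenario, t_end: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4 integration of the pool and labelled-pool balances.

    State is (C, L) with L = f·C; dC/dt = v₁(t)+v₂(t)−v_c and
    dL/dt = v₂(t)·f_Tyr(t) − v_c·L/C.  Returns (times, C, f).
    """
    t_end = scenario.horizon if t_end is None else t_end
    h = scenario.ode_step_h
    n_steps = int(np.ceil(t_end / h - 1e-12))
    a1, b1 = scenario.v1_coeffs
    a2, b2 = scenario.v2_coeffs

    def rhs(t, state):
        C, L = state
        if C <= 0:
            raise InfeasibleScenarioError(f"pool non-positive at t={t:.3f} h")
        v1 = a1 + b1 * t
        v2 = a2 + b2 * t
        dC = v1 + v2 - scenario.v_c
        dL = v2 * _f_tyr_profile(scenario, t) - scenario.v_c * L / C
        return np.array([dC, dL])

    times = np.empty(n_steps + 1)
    states = np.empty((n_steps + 1, 2))
    times[0] = 0.0
    states[0] = (scenario.pool_t0, scenario.frac_t0 * scenario.pool_t0)
    t, y = 0.0, states[0].copy()
    for i in range(n_steps):
        step = min(h, t_end - t)
        k1 = rhs(t, y)
        k2 = rhs(t + step / 2, y + step / 2 * k1)
        k3 = rhs(t + step / 2, y + step / 2 * k2)
        k4 = rhs(t + step, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + step
        times[i + 1] = t
        states[i + 1] = y
    C = states[:, 0]
    if np.any(C <= 0):
        raise InfeasibleScenarioError("pool non-positive during integration")
    return times, C, states[:, 1] / C


def simulate_mechanistic(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[LabelingDataset, FluxTrajectory]:
    """Generate a dataset by integrating the balances forward.

    The returned trajectory holds the prescribed (exact) v₁(t), v₂(t) on the
    6-min grid — the truth the linear-approximation pipeline is judged
    against.
    """
    if scenario.mode != "mechanistic":
        raise ValueError("scenario mode must be 'mechanistic'")
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    times, C, f = integrate_balances(scenario)

    def interp(t: float, series: np.ndarray) -> float:
        return float(np.interp(t, times, series))

    def sample(t: float):
        return (
            interp(t, C),
            interp(t, f),
            _f_tyr_profile(scenario, t) if t > 0 else 0.0,
            scenario.v_c * t,
        )

    frame, clipped = _noisy_rows(scenario, sample, rng)
    dataset = LabelingDataset.from_frame(
        frame, {"mode": "mechanistic", "clipped_fractions": clipped}
    )
    a1, b1 = scenario.v1_coeffs
    a2, b2 = scenario.v2_coeffs
    grid = DEFAULT_GRID
    truth = FluxTrajectory(
        grid=grid,
        v1=a1 + b1 * grid,
        v2=a2 + b2 * grid,
        vc=scenario.v_c,
        v1_variance=np.zeros_like(grid),
        v2_variance=np.zeros_like(grid),
        genotype=scenario.genotype,
        replicate="truth",
    )
    return dataset, truth


def perturb_scenario(
    control: SyntheticScenario,
    perturbation: Perturbation,
    genotype: str = "rnai",
    replicates: int | None = None,
) -> SyntheticScenario:
    """Exact-linear scenario realising the perturbation.

    The perturbed genotype stays inside the exact-linear family: v_c is
    scaled by the emission fraction, the labelling slope df/dt by the trend
    factor, and the pool slope is solved so that v₁(0) equals
    ``v1_scale``·v₁(0|control) exactly (the conservation identity then fixes
    how the v₁ level propagates along the window).
    """
    if control.mode != "exact_linear":
        raise ValueError("perturbation is defined for exact_linear scenarios")
    truth = ground_truth_fluxes(control, grid=np.array([0.0]))
    v1_0 = float(truth.v1[0])
    vc_new = perturbation.vc_fraction * control.v_c
    frac_slope_new = perturbation.v2_slope_scale * control.frac_slope
    target_v1_0 = perturbation.v1_scale * v1_0
    # v1(0) = bC + vc − (f0·bC + C0·bf + vc·f0)/fT, solved for bC
    f0, ft = control.frac_t0, control.f_tyr
    denom = 1.0 - f0 / ft
    if denom <= 0:
        raise InfeasibleScenarioError("frac_t0 >= f_tyr: v1 level not solvable")
    pool_slope_new = (
        target_v1_0 - vc_new * denom + control.pool_t0 * frac_slope_new / ft
    ) / denom
    perturbed = replace(
        control,
        genotype=genotype,
        pool_slope=pool_slope_new,
        frac_slope=frac_slope_new,
        v_c=vc_new,
        replicates=control.replicates if replicates is None else replicates,
    )
    _check_exact_linear_feasible(perturbed)
    return perturbed


def make_genotype_pair(
    control: SyntheticScenario,
    perturbation: Perturbation = RNAI_PERTURBATION,
    perturbed_genotype: str = "rnai",
    perturbed_replicates: int | None = None,
    seed: int | None = None,
) -> tuple[LabelingDataset, dict[str, FluxTrajectory]]:
    """Two-genotype dataset (control + perturbed) from one seed stream.

    With the identity perturbation both genotypes share the same ground
    truth — the null dataset used for type-I-error calibration.
    """
    seed = control.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    perturbed = perturb_scenario(
        control,
        perturbation,
        genotype=perturbed_genotype,
        replicates=perturbed_replicates,
    )
    ds_control, truth_control = simulate_exact_linear(control, rng)
    ds_perturbed, truth_perturbed = simulate_exact_linear(perturbed, rng)
    frame = pd.concat([ds_control.frame, ds_perturbed.frame], ignore_index=True)
    dataset = LabelingDataset.from_frame(
        frame,
        {
            "mode": "exact_linear_pair",
            "seed": seed,
            "clipped_fractions": ds_control.metadata["clipped_fractions"]
            + ds_perturbed.metadata["clipped_fractions"],
            "vc_fraction": perturbation.vc_fraction,
        },
    )
    return dataset, {
        control.genotype: truth_control,
        perturbed_genotype: truth_perturbed,
    }


def write_ground_truth(truth: FluxTrajectory, path) -> None:
    """Ground-truth flux TSV: ``time_h  v1_true  v2_true  vc_true``."""
    df = pd.DataFrame(
        {
            "time_h": truth.grid,
            "v1_true": truth.v1,
            "v2_true": truth.v2,
            "vc_true": truth.vc,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
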