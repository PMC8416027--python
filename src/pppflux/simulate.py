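"""Forward simulation of 1,2-13C2 glucose label propagation through the PPP.

The model tracks mass-isotopologue distributions (labelled-carbon counts) of
four well-mixed pools — G6P, F6P, GAP (trioses lumped), Ru5P — under
steady-state metabolism: pool sizes and fluxes are constant, so each pool's
MID relaxes towards the flux-weighted MID of its inputs at rate
(total influx / pool size).

Positional information is folded into tracer-specific transition rules: with
1,2-13C2 glucose the two labels sit on C1-C2 of hexoses, so the oxidative
branch (which releases C1 as CO2) converts m2 G6P into m1 Ru5P, glycolytic
cleavage sends the labels exclusively into the C1-C3 triose, and the
non-oxidative branch assembles Ru5P from the C1-C2 fragment of F6P plus a
GAP-derived three-carbon unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .isotope import MassIsotopologueDistribution, natural_abundance_matrix

__all__ = [
    "N_CARBONS",
    "PAPER_TIME_GRID_S",
    "TracerSpec",
    "NetworkConfig",
    "RuleTable",
    "NoiseModel",
    "LabelingTrajectories",
    "simulate_labeling",
    "steady_state_mids",
    "generate_experiment",
    "noisy_table_from_trajectories",
    "default_scenarios",
]

#: Carbon counts of the simulated pools.
N_CARBONS = {"G6P": 6, "F6P": 6, "GAP": 3, "Ru5P": 5}

#: Sampling times of the spike-in labelling time course, in seconds.
PAPER_TIME_GRID_S = (0.0, 10.0, 60.0, 120.0, 240.0, 480.0, 900.0)

_POOLS = ("G6P", "F6P", "GAP", "Ru5P")


def _m0(n: int) -> np.ndarray:
    v = np.zeros(n + 1)
    v[0] = 1.0
    return v


@dataclass(frozen=True)
class TracerSpec:
    """Composition of the labelling medium.

    ``tracer_fraction`` is the fraction of medium glucose that is tracer
    (0.5 for a 1:1 spike with natural glucose); ``purity`` is the fraction of
    tracer molecules that actually carry both labels, applied as a pre-mixing
    dilution of the tracer MID towards m0.
    """

    tracer_fraction: float = 0.5
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tracer_fraction <= 1.0:
            raise ValueError("tracer_fraction must be in [0, 1]")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")

    def medium_mid(self) -> np.ndarray:
        """MID of medium glucose (6 carbons): tracer m2 diluted into natural m0."""
        mid = _m0(6)
        m2 = self.tracer_fraction * self.purity
        mid[0] = 1.0 - m2
        mid[2] = m2
        return mid


@dataclass(frozen=True)
class NetworkConfig:
    """Pool sizes (arbitrary amount units) and fluxes (amount/s) of the network.

    ``v_glycolysis`` feeds G6P from medium glucose; ``v_ox`` is the oxidative
    branch G6P -> (6PG) -> Ru5P + CO2; ``v_nonox`` is the net non-oxidative
    flux assembling Ru5P from F6P/GAP; ``v_lower`` is glycolytic cleavage
    F6P -> trioses.  Steady-state metabolism is assumed, so the G6P -> F6P
    flux is ``v_glycolysis - v_ox`` and must be nonnegative.

    Default pool sizes place the hexose/triose phosphates downstream of G6P
    (the F6P and GAP nodes lump F6P with FBP and GAP with DHAP) in large,
    slowly-labelling pools, while Ru5P is a small fast pool.  The oxidative
    (m1) labelling kinetics then track Ru5P turnover — and hence v_ox —
    whereas the non-oxidative (m2) kinetics are rate-limited upstream and
    stay nearly unchanged when only the oxidative branch is suppressed.
    """

    pool_sizes: dict[str, float] = field(
        default_factory=lambda: {"G6P": 1.0, "F6P": 20.0, "GAP": 5.0, "Ru5P": 0.4}
    )
    v_glycolysis: float = 0.05
    v_ox: float = 0.006
    v_nonox: float = 0.004
    v_lower: float = 0.04

    def __post_init__(self) -> None:
        for name in _POOLS:
            if name not in self.pool_sizes:
                raise ValueError(f"pool_sizes missing {name}")
            if self.pool_sizes[name] < 0:
                raise ValueError(f"pool size of {name} must be >= 0")
        for attr in ("v_glycolysis", "v_ox", "v_nonox", "v_lower"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.v_ox > self.v_glycolysis:
            raise ValueError("v_ox cannot exceed v_glycolysis (G6P->F6P flux < 0)")
        for name, influx in self._influxes().items():
            if influx > 0 and self.pool_sizes[name] <= 0:
                raise ValueError(f"{name}: zero pool size with positive influx")

    def _influxes(self) -> dict[str, float]:
        return {
            "G6P": self.v_glycolysis,
            "F6P": self.v_glycolysis - self.v_ox,
            "GAP": self.v_lower,
            "Ru5P": self.v_ox + self.v_nonox,
        }

    def scaled(self, ox: float = 1.0, nonox: float = 1.0) -> "NetworkConfig":
        """Return a copy with branch fluxes scaled (knockdown scenarios)."""
        return replace(self, v_ox=self.v_ox * ox, v_nonox=self.v_nonox * nonox)


class RuleTable:
    """Atom-transition rules for the 1,2-13C2 glucose tracer.

    All rules map labelled-carbon-count distributions; they are only valid
    for tracers whose labels occupy C1-C2 of hexoses.
    """

    @staticmethod
    def oxidative(g6p: np.ndarray) -> np.ndarray:
        """G6P -> Ru5P losing C1 as CO2: mk -> m(k-1) for k >= 1, m0 -> m0."""
        out = g6p[1:7].copy()  # mk -> m(k-1); m6 hexose -> m5 pentose
        out[0] += g6p[0]
        return out

    @staticmethod
    def triose_split(f6p: np.ndarray) -> np.ndarray:
        """F6P -> 2 trioses: labels (C1-C2) ride the C1-C3 fragment only.

        The GAP pool receives an equal mixture of the labelled C1-C3 fragment
        and the unlabelled C4-C6 fragment.
        """
        out = np.zeros(4)
        out[0] += 0.5 * f6p.sum()  # C4-C6 fragment, always m0
        for k in range(7):
            out[min(k, 3)] += 0.5 * f6p[k]
        return out

    @staticmethod
    def f6p_fragment(f6p: np.ndarray) -> np.ndarray:
        """Label count carried by the C1-C2 fragment of F6P (0, 1 or 2)."""
        out = np.zeros(3)
        for k in range(7):
            out[min(k, 2)] += f6p[k]
        return out

    @classmethod
    def non_oxidative(cls, f6p: np.ndarray, gap: np.ndarray) -> np.ndarray:
        """Ru5P assembled from the F6P C1-C2 fragment plus a GAP unit."""
        conv = np.convolve(cls.f6p_fragment(f6p), gap)  # length 6, shifts 0..5
        return conv[:6]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on isotopologue fractions, clamp-and-renormalise."""

    sd_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")


@dataclass(frozen=True)
class LabelingTrajectories:
    """Noiseless MID trajectories: ``mids[metabolite][t_index, mass_shift]``."""

    times: np.ndarray
    mids: dict[str, np.ndarray]

    def mid_at(self, metabolite: str, t_index: int) -> MassIsotopologueDistribution:
        return MassIsotopologueDistribution(
            metabolite, N_CARBONS[metabolite], self.mids[metabolite][t_index]
        )


_SLICES = {"G6P": slice(0, 7), "F6P": slice(7, 14), "GAP": slice(14, 18), "Ru5P": slice(18, 24)}


def _rhs(t: float, y: np.ndarray, config: NetworkConfig, medium: np.ndarray) -> np.ndarray:
    g6p = y[_SLICES["G6P"]]
    f6p = y[_SLICES["F6P"]]
    gap = y[_SLICES["GAP"]]
    ru5p = y[_SLICES["Ru5P"]]
    pools = config.pool_sizes
    dy = np.zeros_like(y)

    if config.v_glycolysis > 0:
        dy[_SLICES["G6P"]] = (config.v_glycolysis / pools["G6P"]) * (medium - g6p)
    v_gf = config.v_glycolysis - config.v_ox
    if v_gf > 0:
        dy[_SLICES["F6P"]] = (v_gf / pools["F6P"]) * (g6p - f6p)
    if config.v_lower > 0:
        dy[_SLICES["GAP"]] = (config.v_lower / pools["GAP"]) * (
            RuleTable.triose_split(f6p) - gap
        )
    v_tot = config.v_ox + config.v_nonox
    if v_tot > 0:
        influx_mid = (
            config.v_ox * RuleTable.oxidative(g6p)
            + config.v_nonox * RuleTable.non_oxidative(f6p, gap)
        ) / v_tot
        dy[_SLICES["Ru5P"]] = (v_tot / pools["Ru5P"]) * (influx_mid - ru5p)
    return dy


def simulate_labeling(
    config: NetworkConfig,
    tracer: TracerSpec,
    times: np.ndarray,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> LabelingTrajectories:
    """Integrate the labelling dynamics and return MIDs at the requested times.

    All pools start unlabelled (m0 = 1).  ``times`` must be sorted, start at
    0 and be nonnegative.  The dynamics are smooth and non-stiff at
    physiological turnover rates; an adaptive Runge-Kutta scheme with tight
    tolerances integrates them to well below measurement noise.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 1:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("negative time in time grid")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if times[0] != 0:
        raise ValueError("time grid must start at 0")

    y0 = np.concatenate([_m0(N_CARBONS[m]) for m in _POOLS])
    medium = tracer.medium_mid()
    if times[-1] == 0:
        ys = y0[:, None]
    else:
        sol = solve_ivp(
            _rhs,
            (0.0, float(times[-1])),
            y0,
            t_eval=times,
            args=(config, medium),
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - non-stiff smooth system
            raise RuntimeError(f"labelling integration failed: {sol.message}")
        ys = sol.y
    mids = {}
    for name in _POOLS:
        block = np.clip(ys[_SLICES[name]].T, 0.0, None)
        mids[name] = block / block.sum(axis=1, keepdims=True)
    return LabelingTrajectories(times=times, mids=mids)


def steady_state_mids(config: NetworkConfig, tracer: TracerSpec) -> dict[str, np.ndarray]:
    """Closed-form isotopic steady state (infinite-time limit) of every pool.

    The network is a feed-forward cascade, so the fixed point is obtained in
    topological order: G6P equals the medium MID, F6P equals G6P, GAP is the
    triose split of F6P, and Ru5P is the flux-weighted mix of the oxidative
    and non-oxidative input MIDs.  Pools with zero influx stay unlabelled.
    """
    medium = tracer.medium_mid()
    g6p = medium if config.v_glycolysis > 0 else _m0(6)
    f6p = g6p if (config.v_glycolysis - config.v_ox) > 0 else _m0(6)
    gap = RuleTable.triose_split(f6p) if config.v_lower > 0 else _m0(3)
    v_tot = config.v_ox + config.v_nonox
    if v_tot > 0:
        ru5p = (
            config.v_ox * RuleTable.oxidative(g6p)
            + config.v_nonox * RuleTable.non_oxidative(f6p, gap)
        ) / v_tot
    else:
        ru5p = _m0(5)
    return {"G6P": g6p, "F6P": f6p, "GAP": gap, "Ru5P": ru5p}


def default_scenarios(
    base: NetworkConfig | None = None,
    *,
    knockdown_scale: float = 0.4,
) -> dict[str, NetworkConfig]:
    """Control plus knockdown scenarios mirroring the siRNA design.

    ``si6PGD`` scales only the oxidative branch; ``siAR`` and ``siSREBP1``
    scale both branches.  The 0.4 scale factor is a synthetic effect size.
    """
    base = base or NetworkConfig()
    return {
        "siCon": base,
        "si6PGD": base.scaled(ox=knockdown_scale),
        "siAR": base.scaled(ox=knockdown_scale, nonox=knockdown_scale),
        "siSREBP1": base.scaled(ox=knockdown_scale, nonox=knockdown_scale),
    }


def noisy_table_from_trajectories(
    trajectories: dict[str, LabelingTrajectories],
    replicates: int,
    noise: NoiseModel,
    *,
    p13C: float = 0.0,
    max_shift: int = 2,
) -> pd.DataFrame:
    """Turn noiseless per-condition trajectories into a noisy long-format table.

    Per (condition, metabolite, time, replicate) the full MID receives
    additive Gaussian noise, is clamped to [0, 1] and renormalised; mass
    shifts up to ``max_shift`` are then reported.  If ``p13C`` > 0 the
    natural-abundance envelope is forward-applied before noise, emulating
    uncorrected measurements.  Deterministic given ``noise.seed``: each
    condition draws from an independent child stream.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    matrices = {
        m: natural_abundance_matrix(n, p13C).entries if p13C > 0 else None
        for m, n in N_CARBONS.items()
    }
    children = np.random.SeedSequence(noise.seed).spawn(len(trajectories))
    records = []
    for (condition, traj), child in zip(trajectories.items(), children):
        rng = np.random.default_rng(child)
        for metabolite in _POOLS:
            n = N_CARBONS[metabolite]
            shifts = range(min(max_shift, n) + 1)
            for ti, t in enumerate(traj.times):
                true = traj.mids[metabolite][ti]
                if matrices[metabolite] is not None:
                    true = matrices[metabolite] @ true
                for rep in range(1, replicates + 1):
                    noisy = true + rng.normal(0.0, noise.sd_fraction, size=n + 1)
                    noisy = np.clip(noisy, 0.0, 1.0)
                    total = noisy.sum()
                    noisy = noisy / total if total > 0 else _m0(n)
                    for s in shifts:
                        records.append(
                            (condition, rep, metabolite, n, s, float(t), noisy[s], "fraction")
                        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "condition", "replicate", "metabolite", "n_carbons",
            "mass_shift", "time_s", "value", "value_type",
        ],
    )


def generate_experiment(
    scenarios: dict[str, NetworkConfig],
    tracer: TracerSpec,
    times: np.ndarray,
    replicates: int,
    noise: NoiseModel,
    *,
    p13C: float = 0.0,
    max_shift: int = 2,
) -> pd.DataFrame:
    """Simulate a full multi-condition labelling experiment.

    Returns the long-format measurement table (fractions) for every
    (condition, metabolite, mass shift, time, replicate).
    """
    if not scenarios:
        raise ValueError("at least one scenario is required")
    trajectories = {
        condition: simulate_labeling(config, tracer, times)
        for condition, config in scenarios.items()
    }
    return noisy_table_from_trajectories(
        trajectories, replicates, noise, p13C=p13C, max_shift=max_shift
    )
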