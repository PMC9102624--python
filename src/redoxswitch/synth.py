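"""Synthetic assay traces and readouts with known ground truth.

Every generator draws seeded additive Gaussian noise and returns the
observable together with a separate truth record (the truth never enters
the trace itself, so blind recovery studies are possible).  Scenario
presets mirror the rapid-oxidation working conditions: 2.5 uM tetramer,
1.5 mM H2O2, 5 mM DTNB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .fitting import KineticTrace, tnb_thiosulfinate_curve
from .inventory import INVENTORIES, SpeciesInventory, predicted_state_counts
from .network import RateSet, build_switch_network, simulate

__all__ = [
    "NoiseSpec",
    "ScenarioPreset",
    "PRESETS",
    "gen_h2o2_trace",
    "gen_quench_trace",
    "gen_multiphase_trace",
    "gen_tnb_thiosulfinate_trace",
    "gen_nad_trace",
    "gen_inactivation_series",
    "gen_assay_counts",
]


@dataclass
class NoiseSpec:
    """Additive Gaussian noise on the observed signal.

    ``sd`` is in signal units unless ``relative_to_range`` is set, in which
    case it is a fraction of the noiseless trace's dynamic range (max-min)
    — the natural scale for "1% noise" on traces whose absolute baseline
    dwarfs the kinetic excursion.  With ``clip_nonnegative`` the number of
    clipped samples is recorded on the spec after each application.
    """

    sd: float = 0.0
    seed: int = 0
    kind: str = "gaussian"
    clip_nonnegative: bool = False
    relative_to_range: bool = False
    n_clipped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.kind != "gaussian":
            raise ValueError("only additive Gaussian noise is supported")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if self.sd == 0:
            self.n_clipped = 0
            return signal.copy()
        sd = self.sd
        if self.relative_to_range:
            rng_span = float(signal.max() - signal.min())
            sd = self.sd * rng_span
        rng = np.random.default_rng(self.seed)
        noisy = signal + rng.normal(0.0, sd, size=signal.shape)
        if self.clip_nonnegative:
            below = noisy < 0
            self.n_clipped = int(below.sum())
            noisy = np.where(below, 0.0, noisy)
        else:
            self.n_clipped = 0
        return noisy


@dataclass(frozen=True)
class ScenarioPreset:
    """Named concentration regime + rate set for one oxidation condition."""

    name: str
    rates: RateSet
    tetramer_conc: float = 2.5e-6
    h2o2_0: float = 1.5e-3
    dtnb_conc: float = 5e-3
    temperature: str = "14C"  # label only; rates are whatever the caller set

    @property
    def equiv_conc(self) -> float:
        """Oxidizable thiol equivalents: two per subunit, four subunits."""
        return 8.0 * self.tetramer_conc

    @property
    def subunit_conc(self) -> float:
        return 4.0 * self.tetramer_conc


PRESETS: Dict[str, ScenarioPreset] = {
    "ph7": ScenarioPreset("ph7", RateSet.default(9.4), temperature="37C"),
    "ph7.8": ScenarioPreset("ph7.8", RateSet.default(13.7, 6.6), temperature="37C"),
    "ph9": ScenarioPreset("ph9", RateSet.default(25.6, 2.6), temperature="37C"),
    "rapid_oxidation": ScenarioPreset("rapid_oxidation", RateSet.default(9.4)),
}


def _truth(**kw) -> Dict[str, object]:
    return {k: v for k, v in kw.items() if v is not None}


def gen_h2o2_trace(
    rates: RateSet,
    scenario: ScenarioPreset,
    n_points: int = 120,
    noise: Optional[NoiseSpec] = None,
    duration: Optional[float] = None,
    variant: str = "i",
    inventory: Optional[SpeciesInventory] = None,
) -> Tuple[KineticTrace, Dict[str, object]]:
    """H2O2-consumption time course from the mass-action switch network.

    Duration defaults to ~6 pseudo-first-order lifetimes of the slower
    oxidation step, enough to span completion of both phases.
    """
    noise = noise or NoiseSpec()
    inventory = inventory or INVENTORIES["porcine"]
    if duration is None:
        k_slow = min(rates.k_prime, rates.k_dprime)
        duration = 6.0 / (k_slow * scenario.h2o2_0)
    t = np.linspace(0.0, float(duration), int(n_points))
    net = build_switch_network(rates, inventory, variant)
    traj = simulate(net, {"H2O2": scenario.h2o2_0, "E_red": scenario.subunit_conc}, t)
    clean = traj.pool("H2O2")
    trace = KineticTrace(
        t,
        noise.apply(clean),
        meta={
            "assay_type": "h2o2_consumption",
            "units": "M",
            "tetramer_conc_M": scenario.tetramer_conc,
            "equiv_conc_M": scenario.equiv_conc,
            "temperature": scenario.temperature,
        },
    )
    truth = _truth(
        k_prime=rates.k_prime, k_dprime=rates.k_dprime, variant=variant,
        h2o2_0=scenario.h2o2_0, noise_sd=noise.sd, seed=noise.seed,
    )
    return trace, truth


def gen_quench_trace(
    k: float,
    a0: float = 0.5,
    a_inf: float = 0.1,
    duration: Optional[float] = None,
    n_points: int = 80,
    noise: Optional[NoiseSpec] = None,
) -> Tuple[KineticTrace, Dict[str, object]]:
    """Racker-band (365 nm) pseudo-first-order quench decay.

    ``a0``/``a_inf`` are initial and plateau absorbances; sampling is
    logarithmic (decays carry most information early)."""
    if k <= 0:
        raise ValueError("quench rate must be positive")
    noise = noise or NoiseSpec()
    if duration is None:
        duration = 6.0 / k
    t = np.concatenate([[0.0], np.geomspace(duration / 200.0, duration, n_points - 1)])
    clean = a_inf + (a0 - a_inf) * np.exp(-k * t)
    trace = KineticTrace(
        t, noise.apply(clean),
        meta={"assay_type": "racker_quench", "units": "AU", "wavelength_nm": 365},
    )
    return trace, _truth(k1=k, a0=a0, a_inf=a_inf, noise_sd=noise.sd, seed=noise.seed)


def gen_multiphase_trace(
    ks: Sequence[float],
    phase_stoich: Sequence[float] = (1, 1, 2),
    per_phase_amp: float = 1.0e-5,
    duration: Optional[float] = None,
    n_points: int = 200,
    noise: Optional[NoiseSpec] = None,
) -> Tuple[KineticTrace, Dict[str, object]]:
    """Saturating multiphase TNB release (DTNB oxidation phases).

    ``per_phase_amp`` is the signal per unit stoichiometry (per-subunit TNB
    yield); phase amplitudes are exactly ``phase_stoich * per_phase_amp``.
    """
    ks = np.asarray(ks, dtype=float)
    stoich = np.asarray(phase_stoich, dtype=float)
    if len(ks) != len(stoich):
        raise ValueError("ks and phase_stoich must have equal length")
    if np.any(ks <= 0):
        raise ValueError("phase rates must be positive")
    noise = noise or NoiseSpec()
    if duration is None:
        duration = 6.0 / ks.min()
    t = np.concatenate([[0.0], np.geomspace(duration / 500.0, duration, n_points - 1)])
    clean = np.zeros_like(t)
    for k_i, s_i in zip(ks, stoich):
        clean = clean + per_phase_amp * s_i * (1 - np.exp(-k_i * t))
    trace = KineticTrace(
        t, noise.apply(clean),
        meta={"assay_type": "dtnb_release", "units": "M", "wavelength_nm": 412},
    )
    truth = _truth(ks=list(map(float, ks)), phase_stoich=list(map(float, stoich)),
                   per_phase_amp=per_phase_amp, noise_sd=noise.sd, seed=noise.seed)
    return trace, truth


def gen_tnb_thiosulfinate_trace(
    k: float,
    tnb0: float,
    ts0: float,
    duration: Optional[float] = None,
    n_points: int = 150,
    noise: Optional[NoiseSpec] = None,
) -> Tuple[KineticTrace, Dict[str, object]]:
    """TNB 412-nm decay against a thiosulfinate (2:1, first step limiting)."""
    if k <= 0 or tnb0 <= 0 or ts0 < 0:
        raise ValueError("k and tnb0 must be positive; ts0 non-negative")
    noise = noise or NoiseSpec()
    if duration is None:
        scale = max(ts0, tnb0 / 2)
        duration = 6.0 / (k * max(scale, 1e-30))
    t = np.linspace(0.0, float(duration), int(n_points))
    clean = tnb_thiosulfinate_curve(t, k, tnb0, ts0)
    trace = KineticTrace(
        t, noise.apply(clean),
        meta={"assay_type": "tnb_thiosulfinate", "units": "M", "wavelength_nm": 412,
              "tnb0_M": tnb0, "ts0_M": ts0},
    )
    return trace, _truth(k_bimolecular=k, tnb0=tnb0, ts0=ts0,
                         noise_sd=noise.sd, seed=noise.seed)


def gen_nad_trace(
    k_diss: float,
    plateau: float,
    duration: Optional[float] = None,
    n_points: int = 60,
    noise: Optional[NoiseSpec] = None,
) -> Tuple[KineticTrace, Dict[str, object]]:
    """Free-NAD+ rise from limited first-order subunit unfolding.

    ``plateau`` equals the total initially bound NAD+ (one per subunit).
    Default window ~2 half-lives, matching how slow dissociation data are
    realistically collected."""
    if k_diss <= 0 or plateau <= 0:
        raise ValueError("k_diss and plateau must be positive")
    noise = noise or NoiseSpec()
    if duration is None:
        duration = 2.0 * np.log(2) / k_diss
    t = np.linspace(0.0, float(duration), int(n_points))
    clean = plateau * (1 - np.exp(-k_diss * t))
    trace = KineticTrace(
        t, noise.apply(clean),
        meta={"assay_type": "nad_dissociation", "units": "M"},
    )
    return trace, _truth(k_diss=k_diss, plateau=plateau,
                         noise_sd=noise.sd, seed=noise.seed)


def gen_inactivation_series(
    mechanism: str,
    scenario: Optional[ScenarioPreset] = None,
    sample_times: Optional[Sequence[float]] = None,
    noise: Optional[NoiseSpec] = None,
    n_samples: int = 12,
    x_final: float = 0.95,
):
    """Paired (fractional inactivation x, fractional consumption y) series.

    ``mechanism`` is ``"two_step"`` (the H2O2 switch: two oxidations per
    irreversible event, sampled from the simulated variant-(i) network) or
    ``"one_step"`` (an IAA-like single alkylation event per subunit, for
    which y = x identically).  Default sampling places ``n_samples`` points
    at equally spaced inactivation levels up to ``x_final`` ~ 0.95, the
    point where residual activity P' reaches ~5% of P0.
    """
    from .stoichiometry import InactivationSeries  # local import, no cycle

    noise = noise or NoiseSpec()
    scenario = scenario or PRESETS["ph7"]
    if mechanism == "one_step":
        k_pseudo = scenario.rates.k_prime * scenario.h2o2_0
        if sample_times is None:
            levels = np.linspace(x_final / n_samples, x_final, n_samples)
            sample_times = -np.log(1 - levels) / k_pseudo
        t = np.asarray(sample_times, dtype=float)
        x = 1.0 - np.exp(-k_pseudo * t)
        y = x.copy()
        truth = _truth(mechanism=mechanism, alpha_over_beta=1.0,
                       noise_sd=noise.sd, seed=noise.seed)
    elif mechanism == "two_step":
        net = build_switch_network(scenario.rates, INVENTORIES["rabbit"], "i")
        init = {"H2O2": scenario.h2o2_0, "E_red": scenario.subunit_conc}
        k_slow = min(scenario.rates.k_prime, scenario.rates.k_dprime)
        t_max = 12.0 / (k_slow * scenario.h2o2_0)
        dense = np.linspace(0.0, t_max, 4000)
        traj = simulate(net, init, dense)
        xf = traj.committed_fraction()
        if sample_times is None:
            levels = np.linspace(x_final / n_samples, min(x_final, xf[-1] * 0.999),
                                 n_samples)
            sample_times = np.interp(levels, xf, dense)
        t = np.asarray(sample_times, dtype=float)
        traj_s = simulate(net, init, np.concatenate([[0.0], t]))
        x = traj_s.committed_fraction()[1:]
        y = (traj_s.h2o2_consumed[1:] / (2.0 * scenario.subunit_conc))
        truth = _truth(mechanism=mechanism, k_prime=scenario.rates.k_prime,
                       k_dprime=scenario.rates.k_dprime,
                       noise_sd=noise.sd, seed=noise.seed)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}; "
                         "expected 'one_step' or 'two_step'")
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        x = np.clip(x + rng.normal(0, noise.sd, x.shape), 0.0, 1.0)
        y = np.clip(y + rng.normal(0, noise.sd, y.shape), 0.0, 1.0)
    series = InactivationSeries(x=np.clip(x, 0.0, 1.0), y=np.clip(y, 0.0, 1.0))
    return series, truth


#: typical replicate scatter (counts per tetramer) of the DTNB/NTSB assays
DEFAULT_COUNT_SD = 0.5


def gen_assay_counts(
    stage: str,
    inventory: SpeciesInventory,
    noise_sd: float = DEFAULT_COUNT_SD,
    n_replicates: int = 4,
    seed: int = 0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, object]]:
    """Replicate DTNB/NTSB readouts (counts per tetramer) for one redox stage.

    Returns per-replicate arrays for free cysteines (DTNB), disulfides
    (NTSB) and bound TNB adducts, each the predicted census value plus
    Gaussian replicate noise, floored at zero.
    """
    if noise_sd < 0 or n_replicates < 1:
        raise ValueError("noise_sd must be >= 0 and n_replicates >= 1")
    counts = predicted_state_counts(stage, inventory)
    rng = np.random.default_rng(seed)
    out = {}
    for key, name in (("free_SH", "dtnb_free_sh"), ("disulfides", "ntsb_disulfides"),
                      ("TNB_adducts", "tnb_adducts")):
        vals = counts[key] + rng.normal(0.0, noise_sd, n_replicates)
        out[name] = np.clip(vals, 0.0, None)
    truth = _truth(stage=stage, species=inventory.species_name,
                   noise_sd=noise_sd, seed=seed, **{f"true_{k}": v
                                                    for k, v in counts.items()})
    return out, truth
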