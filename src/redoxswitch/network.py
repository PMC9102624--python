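"""Mass-action kinetics of the GAPDH two-cysteine switch.

The switch pathway per subunit is a consecutive scheme

    E(SH,SH) + H2O2 -k'->  E(SOH,SH)            (step 1, Cc oxidation)
    E(SOH,SH) + H2O2 -k''-> E(SOH,SOH)          (step 2, Cv oxidation)
    E(SOH,SOH) -k'''-> thiosulfinate            (fast, committed condensation)
    thiosulfinate -k_hyd-> thiosulfonate        (hydrolysis, t1/2 ~15 min)
    thiosulfonate -k_res-> Cc(SO2H) + Cv-SS-C   (resolution by a downstream thiol)
    resolved -k_unfold-> unfolded (NAD+ released)

with a slow side branch E(SOH,SH) + H2O2 -k_side-> Cc(SO2H) competing with
step 2.  Mechanistic order variants permute which cysteine is oxidized
first; enzymes without the vicinal cysteine only have the side branch.
Subunit-state pools are tracked as concentrations (subunits are oxidized
uniformly and independently, so tetramer-level correlations are not
modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .inventory import SpeciesInventory

__all__ = [
    "RateSet",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "SolverError",
    "build_switch_network",
    "simulate",
    "endpoint_h2o2_stoichiometry",
]

H2O2 = "H2O2"

#: thiosulfinate hydrolysis half-life at neutral pH, ~15 min
HYDROLYSIS_HALFLIFE_S = 900.0

VARIANTS = ("i", "ii", "iiia", "iiib")


class SolverError(RuntimeError):
    """ODE integration failed; carries solver diagnostics."""


@dataclass(frozen=True)
class RateSet:
    """Rate constants of the switch network.

    Parameters
    ----------
    k_prime : float
        Bimolecular rate (M-1 s-1) of Cc(SH) + H2O2 -> Cc(SOH).
    k_dprime : float
        Bimolecular rate (M-1 s-1) of Cv(SH) + H2O2 -> Cv(SOH).
    k_tprime : float
        First-order rate (s-1) of sulfenic condensation to the
        thiosulfinate; must exceed the oxidation pseudo-rates so the
        condensation is the committed step.
    k_hydrolysis : float
        First-order rate (s-1) of thiosulfinate -> thiosulfonate;
        default ln2 / 900 s (half-life ~15 min).
    k_resolution : float
        First-order rate (s-1) of thiosulfonate attack by the downstream
        thiol; the thiosulfonate is highly reactive, so the default is
        100x k_hydrolysis and hydrolysis stays rate-limiting.
    k_side : float
        Bimolecular rate (M-1 s-1) of Cc(SOH) + H2O2 -> Cc(SO2H);
        default 0.4, the sluggish sulfinic-acid branch.
    k_unfold : float
        First-order rate (s-1) of post-resolution subunit unfolding with
        NAD+ release; default the measured NAD+ dissociation rate
        19.95e-6 s-1.
    """

    k_prime: float = 9.4
    k_dprime: float = 9.4
    k_tprime: float = 1.41
    k_hydrolysis: float = float(np.log(2) / HYDROLYSIS_HALFLIFE_S)
    k_resolution: float = float(100 * np.log(2) / HYDROLYSIS_HALFLIFE_S)
    k_side: float = 0.4
    k_unfold: float = 19.95e-6

    def __post_init__(self) -> None:
        for name in (
            "k_prime",
            "k_dprime",
            "k_tprime",
            "k_hydrolysis",
            "k_resolution",
            "k_side",
            "k_unfold",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    @classmethod
    def default(
        cls, k_prime: float = 9.4, k_dprime: Optional[float] = None,
        h2o2: float = 1.5e-3, condensation_factor: float = 100.0, **kw
    ) -> "RateSet":
        """Rates with the condensation pseudo-rate set ``condensation_factor``
        times the fastest oxidation pseudo-rate at the working [H2O2]."""
        if k_dprime is None:
            k_dprime = k_prime
        k_t = condensation_factor * max(k_prime, k_dprime) * h2o2
        return cls(k_prime=k_prime, k_dprime=k_dprime, k_tprime=k_t, **kw)

    def with_(self, **kw) -> "RateSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: rate = k * prod_i [reactant_i]^order_i."""

    name: str
    reactants: Dict[str, int]
    products: Dict[str, int]
    k: float

    @property
    def h2o2_consumed(self) -> int:
        return self.reactants.get(H2O2, 0) - self.products.get(H2O2, 0)


@dataclass
class ReactionNetwork:
    """Named species pools plus mass-action reactions and conservation laws."""

    species: List[str]
    reactions: List[Reaction]
    inventory: SpeciesInventory
    variant: str
    conserved: List[Dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def subunit_species(self) -> List[str]:
        return [s for s in self.species if s != H2O2]

    def validate(self) -> None:
        """Every reaction must conserve subunit count (and hence the sulfur
        carried by each subunit pool — pools of one inventory all hold
        ``cys_per_subunit`` sulfurs)."""
        sub = set(self.subunit_species)
        for rxn in self.reactions:
            for sp in list(rxn.reactants) + list(rxn.products):
                if sp not in self.species:
                    raise ValueError(f"reaction {rxn.name} uses unknown species {sp}")
            n_in = sum(v for s, v in rxn.reactants.items() if s in sub)
            n_out = sum(v for s, v in rxn.products.items() if s in sub)
            if n_in != n_out:
                raise ValueError(f"reaction {rxn.name} does not conserve subunits")

    def stoichiometry_matrix(self) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        mat = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, v in rxn.reactants.items():
                mat[idx[s], j] -= v
            for s, v in rxn.products.items():
                mat[idx[s], j] += v
        return mat


# ---------------------------------------------------------------------------
# network construction


def _switch_steps(rates: RateSet, variant: str) -> List[Reaction]:
    """Oxidation/condensation steps for the chosen mechanistic order."""
    r = []
    if variant == "i":  # Cc first, then Cv
        r.append(Reaction("ox_cc", {"E_red": 1, H2O2: 1}, {"E_cc_soh": 1}, rates.k_prime))
        r.append(Reaction("ox_cv", {"E_cc_soh": 1, H2O2: 1}, {"E_bis_soh": 1}, rates.k_dprime))
        r.append(
            Reaction("side_so2h", {"E_cc_soh": 1, H2O2: 1}, {"E_cc_so2h": 1}, rates.k_side)
        )
    elif variant == "ii":  # Cv first, then Cc
        r.append(Reaction("ox_cv", {"E_red": 1, H2O2: 1}, {"E_cv_soh": 1}, rates.k_dprime))
        r.append(Reaction("ox_cc", {"E_cv_soh": 1, H2O2: 1}, {"E_bis_soh": 1}, rates.k_prime))
    else:  # parallel-consecutive: either residue may go first
        r.append(Reaction("ox_cc_first", {"E_red": 1, H2O2: 1}, {"E_cc_soh": 1}, rates.k_prime))
        r.append(Reaction("ox_cv_first", {"E_red": 1, H2O2: 1}, {"E_cv_soh": 1}, rates.k_dprime))
        r.append(Reaction("ox_cv_second", {"E_cc_soh": 1, H2O2: 1}, {"E_bis_soh": 1}, rates.k_dprime))
        r.append(Reaction("ox_cc_second", {"E_cv_soh": 1, H2O2: 1}, {"E_bis_soh": 1}, rates.k_prime))
        r.append(
            Reaction("side_so2h", {"E_cc_soh": 1, H2O2: 1}, {"E_cc_so2h": 1}, rates.k_side)
        )
    r.append(Reaction("condense", {"E_bis_soh": 1}, {"E_ester": 1}, rates.k_tprime))
    r.append(Reaction("hydrolyse", {"E_ester": 1}, {"E_thiosulfonate": 1}, rates.k_hydrolysis))
    r.append(
        Reaction("resolve", {"E_thiosulfonate": 1}, {"E_resolved": 1}, rates.k_resolution)
    )
    r.append(Reaction("unfold", {"E_resolved": 1}, {"E_unfolded": 1}, rates.k_unfold))
    return r


def build_switch_network(
    rates: RateSet, inventory: SpeciesInventory, variant: str = "i"
) -> ReactionNetwork:
    """Build the mass-action network for one mechanism-order variant.

    Variants: ``"i"`` Cc then Cv (the experimentally supported order),
    ``"ii"`` Cv then Cc, ``"iiia"``/``"iiib"`` parallel-consecutive (either
    residue first).  An inventory without the vicinal cysteine has no
    condensation path — the only route past the sulfenic acid is the slow
    ``k_side`` branch.

    When the resolution step has no downstream thiol on the same subunit
    (yeast-like inventories) the resolving thiol is drawn from the sibling
    subunit's pool; the pool-level network is unchanged.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown mechanism variant {variant!r}; expected one of {VARIANTS}")
    if not inventory.has_vicinal_cys:
        reactions = [
            Reaction("ox_cc", {"E_red": 1, H2O2: 1}, {"E_cc_soh": 1}, rates.k_prime),
            Reaction("side_so2h", {"E_cc_soh": 1, H2O2: 1}, {"E_cc_so2h": 1}, rates.k_side),
        ]
    else:
        reactions = _switch_steps(rates, variant)
    species = [H2O2]
    seen = set()
    for rxn in reactions:
        for sp in list(rxn.reactants) + list(rxn.products):
            if sp != H2O2 and sp not in seen:
                seen.add(sp)
                species.append(sp)
    net = ReactionNetwork(species=species, reactions=reactions, inventory=inventory,
                          variant=variant)
    net.conserved = [
        {s: 1.0 for s in net.subunit_species},  # total subunits
        {s: float(inventory.cys_per_subunit) for s in net.subunit_species},  # sulfur
    ]
    return net


# ---------------------------------------------------------------------------
# simulation

#: species downstream of (and including) each landmark, per pathway position
_PAST_STEP1 = ("E_cc_soh", "E_cv_soh", "E_bis_soh", "E_ester", "E_thiosulfonate",
               "E_resolved", "E_unfolded", "E_cc_so2h")
_PAST_STEP2 = ("E_bis_soh", "E_ester", "E_thiosulfonate", "E_resolved", "E_unfolded")
#: irreversibly inactivated = condensed or beyond (sulfenic states are
#: thiol-reversible; the ester and the side-branch sulfinic acid are not)
COMMITTED = ("E_ester", "E_thiosulfonate", "E_resolved", "E_unfolded", "E_cc_so2h")


@dataclass
class Trajectory:
    """Time course of every pool plus cumulative H2O2 consumption."""

    times: np.ndarray
    concentrations: Dict[str, np.ndarray]
    h2o2_consumed: np.ndarray
    network: ReactionNetwork

    def pool(self, name: str) -> np.ndarray:
        return self.concentrations[name]

    def pools(self, names: Sequence[str]) -> np.ndarray:
        """Sum of the named pools (absent pools count zero)."""
        out = np.zeros_like(self.times, dtype=float)
        for n in names:
            if n in self.concentrations:
                out = out + self.concentrations[n]
        return out

    def subunit_total(self) -> np.ndarray:
        return self.pools(self.network.subunit_species)

    def committed_fraction(self) -> np.ndarray:
        return self.pools(COMMITTED) / self.subunit_total()

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        data.update({s: self.concentrations[s] for s in self.network.species})
        data["h2o2_consumed_M"] = self.h2o2_consumed
        return pd.DataFrame(data)

    def final_oxidation_flux(self) -> float:
        """Instantaneous H2O2-consuming flux (M/s) at the last time point."""
        c = {s: self.concentrations[s][-1] for s in self.network.species}
        flux = 0.0
        for rxn in self.network.reactions:
            if rxn.h2o2_consumed > 0:
                rate = rxn.k
                for sp, order in rxn.reactants.items():
                    rate *= c[sp] ** order
                flux += rxn.h2o2_consumed * rate
        return flux


def simulate(
    network: ReactionNetwork,
    initial: Dict[str, float],
    time_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the network with a stiff-safe solver (LSODA).

    ``initial`` maps species names to molar concentrations; unnamed species
    start at zero.  ``time_grid`` must be strictly increasing from 0.
    Cumulative H2O2 consumption is integrated as an extra state so the
    closure ``consumed(t) + [H2O2](t) = [H2O2](0)`` is a genuine solver
    invariant, not an identity.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing and start at 0")
    for sp, c in initial.items():
        if sp not in network.species:
            raise ValueError(f"unknown species {sp!r} in initial concentrations")
        if c < 0:
            raise ValueError(f"negative initial concentration for {sp}")

    idx = {s: i for i, s in enumerate(network.species)}
    y0 = np.zeros(len(network.species) + 1)
    for sp, c in initial.items():
        y0[idx[sp]] = c

    _warn_if_not_committed(network, y0[idx[H2O2]])

    smat = network.stoichiometry_matrix()
    rxn_orders = [list(r.reactants.items()) for r in network.reactions]
    h2o2_cols = np.array([r.h2o2_consumed for r in network.reactions], dtype=float)

    def rhs(_t, y):
        rates = np.empty(len(network.reactions))
        for j, terms in enumerate(rxn_orders):
            r = network.reactions[j].k
            for sp, order in terms:
                conc = y[idx[sp]]
                r *= conc if order == 1 else conc**order
            rates[j] = r
        dy = np.empty_like(y)
        dy[:-1] = smat @ rates
        dy[-1] = h2o2_cols @ rates
        return dy

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, method="LSODA", t_eval=t,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message!r} "
                          f"(reached t={sol.t[-1] if len(sol.t) else 'n/a'})")
    conc = {s: sol.y[idx[s]] for s in network.species}
    return Trajectory(times=t, concentrations=conc,
                      h2o2_consumed=sol.y[-1], network=network)


def _warn_if_not_committed(network: ReactionNetwork, h2o2_0: float) -> None:
    k_t = next((r.k for r in network.reactions if r.name == "condense"), None)
    if k_t is None:
        return
    k_ox = max(r.k for r in network.reactions if r.name.startswith("ox"))
    if k_t <= k_ox * h2o2_0:
        warnings.warn(
            "condensation rate k''' does not exceed the oxidation pseudo-rate; "
            "the sulfenic intermediates are not committed to the ester",
            stacklevel=3,
        )


def endpoint_h2o2_stoichiometry(
    trajectory: Trajectory, tetramer_conc: float, flux_tol: float = 1e-12
) -> float:
    """Mol H2O2 consumed per mol tetramer at completion of the oxidation.

    Raises if the trajectory has not run to completion (residual
    H2O2-consuming flux above ``flux_tol`` M/s).
    """
    if tetramer_conc <= 0:
        raise ValueError("tetramer concentration must be positive")
    flux = trajectory.final_oxidation_flux()
    if flux > flux_tol:
        raise RuntimeError(
            f"oxidation not complete: residual H2O2 flux {flux:.3e} M/s "
            f"exceeds tolerance {flux_tol:.1e} M/s"
        )
    return float(trajectory.h2o2_consumed[-1] / tetramer_conc)
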