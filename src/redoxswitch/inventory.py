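"""Cysteine inventories and per-subunit redox bookkeeping for GAPDH tetramers.

GAPDH is a homotetramer whose catalytic cysteine (Cc, C152 in the human
enzyme) and vicinal cysteine (Cv, C156) form a two-cysteine redox switch:
H2O2 oxidizes both to sulfenic acids, which condense to an intrachain
thiosulfinic ester.  The remaining ("downstream") cysteines stay reduced
until the thiosulfonate resolution step recruits one of them into a mixed
disulfide.  This module tracks those states at integer, per-tetramer
resolution; the kinetics live in :mod:`redoxswitch.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "CysteineState",
    "SubunitRedoxState",
    "SpeciesInventory",
    "INVENTORIES",
    "predicted_state_counts",
]

#: Labels a single cysteine may carry.  ``thiosulfinate_pair`` and
#: ``thiosulfonate_pair`` are joint states of Cc and Cv of one subunit
#: (R-S(=O)-S-R' and R-SO2-S-R' respectively).
VALID_LABELS = frozenset(
    {
        "SH",
        "SOH",
        "SO2H",
        "SO3H",
        "thiosulfinate_pair",
        "thiosulfonate_pair",
        "disulfide",
        "TNB_adduct",
        "alkylated",
    }
)

_ALKYL_AGENTS = frozenset({"NEM", "IAM", "IAA"})


@dataclass(frozen=True)
class CysteineState:
    """Oxidation/bonding state of one cysteine residue.

    Parameters
    ----------
    label:
        One of ``SH, SOH, SO2H, SO3H, thiosulfinate_pair, thiosulfonate_pair,
        disulfide, TNB_adduct, alkylated``.
    partner_id:
        For ``disulfide``: identifier of the partner cysteine.  Symmetry
        (A lists B iff B lists A) is enforced by :class:`SubunitRedoxState`.
    agent:
        For ``alkylated``: one of NEM / IAM / IAA.
    """

    label: str
    partner_id: Optional[str] = None
    agent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown cysteine state label {self.label!r}")
        if self.label == "disulfide" and self.partner_id is None:
            raise ValueError("disulfide state requires a partner_id")
        if self.label == "alkylated" and self.agent not in _ALKYL_AGENTS:
            raise ValueError(f"alkylating agent must be one of {sorted(_ALKYL_AGENTS)}")


@dataclass
class SubunitRedoxState:
    """Redox state of one GAPDH subunit: Cc, Cv, downstream cysteines, cofactor.

    NAD+ dissociates when the oxidized subunit unfolds, so an unfolded
    subunit cannot hold the cofactor.
    """

    cc: CysteineState
    cv: CysteineState
    downstream: list = field(default_factory=list)
    nad_bound: bool = True
    folded: bool = True

    def __post_init__(self) -> None:
        if not self.folded and self.nad_bound:
            raise ValueError("an unfolded subunit cannot retain bound NAD+")
        pair = {"thiosulfinate_pair", "thiosulfonate_pair"}
        if (self.cc.label in pair) != (self.cv.label in pair):
            raise ValueError(
                "thiosulfinate/thiosulfonate states are joint Cc/Cv states and "
                "must be assigned to both cysteines of the subunit"
            )
        for ds in self.downstream:
            if ds.label in pair:
                raise ValueError("downstream cysteines cannot form the Cc/Cv pair ester")
        # disulfide symmetry within the subunit's own slots
        ids = {}
        for name, st in self.named_states():
            if st.label == "disulfide":
                ids[name] = st.partner_id
        for name, partner in ids.items():
            if partner in ids and ids[partner] != name:
                raise ValueError(f"asymmetric disulfide partnership {name}<->{partner}")

    def named_states(self):
        yield "cc", self.cc
        yield "cv", self.cv
        for i, st in enumerate(self.downstream):
            yield f"d{i}", st

    @property
    def n_cysteines(self) -> int:
        return 2 + len(self.downstream)


@dataclass(frozen=True)
class SpeciesInventory:
    """Cysteine census of one GAPDH species.

    ``has_vicinal_cys`` is False for enzymes whose Cv is replaced by serine
    (e.g. the *L. acidophilus* enzyme, or a C156S-type mutant); those lack
    the switch and are only slowly inactivated through the sulfinic-acid
    side branch.
    """

    species_name: str
    cys_per_subunit: int
    subunits: int = 4
    has_vicinal_cys: bool = True

    def __post_init__(self) -> None:
        if self.cys_per_subunit < 0 or self.subunits < 1:
            raise ValueError("inventory counts must be positive")
        if self.has_vicinal_cys and self.cys_per_subunit < 2:
            raise ValueError("a vicinal-cysteine enzyme needs at least Cc and Cv")

    @property
    def cys_per_tetramer(self) -> int:
        return self.cys_per_subunit * self.subunits

    @property
    def downstream_per_subunit(self) -> int:
        return self.cys_per_subunit - (2 if self.has_vicinal_cys else 1)


#: Tetramer totals: porcine/rabbit 16, human 12, yeast 8 cysteines.
INVENTORIES = {
    "porcine": SpeciesInventory("porcine", 4),
    "rabbit": SpeciesInventory("rabbit", 4),
    "human": SpeciesInventory("human", 3),
    "yeast": SpeciesInventory("yeast", 2),
    "l_acidophilus": SpeciesInventory("l_acidophilus", 3, has_vicinal_cys=False),
    "l_plantarum": SpeciesInventory("l_plantarum", 4),
}

_STAGES = ("native", "post_oxidation", "post_incubation", "denatured_DTNB")


def predicted_state_counts(stage: str, inventory: SpeciesInventory) -> dict:
    """Per-tetramer cysteine-state census predicted by the switch mechanism.

    Stages
    ------
    native
        All cysteines reduced.
    post_oxidation
        Immediately after rapid H2O2 oxidation: every subunit carries one
        Cc/Cv thiosulfinic ester; downstream thiols untouched.
    post_incubation
        After the post-oxidation incubation: the ester has hydrolysed to the
        thiosulfonate and been resolved by a downstream thiol, leaving per
        subunit one Cc sulfinic acid, one Cv mixed disulfide and (for the
        rabbit inventory) one remaining free thiol.
    denatured_DTNB
        Oxidized enzyme denatured in DTNB buffer: free thiols form CSSTNB
        adducts and the liberated TNB opens the thiosulfinate, so every
        cysteine slot ends TNB-bound.

    Returns a dict with integer per-tetramer counts
    ``free_SH, disulfides, thiosulfinate, sulfinic_Cc, TNB_adducts``.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    n = inventory.subunits
    total = inventory.cys_per_tetramer
    counts = dict.fromkeys(
        ("free_SH", "disulfides", "thiosulfinate", "sulfinic_Cc", "TNB_adducts"), 0
    )
    if stage == "native":
        counts["free_SH"] = total
        return counts
    if not inventory.has_vicinal_cys:
        raise ValueError(
            f"stage {stage!r} requires the two-cysteine switch; "
            f"{inventory.species_name} has no vicinal cysteine"
        )
    if stage == "post_oxidation":
        counts["thiosulfinate"] = n  # one Cc/Cv ester per subunit (2 S each)
        counts["free_SH"] = total - 2 * n
    elif stage == "post_incubation":
        if inventory.downstream_per_subunit < 1:
            raise ValueError(
                "post_incubation resolution needs a downstream thiol; "
                f"{inventory.species_name} has none"
            )
        counts["sulfinic_Cc"] = n
        counts["disulfides"] = n  # Cv-S-S-C(y,z), intrachain
        counts["free_SH"] = total - 3 * n
    else:  # denatured_DTNB
        counts["TNB_adducts"] = total
    _check_closure(counts, total)
    return counts


def _check_closure(counts: dict, total: int) -> None:
    # free SH + 2 S per disulfide + 2 S per thiosulfinate pair + sulfinic + adducts
    s = (
        counts["free_SH"]
        + 2 * counts["disulfides"]
        + 2 * counts["thiosulfinate"]
        + counts["sulfinic_Cc"]
        + counts["TNB_adducts"]
    )
    if s != total:
        raise AssertionError(f"cysteine accounting violated: {s} != {total}")
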