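"""Reaction-network definition for the irradiation-induced senescence model.

The model couples five cellular modules -- DNA-damage response, oxidative
stress, FoxO3a signalling, insulin/IIS-mTOR signalling and mitochondrial
dynamics -- as 23 state variables linked by 41 irreversible mass-action
reactions.  Three external inputs drive the network: insulin and amino acids
(constant), and an irradiation impulse at time zero lasting five minutes
(model time is measured in days).

Species carry token ids ``X1``..``X23`` and reactions carry the id of their
rate constant ``k1``..``k41``.  Four activation/inactivation pairs (Akt,
mTORC1, AMPK, IKK-beta) have no synthesis or degradation, so their pool
totals are conserved and the dynamical system is effectively 19-dimensional.

The mitochondrial population is split into a "new" (functional, high membrane
potential) and an "old" (dysfunctional, low membrane potential) pool.
Biogenesis creates new mitochondria only; CDKN1A-dependent deterioration
converts new into old; mitophagy removes each pool with its own rate
constant, constrained so that clearance of old mitochondria is slower than
clearance of new ones (``k36 < k35``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "InputSignal",
    "ObservableDef",
    "ConstraintDef",
    "NetworkModel",
    "build_reference_network",
    "conservation_analysis",
    "ode_right_hand_side",
    "IRRADIATION_PULSE_WIDTH",
    "PARAM_BOUNDS",
]

#: Five minutes expressed in days: duration of the irradiation impulse.
IRRADIATION_PULSE_WIDTH = 5.0 / 1440.0

#: Bounds within which every rate constant (and scaling factor) must lie.
PARAM_BOUNDS = (1e-6, 1e4)

MODULE_TAGS = (
    "DNA-damage",
    "oxidative-stress",
    "FoxO",
    "IIS-mTOR",
    "mitochondria",
)

INPUT_NAMES = ("insulin", "amino-acids", "irradiation")


@dataclass
class SpeciesDef:
    """A model state variable (amounts in arbitrary units, a.u.)."""

    id: str
    name: str
    initial_amount: float
    module_tag: str
    conserved_pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ValueError(f"{self.id}: initial amount must be >= 0")
        if self.module_tag not in MODULE_TAGS:
            raise ValueError(f"{self.id}: unknown module tag {self.module_tag!r}")


@dataclass
class ReactionDef:
    """An irreversible mass-action reaction.

    The rate is ``k * prod(reactant amounts ** stoich) * prod(modifier
    amounts)``; modifiers enter the rate multiplicatively without being
    consumed.  Modifiers may be species ids or input names.
    """

    id: str
    reactants: dict[str, int]
    products: dict[str, int]
    modifiers: tuple[str, ...] = ()
    rate_constant: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"{self.id}: rate constant must be >= 0")
        for stoich in (*self.reactants.values(), *self.products.values()):
            if not (isinstance(stoich, (int, np.integer)) and stoich >= 0):
                raise ValueError(f"{self.id}: stoichiometries must be nonnegative integers")


@dataclass
class InputSignal:
    """External input: constant level or a square pulse starting at t=0."""

    name: str
    kind: str  # "constant" | "pulse"
    level: float
    pulse_start: float = 0.0
    pulse_width: float = IRRADIATION_PULSE_WIDTH

    def value(self, t: float) -> float:
        if self.kind == "constant":
            return self.level
        if self.pulse_start <= t < self.pulse_start + self.pulse_width:
            return self.level
        return 0.0


@dataclass
class ObservableDef:
    """A measured readout: positive scale times a sum of species amounts."""

    id: str
    name: str
    component_species: tuple[str, ...]
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.scaling_factor <= 0:
            raise ValueError(f"{self.id}: scaling factor must be positive")


@dataclass
class ConstraintDef:
    """Inequality constraint over rate constants, soft-penalised when fitting.

    ``expression`` is ``(smaller_id, larger_id)`` meaning the constraint
    ``k[smaller_id] < k[larger_id]``; ``penalty_strength`` is the lambda
    weight of the hinge penalty added to the objective.
    """

    id: str
    expression: tuple[str, str]
    penalty_strength: float = 100.0


class NetworkModel:
    """Species, reactions, inputs, observables and constraints of a network."""

    def __init__(
        self,
        species: list[SpeciesDef],
        reactions: list[ReactionDef],
        inputs: list[InputSignal],
        observables: list[ObservableDef],
        constraints: list[ConstraintDef] | None = None,
        fixed_parameter_ids: tuple[str, ...] = (),
        name: str = "model",
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.inputs = list(inputs)
        self.observables = list(observables)
        self.constraints = list(constraints or [])
        self.fixed_parameter_ids = tuple(fixed_parameter_ids)
        self.name = name
        self._validate()
        self._compile()

    # -- construction ------------------------------------------------------
    def _validate(self) -> None:
        sp_ids = [s.id for s in self.species]
        if len(set(sp_ids)) != len(sp_ids):
            raise ValueError("duplicate species ids")
        rx_ids = [r.id for r in self.reactions]
        if len(set(rx_ids)) != len(rx_ids):
            raise ValueError("duplicate reaction/parameter ids")
        known = set(sp_ids) | set(i.name for i in self.inputs)
        for r in self.reactions:
            for sid in (*r.reactants, *r.products):
                if sid not in sp_ids:
                    raise ValueError(f"reaction {r.id} references unknown species {sid!r}")
            for m in r.modifiers:
                if m not in known:
                    raise ValueError(f"reaction {r.id} references unknown modifier {m!r}")
        for obs in self.observables:
            for sid in obs.component_species:
                if sid not in sp_ids:
                    raise ValueError(f"observable {obs.id} references unknown species {sid!r}")
        for c in self.constraints:
            for pid in c.expression:
                if pid not in rx_ids:
                    raise ValueError(f"constraint {c.id} references unknown parameter {pid!r}")

    def _compile(self) -> None:
        """Precompute index arrays for fast rate evaluation."""
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        self.reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        n, m = len(self.species), len(self.reactions)
        S = np.zeros((n, m))
        self._reactant_idx: list[np.ndarray] = []
        self._reactant_sto: list[np.ndarray] = []
        self._modifier_idx: list[np.ndarray] = []
        self._input_mods: list[tuple[str, ...]] = []
        for j, r in enumerate(self.reactions):
            ridx, rsto = [], []
            for sid, sto in r.reactants.items():
                i = self.species_index[sid]
                S[i, j] -= sto
                ridx.append(i)
                rsto.append(sto)
            for sid, sto in r.products.items():
                S[self.species_index[sid], j] += sto
            smods = [self.species_index[m] for m in r.modifiers if m in self.species_index]
            imods = tuple(m for m in r.modifiers if m not in self.species_index)
            self._reactant_idx.append(np.asarray(ridx, dtype=np.intp))
            self._reactant_sto.append(np.asarray(rsto, dtype=np.intp))
            self._modifier_idx.append(np.asarray(smods, dtype=np.intp))
            self._input_mods.append(imods)
        self.stoichiometry = S
        self._inputs_by_name = {i.name: i for i in self.inputs}

    # -- basic queries -----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def parameter_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def parameter_vector(self) -> np.ndarray:
        return np.array([r.rate_constant for r in self.reactions])

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species])

    def input_levels(self, t: float) -> dict[str, float]:
        return {i.name: i.value(t) for i in self.inputs}

    def with_parameters(self, params: np.ndarray | dict) -> "NetworkModel":
        """Return a copy of the model with the given rate constants."""
        if isinstance(params, dict):
            vec = self.parameter_vector()
            for pid, val in params.items():
                vec[self.reaction_index[pid]] = val
        else:
            vec = np.asarray(params, dtype=float)
        clone = self.copy()
        for r, k in zip(clone.reactions, vec):
            r.rate_constant = float(k)
        return clone

    def copy(self) -> "NetworkModel":
        import copy as _copy

        return NetworkModel(
            _copy.deepcopy(self.species),
            _copy.deepcopy(self.reactions),
            _copy.deepcopy(self.inputs),
            _copy.deepcopy(self.observables),
            _copy.deepcopy(self.constraints),
            self.fixed_parameter_ids,
            self.name,
        )

    # -- kinetics ----------------------------------------------------------
    def rate_vector(self, state: np.ndarray, t: float, params: np.ndarray | None = None) -> np.ndarray:
        """Mass-action rates of all reactions at the given state and time."""
        if params is None:
            params = self.parameter_vector()
        rates = np.array(params, dtype=float, copy=True)
        for j in range(self.n_reactions):
            for i, sto in zip(self._reactant_idx[j], self._reactant_sto[j]):
                rates[j] *= state[i] ** sto
            for i in self._modifier_idx[j]:
                rates[j] *= state[i]
            for iname in self._input_mods[j]:
                rates[j] *= self._inputs_by_name[iname].value(t)
        return rates

    def summary_tables(self):
        """Species, reaction and parameter tables as DataFrames for export."""
        import pandas as pd

        species = pd.DataFrame(
            [
                dict(id=s.id, name=s.name, initial_amount=s.initial_amount,
                     module=s.module_tag, conserved_pair=s.conserved_pair_id or "")
                for s in self.species
            ]
        )
        reactions = pd.DataFrame(
            [
                dict(
                    id=r.id,
                    name=r.name,
                    reactants=" + ".join(f"{v}*{k}" if v > 1 else k
                                         for k, v in r.reactants.items()),
                    products=" + ".join(f"{v}*{k}" if v > 1 else k
                                        for k, v in r.products.items()),
                    modifiers=" ".join(r.modifiers),
                    rate_constant=r.rate_constant,
                )
                for r in self.reactions
            ]
        )
        parameters = pd.DataFrame(
            [dict(id=r.id, value=r.rate_constant,
                  fixed=r.id in self.fixed_parameter_ids) for r in self.reactions]
        )
        return {"species": species, "reactions": reactions, "parameters": parameters}

    def summary(self) -> dict[str, int]:
        return {
            "n_species": self.n_species,
            "n_reactions": self.n_reactions,
            "n_inputs": len(self.inputs),
            "n_observables": len(self.observables),
            "n_constraints": len(self.constraints),
        }


def ode_right_hand_side(
    model: NetworkModel, state: np.ndarray, t: float, params: np.ndarray | None = None
) -> np.ndarray:
    """Time derivative of the state: stoichiometry times mass-action rates.

    Raises ``ValueError`` on a negative state entry (amounts are physical).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError(f"state must have {model.n_species} entries")
    if np.any(state < 0):
        raise ValueError("state amounts must be nonnegative")
    return model.stoichiometry @ model.rate_vector(state, t, params)


def conservation_analysis(model: NetworkModel):
    """Conserved moieties of the network from the left null space of S.

    Returns ``(laws, reduced_dim)`` where each law is a dict mapping species
    id to a nonnegative integer weight such that the weighted sum of amounts
    is constant in time, and ``reduced_dim = n_species - n_laws``.
    """
    import sympy

    S = sympy.Matrix(model.stoichiometry.astype(int))
    basis = S.T.nullspace()
    laws = []
    for vec in basis:
        denominators = [sympy.fraction(sympy.nsimplify(x))[1] for x in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denominators]) if denominators else 1
        ints = [sympy.Integer(x * scale) for x in vec]
        if all(x <= 0 for x in ints):
            ints = [-x for x in ints]
        if any(x < 0 for x in ints):  # mixed-sign basis vector: keep as is
            pass
        law = {
            model.species[i].id: int(w)
            for i, w in enumerate(ints)
            if w != 0
        }
        laws.append(law)
    return laws, model.n_species - len(laws)


# ---------------------------------------------------------------------------
# Reference reconstruction
# ---------------------------------------------------------------------------

#: Calibrated rate constants of the reference parameterisation (per day in the
#: appropriate mass-action units).  k27/k28 (IKK-beta cycling) are assumed a
#: priori and held fixed during fitting.
REFERENCE_PARAMS: dict[str, float] = {
    # IIS-mTOR signalling (k1-k11)
    "k1": 1.0,                  # Akt activation by insulin
    "k2": 2.0,                  # Akt inactivation, mTORC1-S6K negative feedback
    "k3": 2.9999825026707420,   # AMPK activation
    "k4": 2.0,                  # AMPK inactivation by cellular energy (consumes energy)
    "k5": 1e-4,                 # energy production by old (dysfunctional) mitochondria
    "k6": 0.5970174455518106,   # mTORC1 activation by amino acids
    "k7": 8.2556378095256400,   # mTORC1 activation by Akt (insulin-dependent)
    "k8": 9.9503139731340530,   # mTORC1 inactivation by AMPK
    "k9": 1.0,                  # mitophagy induction by AMPK and nuclear FoxO3a
    "k10": 1.1999972004175217,  # mitophagy decay
    "k11": 1.1999972004175217,  # energy production by new mitochondria
    # DDR / oxidative-stress / FoxO signalling (k12-k32)
    "k12": 5.0,                 # ROS clearance
    "k13": 2.0,                 # JNK activation by ROS
    "k14": 0.015,               # FoxO3a synthesis (constitutive)
    "k15": 1.25,                # FoxO3a nuclear import, JNK-driven
    "k16": 0.075,               # FoxO3a phosphorylation at S253 by Akt (nuclear export)
    "k17": 0.05,                # FoxO3a-pS253 ubiquitination and degradation
    "k18": 2.0,                 # JNK inactivation
    "k19": 21.529423448713800,  # irradiation-induced DNA damage
    "k20": 3.1115827325019225,  # ROS-induced DNA damage
    "k21": 3.1115827325019225,  # DNA damage repair
    "k22": 1.6147988096755377,  # CDKN1A induction by DNA damage (cooperative)
    "k23": 0.3005601009797070,  # CDKN1A removal, Akt-dependent
    "k24": 0.125,               # CDKN1B induction by nuclear FoxO3a
    "k25": 2.0,                 # CDKN1B removal, Akt-dependent
    "k26": 0.1,                 # ROS production by new mitochondria (membrane potential)
    "k27": 3.0,                 # IKK-beta activation by ROS (assumed a priori)
    "k28": 0.2478343784941838,  # IKK-beta inactivation (assumed a priori)
    "k29": 6.3892980271739335,  # mTORC1 activation by IKK-beta (inflammatory arm)
    "k30": 1.0,                 # SA-beta-gal production from ROS (lipofuscin)
    "k31": 1.0,                 # SA-beta-gal clearance by autophagic flux
    "k32": 0.7688413936384780,  # ROS amplification by old mitochondria (second order)
    # mitochondrial dynamics (k33-k41)
    "k33": 2.3906098340642803,  # biogenesis of new mitochondria via mTORC1
    "k34": 0.01,                # biogenesis of new mitochondria via AMPK
    "k35": 5.9988074193683730,  # mitophagy of new mitochondria
    "k36": 1e-3,                # mitophagy of old mitochondria (constrained < k35)
    "k37": 0.3590928913019030,  # deterioration of new into old mitochondria (CDKN1A)
    "k38": 2.0,                 # membrane-potential generation by new mass
    "k39": 1.8831148380631660,  # basal membrane-potential decay, new pool
    "k40": 5.8442580968417090,  # ROS-driven membrane-potential loss, new pool
    "k41": 2.0,                 # membrane-potential decay, old pool
}

#: Basal (pre-irradiation) amounts, a.u.  Phosphorylated and unphosphorylated
#: states across the IIS-TOR pathway start with equal amounts; stress-response
#: species start at a low but nonzero basal level; the old mitochondrial pool
#: starts empty.
REFERENCE_INITIAL: dict[str, float] = {
    "X1": 0.5,                     # Akt (inactive)
    "X2": 0.5,                     # Akt-pS473
    "X3": 0.5,                     # mTORC1 (inactive)
    "X4": 0.5,                     # mTOR-pS2448
    "X5": 0.4000013997912392,      # AMPK (inactive)
    "X6": 0.5999986002087608,      # AMPK-pT172
    "X7": 1.0,                     # Energy (ATP)
    "X8": 0.4,                     # FoxO3a-nuc
    "X9": 0.6,                     # FoxO3a-cyt
    "X10": 0.3,                    # FoxO3a-pS253
    "X11": 0.02,                   # DNA damage
    "X12": 0.004298105581976936,   # CDKN1A
    "X13": 0.05,                   # CDKN1B
    "X14": 0.02,                   # ROS
    "X15": 0.02,                   # JNK-pT183
    "X16": 0.1,                    # SA-beta-gal
    "X17": 0.8050899958169109,     # IKK-beta (inactive)
    "X18": 0.1949100041830891,     # IKK-beta (active)
    "X19": 0.2,                    # Mitophagy
    "X20": 1.0,                    # Mito-mass-new
    "X21": 0.0,                    # Mito-mass-old
    "X22": 1.0,                    # Mito-psim-new
    "X23": 0.0,                    # Mito-psim-old
}

#: Amplitude of the irradiation input encoding the 20 Gy X-ray dose.  This is
#: a calibrated model parameter, not a physical dose conversion.
IRRADIATION_AMPLITUDE = 20.0

_SPECIES_TABLE = [
    # id, name, module, conserved pair
    ("X1", "Akt", "IIS-mTOR", "Akt"),
    ("X2", "Akt-pS473", "IIS-mTOR", "Akt"),
    ("X3", "mTORC1", "IIS-mTOR", "mTORC1"),
    ("X4", "mTOR-pS2448", "IIS-mTOR", "mTORC1"),
    ("X5", "AMPK", "IIS-mTOR", "AMPK"),
    ("X6", "AMPK-pT172", "IIS-mTOR", "AMPK"),
    ("X7", "Energy", "IIS-mTOR", None),
    ("X8", "FoxO3a-nuc", "FoxO", None),
    ("X9", "FoxO3a-cyt", "FoxO", None),
    ("X10", "FoxO3a-pS253", "FoxO", None),
    ("X11", "DNA-damage", "DNA-damage", None),
    ("X12", "CDKN1A", "DNA-damage", None),
    ("X13", "CDKN1B", "DNA-damage", None),
    ("X14", "ROS", "oxidative-stress", None),
    ("X15", "JNK-pT183", "oxidative-stress", None),
    ("X16", "SA-beta-gal", "oxidative-stress", None),
    ("X17", "IKK-beta", "oxidative-stress", "IKK-beta"),
    ("X18", "IKK-beta-active", "oxidative-stress", "IKK-beta"),
    ("X19", "Mitophagy", "mitochondria", None),
    ("X20", "Mito-mass-new", "mitochondria", None),
    ("X21", "Mito-mass-old", "mitochondria", None),
    ("X22", "Mito-psim-new", "mitochondria", None),
    ("X23", "Mito-psim-old", "mitochondria", None),
]

_REACTION_TABLE = [
    # id, reactants, products, modifiers, name
    ("k1", {"X1": 1}, {"X2": 1}, ("insulin",), "Akt activation by insulin"),
    ("k2", {"X2": 1}, {"X1": 1}, ("X4",), "Akt inactivation (mTORC1-S6K feedback)"),
    ("k3", {"X5": 1}, {"X6": 1}, (), "AMPK activation"),
    ("k4", {"X6": 1, "X7": 1}, {"X5": 1}, (), "AMPK inactivation by energy"),
    ("k5", {}, {"X7": 1}, ("X23",), "energy production by old mitochondria"),
    ("k6", {"X3": 1}, {"X4": 1}, ("amino-acids",), "mTORC1 activation by amino acids"),
    ("k7", {"X3": 1}, {"X4": 1}, ("X2",), "mTORC1 activation by Akt"),
    ("k8", {"X4": 1}, {"X3": 1}, ("X6",), "mTORC1 inactivation by AMPK"),
    ("k9", {}, {"X19": 1}, ("X6", "X8"), "mitophagy induction by AMPK and FoxO3a"),
    ("k10", {"X19": 1}, {}, (), "mitophagy decay"),
    ("k11", {}, {"X7": 1}, ("X22",), "energy production by new mitochondria"),
    ("k12", {"X14": 1}, {}, (), "ROS clearance"),
    ("k13", {}, {"X15": 1}, ("X14",), "JNK activation by ROS"),
    ("k14", {}, {"X9": 1}, (), "FoxO3a synthesis (constitutive)"),
    ("k15", {"X9": 1}, {"X8": 1}, ("X15",), "FoxO3a nuclear import (JNK)"),
    ("k16", {"X8": 1}, {"X10": 1}, ("X2",), "FoxO3a phosphorylation by Akt (export)"),
    ("k17", {"X10": 1}, {}, (), "FoxO3a-pS253 degradation"),
    ("k18", {"X15": 1}, {}, (), "JNK inactivation"),
    ("k19", {}, {"X11": 1}, ("irradiation",), "irradiation-induced DNA damage"),
    ("k20", {}, {"X11": 1}, ("X14",), "ROS-induced DNA damage"),
    ("k21", {"X11": 1}, {}, (), "DNA damage repair"),
    ("k22", {}, {"X12": 1}, ("X11", "X11"), "CDKN1A induction by DNA damage (cooperative)"),
    ("k23", {"X12": 1}, {}, ("X2",), "CDKN1A removal (Akt-dependent)"),
    ("k24", {}, {"X13": 1}, ("X8",), "CDKN1B induction by FoxO3a"),
    ("k25", {"X13": 1}, {}, ("X2",), "CDKN1B removal (Akt-dependent)"),
    ("k26", {}, {"X14": 1}, ("X22",), "ROS production by new mitochondria"),
    ("k27", {"X17": 1}, {"X18": 1}, ("X14",), "IKK-beta activation by ROS"),
    ("k28", {"X18": 1}, {"X17": 1}, (), "IKK-beta inactivation"),
    ("k29", {"X3": 1}, {"X4": 1}, ("X18",), "mTORC1 activation by IKK-beta"),
    ("k30", {}, {"X16": 1}, ("X14",), "SA-beta-gal production from ROS"),
    ("k31", {"X16": 1}, {}, ("X19",), "SA-beta-gal clearance by autophagy"),
    ("k32", {}, {"X14": 1}, ("X21", "X21"), "ROS amplification by old mitochondria (cooperative)"),
    ("k33", {}, {"X20": 1}, ("X4",), "mitochondrial biogenesis via mTORC1"),
    ("k34", {}, {"X20": 1}, ("X6",), "mitochondrial biogenesis via AMPK"),
    ("k35", {"X20": 1}, {}, ("X19",), "mitophagy of new mitochondria"),
    ("k36", {"X21": 1}, {}, ("X19",), "mitophagy of old mitochondria"),
    ("k37", {"X20": 1}, {"X21": 1, "X23": 1}, ("X12",), "deterioration of new into old mitochondria"),
    ("k38", {}, {"X22": 1}, ("X20",), "membrane potential generation (new)"),
    ("k39", {"X22": 1}, {}, (), "membrane potential decay (new)"),
    ("k40", {"X22": 1}, {}, ("X14",), "membrane potential loss by ROS (new)"),
    ("k41", {"X23": 1}, {}, (), "membrane potential decay (old)"),
]

_OBSERVABLE_TABLE = [
    ("Y1", "Akt-pS473", ("X2",)),
    ("Y2", "mTOR-pS2448", ("X4",)),
    ("Y3", "AMPK-pT172", ("X6",)),
    ("Y4", "JNK-pT183", ("X15",)),
    ("Y5", "FoxO3a-total", ("X8", "X9")),
    ("Y6", "FoxO3a-pS253", ("X10",)),
    ("Y7", "CDKN1A", ("X12",)),
    ("Y8", "CDKN1B", ("X13",)),
    ("Y9", "DNA-damage", ("X11",)),
    ("Y10", "ROS", ("X14",)),
    ("Y11", "SA-beta-gal", ("X16",)),
    ("Y12", "Mitophagy", ("X19",)),
    ("Y13", "Mitochondrial-Mass", ("X20", "X21")),
    ("Y14", "Mitochondrial-Membrane-Potential", ("X22", "X23")),
]


def build_reference_network(
    params: dict[str, float] | None = None,
    initial: dict[str, float] | None = None,
    irradiation_amplitude: float = IRRADIATION_AMPLITUDE,
) -> NetworkModel:
    """Build the reference 23-species / 41-reaction senescence network.

    ``params`` / ``initial`` override individual rate constants or initial
    amounts of the calibrated reference parameterisation.
    """
    kvals = dict(REFERENCE_PARAMS)
    if params:
        kvals.update(params)
    x0 = dict(REFERENCE_INITIAL)
    if initial:
        x0.update(initial)

    species = [
        SpeciesDef(sid, name, x0[sid], module, pair)
        for sid, name, module, pair in _SPECIES_TABLE
    ]
    reactions = [
        ReactionDef(rid, dict(rea), dict(pro), mods, kvals[rid], name)
        for rid, rea, pro, mods, name in _REACTION_TABLE
    ]
    inputs = [
        InputSignal("insulin", "constant", 1.0),
        InputSignal("amino-acids", "constant", 1.0),
        InputSignal("irradiation", "pulse", irradiation_amplitude, 0.0, IRRADIATION_PULSE_WIDTH),
    ]
    observables = [ObservableDef(oid, name, comps) for oid, name, comps in _OBSERVABLE_TABLE]
    constraints = [ConstraintDef("CS1", ("k36", "k35"), penalty_strength=100.0)]
    return NetworkModel(
        species,
        reactions,
        inputs,
        observables,
        constraints,
        fixed_parameter_ids=("k27", "k28"),
        name="senescence-reference",
    )
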