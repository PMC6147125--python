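"""Temperature-dependent Gibbs free energies of the four central pathways.

The anaerobic degradation of rice straw in paddy-soil slurries funnels
carbon through acetate, propionate and H2 into CH4.  Whether a given
pathway can run at all is decided by its Gibbs free energy under the
*actual* (non-standard) concentrations and partial pressures, evaluated
with the Nernst equation in the linearised form

    dG(T) = dH0 - RB*T + R*T*ln(Q)

where dH0 is the reaction enthalpy (kJ/mol), RB the linearised entropy
constant (kJ/mol/K, so that dH0 - RB*T is the standard-state dG at T),
R = 8.3145e-3 kJ/mol/K, and Q the mass-action quotient of the reaction
with gases expressed in bar and solutes in mol/L.

The four reactions, written per mole of organic substrate (per CH4 for
hydrogenotrophic methanogenesis):

1. syntrophic acetate oxidation (SAO):
       CH3COO- + H+ + 2 H2O -> 4 H2 + 2 CO2
2. syntrophic propionate oxidation (SPO):
       CH3CH2COO- + 2 H2O -> CH3COO- + CO2 + 3 H2
3. acetoclastic methanogenesis (AM):
       CH3COO- + H+ -> CH4 + CO2
4. hydrogenotrophic methanogenesis (HM):
       4 H2 + CO2 -> CH4 + 2 H2O

SAO is endergonic unless a hydrogenotrophic partner keeps p(H2) very
low; its feasibility window is the thermodynamic core of the 30 degC vs
45 degC contrast this package analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import pandas as pd

from paddyweb.errors import ConfigurationError, DomainError, ValidationError

logger = logging.getLogger(__name__)

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.3145e-3

#: Default detection floors used when converting raw measurements:
#: gases in bar, solutes in mol/L.  H2 in particular falls below the
#: detection limit during the late incubation stage and must be floored
#: for ln(Q) to stay defined.
DEFAULT_FLOORS = MappingProxyType(
    {"p_H2": 1e-6, "p_CO2": 1e-6, "p_CH4": 1e-6, "acetate": 1e-6, "propionate": 1e-6}
)

SAO = "syntrophic_acetate_oxidation"
SPO = "syntrophic_propionate_oxidation"
AM = "acetoclastic_methanogenesis"
HM = "hydrogenotrophic_methanogenesis"

REACTION_NAMES = (SAO, SPO, AM, HM)


@dataclass(frozen=True)
class ReactionSpec:
    """Identity and thermodynamic constants of one pathway.

    ``quotient_exponents`` maps species names to their signed exponent
    in the mass-action quotient Q (positive exponents are products in
    the numerator).  Water does not appear: its activity is taken as 1.
    """

    name: str
    delta_H0: float  # kJ/mol
    RB: float  # kJ/mol/K
    quotient_exponents: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "quotient_exponents", MappingProxyType(dict(self.quotient_exponents))
        )


_REGISTRY: tuple[ReactionSpec, ...] = (
    ReactionSpec(
        name=SAO,
        delta_H0=270.6,
        RB=0.723,
        quotient_exponents={"p_H2": 4, "p_CO2": 2, "acetate": -1, "proton": -1},
    ),
    ReactionSpec(
        name=SPO,
        delta_H0=205.1,
        RB=0.447,
        quotient_exponents={"acetate": 1, "p_CO2": 1, "p_H2": 3, "propionate": -1},
    ),
    ReactionSpec(
        name=AM,
        delta_H0=17.7,
        RB=0.314,
        quotient_exponents={"p_CO2": 1, "p_CH4": 1, "acetate": -1, "proton": -1},
    ),
    ReactionSpec(
        name=HM,
        delta_H0=-252.9,
        RB=-0.41,
        quotient_exponents={"p_CH4": 1, "p_H2": -4, "p_CO2": -1},
    ),
)


def reaction_registry() -> tuple[ReactionSpec, ...]:
    """Return the four pathway specs (immutable)."""
    return _REGISTRY


def get_reaction(name: str) -> ReactionSpec:
    """Look up one pathway spec by name."""
    for spec in _REGISTRY:
        if spec.name == name:
            return spec
    raise ConfigurationError(f"unknown reaction {name!r}; choose from {REACTION_NAMES}")


@dataclass(frozen=True)
class ChemicalState:
    """One sample's measured chemistry in SI-consistent units.

    Temperature in K, solutes in mol/L, gas partial pressures in bar.
    Use :meth:`from_measurements` to convert the units the chemistry is
    measured in (degC, mM, kPa) and to apply detection floors.
    """

    temperature: float
    pH: float = 7.0
    acetate: float = 1.0
    propionate: float = 1.0
    p_H2: float = 1.0
    p_CO2: float = 1.0
    p_CH4: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError(f"temperature must be positive K, got {self.temperature}")
        if not (0.0 <= self.pH <= 14.0):
            raise ValidationError(f"pH must lie in [0, 14], got {self.pH}")
        for species in ("acetate", "propionate", "p_H2", "p_CO2", "p_CH4"):
            value = getattr(self, species)
            if not (value > 0) or not math.isfinite(value):
                raise DomainError(f"activity of {species} must be positive and finite, got {value}")

    @classmethod
    def from_measurements(
        cls,
        temperature_C: float,
        pH: float = 7.0,
        acetate_mM: float = 0.0,
        propionate_mM: float = 0.0,
        pH2_kPa: float = 0.0,
        pCO2_kPa: float = 0.0,
        pCH4_kPa: float = 0.0,
        floors: Mapping[str, float] = DEFAULT_FLOORS,
    ) -> "ChemicalState":
        """Build a state from field units (degC, mM, kPa), flooring
        undetectable values at the configured minima (bar / mol/L)."""

        def floored(species: str, value: float) -> float:
            floor = floors[species]
            if value < floor:
                logger.debug("flooring %s: %.3g -> %.3g", species, value, floor)
                return floor
            return value

        return cls(
            temperature=temperature_C + 273.15,
            pH=pH,
            acetate=floored("acetate", acetate_mM * 1e-3),
            propionate=floored("propionate", propionate_mM * 1e-3),
            p_H2=floored("p_H2", pH2_kPa * 0.01),
            p_CO2=floored("p_CO2", pCO2_kPa * 0.01),
            p_CH4=floored("p_CH4", pCH4_kPa * 0.01),
        )

    def activity(self, species: str) -> float:
        """Dimensionless activity of a species (1 bar / 1 M standard state)."""
        if species == "proton":
            return 10.0 ** (-self.pH)
        try:
            return getattr(self, species)
        except AttributeError:
            raise ConfigurationError(f"state has no species {species!r}") from None


@dataclass(frozen=True)
class GibbsResult:
    """dG of one reaction in one state, with the feasibility verdict."""

    reaction: str
    delta_G: float  # kJ/mol reaction as written
    ln_Q: float
    feasible: bool
    threshold_used: float


def reaction_quotient(spec: ReactionSpec, state: ChemicalState) -> float:
    """ln Q = sum over species of exponent * ln(activity).

    Activities: gases in bar, solutes in mol/L, [H+] = 10^-pH, water
    omitted (activity 1).
    """
    ln_q = 0.0
    for species, exponent in spec.quotient_exponents.items():
        a = state.activity(species)
        if not (a > 0):
            raise DomainError(f"non-positive activity for {species}: {a}")
        ln_q += exponent * math.log(a)
    return ln_q


def gibbs_energy(
    spec: ReactionSpec, state: ChemicalState, threshold: float = 0.0
) -> GibbsResult:
    """Evaluate dG(T) = dH0 - RB*T + R*T*ln(Q) for one state.

    dG is per mole of reaction as written: per acetate for SAO and AM,
    per propionate for SPO, per CH4 for HM.
    """
    ln_q = reaction_quotient(spec, state)
    delta_g = spec.delta_H0 - spec.RB * state.temperature + R_KJ * state.temperature * ln_q
    return GibbsResult(
        reaction=spec.name,
        delta_G=delta_g,
        ln_Q=ln_q,
        feasible=feasibility(delta_g, threshold),
        threshold_used=threshold,
    )


def feasibility(delta_G: float, threshold: float = 0.0) -> bool:
    """A pathway is feasible iff dG < threshold (strict).

    The default threshold is 0 kJ/mol; pass e.g. -20 kJ/mol to require
    the biological energy quantum instead.
    """
    if math.isnan(delta_G):
        raise DomainError("delta_G is NaN")
    return delta_G < threshold


def states_from_frame(
    chem: pd.DataFrame,
    pH: float | None = None,
    floors: Mapping[str, float] = DEFAULT_FLOORS,
) -> list[ChemicalState]:
    """Convert a chemistry table (day, replicate, temperature_C, [pH],
    acetate_mM, propionate_mM, pH2_kPa, pCO2_kPa, pCH4_kPa) into states.

    ``pH`` overrides any pH column; when neither is present the default
    7.0 is used and logged.
    """
    required = {"temperature_C", "acetate_mM", "propionate_mM", "pH2_kPa", "pCO2_kPa", "pCH4_kPa"}
    missing = required - set(chem.columns)
    if missing:
        raise ConfigurationError(f"chemistry table lacks columns: {sorted(missing)}")
    if pH is None and "pH" not in chem.columns:
        logger.info("no pH column and no override: assuming pH 7.0 for all samples")
    states = []
    for _, row in chem.iterrows():
        row_ph = pH if pH is not None else float(row.get("pH", 7.0))
        states.append(
            ChemicalState.from_measurements(
                temperature_C=float(row["temperature_C"]),
                pH=row_ph,
                acetate_mM=float(row["acetate_mM"]),
                propionate_mM=float(row["propionate_mM"]),
                pH2_kPa=float(row["pH2_kPa"]),
                pCO2_kPa=float(row["pCO2_kPa"]),
                pCH4_kPa=float(row["pCH4_kPa"]),
                floors=floors,
            )
        )
    return states


def gibbs_profile(
    chem: pd.DataFrame,
    reactions: Sequence[str] | None = None,
    pH: float | None = None,
    threshold: float = 0.0,
    floors: Mapping[str, float] = DEFAULT_FLOORS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """dG time course for every sample x reaction.

    ``chem`` is the chemistry table with ``day`` and ``replicate``
    columns.  Returns ``(per_sample, summary)``: one row per state and
    reaction, and the replicate mean +/- SE per (day, reaction).
    """
    if chem.empty:
        raise ValidationError("chemistry table is empty")
    for col in ("day", "replicate"):
        if col not in chem.columns:
            raise ValidationError(f"chemistry table lacks required column {col!r}")
    if chem.duplicated(subset=["day", "replicate"]).any():
        raise ValidationError("duplicate (day, replicate) pairs in chemistry table")
    if reactions is None:
        reactions = REACTION_NAMES
    specs = [get_reaction(name) for name in reactions]
    states = states_from_frame(chem, pH=pH, floors=floors)

    rows = []
    for (_, meta), state in zip(chem.iterrows(), states):
        for spec in specs:
            res = gibbs_energy(spec, state, threshold=threshold)
            rows.append(
                {
                    "day": meta["day"],
                    "replicate": meta["replicate"],
                    "reaction": spec.name,
                    "delta_G": res.delta_G,
                    "ln_Q": res.ln_Q,
                    "feasible": res.feasible,
                }
            )
    per_sample = pd.DataFrame(rows)
    grouped = per_sample.groupby(["day", "reaction"], sort=True)["delta_G"]
    summary = grouped.agg(
        mean_delta_G="mean",
        se_delta_G=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
        n="size",
    ).reset_index()
    return per_sample, summary


# ---------------------------------------------------------------------------
# Validation of the registry constants from standard formation data
# ---------------------------------------------------------------------------

#: CODATA/NIST standard formation enthalpies (kJ/mol) and absolute
#: entropies (J/mol/K) at 298.15 K.  Aqueous ions on the conventional
#: H+(aq) = (0, 0) scale.
FORMATION_DATA: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        "H2(g)": (0.0, 130.68),
        "CO2(g)": (-393.51, 213.79),
        "CH4(g)": (-74.81, 186.26),
        "H2O(l)": (-285.83, 69.95),
        "H+(aq)": (0.0, 0.0),
        "acetate(aq)": (-486.0, 86.6),
        "propionate(aq)": (-511.9, 111.0),
    }
)

#: Stoichiometries of the four reactions as written (products positive),
#: for checking the registry constants against formation data.
REACTION_STOICHIOMETRY: Mapping[str, Mapping[str, float]] = MappingProxyType(
    {
        SAO: {"acetate(aq)": -1, "H+(aq)": -1, "H2O(l)": -2, "H2(g)": 4, "CO2(g)": 2},
        SPO: {"propionate(aq)": -1, "H2O(l)": -2, "acetate(aq)": 1, "CO2(g)": 1, "H2(g)": 3},
        AM: {"acetate(aq)": -1, "H+(aq)": -1, "CH4(g)": 1, "CO2(g)": 1},
        HM: {"H2(g)": -4, "CO2(g)": -1, "CH4(g)": 1, "H2O(l)": 2},
    }
)


def enthalpy_entropy_check(
    formation_table: Mapping[str, tuple[float, float]],
    stoichiometry: Mapping[str, float],
) -> tuple[float, float]:
    """Reaction dH0 (kJ/mol) and dS0 (kJ/mol/K) from formation data.

    dH0 = sum(nu * dHf); dS0 = sum(nu * S0)/1000.  Used to validate the
    registry's printed (dH0, RB) pairs: in the linearised Nernst form,
    RB plays the role of the standard reaction entropy.
    """
    dh = 0.0
    ds = 0.0
    for species, nu in stoichiometry.items():
        if species not in formation_table:
            raise ConfigurationError(f"formation table lacks species {species!r}")
        hf, s0 = formation_table[species]
        dh += nu * hf
        ds += nu * s0
    return dh, ds / 1000.0
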