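"""Kinetic parameterizations, reaction schemes, and closed-form rate expressions.

The central reaction scheme couples a classical enzyme-substrate cycle to a
slowly interconverting alternate enzyme form::

    E  + S <-> ES  -> E  + P        (k1, k_off, kcat_E)
    E* + S <-> E*S -> E* + P        (k1, k_off_star, kcat_Estar)
    E  <-> E*                        (kE_fwd / kE_rev)
    ES <-> E*S                       (kES_fwd / kES_rev)

The four-state sub-cycle E -> ES -> E*S -> E* -> E is closed, so only seven of
the eight first-order rates are independent: the dissociation rate of E*S is
always derived from the others (thermodynamic cycle closure).

Units: time s, concentration uM, first-order rates 1/s, k1 in 1/(s*uM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "RateParameters",
    "EquilibriumParams",
    "ApparentParams",
    "Reaction",
    "SchemeSpec",
    "DegenerateCycleError",
    "cycle_closure",
    "eq_to_rates",
    "rates_to_eq",
    "michaelis_constants",
    "apparent_post_params",
    "initial_rate_short_time",
    "build_single_substrate_scheme",
    "build_coupled_scheme",
]

#: Default second-order association rate, 1/(s*uM).  Treated as known rather
#: than fitted: the data carry little information on it and it sits near the
#: diffusion limit.
DEFAULT_K1 = 0.2


class DegenerateCycleError(ValueError):
    """Raised when cycle closure is requested with a vanishing reverse rate."""


@dataclass(frozen=True)
class RateParameters:
    """Micro-kinetic rate constants of one enzyme's alternate-state scheme.

    ``k_off_star`` (dissociation of E*S) is derived, never stored: see
    :func:`cycle_closure`.
    """

    k1: float = DEFAULT_K1  # 1/(s*uM), shared by E+S and E*+S
    k_off: float = 10.0     # 1/s, dissociation of ES
    kcat_E: float = 0.1     # 1/s
    kcat_Estar: float = 0.0  # 1/s
    kE_fwd: float = 0.001   # 1/s, E -> E*
    kE_rev: float = 0.001   # 1/s, E* -> E
    kES_fwd: float = 0.001  # 1/s, ES -> E*S
    kES_rev: float = 0.001  # 1/s, E*S -> ES

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"rate {f.name} must be finite and >= 0, got {v!r}")

    @property
    def Keq_E(self) -> float:
        """Equilibrium constant [E*]/[E] of the free-enzyme exchange."""
        if self.kE_rev == 0.0:
            raise DegenerateCycleError("Keq(E) undefined: kE_rev is zero")
        return self.kE_fwd / self.kE_rev

    @property
    def Keq_ES(self) -> float:
        """Equilibrium constant [E*S]/[ES] of the complex exchange."""
        if self.kES_rev == 0.0:
            raise DegenerateCycleError("Keq(ES) undefined: kES_rev is zero")
        return self.kES_fwd / self.kES_rev

    @property
    def k_off_star(self) -> float:
        return cycle_closure(self)

    @property
    def p_E(self) -> float:
        """Population of E (not E*) at the pre-reaction exchange equilibrium."""
        return 1.0 / (1.0 + self.Keq_E)

    def replace(self, **changes: float) -> "RateParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        """Serializable mapping keyed by conventional symbol names."""
        return {
            "k1": self.k1,
            "k_m1": self.k_off,
            "kcat_E": self.kcat_E,
            "kcat_Estar": self.kcat_Estar,
            "kE": self.kE_fwd,
            "k_mE": self.kE_rev,
            "kES": self.kES_fwd,
            "k_mES": self.kES_rev,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RateParameters":
        return cls(
            k1=d["k1"],
            k_off=d["k_m1"],
            kcat_E=d["kcat_E"],
            kcat_Estar=d["kcat_Estar"],
            kE_fwd=d["kE"],
            kE_rev=d["k_mE"],
            kES_fwd=d["kES"],
            kES_rev=d["k_mES"],
        )


def cycle_closure(params: RateParameters) -> float:
    """Derived dissociation rate of E*S, ``k_off_star``.

    Net flux around the cycle E -> ES -> E*S -> E* -> E must vanish at
    equilibrium, which forces

        k_off_star = Keq(E) / Keq(ES) * k_off
    """
    if params.k_off == 0.0:
        return 0.0
    if params.kE_rev == 0.0:
        raise DegenerateCycleError(
            "cannot close the exchange cycle: kE_rev (E* -> E) is zero"
        )
    if params.kES_fwd == 0.0:
        raise DegenerateCycleError(
            "cannot close the exchange cycle: kES_fwd (ES -> E*S) is zero"
        )
    if params.kE_fwd == 0.0 or params.kES_rev == 0.0:
        # Keq(E)=0 or Keq(ES)=inf: E*S cannot release substrate.
        return 0.0
    return (params.kE_fwd / params.kE_rev) * (params.kES_rev / params.kES_fwd) * params.k_off


@dataclass(frozen=True)
class EquilibriumParams:
    """(Keq, kex) description of a two-state exchange.

    Convention: ``kex = forward + reverse`` and ``Keq = forward / reverse``
    (the usual NMR exchange-rate convention).  Conversion to and from the
    rate pair is exact, see :func:`eq_to_rates` / :func:`rates_to_eq`.
    """

    Keq: float
    kex: float

    def __post_init__(self) -> None:
        if not self.Keq > 0.0:
            raise ValueError(f"Keq must be > 0, got {self.Keq!r}")
        if self.kex < 0.0:
            raise ValueError(f"kex must be >= 0, got {self.kex!r}")


def eq_to_rates(eq: EquilibriumParams) -> tuple[float, float]:
    """Convert (Keq, kex) to the (forward, reverse) first-order rate pair."""
    fwd = eq.kex * eq.Keq / (1.0 + eq.Keq)
    rev = eq.kex / (1.0 + eq.Keq)
    return fwd, rev


def rates_to_eq(forward: float, reverse: float) -> EquilibriumParams:
    """Inverse of :func:`eq_to_rates`."""
    if not reverse > 0.0:
        raise ValueError("reverse rate must be > 0 to define Keq")
    return EquilibriumParams(Keq=forward / reverse, kex=forward + reverse)


@dataclass(frozen=True)
class ApparentParams:
    """Post-equilibrium apparent Michaelis-Menten parameters."""

    KM_app: float    # uM
    kcat_app: float  # 1/s

    @property
    def efficiency(self) -> float:
        """kcat_app / KM_app in 1/(s*mM)."""
        return self.kcat_app / self.KM_app * 1000.0


def michaelis_constants(params: RateParameters) -> tuple[float, float]:
    """Michaelis constants of the E and E* branches, in uM.

    KM_E  = (kcat_E + k_off) / k1
    KM_E* = (kcat_Estar + k_off_star) / k1
    """
    if params.k1 == 0.0:
        raise ValueError("k1 must be > 0 to define Michaelis constants")
    km_e = (params.kcat_E + params.k_off) / params.k1
    km_estar = (params.kcat_Estar + params.k_off_star) / params.k1
    return km_e, km_estar


def apparent_post_params(params: RateParameters) -> ApparentParams:
    """Apparent MM parameters valid once ES <-> E*S exchange has equilibrated.

        KM_app   = KM_E * (1 + Keq(E)) / (1 + Keq(ES))
        kcat_app = (kcat_E + Keq(ES) * kcat_Estar) / (1 + Keq(ES))

    kcat_app is evaluated in the division-safe form (no kcat_E denominator);
    it is algebraically identical to kcat_E*(1 + Keq(ES)*kcat_Estar/kcat_E)
    / (1 + Keq(ES)) wherever that form is defined.
    """
    km_e, _ = michaelis_constants(params)
    keq_e, keq_es = params.Keq_E, params.Keq_ES
    km_app = km_e * (1.0 + keq_e) / (1.0 + keq_es)
    kcat_app = (params.kcat_E + keq_es * params.kcat_Estar) / (1.0 + keq_es)
    return ApparentParams(KM_app=km_app, kcat_app=kcat_app)


def initial_rate_short_time(params: RateParameters, S: float, E0: float) -> float:
    """Initial rate v0 (uM/s) in the short-time limit, before exchange relaxes.

    E and E* start at their pre-reaction equilibrium (population of E is
    p_E = 1/(1+Keq(E))) and convert substrate independently:

        v0 = E0/(1+Keq(E)) * (kcat_E + kcat_Estar*Keq(E))
             / (1 + KM_E/S + KM_E*/S + KM_E*KM_E*/S^2)

    This cannot be cast as apparent Michaelis-Menten parameters; the
    denominator is kept exactly as derived.
    """
    if not S > 0.0:
        raise ValueError(f"substrate concentration must be > 0, got {S!r}")
    km_e, km_estar = michaelis_constants(params)
    keq_e = params.Keq_E
    num = E0 / (1.0 + keq_e) * (params.kcat_E + params.kcat_Estar * keq_e)
    den = 1.0 + km_e / S + km_estar / S + km_e * km_estar / (S * S)
    return num / den


# ---------------------------------------------------------------------------
# Reaction schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: reactants -> products at rate ``rate_key``."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_key: str

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass
class SchemeSpec:
    """Species list + mass-action reaction list defining an ODE right-hand side.

    ``rates`` maps every rate key referenced by a reaction to its value;
    ``conserved_totals`` lists (name, species-index tuple) combinations whose
    unweighted sums are invariant under every reaction.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    rates: dict[str, float]
    conserved_totals: tuple[tuple[str, tuple[int, ...]], ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.index
        for rxn in self.reactions:
            if rxn.rate_key not in self.rates:
                raise ValueError(f"unresolved rate constant reference {rxn.rate_key!r}")
            for sp in rxn.reactants + rxn.products:
                if sp not in idx:
                    raise ValueError(f"reaction references unknown species {sp!r}")
        for name, members in self.conserved_totals:
            for rxn in self.reactions:
                net = sum(1 for sp in rxn.products if self.index[sp] in members) - sum(
                    1 for sp in rxn.reactants if self.index[sp] in members
                )
                if net != 0:
                    raise ValueError(
                        f"conserved total {name!r} broken by reaction "
                        f"{rxn.reactants} -> {rxn.products}"
                    )

    @property
    def index(self) -> dict[str, int]:
        return {sp: i for i, sp in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def stoichiometry(self):
        """Stoichiometry matrix N (n_species x n_reactions)."""
        import numpy as np

        n = np.zeros((len(self.species), len(self.reactions)))
        idx = self.index
        for j, rxn in enumerate(self.reactions):
            for sp in rxn.reactants:
                n[idx[sp], j] -= 1.0
            for sp in rxn.products:
                n[idx[sp], j] += 1.0
        return n

    def rate_vector(self):
        import numpy as np

        return np.array([self.rates[r.rate_key] for r in self.reactions])

    def with_rates(self, rates: dict[str, float]) -> "SchemeSpec":
        """Copy of the scheme with updated rate values (same topology)."""
        new = dict(self.rates)
        for k, v in rates.items():
            if k not in new:
                raise KeyError(f"unknown rate key {k!r}")
            new[k] = v
        return SchemeSpec(
            species=self.species,
            reactions=self.reactions,
            rates=new,
            conserved_totals=self.conserved_totals,
            meta=dict(self.meta),
        )

    def rhs(self, conc):
        """Time derivative of all species at concentrations ``conc`` (uM/s)."""
        import numpy as np

        conc = np.asarray(conc, dtype=float)
        idx = self.index
        flux = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            f = self.rates[rxn.rate_key]
            for sp in rxn.reactants:
                f *= conc[idx[sp]]
            flux[j] = f
        return self.stoichiometry() @ flux


def build_single_substrate_scheme(params: RateParameters) -> SchemeSpec:
    """Full alternate-state scheme for one substrate: species E, E*, ES, E*S, S, P."""
    rates = {
        "k1": params.k1,
        "k_off": params.k_off,
        "k_off_star": params.k_off_star,
        "kcat_E": params.kcat_E,
        "kcat_Estar": params.kcat_Estar,
        "kE_fwd": params.kE_fwd,
        "kE_rev": params.kE_rev,
        "kES_fwd": params.kES_fwd,
        "kES_rev": params.kES_rev,
    }
    reactions = (
        Reaction(("E", "S"), ("ES",), "k1"),
        Reaction(("ES",), ("E", "S"), "k_off"),
        Reaction(("Estar", "S"), ("EstarS",), "k1"),
        Reaction(("EstarS",), ("Estar", "S"), "k_off_star"),
        Reaction(("ES",), ("E", "P"), "kcat_E"),
        Reaction(("EstarS",), ("Estar", "P"), "kcat_Estar"),
        Reaction(("E",), ("Estar",), "kE_fwd"),
        Reaction(("Estar",), ("E",), "kE_rev"),
        Reaction(("ES",), ("EstarS",), "kES_fwd"),
        Reaction(("EstarS",), ("ES",), "kES_rev"),
    )
    species = ("E", "Estar", "ES", "EstarS", "S", "P")
    conserved = (
        ("enzyme", (0, 1, 2, 3)),
        ("substrate_mass", (2, 3, 4, 5)),
    )
    return SchemeSpec(
        species=species,
        reactions=reactions,
        rates=rates,
        conserved_totals=conserved,
        meta={"kind": "single_substrate", "params": params.to_dict(),
              "enzyme_pools": {"E": ("kE_fwd", "kE_rev")}},
    )


# Peptide modification states of the coupled dual-substrate network.
_SME = "K4meK9"     # demethylase substrate
_SAC = "K4K9ac"     # deacetylase substrate
_SDUAL = "K4meK9ac"  # substrate of both sites
_SDONE = "K4K9"     # fully processed
_ACETATE = "acetate"


def _pair_reactions(pool: str, sub: str, prods: tuple[str, ...], tag: str,
                    prefix: str, with_star: bool) -> tuple[tuple[Reaction, ...], list[str]]:
    """Reactions of one enzyme-pool/substrate pair; rate keys ``prefix.*``."""
    c, cs = f"C_{tag}", f"Cstar_{tag}"
    e, es = pool, pool + "star"
    rxns = [
        Reaction((e, sub), (c,), f"{prefix}.k1"),
        Reaction((c,), (e, sub), f"{prefix}.k_off"),
        Reaction((c,), (e,) + prods, f"{prefix}.kcat_E"),
    ]
    complexes = [c]
    if with_star:
        rxns += [
            Reaction((es, sub), (cs,), f"{prefix}.k1"),
            Reaction((cs,), (es, sub), f"{prefix}.k_off_star"),
            Reaction((cs,), (es,) + prods, f"{prefix}.kcat_Estar"),
            Reaction((c,), (cs,), f"{prefix}.kES_fwd"),
            Reaction((cs,), (c,), f"{prefix}.kES_rev"),
        ]
        complexes.append(cs)
    return tuple(rxns), complexes


def build_coupled_scheme(
    params_me: RateParameters,
    params_ac: RateParameters,
    params_me_on_dual: RateParameters | None = None,
    params_ac_on_dual: RateParameters | None = None,
    *,
    single_occupancy: bool = True,
    shared_kinetics: bool = False,
    with_alternate_state: bool = True,
) -> SchemeSpec:
    """Dual-substrate network for a bifunctional complex.

    Substrates: K4meK9 (demethylation only), K4K9ac (deacetylation only) and
    the doubly modified K4meK9ac, whose demethylation yields K4K9ac and whose
    deacetylation yields K4meK9 plus one acetate; singly modified products
    re-enter as substrates until K4K9 is reached.

    ``single_occupancy``: one shared E/E* pool serves every complex, so
    substrate engagement at either catalytic site excludes the other.
    Otherwise each site gets its own independent enzyme pool.
    ``shared_kinetics``: the doubly modified substrate reuses the rate
    constants of the corresponding singly modified substrate.
    ``with_alternate_state``: include E*/E*S species and exchange; when off,
    the scheme reduces to two classical Michaelis-Menten branches.
    """
    if shared_kinetics:
        if params_me_on_dual is not None or params_ac_on_dual is not None:
            raise ValueError(
                "shared_kinetics ties dual-substrate rates to the single-substrate "
                "ones; do not pass separate dual parameter sets"
            )
        params_me_on_dual, params_ac_on_dual = params_me, params_ac
    if params_me_on_dual is None or params_ac_on_dual is None:
        raise ValueError("substrate-specific kinetics need explicit dual-substrate parameters")

    psets = {
        "me": params_me,
        "ac": params_ac,
        "me_dual": params_me_on_dual,
        "ac_dual": params_ac_on_dual,
    }
    rates: dict[str, float] = {}
    for prefix, p in psets.items():
        rates[f"{prefix}.k1"] = p.k1
        rates[f"{prefix}.k_off"] = p.k_off
        rates[f"{prefix}.kcat_E"] = p.kcat_E
        if with_alternate_state:
            rates[f"{prefix}.k_off_star"] = p.k_off_star
            rates[f"{prefix}.kcat_Estar"] = p.kcat_Estar
            rates[f"{prefix}.kES_fwd"] = p.kES_fwd
            rates[f"{prefix}.kES_rev"] = p.kES_rev

    if single_occupancy:
        pools = {"me": "E", "ac": "E", "me_dual": "E", "ac_dual": "E"}
        pool_names = ["E"]
        # shared free-enzyme exchange rates come from the demethylation set
        pool_params = {"E": params_me}
    else:
        # independent sites: demethylase pool EL, deacetylase pool EH
        pools = {"me": "EL", "ac": "EH", "me_dual": "EL", "ac_dual": "EH"}
        pool_names = ["EL", "EH"]
        pool_params = {"EL": params_me, "EH": params_ac}

    reactions: list[Reaction] = []
    complex_species: list[str] = []
    pair_defs = {
        "me": (_SME, (_SDONE,)),
        "ac": (_SAC, (_SDONE, _ACETATE)),
        "me_dual": (_SDUAL, (_SAC,)),
        "ac_dual": (_SDUAL, (_SME, _ACETATE)),
    }
    for tag, (sub, prods) in pair_defs.items():
        rxns, cxs = _pair_reactions(pools[tag], sub, prods, tag, tag, with_alternate_state)
        reactions.extend(rxns)
        complex_species.extend(cxs)

    enzyme_species: list[str] = []
    for pool in pool_names:
        enzyme_species.append(pool)
        if with_alternate_state:
            enzyme_species.append(pool + "star")
            rates[f"{pool}.kE_fwd"] = pool_params[pool].kE_fwd
            rates[f"{pool}.kE_rev"] = pool_params[pool].kE_rev
            reactions.append(Reaction((pool,), (pool + "star",), f"{pool}.kE_fwd"))
            reactions.append(Reaction((pool + "star",), (pool,), f"{pool}.kE_rev"))

    peptides = (_SME, _SAC, _SDUAL, _SDONE)
    species = tuple(enzyme_species) + tuple(complex_species) + peptides + (_ACETATE,)
    idx = {sp: i for i, sp in enumerate(species)}

    conserved: list[tuple[str, tuple[int, ...]]] = []
    if single_occupancy:
        conserved.append(("enzyme", tuple(idx[s] for s in enzyme_species + complex_species)))
    else:
        for pool in pool_names:
            members = [s for s in enzyme_species if s.startswith(pool)]
            members += [c for c in complex_species
                        if pools[c.split("_", 1)[1]] == pool]
            conserved.append((f"enzyme_{pool}", tuple(idx[s] for s in members)))
    conserved.append(
        ("peptide", tuple(idx[s] for s in complex_species + list(peptides)))
    )
    # acetyl marks: acetylated peptides (free or bound) + released acetate
    acetyl = [s for s in (_SAC, _SDUAL, _ACETATE)]
    acetyl += [c for c in complex_species if c.split("_", 1)[1] in ("ac", "me_dual", "ac_dual")]
    conserved.append(("acetyl", tuple(sorted(idx[s] for s in acetyl))))

    return SchemeSpec(
        species=species,
        reactions=tuple(reactions),
        rates=rates,
        conserved_totals=tuple(conserved),
        meta={
            "kind": "coupled",
            "single_occupancy": single_occupancy,
            "shared_kinetics": shared_kinetics,
            "with_alternate_state": with_alternate_state,
            "enzyme_pools": {
                pool: (f"{pool}.kE_fwd", f"{pool}.kE_rev") if with_alternate_state
                else (None, None)
                for pool in pool_names
            },
        },
    )
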