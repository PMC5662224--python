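"""Reaction-network definitions for the five regulatory circuit schemes.

The model is a mass-action chemical network for plasmid-borne, inducible
gene expression in *Escherichia coli*: a gene of interest (protein P) is
transcribed from DNA copies D1, a transcriptional repressor R binds free
DNA to block transcription, and an inducer I sequesters the repressor.
Five wiring schemes are supported:

- ``constitutive`` (i): unregulated expression of P.
- ``constitutive_repressor`` (ii): R expressed constitutively from a second
  gene (D2) and represses D1 — the conventional inducible system.
- ``autoregulated_repressor`` (iii): as (ii) but R also represses its own
  gene D2.
- ``bicistronic_autoregulation`` (iv): P and R translated from the same
  autoregulated transcript M1.
- ``hybrid`` (v): scheme (iv) plus a weak, never-repressed constitutive
  promoter expressing extra R, trading some noise for dynamic range.

All reactions are at most bimolecular with unit stoichiometry, simulated in
unit volume so molecule numbers and concentrations coincide and every
propensity has units of s^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Literal

__all__ = [
    "SPECIES",
    "RateSet",
    "Reaction",
    "NetworkSpec",
    "SCHEMES",
    "default_rates",
    "build_network",
    "network_to_config",
    "network_from_config",
]

#: Canonical species ordering used by every state vector in the package.
SPECIES = ("D1", "D1R", "D2", "D2R", "M1", "M2", "P", "R", "RI", "I")

SCHEMES = (
    "constitutive",
    "constitutive_repressor",
    "autoregulated_repressor",
    "bicistronic_autoregulation",
    "hybrid",
)

#: Roman-numeral aliases accepted anywhere a scheme name is.
_SCHEME_ALIASES = {
    "i": "constitutive",
    "ii": "constitutive_repressor",
    "iii": "autoregulated_repressor",
    "iv": "bicistronic_autoregulation",
    "v": "hybrid",
}

InducerMode = Literal["fast", "slow"]


def resolve_scheme(scheme: str) -> str:
    """Normalize a scheme name or roman-numeral alias; raise on unknown."""
    s = str(scheme).strip().lower()
    s = _SCHEME_ALIASES.get(s, s)
    if s not in SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {SCHEMES} "
            f"or aliases {tuple(_SCHEME_ALIASES)}"
        )
    return s


@dataclass(frozen=True)
class RateSet:
    """Rate constants of the circuit model (all in s^-1, unit volume).

    Defaults are the fixed values used throughout the simulations:
    strong transcription at 1.7e-3 s^-1, translation of the protein of
    interest at 0.67 s^-1 (burst size kTL_P/deg_M ~ 203), repressor
    translation ~20x weaker, mRNA lifetime ~5 min, and protein dilution
    matching a ~69-min doubling time.
    """

    kTX1: float = 1.7e-3       # transcription of gene-of-interest DNA (D1)
    kTX2: float = 1.7e-3       # transcription of the separate repressor DNA (D2)
    kTL_P: float = 0.67        # translation of P per M1
    kTL_R: float = 0.0333      # translation of R per mRNA (M1 in iv/v, M2 in ii/iii/v)
    k_rep_on: float = 1e-5     # repressor-DNA association
    k_rep_off: float = 1e-4    # repressor-DNA dissociation
    k_ind_on: float = 1e-5     # repressor-inducer association
    k_ind_off: float = 1e-7    # repressor-inducer dissociation
    deg_M: float = 0.0033      # mRNA degradation (M1 and M2)
    deg_P: float = 1.6667e-4   # protein dilution/degradation
    deg_R: float = 1.6667e-4   # free-repressor dilution (DNA-bound R is protected)
    deg_RI: float = 1.6667e-4  # inducer-bound repressor; degradation frees one I

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value >= 0.0) or value != value:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value}")

    def replace(self, **kwargs: float) -> "RateSet":
        return replace(self, **kwargs)


#: Default transcription rate of the hybrid scheme's weak constitutive
#: promoter: 40% of the strong promoter's rate.
HYBRID_KTX2 = 6.7e-4


def default_rates(scheme: str = "constitutive") -> RateSet:
    """Table defaults for a scheme; the hybrid uses the weak kTX2."""
    scheme = resolve_scheme(scheme)
    if scheme == "hybrid":
        return RateSet(kTX2=HYBRID_KTX2)
    return RateSet()


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants`` enter the propensity (rate x product of their counts);
    ``stoich`` is the net count change applied when the reaction fires.
    The two are kept separate so the fast-inducer limit can hold the free
    inducer count constant while it still drives binding propensities.
    ``is_translation`` marks the reactions whose propensity is multiplied
    by the extrinsic translation-capacity factor.
    """

    name: str
    reactants: tuple[str, ...]
    stoich: dict[str, int]
    rate: float
    is_translation: bool = False

    def __post_init__(self) -> None:
        for sp in self.reactants:
            if sp not in SPECIES:
                raise ValueError(f"unknown reactant species {sp!r}")
        for sp, d in self.stoich.items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r} in stoichiometry")
            if d != int(d):
                raise ValueError("stoichiometry changes must be integers")
        if not (self.rate >= 0.0) or self.rate != self.rate:
            raise ValueError(f"reaction {self.name}: rate must be finite and >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """A concrete circuit: scheme, rates, copy numbers and reaction list."""

    scheme: str
    rates: RateSet
    n_DNA1: int
    n_DNA2: int
    inducer_count: int
    inducer_mode: InducerMode
    reactions: tuple[Reaction, ...]

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES

    def initial_state(self) -> dict[str, int]:
        """All DNA unrepressed, no mRNA/protein/repressor, free inducer set."""
        state = {sp: 0 for sp in SPECIES}
        state["D1"] = self.n_DNA1
        state["D2"] = self.n_DNA2
        state["I"] = self.inducer_count
        return state

    def with_inducer(self, inducer_count: int) -> "NetworkSpec":
        """Same circuit at a different initial free-inducer count."""
        return build_network(
            self.scheme,
            rates=self.rates,
            n_DNA1=self.n_DNA1,
            n_DNA2=self.n_DNA2,
            inducer_count=inducer_count,
            inducer_mode=self.inducer_mode,
        )


def _reactions_for(scheme: str, r: RateSet, inducer_mode: str) -> list[Reaction]:
    fast = inducer_mode == "fast"
    rxns: list[Reaction] = []

    def add(name, reactants, stoich, rate, is_translation=False):
        rxns.append(Reaction(name, tuple(reactants), dict(stoich), rate, is_translation))

    has_d2_gene = scheme in ("constitutive_repressor", "autoregulated_repressor", "hybrid")
    has_repression = scheme != "constitutive"
    bicistronic = scheme in ("bicistronic_autoregulation", "hybrid")

    # Transcription
    add("TX1", ["D1"], {"M1": +1}, r.kTX1)
    if has_d2_gene:
        add("TX2", ["D2"], {"M2": +1}, r.kTX2)

    # Repression (monomer binding free DNA; bound DNA is a distinct species)
    if has_repression:
        add("rep1_on", ["D1", "R"], {"D1": -1, "R": -1, "D1R": +1}, r.k_rep_on)
        add("rep1_off", ["D1R"], {"D1R": -1, "D1": +1, "R": +1}, r.k_rep_off)
    if scheme == "autoregulated_repressor":
        add("rep2_on", ["D2", "R"], {"D2": -1, "R": -1, "D2R": +1}, r.k_rep_on)
        add("rep2_off", ["D2R"], {"D2R": -1, "D2": +1, "R": +1}, r.k_rep_off)

    # Translation (scaled by the extrinsic factor)
    add("TL_P", ["M1"], {"P": +1}, r.kTL_P, is_translation=True)
    if bicistronic:
        add("TL_R_M1", ["M1"], {"R": +1}, r.kTL_R, is_translation=True)
    if has_d2_gene:
        add("TL_R_M2", ["M2"], {"R": +1}, r.kTL_R, is_translation=True)

    # Induction: inducer sequesters the repressor.  In the fast limit the
    # free-inducer count is clamped (environment replenishes instantly), so
    # I never appears in any stoichiometry change; in the slow limit the
    # pool is an ordinary conserved species.
    if has_repression:
        i_on = {"R": -1, "RI": +1} if fast else {"R": -1, "I": -1, "RI": +1}
        i_off = {"RI": -1, "R": +1} if fast else {"RI": -1, "R": +1, "I": +1}
        add("ind_on", ["R", "I"], i_on, r.k_ind_on)
        add("ind_off", ["RI"], i_off, r.k_ind_off)

    # Degradation.  DNA-bound repressor is protected; degradation of
    # inducer-bound repressor liberates its inducer molecule.
    add("deg_M1", ["M1"], {"M1": -1}, r.deg_M)
    if has_d2_gene:
        add("deg_M2", ["M2"], {"M2": -1}, r.deg_M)
    add("deg_P", ["P"], {"P": -1}, r.deg_P)
    if has_repression:
        add("deg_R", ["R"], {"R": -1}, r.deg_R)
        ri_deg = {"RI": -1} if fast else {"RI": -1, "I": +1}
        add("deg_RI", ["RI"], ri_deg, r.deg_RI)

    return rxns


def build_network(
    scheme: str,
    rates: RateSet | None = None,
    n_DNA1: int = 10,
    n_DNA2: int | None = None,
    inducer_count: int = 0,
    inducer_mode: InducerMode = "fast",
) -> NetworkSpec:
    """Build the concrete reaction list for one circuit scheme.

    Parameters
    ----------
    scheme
        Scheme name or roman-numeral alias (``"i"`` .. ``"v"``).
    rates
        Rate constants; defaults to the scheme's table values (the hybrid
        scheme defaults to the weak constitutive promoter, kTX2 = 6.7e-4).
    n_DNA1, n_DNA2
        Plasmid copy numbers of the two genes (default 10 each; n_DNA2 is
        forced to 0 for schemes without a separate repressor gene).
    inducer_count
        Initial number of free inducer molecules.
    inducer_mode
        ``"fast"`` clamps the free inducer count (instant exchange with the
        environment); ``"slow"`` makes it a conserved pool that is consumed
        by binding and liberated by unbinding/degradation.
    """
    scheme = resolve_scheme(scheme)
    if rates is None:
        rates = default_rates(scheme)
    if inducer_mode not in ("fast", "slow"):
        raise ValueError(f"inducer_mode must be 'fast' or 'slow', got {inducer_mode!r}")
    if n_DNA1 < 1:
        raise ValueError("n_DNA1 must be >= 1")
    has_d2_gene = scheme in ("constitutive_repressor", "autoregulated_repressor", "hybrid")
    if n_DNA2 is None:
        n_DNA2 = 10 if has_d2_gene else 0
    if n_DNA2 < 0 or inducer_count < 0:
        raise ValueError("copy numbers and inducer counts must be >= 0")
    if not has_d2_gene and n_DNA2 != 0:
        raise ValueError(f"scheme {scheme!r} has no separate repressor gene; n_DNA2 must be 0")

    reactions = tuple(_reactions_for(scheme, rates, inducer_mode))
    return NetworkSpec(
        scheme=scheme,
        rates=rates,
        n_DNA1=int(n_DNA1),
        n_DNA2=int(n_DNA2),
        inducer_count=int(inducer_count),
        inducer_mode=inducer_mode,
        reactions=reactions,
    )


# ---------------------------------------------------------------------------
# Configuration (JSON/YAML-friendly dicts)
# ---------------------------------------------------------------------------

def network_to_config(network: NetworkSpec) -> dict:
    """Serialize to a plain dict (JSON/YAML-ready); defaults round-trip."""
    return {
        "scheme": network.scheme,
        "rates": asdict(network.rates),
        "n_DNA1": network.n_DNA1,
        "n_DNA2": network.n_DNA2,
        "inducer_count": network.inducer_count,
        "inducer_mode": network.inducer_mode,
    }


def network_from_config(config: dict) -> NetworkSpec:
    """Build a network from a config dict (e.g. parsed JSON/YAML).

    ``rates`` may be omitted (scheme defaults) or partial (overrides).
    """
    if "scheme" not in config:
        raise ValueError("config must contain a 'scheme' entry")
    scheme = resolve_scheme(config["scheme"])
    overrides = dict(config.get("rates") or {})
    base = default_rates(scheme)
    unknown = set(overrides) - set(asdict(base))
    if unknown:
        raise ValueError(f"unknown rate name(s) in config: {sorted(unknown)}")
    rates = base.replace(**{k: float(v) for k, v in overrides.items()})
    return build_network(
        scheme,
        rates=rates,
        n_DNA1=int(config.get("n_DNA1", 10)),
        n_DNA2=config.get("n_DNA2"),
        inducer_count=int(config.get("inducer_count", 0)),
        inducer_mode=config.get("inducer_mode", "fast"),
    )


def save_network(network: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_config(network), fh, indent=2)


def load_network(path) -> NetworkSpec:
    with open(path) as fh:
        return network_from_config(json.load(fh))
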