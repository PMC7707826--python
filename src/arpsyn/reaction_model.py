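"""Mass-action kinetic models of actin polymerization and Arp2/3 activation.

The networks built here describe pyrene-actin polymerization assays in which
Arp2/3 complex is activated by the WISH/DIP/SPIN90-family NPF Dip1, either
alone or together with (implicitly modeled) Wsp1-VCA.  Three ingredients:

* Spontaneous nucleation: actin dimers, trimers and tetramers form reversibly
  (on-rate fixed at the barbed-end monomer on-rate, 1.16e7 / M / s) and each
  oligomer tier can irreversibly convert into a filament nucleus.
* Nuclei as catalysts: a nucleus species represents one free barbed end that
  converts monomeric actin (G) into filamentous actin (F); the subunits of the
  oligomer that became the nucleus are released into F so actin mass is
  conserved.  Pointed-end dynamics are neglected.
* Dip1 pathway: Dip1 (D) binds Arp2/3 complex (C) reversibly (k9 / km9);
  0-3 actin monomers then bind the D-C assembly reversibly (k10 / km10);
  a final irreversible activation step (k11) creates a Dip1-capped barbed end.
  Dip1 is single turnover: it stays on the nucleated end and is consumed.

Units: concentrations in uM, first-order constants in 1/s, second-order
constants in 1/(uM*s) (so 1.16e7 /M/s is stored as 11.6 /uM/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

# ---------------------------------------------------------------------------
# Fixed physical constants (uM / s unit system)
# ---------------------------------------------------------------------------

#: Barbed-end monomer on-rate, 1.16e7 /M/s.  Also used as the on-rate for
#: actin dimerization, trimerization and tetramerization.
K_ON_BARBED = 11.6  # /uM/s

#: Critical concentration: free monomer left unpolymerized at equilibrium.
CRITICAL_CONC = 0.1  # uM

#: Barbed-end off-rate chosen so the elongation submodel equilibrates at the
#: critical concentration: k_off = k_on * C_c.
K_OFF_BARBED = K_ON_BARBED * CRITICAL_CONC  # 1.16 /s

#: Smoothing scale for the F>0 indicator in the catalytic depolymerization
#: rate law (keeps the RHS continuously differentiable for stiff solvers).
_DEPOL_EPS = 1e-8  # uM

#: Names the primary text uses for rate constants, mapped to this module's
#: canonical names (the full k1..k8 numbering of the spontaneous pathway is
#: not text-named; only these symbols are).
TEXT_NAMED_CONSTANTS = {
    "k_-1": "kd2",   # dimer dissociation, re-fit per reaction set
    "k_9": "k9",     # Dip1 + Arp2/3 association
    "k_-9": "km9",
    "k_10": "k10",   # monomer + Dip1-Arp2/3 association
    "k_-10": "km10",
    "k_11": "k11",   # irreversible activation
}

#: Rate constants eligible for floating in the synergy (Dip1 + Wsp1) model.
SYNERGY_FLOATABLE = frozenset({"km9", "km10", "k11", "k9", "k10"})

# Default spontaneous-nucleation constants.  Calibrated once on synthetic
# actin-alone titrations (2-6 uM) so that 3 uM actin polymerizes with a
# sigmoidal time course reaching plateau within ~25 min, and frozen here.
SPONTANEOUS_DEFAULTS = {
    "kd2": 1.0e5,   # /s   dimer dissociation (highly unstable)
    "kd3": 1.0e3,   # /s   trimer dissociation
    "kd4": 1.0e2,   # /s   tetramer dissociation
    "kn2": 1.0e-8,  # /s   dimer -> nucleus
    "kn3": 1.0e-4,  # /s   trimer -> nucleus
    "kn4": 5.0e-2,  # /s   tetramer -> nucleus
}

# Default Dip1-pathway constants (package presets, self-calibrated; see the
# synthetic_data presets for the generative "truth" sets derived from these).
DIP1_DEFAULTS = {
    "k9": 0.5,     # /uM/s
    "km9": 2.0,    # /s
    "k10": 11.6,   # /uM/s
    "km10": 100.0,  # /s
    "k11": 0.02,   # /s
}

DEFAULT_RTOL = 1e-8
#: Absolute tolerance in uM.  Error in the nM-scale nucleus pools propagates
#: multiplicatively into the polymer curve, so the default sits well below
#: the smallest species scale.
DEFAULT_ATOL = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RateConstant:
    """A named rate constant with float/fix status and search bounds."""

    name: str
    value: float
    fixed: bool = True
    bounds: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"rate constant {self.name} must be >= 0")
        lo, hi = self.bounds
        if not self.fixed and not (lo <= self.value <= hi):
            raise ValueError(
                f"floated constant {self.name}={self.value} outside bounds {self.bounds}"
            )


@dataclass
class Reaction:
    """One reaction with mass-action or catalytic-depolymerization kinetics.

    ``reactants`` and ``products`` map species name -> stoichiometric count.
    A reversible reaction carries a ``reverse`` constant; irreversible
    reactions (nucleus creation, activation) have ``reverse=None``.
    For ``rate_law == "catalytic_depol"`` the rate is
    ``k * [end] * F/(F+eps)`` and converts F -> G; ``reactants`` names the
    catalyst end species.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    forward: RateConstant
    reverse: RateConstant | None = None
    rate_law: str = "mass_action"


# Actin subunit content per species role; used for the conservation check and
# for building nucleus-creation stoichiometry.
_ACTIN_CONTENT = {
    "G": 1, "F": 1, "A2": 2, "A3": 3, "A4": 4,
    "E_spont": 0, "E_dip": 0, "D": 0, "C": 0, "DC": 0,
}


@dataclass
class ReactionNetwork:
    """Species, reactions and rate constants for one model variant."""

    variant: str
    species: list[str]
    reactions: list[Reaction]
    params: dict[str, RateConstant]
    n_monomer_steps: int = 0

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        self._index = {s: i for i, s in enumerate(self.species)}
        self._compile()
        self._check_actin_conservation()

    # -- construction helpers ------------------------------------------------

    def actin_content(self) -> np.ndarray:
        """Actin subunits carried by each species (DCA_i holds i monomers)."""
        out = np.zeros(len(self.species))
        for i, s in enumerate(self.species):
            if s.startswith("DCA"):
                out[i] = int(s[3:])
            else:
                out[i] = _ACTIN_CONTENT[s]
        return out

    def _check_actin_conservation(self) -> None:
        content = {s: self.actin_content()[i] for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            if rxn.rate_law == "catalytic_depol":
                continue  # F -> G, conserves by construction
            lhs = sum(content[s] * n for s, n in rxn.reactants.items())
            rhs = sum(content[s] * n for s, n in rxn.products.items())
            if lhs != rhs:
                raise ValueError(
                    f"reaction {rxn.reactants}->{rxn.products} does not conserve actin"
                )

    def _compile(self) -> None:
        """Flatten reactions into unimolecular / bimolecular / depol terms.

        Every mass-action direction is expanded into (rate-constant name,
        reactant index list, net stoichiometry vector); reactant lists carry
        one entry per molecule, so G+G appears as [iG, iG].  Molecularity
        above two is not needed by these networks and is rejected.
        """
        uni: list[tuple[str, list[int], np.ndarray]] = []
        bi: list[tuple[str, list[int], np.ndarray]] = []
        depol: list[tuple[str, int]] = []

        def delta(reactants: dict[str, int], products: dict[str, int]) -> np.ndarray:
            d = np.zeros(len(self.species))
            for s, n in reactants.items():
                d[self._index[s]] -= n
            for s, n in products.items():
                d[self._index[s]] += n
            return d

        def add(reactants, products, kname):
            idx: list[int] = []
            for s, n in reactants.items():
                idx += [self._index[s]] * n
            if len(idx) == 1:
                uni.append((kname, idx, delta(reactants, products)))
            elif len(idx) == 2:
                bi.append((kname, idx, delta(reactants, products)))
            else:
                raise ValueError("reactions above bimolecular are not supported")

        for rxn in self.reactions:
            if rxn.rate_law == "catalytic_depol":
                (end_sp,) = rxn.reactants
                depol.append((rxn.forward.name, self._index[end_sp]))
                continue
            add(rxn.reactants, rxn.products, rxn.forward.name)
            if rxn.reverse is not None:
                add(rxn.products, rxn.reactants, rxn.reverse.name)

        self._uni_k = [k for k, _, _ in uni]
        self._uni_i = np.array([i[0] for _, i, _ in uni], dtype=int)
        self._uni_d = (np.array([d for _, _, d in uni])
                       if uni else np.zeros((0, len(self.species))))
        self._bi_k = [k for k, _, _ in bi]
        self._bi_i = np.array([i[0] for _, i, _ in bi], dtype=int)
        self._bi_j = np.array([i[1] for _, i, _ in bi], dtype=int)
        self._bi_d = (np.array([d for _, _, d in bi])
                      if bi else np.zeros((0, len(self.species))))
        self._depol_k = [k for k, _ in depol]
        self._depol_i = np.array([i for _, i in depol], dtype=int)

    def make_odes(self):
        """Return (rhs, jac) closures with the current constant values baked in.

        Used by :func:`simulate`; call again after changing parameter values.
        """
        ku = np.array([self.params[k].value for k in self._uni_k])
        kb = np.array([self.params[k].value for k in self._bi_k])
        kd = np.array([self.params[k].value for k in self._depol_k])
        ui, du = self._uni_i, self._uni_d
        b1, b2, db = self._bi_i, self._bi_j, self._bi_d
        di = self._depol_i
        iF, iG = self._index["F"], self._index["G"]
        n = len(self.species)
        eps = _DEPOL_EPS

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            yc = np.maximum(y, 0.0)
            dy = (ku * yc[ui]) @ du + (kb * yc[b1] * yc[b2]) @ db
            f = yc[iF]
            r = float((kd * yc[di]).sum()) * f / (f + eps)
            dy[iF] -= r
            dy[iG] += r
            return dy

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            yc = np.maximum(y, 0.0)
            J = np.zeros((n, n))
            for m in range(len(ku)):
                J[:, ui[m]] += du[m] * ku[m]
            for m in range(len(kb)):
                J[:, b1[m]] += db[m] * kb[m] * yc[b2[m]]
                J[:, b2[m]] += db[m] * kb[m] * yc[b1[m]]
            f = yc[iF]
            gate = f / (f + eps)
            ksum = float((kd * yc[di]).sum())
            for m in range(len(kd)):
                J[iF, di[m]] -= kd[m] * gate
                J[iG, di[m]] += kd[m] * gate
            dgate = eps / (f + eps) ** 2
            J[iF, iF] -= ksum * dgate
            J[iG, iF] += ksum * dgate
            return J

        return rhs, jac

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Mass-action right-hand side at the current constant values."""
        return self.make_odes()[0](t, y)

    # -- parameter access ----------------------------------------------------

    def floated(self) -> list[str]:
        return [name for name, p in self.params.items() if not p.fixed]

    def with_values(self, updates: dict[str, float]) -> "ReactionNetwork":
        """Return a copy with the given rate-constant values replaced."""
        params = dict(self.params)
        for name, value in updates.items():
            if name not in params:
                raise KeyError(f"unknown rate constant {name!r}")
            params[name] = replace(params[name], value=value)
        net = ReactionNetwork.__new__(ReactionNetwork)
        net.variant = self.variant
        net.species = self.species
        net.params = params
        net.n_monomer_steps = self.n_monomer_steps
        net.reactions = self.reactions
        net._index = self._index
        for attr in ("_uni_k", "_uni_i", "_uni_d", "_bi_k", "_bi_i", "_bi_j",
                     "_bi_d", "_depol_k", "_depol_i"):
            setattr(net, attr, getattr(self, attr))
        return net

    # -- right-hand side -----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        dy = np.zeros_like(y)
        iF = self._index["F"]
        iG = self._index["G"]
        for r_idx, r_sto, delta, kname, kind in self._terms:
            k = self.params[kname].value
            if k == 0.0:
                continue
            if kind == "depol":
                f = yc[iF]
                rate = k * yc[r_idx[0]] * f / (f + _DEPOL_EPS)
                dy[iF] -= rate
                dy[iG] += rate
            else:
                rate = k * np.prod(yc[r_idx] ** r_sto)
                dy += rate * delta
        return dy


@dataclass
class SimulationResult:
    """Deterministic trajectory of one network on a reporting time grid."""

    times: np.ndarray
    species: list[str]
    concentrations: np.ndarray  # shape (n_species, n_times), uM
    variant: str

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[self.species.index(name)]

    @property
    def filamentous(self) -> np.ndarray:
        return self["F"]

    @property
    def ends_spontaneous(self) -> np.ndarray:
        """Cumulative concentration of spontaneously nucleated barbed ends."""
        return self["E_spont"]

    @property
    def ends_dip1(self) -> np.ndarray:
        """Cumulative concentration of Dip1-pathway barbed ends."""
        if "E_dip" in self.species:
            return self["E_dip"]
        return np.zeros_like(self.times)

    def total_actin(self, net: ReactionNetwork) -> np.ndarray:
        return net.actin_content() @ self.concentrations

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_s, species, concentration_uM."""
        n = len(self.times)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(self.species)),
            "species": np.tile(self.species, n),
            "concentration_uM": self.concentrations.T.ravel(),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------

def _spontaneous_reactions(params: dict[str, RateConstant]) -> list[Reaction]:
    rxns = [
        Reaction({"G": 2}, {"A2": 1}, params["kf2"], params["kd2"]),
        Reaction({"A2": 1, "G": 1}, {"A3": 1}, params["kf3"], params["kd3"]),
        Reaction({"A3": 1, "G": 1}, {"A4": 1}, params["kf4"], params["kd4"]),
        # Irreversible nucleus creation from each oligomer tier; the
        # constituent subunits are released into F (nucleus is a catalyst).
        Reaction({"A2": 1}, {"E_spont": 1, "F": 2}, params["kn2"]),
        Reaction({"A3": 1}, {"E_spont": 1, "F": 3}, params["kn3"]),
        Reaction({"A4": 1}, {"E_spont": 1, "F": 4}, params["kn4"]),
        # Barbed-end elongation and catalytic depolymerization.
        Reaction({"E_spont": 1, "G": 1}, {"E_spont": 1, "F": 1}, params["kon"]),
        Reaction({"E_spont": 1}, {}, params["koff"], rate_law="catalytic_depol"),
    ]
    return rxns


def _base_params(overrides: dict[str, float] | None = None) -> dict[str, RateConstant]:
    values = dict(SPONTANEOUS_DEFAULTS)
    if overrides:
        values.update(overrides)
    params = {
        "kon": RateConstant("kon", K_ON_BARBED),
        "koff": RateConstant("koff", K_OFF_BARBED),
        # oligomer on-rates, fixed at the barbed-end value but held as
        # separate constants so the spontaneous pathway can be switched off
        # independently of elongation
        "kf2": RateConstant("kf2", values.get("kf2", K_ON_BARBED)),
        "kf3": RateConstant("kf3", values.get("kf3", K_ON_BARBED)),
        "kf4": RateConstant("kf4", values.get("kf4", K_ON_BARBED)),
    }
    for name in SPONTANEOUS_DEFAULTS:
        params[name] = RateConstant(name, values[name])
    return params


def build_actin_alone(overrides: dict[str, float] | None = None) -> ReactionNetwork:
    """Spontaneous nucleation/elongation network for actin-alone reactions.

    Dimers, trimers and tetramers form reversibly with on-rate fixed at the
    barbed-end value; each tier can irreversibly become a nucleus (three
    parallel tiers).  No pointed-end reactions.
    """
    params = _base_params(overrides)
    species = ["G", "F", "A2", "A3", "A4", "E_spont"]
    return ReactionNetwork("actin_alone", species, _spontaneous_reactions(params), params)


def build_dip1_model(
    n_monomer_steps: int,
    overrides: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Actin-alone network extended with the Dip1 activation pathway.

    ``n_monomer_steps`` actin monomers (0-3) bind the Dip1-Arp2/3 assembly
    reversibly before the irreversible activation step creates a Dip1-capped
    barbed end.  All monomer-addition steps share k10/km10.  Dip1 is consumed
    (single turnover).
    """
    if n_monomer_steps not in (0, 1, 2, 3):
        raise ValueError(
            f"invalid variant: n_monomer_steps must be 0..3, got {n_monomer_steps}"
        )
    values = dict(DIP1_DEFAULTS)
    if overrides:
        for k, v in overrides.items():
            if k in values:
                values[k] = v
    params = _base_params(overrides)
    for name in DIP1_DEFAULTS:
        params[name] = RateConstant(name, values[name])

    species = ["G", "F", "A2", "A3", "A4", "E_spont", "D", "C", "DC"]
    species += [f"DCA{i}" for i in range(1, n_monomer_steps + 1)]
    species += ["E_dip"]

    rxns = _spontaneous_reactions(params)
    rxns.append(Reaction({"D": 1, "C": 1}, {"DC": 1}, params["k9"], params["km9"]))
    chain = ["DC"] + [f"DCA{i}" for i in range(1, n_monomer_steps + 1)]
    for prev, nxt in zip(chain[:-1], chain[1:]):
        rxns.append(Reaction({prev: 1, "G": 1}, {nxt: 1}, params["k10"], params["km10"]))
    # Irreversible activation: bound monomers released into F, D+C consumed
    # into the Dip1-capped end.
    released = {"E_dip": 1}
    if n_monomer_steps > 0:
        released["F"] = n_monomer_steps
    rxns.append(Reaction({chain[-1]: 1}, released, params["k11"]))
    rxns.append(Reaction({"E_dip": 1, "G": 1}, {"E_dip": 1, "F": 1}, params["kon"]))
    rxns.append(Reaction({"E_dip": 1}, {}, params["koff"], rate_law="catalytic_depol"))

    return ReactionNetwork(
        f"dip1_{n_monomer_steps}_monomers", species, rxns, params,
        n_monomer_steps=n_monomer_steps,
    )


def build_synergy_model(
    float_mask: set[str] | frozenset[str] | list[str],
    fitted_values: dict[str, float] | None = None,
) -> ReactionNetwork:
    """One-monomer Dip1 pathway with selected constants flagged floated.

    Wsp1-VCA is not an explicit species: its effect is absorbed into the
    floated constants of the Dip1 pathway.  ``fitted_values`` supplies the
    Dip1-alone estimates at which all non-floated constants are fixed.
    """
    mask = set(float_mask)
    if not mask:
        raise ValueError("invalid variant: float mask must be non-empty")
    bad = mask - SYNERGY_FLOATABLE
    if bad:
        raise ValueError(f"invalid variant: constants not floatable: {sorted(bad)}")
    net = build_dip1_model(1, overrides=fitted_values)
    for name in mask:
        p = net.params[name]
        net.params[name] = RateConstant(
            p.name, p.value, fixed=False, bounds=default_bounds(name)
        )
    net.variant = "synergy_" + "_".join(sorted(mask))
    return net


def default_bounds(name: str) -> tuple[float, float]:
    """Log-search bounds by constant class: on-rates, off-rates, activation."""
    if name in ("k9", "k10"):
        return (1e3 / 1e6, 1e8 / 1e6)  # 1e3..1e8 /M/s in /uM/s
    if name == "k11":
        return (1e-4, 1e2)
    return (1e-4, 1e3)  # first-order off-rates, /s


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    net: ReactionNetwork,
    initial: dict[str, float],
    t_grid: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate the network ODEs on ``t_grid`` (seconds, starting at 0).

    Uses a stiff solver (BDF) with dense output on the reporting grid.
    Tiny negative excursions within solver tolerance are clipped to zero in
    the reported concentrations.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")
    y0 = np.zeros(len(net.species))
    for name, conc in initial.items():
        if name not in net._index:
            raise KeyError(f"species {name!r} not in variant {net.variant}")
        if conc < 0:
            raise ValueError(f"negative initial concentration for {name}")
        y0[net._index[name]] = conc

    rhs, jac = net.make_odes()
    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid,
        method=method, rtol=rtol, atol=atol, jac=jac,
    )
    if not sol.success:
        pvals = {n: p.value for n, p in net.params.items()}
        raise RuntimeError(
            f"integration failed for variant {net.variant!r} (params={pvals}): {sol.message}"
        )
    y = sol.y
    if y.min() < -1e-3:
        raise RuntimeError(
            f"integration produced large negative concentrations for {net.variant!r}"
        )
    y = np.maximum(y, 0.0)
    return SimulationResult(t_grid, list(net.species), y, net.variant)


# ---------------------------------------------------------------------------
# Parameter / preset serialization
# ---------------------------------------------------------------------------

def params_to_tsv(params: dict[str, RateConstant], path) -> None:
    rows = [
        {"name": p.name, "value": p.value, "fixed": p.fixed,
         "lower": p.bounds[0], "upper": p.bounds[1]}
        for p in params.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def params_from_tsv(path) -> dict[str, RateConstant]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.name] = RateConstant(
            row.name, float(row.value), bool(row.fixed),
            (float(row.lower), float(row.upper)),
        )
    return out


def network_to_yaml(net: ReactionNetwork, path) -> None:
    doc = {
        "variant": net.variant,
        "n_monomer_steps": net.n_monomer_steps,
        "params": {
            name: {"value": float(p.value), "fixed": bool(p.fixed),
                   "lower": float(p.bounds[0]),
                   "upper": (None if np.isinf(p.bounds[1]) else float(p.bounds[1]))}
            for name, p in net.params.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def network_from_yaml(path) -> ReactionNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    values = {n: d["value"] for n, d in doc["params"].items()}
    variant = doc["variant"]
    if variant == "actin_alone":
        net = build_actin_alone(values)
    else:
        net = build_dip1_model(doc["n_monomer_steps"], overrides=values)
        net.variant = variant
    for name, d in doc["params"].items():
        if not d["fixed"]:
            upper = np.inf if d["upper"] is None else d["upper"]
            net.params[name] = RateConstant(
                name, d["value"], fixed=False, bounds=(d["lower"], upper)
            )
    return net
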