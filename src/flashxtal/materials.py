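"""Element data, cross-section interpolation and sample compositions.

The bundled tables (``data/elements.csv``, ``data/xsections.csv``) are the
package's single source of truth for photoabsorption and elastic-scattering
cross sections on a 0.2–12 keV grid; interpolation between grid nodes is
log-log linear, with grid points placed on both sides of each K edge so no
smoothing occurs across an edge.

A :class:`Composition` is an empirical formula (fractional counts allowed)
plus an optional mass density, from which the mean atomic mass, attenuation
coefficient μ and absorption length follow.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import gemmi
import numpy as np

from .constants import A_PER_CM, BARN_TO_CM2, N_A, UM_PER_CM

__all__ = [
    "ElementRecord",
    "CrossSectionTable",
    "Composition",
    "parse_formula",
    "get_element",
    "get_table",
    "builtin_material",
    "mean_atomic_mass",
    "photoabsorption_cross_section",
    "elastic_cross_section",
    "attenuation_coefficient",
    "absorption_length",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


@dataclass(frozen=True)
class ElementRecord:
    """Static per-element data: mass, K-edge, K-hole Auger lifetime."""

    symbol: str
    Z: int
    m_A: float              # g/mol
    E_K: float              # eV
    tau_auger: float | None  # fs; None where not bundled

    def __post_init__(self):
        if self.Z < 1 or self.m_A <= 0:
            raise ValueError(f"invalid element record for {self.symbol}")
        if self.tau_auger is not None and self.tau_auger <= 0:
            raise ValueError("Auger lifetime must be positive")


class CrossSectionTable:
    """Per-element photoabsorption and elastic cross sections vs energy.

    Values between grid nodes are interpolated log-log; queries outside the
    tabulated energy range raise rather than extrapolate.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = dict(data)
        for sym, (e, sa, ss) in self._data.items():
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"energy grid for {sym} not strictly increasing")
            if np.any(sa < 0) or np.any(ss < 0):
                raise ValueError(f"negative cross section for {sym}")

    @classmethod
    def from_csv(cls, path_or_buf) -> "CrossSectionTable":
        rows: dict[str, list[tuple[float, float, float]]] = {}
        reader = csv.DictReader(path_or_buf)
        for r in reader:
            rows.setdefault(r["symbol"], []).append(
                (float(r["energy_ev"]), float(r["sigma_a_barn"]), float(r["sigma_s_barn"]))
            )
        data = {}
        for sym, vals in rows.items():
            vals.sort()
            arr = np.array(vals)
            data[sym] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(data)

    @property
    def elements(self) -> list[str]:
        return sorted(self._data)

    def _interp(self, symbol: str, energy_ev: float, column: int) -> float:
        try:
            e, sa, ss = self._data[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in cross-section table") from None
        if not (e[0] <= energy_ev <= e[-1]):
            raise ValueError(
                f"energy {energy_ev} eV outside tabulated range "
                f"[{e[0]:.0f}, {e[-1]:.0f}] eV for {symbol}"
            )
        y = (sa, ss)[column - 1]
        return float(np.exp(np.interp(np.log(energy_ev), np.log(e), np.log(y))))

    def photoabsorption(self, symbol: str, energy_ev: float) -> float:
        """σ_A in barn."""
        return self._interp(symbol, energy_ev, 1)

    def elastic(self, symbol: str, energy_ev: float) -> float:
        """σ_S in barn."""
        return self._interp(symbol, energy_ev, 2)


@lru_cache(maxsize=1)
def _element_records() -> dict[str, ElementRecord]:
    out = {}
    with resources.files("flashxtal.data").joinpath("elements.csv").open() as fh:
        for r in csv.DictReader(fh):
            out[r["symbol"]] = ElementRecord(
                symbol=r["symbol"],
                Z=int(r["Z"]),
                m_A=float(r["mass_g_mol"]),
                E_K=float(r["e_k_ev"]),
                tau_auger=float(r["tau_auger_fs"]) if r["tau_auger_fs"] else None,
            )
    return out


@lru_cache(maxsize=1)
def get_table() -> CrossSectionTable:
    """The bundled cross-section table."""
    with resources.files("flashxtal.data").joinpath("xsections.csv").open() as fh:
        return CrossSectionTable.from_csv(fh)


def get_element(symbol: str) -> ElementRecord:
    """Bundled record if available, else mass/Z from the periodic table."""
    rec = _element_records().get(symbol)
    if rec is not None:
        return rec
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise KeyError(f"unknown element symbol {symbol!r}")
    return ElementRecord(symbol=symbol, Z=el.atomic_number, m_A=el.weight,
                         E_K=float("nan"), tau_auger=None)


@dataclass(frozen=True)
class Composition:
    """Stoichiometry (possibly fractional counts) with optional density."""

    counts: Mapping[str, float]
    rho: float | None = None    # g/cm³
    name: str = ""

    def __post_init__(self):
        if not self.counts:
            raise ValueError("composition must contain at least one element")
        for sym, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"count for {sym} must be positive")
            get_element(sym)  # validates the symbol
        if self.rho is not None and self.rho <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "counts", dict(self.counts))

    def with_density(self, rho: float) -> "Composition":
        return replace(self, rho=rho)

    @property
    def n_atoms_per_formula(self) -> float:
        return sum(self.counts.values())

    @property
    def formula_mass(self) -> float:
        """g/mol per formula unit."""
        return sum(c * get_element(s).m_A for s, c in self.counts.items())

    @property
    def mean_atomic_mass(self) -> float:
        """g/mol per atom, stoichiometrically weighted."""
        return self.formula_mass / self.n_atoms_per_formula

    @property
    def mean_electrons_per_atom(self) -> float:
        return sum(c * get_element(s).Z for s, c in self.counts.items()) / self.n_atoms_per_formula

    @property
    def number_density(self) -> float:
        """Atoms per cm³ (requires density)."""
        self._require_density()
        return self.rho * N_A / self.mean_atomic_mass

    def _require_density(self):
        if self.rho is None:
            raise ValueError(f"composition {self.name or self.counts} has no density set")

    def formula(self) -> str:
        def fmt(c: float) -> str:
            return f"{c:g}" if c != 1 else ""
        return "".join(f"{s}{fmt(c)}" for s, c in self.counts.items())


def parse_formula(text: str) -> Composition:
    """Parse an empirical formula like ``H50C30N9O10S1`` (density unset).

    A missing count means 1; fractional counts are accepted. Formatting the
    result with :meth:`Composition.formula` and re-parsing is the identity.
    """
    if not text:
        raise ValueError("empty formula")
    counts: dict[str, float] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        sym, num = m.group(1), m.group(2)
        try:
            get_element(sym)
        except KeyError:
            raise ValueError(f"unknown element symbol {sym!r} in formula {text!r}") from None
        counts[sym] = counts.get(sym, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    return Composition(counts=counts)


_BUILTINS = {
    "avg_protein": ("H50C30N9O10S1", 1.35),
    "water": ("H2O", 1.0),
    "carbon": ("C", 2.0),
    "psi_crystal": ("H141400O57300C16900N3310S89Fe12Mg96P3Ca1", 1.077),
}


def builtin_material(name: str) -> Composition:
    """Built-in sample compositions (avg_protein, water, carbon, psi_crystal)."""
    try:
        formula, rho = _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; choose from {sorted(_BUILTINS)}") from None
    return replace(parse_formula(formula), rho=rho, name=name)


def mean_atomic_mass(comp: Composition) -> float:
    """Mean atomic mass of a composition, g/mol per atom."""
    return comp.mean_atomic_mass


def photoabsorption_cross_section(element: str, energy_ev: float,
                                  table: CrossSectionTable | None = None) -> float:
    """σ_A of an element at the given photon energy, in barn."""
    return (table or get_table()).photoabsorption(element, energy_ev)


def elastic_cross_section(element: str, energy_ev: float,
                          table: CrossSectionTable | None = None) -> float:
    """σ_S of an element at the given photon energy, in barn."""
    return (table or get_table()).elastic(element, energy_ev)


def attenuation_coefficient(comp: Composition, energy_ev: float,
                            table: CrossSectionTable | None = None) -> float:
    """Linear attenuation coefficient μ in cm⁻¹ (transmission I = I₀ e^{−μt}).

    μ = ρ N_A Σᵢ cᵢ σ_A,ᵢ / Σᵢ cᵢ m_A,ᵢ — linear in density.
    """
    comp._require_density()
    tab = table or get_table()
    sigma_sum = sum(c * tab.photoabsorption(s, energy_ev) for s, c in comp.counts.items())
    return comp.rho * N_A * sigma_sum * BARN_TO_CM2 / comp.formula_mass


def mass_attenuation(comp: Composition, energy_ev: float,
                     table: CrossSectionTable | None = None) -> float:
    """μ/ρ in cm²/g — intensive, independent of density."""
    tab = table or get_table()
    sigma_sum = sum(c * tab.photoabsorption(s, energy_ev) for s, c in comp.counts.items())
    return N_A * sigma_sum * BARN_TO_CM2 / comp.formula_mass


def absorption_length(comp: Composition, energy_ev: float,
                      table: CrossSectionTable | None = None) -> float:
    """1/μ in micrometres."""
    return 1.0 / attenuation_coefficient(comp, energy_ev, table) * UM_PER_CM
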