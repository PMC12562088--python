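"""Parameter sets, characteristic scales and the nondimensionalization map.

The model works almost entirely in nondimensional variables: lengths are
rescaled by a characteristic tissue length ``L`` (vessel-to-tumor distance),
time by the diffusion time ``tau = L**2 / D`` of a reference diffusivity
``D``, and the four fields by reference densities/concentrations
``(n0, c0, d0, omax)``.  :class:`NDParams` is the single authoritative
parameter container consumed by every solver and agent rule; its defaults
reproduce the published reference set (see :func:`default_parameters`).

:func:`nondimensionalize` maps SI-valued :class:`DimensionalParams` onto
:class:`NDParams`:

* diffusivities divide by ``D``,
* first-order rates multiply by ``tau``,
* per-cell volumetric rates multiply by ``tau * n0``,
* per-cell molar sources additionally divide by the target concentration
  scale (``c0``, ``d0`` or ``omax``),
* the chemotactic coefficient maps as ``chi0 * c0 / D`` and the saturation
  ratio as ``alpha = c0 / k1``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "Scales",
    "DimensionalParams",
    "NDParams",
    "nondimensionalize",
    "default_parameters",
    "default_dimensional_parameters",
    "default_scales",
    "validate_against_reference",
    "load_config",
    "save_config",
]


class InvalidScalesError(ValueError):
    """Raised when a characteristic scale is nonpositive or inconsistent."""


@dataclass(frozen=True)
class Scales:
    """Characteristic quantities used for nondimensionalization.

    ``tau`` must equal ``L**2 / D`` (relative tolerance 1e-9); all entries
    are strictly positive.
    """

    L: float = 5.0e-3            # m, parent-vessel-to-tumor distance
    tau: float = 5.76e4          # s, diffusion time L^2/D
    D: float = 5.0e-3 ** 2 / 5.76e4   # m^2/s, reference diffusivity
    n0: float = 6.4e13           # cell/m^3, densely packed tissue
    c0: float = 1.0e-7           # mol/m^3, TAF concentration scale
    d0: float = 0.07262208       # mol/m^3, drug scale chosen so Sd_nd = 2
    omax: float = 6.7            # mol/m^3, vessel oxygen saturation

    def __post_init__(self) -> None:
        for name in ("L", "tau", "D", "n0", "c0", "d0", "omax"):
            if getattr(self, name) <= 0:
                raise InvalidScalesError(f"scale {name!r} must be positive")
        if not math.isclose(self.tau, self.L ** 2 / self.D, rel_tol=1e-9):
            raise InvalidScalesError("tau must equal L**2 / D")


@dataclass(frozen=True)
class DimensionalParams:
    """SI-valued model parameters (one entry per published dimensional row)."""

    Dn: float = 2.00e-13         # m^2/s endothelial diffusion
    Dc: float = 5.21e-11         # m^2/s TAF diffusion
    Dd: float = 2.17e-10         # m^2/s drug diffusion
    Do: float = 2.78e-10         # m^2/s oxygen diffusion
    xi_c: float = 3.47e-8        # 1/s TAF decay
    xi_d: float = 1.74e-7        # 1/s drug decay
    xi_o: float = 4.34e-7        # 1/s oxygen decay
    eta: float = 1.7e-22         # mol/(cell s) TAF secretion per hypoxic cell
    lam_uptake: float = 2.71e-20  # m^3/(cell s) TAF uptake at vessels
    rho_d: float = 1.36e-19      # m^3/(cell s) drug uptake per tumor cell
    So: float = 9.33e-19         # m^3/(cell s) oxygen supply per vessel site
    Sd_rate: float = 3.94e-20    # mol/(cell s) drug supply per vessel site
    rho_o: float = 6.25e-17      # mol/(cell s) oxygen uptake per tumor cell
    chi0: float = 2.60e-4        # m^5/(s mol) chemotactic coefficient
    k1: float = 1.6667e-7        # mol/m^3 receptor half-saturation
    Rc: float = 1.25e-5          # m cell radius
    o_hyp: float = 1.675         # mol/m^3 hypoxia threshold
    o_apop: float = 0.335        # mol/m^3 apoptosis threshold
    omax: float = 6.7            # mol/m^3 oxygen saturation
    psi_age: float = 6.48e4      # s minimum branching age
    tau_tip: float = 6.48e4      # s tip doubling time
    cell_cycle_range: tuple[float, float] = (3.24e4, 3.96e4)  # s

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"dimensional parameter {f.name!r} must be nonnegative")
        if not (self.o_apop < self.o_hyp < self.omax):
            raise ValueError("oxygen thresholds must satisfy o_apop < o_hyp < omax")


@dataclass(frozen=True)
class NDParams:
    """Nondimensional parameter set (the authoritative reference defaults).

    ``Kd``, ``Ko``, ``Kc`` are half-saturation constants used only when
    Michaelis-Menten kinetics are selected; they have no default because the
    reference simulations use linear kinetics.
    """

    # relative diffusivities
    Dn: float = 4.61e-4
    Dc: float = 0.12
    Dd: float = 0.5
    Do: float = 0.64
    # chemotaxis
    chi0: float = 0.0599
    alpha: float = 0.6
    # decay rates
    xi_c: float = 0.002
    xi_d: float = 0.01
    xi_o: float = 0.025
    # source / sink rates
    eta: float = 6.27e3
    lam_uptake: float = 0.1
    rho_d: float = 0.5
    rho_o: float = 34.39
    Sd: float = 2.0
    So: float = 3.44
    eta_n: float = 0.0           # endothelial TAF production (0 = unidirectional)
    # geometry and thresholds
    Rc: float = 0.005
    o_hyp: float = 0.25
    o_apop: float = 0.05
    # tumor agent parameters
    eps_motility: float = 0.0215
    mu: float = 0.0              # mutation intensity (mutations off by default)
    p_r: float = 0.2
    Fmax: int = 10
    a_death_S: float = 0.5
    Th_multi: float = 5.0
    age_range: tuple[float, float] = (0.5625, 0.6875)
    # endothelial tip parameters
    psi_age: float = 1.125
    c_br: float = 1.0
    tau_tip: float = 1.125
    # optional Michaelis-Menten half-saturations
    Kd: Optional[float] = None
    Ko: Optional[float] = None
    Kc: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.o_apop < self.o_hyp):
            raise ValueError("thresholds must satisfy 0 <= o_apop < o_hyp")

    def replace(self, **changes) -> "NDParams":
        """Return a copy with the given fields replaced (params are immutable)."""
        return dataclasses.replace(self, **changes)

    def chi(self, c):
        """Saturating chemotactic sensitivity chi(c) = chi0 / (1 + alpha*c)."""
        return self.chi0 / (1.0 + self.alpha * c)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NDParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def default_scales() -> Scales:
    return Scales()


def default_dimensional_parameters() -> DimensionalParams:
    return DimensionalParams()


def default_parameters() -> NDParams:
    """The published nondimensional reference set, side-effect free."""
    return NDParams()


def nondimensionalize(dim: DimensionalParams, scales: Scales, **overrides) -> NDParams:
    """Map a dimensional parameter set onto nondimensional form.

    Parameters with no dimensional counterpart (motility amplitude, mutation
    intensity, repair rate, crowding threshold, death thresholds, branching
    rate) keep their :class:`NDParams` defaults unless supplied via
    ``overrides``.
    """
    if not isinstance(scales, Scales):
        raise TypeError("scales must be a Scales instance")
    s = scales
    nd = dict(
        Dn=dim.Dn / s.D,
        Dc=dim.Dc / s.D,
        Dd=dim.Dd / s.D,
        Do=dim.Do / s.D,
        chi0=dim.chi0 * s.c0 / s.D,
        alpha=s.c0 / dim.k1,
        xi_c=s.tau * dim.xi_c,
        xi_d=s.tau * dim.xi_d,
        xi_o=s.tau * dim.xi_o,
        eta=dim.eta * s.tau * s.n0 / s.c0,
        lam_uptake=dim.lam_uptake * s.tau * s.n0,
        rho_d=dim.rho_d * s.tau * s.n0,
        Sd=dim.Sd_rate * s.tau * s.n0 / s.d0,
        rho_o=dim.rho_o * s.tau * s.n0 / s.omax,
        So=dim.So * s.tau * s.n0,
        Rc=dim.Rc / s.L,
        o_hyp=dim.o_hyp / dim.omax,
        o_apop=dim.o_apop / dim.omax,
        psi_age=dim.psi_age / s.tau,
        tau_tip=dim.tau_tip / s.tau,
        age_range=(dim.cell_cycle_range[0] / s.tau, dim.cell_cycle_range[1] / s.tau),
    )
    nd.update(overrides)
    return NDParams(**nd)


#: printed reference values and the number of significant figures they carry,
#: used by :func:`validate_against_reference`.
_REFERENCE_ND = {
    "Dn": (4.61e-4, 3),
    "Dc": (0.12, 2),
    "Dd": (0.5, 1),
    "Do": (0.64, 2),
    "chi0": (0.0599, 3),
    "alpha": (0.6, 1),
    "xi_c": (0.002, 1),
    "xi_d": (0.01, 1),
    "xi_o": (0.025, 2),
    "eta": (6.27e3, 3),
    "lam_uptake": (0.1, 1),
    "rho_d": (0.5, 1),
    "rho_o": (34.39, 4),
    "Sd": (2.0, 1),
    "So": (3.44, 3),
    "Rc": (0.005, 1),
    "o_hyp": (0.25, 2),
    "o_apop": (0.05, 1),
    "psi_age": (1.125, 4),
    "tau_tip": (1.125, 4),
}


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def validate_against_reference(nd: NDParams) -> dict[str, tuple[float, float]]:
    """Compare a nondimensional set against the printed reference values.

    Returns ``{name: (computed, printed)}`` for every entry that disagrees
    with the printed value beyond its printed precision.  Used to audit a
    freshly nondimensionalized set; disagreements are reported, never raised
    (the printed ND table is authoritative for defaults).
    """
    report = {}
    for name, (printed, sig) in _REFERENCE_ND.items():
        computed = getattr(nd, name)
        if _round_sig(computed, sig) != printed:
            report[name] = (computed, printed)
    return report


def load_config(path: str | Path) -> NDParams:
    """Load an :class:`NDParams` set from a JSON or YAML config file.

    Keys are the ASCII parameter names (``chi0``, ``xi_c``, ``eta_n``, ...);
    missing keys fall back to the reference defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    base = default_parameters().to_dict()
    base.update(data or {})
    return NDParams.from_dict(base)


def save_config(nd: NDParams, path: str | Path) -> None:
    path = Path(path)
    data = nd.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
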