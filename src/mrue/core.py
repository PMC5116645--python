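"""Multiple-resource-use-efficiency (mRUE) algebra.

ANPP (aboveground net primary production) is decomposed, for each resource
``i`` (light, water, nitrogen), into an availability term, an absorption
rate and a use efficiency::

    ANPP = available_i * eps_i * RUE_i

where ``eps_i = absorbed_i / available_i`` (a fraction in (0, 1]) and
``RUE_i = ANPP / absorbed_i``.  When the three resources are considered
jointly, geometric means preserve the identity::

    ANPP = R_avail * eps * mRUE

with ``mRUE = (WUE * LUE * NUE)^(1/3)``, ``eps = (eps_l * eps_w * eps_n)^(1/3)``
and ``R_avail`` the geometric mean of the three available quantities.

All resources are carried in mass-equivalent units of g m^-2 yr^-1; incident
and absorbed light, usually measured in MJ m^-2, are converted with the plant
caloric value (default 19.38 kJ g^-1 for semi-arid grassland).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CALORIC_VALUE",
    "TREATMENT_LEVELS",
    "ResourceRecord",
    "EfficiencySet",
    "caloric_convert",
    "geometric_mean",
    "compute_rue",
    "compute_epsilon",
    "compute_efficiency_set",
    "reconstruct_anpp",
    "efficiency_table",
]

#: Plant caloric value used to convert light from MJ m^-2 to g m^-2 (kJ g^-1).
DEFAULT_CALORIC_VALUE = 19.38

#: Precipitation manipulation levels of the randomized-block design
#: (fractional change relative to ambient).
TREATMENT_LEVELS = (-0.6, -0.4, -0.2, 0.0, 0.2, 0.4, 0.6)


class InvalidRecordError(ValueError):
    """A plot-year record violates a positivity or absorbed<=available bound."""


@dataclass(frozen=True)
class ResourceRecord:
    """One plot-year of the water-gradient experiment.

    All resource quantities are annual accumulations in g m^-2 yr^-1
    (light after caloric conversion).

    Attributes
    ----------
    plot_id : str
        Plot identifier.
    treatment : float
        Precipitation delta fraction (one of ``TREATMENT_LEVELS`` in the
        reference design, but any value > -1 is accepted).
    year : int
        Calendar year of the record.
    anpp : float
        Aboveground net primary production.
    par, apar : float
        Incident and absorbed photosynthetically active radiation
        (mass-equivalent).
    ms, tr : float
        Accumulated soil water content and accumulated transpiration.
    ns, n_uptake : float
        Accumulated soil nitrogen and plant nitrogen uptake.
    """

    plot_id: str
    treatment: float
    year: int
    anpp: float
    par: float
    apar: float
    ms: float
    tr: float
    ns: float
    n_uptake: float

    def __post_init__(self) -> None:
        for f in ("anpp", "par", "apar", "ms", "tr", "ns", "n_uptake"):
            v = getattr(self, f)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidRecordError(
                    f"{f} must be strictly positive and finite, got {v!r} "
                    f"(plot {self.plot_id}, year {self.year})"
                )
        for absorbed, available in (("apar", "par"), ("tr", "ms"), ("n_uptake", "ns")):
            if getattr(self, absorbed) > getattr(self, available):
                raise InvalidRecordError(
                    f"absorbed {absorbed}={getattr(self, absorbed)} exceeds "
                    f"available {available}={getattr(self, available)} "
                    f"(plot {self.plot_id}, year {self.year})"
                )


@dataclass(frozen=True)
class EfficiencySet:
    """Per-resource efficiencies and absorption rates plus their composites.

    ``wue``, ``lue``, ``nue`` are the single-resource use efficiencies
    (ANPP per unit absorbed water / light / nitrogen); ``eps_l``, ``eps_w``,
    ``eps_n`` the absorption fractions; ``mrue`` and ``eps`` their geometric
    means; ``r_avail_comp`` the geometric mean of the three available
    quantities (g m^-2 yr^-1).
    """

    wue: float
    lue: float
    nue: float
    eps_l: float
    eps_w: float
    eps_n: float
    mrue: float
    eps: float
    r_avail_comp: float

    FIELD_NAMES = (
        "wue", "lue", "nue", "eps_l", "eps_w", "eps_n", "mrue", "eps", "r_avail_comp",
    )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def caloric_convert(energy: float, caloric_value: float = DEFAULT_CALORIC_VALUE) -> float:
    """Convert light energy (MJ m^-2) to dry-matter mass equivalent (g m^-2).

    ``mass = energy * 1000 / caloric_value`` — 1 MJ is 1000 kJ, and the
    caloric value (kJ g^-1) is the energy content of a gram of plant matter.
    """
    if not caloric_value > 0:
        raise ValueError(f"caloric value must be positive, got {caloric_value!r}")
    if energy < 0:
        raise ValueError(f"energy must be non-negative, got {energy!r}")
    return energy * 1000.0 / caloric_value


def geometric_mean(values) -> float:
    """Geometric mean (prod values)^(1/n), computed in log space.

    All values must be strictly positive; the composite indices mRUE, eps
    and R_avail are geometric means of their per-resource components.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def compute_rue(anpp: float, absorbed: float) -> float:
    """Single-resource use efficiency: production per unit absorbed resource."""
    if not absorbed > 0:
        raise ValueError(f"absorbed amount must be positive, got {absorbed!r}")
    if not anpp > 0:
        raise ValueError(f"anpp must be positive, got {anpp!r}")
    return anpp / absorbed


def compute_epsilon(absorbed: float, available: float) -> float:
    """Absorption rate eps_i = absorbed / available, constrained to (0, 1]."""
    if not available > 0:
        raise ValueError(f"available amount must be positive, got {available!r}")
    if not absorbed > 0:
        raise ValueError(f"absorbed amount must be positive, got {absorbed!r}")
    if absorbed > available:
        raise InvalidRecordError(
            f"absorbed ({absorbed}) exceeds available ({available})"
        )
    return absorbed / available


def compute_efficiency_set(record: ResourceRecord) -> EfficiencySet:
    """All nine efficiency quantities of one plot-year record."""
    wue = compute_rue(record.anpp, record.tr)
    lue = compute_rue(record.anpp, record.apar)
    nue = compute_rue(record.anpp, record.n_uptake)
    eps_l = compute_epsilon(record.apar, record.par)
    eps_w = compute_epsilon(record.tr, record.ms)
    eps_n = compute_epsilon(record.n_uptake, record.ns)
    return EfficiencySet(
        wue=wue,
        lue=lue,
        nue=nue,
        eps_l=eps_l,
        eps_w=eps_w,
        eps_n=eps_n,
        mrue=geometric_mean([wue, lue, nue]),
        eps=geometric_mean([eps_l, eps_w, eps_n]),
        r_avail_comp=geometric_mean([record.par, record.ms, record.ns]),
    )


def reconstruct_anpp(eff: EfficiencySet) -> float:
    """ANPP implied by the composite identity R_avail * eps * mRUE."""
    return eff.r_avail_comp * eff.eps * eff.mrue


def efficiency_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised `compute_efficiency_set` over a record table.

    Parameters
    ----------
    records : DataFrame
        Columns ``plot_id, treatment, year, anpp, par, apar, ms, tr, ns,
        n_uptake`` (extra columns are carried through).

    Returns
    -------
    DataFrame
        Input keys plus the nine ``EfficiencySet`` columns.
    """
    out = records.copy()
    out["wue"] = records["anpp"] / records["tr"]
    out["lue"] = records["anpp"] / records["apar"]
    out["nue"] = records["anpp"] / records["n_uptake"]
    out["eps_l"] = records["apar"] / records["par"]
    out["eps_w"] = records["tr"] / records["ms"]
    out["eps_n"] = records["n_uptake"] / records["ns"]
    out["mrue"] = (out["wue"] * out["lue"] * out["nue"]) ** (1.0 / 3.0)
    out["eps"] = (out["eps_l"] * out["eps_w"] * out["eps_n"]) ** (1.0 / 3.0)
    out["r_avail_comp"] = (records["par"] * records["ms"] * records["ns"]) ** (1.0 / 3.0)
    return out
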