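"""Synthetic precipitation-gradient experiment generator.

Emulates a randomized-block water-manipulation experiment in semi-arid
grassland: 7 precipitation levels (-60% .. +60% of ambient, ambient about
380 mm) x 6 replicate blocks x 3 years = 126 plot-year records.  Variables
are generated on the log scale (they are positive and multiplicative;
log-transformation is also what homogenises their variance for analysis):

* a standardized precipitation driver ``x_p = log(1+delta)/scale`` (zero at
  ambient; ``scale`` is the design RMS so the driver has unit spread);
* accumulated soil water Ms and transpiration Tr respond to the driver and
  carry additive block- and year-intercepts;
* nitrogen uptake follows transpiration (mass-flow), absorbed light follows
  soil water and nitrogen uptake, and ANPP is a log-linear combination of
  the absorbed resources with configurable loadings;
* incident light PAR and soil nitrogen Ns are exogenous availabilities.

Every structural equation is scaled so its variable has (near-)unit
variance on the standardized log scale, which makes the structural
coefficients directly comparable to standardized path coefficients; each
log variable is then mapped to the measurement scale as
``exp(mu + sigma * z)`` with the experiment's log-means and log-SDs.
Absorbed quantities stay below their availabilities by construction of the
baseline log-means (about one log unit of separation); a parameter set
that nonetheless produces an absorption fraction >= 1 raises with the
offending resource named.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd

from .core import TREATMENT_LEVELS

__all__ = [
    "ExperimentDesign",
    "GeneratorParams",
    "precipitation_for_level",
    "generate_experiment",
    "calibrate_to_control",
]

VARIABLES = ("aPAR", "PAR", "Tr", "Ms", "N_uptake", "Ns", "ANPP")

_DEFAULT_LOG_MEANS = {
    "aPAR": 10.0, "PAR": 11.0, "Tr": 13.0, "Ms": 15.0,
    "N_uptake": 1.2, "Ns": 3.7, "ANPP": 5.3,
}
_DEFAULT_LOG_SDS = {
    "aPAR": 0.3, "PAR": 0.04, "Tr": 0.3, "Ms": 0.2,
    "N_uptake": 0.05, "Ns": 0.17, "ANPP": 0.4,
}


class GenerationError(RuntimeError):
    """Parameter set produced an invalid record (e.g. absorption >= 1)."""


class CalibrationError(ValueError):
    """Calibration targets imply an absorption fraction outside (0, 1)."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of the randomized-block experiment."""

    deltas: tuple[float, ...] = TREATMENT_LEVELS
    reps: int = 6
    years: int = 3
    base_precip: float = 380.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= -1 for d in self.deltas):
            raise ValueError("precipitation deltas must exceed -1 (cannot remove >100%)")
        if self.reps < 1 or self.years < 1:
            raise ValueError("need at least one replicate and one year")
        if not self.base_precip > 0:
            raise ValueError("base precipitation must be positive")

    @property
    def n_records(self) -> int:
        return len(self.deltas) * self.reps * self.years


@dataclass(frozen=True)
class GeneratorParams:
    """Structural parameters of the generator, on the standardized log scale.

    ``log_means``/``log_sds`` place each variable on the measurement scale;
    ``precip_to_ms``/``precip_to_tr`` are the water sensitivities of soil
    water and transpiration to the standardized precipitation driver;
    ``tr_to_nup``, ``ms_to_apar``, ``nup_to_apar`` are the resource-coupling
    coefficients; ``anpp_loadings`` weight the absorbed resources (and soil
    water, negatively by default: surplus water depresses efficiency) in
    the production equation.  ``block_sd``/``year_sd`` are the random-
    intercept SDs of the design; ``noise_scale`` scales all stochastic
    terms jointly (0 gives the deterministic skeleton).
    """

    log_means: dict = field(default_factory=lambda: dict(_DEFAULT_LOG_MEANS))
    log_sds: dict = field(default_factory=lambda: dict(_DEFAULT_LOG_SDS))
    precip_to_ms: float = 0.8
    precip_to_tr: float = 0.8
    tr_to_nup: float = 0.32
    ms_to_apar: float = 0.58
    nup_to_apar: float = 0.35
    anpp_loadings: dict = field(
        default_factory=lambda: {"Tr": 0.35, "aPAR": 0.30, "N_uptake": 0.20, "Ms": -0.35}
    )
    block_sd: float = 0.1
    year_sd: float = 0.1
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.log_means)
        if missing:
            raise ValueError(f"log_means missing {sorted(missing)}")
        missing = set(VARIABLES) - set(self.log_sds)
        if missing:
            raise ValueError(f"log_sds missing {sorted(missing)}")
        if any(s <= 0 for s in self.log_sds.values()):
            raise ValueError("log-scale noise sds must be positive")
        if self.block_sd < 0 or self.year_sd < 0 or self.noise_scale < 0:
            raise ValueError("random-effect sds and noise_scale must be non-negative")


def precipitation_for_level(base: float, delta: float) -> float:
    """Realised annual precipitation (mm) of one treatment level."""
    if delta <= -1:
        raise ValueError(f"delta must exceed -1, got {delta}")
    return base * (1.0 + delta)


def _residual_sd(explained_var: float, context: str) -> float:
    resid = 1.0 - explained_var
    if resid <= 0:
        raise ValueError(
            f"{context}: structural coefficients explain variance {explained_var:.3f} "
            ">= 1; no positive residual variance remains"
        )
    return math.sqrt(resid)


def generate_experiment(
    design: ExperimentDesign,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one ResourceRecord table for the full factorial design.

    Returns a DataFrame with columns ``plot_id, treatment, year, anpp, par,
    apar, ms, tr, ns, n_uptake`` and ``design.n_records`` rows, satisfying
    all record invariants (positive quantities, absorbed <= available).
    """
    params = params or GeneratorParams()
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    d = np.array([math.log1p(delta) for delta in design.deltas])
    scale = math.sqrt(float(np.mean(d**2)))
    xp_level = d / scale if scale > 0 else np.zeros_like(d)

    ns_ = params.noise_scale
    blocks = ns_ * rng.normal(0.0, params.block_sd, size=design.reps)
    years_eff = ns_ * rng.normal(0.0, params.year_sd, size=design.years)

    # variance bookkeeping at unit driver/intercept variance, so each z is
    # approximately standardized and coefficients read as path coefficients
    re_var = params.block_sd**2 + params.year_sd**2
    s_ms = _residual_sd(params.precip_to_ms**2 + re_var, "Ms equation")
    s_tr = _residual_sd(params.precip_to_tr**2 + re_var, "Tr equation")
    cov_ms_tr = params.precip_to_ms * params.precip_to_tr + re_var
    s_nup = _residual_sd(params.tr_to_nup**2, "N_uptake equation")
    cov_ms_nup = params.tr_to_nup * cov_ms_tr
    var_apar_hat = (
        params.ms_to_apar**2
        + params.nup_to_apar**2
        + 2 * params.ms_to_apar * params.nup_to_apar * cov_ms_nup
    )
    s_apar = _residual_sd(var_apar_hat, "aPAR equation")

    lam = {v: params.anpp_loadings.get(v, 0.0) for v in ("Tr", "aPAR", "N_uptake", "Ms")}
    cov = _z_covariance(params, cov_ms_tr, cov_ms_nup, s_nup, s_apar)
    explained = 0.0
    keys = list(lam)
    for a in keys:
        for b in keys:
            explained += lam[a] * lam[b] * cov[(a, b)]
    s_anpp = _residual_sd(explained, "ANPP equation")

    for absorbed, available in (("aPAR", "PAR"), ("Tr", "Ms"), ("N_uptake", "Ns")):
        if params.log_means[absorbed] >= params.log_means[available]:
            raise GenerationError(
                f"baseline log-mean of {absorbed} is not below {available}: "
                "parameters imply an absorption fraction >= 1"
            )

    rows = []
    for li, delta in enumerate(design.deltas):
        for b in range(design.reps):
            for t in range(design.years):
                xp = xp_level[li]
                env = blocks[b] + years_eff[t]
                # rare tail draws can push an absorbed quantity above its
                # availability; such rows are redrawn (a hard physical bound,
                # not a distributional truncation of any consequence at the
                # default log-mean separations)
                for attempt in range(100):
                    e = ns_ * rng.standard_normal(7)
                    z_ms = params.precip_to_ms * xp + env + s_ms * e[0]
                    z_tr = params.precip_to_tr * xp + env + s_tr * e[1]
                    z_par = e[2]
                    z_ns = e[3]
                    z_nup = params.tr_to_nup * z_tr + s_nup * e[4]
                    z_apar = (
                        params.ms_to_apar * z_ms
                        + params.nup_to_apar * z_nup
                        + s_apar * e[5]
                    )
                    z = {"Ms": z_ms, "Tr": z_tr, "aPAR": z_apar, "N_uptake": z_nup}
                    z_anpp = sum(lam[v] * z[v] for v in lam) + s_anpp * e[6]
                    z.update({"PAR": z_par, "Ns": z_ns, "ANPP": z_anpp})
                    value = {
                        v: math.exp(params.log_means[v] + params.log_sds[v] * z[v])
                        for v in VARIABLES
                    }
                    bad = _absorption_violation(value)
                    if bad is None:
                        break
                else:
                    raise GenerationError(
                        f"generated {bad[0]} >= {bad[1]} persistently at level "
                        f"{li + 1}, block {b + 1}, year {t + 1}: parameters imply "
                        "an absorption fraction >= 1"
                    )
                rows.append(
                    {
                        "plot_id": f"P{li + 1}B{b + 1}",
                        "treatment": delta,
                        "year": 1 + t,
                        "anpp": value["ANPP"],
                        "par": value["PAR"],
                        "apar": value["aPAR"],
                        "ms": value["Ms"],
                        "tr": value["Tr"],
                        "ns": value["Ns"],
                        "n_uptake": value["N_uptake"],
                    }
                )
    return pd.DataFrame(rows)


def _z_covariance(params, cov_ms_tr, cov_ms_nup, s_nup, s_apar) -> dict:
    """Covariances among the (approximately unit-variance) structural z's."""
    c = {}
    for v in ("Tr", "aPAR", "N_uptake", "Ms"):
        c[(v, v)] = 1.0
    c[("Ms", "Tr")] = cov_ms_tr
    c[("Ms", "N_uptake")] = cov_ms_nup
    c[("Tr", "N_uptake")] = params.tr_to_nup
    c[("Ms", "aPAR")] = params.ms_to_apar + params.nup_to_apar * cov_ms_nup
    c[("Tr", "aPAR")] = (
        params.ms_to_apar * cov_ms_tr + params.nup_to_apar * params.tr_to_nup
    )
    c[("N_uptake", "aPAR")] = (
        params.nup_to_apar + params.ms_to_apar * cov_ms_nup
    )
    for (a, b), v in list(c.items()):
        c[(b, a)] = v
    return c


def _absorption_violation(value: dict) -> tuple[str, str] | None:
    for absorbed, available in (("aPAR", "PAR"), ("Tr", "Ms"), ("N_uptake", "Ns")):
        if value[absorbed] >= value[available]:
            return absorbed, available
    return None


def calibrate_to_control(
    params: GeneratorParams,
    targets: dict[str, float],
) -> GeneratorParams:
    """Shift baseline log-means so the noiseless ambient record matches
    target control-plot efficiencies.

    ``targets`` provides ``wue``, ``lue``, ``nue`` (use efficiencies) and
    ``anpp``; absorbed baselines follow from ``absorbed_i = anpp / RUE_i``
    and availability baselines are kept, so the implied absorption
    fractions must remain in (0, 1).
    """
    required = {"wue", "lue", "nue", "anpp"}
    missing = required - set(targets)
    if missing:
        raise ValueError(f"calibration targets missing {sorted(missing)}")
    if any(not targets[k] > 0 for k in required):
        raise ValueError("calibration targets must be positive")
    anpp = targets["anpp"]
    new_means = dict(params.log_means)
    new_means["ANPP"] = math.log(anpp)
    for key, rue in (("Tr", "wue"), ("aPAR", "lue"), ("N_uptake", "nue")):
        new_means[key] = math.log(anpp / targets[rue])
    for absorbed, available in (("aPAR", "PAR"), ("Tr", "Ms"), ("N_uptake", "Ns")):
        if new_means[absorbed] >= new_means[available]:
            raise CalibrationError(
                f"targets imply {absorbed} >= {available} at baseline "
                f"({new_means[absorbed]:.3f} >= {new_means[available]:.3f}); "
                "absorption fraction would leave (0, 1)"
            )
    return replace(params, log_means=new_means)
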