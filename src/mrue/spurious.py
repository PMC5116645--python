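"""Monte Carlo quantification of spurious correlation among ratio composites.

A composite index built from several variables (the absorption rate
eps = ((aPAR/PAR)(Tr/Ms)(N_uptake/N_avail))^(1/3), or the use efficiency
mRUE = ANPP/(aPAR*Tr*N_uptake)^(1/3)) is correlated with any variable
appearing in its own formula even when all inputs are mutually
independent.  Drawing the seven inputs as independent normals with the
experiment's means and SDs, computing the composite per draw, and
recording the squared Pearson correlation between (the log of) a shared
variable and (the log of) the composite over many replicates measures
exactly this spurious determination coefficient — the part of an observed
bivariate R² that carries no ecological information.

A delta-method closed form serves as an independent check: for small
coefficients of variation, log X is approximately normal with sd ≈ sd/mean,
so the population correlation between a common variable and the composite is
its share of the composite's log-variance, and the expected sample R² adds
the finite-sample bias (1-rho²)²/n of a squared correlation.

Sensitivity scans reproduce the generic two-variable setting (a common
variable A and an independent variable B entering a ratio composite) under
scaled SDs, SD ratios and sample sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import MC_VARIABLE_SPECS

__all__ = [
    "VariableSpec",
    "MonteCarloConfig",
    "SpuriousDistribution",
    "default_config",
    "draw_variables",
    "composite_from_draws",
    "spurious_r2",
    "analytic_spurious_r2",
    "ScanBase",
    "sd_scaling_scan",
    "sd_ratio_scan",
    "sample_size_scan",
    "compare_groups",
    "weighted_spurious",
]

logger = logging.getLogger(__name__)

_QUANTS = (10, 25, 50, 75, 90)

#: Signed weight of each variable in the log of each composite.
COMPOSITE_TERMS = {
    "eps": {
        "aPAR": 1 / 3, "PAR": -1 / 3,
        "Tr": 1 / 3, "Ms": -1 / 3,
        "N_uptake": 1 / 3, "N_avail": -1 / 3,
    },
    "mrue": {"ANPP": 1.0, "aPAR": -1 / 3, "Tr": -1 / 3, "N_uptake": -1 / 3},
}


@dataclass(frozen=True)
class VariableSpec:
    """Mean and SD of one simulated variable, on the measurement scale."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"{self.name}: mean must be positive (enters ratios/logs)")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be non-negative")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Replication settings of the spurious-correlation Monte Carlo."""

    variable_specs: tuple[VariableSpec, ...]
    n: int = 126
    reps: int = 1000
    seed: int = 0
    correlate_on_log: bool = True

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("per-replicate sample size must be at least 3")
        if self.reps < 1:
            raise ValueError("need at least one replicate")
        names = [v.name for v in self.variable_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in config")

    def spec(self, name: str) -> VariableSpec:
        for v in self.variable_specs:
            if v.name == name:
                return v
        raise KeyError(f"no variable named {name!r} in config")


def default_config(seed: int = 0, n: int = 126, reps: int = 1000) -> MonteCarloConfig:
    """The experiment's seven-variable configuration."""
    specs = tuple(
        VariableSpec(name, mean, sd) for name, (mean, sd) in MC_VARIABLE_SPECS.items()
    )
    return MonteCarloConfig(variable_specs=specs, n=n, reps=reps, seed=seed)


@dataclass
class SpuriousDistribution:
    """Replicate distribution of the spurious R² for one (variable, composite) pair."""

    label: str
    r2_samples: np.ndarray = field(repr=False)
    mean_r2: float = 0.0
    quantiles: dict[int, float] = field(default_factory=dict)
    mc_standard_error: float = 0.0

    @classmethod
    def from_samples(cls, label: str, samples: np.ndarray) -> "SpuriousDistribution":
        samples = np.asarray(samples, dtype=float)
        q = np.percentile(samples, _QUANTS)
        return cls(
            label=label,
            r2_samples=samples,
            mean_r2=float(samples.mean()),
            quantiles={k: float(v) for k, v in zip(_QUANTS, q)},
            mc_standard_error=float(samples.std(ddof=1) / np.sqrt(samples.size))
            if samples.size > 1 else 0.0,
        )

    @property
    def iqr(self) -> float:
        return self.quantiles[75] - self.quantiles[25]

    def summary_row(self) -> dict:
        row = {"pair": self.label, "mean_r2": self.mean_r2, "mc_se": self.mc_standard_error}
        row.update({f"q{k}": v for k, v in self.quantiles.items()})
        return row


# ---------------------------------------------------------------------------
# drawing and composites
# ---------------------------------------------------------------------------

def _draw_positive(rng: np.random.Generator, mean: float, sd: float, shape) -> tuple[np.ndarray, int]:
    """Normal draws, rejection-resampled to stay positive (they enter logs)."""
    x = rng.normal(mean, sd, size=shape)
    rejected = 0
    bad = x <= 0
    while np.any(bad):
        rejected += int(bad.sum())
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= 0
    return x, rejected


def draw_variables(config: MonteCarloConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One replicate table of independent normal draws (n rows x variables)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    data, total_rejected, total_drawn = {}, 0, 0
    for v in config.variable_specs:
        col, rej = _draw_positive(rng, v.mean, v.sd, config.n)
        data[v.name] = col
        total_rejected += rej
        total_drawn += config.n + rej
    if total_rejected:
        logger.info("rejection-resampled %d non-positive draws", total_rejected)
        if total_rejected / total_drawn > 0.10:
            raise ValueError(
                f"rejection rate {total_rejected / total_drawn:.1%} exceeds 10%; "
                "means/SDs imply frequent non-positive values"
            )
    return pd.DataFrame(data)


def composite_from_draws(table: pd.DataFrame, which: str) -> np.ndarray:
    """Per-row composite (eps or mrue) from a seven-variable draw table."""
    if which not in COMPOSITE_TERMS:
        raise ValueError(f"unknown composite {which!r}; use 'eps' or 'mrue'")
    missing = set(COMPOSITE_TERMS[which]) - set(table.columns)
    if missing:
        raise KeyError(f"draw table is missing column(s) {sorted(missing)}")
    log_comp = np.zeros(len(table))
    for name, w in COMPOSITE_TERMS[which].items():
        log_comp = log_comp + w * np.log(table[name].to_numpy(dtype=float))
    return np.exp(log_comp)


def _r2_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise squared Pearson correlation of (reps, n) arrays."""
    mx = x.mean(axis=1, keepdims=True)
    my = y.mean(axis=1, keepdims=True)
    xc = x - mx
    yc = y - my
    ssx = (xc**2).sum(axis=1)
    ssy = (yc**2).sum(axis=1)
    # a column of identical values can leave ~1-ulp centering residue;
    # treat relative sd below 1e-12 as a constant replicate
    n = x.shape[1]
    tiny_x = n * (1e-12 * np.maximum(1.0, np.abs(mx[:, 0]))) ** 2
    tiny_y = n * (1e-12 * np.maximum(1.0, np.abs(my[:, 0]))) ** 2
    ok = (ssx > tiny_x) & (ssy > tiny_y)
    num = (xc * yc).sum(axis=1)
    out = np.zeros(x.shape[0])
    out[ok] = (num[ok] / np.sqrt(ssx[ok] * ssy[ok])) ** 2
    if not np.all(ok):
        warnings.warn(
            "degenerate replicate(s) with zero variance: R² reported as 0",
            RuntimeWarning, stacklevel=2,
        )
    return out


def spurious_r2(config: MonteCarloConfig, common: str, which: str) -> SpuriousDistribution:
    """Spurious determination coefficient between a variable and a composite.

    Per replicate: draw the variable table, form the composite, and square
    the Pearson correlation between the common variable and the composite
    (both log-transformed when ``correlate_on_log``, the reporting default).
    A variable absent from the composite's formula is allowed and yields
    the independence baseline E[R²] ≈ 1/(n-1).
    """
    config.spec(common)  # validate name
    if which not in COMPOSITE_TERMS:
        raise ValueError(f"unknown composite {which!r}")
    rng = np.random.default_rng(config.seed)
    cols = {}
    for v in config.variable_specs:
        cols[v.name], _ = _draw_positive(rng, v.mean, v.sd, (config.reps, config.n))
    log_comp = np.zeros((config.reps, config.n))
    for name, w in COMPOSITE_TERMS[which].items():
        log_comp = log_comp + w * np.log(cols[name])
    if config.correlate_on_log:
        x, y = np.log(cols[common]), log_comp
    else:
        x, y = cols[common], np.exp(log_comp)
    return SpuriousDistribution.from_samples(f"{common}~{which}", _r2_rows(x, y))


def _log_sd(mean: float, sd: float) -> float:
    """SD of log X for X normal(mean, sd) truncated to (0, inf), by
    Gauss-Hermite quadrature (equals sd/mean to first order in the CV)."""
    if sd == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    x = mean + sd * nodes
    keep = x > 0
    w = weights[keep] / weights[keep].sum()
    lx = np.log(x[keep])
    m = float(w @ lx)
    return float(np.sqrt(w @ (lx - m) ** 2))


def analytic_spurious_r2(
    specs, common: str, which: str, n: int = 126
) -> float:
    """Delta-method approximation to the expected sample spurious R².

    ``specs`` is a mapping name -> (mean, sd) or an iterable of
    `VariableSpec`.  Because the composite is an exact product of powers,
    its log is the weighted sum of the input logs, so under independence
    the population correlation between log(common) and log(composite) is
    exactly ``rho = w_c sigma_c / sqrt(sum_v w_v² sigma_v²)`` with
    ``sigma_v = sd(log X_v)`` (delta method gives sigma_v ≈ sd/mean; here
    sigma_v is computed by quadrature over the positive-truncated normal
    draw distribution).  The returned value is the bivariate-normal
    expectation of the squared sample correlation at that rho,
    ``1 - (n-2)/(n-1) (1-rho²) 2F1(1, 1; (n+1)/2; rho²)``,
    which reduces to the familiar ``rho² + (1-rho²)²/n`` bias formula to
    leading order (and to 1/(n-1) under independence).  Meaningful for
    coefficients of variation below 0.5 (warns beyond).
    """
    if hasattr(specs, "items"):
        lookup = {k: tuple(v) for k, v in specs.items()}
    else:
        lookup = {v.name: (v.mean, v.sd) for v in specs}
    if which not in COMPOSITE_TERMS:
        raise ValueError(f"unknown composite {which!r}")
    terms = COMPOSITE_TERMS[which]
    sig = {}
    for name in set(terms) | {common}:
        mean, sd = lookup[name]
        cv = sd / mean
        if cv >= 0.5:
            warnings.warn(
                f"{name}: CV {cv:.2f} >= 0.5, outside the small-CV domain",
                RuntimeWarning, stacklevel=2,
            )
        sig[name] = _log_sd(mean, sd)
    var_comp = sum((w * sig[name]) ** 2 for name, w in terms.items())
    w_common = terms.get(common, 0.0)
    if sig[common] == 0.0 or var_comp == 0.0 or w_common == 0.0:
        rho2 = 0.0
    else:
        rho = w_common * sig[common] / np.sqrt(var_comp)
        rho2 = float(rho**2)
    from scipy.special import hyp2f1

    return float(
        1.0 - (n - 2) / (n - 1) * (1.0 - rho2) * hyp2f1(1.0, 1.0, (n + 1) / 2.0, rho2)
    )


# ---------------------------------------------------------------------------
# sensitivity scans (generic two-variable composite)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanBase:
    """Generic scan setting: common variable A and independent variable B.

    The composite is the ratio A/B for the eps-type (common variable in the
    numerator) or B/A for the mRUE-type (common variable in the
    denominator); either way the spurious R² is A's share of the
    composite's log-variance.
    """

    n: int = 200
    mean: float = 20.0
    sd_a: float = 1.0
    reps: int = 1000
    seed: int = 0
    which: str = "eps"


def _scan_distribution(base: ScanBase, sd_a: float, sd_b: float, n: int, label: str,
                       rng: np.random.Generator) -> SpuriousDistribution:
    a, _ = _draw_positive(rng, base.mean, sd_a, (base.reps, n))
    b, _ = _draw_positive(rng, base.mean, sd_b, (base.reps, n))
    sign = 1.0 if base.which == "eps" else -1.0
    log_comp = sign * (np.log(a) - np.log(b))
    return SpuriousDistribution.from_samples(label, _r2_rows(np.log(a), log_comp))


def sd_scaling_scan(base: ScanBase, multipliers=(1, 2, 5)) -> list[SpuriousDistribution]:
    """Scale the SD of A and B jointly (T1, T2, T5 scenarios)."""
    rng = np.random.default_rng(base.seed)
    return [
        _scan_distribution(base, m * base.sd_a, m * base.sd_a, base.n, f"T{m}", rng)
        for m in multipliers
    ]


def sd_ratio_scan(base: ScanBase, multiples=(2, 5, 10)) -> list[SpuriousDistribution]:
    """Hold SD(A), set SD(B) to a multiple of it (T2, T5, T10 scenarios)."""
    rng = np.random.default_rng(base.seed)
    return [
        _scan_distribution(base, base.sd_a, m * base.sd_a, base.n, f"T{m}", rng)
        for m in multiples
    ]


def sample_size_scan(base: ScanBase, sizes=(500, 1000, 2000, 10000)) -> list[SpuriousDistribution]:
    """Hold both SDs, vary the per-replicate sample size."""
    rng = np.random.default_rng(base.seed)
    return [
        _scan_distribution(base, base.sd_a, base.sd_a, n, str(n), rng) for n in sizes
    ]


def compare_groups(
    distributions: list[SpuriousDistribution], alpha: float = 0.05
) -> dict[str, str]:
    """Connected-letter grouping of scan scenarios.

    All-pairs Welch t-tests on the R² samples with Holm family-wise
    correction; scenarios not significantly different share a letter.
    """
    if len(distributions) < 2:
        raise ValueError("need at least two distributions to compare")
    reps = {d.r2_samples.size for d in distributions}
    if len(reps) != 1:
        raise ValueError("distributions must have equal replicate counts")
    labels = [d.label for d in distributions]
    pairs, pvals = [], []
    for i in range(len(distributions)):
        for j in range(i + 1, len(distributions)):
            a, b = distributions[i].r2_samples, distributions[j].r2_samples
            if np.array_equal(a, b):
                p = 1.0
            else:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            pairs.append((i, j))
            pvals.append(p)
    reject, *_ = multipletests(pvals, alpha=alpha, method="holm")
    differ = {pair for pair, r in zip(pairs, reject) if r}
    letters = _connected_letters(len(distributions), differ)
    return {lab: let for lab, let in zip(labels, letters)}


def _connected_letters(k: int, differ: set[tuple[int, int]]) -> list[str]:
    """Compact letter display: letters are maximal cliques of the
    not-significantly-different relation."""
    import networkx as nx

    same = nx.Graph()
    same.add_nodes_from(range(k))
    same.add_edges_from(
        (i, j) for i in range(k) for j in range(i + 1, k) if (i, j) not in differ
    )
    groups = sorted((sorted(c) for c in nx.find_cliques(same)), key=lambda g: g[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return [
        "".join(alphabet[gi] for gi, g in enumerate(groups) if i in g)
        for i in range(k)
    ]


def weighted_spurious(spurious_mean_r2: float, importance_share: float) -> float:
    """Spurious R² weighted by a variable's relative-importance share.

    Both arguments are fractions in [0, 1]; the product is the variable's
    contribution to the total spurious component of an explained variance.
    """
    for name, v in (("spurious_mean_r2", spurious_mean_r2),
                    ("importance_share", importance_share)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    return spurious_mean_r2 * importance_share
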