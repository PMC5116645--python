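"""Non-recursive path analysis over observed variables.

Structural model for endogenous variables y and exogenous variables x::

    y = B y + G x + zeta,   x ~ (0, Phi),   zeta ~ (0, Psi)

B may contain directed cycles (non-recursive model); a feedback loop is
admissible when the magnitude of the product of coefficients around it is
below one (stability condition).  Fitting minimises the maximum-likelihood
discrepancy between the sample covariance S and the model-implied
covariance Sigma(theta)::

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

Effects of one variable on another are decomposed into a direct effect
(the structural coefficient), an indirect effect (transmission through
intermediate variables) and their total.  Two conventions are offered:
"path-sum" sums coefficient products over simple directed paths, which is
the arithmetic used in standard effect tables; "series-limit" uses the
closed forms (I-B)^-1 G and (I-B)^-1 - I, which additionally count walks
that revisit feedback loops (the two agree exactly on acyclic models).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModelSpec",
    "PathCoefficients",
    "EffectTable",
    "FitResult",
    "implied_covariance",
    "fit_ml",
    "decompose_effects",
    "aggregate_effects",
    "stability_index",
    "fit_indices",
    "normality_diagnostics",
    "mardia_test",
]


class ModelError(ValueError):
    """Structural-model specification or identification problem."""


class DivergentLoopError(ArithmeticError):
    """A feedback loop with |product of coefficients| >= 1."""


# ---------------------------------------------------------------------------
# model specification and coefficient containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModelSpec:
    """Topology of an observed-variable structural model.

    ``variables`` fixes the observed order; ``exogenous`` lists the purely
    upstream variables (no structural equation); ``directed_edges`` are
    (source, target) pairs, targets necessarily endogenous;
    ``error_covariances`` are unordered endogenous pairs whose structural
    errors are allowed to covary.
    """

    variables: tuple[str, ...]
    exogenous: tuple[str, ...]
    directed_edges: tuple[tuple[str, str], ...]
    error_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ModelError("duplicate variable names")
        unknown = set(self.exogenous) - set(self.variables)
        if unknown:
            raise ModelError(f"exogenous variables not declared: {sorted(unknown)}")
        endo = set(self.endogenous)
        for s, t in self.directed_edges:
            if s == t:
                raise ModelError(f"self-edge on {s!r}")
            if s not in self.variables or t not in self.variables:
                raise ModelError(f"edge ({s!r}, {t!r}) uses undeclared variable")
            if t not in endo:
                raise ModelError(f"edge into exogenous variable {t!r}")
        for a, b in self.error_covariances:
            if a not in endo or b not in endo:
                raise ModelError(f"error covariance ({a!r}, {b!r}) must pair endogenous variables")

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.exogenous)

    @property
    def n_free_parameters(self) -> int:
        nx_ = len(self.exogenous)
        return (
            len(self.directed_edges)
            + nx_ * (nx_ + 1) // 2
            + len(self.endogenous)
            + len(self.error_covariances)
        )

    def graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.directed_edges)
        return g


@dataclass
class PathCoefficients:
    """Structural coefficient matrices tied to a `PathModelSpec`.

    ``B`` is endogenous x endogenous (entry [i, j] = coefficient of variable
    j in the equation of variable i), ``G`` endogenous x exogenous, ``Phi``
    the exogenous covariance, ``Psi`` the endogenous error covariance.
    """

    spec: PathModelSpec
    B: np.ndarray
    G: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    standardized: bool = True

    def __post_init__(self) -> None:
        ny, nx_ = len(self.spec.endogenous), len(self.spec.exogenous)
        self.B = np.asarray(self.B, dtype=float).reshape(ny, ny)
        self.G = np.asarray(self.G, dtype=float).reshape(ny, nx_)
        self.Phi = np.asarray(self.Phi, dtype=float).reshape(nx_, nx_)
        self.Psi = np.asarray(self.Psi, dtype=float).reshape(ny, ny)
        self._check_sparsity()

    def _check_sparsity(self) -> None:
        endo = {v: i for i, v in enumerate(self.spec.endogenous)}
        exo = {v: i for i, v in enumerate(self.spec.exogenous)}
        allowed_b = np.zeros_like(self.B, dtype=bool)
        allowed_g = np.zeros_like(self.G, dtype=bool)
        for s, t in self.spec.directed_edges:
            if s in endo:
                allowed_b[endo[t], endo[s]] = True
            else:
                allowed_g[endo[t], exo[s]] = True
        if np.any(self.B[~allowed_b] != 0):
            raise ModelError("nonzero B entry outside the specified edge set")
        if np.any(self.G[~allowed_g] != 0):
            raise ModelError("nonzero G entry outside the specified edge set")

    @classmethod
    def from_edges(
        cls,
        spec: PathModelSpec,
        edge_values: dict[tuple[str, str], float],
        Phi: np.ndarray | None = None,
        Psi: np.ndarray | None = None,
        standardized: bool = True,
    ) -> "PathCoefficients":
        """Build coefficient matrices from a (source, target) -> beta mapping."""
        endo = {v: i for i, v in enumerate(spec.endogenous)}
        exo = {v: i for i, v in enumerate(spec.exogenous)}
        B = np.zeros((len(endo), len(endo)))
        G = np.zeros((len(endo), len(exo)))
        for (s, t), val in edge_values.items():
            if (s, t) not in spec.directed_edges:
                raise ModelError(f"({s!r}, {t!r}) is not an edge of the model")
            if s in endo:
                B[endo[t], endo[s]] = val
            else:
                G[endo[t], exo[s]] = val
        if Phi is None:
            Phi = np.eye(len(exo))
        if Psi is None:
            Psi = np.eye(len(endo))
        return cls(spec=spec, B=B, G=G, Phi=Phi, Psi=Psi, standardized=standardized)

    def coefficient(self, source: str, target: str) -> float:
        endo = {v: i for i, v in enumerate(self.spec.endogenous)}
        exo = {v: i for i, v in enumerate(self.spec.exogenous)}
        if target not in endo:
            raise KeyError(f"{target!r} is not endogenous")
        if source in endo:
            return float(self.B[endo[target], endo[source]])
        if source in exo:
            return float(self.G[endo[target], exo[source]])
        raise KeyError(f"unknown variable {source!r}")


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------

def _feedback_loops(spec: PathModelSpec) -> list[list[str]]:
    endo = set(spec.endogenous)
    g = nx.DiGraph((s, t) for s, t in spec.directed_edges if s in endo and t in endo)
    return [c for c in nx.simple_cycles(g)]


def implied_covariance(coeffs: PathCoefficients, spec: PathModelSpec | None = None) -> np.ndarray:
    """Model-implied covariance over all observed variables, in spec order."""
    spec = spec or coeffs.spec
    ny = len(spec.endogenous)
    ident = np.eye(ny)
    imb = ident - coeffs.B
    if abs(np.linalg.det(imb)) < 1e-12:
        loops = _feedback_loops(spec)
        raise DivergentLoopError(
            "I - B is singular; feedback loop(s) "
            + "; ".join(" -> ".join(c + [c[0]]) for c in loops)
            + " have no stable solution"
        )
    A = np.linalg.inv(imb)
    syy = A @ (coeffs.G @ coeffs.Phi @ coeffs.G.T + coeffs.Psi) @ A.T
    syx = A @ coeffs.G @ coeffs.Phi
    order = list(spec.variables)
    endo = {v: i for i, v in enumerate(spec.endogenous)}
    exo = {v: i for i, v in enumerate(spec.exogenous)}
    p = len(order)
    sigma = np.empty((p, p))
    for i, vi in enumerate(order):
        for j, vj in enumerate(order):
            if vi in endo and vj in endo:
                sigma[i, j] = syy[endo[vi], endo[vj]]
            elif vi in endo:
                sigma[i, j] = syx[endo[vi], exo[vj]]
            elif vj in endo:
                sigma[i, j] = syx[endo[vj], exo[vi]]
            else:
                sigma[i, j] = coeffs.Phi[exo[vi], exo[vj]]
    return 0.5 * (sigma + sigma.T)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted coefficients with discrepancy, fit indices and diagnostics."""

    coefficients: PathCoefficients
    discrepancy: float
    chi2: float
    df: int
    p_value: float
    gfi: float
    agfi: float
    nfi: float
    rmsea: float
    stability: float
    r2: dict[str, float]
    converged: bool
    n: int = 0
    implied: np.ndarray | None = field(default=None, repr=False)


def _pack(spec: PathModelSpec):
    """Index maps for the free-parameter vector."""
    endo = {v: i for i, v in enumerate(spec.endogenous)}
    exo = {v: i for i, v in enumerate(spec.exogenous)}
    b_idx = [(endo[t], endo[s]) for s, t in spec.directed_edges if s in endo]
    g_idx = [(endo[t], exo[s]) for s, t in spec.directed_edges if s in exo]
    nx_ = len(exo)
    phi_idx = [(i, j) for i in range(nx_) for j in range(i + 1)]
    psi_cov_idx = [(endo[a], endo[b]) for a, b in spec.error_covariances]
    return b_idx, g_idx, phi_idx, psi_cov_idx


def _unpack(theta: np.ndarray, spec: PathModelSpec) -> PathCoefficients:
    b_idx, g_idx, phi_idx, psi_cov_idx = _pack(spec)
    ny, nx_ = len(spec.endogenous), len(spec.exogenous)
    B = np.zeros((ny, ny))
    G = np.zeros((ny, nx_))
    Phi = np.zeros((nx_, nx_))
    Psi = np.zeros((ny, ny))
    k = 0
    for i, j in b_idx:
        B[i, j] = theta[k]; k += 1
    for i, j in g_idx:
        G[i, j] = theta[k]; k += 1
    for i, j in phi_idx:
        Phi[i, j] = Phi[j, i] = theta[k]; k += 1
    for i in range(ny):
        Psi[i, i] = theta[k]; k += 1
    for i, j in psi_cov_idx:
        Psi[i, j] = Psi[j, i] = theta[k]; k += 1
    return PathCoefficients(spec=spec, B=B, G=G, Phi=Phi, Psi=Psi)


def _ml_discrepancy(sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        trace = float(np.trace(np.linalg.solve(sigma, S)))
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + trace - logdet_S - S.shape[0]


def _start_vector(spec: PathModelSpec, S: np.ndarray) -> np.ndarray:
    """Heuristic start: small coefficients, sample exogenous moments."""
    b_idx, g_idx, phi_idx, psi_cov_idx = _pack(spec)
    order = {v: i for i, v in enumerate(spec.variables)}
    exo_pos = [order[v] for v in spec.exogenous]
    endo_pos = [order[v] for v in spec.endogenous]
    theta = []
    theta.extend(0.1 for _ in b_idx)
    theta.extend(0.1 for _ in g_idx)
    Sxx = S[np.ix_(exo_pos, exo_pos)]
    nx_ = len(exo_pos)
    for i in range(nx_):
        for j in range(i + 1):
            theta.append(Sxx[i, j])
    theta.extend(0.5 * S[i, i] for i in endo_pos)
    theta.extend(0.0 for _ in psi_cov_idx)
    return np.array(theta)


def fit_ml(
    sample_cov: np.ndarray,
    n: int,
    spec: PathModelSpec,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    n_starts: int = 5,
    seed: int = 0,
    standardized: bool = True,
    max_iter: int = 2000,
) -> FitResult:
    """Fit the structural model to a sample covariance by maximum likelihood.

    When ``standardized`` the sample covariance is rescaled to a correlation
    matrix first, so fitted coefficients are standardized betas (the usual
    reporting convention for path diagrams).  Multi-start quasi-Newton
    optimisation guards against local minima in non-recursive models; a
    model that fails to converge is flagged, not silently returned.
    """
    S = np.asarray(sample_cov, dtype=float)
    p = len(spec.variables)
    if S.shape != (p, p):
        raise ModelError(f"sample covariance must be {p}x{p} for this model")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ModelError("sample covariance is not symmetric")
    if np.any(np.linalg.eigvalsh(S) <= 0):
        raise ModelError("sample covariance is not positive definite")
    if standardized:
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    nfree = spec.n_free_parameters
    df = p * (p + 1) // 2 - nfree
    if df < 0:
        raise ModelError(
            f"model is not identified: {nfree} free parameters exceed "
            f"{p * (p + 1) // 2} sample moments"
        )
    if n <= nfree:
        raise ModelError(f"sample size {n} must exceed the {nfree} free parameters")

    sign, logdet_S = np.linalg.slogdet(S)

    def objective(theta: np.ndarray) -> float:
        try:
            coeffs = _unpack(theta, spec)
            if np.any(np.diag(coeffs.Psi) <= 0):
                return np.inf
            sigma = implied_covariance(coeffs, spec)
        except (DivergentLoopError, np.linalg.LinAlgError):
            return np.inf
        return _ml_discrepancy(sigma, S, logdet_S)

    rng = np.random.default_rng(seed)
    base = _start_vector(spec, S) if start is None else np.asarray(start, dtype=float)
    best, best_f = None, np.inf
    converged = False
    for attempt in range(max(1, n_starts)):
        x0 = base if attempt == 0 else base + rng.normal(0, 0.1, size=base.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", tol=tol,
                options={"maxiter": max_iter, "maxfun": 5 * max_iter},
            )
        if res.fun < best_f - 1e-12:
            best, best_f = res, res.fun
            converged = bool(res.success) and np.isfinite(res.fun)
        elif res.success and abs(res.fun - best_f) <= 1e-9:
            converged = True
    if best is None or not np.isfinite(best_f):
        raise ModelError("optimizer failed to produce a finite discrepancy")

    coeffs = _unpack(best.x, spec)
    coeffs.standardized = standardized
    sigma = implied_covariance(coeffs, spec)
    f_ml = max(best_f, 0.0)
    chi2 = (n - 1) * f_ml

    baseline_chi2 = _baseline_chi2(S, n)
    gfi, agfi, nfi, rmsea, p_value = fit_indices(chi2, df, n, S, sigma, baseline_chi2)

    endo = spec.endogenous
    endo_pos = {v: i for i, v in enumerate(endo)}
    order = {v: i for i, v in enumerate(spec.variables)}
    r2 = {}
    for v in endo:
        var_y = sigma[order[v], order[v]]
        psi = coeffs.Psi[endo_pos[v], endo_pos[v]]
        r2[v] = float(min(max(1.0 - psi / var_y, 0.0), 1.0))

    return FitResult(
        coefficients=coeffs,
        discrepancy=f_ml,
        chi2=chi2,
        df=df,
        p_value=p_value,
        gfi=gfi,
        agfi=agfi,
        nfi=nfi,
        rmsea=rmsea,
        stability=stability_index(coeffs.B),
        r2=r2,
        converged=converged,
        n=n,
        implied=sigma,
    )


def _baseline_chi2(S: np.ndarray, n: int) -> float:
    """Independence-model chi-square (diagonal Sigma), used for NFI."""
    sigma0 = np.diag(np.diag(S))
    sign, logdet_S = np.linalg.slogdet(S)
    return (n - 1) * _ml_discrepancy(sigma0, S, logdet_S)


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """Direct/indirect/total standardized effects per (source, target) pair."""

    effects: dict[tuple[str, str], dict[str, float]]
    mode: str = "path-sum"

    def effect(self, source: str, target: str, component: str = "total") -> float:
        if component not in ("direct", "indirect", "total"):
            raise KeyError(f"unknown component {component!r}")
        entry = self.effects.get((source, target))
        if entry is None:
            return 0.0
        return entry[component]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": s, "target": t, **vals}
            for (s, t), vals in sorted(self.effects.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "direct", "indirect", "total"])

    @classmethod
    def from_components(
        cls, entries: dict[tuple[str, str], tuple[float, float]], mode: str = "reported"
    ) -> "EffectTable":
        """Build from (direct, indirect) pairs, e.g. a published effect table."""
        effects = {
            key: {"direct": d, "indirect": i, "total": d + i}
            for key, (d, i) in entries.items()
        }
        return cls(effects=effects, mode=mode)


def decompose_effects(
    coeffs: PathCoefficients,
    mode: str = "path-sum",
    max_path_len: int | None = None,
    mediators: set[str] | None = None,
) -> EffectTable:
    """Decompose every source -> target influence into direct/indirect/total.

    "path-sum" totals coefficient products over simple directed paths
    (each intermediate variable visited once); "series-limit" uses the
    matrix closed forms, which also count walks around feedback loops and
    therefore require spectral radius of B below one.  The two agree on
    acyclic models.

    ``mediators`` (path-sum only) restricts indirect transmission to paths
    whose intermediate variables all lie in the given set — the
    "indirect effect via X and Y" reading of an effect table.
    """
    spec = coeffs.spec
    endo = list(spec.endogenous)
    exo = list(spec.exogenous)
    effects: dict[tuple[str, str], dict[str, float]] = {}

    if mode == "series-limit":
        if mediators is not None:
            raise ValueError("mediator restriction is only defined for path-sum mode")
        rho = max(abs(np.linalg.eigvals(coeffs.B))) if len(endo) else 0.0
        if rho >= 1:
            raise DivergentLoopError(
                f"spectral radius of B is {rho:.4f} >= 1; series-limit totals diverge"
            )
        A = np.linalg.inv(np.eye(len(endo)) - coeffs.B)
        total_endo = A - np.eye(len(endo))
        total_exo = A @ coeffs.G
        for j, s in enumerate(endo):
            for i, t in enumerate(endo):
                if i == j:
                    continue
                _store(effects, s, t, coeffs.B[i, j], total_endo[i, j])
        for j, s in enumerate(exo):
            for i, t in enumerate(endo):
                _store(effects, s, t, coeffs.G[i, j], total_exo[i, j])
    elif mode == "path-sum":
        g = nx.DiGraph()
        g.add_nodes_from(spec.variables)
        for s, t in spec.directed_edges:
            g.add_edge(s, t, weight=coeffs.coefficient(s, t))
        cutoff = max_path_len if max_path_len is not None else len(spec.variables)
        for s in spec.variables:
            for t in endo:
                if s == t:
                    continue
                total = 0.0
                for path in nx.all_simple_paths(g, s, t, cutoff=cutoff):
                    if mediators is not None and any(
                        v not in mediators for v in path[1:-1]
                    ):
                        continue
                    w = 1.0
                    for a, b in zip(path, path[1:]):
                        w *= g[a][b]["weight"]
                    total += w
                direct = coeffs.coefficient(s, t) if (s, t) in spec.directed_edges else 0.0
                if total != 0.0 or direct != 0.0:
                    _store(effects, s, t, direct, total)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'path-sum' or 'series-limit'")
    return EffectTable(effects=effects, mode=mode)


def _store(effects, source, target, direct, total) -> None:
    effects[(source, target)] = {
        "direct": float(direct),
        "indirect": float(total - direct),
        "total": float(total),
    }


def aggregate_effects(
    table: EffectTable,
    sources,
    target: str,
    components: tuple[str, ...] = ("direct", "indirect"),
) -> float:
    """Sum the requested effect components of a source group on one target.

    ``components`` selects which parts enter the sum; the default
    (direct + indirect) yields the group's total effect.  ``sources`` may
    be a collection of names, or a mapping name -> component(s) when
    different sources contribute different components.
    """
    known = {s for (s, t) in table.effects} | {t for (s, t) in table.effects}
    if isinstance(sources, dict):
        items = [(s, (c,) if isinstance(c, str) else tuple(c)) for s, c in sources.items()]
    else:
        items = [(s, components) for s in sources]
    total = 0.0
    for s, comps in items:
        if s not in known and len(items) > 0:
            raise KeyError(f"unknown variable {s!r} in effect table")
        for c in comps:
            total += table.effect(s, target, c)
    if items and target not in known:
        raise KeyError(f"unknown target {target!r} in effect table")
    return total


# ---------------------------------------------------------------------------
# stability and fit indices
# ---------------------------------------------------------------------------

def stability_index(B: np.ndarray, method: str = "loop-product") -> float:
    """Stability of the feedback structure of an endogenous coefficient matrix.

    "loop-product" (default) enumerates directed cycles in the sparsity
    pattern of B and returns the maximum magnitude of the product of
    coefficients around any cycle (0 for acyclic B); the model is stable
    when the index is below one.  "eigenvalue" returns the spectral radius
    of B instead.
    """
    B = np.asarray(B, dtype=float)
    if method == "eigenvalue":
        return float(max(abs(np.linalg.eigvals(B)))) if B.size else 0.0
    if method != "loop-product":
        raise ValueError(f"unknown method {method!r}")
    ny = B.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(ny))
    for i in range(ny):
        for j in range(ny):
            if B[i, j] != 0:
                g.add_edge(j, i)  # j influences i
    best = 0.0
    for cycle in nx.simple_cycles(g):
        prod = 1.0
        for a, b in zip(cycle, cycle[1:] + [cycle[0]]):
            prod *= B[b, a]
        best = max(best, abs(prod))
    return best


_NA = float("nan")


def fit_indices(
    chi2: float,
    df: int,
    n: int,
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    baseline_chi2: float | None = None,
):
    """GFI, AGFI, NFI, RMSEA and the chi-square p-value.

    With df = 0 (saturated model) RMSEA and AGFI are undefined and returned
    as NaN markers.
    """
    if df < 0:
        raise ModelError("negative degrees of freedom")
    if n <= 1:
        raise ModelError("fit indices require n > 1")
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(implied_cov, dtype=float)
    p = S.shape[0]
    W = np.linalg.solve(sigma, S)
    resid = W - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(W @ W)
    if df > 0:
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
        rmsea = math.sqrt(max((chi2 - df) / (df * (n - 1)), 0.0))
        p_value = float(stats.chi2.sf(chi2, df))
    else:
        agfi, rmsea = _NA, _NA
        p_value = 1.0 if chi2 <= 1e-12 else 0.0
    nfi = 1.0 - chi2 / baseline_chi2 if baseline_chi2 else _NA
    return float(gfi), float(agfi), float(nfi), float(rmsea), p_value


# ---------------------------------------------------------------------------
# normality diagnostics
# ---------------------------------------------------------------------------

def normality_diagnostics(data: pd.DataFrame) -> dict:
    """Univariate skewness/kurtosis and Mardia's multivariate statistics.

    Kurtosis is reported on the raw b2 scale (normal reference 3).  Raises
    on constant columns, whose moments are undefined.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        cols = list(data.columns) if hasattr(data, "columns") else list(range(p))
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant column(s) {bad}: moments undefined")
    cols = list(data.columns) if hasattr(data, "columns") else [str(i) for i in range(p)]
    uni = {
        c: {
            "skewness": float(stats.skew(X[:, i], bias=True)),
            "kurtosis": float(stats.kurtosis(X[:, i], fisher=False, bias=True)),
        }
        for i, c in enumerate(cols)
    }
    return {"univariate": uni, "mardia": mardia_test(X)}


def mardia_test(X: np.ndarray) -> dict:
    """Mardia's multivariate skewness b1,p and kurtosis b2,p with p-values.

    Skewness statistic n*b1p/6 refers to chi-square with p(p+1)(p+2)/6 df;
    kurtosis is referred to its asymptotic normal, mean p(p+2) and variance
    8p(p+2)/n.  The covariance uses the ML (1/n) scaling, the convention of
    the original statistics.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    # whiten so pairwise Mahalanobis products become plain dot products;
    # b1p then reduces to the squared norm of the third-moment tensor,
    # avoiding the n x n pairwise matrix
    L = np.linalg.cholesky(S)
    Y = np.linalg.solve(L, Xc.T).T
    M = np.einsum("ia,ib,ic->abc", Y, Y, Y) / n
    b1p = float(np.sum(M**2))
    d = np.einsum("ij,ij->i", Y, Y)
    b2p = float(np.mean(d**2))
    skew_stat = n * b1p / 6.0
    skew_df = p * (p + 1) * (p + 2) // 6
    skew_p = float(stats.chi2.sf(skew_stat, skew_df))
    kurt_z = (b2p - p * (p + 2)) / math.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2 * stats.norm.sf(abs(kurt_z)))
    return {
        "b1p": b1p,
        "skew_statistic": skew_stat,
        "skew_df": skew_df,
        "skew_p": skew_p,
        "b2p": b2p,
        "kurtosis_z": float(kurt_z),
        "kurtosis_p": kurt_p,
    }
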