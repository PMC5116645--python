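"""File formats, run configuration and the end-to-end pipeline.

Tables are plain CSV with a leading ``#``-comment header recording the
seed and config hash of the run that wrote them.  The run configuration is
a YAML mapping; the path-model topology can also be given as a small
structured text file (``variables:``/``exogenous:`` lines, ``edges:`` as
``source -> target``, ``covary:`` as ``a ~~ b``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core
from .core import DEFAULT_CALORIC_VALUE, caloric_convert, efficiency_table
from .path import PathModelSpec, aggregate_effects, decompose_effects, fit_ml
from .reference import (
    MC_VARIABLE_SPECS,
    REPORTED_SPURIOUS_R2,
    reference_model_spec,
)
from .relimp import lmg
from .spurious import MonteCarloConfig, VariableSpec, spurious_r2
from .synth import ExperimentDesign, GeneratorParams, generate_experiment

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "plot_id", "treatment", "year", "anpp", "par", "apar", "ms", "tr", "ns", "n_uptake",
)
_NUMERIC = RECORD_COLUMNS[1:]
_SIG_DIGITS = 12


class SchemaError(ValueError):
    """Input table does not match the expected record schema."""


@dataclass
class RunConfig:
    """Configuration of one reproducible run."""

    seed: int = 0
    input: str | None = None
    output_dir: str = "mrue_out"
    light_units: str = "g"  # "g" (mass-equivalent) or "MJ"
    caloric_value: float = DEFAULT_CALORIC_VALUE
    strict: bool = True
    mc: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    model_spec_path: str | None = None
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not self.caloric_value > 0:
            raise ValueError("caloric value must be positive")
        if self.light_units not in ("g", "MJ"):
            raise ValueError(f"light_units must be 'g' or 'MJ', got {self.light_units!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and logging
        verbosity excluded, so reruns into different directories match)."""
        payload = {
            k: v for k, v in self.__dict__.items()
            if k not in ("output_dir", "verbosity")
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def mc_config(self) -> MonteCarloConfig:
        variables = self.mc.get("variables") or {
            name: list(ms) for name, ms in MC_VARIABLE_SPECS.items()
        }
        specs = tuple(
            VariableSpec(name, float(m), float(s)) for name, (m, s) in variables.items()
        )
        return MonteCarloConfig(
            variable_specs=specs,
            n=int(self.mc.get("n", 126)),
            reps=int(self.mc.get("reps", 1000)),
            seed=int(self.mc.get("seed", self.seed)),
        )

    def experiment_design(self) -> ExperimentDesign:
        g = self.generator
        return ExperimentDesign(
            deltas=tuple(g.get("deltas", core.TREATMENT_LEVELS)),
            reps=int(g.get("reps", 6)),
            years=int(g.get("years", 3)),
            base_precip=float(g.get("base_precip", 380.0)),
            seed=int(g.get("seed", self.seed)),
        )


# ---------------------------------------------------------------------------
# record tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str = "-") -> None:
    """CSV with a comment header carrying seed and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format=f"%.{_SIG_DIGITS}g")


def read_records(path: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Read and validate a plot-year record table.

    Applies the caloric light conversion when the config declares MJ
    inputs; in strict mode any invariant violation is an error naming the
    row, otherwise offending rows are dropped with a warning.
    """
    config = config or RunConfig()
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    df = df[list(RECORD_COLUMNS) + [c for c in df.columns if c not in RECORD_COLUMNS]]
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
        df[col] = coerced
    if config.light_units == "MJ":
        df["par"] = [caloric_convert(v, config.caloric_value) for v in df["par"]]
        df["apar"] = [caloric_convert(v, config.caloric_value) for v in df["apar"]]
    return _validate_records(df, strict=config.strict, source=str(path))


def _validate_records(df: pd.DataFrame, strict: bool, source: str = "table") -> pd.DataFrame:
    quantity_cols = ["anpp", "par", "apar", "ms", "tr", "ns", "n_uptake"]
    bad = ~np.isfinite(df[quantity_cols]).all(axis=1) | (df[quantity_cols] <= 0).any(axis=1)
    for absorbed, available in (("apar", "par"), ("tr", "ms"), ("n_uptake", "ns")):
        bad |= df[absorbed] > df[available]
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]
        msg = (
            f"{source}: {int(bad.sum())} row(s) violate record invariants "
            f"(positivity / absorbed <= available) at line(s) {rows[:10]}"
        )
        if strict:
            raise SchemaError(msg)
        logger.warning("%s; dropped", msg)
        df = df[~bad].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# model-spec text format
# ---------------------------------------------------------------------------

def parse_model_spec(text: str) -> PathModelSpec:
    """Parse the structured-text path-model format.

    Example::

        variables: Ms Tr aPAR N_uptake eps mRUE
        exogenous: Ms Tr
        edges:
          Ms -> aPAR
          Tr -> N_uptake
        covary:
          aPAR ~~ N_uptake
    """
    variables: list[str] = []
    exogenous: list[str] = []
    edges: list[tuple[str, str]] = []
    covary: list[tuple[str, str]] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lower = line.lower()
        if lower.startswith("variables:"):
            variables += line.split(":", 1)[1].replace(",", " ").split()
            section = None
        elif lower.startswith("exogenous:"):
            exogenous += line.split(":", 1)[1].replace(",", " ").split()
            section = None
        elif lower.startswith("edges:"):
            section = "edges"
        elif lower.startswith("covary:"):
            section = "covary"
        elif "->" in line and section in (None, "edges"):
            s, t = (x.strip() for x in line.split("->", 1))
            edges.append((s, t))
        elif "~~" in line and section in (None, "covary"):
            a, b = (x.strip() for x in line.split("~~", 1))
            covary.append((a, b))
        else:
            raise SchemaError(f"model spec line {lineno}: cannot parse {raw!r}")
    return PathModelSpec(
        variables=tuple(variables),
        exogenous=tuple(exogenous),
        directed_edges=tuple(edges),
        error_covariances=tuple(covary),
    )


def load_model_spec(path: str | Path) -> PathModelSpec:
    return parse_model_spec(Path(path).read_text())


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _log_model_frame(eff: pd.DataFrame) -> pd.DataFrame:
    """Log-transformed analysis variables in the reporting order."""
    return pd.DataFrame(
        {
            "Ms": np.log(eff["ms"]),
            "Tr": np.log(eff["tr"]),
            "aPAR": np.log(eff["apar"]),
            "N_uptake": np.log(eff["n_uptake"]),
            "eps": np.log(eff["eps"]),
            "mRUE": np.log(eff["mrue"]),
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain on one configuration.

    Stages: obtain records (read, or generate when no input is given) ->
    efficiency table -> path-model fit on the log variables -> effect
    decomposition -> LMG relative importance of the single-resource
    efficiencies for the composite -> spurious-correlation Monte Carlo for
    the reported pairs.  Every artifact lands in ``config.output_dir`` with
    the seed and config hash in its header; a flat key-value ``summary.txt``
    aggregates the headline numbers.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict[str, object] = {"seed": config.seed, "config_hash": chash}
    timings: dict[str, float] = {}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        if config.input:
            stage = "read"
            records = read_records(config.input, config)
        else:
            records = generate_experiment(
                config.experiment_design(),
                GeneratorParams(),
                rng=np.random.default_rng(config.seed),
            )
        timings[stage] = time.perf_counter() - t0

        stage = "efficiencies"
        t0 = time.perf_counter()
        eff = efficiency_table(records)
        write_table(eff, out / "efficiencies.csv", config.seed, chash)
        timings[stage] = time.perf_counter() - t0

        stage = "fit-path"
        t0 = time.perf_counter()
        spec = (
            load_model_spec(config.model_spec_path)
            if config.model_spec_path
            else reference_model_spec()
        )
        frame = _log_model_frame(eff)[list(spec.variables)]
        S = np.cov(frame.to_numpy(), rowvar=False)
        fit = fit_ml(S, n=len(frame), spec=spec, seed=config.seed)
        fit_rows = [
            {"source": s, "target": t, "beta": fit.coefficients.coefficient(s, t)}
            for s, t in spec.directed_edges
        ]
        fit_df = pd.DataFrame(fit_rows)
        write_table(fit_df, out / "path_fit.csv", config.seed, chash)
        summary.update(
            chi2=round(fit.chi2, 4), df=fit.df, p_value=round(fit.p_value, 4),
            gfi=round(fit.gfi, 4), rmsea=round(fit.rmsea, 4),
            stability_index=round(fit.stability, 4), converged=fit.converged,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "decompose"
        t0 = time.perf_counter()
        table = decompose_effects(fit.coefficients, mode="path-sum")
        write_table(table.to_frame(), out / "effects.csv", config.seed, chash)
        summary["water_total_on_eps"] = round(
            aggregate_effects(table, ("Ms", "Tr"), "eps"), 4
        )
        summary["water_total_on_mrue"] = round(
            aggregate_effects(table, ("Ms", "Tr"), "mRUE"), 4
        )
        timings[stage] = time.perf_counter() - t0

        stage = "relimp"
        t0 = time.perf_counter()
        predictors = pd.DataFrame(
            {
                "WUE": np.log(eff["wue"]),
                "LUE": np.log(eff["lue"]),
                "NUE": np.log(eff["nue"]),
            }
        )
        rel = lmg(predictors, np.log(eff["mrue"]))
        write_table(rel.to_frame(), out / "relimp.csv", config.seed, chash)
        summary["relimp_total_r2"] = round(rel.total_r2, 6)
        timings[stage] = time.perf_counter() - t0

        stage = "spurious"
        t0 = time.perf_counter()
        mc = config.mc_config()
        rows = []
        for common, which in REPORTED_SPURIOUS_R2:
            dist = spurious_r2(mc, common, which)
            rows.append(dist.summary_row())
            summary[f"spurious_{common}_{which}"] = round(dist.mean_r2, 4)
        write_table(pd.DataFrame(rows), out / "spurious.csv", config.seed, chash)
        timings[stage] = time.perf_counter() - t0
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    for k, v in timings.items():
        summary[f"time_{k}_s"] = round(v, 3)
    with open(out / "summary.txt", "w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}={v}\n")
    logger.info("pipeline complete: %s", out)
    return summary
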