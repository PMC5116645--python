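"""Published reference values for the grassland water-gradient study.

These are the reported standardized path coefficients, decomposed effects
and Monte Carlo variable settings from the semi-arid grassland experiment
that motivated the model (Duolun, Inner Mongolia; randomized-block design,
7 precipitation levels x 6 replicates, 2010-2012).  They serve as inputs
for effect arithmetic, as defaults for the spurious-correlation Monte
Carlo, and as calibration targets for the synthetic generator.
"""

from __future__ import annotations

from .path import EffectTable, PathCoefficients, PathModelSpec

__all__ = [
    "VARIABLES",
    "reference_model_spec",
    "reference_path_coefficients",
    "reference_effect_table",
    "MC_VARIABLE_SPECS",
    "LOOP_EPS_TO_MRUE",
    "LOOP_MRUE_TO_EPS",
    "REPORTED_SPURIOUS_R2",
    "CONTROL_TARGETS",
]

#: Observed variables of the structural model, in reporting order.
VARIABLES = ("Ms", "Tr", "aPAR", "N_uptake", "eps", "mRUE")

#: Reported standardized direct path coefficients (source, target) -> beta.
#: The eps -> mRUE path (0.23) was reported with P = 0.387; the reciprocal
#: mRUE -> eps path (-0.11) with P = 0.014.
_DIRECT_PATHS = {
    ("Ms", "aPAR"): 0.58,
    ("N_uptake", "aPAR"): 0.35,
    ("Tr", "N_uptake"): 0.32,
    ("Ms", "eps"): -0.15,
    ("Tr", "eps"): 0.43,
    ("aPAR", "eps"): 0.30,
    ("N_uptake", "eps"): 0.67,
    ("mRUE", "eps"): -0.11,
    ("Ms", "mRUE"): -0.49,
    ("N_uptake", "mRUE"): 0.66,
    ("eps", "mRUE"): 0.23,
}

#: Edges that were reported as statistically insignificant (dashed in the
#: published diagram); effect decomposition conventionally drops them.
_NS_EDGES = frozenset({("eps", "mRUE")})

#: Reciprocal feedback-loop coefficients between the composite absorption
#: rate and the composite use efficiency.
LOOP_EPS_TO_MRUE = 0.23
LOOP_MRUE_TO_EPS = -0.11

#: Reported decomposed effects, (source, target) -> (direct, indirect).
#: Blank cells of the published table are zeros.
_REPORTED_EFFECTS = {
    ("Ms", "aPAR"): (0.58, 0.0),
    ("Tr", "aPAR"): (0.0, 0.11),
    ("N_uptake", "aPAR"): (0.35, 0.0),
    ("Tr", "N_uptake"): (0.32, 0.0),
    ("Ms", "eps"): (-0.15, 0.20),
    ("Tr", "eps"): (0.43, 0.25),
    ("aPAR", "eps"): (0.30, 0.0),
    ("N_uptake", "eps"): (0.67, 0.03),
    ("mRUE", "eps"): (-0.11, 0.0),
    ("Ms", "mRUE"): (-0.49, 0.0),
    ("Tr", "mRUE"): (0.0, 0.21),
    ("N_uptake", "mRUE"): (0.66, 0.0),
    ("eps", "mRUE"): (0.23, 0.0),
}

#: Monte Carlo variable settings (measurement-scale mean, sd) of the
#: experiment, used to quantify spurious correlation among the composites.
MC_VARIABLE_SPECS = {
    "aPAR": (10.0, 0.3),
    "PAR": (11.0, 0.04),
    "Tr": (13.0, 0.3),
    "Ms": (15.0, 0.2),
    "N_uptake": (1.2, 0.05),
    "N_avail": (3.7, 0.17),
    "ANPP": (5.3, 0.4),
}

#: Reported mean spurious determination coefficients (common variable,
#: composite) -> R^2, at n = 126 and 1000 replicates.
REPORTED_SPURIOUS_R2 = {
    ("aPAR", "eps"): 0.16,
    ("N_uptake", "eps"): 0.32,
    ("Tr", "eps"): 0.10,
    ("Ms", "eps"): 0.04,
    ("N_uptake", "mrue"): 0.038,
}

#: Control-plot efficiency summary of the study (means): WUE and LUE as
#: fractions, NUE dimensionless, ANPP in g m^-2 yr^-1.
CONTROL_TARGETS = {"wue": 0.0005, "lue": 0.012, "nue": 62.47, "anpp": 221.04}


def reference_model_spec(include_ns: bool = True) -> PathModelSpec:
    """Topology of the reported non-recursive model.

    Ms and Tr (the water-driven quantities) are exogenous; absorbed light,
    nitrogen uptake and the two composites are endogenous.  With
    ``include_ns=False`` the insignificant eps -> mRUE path is dropped,
    which also removes the feedback loop.
    """
    edges = tuple(e for e in _DIRECT_PATHS if include_ns or e not in _NS_EDGES)
    return PathModelSpec(
        variables=VARIABLES,
        exogenous=("Ms", "Tr"),
        directed_edges=edges,
    )


def reference_path_coefficients(include_ns: bool = True) -> PathCoefficients:
    """Reported standardized coefficients assembled into matrices."""
    spec = reference_model_spec(include_ns=include_ns)
    values = {e: v for e, v in _DIRECT_PATHS.items() if e in spec.directed_edges}
    return PathCoefficients.from_edges(spec, values)


def reference_effect_table() -> EffectTable:
    """The reported direct/indirect effect decomposition as an EffectTable."""
    return EffectTable.from_components(_REPORTED_EFFECTS, mode="reported")
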