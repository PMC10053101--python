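"""Seeded generators for every dataset shape the analysis stages consume.

No raw assay data accompany the study design this package implements, so the
generators emulate the statistical structure of the assays: Michaelis–Menten
velocity curves on the two substrate-gradient designs (10 levels over
0–800 µM; 16 levels over 0–6000 µM), the six-dose deglycosylation
dose-response, thermal series over 22–80 °C, and two-isoform activity
mixtures with differential inhibitor sensitivity.  Noise is additive Gaussian
on the response scale, replicate by replicate; identical spec + seed gives a
bit-identical dataset.

Named presets embed the published parameter estimates for each experimental
condition; preset noise levels are calibrated so that fitted parameter SEs on
simulated data are of the same order as the published SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
import pandas as pd

from .core_io import DoseResponseTable, KineticDataset, SchemaError, ThermalSeries
from .kinetic_models import (
    exponential_response,
    michaelis_menten,
    quadratic_response,
    sigmoid_dose_response,
)

MODELS = (
    "michaelis_menten",
    "sigmoid_4pl",
    "exponential",
    "quadratic",
    "thermal_inhibition",
    "isozyme_mixture",
)

#: the two substrate-gradient designs used for kinetics
GRID_10 = tuple(np.linspace(0.0, 800.0, 10))      # µM
GRID_16 = tuple(np.linspace(0.0, 6000.0, 16))     # µM
#: the six enzyme doses of the deglycosylation dose-response, U/mg protein
DOSES_6 = (0.0, 1430.0, 4289.0, 7150.0, 8579.0, 12868.0)
#: thermal treatments, °C: six levels from room temperature to 80 °C
TEMPS_6 = tuple(np.linspace(22.0, 80.0, 6))


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one synthetic dataset."""

    model: str
    parameters: dict
    grid: tuple = ()
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise SchemaError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SchemaError("replicates must be >= 1")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        object.__setattr__(self, "parameters", dict(self.parameters))


def _rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


# ---------------------------------------------------------------------------
# presets: published parameter estimates per experimental condition
# ---------------------------------------------------------------------------

PRESETS = MappingProxyType({
    # FPLC-purified jejunal IAP fractions (10-level design, 3 replicates)
    "table2-fraction1": SimulationSpec(
        "michaelis_menten", {"Km": 22.28, "Vmax": 89.26},
        grid=GRID_10, noise_sd=5.0, replicates=3),
    "table2-fraction2": SimulationSpec(
        "michaelis_menten", {"Km": 53.12, "Vmax": 56.75},
        grid=GRID_10, noise_sd=3.0, replicates=3),
    "table2-fraction3": SimulationSpec(
        "michaelis_menten", {"Km": 327.0, "Vmax": 349.1},
        grid=GRID_10, noise_sd=12.0, replicates=3),
    "table2-fraction4": SimulationSpec(
        "michaelis_menten", {"Km": 233.7, "Vmax": 131.2},
        grid=GRID_10, noise_sd=4.5, replicates=3),
    # recombinant-isoform lysates (16-level design, 4 replicates)
    "table4-total": SimulationSpec(
        "michaelis_menten", {"Km": 3064.0, "Vmax": 1.64},
        grid=GRID_16, noise_sd=0.07, replicates=4),
    "table4-intrinsic": SimulationSpec(
        "michaelis_menten", {"Km": 4068.0, "Vmax": 0.89},
        grid=GRID_16, noise_sd=0.04, replicates=4),
    "table4-partitioned": SimulationSpec(
        "michaelis_menten", {"Km": 2102.0, "Vmax": 0.75},
        grid=GRID_16, noise_sd=0.075, replicates=4),
    # deglycosylation dose-response (six doses, 4 replicates)
    "fig5": SimulationSpec(
        "sigmoid_4pl",
        {"Bo": 1.98, "To": 4.95, "ED50": 4605.0, "hill_slope": -0.002},
        grid=DOSES_6, noise_sd=0.25, replicates=4),
    # thermal responses of the host-lysate and isoform-specific activities
    "fig8-quad": SimulationSpec(
        "quadratic", {"c0": 2.209, "c1": -0.064, "c2": 0.0007},
        grid=TEMPS_6, noise_sd=0.25, replicates=4),
    "fig8-exp": SimulationSpec(
        "exponential", {"J0": 0.5859, "b": 0.0114},
        grid=TEMPS_6, noise_sd=0.25, replicates=4),
    "fig9-quad": SimulationSpec(
        "quadratic", {"c0": 0.3034, "c1": 0.0792, "c2": -0.0011},
        grid=TEMPS_6, noise_sd=0.45, replicates=4),
    "fig9-exp": SimulationSpec(
        "exponential", {"J0": 3.014, "b": -0.0218},
        grid=TEMPS_6, noise_sd=0.45, replicates=4),
    # saturating thermal-inhibition forward model at the isoform-specific
    # parameter set (control mean 1.36, maximal inhibition 1.20, TC50 31.1)
    "table5-iapx1": SimulationSpec(
        "thermal_inhibition",
        {"I_C": 1.36, "I_MAX": 1.20, "TC50": 31.1, "T_ref": 22.0},
        grid=TEMPS_6, noise_sd=0.08, replicates=4),
})


#: segment-like two-isoform mixture scenarios for the inhibition experiments.
#: Baseline activities and replicate noise follow the published group means
#: and pooled SEMs (per-replicate sd = SEM·√6, n = 6 pigs); the inhibition
#: fractions reproduce the printed percent-inhibition ranges per segment.
#: ``label`` is the dominance class the noise-free means imply.
SEGMENT_MIXTURES = MappingProxyType({
    "jejunum": {
        "params": {"total": 30.64, "f_iap": 0.90,
                   "phi_phe": {10.0: 0.86, 100.0: 0.97},
                   "phi_harg": {10.0: 0.05, 100.0: 0.35}},
        "noise_sd": 3.31 * 6 ** 0.5, "label": "IAP-dominant"},
    "ileum": {
        "params": {"total": 23.25, "f_iap": 0.85,
                   "phi_phe": {10.0: 0.90, 100.0: 0.99},
                   "phi_harg": {10.0: 0.05, 100.0: 0.38}},
        "noise_sd": 1.50 * 6 ** 0.5, "label": "IAP-dominant"},
    "colon-mirror": {
        "params": {"total": 11.63, "f_iap": 0.15,
                   "phi_phe": {10.0: 0.05, 100.0: 0.38},
                   "phi_harg": {10.0: 0.90, 100.0: 0.99}},
        "noise_sd": 1.47 * 6 ** 0.5, "label": "TNAP-dominant"},
    "cecum": {
        "params": {"total": 5.76, "f_iap": 0.50,
                   "phi_phe": {10.0: 0.30, 100.0: 0.55},
                   "phi_harg": {10.0: 0.30, 100.0: 0.55}},
        "noise_sd": 0.71 * 6 ** 0.5, "label": "mixed"},
})


def segment_mixture_spec(segment: str, seed: int = 0) -> SimulationSpec:
    """SimulationSpec for one of the segment-like mixture scenarios."""
    if segment not in SEGMENT_MIXTURES:
        raise SchemaError(
            f"unknown segment {segment!r}; one of {sorted(SEGMENT_MIXTURES)}")
    sc = SEGMENT_MIXTURES[segment]
    return SimulationSpec("isozyme_mixture", sc["params"],
                          noise_sd=sc["noise_sd"], replicates=6, seed=seed)


def preset(name: str, seed: int | None = None, noise_sd: float | None = None,
           replicates: int | None = None) -> SimulationSpec:
    """Look up a preset, optionally overriding seed/noise/replicates."""
    if name not in PRESETS:
        raise SchemaError(f"unknown preset {name!r}; one of {sorted(PRESETS)}")
    spec = PRESETS[name]
    kw = {}
    if seed is not None:
        kw["seed"] = seed
    if noise_sd is not None:
        kw["noise_sd"] = noise_sd
    if replicates is not None:
        kw["replicates"] = replicates
    if not kw:
        return spec
    from dataclasses import replace
    return replace(spec, **kw)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_kinetic(spec: SimulationSpec) -> KineticDataset:
    """Michaelis–Menten velocities with Gaussian replicate noise."""
    if spec.model != "michaelis_menten":
        raise SchemaError(f"gen_kinetic needs model 'michaelis_menten', got {spec.model!r}")
    km, vmax = spec.parameters["Km"], spec.parameters["Vmax"]
    if km <= 0 or vmax <= 0:
        raise SchemaError("Km and Vmax must be > 0")
    if not spec.grid:
        raise SchemaError("empty substrate grid")
    rng = _rng(spec)
    s = np.repeat(np.asarray(spec.grid), spec.replicates)
    v = michaelis_menten(s, km, vmax)
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=s.shape)
    reps = np.tile(np.arange(1, spec.replicates + 1), len(spec.grid))
    return KineticDataset.from_arrays(s, v, unit="uM", specimen_id="synthetic",
                                      condition=f"seed={spec.seed}", replicate=reps)


def gen_dose_response(spec: SimulationSpec) -> DoseResponseTable:
    """Four-parameter-logistic responses at the standard six doses."""
    if spec.model != "sigmoid_4pl":
        raise SchemaError(f"gen_dose_response needs model 'sigmoid_4pl', got {spec.model!r}")
    p = spec.parameters
    if not spec.grid:
        raise SchemaError("empty dose grid")
    rng = _rng(spec)
    x = np.repeat(np.asarray(spec.grid), spec.replicates)
    y = sigmoid_dose_response(x, p["Bo"], p["To"], p["ED50"], p["hill_slope"])
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=x.shape)
    return DoseResponseTable(tuple(x), tuple(y))


def thermal_inhibition_response(temps, I_C, I_MAX, TC50, T_ref=22.0):
    """Saturating thermal-inhibition forward model.

    J = I_C − I_MAX·I′/(TC50 + I′) with I′ = max(I − T_ref, 0): activity falls
    from the control level I_C toward the plateau I_C − I_MAX as the treatment
    temperature rises above the reference, with half of the maximal inhibition
    reached TC50 degrees above it.  This forward model is a package
    construction consistent with the Eadie–Hofstee estimator's semantics; it
    is not itself part of the published analysis.
    """
    t = np.asarray(temps, dtype=float)
    i_prime = np.clip(t - T_ref, 0.0, None)
    return I_C - I_MAX * i_prime / (TC50 + i_prime)


def gen_thermal(spec: SimulationSpec) -> ThermalSeries:
    """Thermal series from the exponential, quadratic or thermal-inhibition
    forward model over the 22–80 °C design."""
    if spec.model not in ("exponential", "quadratic", "thermal_inhibition"):
        raise SchemaError(f"gen_thermal cannot use model {spec.model!r}")
    if not spec.grid:
        raise SchemaError("empty temperature grid")
    p = spec.parameters
    rng = _rng(spec)
    t = np.repeat(np.asarray(spec.grid), spec.replicates)
    if spec.model == "exponential":
        j = exponential_response(t, p["J0"], p["b"])
    elif spec.model == "quadratic":
        j = quadratic_response(t, p["c0"], p["c1"], p["c2"])
    else:
        if p["I_MAX"] > p["I_C"]:
            raise SchemaError("I_MAX > I_C: residual activity would go negative")
        j = thermal_inhibition_response(t, p["I_C"], p["I_MAX"], p["TC50"],
                                        p.get("T_ref", 22.0))
    if spec.noise_sd > 0:
        j = j + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return ThermalSeries(tuple(t), tuple(j), is_relative=False)


def gen_isozyme_mixture(spec: SimulationSpec) -> pd.DataFrame:
    """Raw activity table for a two-isoform inhibition experiment.

    Parameters: ``total`` (baseline activity), ``f_iap`` (IAP activity
    fraction; the TNAP fraction is 1 − f_iap), and per-inhibitor inhibition
    fractions ``phi_phe``/``phi_harg`` mapping concentration (mM) to the
    fraction of the *sensitive* isoform's activity removed.  Group means are

        L-Phe  at c:  total · [f_iap·(1 − φ_Phe(c)) + (1 − f_iap)]
        L-hArg at c:  total · [f_iap + (1 − f_iap)·(1 − φ_hArg(c))]

    plus replicate Gaussian noise.  The returned long table (inhibitor,
    conc_mM, activity, replicate) is what ``normalize_to_baseline`` consumes;
    a shared 0-mM baseline group is emitted once per inhibitor.
    """
    if spec.model != "isozyme_mixture":
        raise SchemaError(f"gen_isozyme_mixture needs model 'isozyme_mixture', got {spec.model!r}")
    p = spec.parameters
    total, f_iap = float(p["total"]), float(p["f_iap"])
    if not 0.0 <= f_iap <= 1.0:
        raise SchemaError("f_iap must lie in [0, 1]")
    f_tnap = 1.0 - f_iap
    phis = {"L-Phe": dict(p["phi_phe"]), "L-hArg": dict(p["phi_harg"])}
    for inh, phi in phis.items():
        for c, frac in phi.items():
            if not 0.0 <= frac <= 1.0:
                raise SchemaError(f"inhibition fraction {frac} for {inh} at {c} mM "
                                  "outside [0, 1]")
    rng = _rng(spec)
    rows = []
    for inh, phi in phis.items():
        concs = sorted(set(phi) | {0.0})
        for c in concs:
            frac = phi.get(c, 0.0)
            if inh == "L-Phe":
                mean = total * (f_iap * (1.0 - frac) + f_tnap)
            else:
                mean = total * (f_iap + f_tnap * (1.0 - frac))
            for r in range(1, spec.replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                rows.append((inh, c, mean + noise, r))
    return pd.DataFrame(rows, columns=["inhibitor", "conc_mM", "activity", "replicate"])
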