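"""Probabilistic engine: Gaussian input perturbation, CDFs, sensitivities.

All 14 model inputs (four attachment groups x three axes, glenoid
inclination, stability offset) are perturbed simultaneously and
independently from their Gaussian distributions (input covariance is assumed
negligible and is not modelled). Each (species, instance) run draws one
common input matrix; a single model solve yields all seven cuff outputs, so
the seven analyses of a run share identical model states. Cumulative
distribution functions are tabulated at 11 probability levels and summarised
at the {1, 25, 50, 75, 99} percentiles. Absolute sensitivity factors
|dp/dmu| * sigma / p are estimated by central finite differences of the CDF
probability with respect to each input mean, with common random numbers,
then averaged across levels and support instances.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import INPUT_NAMES, GlenohumeralModel
from .species_params import CUFF_OUTPUTS, SpeciesParameterSet

CDF_LEVELS = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)
SUMMARY_PERCENTILES = (1, 25, 50, 75, 99)

#: Relative finite-difference step (fraction of the input SD) for
#: mean-perturbation sensitivity factors.
SENSITIVITY_STEP_FRACTION = 0.1


@dataclass(frozen=True)
class InputVariable:
    """One perturbed model input (native units)."""

    name: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")


def input_variables(species: SpeciesParameterSet) -> list[InputVariable]:
    """The 14 probabilistic inputs of one species model, canonical order."""
    model = _dummy_model_inputs(species)
    return [
        InputVariable(name=n, mean=m, sd=s)
        for n, m, s in zip(INPUT_NAMES, model[0], model[1])
    ]


def _dummy_model_inputs(species):
    means, sds = [], []
    from .model import INPUT_GROUPS

    for group in INPUT_GROUPS:
        d = species.distribution(group)
        means.extend(d.mean)
        sds.extend(d.sd)
    means.append(species.glenoid_inclination_mean_cm)
    sds.append(species.glenoid_inclination_sd_cm)
    means.append(species.stability.offset_pct)
    sds.append(species.stability.sd_pct)
    return np.array(means), np.array(sds)


def draw_inputs(
    variables: Sequence[InputVariable], n: int, seed: int
) -> np.ndarray:
    """n independent Gaussian draws of every input (n x len(variables)).

    Reproducible for a fixed seed; the same matrix is reused across the
    outputs of one run so all outputs see identical model states.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = np.array([v.mean for v in variables])
    sds = np.array([v.sd for v in variables])
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(variables)))
    return means + sds * z


@dataclass(frozen=True)
class CdfSummary:
    levels: tuple
    values: np.ndarray         # force (% max) at each level, nondecreasing
    percentiles: dict          # {1, 25, 50, 75, 99} -> force (% max)


def build_cdf(
    samples: np.ndarray, n_infeasible: int = 0, min_feasible: int = 100
) -> CdfSummary:
    """Empirical CDF at the 11 study levels plus the percentile summary.

    Quantiles use the linear-interpolation (type-7) rule for bit-exact
    reproducibility across runs.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_feasible:
        raise ValueError(
            f"too few feasible samples ({samples.size}; "
            f"n_infeasible={n_infeasible}, required {min_feasible})"
        )
    values = np.quantile(samples, CDF_LEVELS, method="linear")
    pct = {
        p: float(np.quantile(samples, p / 100.0, method="linear"))
        for p in SUMMARY_PERCENTILES
    }
    return CdfSummary(levels=CDF_LEVELS, values=values, percentiles=pct)


@dataclass
class MonteCarloResult:
    """Distributional result for one output of one (species, instance) run."""

    species: str
    output_name: str
    instance: str
    samples: np.ndarray            # feasible normalized forces, %
    n_infeasible: int
    cdf: CdfSummary
    sensitivities: pd.Series | None = None  # per input, averaged over levels


def run_monte_carlo(
    model: GlenohumeralModel,
    n: int,
    seed: int,
    min_feasible: int | None = None,
) -> tuple[list[MonteCarloResult], np.ndarray, np.ndarray]:
    """One Monte Carlo run: 7 output distributions from n common draws.

    Returns (results, output matrix (n x 7, NaN where infeasible), draw
    matrix). Infeasible iterations are counted and excluded from the CDFs.
    """
    variables = input_variables(model.species)
    draws = draw_inputs(variables, n, seed)
    outputs = np.full((n, len(CUFF_OUTPUTS)), np.nan)
    for i in range(n):
        vals, feasible = model.evaluate_outputs(draws[i])
        if feasible:
            outputs[i] = vals
    feasible_mask = ~np.isnan(outputs[:, 0])
    n_bad = int(n - feasible_mask.sum())
    if min_feasible is None:
        min_feasible = min(100, max(10, int(0.8 * n)))
    results = []
    for j, name in enumerate(CUFF_OUTPUTS):
        cdf = build_cdf(outputs[feasible_mask, j], n_bad, min_feasible)
        results.append(
            MonteCarloResult(
                species=model.species.species_id,
                output_name=name,
                instance=model.instance,
                samples=outputs[feasible_mask, j],
                n_infeasible=n_bad,
                cdf=cdf,
            )
        )
    return results, outputs, draws


# ---------------------------------------------------------------------------
# sensitivity factors

def sensitivity_factors(
    evaluate: Callable[[np.ndarray], np.ndarray],
    variables: Sequence[InputVariable],
    n: int,
    seed: int,
    levels: Sequence[float] = CDF_LEVELS,
    step_fraction: float = SENSITIVITY_STEP_FRACTION,
    output_names: Sequence[str] = CUFF_OUTPUTS,
) -> pd.DataFrame:
    """Absolute mean-perturbation sensitivity factors, averaged over levels.

    For input i at probability level p the factor is
    S = |dp/dmu_i| * sigma_i / p, estimated by a central finite difference
    (step = ``step_fraction`` * sigma_i) of the probability of staying below
    the base CDF's level threshold, re-evaluating the model with the shifted
    mean under common random numbers. ``evaluate`` maps an (n x k) draw
    matrix to an (n x m) output matrix with NaN rows for infeasible states.

    Returns a (len(variables) x len(output_names)) DataFrame of
    nonnegative factors.
    """
    means = np.array([v.mean for v in variables])
    sds = np.array([v.sd for v in variables])
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(variables)))
    base = evaluate(means + sds * z)
    levels = np.asarray(levels, dtype=float)
    factors = np.zeros((len(variables), base.shape[1]))
    base_ok = base[~np.isnan(base[:, 0])]
    thresholds = np.quantile(base_ok, levels, axis=0)  # L x m
    for i, var in enumerate(variables):
        if var.sd == 0:
            continue
        h = step_fraction * var.sd
        shift = np.zeros_like(means)
        shift[i] = h
        up = evaluate(means + shift + sds * z)
        dn = evaluate(means - shift + sds * z)
        up = up[~np.isnan(up[:, 0])]
        dn = dn[~np.isnan(dn[:, 0])]
        for j in range(base.shape[1]):
            s_levels = []
            for li, p in enumerate(levels):
                t = thresholds[li, j]
                p_up = np.mean(up[:, j] <= t) if len(up) else np.nan
                p_dn = np.mean(dn[:, j] <= t) if len(dn) else np.nan
                if np.isnan(p_up) or np.isnan(p_dn) or p <= 0:
                    continue
                s_levels.append(abs(p_up - p_dn) / (2 * h) * var.sd / p)
            factors[i, j] = np.mean(s_levels) if s_levels else np.nan
    return pd.DataFrame(
        factors, index=[v.name for v in variables], columns=list(output_names)
    )


def model_sensitivity(
    model: GlenohumeralModel, n: int, seed: int, **kwargs
) -> pd.DataFrame:
    """Sensitivity matrix of one (species, instance) model closure."""
    variables = input_variables(model.species)

    def evaluate(draws: np.ndarray) -> np.ndarray:
        out = np.full((len(draws), len(CUFF_OUTPUTS)), np.nan)
        for i, x in enumerate(draws):
            vals, feasible = model.evaluate_outputs(x)
            if feasible:
                out[i] = vals
        return out

    return sensitivity_factors(evaluate, variables, n, seed, **kwargs)


# ---------------------------------------------------------------------------
# full study

@dataclass
class StudyConfig:
    """Study design; defaults reproduce the published protocol
    (2 species x 3 instances x 7 outputs, 2500 iterations, 11 CDF levels)."""

    species: tuple = ("human", "chimpanzee")
    instances: tuple = ("early_support", "mid_support", "late_support")
    n_iterations: int = 2500
    seed: int = 0
    sigma_max: float = 88.0
    objective_exponent: int = 3
    stability_offset_mode: str = "multiplicative"
    sensitivity_iterations: int = 0  # 0 disables sensitivity estimation
    fixture_seed: int = 0
    min_feasible: int | None = None


@dataclass
class SuiteResult:
    results: list                      # MonteCarloResult, one per analysis
    sensitivity: dict                  # species -> 14 x 7 DataFrame (or None)
    manifest: dict

    def result(self, species: str, instance: str, output: str) -> MonteCarloResult:
        for r in self.results:
            if (r.species, r.instance, r.output_name) == (species, instance, output):
                return r
        raise KeyError((species, instance, output))


def derive_seed(base_seed: int, species: str, instance: str) -> int:
    """Stable per-analysis seed below 2^31."""
    key = f"{base_seed}:{species}:{instance}".encode()
    return zlib.adler32(key) % (2**31)


def run_analysis_suite(
    config: StudyConfig,
    parameter_sets: dict[str, SpeciesParameterSet] | None = None,
) -> SuiteResult:
    """Execute the full probabilistic study.

    7 outputs x len(instances) x len(species) Monte Carlo analyses (42 with
    the default design), plus per-species sensitivity matrices averaged over
    the 11 levels and the instances when ``sensitivity_iterations`` > 0.
    """
    from .species_params import load_default

    if parameter_sets is None:
        parameter_sets = {s: load_default(s) for s in config.species}
    results: list[MonteCarloResult] = []
    sensitivity: dict[str, pd.DataFrame | None] = {}
    manifest = {
        "base_seed": config.seed,
        "n_iterations": config.n_iterations,
        "sensitivity_iterations": config.sensitivity_iterations,
        "analyses": [],
    }
    for species_id in config.species:
        sp = parameter_sets[species_id]
        if sp.stability_offset_mode != config.stability_offset_mode:
            sp = _with_offset_mode(sp, config.stability_offset_mode)
        instance_sens = []
        for instance in config.instances:
            seed = derive_seed(config.seed, species_id, instance)
            model = GlenohumeralModel(
                sp,
                instance,
                seed=config.fixture_seed,
                sigma_max=config.sigma_max,
                exponent=config.objective_exponent,
            )
            try:
                run_results, outputs, _ = run_monte_carlo(
                    model, config.n_iterations, seed, config.min_feasible
                )
            except Exception as exc:
                raise RuntimeError(
                    f"analysis failed for ({species_id}, {instance}): {exc}"
                ) from exc
            results.extend(run_results)
            manifest["analyses"].append(
                {
                    "species": species_id,
                    "instance": instance,
                    "seed": seed,
                    "n_infeasible": run_results[0].n_infeasible,
                }
            )
            if config.sensitivity_iterations > 0:
                instance_sens.append(
                    model_sensitivity(model, config.sensitivity_iterations, seed)
                )
        if instance_sens:
            stacked = pd.concat(instance_sens)
            sensitivity[species_id] = stacked.groupby(level=0, sort=False).mean()
        else:
            sensitivity[species_id] = None
    return SuiteResult(results=results, sensitivity=sensitivity, manifest=manifest)


def _with_offset_mode(sp: SpeciesParameterSet, mode: str) -> SpeciesParameterSet:
    import dataclasses

    return dataclasses.replace(sp, stability_offset_mode=mode)


def suite_to_frame(suite: SuiteResult) -> pd.DataFrame:
    """Long-format table of CDF values (one row per output/instance/level)."""
    rows = []
    for r in suite.results:
        for level, value in zip(r.cdf.levels, r.cdf.values):
            rows.append(
                {
                    "species": r.species,
                    "output": r.output_name,
                    "instance": r.instance,
                    "level": level,
                    "force_pct": value,
                }
            )
    return pd.DataFrame(rows)


def percentile_frame(suite: SuiteResult) -> pd.DataFrame:
    rows = []
    for r in suite.results:
        row = {
            "species": r.species,
            "output": r.output_name,
            "instance": r.instance,
            "n_infeasible": r.n_infeasible,
        }
        row.update({f"p{p}": v for p, v in r.cdf.percentiles.items()})
        rows.append(row)
    return pd.DataFrame(rows)
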