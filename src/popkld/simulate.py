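"""Synthetic EHR laboratory cohort generator with known ground truth.

Emulates the statistical texture of raw EHR lab extracts so the whole
pipeline can be exercised and evaluated without any real patient data:

* sparse per-patient sampling — observation counts follow a shifted
  negative binomial with a floor of 5 and a median under 10, matching the
  outpatient regime where most individuals have fewer than ten values;
  ICU-context patients instead have a floor of 25;
* per-patient latent distribution parameters drawn around population-level
  hyper-parameters (a population that is "one family with patient-level
  variation");
* four mixing regimes describing how individual generating distributions
  compose into the population: every patient a different single
  distribution (``case1``), every patient a different two-component mixture
  (``case2``), one shared family with tight patient-level parameter
  variation (``case3``, the regime the summarization algorithm assumes),
  and one shared mixture (``case4``);
* unit-error outliers — a small Bernoulli fraction of values multiplied by
  100–1000, the way a mis-keyed unit produces a wildly inflated lab value;
* an optional glucose-like physiologic coupling in which each patient's
  latent standard deviation is linear in their latent mean.

All randomness flows from a single seed through named substreams, so any
cohort is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import get_family, list_families

__all__ = [
    "ObsCountModel",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "label_by_latent",
    "DEFAULT_LATENTS",
]

# typical-magnitude latent hyper-parameters per family: (base, jitter sd).
# magnitudes are glucose-like (mg/dL) where a location scale makes sense;
# jitters are tight so a case-3 population stays close to its family
DEFAULT_LATENTS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {"loc": (100.0, 3.0), "scale": (15.0, 1.0)},
    "lognormal": {"mu": (4.9, 0.05), "sigma": (0.25, 0.015)},
    "gamma": {"shape": (8.0, 0.4), "scale": (18.0, 0.8)},
    "weibull": {"shape": (3.5, 0.15), "scale": (15.0, 0.5)},
    "logistic": {"loc": (100.0, 3.0), "scale": (9.0, 0.4)},
    "uniform": {"lower": (60.0, 1.5), "upper": (140.0, 1.5)},
    "student_t": {"df": (6.0, 0.25), "loc": (100.0, 3.0), "scale": (12.0, 0.5)},
    "rayleigh": {"scale": (80.0, 3.0)},
    "gev": {"loc": (95.0, 3.0), "scale": (20.0, 0.8), "shape": (0.15, 0.015)},
}

MIXING_CASES = ("case1", "case2", "case3", "case4")


@dataclass(frozen=True)
class ObsCountModel:
    """Shifted negative-binomial observation counts: ``floor + NB(n, p)``."""

    floor: int = 5
    nb_n: float = 2.0
    nb_p: float = 0.45

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if size == 0:
            return np.zeros(0, dtype=int)
        return self.floor + rng.negative_binomial(self.nb_n, self.nb_p, size)


OUTPATIENT_COUNTS = ObsCountModel(floor=5, nb_n=2.0, nb_p=0.45)
ICU_COUNTS = ObsCountModel(floor=25, nb_n=3.0, nb_p=0.3)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort.

    ``meansd_coupling = (slope, intercept, noise_sd)`` replaces the default
    latent draw: each patient's mean is drawn from ``mean_hyper`` and their
    standard deviation is ``slope * mean + intercept + N(0, noise_sd)``,
    then converted to the family's native parameters (supported for normal,
    lognormal and gamma, the families with a clean mean/sd
    reparametrization).
    """

    n_patients: int = 500
    family_name: str = "normal"
    lab_name: str = "lab"
    hyper: dict[str, tuple[float, float]] | None = None
    obs_counts: ObsCountModel = OUTPATIENT_COUNTS
    mixing_case: str = "case3"
    mixture_families: tuple[str, str] | None = None
    outlier_rate: float = 0.0
    outlier_multiplier: float = 1000.0
    outlier_mode: str = "multiplicative"  # or "additive"
    meansd_coupling: tuple[float, float, float] | None = None
    mean_hyper: tuple[float, float] = (140.0, 25.0)
    icu_fraction: float = 0.0
    icu_obs_counts: ObsCountModel = ICU_COUNTS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.icu_fraction <= 1.0:
            raise ValueError("icu_fraction must be in [0, 1]")
        if self.mixing_case not in MIXING_CASES:
            raise ValueError(f"mixing_case must be one of {MIXING_CASES}")
        if self.obs_counts.floor < 1 or self.icu_obs_counts.floor < 1:
            raise ValueError("observation count floor must be >= 1")
        get_family(self.family_name)  # raises on unknown families


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth behind it."""

    table: pd.DataFrame              # patient_id, lab_name, value, context
    latents: pd.DataFrame            # per-patient family, params, location/scale
    outlier_flags: np.ndarray        # aligned with table rows
    spec: CohortSpec


def _draw_latent(rng, family_name: str,
                 hyper: dict[str, tuple[float, float]]) -> tuple[float, ...]:
    fam = get_family(family_name)
    vals = []
    for pname in fam.param_names:
        base, jitter = hyper[pname]
        v = base + jitter * rng.standard_normal()
        role = fam.param_roles[pname]
        if role == "scale":
            v = max(v, 1e-3)
        if family_name == "gamma" and pname == "shape":
            v = max(v, 0.05)
        if family_name == "weibull" and pname == "shape":
            v = max(v, 0.05)
        if family_name == "student_t" and pname == "df":
            v = max(v, 2.1)
        vals.append(float(v))
    if family_name == "uniform" and vals[1] <= vals[0]:
        vals[1] = vals[0] + 1e-3
    return tuple(vals)


def _params_from_mean_sd(family_name: str, m: float, s: float) -> tuple[float, ...]:
    """Convert a (mean, sd) pair to native parameters."""
    if family_name == "normal":
        return (m, s)
    if family_name == "lognormal":
        cv2 = (s / m) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(m) - sigma2 / 2.0
        return (float(mu), float(np.sqrt(sigma2)))
    if family_name == "gamma":
        return (float(m * m / (s * s)), float(s * s / m))
    raise ValueError(
        f"mean/sd coupling is not supported for family '{family_name}' "
        "(supported: normal, lognormal, gamma)"
    )


def _patient_latents(spec: CohortSpec, rng) -> list[tuple[str, tuple]]:
    """Per-patient (family, params); mixture cases store component info."""
    n = spec.n_patients
    out: list[tuple[str, tuple]] = []

    if spec.meansd_coupling is not None:
        slope, intercept, noise_sd = spec.meansd_coupling
        mb, msd = spec.mean_hyper
        for _ in range(n):
            m = mb + msd * rng.standard_normal()
            m = max(m, 1.0)
            s = slope * m + intercept + noise_sd * rng.standard_normal()
            s = max(s, 0.5)
            out.append((spec.family_name,
                        _params_from_mean_sd(spec.family_name, m, s)))
        return out

    hyper = spec.hyper or DEFAULT_LATENTS[spec.family_name]

    if spec.mixing_case == "case3":
        for _ in range(n):
            out.append((spec.family_name,
                        _draw_latent(rng, spec.family_name, hyper)))
    elif spec.mixing_case == "case1":
        names = (sorted(set(list_families()) & set(DEFAULT_LATENTS))
                 if spec.mixture_families is None
                 else list(spec.mixture_families))
        for _ in range(n):
            fam = names[rng.integers(len(names))]
            out.append((fam, _draw_latent(rng, fam, DEFAULT_LATENTS[fam])))
    elif spec.mixing_case in ("case2", "case4"):
        pair = spec.mixture_families or ("normal", "gamma")
        if spec.mixing_case == "case4":
            # one shared mixture: components drawn once
            shared = [(f, _draw_latent(rng, f, DEFAULT_LATENTS[f]))
                      for f in pair]
            w = float(rng.uniform(0.3, 0.7))
            for _ in range(n):
                out.append(("mixture", (shared, w)))
        else:
            for _ in range(n):
                comps = [(f, _draw_latent(rng, f, DEFAULT_LATENTS[f]))
                         for f in pair]
                w = float(rng.uniform(0.25, 0.75))
                out.append(("mixture", (comps, w)))
    return out


def _latent_location_scale(family_name: str, params) -> tuple[float, float]:
    if family_name == "mixture":
        comps, w = params
        locs, sds = zip(*(_latent_location_scale(f, p) for f, p in comps))
        return (w * locs[0] + (1 - w) * locs[1],
                w * sds[0] + (1 - w) * sds[1])
    fam = get_family(family_name)
    try:
        m, s = fam.mean(params), fam.sd(params)
    except ValueError:
        m, s = np.nan, np.nan
    loc = fam.location_like(params)
    return (float(loc if np.isfinite(loc) else m), float(s))


def _draw_values(family_name: str, params, n: int, rng) -> np.ndarray:
    if family_name == "mixture":
        comps, w = params
        pick = rng.random(n) < w
        vals = np.empty(n)
        n0 = int(pick.sum())
        vals[pick] = get_family(comps[0][0]).sample(comps[0][1], n0, rng)
        vals[~pick] = get_family(comps[1][0]).sample(comps[1][1], n - n0, rng)
        return vals
    return get_family(family_name).sample(params, n, rng)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a cohort from ``spec``; deterministic given ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    rng_latents, rng_counts, rng_values, rng_outliers, rng_context = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    n = spec.n_patients
    latents = _patient_latents(spec, rng_latents)
    contexts = np.where(rng_context.random(n) < spec.icu_fraction,
                        "icu", "outpatient")
    counts = np.empty(n, dtype=int)
    is_icu = contexts == "icu"
    counts[is_icu] = spec.icu_obs_counts.draw(rng_counts, int(is_icu.sum()))
    counts[~is_icu] = spec.obs_counts.draw(rng_counts, int((~is_icu).sum()))

    pid_width = max(len(str(max(n - 1, 0))), 1)
    patient_ids = [f"p{idx:0{pid_width}d}" for idx in range(n)]

    rows_pid, rows_val, rows_ctx = [], [], []
    latent_rows = []
    for idx in range(n):
        fam_name, params = latents[idx]
        vals = _draw_values(fam_name, params, int(counts[idx]), rng_values)
        rows_pid.extend([patient_ids[idx]] * int(counts[idx]))
        rows_val.append(vals)
        rows_ctx.extend([contexts[idx]] * int(counts[idx]))
        loc, scl = _latent_location_scale(fam_name, params)
        latent_rows.append({
            "patient_id": patient_ids[idx],
            "family": fam_name,
            "params": params if fam_name != "mixture" else None,
            "location_like": loc,
            "scale_like": scl,
            "context": contexts[idx],
            "n_obs": int(counts[idx]),
        })

    values = np.concatenate(rows_val) if rows_val else np.zeros(0)
    flags = np.zeros(values.size, dtype=bool)
    if spec.outlier_rate > 0 and values.size:
        flags = rng_outliers.random(values.size) < spec.outlier_rate
        if spec.outlier_mode == "multiplicative":
            values = np.where(flags, values * spec.outlier_multiplier, values)
        elif spec.outlier_mode == "additive":
            values = np.where(flags, values + spec.outlier_multiplier, values)
        else:
            raise ValueError(f"unknown outlier_mode '{spec.outlier_mode}'")

    table = pd.DataFrame({
        "patient_id": pd.Series(rows_pid, dtype=str),
        "lab_name": spec.lab_name,
        "value": values,
        "context": pd.Series(rows_ctx, dtype=str),
    })
    latents_frame = pd.DataFrame(
        latent_rows, columns=["patient_id", "family", "params",
                              "location_like", "scale_like", "context",
                              "n_obs"])
    return SimulatedCohort(table=table, latents=latents_frame,
                           outlier_flags=flags, spec=spec)


def glucose_coupled_spec(family_name: str = "gamma", *,
                         n_patients: int = 800,
                         outlier_rate: float = 0.0,
                         outlier_multiplier: float = 1000.0,
                         seed: int = 0) -> CohortSpec:
    """ICU-glucose-like coupled cohort: per-patient SD linear in the mean.

    The canonical conditions used in the physiologic-relation evaluations:
    800 densely measured patients (ICU regime, ≥25 values each), patient
    mean glucose around 150 mg/dL with population spread 40, and the known
    glucose physiology ``sd ≈ 0.3·mean + 10`` plus N(0, 5) noise.
    """
    return CohortSpec(
        n_patients=n_patients, family_name=family_name, lab_name="glucose",
        obs_counts=ICU_COUNTS, meansd_coupling=(0.3, 10.0, 5.0),
        mean_hyper=(150.0, 40.0), outlier_rate=outlier_rate,
        outlier_multiplier=outlier_multiplier, seed=seed,
    )


def label_by_latent(cohort: SimulatedCohort,
                    threshold_quantile: float = 0.9) -> pd.Series:
    """Binary disease-like labels from the true location latents.

    A synthetic stand-in for a chart-review gold standard: a patient is
    "diseased" when their latent location exceeds the given population
    quantile.  Indexed by patient_id.
    """
    loc = cohort.latents.set_index("patient_id")["location_like"]
    if threshold_quantile <= 0.0:
        labels = pd.Series(1, index=loc.index)
    elif threshold_quantile >= 1.0:
        labels = pd.Series(0, index=loc.index)
    else:
        thr = float(np.quantile(loc.to_numpy(), threshold_quantile))
        labels = (loc > thr).astype(int)
    labels.name = "label"
    return labels
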