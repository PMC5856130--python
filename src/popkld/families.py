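"""Registry of parametric distribution families.

Each candidate summary model (normal, log-normal, gamma, generalized extreme
value, ...) is wrapped as a :class:`DistributionFamily` that knows its
canonical parameter names and roles, its support, how to evaluate its density,
how to fit itself by maximum likelihood, and how to sample from itself.  The
rest of the pipeline refers to families only by their registered name, so new
families can be added without touching the selection code.

Parameter conventions
---------------------
* ``normal``: ``loc`` (mean), ``scale`` (standard deviation).
* ``lognormal``: ``mu``, ``sigma`` — mean and standard deviation of
  ``log(X)``; support is the positive half line.
* ``gamma``: ``shape`` (often written *a*), ``scale`` (often *b*); the mean is
  ``shape * scale``.
* ``weibull``: ``shape`` (*k*), ``scale``.
* ``logistic``: ``loc``, ``scale``.
* ``uniform``: ``lower``, ``upper``; the MLE is the sample minimum/maximum.
* ``student_t``: ``df``, ``loc``, ``scale`` (location–scale *t*).
* ``rayleigh``: ``scale`` only.
* ``gev``: ``loc``, ``scale``, ``shape`` (xi).  The sign convention follows
  the extreme-value literature: ``shape < 0`` gives a *finite upper* endpoint
  at ``loc - scale/shape`` (reversed-Weibull domain), ``shape > 0`` a heavy
  right tail with finite lower endpoint, ``shape = 0`` the Gumbel limit.
  SciPy's ``genextreme`` uses the opposite sign (``c = -shape``); conversion
  happens inside this module only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ParamVector",
    "FitResult",
    "DistributionFamily",
    "FAMILY_REGISTRY",
    "list_families",
    "get_family",
    "register_family",
    "fit_mle",
    "sample",
]

# failure_reason vocabulary for FitResult
FAILURE_NONE = "none"
FAILURE_OPTIMIZER = "optimizer_failure"
FAILURE_SUPPORT = "support_violation"
FAILURE_DEGENERATE = "degenerate_data"


@dataclass(frozen=True)
class ParamVector:
    """Ordered parameter values for one family, in its canonical order."""

    family_name: str
    values: tuple[float, ...]

    def as_dict(self) -> dict[str, float]:
        fam = get_family(self.family_name)
        return dict(zip(fam.param_names, self.values))

    def __post_init__(self) -> None:
        fam = FAMILY_REGISTRY.get(self.family_name)
        if fam is not None and len(self.values) != len(fam.param_names):
            raise ValueError(
                f"family '{self.family_name}' expects {len(fam.param_names)} "
                f"parameters, got {len(self.values)}"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``converged`` is true only when the optimizer succeeded, the
    log-likelihood is finite, and the parameters are valid for the family;
    otherwise ``failure_reason`` says why.  Ordinary data pathologies
    (constant values, negatives under a positive-support family) never raise —
    they come back as non-converged results so that per-patient loops can
    simply record the exclusion.
    """

    params: ParamVector | None
    converged: bool
    log_likelihood: float
    failure_reason: str = FAILURE_NONE

    def __post_init__(self) -> None:
        if self.converged and (
            not math.isfinite(self.log_likelihood)
            or self.failure_reason != FAILURE_NONE
        ):
            raise ValueError("converged fit must have finite log-likelihood "
                             "and failure_reason='none'")


@dataclass
class DistributionFamily:
    """A named parametric family with density, MLE, and sampling.

    Parameters
    ----------
    name : str
        Registry key, e.g. ``"gev"``.
    param_names : sequence of str
        Canonical, frozen parameter order (serialized summaries rely on it).
    param_roles : dict
        Maps each parameter to ``"location"``, ``"scale"`` or ``"shape"``.
    to_scipy / from_scipy
        Converters between canonical parameters and the SciPy
        ``(shapes..., loc, scale)`` convention.
    max_support : tuple
        The union of supports over all valid parameters, used to detect
        support violations *before* optimization (open intervals: a datum on
        a zero-density boundary counts as a violation).
    """

    name: str
    param_names: tuple[str, ...]
    param_roles: dict[str, str]
    dist: stats.rv_continuous
    to_scipy: Callable[[Sequence[float]], tuple]
    from_scipy: Callable[[Sequence[float]], tuple]
    max_support: tuple[float, float] = (-np.inf, np.inf)
    support_fn: Callable[[Sequence[float]], tuple[float, float]] | None = None
    initial_guess: Callable[[np.ndarray], tuple] | None = None
    closed_form_mle: Callable[[np.ndarray], tuple] | None = None
    fixed_fit_kwargs: dict = field(default_factory=dict)
    validate: Callable[[Sequence[float]], str | None] | None = None

    # -- basic queries -----------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def support(self, params: Sequence[float]) -> tuple[float, float]:
        """Support interval ``(lower, upper)`` at the given parameters."""
        if self.support_fn is not None:
            return self.support_fn(tuple(params))
        frozen = self._frozen(params)
        return frozen.support()

    def _check_params(self, params: Sequence[float]) -> None:
        params = tuple(float(v) for v in params)
        if len(params) != self.n_params:
            raise ValueError(
                f"{self.name}: expected {self.n_params} parameters, "
                f"got {len(params)}"
            )
        for pname, value in zip(self.param_names, params):
            if not math.isfinite(value):
                raise ValueError(f"{self.name}: parameter '{pname}' is not finite")
            if self.param_roles[pname] == "scale" and value <= 0:
                raise ValueError(
                    f"{self.name}: scale-like parameter '{pname}' must be > 0, "
                    f"got {value}"
                )
        if self.validate is not None:
            msg = self.validate(params)
            if msg:
                raise ValueError(f"{self.name}: {msg}")

    def _frozen(self, params: Sequence[float]):
        self._check_params(params)
        args = self.to_scipy(tuple(float(v) for v in params))
        return self.dist(*args[:-2], loc=args[-2], scale=args[-1])

    # -- density / moments -------------------------------------------------
    def pdf(self, x, params: Sequence[float]) -> np.ndarray:
        return self._frozen(params).pdf(np.asarray(x, dtype=float))

    def logpdf(self, x, params: Sequence[float]) -> np.ndarray:
        return self._frozen(params).logpdf(np.asarray(x, dtype=float))

    def log_likelihood(self, x, params: Sequence[float]) -> float:
        return float(np.sum(self.logpdf(x, params)))

    def mean(self, params: Sequence[float]) -> float:
        """Model mean (the "mean-like" quantity); may be infinite."""
        return float(self._frozen(params).mean())

    def sd(self, params: Sequence[float]) -> float:
        """Model standard deviation (the "sd-like" quantity)."""
        return float(self._frozen(params).std())

    def location_like(self, params: Sequence[float]) -> float:
        """The location parameter if the family has one, else the mean."""
        for pname, value in zip(self.param_names, params):
            if self.param_roles[pname] == "location":
                return float(value)
        return self.mean(params)

    # -- sampling ----------------------------------------------------------
    def sample(self, params: Sequence[float], n: int, seed=None) -> np.ndarray:
        """Draw ``n`` i.i.d. values; deterministic given ``seed``."""
        if n < 0:
            raise ValueError("n must be >= 0")
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        frozen = self._frozen(params)
        return np.asarray(frozen.rvs(size=n, random_state=rng), dtype=float)

    # -- fitting -----------------------------------------------------------
    def _support_ok(self, x: np.ndarray) -> bool:
        lo, hi = self.max_support
        return bool(np.all(x > lo) and np.all(x < hi))

    def fit(self, values) -> FitResult:
        """Maximum-likelihood fit with moment-based initialization.

        Never raises for ordinary data pathologies; returns a non-converged
        :class:`FitResult` with a specific ``failure_reason`` instead.
        """
        x = np.asarray(values, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("cannot fit an empty sample")
        if not np.all(np.isfinite(x)):
            raise ValueError("values must all be finite")

        if np.unique(x).size == 1:
            return FitResult(None, False, -np.inf, FAILURE_DEGENERATE)
        if not self._support_ok(x):
            return FitResult(None, False, -np.inf, FAILURE_SUPPORT)

        if self.closed_form_mle is not None:
            try:
                params = self.closed_form_mle(x)
            except (ValueError, FloatingPointError):
                return FitResult(None, False, -np.inf, FAILURE_DEGENERATE)
            return self._finish_fit(x, params, guess=None)

        guess = self.initial_guess(x) if self.initial_guess else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if guess is not None:
                    scipy_guess = self.to_scipy(guess)
                    shapes = scipy_guess[:-2]
                    raw = self.dist.fit(
                        x, *shapes,
                        loc=scipy_guess[-2], scale=scipy_guess[-1],
                        **self.fixed_fit_kwargs,
                    )
                else:
                    raw = self.dist.fit(x, **self.fixed_fit_kwargs)
            params = self.from_scipy(raw)
        except (stats.FitError, ValueError, RuntimeError, OverflowError):
            return FitResult(None, False, -np.inf, FAILURE_OPTIMIZER)
        return self._finish_fit(x, params, guess=guess)

    def _finish_fit(self, x, params, guess) -> FitResult:
        try:
            ll = self.log_likelihood(x, params)
        except ValueError:
            return FitResult(None, False, -np.inf, FAILURE_OPTIMIZER)
        # the optimizer must not end up below its own starting point
        if guess is not None:
            try:
                ll_guess = self.log_likelihood(x, guess)
            except ValueError:
                ll_guess = -np.inf
            if math.isfinite(ll_guess) and ll_guess > ll:
                params, ll = guess, ll_guess
        if not math.isfinite(ll):
            return FitResult(None, False, -np.inf, FAILURE_OPTIMIZER)
        pv = ParamVector(self.name, tuple(float(v) for v in params))
        return FitResult(pv, True, ll, FAILURE_NONE)


# ---------------------------------------------------------------------------
# registry construction
# ---------------------------------------------------------------------------

FAMILY_REGISTRY: dict[str, DistributionFamily] = {}


def register_family(family: DistributionFamily, overwrite: bool = False) -> None:
    """Add a family to the registry (selection code picks it up automatically)."""
    if family.name in FAMILY_REGISTRY and not overwrite:
        raise ValueError(f"family '{family.name}' already registered")
    FAMILY_REGISTRY[family.name] = family


def list_families() -> dict[str, DistributionFamily]:
    """All registered families keyed by name."""
    return dict(FAMILY_REGISTRY)


def get_family(name: str | DistributionFamily) -> DistributionFamily:
    if isinstance(name, DistributionFamily):
        return name
    try:
        return FAMILY_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown family '{name}'; registered: {sorted(FAMILY_REGISTRY)}"
        ) from None


def _normal_mle(x: np.ndarray) -> tuple:
    # divisor-n standard deviation (the MLE, not the unbiased estimator)
    return (float(np.mean(x)), float(np.std(x)))


def _lognormal_mle(x: np.ndarray) -> tuple:
    logs = np.log(x)
    sigma = float(np.std(logs))
    if sigma == 0.0:
        raise ValueError("degenerate log-scale spread")
    return (float(np.mean(logs)), sigma)


def _uniform_mle(x: np.ndarray) -> tuple:
    return (float(np.min(x)), float(np.max(x)))


def _rayleigh_mle(x: np.ndarray) -> tuple:
    return (float(np.sqrt(np.mean(x**2) / 2.0)),)


def _gamma_guess(x: np.ndarray) -> tuple:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-12)
    return (max(m * m / v, 1e-3), max(v / m, 1e-12))


def _weibull_guess(x: np.ndarray) -> tuple:
    # quantile heuristic: slope of log(-log(1-F)) vs log(x) ~ shape
    s = float(np.std(np.log(x)))
    k = 1.2 / s if s > 0 else 1.0
    return (float(np.clip(k, 0.1, 50.0)), float(np.mean(x)))


def _logistic_guess(x: np.ndarray) -> tuple:
    return (float(np.mean(x)), max(float(np.std(x)) * math.sqrt(3) / math.pi, 1e-12))


def _t_guess(x: np.ndarray) -> tuple:
    kurt = float(stats.kurtosis(x, fisher=True))
    df = 4.0 + 6.0 / kurt if kurt > 0.1 else 20.0
    df = float(np.clip(df, 2.2, 100.0))
    scale = float(np.std(x)) * math.sqrt((df - 2.0) / df)
    return (df, float(np.mean(x)), max(scale, 1e-12))


_EULER = 0.5772156649015329


def _gev_guess(x: np.ndarray) -> tuple:
    # Gumbel moment start with a mildly heavy tail
    sd = float(np.std(x))
    scale = max(sd * math.sqrt(6) / math.pi, 1e-12)
    loc = float(np.mean(x)) - _EULER * scale
    return (loc, scale, 0.1)


def _gev_support(params) -> tuple[float, float]:
    loc, scale, shape = params
    if shape > 0:
        return (loc - scale / shape, np.inf)
    if shape < 0:
        return (-np.inf, loc - scale / shape)
    return (-np.inf, np.inf)


def _build_registry() -> None:
    register_family(DistributionFamily(
        name="normal",
        param_names=("loc", "scale"),
        param_roles={"loc": "location", "scale": "scale"},
        dist=stats.norm,
        to_scipy=lambda p: (p[0], p[1]),
        from_scipy=lambda r: (r[0], r[1]),
        closed_form_mle=_normal_mle,
    ))
    register_family(DistributionFamily(
        name="lognormal",
        param_names=("mu", "sigma"),
        param_roles={"mu": "location", "sigma": "scale"},
        dist=stats.lognorm,
        to_scipy=lambda p: (p[1], 0.0, math.exp(p[0])),
        from_scipy=lambda r: (math.log(r[2]), r[0]),
        max_support=(0.0, np.inf),
        support_fn=lambda p: (0.0, np.inf),
        closed_form_mle=_lognormal_mle,
    ))
    register_family(DistributionFamily(
        name="gamma",
        param_names=("shape", "scale"),
        param_roles={"shape": "shape", "scale": "scale"},
        dist=stats.gamma,
        to_scipy=lambda p: (p[0], 0.0, p[1]),
        from_scipy=lambda r: (r[0], r[2]),
        max_support=(0.0, np.inf),
        support_fn=lambda p: (0.0, np.inf),
        initial_guess=_gamma_guess,
        fixed_fit_kwargs={"floc": 0.0},
        validate=lambda p: "shape must be > 0" if p[0] <= 0 else None,
    ))
    register_family(DistributionFamily(
        name="weibull",
        param_names=("shape", "scale"),
        param_roles={"shape": "shape", "scale": "scale"},
        dist=stats.weibull_min,
        to_scipy=lambda p: (p[0], 0.0, p[1]),
        from_scipy=lambda r: (r[0], r[2]),
        max_support=(0.0, np.inf),
        support_fn=lambda p: (0.0, np.inf),
        initial_guess=_weibull_guess,
        fixed_fit_kwargs={"floc": 0.0},
        validate=lambda p: "shape must be > 0" if p[0] <= 0 else None,
    ))
    register_family(DistributionFamily(
        name="logistic",
        param_names=("loc", "scale"),
        param_roles={"loc": "location", "scale": "scale"},
        dist=stats.logistic,
        to_scipy=lambda p: (p[0], p[1]),
        from_scipy=lambda r: (r[0], r[1]),
        initial_guess=_logistic_guess,
    ))
    register_family(DistributionFamily(
        name="uniform",
        param_names=("lower", "upper"),
        param_roles={"lower": "location", "upper": "location"},
        dist=stats.uniform,
        to_scipy=lambda p: (p[0], p[1] - p[0]),
        from_scipy=lambda r: (r[0], r[0] + r[1]),
        support_fn=lambda p: (p[0], p[1]),
        closed_form_mle=_uniform_mle,
        validate=lambda p: "upper must exceed lower" if p[1] <= p[0] else None,
    ))
    register_family(DistributionFamily(
        name="student_t",
        param_names=("df", "loc", "scale"),
        param_roles={"df": "shape", "loc": "location", "scale": "scale"},
        dist=stats.t,
        to_scipy=lambda p: (p[0], p[1], p[2]),
        from_scipy=lambda r: (r[0], r[1], r[2]),
        initial_guess=_t_guess,
        validate=lambda p: "df must be > 0" if p[0] <= 0 else None,
    ))
    register_family(DistributionFamily(
        name="rayleigh",
        param_names=("scale",),
        param_roles={"scale": "scale"},
        dist=stats.rayleigh,
        to_scipy=lambda p: (0.0, p[0]),
        from_scipy=lambda r: (r[1],),
        max_support=(0.0, np.inf),
        support_fn=lambda p: (0.0, np.inf),
        closed_form_mle=_rayleigh_mle,
    ))
    register_family(DistributionFamily(
        name="gev",
        param_names=("loc", "scale", "shape"),
        param_roles={"loc": "location", "scale": "scale", "shape": "shape"},
        dist=stats.genextreme,
        # our shape (xi) is the negative of scipy's c
        to_scipy=lambda p: (-p[2], p[0], p[1]),
        from_scipy=lambda r: (r[1], r[2], -r[0]),
        support_fn=_gev_support,
        initial_guess=_gev_guess,
    ))


_build_registry()


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_mle(values, family: str | DistributionFamily) -> FitResult:
    """Fit ``family`` to ``values`` by maximum likelihood.

    Thin wrapper over :meth:`DistributionFamily.fit`.
    """
    return get_family(family).fit(values)


def sample(family: str | DistributionFamily, params, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` values from ``family`` at ``params``; deterministic given seed."""
    fam = get_family(family)
    if isinstance(params, ParamVector):
        params = params.values
    return fam.sample(params, n, seed)
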