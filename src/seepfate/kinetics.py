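"""First-order methane biodegradation kinetics from tritium-tracer data.

The laboratory experiment spikes tritium-labelled methane into natural
seawater; as methanotrophs oxidise the methane, labelled water
accumulates.  After sparging, the measured activity C(t) rises from the
sterile-control background Cb toward the pre-incubation total Ctot:

    C(t; T) = Ctot + (Cb - Ctot) * 2**(-t / t12(T))

with a concentration-independent half-life t12 that follows a Q10
temperature scaling,

    t12(T) = t12_ref * Q10**(-(T - T_ref) / 10).

Parameters (t12_ref, Cb, Ctot) and a single Gaussian noise scale
s_n = exp(ln_sigma) are estimated by maximum likelihood and by MCMC
sampling of the posterior under uniform priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import emcee
import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize

LN2 = float(np.log(2.0))

#: uniform prior support for the half-life (days)
HALFLIFE_MIN = 0.25
HALFLIFE_MAX = 100.0

PARAM_NAMES = ("t12_ref", "Cb", "Ctot", "ln_sigma")

_KINDS = ("test", "control", "pre")


class ConvergenceError(RuntimeError):
    """An optimiser or sampler failed to converge on valid input."""


# ---------------------------------------------------------------------------
# Parameters and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsParams:
    """Parameter vector of the biodegradation data model.

    Activities are normalised (dimensionless); t12_ref is the half-life
    in days at the reference temperature T_ref; Q10 is held fixed.
    """

    t12_ref: float
    Cb: float
    Ctot: float
    ln_sigma: float
    Q10: float = 2.0
    T_ref: float = 5.0

    def __post_init__(self):
        if self.t12_ref <= 0:
            raise ValueError("t12_ref must be positive")
        if self.Cb < 0 or self.Ctot < 0:
            raise ValueError("Cb and Ctot must be non-negative")
        if self.Q10 <= 0:
            raise ValueError("Q10 must be positive")

    @property
    def sigma(self) -> float:
        return float(np.exp(self.ln_sigma))

    def free_vector(self) -> np.ndarray:
        return np.array([self.t12_ref, self.Cb, self.Ctot, self.ln_sigma])

    def with_free_vector(self, theta) -> "KineticsParams":
        t12, cb, ctot, lns = (float(v) for v in theta)
        return replace(self, t12_ref=t12, Cb=cb, Ctot=ctot, ln_sigma=lns)


@dataclass
class TracerDataset:
    """Normalised tracer-activity observations.

    Rows carry kind 'test' (incubated flasks, modelled by the decay
    curve), 'control' (sterile background, direct observation of Cb)
    or 'pre' (pre-incubation total activity, direct observation of
    Ctot).
    """

    frame: pd.DataFrame

    COLUMNS = ("day", "temperature_C", "replicate", "kind", "activity_normalized")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"tracer dataset missing columns: {sorted(missing)}")
        bad = set(self.frame["kind"]) - set(_KINDS)
        if bad:
            raise ValueError(f"unknown observation kinds: {sorted(bad)}")
        if (self.frame["day"] < 0).any():
            raise ValueError("sampling days must be non-negative")

    def __len__(self):
        return len(self.frame)

    @property
    def activities(self) -> np.ndarray:
        return self.frame["activity_normalized"].to_numpy(float)

    def model_values(self, params: KineticsParams) -> np.ndarray:
        """Expected activity for every row under the data model."""
        kind = self.frame["kind"].to_numpy()
        out = np.empty(len(self.frame))
        test = kind == "test"
        out[test] = predict_activity(
            params,
            self.frame.loc[test, "day"].to_numpy(float),
            self.frame.loc[test, "temperature_C"].to_numpy(float),
        )
        out[kind == "control"] = params.Cb
        out[kind == "pre"] = params.Ctot
        return out

    def normalized_by_background(self) -> "TracerDataset":
        """Divide all activities by the mean sterile-control activity."""
        controls = self.frame.loc[self.frame["kind"] == "control",
                                  "activity_normalized"]
        if controls.empty:
            raise ValueError("no control samples to normalise against")
        scale = controls.mean()
        if scale <= 0:
            raise ValueError("mean control activity must be positive")
        out = self.frame.copy()
        out["activity_normalized"] = out["activity_normalized"] / scale
        return TracerDataset(out)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TracerDataset":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def scale_halflife(t12_ref, T, Q10=2.0, T_ref=5.0):
    """Half-life at temperature T under Q10 scaling.

    A Q10 of 2 halves the half-life for every 10 degC of warming.
    """
    t12_ref = np.asarray(t12_ref, dtype=float)
    if np.any(t12_ref <= 0) or Q10 <= 0:
        raise ValueError("t12_ref and Q10 must be positive")
    T = np.asarray(T, dtype=float)
    return t12_ref * Q10 ** (-(T - T_ref) / 10.0)


def halflife_to_rate(t12):
    """First-order rate coefficient k1 = ln 2 / t12 (1/day)."""
    t12 = np.asarray(t12, dtype=float)
    if np.any(t12 <= 0):
        raise ValueError("half-life must be positive")
    return LN2 / t12


def rate_to_halflife(k1):
    """Half-life t12 = ln 2 / k1 (days)."""
    k1 = np.asarray(k1, dtype=float)
    if np.any(k1 <= 0):
        raise ValueError("rate coefficient must be positive")
    return LN2 / k1


def predict_activity(params: KineticsParams, t, T):
    """Expected normalised activity after incubating for t days at T degC."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("incubation time must be non-negative")
    t12 = scale_halflife(params.t12_ref, T, params.Q10, params.T_ref)
    return params.Ctot + (params.Cb - params.Ctot) * np.exp2(-t / t12)


class LikelihoodKernel:
    """Precomputed design arrays for fast repeated likelihood evaluation.

    The Q10 temperature scaling enters only through an effective
    incubation time day / Q10**(-(T - T_ref)/10), which is fixed by the
    design and precomputed once.
    """

    def __init__(self, dataset: TracerDataset, Q10: float = 2.0,
                 T_ref: float = 5.0):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        f = dataset.frame
        kind = f["kind"].to_numpy()
        y = f["activity_normalized"].to_numpy(float)
        test = kind == "test"
        q = Q10 ** (-(f["temperature_C"].to_numpy(float) - T_ref) / 10.0)
        self.day_scaled = f["day"].to_numpy(float)[test] / q[test]
        self.y_test = y[test]
        self.y_ctrl = y[kind == "control"]
        self.y_pre = y[kind == "pre"]
        self.n = len(y)

    def residual_ss(self, t12, cb, ctot):
        """Sum of squared residuals; arguments may be scalars or
        same-shaped arrays (then day_scaled broadcasts on a new axis)."""
        t12, cb, ctot = np.asarray(t12), np.asarray(cb), np.asarray(ctot)
        if t12.ndim:
            mean = (ctot[..., None] + (cb - ctot)[..., None]
                    * np.exp2(-self.day_scaled / t12[..., None]))
            ss = ((self.y_test - mean) ** 2).sum(axis=-1)
        else:
            mean = ctot + (cb - ctot) * np.exp2(-self.day_scaled / t12)
            ss = ((self.y_test - mean) ** 2).sum()
        ss = ss + ((self.y_ctrl - cb[..., None]) ** 2).sum(axis=-1)
        ss = ss + ((self.y_pre - ctot[..., None]) ** 2).sum(axis=-1)
        return ss

    def log_likelihood(self, theta):
        """Gaussian log-likelihood; theta is (..., 4)."""
        theta = np.asarray(theta, dtype=float)
        t12, cb, ctot, lns = np.moveaxis(theta, -1, 0)
        ss = self.residual_ss(t12, cb, ctot)
        return (-0.5 * ss * np.exp(-2.0 * lns)
                - self.n * lns - 0.5 * self.n * np.log(2.0 * np.pi))


def log_likelihood(params: KineticsParams, dataset: TracerDataset) -> float:
    """Gaussian log-likelihood with a single shared noise scale."""
    kernel = LikelihoodKernel(dataset, params.Q10, params.T_ref)
    return float(kernel.log_likelihood(params.free_vector()))


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class MLEFit:
    params: KineticsParams
    stderr: dict
    cov: np.ndarray
    neg_loglik: float
    success: bool
    message: str = ""

    def stderr_vector(self) -> np.ndarray:
        return np.array([self.stderr[p] for p in PARAM_NAMES])


def default_bounds(dataset: TracerDataset):
    """Uniform-prior bounds: half-life within its stated support, amplitudes
    non-negative with an upper bound of 10x the largest observed activity."""
    amax = 10.0 * max(float(dataset.activities.max()), 1e-12)
    return {
        "t12_ref": (HALFLIFE_MIN, HALFLIFE_MAX),
        "Cb": (0.0, amax),
        "Ctot": (0.0, amax),
        "ln_sigma": (-12.0, 5.0),
    }


def _initial_guess(dataset: TracerDataset, bounds) -> np.ndarray:
    act = dataset.activities
    cb0 = float(np.clip(act.min(), *bounds["Cb"]))
    ctot0 = float(np.clip(act.max(), *bounds["Ctot"]))
    lns0 = float(np.clip(np.log(max(act.std() / 4.0, 1e-6)), *bounds["ln_sigma"]))
    return np.array([10.0, cb0, ctot0, lns0])


def _hessian_fd(f, x, rel_step=1e-5):
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_mle(dataset: TracerDataset, bounds=None, template=None) -> MLEFit:
    """Maximum-likelihood fit of (t12_ref, Cb, Ctot, ln_sigma).

    Two-stage: bounded least squares for the three physical parameters,
    noise scale from the residuals, then a joint quasi-Newton polish of
    the full negative log-likelihood.  Standard errors come from the
    local curvature (finite-difference Hessian at the optimum).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    template = template or KineticsParams(10.0, 0.0, 1.0, 0.0)
    bounds = bounds or default_bounds(dataset)
    x0 = _initial_guess(dataset, bounds)
    kernel = LikelihoodKernel(dataset, template.Q10, template.T_ref)

    def residuals(phys):
        t12, cb, ctot = phys
        mean = ctot + (cb - ctot) * np.exp2(-kernel.day_scaled / t12)
        return np.concatenate([kernel.y_test - mean,
                               kernel.y_ctrl - cb, kernel.y_pre - ctot])

    lo = [bounds[p][0] for p in PARAM_NAMES[:3]]
    hi = [bounds[p][1] for p in PARAM_NAMES[:3]]
    ls = optimize.least_squares(residuals, x0[:3], bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
    sigma2 = float(np.mean(ls.fun**2))
    lns = float(np.clip(0.5 * np.log(max(sigma2, 1e-300)), *bounds["ln_sigma"]))
    x1 = np.array([*ls.x, lns])

    def nll(theta):
        return -float(kernel.log_likelihood(theta))

    box = [bounds[p] for p in PARAM_NAMES]
    res = optimize.minimize(nll, x1, method="L-BFGS-B", bounds=box,
                            options={"ftol": 1e-15, "gtol": 1e-12,
                                     "maxiter": 5000})
    best = res.x if res.fun <= nll(x1) else x1
    if not (res.success or ls.success):
        raise ConvergenceError(f"MLE did not converge: {res.message}")

    H = _hessian_fd(nll, best)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        stderr_vec = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
        stderr_vec = np.full(4, np.nan)

    params = template.with_free_vector(best)
    return MLEFit(
        params=params,
        stderr=dict(zip(PARAM_NAMES, stderr_vec)),
        cov=cov,
        neg_loglik=float(nll(best)),
        success=True,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Posterior sampling
# ---------------------------------------------------------------------------

@dataclass
class UniformPriors:
    """Independent uniform priors; a box in parameter space."""

    t12_ref: tuple = (HALFLIFE_MIN, HALFLIFE_MAX)
    Cb: tuple = (0.0, 10.0)
    Ctot: tuple = (0.0, 10.0)
    ln_sigma: tuple = (-10.0, 5.0)

    @classmethod
    def from_dataset(cls, dataset: TracerDataset) -> "UniformPriors":
        amax = 10.0 * max(float(dataset.activities.max()), 1e-12)
        return cls(Cb=(0.0, amax), Ctot=(0.0, amax))

    def as_array(self) -> np.ndarray:
        return np.array([self.t12_ref, self.Cb, self.Ctot, self.ln_sigma])

    def log_prior(self, theta) -> float:
        box = self.as_array()
        if np.all((theta >= box[:, 0]) & (theta <= box[:, 1])):
            return 0.0
        return -np.inf

    def sample(self, rng, n) -> np.ndarray:
        box = self.as_array()
        return rng.uniform(box[:, 0], box[:, 1], size=(n, 4))


@dataclass
class PosteriorResult:
    summary: pd.DataFrame            # index: parameter; mle, stderr, p16, p50, p84
    chain: np.ndarray                # (step, walker, parameter), post burn-in
    full_chain: np.ndarray           # (step, walker, parameter)
    acceptance_fraction: float
    autocorr_time: np.ndarray
    ess: float
    converged: bool
    mle: MLEFit | None = None
    Q10: float = 2.0
    T_ref: float = 5.0

    @property
    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    def median_params(self) -> KineticsParams:
        p50 = self.summary["p50"]
        return KineticsParams(p50["t12_ref"], p50["Cb"], p50["Ctot"],
                              p50["ln_sigma"], Q10=self.Q10, T_ref=self.T_ref)

    def to_csv(self, path):
        self.summary.rename_axis("parameter").to_csv(path)

    def chain_to_netcdf(self, path):
        da = xr.DataArray(
            np.transpose(self.full_chain, (1, 0, 2)),
            dims=("walker", "step", "parameter"),
            coords={"parameter": list(PARAM_NAMES)},
            name="chain",
        )
        da.to_netcdf(path, engine="scipy")


def sample_posterior(dataset: TracerDataset, priors: UniformPriors | None = None,
                     seed: int = 0, n_walkers: int = 32, n_steps: int = 5000,
                     n_burn: int = 1000, use_likelihood: bool = True,
                     Q10: float = 2.0, T_ref: float = 5.0) -> PosteriorResult:
    """Affine-invariant ensemble MCMC over the kinetics posterior.

    Uniform priors are respected exactly (walkers never leave the box);
    setting use_likelihood=False samples the prior alone, which is a
    useful sanity check of the machinery.  Reproducible for fixed seed.
    """
    if n_walkers <= 0 or n_steps <= 0 or n_burn < 0 or n_burn >= n_steps:
        raise ValueError("chain settings must be positive with n_burn < n_steps")
    priors = priors or UniformPriors.from_dataset(dataset)
    kernel = LikelihoodKernel(dataset, Q10, T_ref)
    box = priors.as_array()

    def log_prob(theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        inbox = np.all((theta >= box[:, 0]) & (theta <= box[:, 1]), axis=1)
        out = np.full(len(theta), -np.inf)
        if use_likelihood:
            if inbox.any():
                out[inbox] = kernel.log_likelihood(theta[inbox])
        else:
            out[inbox] = 0.0
        return out

    rng = np.random.default_rng(seed)
    mle = None
    if use_likelihood:
        try:
            mle = fit_mle(dataset)
            centre = np.clip(mle.params.free_vector(),
                             priors.as_array()[:, 0], priors.as_array()[:, 1])
            scale = 1e-3 * np.maximum(np.abs(centre), 0.1)
            p0 = centre + scale * rng.standard_normal((n_walkers, 4))
            box = priors.as_array()
            p0 = np.clip(p0, box[:, 0] + 1e-9, box[:, 1] - 1e-9)
        except ConvergenceError:
            p0 = priors.sample(rng, n_walkers)
    else:
        p0 = priors.sample(rng, n_walkers)

    sampler = emcee.EnsembleSampler(n_walkers, 4, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    full_chain = sampler.get_chain()           # (step, walker, param)
    chain = full_chain[n_burn:]
    flat = chain.reshape(-1, 4)

    acc = float(np.mean(sampler.acceptance_fraction))
    try:
        logging.getLogger("emcee.autocorr").setLevel(logging.ERROR)
        tau = sampler.get_autocorr_time(discard=n_burn, quiet=True)
    except Exception:
        tau = np.full(4, np.nan)
    with np.errstate(invalid="ignore"):
        ess = float(flat.shape[0] / np.nanmax(tau)) if np.any(np.isfinite(tau)) \
            else np.nan
    converged = bool(0.05 < acc < 0.9
                     and np.all(np.isfinite(tau))
                     and (n_steps - n_burn) > 20 * np.nanmax(tau))

    p16, p50, p84 = np.percentile(flat, [16, 50, 84], axis=0)
    summary = pd.DataFrame(
        {
            "mle": mle.params.free_vector() if mle else np.full(4, np.nan),
            "stderr": mle.stderr_vector() if mle else np.full(4, np.nan),
            "p16": p16,
            "p50": p50,
            "p84": p84,
        },
        index=list(PARAM_NAMES),
    )
    return PosteriorResult(summary=summary, chain=chain, full_chain=full_chain,
                           acceptance_fraction=acc, autocorr_time=tau, ess=ess,
                           converged=converged, mle=mle, Q10=Q10, T_ref=T_ref)
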