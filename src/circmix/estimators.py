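"""Scikit-learn-style estimators for the recall-error mixture models.

Each estimator follows the density-estimator contract: ``fit(X)`` on a
matrix of wrapped response errors (column 0 = error to the target,
remaining columns = errors to each non-target, NaN-padded),
``score_samples`` / ``score`` for per-trial and total log-likelihood, and
fitted attributes with trailing underscores (``kappa_``, ``p_u_``, ...).

Fitting is maximum likelihood by the Nelder-Mead simplex, started from a
deterministic grid of parameter permutations (kappa in {1, 10, 100};
mixture probabilities in {0.01, 0.1, 0.4}; capacity K in {1, 2, 4} for
the slots family) to avoid local minima, keeping the lowest converged
negative log-likelihood with ties broken by grid order.  The search runs
on an unconstrained scale — log kappa, log K, and an additive log-ratio
transform of the probability simplex — so the simplex never has to cope
with hard bounds.

kappa is searched inside (1e-3, 100) by default.  The upper bound is an
identifiability guard, not a modelling assumption: the unbounded mixture
likelihood admits degenerate "spike" optima (kappa in the hundreds
fitting a handful of near-identical errors, the circular analogue of the
classic Gaussian-mixture variance collapse), which at low trial counts
otherwise swamp parameter recovery.  kappa = 100 corresponds to a
circular SD under 6 degrees, far more precise than any human
continuous-report data; raise ``kappa_bounds`` explicitly if your
paradigm warrants it.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, i0e
from sklearn.base import BaseEstimator, DensityMixin

from .models import MODELS, TrialErrors, spa_component_kappas

__all__ = [
    "TwoComponentModel",
    "ThreeComponentModel",
    "SlotsModel",
    "SlotsPlusAveragingModel",
    "estimator_for",
]

_TWO_PI = 2.0 * np.pi


class FitError(RuntimeError):
    """Raised when no optimiser start converges to a finite optimum."""


def _as_trial_errors(X, set_size=None) -> TrialErrors:
    if isinstance(X, TrialErrors):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (n_trials, 1 + k) error matrix")
    if np.isnan(X[:, 0]).any():
        raise ValueError("target-error column (X[:, 0]) may not contain NaN")
    return TrialErrors(X[:, 0], X[:, 1:], set_size=set_size)


def _nm_options(tol: float, max_iter: int) -> dict:
    return {"xatol": 1e-6, "fatol": tol, "maxiter": max_iter, "maxfev": 4 * max_iter}


def _multistart(objective, starts, tol, max_iter):
    """Run Nelder-Mead from every start; return (best_x, best_fun, index, n_ok)."""
    best = (None, np.inf, -1)
    n_ok = 0
    opts = _nm_options(tol, max_iter)
    for i, x0 in enumerate(starts):
        res = minimize(objective, x0, method="Nelder-Mead", options=opts)
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best[1]:
                best = (res.x, float(res.fun), i)
    if best[0] is None:
        raise FitError("all optimiser starts failed to reach a finite optimum")
    return best + (n_ok,)


class _MixtureEstimatorBase(DensityMixin, BaseEstimator):
    """Shared multi-start ML machinery; subclasses define the likelihood."""

    _model: str = ""

    def __init__(
        self,
        kappa_starts=(1.0, 10.0, 100.0),
        prob_starts=(0.01, 0.1, 0.4),
        K_starts=(1.0, 2.0, 4.0),
        kappa_bounds=(1e-3, 1e2),
        K_bounds=(1e-4, 64.0),
        tol=1e-8,
        max_iter=2000,
    ):
        self.kappa_starts = kappa_starts
        self.prob_starts = prob_starts
        self.K_starts = K_starts
        self.kappa_bounds = kappa_bounds
        self.K_bounds = K_bounds
        self.tol = tol
        self.max_iter = max_iter

    # -- subclass hooks -------------------------------------------------
    def _starts(self, err: TrialErrors) -> np.ndarray:
        raise NotImplementedError

    def _objective(self, err: TrialErrors):
        raise NotImplementedError

    def _unpack(self, x: np.ndarray, err: TrialErrors) -> dict:
        raise NotImplementedError

    @property
    def n_params_(self) -> int:
        raise NotImplementedError

    # -- shared API ------------------------------------------------------
    def fit(self, X, y=None, set_size=None):
        """Maximum-likelihood fit to an error matrix.

        Parameters
        ----------
        X : array-like of shape (n_trials,) or (n_trials, 1 + k)
            Column 0: wrapped response error to the target.  Columns 1..k:
            wrapped error to each non-target, NaN where absent.
        set_size : int or array-like, optional
            Per-trial set size (slots family); inferred as 1 + number of
            non-missing non-targets when omitted.
        """
        err = _as_trial_errors(X, set_size=set_size)
        if err.n_trials < 2:
            raise ValueError("fitting requires at least 2 trials")
        objective = self._objective(err)
        starts = self._starts(err)
        x, fun, idx, n_ok = _multistart(objective, starts, self.tol, self.max_iter)
        for name, value in self._unpack(x, err).items():
            setattr(self, name + "_", value)
        self.nll_ = fun
        self.log_likelihood_ = -fun
        self.n_trials_ = err.n_trials
        self.best_start_ = int(idx)
        self.n_converged_starts_ = int(n_ok)
        self.n_features_in_ = 1 + err.nontarget_errors.shape[1]
        return self

    def _params_dict(self) -> dict:
        raise NotImplementedError

    def score_samples(self, X, set_size=None):
        """Per-trial log-likelihood under the fitted parameters."""
        err = _as_trial_errors(X, set_size=set_size)
        dens = self._density(err)
        with np.errstate(divide="ignore"):
            return np.log(np.atleast_1d(dens))

    def _density(self, err: TrialErrors) -> np.ndarray:
        from . import models

        p = self._params_dict()
        if self._model == "2_component":
            return np.atleast_1d(models.density_two_component(err, **p))
        if self._model == "3_component":
            return np.atleast_1d(models.density_three_component(err, **p))
        if self._model == "slots":
            return np.atleast_1d(models.slots_density(err, **p))
        return np.atleast_1d(models.spa_density(err, **p))

    def score(self, X, y=None):
        """Total log-likelihood of ``X`` (sum over trials)."""
        return float(self.score_samples(X).sum())

    def sample(self, n_samples: int = 1, set_size: int = 4, random_state=None):
        """Simulate a trial table from the fitted parameters."""
        from .simulate import simulate_mixtur

        kw = self._params_dict().copy()
        kw.pop("set_size", None)
        return simulate_mixtur(
            model=self._model,
            n_trials=n_samples,
            set_size=set_size,
            seed=random_state,
            **kw,
        )


def _vm_dens(cos_x, kappa):
    return np.exp(kappa * (cos_x - 1.0)) / (_TWO_PI * i0e(kappa))


class TwoComponentModel(_MixtureEstimatorBase):
    """Target-plus-guessing mixture (free parameters: kappa, p_u)."""

    _model = "2_component"

    @property
    def n_params_(self) -> int:
        return 2

    def _starts(self, err):
        return np.array(
            [
                [np.log(k), np.log(p / (1.0 - p))]
                for k in self.kappa_starts
                for p in self.prob_starts
            ]
        )

    def _objective(self, err):
        cos_t = err._cos_target
        lo, hi = np.log(self.kappa_bounds[0]), np.log(self.kappa_bounds[1])

        def nll(x):
            if not (lo <= x[0] <= hi):
                return np.inf
            kappa = np.exp(x[0])
            p_u = expit(x[1])
            dens = (1.0 - p_u) * _vm_dens(cos_t, kappa) + p_u / _TWO_PI
            if np.any(dens <= 0.0):
                return np.inf
            return -np.log(dens).sum()

        return nll

    def _unpack(self, x, err):
        p_u = float(expit(x[1]))
        return {"kappa": float(np.exp(x[0])), "p_u": p_u, "p_t": 1.0 - p_u}

    def _params_dict(self):
        return {"kappa": self.kappa_, "p_u": self.p_u_}


class ThreeComponentModel(_MixtureEstimatorBase):
    """Target + swap + guessing mixture (free parameters: kappa, p_u, p_n).

    The swap component shares the target component's kappa.  Cells in
    which no trial has a non-target (set size 1) are fitted with p_n
    fixed at 0, in which case the model coincides with the two-component
    model.  In cells mixing set size 1 with larger set sizes, the swap
    probability falls back to guessing on the non-target-free trials.
    """

    _model = "3_component"

    @property
    def n_params_(self) -> int:
        return 3

    def _starts(self, err):
        if int(err.n_nontargets.max()) == 0:
            return np.array(
                [
                    [np.log(k), np.log(p / (1.0 - p))]
                    for k in self.kappa_starts
                    for p in self.prob_starts
                ]
            )
        starts = []
        for k in self.kappa_starts:
            for p_u in self.prob_starts:
                for p_n in self.prob_starts:
                    p_t = 1.0 - p_u - p_n
                    starts.append([np.log(k), np.log(p_u / p_t), np.log(p_n / p_t)])
        return np.array(starts)

    def _objective(self, err):
        cos_t = err._cos_target
        cos_nt = err._cos_nontarget
        counts = err.n_nontargets
        has_nt = counts > 0
        lo, hi = np.log(self.kappa_bounds[0]), np.log(self.kappa_bounds[1])
        fix_p_n = int(counts.max()) == 0
        mask = err._nt_mask

        if fix_p_n:
            def nll(x):
                if not (lo <= x[0] <= hi):
                    return np.inf
                kappa = np.exp(x[0])
                p_u = expit(x[1])
                dens = (1.0 - p_u) * _vm_dens(cos_t, kappa) + p_u / _TWO_PI
                if np.any(dens <= 0.0):
                    return np.inf
                return -np.log(dens).sum()

            return nll

        safe_counts = np.where(has_nt, counts, 1)

        def nll(x):
            if not (lo <= x[0] <= hi):
                return np.inf
            kappa = np.exp(x[0])
            # clip the log-ratio coordinates so exp never overflows
            ea, eb = np.exp(np.clip(x[1], -300.0, 300.0)), np.exp(np.clip(x[2], -300.0, 300.0))
            denom = 1.0 + ea + eb
            p_u, p_n = ea / denom, eb / denom
            p_t = 1.0 - p_u - p_n
            dens = p_t * _vm_dens(cos_t, kappa) + p_u / _TWO_PI
            swap = (_vm_dens(cos_nt, kappa) * mask).sum(axis=1) / safe_counts
            # trials without non-targets: swap mass degrades to guessing
            dens = dens + p_n * np.where(has_nt, swap, 1.0 / _TWO_PI)
            if np.any(dens <= 0.0) or not np.all(np.isfinite(dens)):
                return np.inf
            return -np.log(dens).sum()

        return nll

    def _unpack(self, x, err):
        kappa = float(np.exp(x[0]))
        if len(x) == 2:  # p_n fixed at zero (no non-targets anywhere)
            p_u = float(expit(x[1]))
            return {"kappa": kappa, "p_u": p_u, "p_n": 0.0, "p_t": 1.0 - p_u}
        ea, eb = np.exp(x[1]), np.exp(x[2])
        denom = 1.0 + ea + eb
        p_u, p_n = float(ea / denom), float(eb / denom)
        return {"kappa": kappa, "p_u": p_u, "p_n": p_n, "p_t": 1.0 - p_u - p_n}

    def _params_dict(self):
        return {"kappa": self.kappa_, "p_u": self.p_u_, "p_n": self.p_n_}


class _SlotsBase(_MixtureEstimatorBase):
    @property
    def n_params_(self) -> int:
        return 2

    def _starts(self, err):
        return np.array(
            [[np.log(k), np.log(K)] for k in self.kappa_starts for K in self.K_starts]
        )

    def _unpack(self, x, err):
        return {"kappa": float(np.exp(x[0])), "K": float(np.exp(x[1]))}

    def _params_dict(self):
        return {"K": self.K_, "kappa": self.kappa_}


class SlotsModel(_SlotsBase):
    """Discrete-capacity slots model (free parameters: K, kappa)."""

    _model = "slots"

    def _objective(self, err):
        cos_t = err._cos_target
        N = np.asarray(err.set_size, dtype=float)
        klo, khi = np.log(self.kappa_bounds[0]), np.log(self.kappa_bounds[1])
        Klo, Khi = np.log(self.K_bounds[0]), np.log(self.K_bounds[1])

        def nll(x):
            if not (klo <= x[0] <= khi and Klo <= x[1] <= Khi):
                return np.inf
            kappa, K = np.exp(x[0]), np.exp(x[1])
            p_u = np.maximum(0.0, 1.0 - K / N)
            dens = (1.0 - p_u) * _vm_dens(cos_t, kappa) + p_u / _TWO_PI
            if np.any(dens <= 0.0):
                return np.inf
            return -np.log(dens).sum()

        return nll


class SlotsPlusAveragingModel(_SlotsBase):
    """Slots model with averaging of duplicate copies when K > set size."""

    _model = "slots_averaging"

    def _objective(self, err):
        cos_t = err._cos_target
        N = np.asarray(err.set_size, dtype=int)
        uniq = np.unique(N)
        groups = [(int(n), N == n) for n in uniq]
        klo, khi = np.log(self.kappa_bounds[0]), np.log(self.kappa_bounds[1])
        Klo, Khi = np.log(self.K_bounds[0]), np.log(self.K_bounds[1])

        def nll(x):
            if not (klo <= x[0] <= khi and Klo <= x[1] <= Khi):
                return np.inf
            kappa, K = np.exp(x[0]), np.exp(x[1])
            total = 0.0
            for n, sel in groups:
                c = cos_t[sel]
                if K <= n:
                    p_u = max(0.0, 1.0 - K / n)
                    dens = (1.0 - p_u) * _vm_dens(c, kappa) + p_u / _TWO_PI
                else:
                    _, _, f_high, k_low, k_high = spa_component_kappas(K, kappa, n)
                    dens = (1.0 - f_high) * _vm_dens(c, k_low)
                    if f_high > 0:
                        dens = dens + f_high * _vm_dens(c, k_high)
                if np.any(dens <= 0.0):
                    return np.inf
                total -= np.log(dens).sum()
            return total

        return nll


_ESTIMATORS = {
    "2_component": TwoComponentModel,
    "3_component": ThreeComponentModel,
    "slots": SlotsModel,
    "slots_averaging": SlotsPlusAveragingModel,
}


def estimator_for(model: str, **kwargs):
    """Instantiate the estimator class registered for a model tag."""
    if model not in _ESTIMATORS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _ESTIMATORS[model](**kwargs)
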