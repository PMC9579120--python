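"""Mixture-model densities for continuous-report recall errors.

Two measurement models and two explanatory (slots-family) models:

* two-component: target responses (von Mises around the target) plus
  uniform guessing;
* three-component: additionally, swap responses centred on non-target
  feature values, sharing the target component's concentration kappa;
* slots: a re-parameterisation of the two-component model in which the
  guess rate follows from a discrete capacity K, p_u = max(0, 1 - K/N)
  for set size N;
* slots-plus-averaging: when K exceeds the set size, surplus slots hold
  duplicate copies of items and the report averages an item's copies,
  shrinking its circular SD by sqrt(m) for m copies.

Densities are evaluated in exponentially scaled form so concentrations in
the thousands neither overflow nor lose the mixture's uniform floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e

from .angles import kappa_to_sd, sd_to_kappa, wrap_angle

__all__ = [
    "MODELS",
    "TrialErrors",
    "density_two_component",
    "density_three_component",
    "slots_density",
    "spa_density",
    "negative_log_likelihood",
    "spa_component_kappas",
]

#: Model tags accepted throughout the package (fit, simulate, CLI).
MODELS = ("2_component", "3_component", "slots", "slots_averaging")

_TWO_PI = 2.0 * np.pi


def _check_probs(p_u: float, p_n: float = 0.0) -> None:
    if not (0.0 <= p_u <= 1.0 and 0.0 <= p_n <= 1.0 and p_u + p_n <= 1.0 + 1e-12):
        raise ValueError(
            f"invalid mixture weights p_u={p_u}, p_n={p_n}; "
            "require p_u, p_n in [0,1] and p_u + p_n <= 1"
        )


def _check_kappa(kappa: float) -> None:
    if not (kappa >= 0 and np.isfinite(kappa)):
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")


@dataclass
class TrialErrors:
    """Wrapped response errors for a block of trials.

    ``target_error[t]`` is response minus target for trial ``t``;
    ``nontarget_errors[t, i]`` is response minus the i-th non-target,
    NaN-padded for trials with fewer non-targets.
    """

    target_error: np.ndarray
    nontarget_errors: np.ndarray  # shape (n_trials, k_max); NaN = missing
    set_size: np.ndarray | None = None

    # caches used by the fitting hot loop
    _cos_target: np.ndarray = field(default=None, repr=False)
    _cos_nontarget: np.ndarray = field(default=None, repr=False)
    _nt_mask: np.ndarray = field(default=None, repr=False)
    _nt_count: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        te = wrap_angle(np.atleast_1d(np.asarray(self.target_error, float)))
        nte = np.asarray(self.nontarget_errors, dtype=float)
        if nte.ndim == 1:
            nte = nte.reshape(len(te), -1)
        if nte.shape[0] != te.shape[0]:
            raise ValueError("target_error and nontarget_errors disagree on n_trials")
        with np.errstate(invalid="ignore"):
            nte = wrap_angle(nte) if nte.size else nte
        self.target_error = te
        self.nontarget_errors = nte
        mask = np.isfinite(nte)
        self._cos_target = np.cos(te)
        self._cos_nontarget = np.where(mask, np.cos(nte), 0.0)
        self._nt_mask = mask
        self._nt_count = mask.sum(axis=1)
        if self.set_size is None:
            self.set_size = self._nt_count + 1
        else:
            self.set_size = np.broadcast_to(
                np.asarray(self.set_size, dtype=int), te.shape
            ).copy()

    @property
    def n_trials(self) -> int:
        return self.target_error.shape[0]

    @property
    def n_nontargets(self) -> np.ndarray:
        """Per-trial count of non-missing non-target errors (the n of the swap term)."""
        return self._nt_count


def _as_errors(e) -> TrialErrors:
    if isinstance(e, TrialErrors):
        return e
    te = np.atleast_1d(np.asarray(e, dtype=float))
    if te.ndim == 2:
        return TrialErrors(te[:, 0], te[:, 1:])
    return TrialErrors(te, np.empty((te.shape[0], 0)))


def _vm_density_from_cos(cos_x: np.ndarray, kappa: float) -> np.ndarray:
    # exp(kappa*(cos-1)) / (2 pi I0e(kappa)): scaled von Mises density
    return np.exp(kappa * (cos_x - 1.0)) / (_TWO_PI * i0e(kappa))


def density_two_component(e, kappa: float, p_u: float) -> np.ndarray:
    """Per-trial likelihood under the target + uniform-guess mixture."""
    _check_kappa(kappa)
    _check_probs(p_u)
    err = _as_errors(e)
    out = (1.0 - p_u) * _vm_density_from_cos(err._cos_target, kappa) + p_u / _TWO_PI
    return out if out.shape[0] > 1 else float(out[0])


def density_three_component(e, kappa: float, p_u: float, p_n: float) -> np.ndarray:
    """Per-trial likelihood under the target + swap + guess mixture.

    The swap term averages von Mises densities centred on each non-target,
    all sharing the target component's kappa.  Trials without non-targets
    are rejected when p_n > 0 (the swap component would be undefined).
    """
    _check_kappa(kappa)
    _check_probs(p_u, p_n)
    err = _as_errors(e)
    if p_n > 0 and np.any(err._nt_count == 0):
        raise ValueError(
            "p_n > 0 requires at least one non-target per trial; "
            "fit set-size-1 cells with p_n fixed at 0"
        )
    p_t = 1.0 - p_u - p_n
    out = p_t * _vm_density_from_cos(err._cos_target, kappa) + p_u / _TWO_PI
    if p_n > 0:
        nt = _vm_density_from_cos(err._cos_nontarget, kappa) * err._nt_mask
        out = out + p_n * nt.sum(axis=1) / err._nt_count
    return out if out.shape[0] > 1 else float(out[0])


def _slots_pu(K: float, set_size) -> np.ndarray:
    return np.maximum(0.0, 1.0 - K / np.asarray(set_size, dtype=float))


def slots_density(e, K: float, kappa: float, set_size=None) -> np.ndarray:
    """Slots-model likelihood: two-component with p_u = max(0, 1 - K/N)."""
    _check_kappa(kappa)
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    err = _as_errors(e)
    N = err.set_size if set_size is None else np.asarray(set_size)
    if np.any(np.asarray(N) < 1):
        raise ValueError("set_size must be >= 1")
    p_u = _slots_pu(K, N)
    out = (1.0 - p_u) * _vm_density_from_cos(err._cos_target, kappa) + p_u / _TWO_PI
    return out if out.shape[0] > 1 else float(out[0])


def spa_component_kappas(K: float, kappa: float, set_size: int):
    """Copy counts and averaged concentrations for slots-plus-averaging.

    Returns ``(m_low, m_high, f_high, kappa_low, kappa_high)``: a fraction
    ``f_high`` of items hold ``m_high`` copies, the rest ``m_low``.  An
    item averaged over m copies responds with concentration
    sd_to_kappa(sd(kappa)/sqrt(m)).  K is continuous; the copy split
    f_high = (K mod N)/N interpolates linearly between integer capacities.
    """
    N = int(set_size)
    q = K / N
    m_low = int(np.floor(q))
    f_high = q - m_low
    m_high = m_low + 1
    sd1 = kappa_to_sd(kappa)

    def _k(m):
        if m <= 0:
            return 0.0
        if m == 1:
            return kappa
        return sd_to_kappa(sd1 / np.sqrt(m))

    return m_low, m_high, f_high, _k(m_low), _k(m_high)


def spa_density(e, K: float, kappa: float, set_size=None) -> np.ndarray:
    """Slots-plus-averaging likelihood.

    For K <= N this is exactly the slots model.  For K > N every item is
    stored; items with m copies are reported from the average of the
    copies, i.e. with circular SD shrunk by sqrt(m), and the probed item
    has m_high copies with probability f_high.
    """
    _check_kappa(kappa)
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    err = _as_errors(e)
    N = err.set_size if set_size is None else np.broadcast_to(
        np.asarray(set_size, dtype=int), err.target_error.shape
    )
    N = np.asarray(N)
    if np.any(N < 1):
        raise ValueError("set_size must be >= 1")
    out = np.empty(err.n_trials)
    for n in np.unique(N):
        sel = N == n
        cos_t = err._cos_target[sel]
        if K <= n:
            p_u = max(0.0, 1.0 - K / n)
            out[sel] = (1.0 - p_u) * _vm_density_from_cos(cos_t, kappa) + p_u / _TWO_PI
        else:
            m_low, _, f_high, k_low, k_high = spa_component_kappas(K, kappa, int(n))
            dens = (1.0 - f_high) * _vm_density_from_cos(cos_t, k_low)
            if f_high > 0:
                dens = dens + f_high * _vm_density_from_cos(cos_t, k_high)
            out[sel] = dens
    return out if out.shape[0] > 1 else float(out[0])


def negative_log_likelihood(e, model: str, params: dict) -> float:
    """-sum(log density) over trials for the tagged model.

    Out-of-bound parameter proposals return +inf (so gradient-free
    optimisers simply step away), as does a density that underflows to
    zero at some trial.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    err = _as_errors(e)
    if err.n_trials == 0:
        raise ValueError("negative_log_likelihood requires at least one trial")
    try:
        if model == "2_component":
            dens = density_two_component(err, params["kappa"], params["p_u"])
        elif model == "3_component":
            dens = density_three_component(
                err, params["kappa"], params["p_u"], params.get("p_n", 0.0)
            )
        elif model == "slots":
            dens = slots_density(err, params["K"], params["kappa"])
        else:
            dens = spa_density(err, params["K"], params["kappa"])
    except ValueError:
        return np.inf
    dens = np.atleast_1d(dens)
    if np.any(dens <= 0.0) or np.any(~np.isfinite(dens)):
        return np.inf
    return float(-np.log(dens).sum())
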