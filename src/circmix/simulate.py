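"""Trial-level simulation of continuous-report experiments.

``generate_stimuli`` draws the per-trial feature values (target plus
non-targets) on an integer-degree grid (1-360), optionally constrained
so that all pairwise circular separations are at least, or exactly, a
given number of degrees.  ``simulate_mixtur`` then draws a latent
response component per trial (target / non-target / guess, or the slots
analogues) and a response around the chosen feature value, returning a
trial table in canonical radians.

All randomness flows through a single ``numpy`` Generator, so a fixed
seed reproduces the table bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import wrap_angle
from .data import TrialTable
from .models import MODELS, spa_component_kappas

__all__ = ["generate_stimuli", "simulate_mixtur", "simulate_errors"]

_TWO_PI = 2.0 * np.pi


#: Default placement policy: all feature values at least 20 degrees apart,
#: the conventional discriminability constraint in continuous-report designs.
DEFAULT_SEPARATION = ("min", 20.0)


def _parse_separation(separation):
    """Normalise the separation policy to (kind, degrees)."""
    if separation is None:
        return DEFAULT_SEPARATION
    if separation == "unconstrained":
        return ("unconstrained", None)
    if isinstance(separation, str):
        kind, _, value = separation.partition(":")
        separation = (kind, float(value))
    kind, value = separation
    if kind not in ("min", "fixed"):
        raise ValueError(
            f"unknown separation policy {kind!r}; expected 'min' or 'fixed'"
        )
    return (kind, float(value))


def _min_separated_degrees(n_trials, set_size, d, rng):
    """Integer-degree values with all pairwise circular separations >= d.

    Sampled by construction rather than naive rejection: consecutive gaps
    around the circle are d plus a uniformly random integer composition
    of the slack 360 - set_size*d, followed by a random rotation and a
    random permutation of item positions.  (Pairwise separation >= d is
    equivalent to all consecutive gaps >= d.)
    """
    slack = 360 - set_size * d
    # cut-point representation of a uniform composition of `slack` into set_size parts
    cuts = np.sort(
        rng.integers(0, slack + 1, size=(n_trials, set_size - 1)), axis=1
    ) if set_size > 1 else np.zeros((n_trials, 0), dtype=int)
    parts = np.diff(
        np.concatenate(
            [np.zeros((n_trials, 1), int), cuts, np.full((n_trials, 1), slack)], axis=1
        ),
        axis=1,
    )
    gaps = parts + int(d)
    start = rng.integers(1, 361, size=(n_trials, 1))
    values = start + np.concatenate(
        [np.zeros((n_trials, 1), int), np.cumsum(gaps[:, :-1], axis=1)], axis=1
    )
    values = (values - 1) % 360 + 1
    # random assignment of which position is the (probed) target
    perm = np.argsort(rng.random(values.shape), axis=1)
    return np.take_along_axis(values, perm, axis=1)


def generate_stimuli(n_trials: int, set_size: int, separation=None, rng=None):
    """Per-trial target and non-target feature values, in radians.

    Returns ``(targets, non_targets)`` with shapes ``(n_trials,)`` and
    ``(n_trials, set_size - 1)``.  Values are drawn on the integer-degree
    grid 1-360 and converted to radians.  Policies: ``("min", d)``
    (uniform subject to all pairwise circular separations >= d; the
    default is d = 20), ``("fixed", d)`` (consecutive values exactly d
    degrees apart ascending from a random start, which is the probed
    item), ``"unconstrained"`` (uniform without replacement).
    """
    if set_size < 1:
        raise ValueError(f"set_size must be >= 1, got {set_size}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(rng)
    kind, d = _parse_separation(separation)
    if kind != "unconstrained" and d * set_size > 360:
        raise ValueError(
            f"separation of {d} deg is infeasible for set size {set_size} on a 360-deg circle"
        )
    if kind == "unconstrained":
        # uniform without replacement per trial: draw with replacement and
        # redraw the (few) rows containing duplicates
        degrees = rng.integers(1, 361, size=(n_trials, set_size))
        if set_size > 1:
            while True:
                dup = (np.diff(np.sort(degrees, axis=1), axis=1) == 0).any(axis=1)
                if not dup.any():
                    break
                degrees[dup] = rng.integers(1, 361, size=(int(dup.sum()), set_size))
    elif kind == "fixed":
        # probed item at the random start; non-targets ascend from it at
        # exact spacing d (e.g. d=5 from start 17 gives 17, 22, 27, 32)
        start = rng.integers(1, 361, size=(n_trials, 1))
        degrees = ((start + d * np.arange(set_size) - 1) % 360 + 1).astype(int)
    else:
        degrees = _min_separated_degrees(n_trials, set_size, d, rng)
    radians = wrap_angle(np.deg2rad(degrees.astype(float)))
    return radians[:, 0], radians[:, 1:]


def _stratified_counts(weights, n, rng):
    """Split ``n`` trials over components in exact proportion to ``weights``.

    Largest-remainder rounding (ties broken at random) so the realised
    component frequencies match the mixture weights as closely as integer
    counts allow: the simulator reproduces the *parameters*, not a
    binomial draw around them.
    """
    weights = np.asarray(weights, dtype=float)
    exact = weights * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short > 0:
        remainders = exact - counts + rng.random(len(weights)) * 1e-9
        counts[np.argsort(-remainders)[:short]] += 1
    return counts


def _component_kappa_and_mu(model, params, targets, non_targets, set_size, rng):
    """Latent component assignment: (mu, kappa, is_guess) arrays per trial.

    Component counts are stratified (exact proportions, randomly
    interleaved); within the swap component the imitated non-target is
    drawn uniformly per trial.
    """
    n = targets.shape[0]
    kappa = float(params["kappa"])
    if model in ("2_component", "3_component"):
        p_u = float(params["p_u"])
        p_n = float(params.get("p_n", 0.0) or 0.0)
        if model == "2_component":
            p_n = 0.0
        if p_n > 0 and set_size < 2:
            raise ValueError("p_n > 0 requires set_size >= 2")
        p_t = 1.0 - p_u - p_n
        if p_t < -1e-12:
            raise ValueError(f"p_u + p_n must be <= 1, got {p_u + p_n}")
        n_t, n_n, n_u = _stratified_counts([max(p_t, 0.0), p_n, p_u], n, rng)
        labels = rng.permutation(np.repeat([0, 1, 2], [n_t, n_n, n_u]))
        is_swap = labels == 1
        mu = targets.copy()
        if is_swap.any():
            pick = rng.integers(0, set_size - 1, size=int(is_swap.sum()))
            mu[is_swap] = non_targets[is_swap, pick]
        return mu, np.full(n, kappa), labels == 2
    # slots family: guessing governed by capacity K
    K = float(params["K"])
    if model == "slots" or K <= set_size:
        p_u = max(0.0, 1.0 - K / set_size)
        n_s, n_u = _stratified_counts([1.0 - p_u, p_u], n, rng)
        is_guess = rng.permutation(np.repeat([False, True], [n_s, n_u]))
        return targets.copy(), np.full(n, kappa), is_guess
    # slots_averaging with spare capacity: per-trial copy count
    _, _, f_high, k_low, k_high = spa_component_kappas(K, kappa, set_size)
    n_lo, n_hi = _stratified_counts([1.0 - f_high, f_high], n, rng)
    high = rng.permutation(np.repeat([False, True], [n_lo, n_hi]))
    return targets.copy(), np.where(high, k_high, k_low), np.zeros(n, dtype=bool)


def simulate_errors(model, params, n_trials, set_size, separation=None, rng=None):
    """Fast path for the study harnesses: returns ``(targets, non_targets,
    responses)`` arrays without building a DataFrame."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    rng = np.random.default_rng(rng)
    targets, non_targets = generate_stimuli(n_trials, set_size, separation, rng)
    mu, kappa, is_guess = _component_kappa_and_mu(
        model, params, targets, non_targets, set_size, rng
    )
    responses = wrap_angle(rng.vonmises(mu, np.maximum(kappa, 1e-12)))
    if is_guess.any():
        responses[is_guess] = rng.uniform(-np.pi, np.pi, size=int(is_guess.sum()))
        responses = wrap_angle(responses)
    return targets, non_targets, responses


def _as_vector(value, n, name):
    if value is None:
        return None
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.repeat(arr, n)
    if arr.size != n:
        raise ValueError(
            f"{name} has length {arr.size} but {n} set size(s) were requested; "
            "provide one value per set size"
        )
    return arr


def simulate_mixtur(
    model: str = "2_component",
    kappa=None,
    p_u=None,
    p_n=None,
    K=None,
    n_trials: int = 500,
    set_size=4,
    separation=None,
    seed=None,
    participant_id=1,
) -> TrialTable:
    """Simulate a trial table from one of the mixture models.

    ``set_size`` may be a sequence, in which case every parameter must be
    scalar or a matching-length vector; trials are split equally across
    set sizes (remainder to the earliest) and randomly interleaved.
    Non-target feature values are always emitted for set sizes > 1, even
    for the two-component model where they do not influence responses.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    rng = np.random.default_rng(seed)
    set_sizes = np.atleast_1d(np.asarray(set_size, dtype=int))
    m = set_sizes.size
    kappa_v = _as_vector(kappa, m, "kappa")
    p_u_v = _as_vector(p_u, m, "p_u")
    p_n_v = _as_vector(p_n, m, "p_n")
    K_v = _as_vector(K, m, "K")
    if kappa_v is None:
        raise ValueError("kappa must be provided")
    counts = np.full(m, n_trials // m)
    counts[: n_trials % m] += 1  # equal allocation, remainder to earliest

    frames = []
    max_nt = int(set_sizes.max()) - 1
    for j, (s, cnt) in enumerate(zip(set_sizes, counts)):
        params = {"kappa": kappa_v[j]}
        if model in ("2_component", "3_component"):
            if p_u_v is None:
                raise ValueError("p_u must be provided for the measurement models")
            params["p_u"] = p_u_v[j]
            if model == "3_component":
                if p_n_v is None:
                    raise ValueError("p_n must be provided for the 3_component model")
                params["p_n"] = p_n_v[j]
        else:
            if K_v is None:
                raise ValueError("K must be provided for the slots models")
            params["K"] = K_v[j]
        targets, non_targets, responses = simulate_errors(
            model, params, int(cnt), int(s), separation, rng
        )
        df = pd.DataFrame(
            {
                "id": participant_id,
                "set_size": int(s),
                "target": targets,
                "response": responses,
            }
        )
        for i in range(max_nt):
            df[f"non_target_{i + 1}"] = (
                non_targets[:, i] if i < non_targets.shape[1] else np.nan
            )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if m > 1:  # interleave set sizes
        out = out.iloc[rng.permutation(len(out))].reset_index(drop=True)
    return TrialTable(out, unit="radians")
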