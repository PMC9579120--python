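"""Grouped maximum-likelihood fitting and information-criterion comparison.

`fit_mixtur` is the user-facing routine: it fits the requested model
independently to every participant x set-size x condition cell of a
trial table and returns one row of best-fitting parameters per cell
(plus log-likelihood, trial count and AIC/AICc/BIC when ``return_fit``).
The per-cell work is done by the estimators in
:mod:`circmix.estimators`; this module is a thin grouping/IO layer over
them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import ColumnMap, TrialTable
from .estimators import estimator_for
from .models import MODELS

__all__ = ["start_grid", "information_criteria", "compare_models", "fit_mixtur"]


def start_grid(model: str) -> list[dict]:
    """Deterministic multi-start grid on the natural parameter scale.

    All permutations of kappa in {1, 10, 100} with p_u (and p_n for the
    three-component model) in {0.01, 0.1, 0.4}; the slots family uses
    capacity starts K in {1, 2, 4}.
    """
    kappas = (1.0, 10.0, 100.0)
    probs = (0.01, 0.1, 0.4)
    if model == "2_component":
        return [{"kappa": k, "p_u": p} for k in kappas for p in probs]
    if model == "3_component":
        return [
            {"kappa": k, "p_u": pu, "p_n": pn}
            for k in kappas
            for pu in probs
            for pn in probs
        ]
    if model in ("slots", "slots_averaging"):
        return [{"kappa": k, "K": K} for k in kappas for K in (1.0, 2.0, 4.0)]
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def information_criteria(log_likelihood: float, n_params: int, n_trials: int) -> dict:
    """AIC, AICc and BIC from a maximised log-likelihood.

    AIC = -2 LL + 2p; AICc multiplies the penalty by n/(n - p - 1) and is
    reported as NaN when n <= p + 1; BIC = -2 LL + p ln(n).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    neg2ll = -2.0 * log_likelihood
    aic = neg2ll + 2.0 * n_params
    if n_trials > n_params + 1:
        aicc = neg2ll + 2.0 * n_params * (n_trials / (n_trials - n_params - 1))
    else:
        aicc = np.nan
    bic = neg2ll + n_params * np.log(n_trials)
    return {"AIC": float(aic), "AICc": float(aicc), "BIC": float(bic)}


def _extract_stats(fit) -> dict:
    """Accept a fitted estimator, a fit_mixtur row, or a plain mapping."""
    if hasattr(fit, "log_likelihood_"):
        ll, p, n = fit.log_likelihood_, fit.n_params_, fit.n_trials_
        return {"n_trials": n, **information_criteria(ll, p, n)}
    mapping = fit if isinstance(fit, dict) else dict(fit)
    if "AIC" in mapping and "BIC" in mapping:
        return mapping
    return {
        "n_trials": mapping["n_trials"],
        **information_criteria(
            mapping["log_likelihood"], mapping["n_params"], mapping["n_trials"]
        ),
    }


def compare_models(fit2, fit3, tol: float = 1e-6) -> dict:
    """AIC/BIC differences between two- and three-component fits to one cell.

    Differences are oriented two-component minus three-component, so
    positive values favour the three-component model.  Because the models
    are nested, the AIC difference can never legitimately fall below -2
    (the penalty gap when the likelihoods tie); a smaller value flags an
    optimiser failure in the three-component fit.
    """
    s2, s3 = _extract_stats(fit2), _extract_stats(fit3)
    if "n_trials" in s2 and "n_trials" in s3 and s2["n_trials"] != s3["n_trials"]:
        raise ValueError(
            "fits being compared cover different trial counts "
            f"({s2['n_trials']} vs {s3['n_trials']}); not the same data cell"
        )
    aic_diff = s2["AIC"] - s3["AIC"]
    bic_diff = s2["BIC"] - s3["BIC"]
    return {
        "AIC_difference": aic_diff,
        "BIC_difference": bic_diff,
        "winner_AIC": "3_component" if aic_diff > 0 else "2_component",
        "winner_BIC": "3_component" if bic_diff > 0 else "2_component",
        "bound_violated": aic_diff < -2.0 - tol,
    }


_PARAM_COLUMNS = {
    "2_component": ["kappa", "p_t", "p_u"],
    "3_component": ["kappa", "p_t", "p_n", "p_u"],
    "slots": ["K", "kappa"],
    "slots_averaging": ["K", "kappa"],
}


def fit_mixtur(
    data,
    model: str = "2_component",
    unit: str = "radians",
    id_var: str = "id",
    response_var: str = "response",
    target_var: str = "target",
    non_target_prefix: str = "non_target",
    set_size_var: str | None = None,
    condition_var: str | None = None,
    group_by=None,
    return_fit: bool = False,
    **estimator_kwargs,
) -> pd.DataFrame:
    """Fit a mixture model per participant (x set size x condition) cell.

    ``data`` may be a :class:`~circmix.data.TrialTable` or a raw
    long-format DataFrame (converted using the column/unit arguments).
    Cells with fewer than two trials are skipped with a warning.  With
    ``return_fit`` the log-likelihood, trial count and information
    criteria are appended to each row.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if isinstance(data, TrialTable):
        table = data
        if group_by is None:
            # default: split on whatever experimental structure the table has
            group_by = tuple(
                c
                for c in ("set_size", "condition")
                if c in table.data.columns and table.data[c].nunique() > 1
            )
    else:
        cmap = ColumnMap(
            id_var=id_var,
            response_var=response_var,
            target_var=target_var,
            non_target_prefix=non_target_prefix,
            set_size_var=set_size_var,
            condition_var=condition_var,
        )
        table = TrialTable.from_dataframe(data, column_map=cmap, unit=unit)
        if group_by is None:
            group_by = tuple(
                name
                for name, col in (("set_size", set_size_var), ("condition", condition_var))
                if col is not None
            )

    rows = []
    for keys, idx in table.group_cells(group_by):
        sub_errors = table.errors(rows=idx)
        if sub_errors.n_trials < 2:
            warnings.warn(f"cell {keys} has fewer than 2 trials; skipped", stacklevel=2)
            continue
        est = estimator_for(model, **estimator_kwargs)
        est.fit(sub_errors)
        row = dict(keys)
        for col in _PARAM_COLUMNS[model]:
            row[col] = getattr(est, col + "_")
        if return_fit:
            row["log_likelihood"] = est.log_likelihood_
            row["n_trials"] = est.n_trials_
            row.update(
                information_criteria(est.log_likelihood_, est.n_params_, est.n_trials_)
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    lead = ["id"] + [c for c in ("set_size", "condition") if c in frame.columns]
    other = [c for c in frame.columns if c not in lead]
    order = ["id"] + [c for c in other] + [c for c in lead if c != "id"]
    return frame[order]
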