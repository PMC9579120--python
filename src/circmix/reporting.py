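"""Response-error density tables, model-fit overlays, and plots.

Every plotting helper returns its underlying tidy table alongside the
figure, so the numbers behind a figure are always available for
inferential analysis.  Binning defaults to 18 bins over (-pi, pi]
(20-degree bins); per participant the binned densities integrate to one,
and participant curves are averaged with +/- 1 SE error bars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import TrialTable
from .models import density_three_component, density_two_component
from .summary import get_summary_statistics, response_error

__all__ = [
    "error_density",
    "model_fit_overlay",
    "plot_error",
    "plot_summary_statistic",
    "plot_model_fit",
    "plot_model_parameters",
]

_DEFAULT_BINS = 18


def _bin_edges(n_bins: int):
    if n_bins < 3:
        raise ValueError(f"n_bins must be >= 3, got {n_bins}")
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def _aggregate(per_participant: pd.DataFrame, group_cols, value="density"):
    grouped = per_participant.groupby(group_cols + ["bin"], sort=True, observed=True)[value]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(
        columns={"mean": "density_mean", "sem": "density_se", "count": "n_participants"}
    )


def error_density(table: TrialTable, n_bins: int = _DEFAULT_BINS, group_by=()) -> pd.DataFrame:
    """Participant-averaged histogram density of response error.

    Returns a tidy frame with bin midpoints, mean density across
    participants, its standard error, and the grouping keys.
    """
    edges = _bin_edges(n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for keys, idx in table.group_cells(group_by):
        sub = table.data.loc[idx]
        if len(sub) == 0:
            warnings.warn(f"cell {keys} is empty; omitted", stacklevel=2)
            continue
        err = np.asarray(response_error(sub["response"], sub["target"]))
        dens, _ = np.histogram(err, bins=edges, density=True)
        for b, d in zip(mids, dens):
            rows.append({**keys, "bin": float(b), "density": float(d)})
    per_participant = pd.DataFrame(rows)
    group_cols = [c for c in group_by]
    return _aggregate(per_participant, group_cols)


def _predicted_trial_density(row, nt_cols, mids, model, params):
    """Model-predicted response-error density at bin midpoints for one trial's
    actual non-target configuration."""
    if model in ("2_component", "slots", "slots_averaging"):
        return density_two_component(mids, params["kappa"], params.get("p_u", 0.0))
    deltas = np.asarray(
        [row[c] - row["target"] for c in nt_cols if np.isfinite(row[c])], dtype=float
    )
    if deltas.size == 0:
        return density_two_component(mids, params["kappa"], params["p_u"] + params["p_n"])
    e = np.column_stack([mids] + [mids - d for d in deltas])
    return np.atleast_1d(
        density_three_component(e, params["kappa"], params["p_u"], params["p_n"])
    )


def model_fit_overlay(
    table: TrialTable,
    fits: pd.DataFrame,
    model: str = "3_component",
    n_bins: int = _DEFAULT_BINS,
    group_by=(),
) -> pd.DataFrame:
    """Empirical and model-predicted error densities on a common grid.

    The predicted curve evaluates each trial's fitted density at the bin
    midpoints given that trial's actual non-target positions, averages
    over trials within a participant, then across participants.  Returns
    a tidy frame with a ``source`` column (``empirical``/``predicted``).
    """
    edges = _bin_edges(n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    nt_cols = table.non_target_columns
    key_cols = ["id"] + list(group_by)
    fit_index = fits.set_index(key_cols)
    rows = []
    for keys, idx in table.group_cells(group_by):
        sub = table.data.loc[idx]
        key = tuple(keys[c] for c in key_cols)
        key = key[0] if len(key) == 1 else key
        try:
            params = fit_index.loc[key]
        except KeyError as exc:
            raise KeyError(f"no fitted parameters for cell {keys}") from exc
        if isinstance(params, pd.DataFrame):
            params = params.iloc[0]
        params = params.to_dict()
        err = np.asarray(response_error(sub["response"], sub["target"]))
        emp, _ = np.histogram(err, bins=edges, density=True)
        pred = np.zeros_like(mids)
        for _, trial in sub.iterrows():
            pred += _predicted_trial_density(trial, nt_cols, mids, model, params)
        pred /= len(sub)
        for b, d_emp, d_pred in zip(mids, emp, pred):
            rows.append({**keys, "bin": float(b), "source": "empirical", "density": d_emp})
            rows.append({**keys, "bin": float(b), "source": "predicted", "density": d_pred})
    per_participant = pd.DataFrame(rows)
    return _aggregate(per_participant, list(group_by) + ["source"])


# ---------------------------------------------------------------------------
# figure helpers (matplotlib, colour-blind-safe default cycle)


def _facet_iter(frame, group_by):
    if not group_by:
        yield None, frame
        return
    for keys, sub in frame.groupby(list(group_by), sort=True, observed=True):
        yield keys, sub


def plot_error(table, n_bins: int = _DEFAULT_BINS, group_by=(), ax=None):
    """Plot participant-averaged response-error density; returns (fig, data)."""
    import matplotlib.pyplot as plt

    data = error_density(table, n_bins=n_bins, group_by=group_by)
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots()
    for keys, sub in _facet_iter(data, group_by):
        label = None if keys is None else str(keys)
        ax.errorbar(
            sub["bin"], sub["density_mean"], yerr=sub["density_se"].fillna(0.0),
            marker="o", linestyle="-", capsize=2, label=label,
        )
    ax.set_xlabel("response error (radians)")
    ax.set_ylabel("probability density")
    if group_by:
        ax.legend(title=" x ".join(group_by), fontsize="small")
    return fig, data


def plot_summary_statistic(
    data, statistic: str = "precision", group_by=None, ax=None, **summary_kwargs
):
    """Plot the participant mean (+/- 1 SE) of a summary statistic; returns (fig, data)."""
    import matplotlib.pyplot as plt

    stats = (
        data
        if isinstance(data, pd.DataFrame) and statistic in getattr(data, "columns", ())
        else get_summary_statistics(data, group_by=group_by, **summary_kwargs)
    )
    group_cols = [c for c in ("set_size", "condition") if c in stats.columns]
    x_col = group_cols[0] if group_cols else None
    hue = group_cols[1] if len(group_cols) > 1 else None
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots()
    if x_col is None:
        mean, se = stats[statistic].mean(), stats[statistic].sem()
        ax.errorbar([0], [mean], yerr=[se], marker="o", capsize=3)
        table = pd.DataFrame({statistic + "_mean": [mean], statistic + "_se": [se]})
    else:
        cols = [x_col] + ([hue] if hue else [])
        table = (
            stats.groupby(cols, observed=True)[statistic]
            .agg(["mean", "sem"])
            .reset_index()
            .rename(columns={"mean": statistic + "_mean", "sem": statistic + "_se"})
        )
        for keys, sub in _facet_iter(table, [hue] if hue else ()):
            ax.errorbar(
                sub[x_col], sub[statistic + "_mean"], yerr=sub[statistic + "_se"],
                marker="o", capsize=3, label=None if keys is None else str(keys),
            )
        ax.set_xlabel(x_col)
        if hue:
            ax.legend(title=hue, fontsize="small")
    ax.set_ylabel(statistic.replace("_", " "))
    return fig, table


def plot_model_fit(
    table, fits, model: str = "3_component", n_bins: int = _DEFAULT_BINS,
    group_by=(), ax=None,
):
    """Overlay model-predicted density (line) on observed density (points)."""
    import matplotlib.pyplot as plt

    data = model_fit_overlay(table, fits, model=model, n_bins=n_bins, group_by=group_by)
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots()
    for keys, sub in _facet_iter(data, group_by):
        label = None if keys is None else str(keys)
        emp = sub[sub["source"] == "empirical"]
        pred = sub[sub["source"] == "predicted"]
        pts = ax.errorbar(
            emp["bin"], emp["density_mean"], yerr=emp["density_se"].fillna(0.0),
            marker="o", linestyle="none", capsize=2, label=label,
        )
        ax.plot(pred["bin"], pred["density_mean"], color=pts.lines[0].get_color())
    ax.set_xlabel("response error (radians)")
    ax.set_ylabel("probability density")
    if group_by:
        ax.legend(title=" x ".join(group_by), fontsize="small")
    return fig, data


def plot_model_parameters(fits: pd.DataFrame, model: str = "3_component", axes=None):
    """Participant-averaged best-fitting parameters by set size/condition."""
    import matplotlib.pyplot as plt

    param_cols = [c for c in ("kappa", "p_t", "p_u", "p_n", "K") if c in fits.columns]
    group_cols = [c for c in ("set_size", "condition") if c in fits.columns]
    x_col = group_cols[0] if group_cols else None
    if axes is None:
        fig, axes = plt.subplots(1, len(param_cols), figsize=(3 * len(param_cols), 3))
    else:
        fig = np.atleast_1d(axes)[0].figure
    axes = np.atleast_1d(axes)
    if x_col is None:
        table = fits[param_cols].agg(["mean", "sem"]).T.reset_index(names="parameter")
        for ax, (_, row) in zip(axes, table.iterrows()):
            ax.errorbar([0], [row["mean"]], yerr=[row["sem"]], marker="o", capsize=3)
            ax.set_title(row["parameter"])
    else:
        table = (
            fits.groupby(group_cols, observed=True)[param_cols]
            .agg(["mean", "sem"])
            .reset_index()
        )
        for ax, p in zip(axes, param_cols):
            ax.errorbar(
                table[x_col], table[(p, "mean")], yerr=table[(p, "sem")],
                marker="o", capsize=3,
            )
            ax.set_title(p)
            ax.set_xlabel(x_col)
    fig.tight_layout()
    return fig, table
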