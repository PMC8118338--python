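"""Group comparison statistics for fragmentation and transition metrics.

Individual animals are the experimental unit.  The fragmentation quartet
(transitions to wake / to sleep, mean wake / NREM bout length) is compared
between groups with a pooled-variance two-sample t-test (df = n1 + n2 - 2).
Per-channel transition metrics are compared with models that include an
animal-level random term: transition *durations* with a gamma-family model
(log link, exchangeable within-animal correlation, fitted by generalised
estimating equations), and *gradients* and *variance peaks* with a linear
mixed model with a random animal intercept after a square-root transform
(absolute value first where a metric is signed, e.g. gradients of transitions
to wake, which are all negative).  Because animals, not channel-epochs, carry
the degrees of freedom, fixed-effect p-values use a t reference distribution
with ``n_animals - 2`` degrees of freedom rather than the asymptotic normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "GroupModelResult",
    "pooled_ttest",
    "sem",
    "fragmentation_table",
    "fit_group_model",
    "transition_metric_models",
    "permutation_calibration",
]

#: Fragmentation summary columns compared between groups.
FRAGMENTATION_MEASURES = {
    "n_transitions_to_wake": "Number of transitions to wake",
    "n_transitions_to_sleep": "Number of transitions to sleep",
    "mean_wake_bout_min": "Mean length of wake episode (mins)",
    "mean_nrem_bout_min": "Mean length of sleep episode (mins)",
}


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class GroupModelResult:
    """Fixed group effect from a mixed/marginal model."""

    measure: str
    effect: float  # group coefficient (second group relative to first)
    se: float
    t: float
    df: int
    p: float
    model: str
    transform: str
    n_obs: int


def sem(x) -> float:
    """Standard error of the mean (ddof=1)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def pooled_ttest(x, y) -> TTestResult:
    """Two-sample t-test with pooled variance; t is for mean(x) - mean(y).

    df = n1 + n2 - 2.  Identical samples give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    else:
        t = float(diff / se)
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(t=t, df=df, p=p)


def _group_levels(df: pd.DataFrame) -> list[str]:
    return list(pd.unique(df["group"]))


def fragmentation_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group means +/- SEM and t-tests for the fragmentation quartet.

    ``summaries`` has one row per animal with a ``group`` column and the four
    measure columns.  The t statistic is for the second group minus the first
    (so a lower second-group mean gives a negative t).  Groups with fewer
    than 2 animals skip the test but still report means.
    """
    g1, g2 = _group_levels(summaries)[:2]
    rows = []
    for col, label in FRAGMENTATION_MEASURES.items():
        if col not in summaries.columns:
            continue
        a = summaries.loc[summaries["group"] == g1, col].to_numpy(dtype=float)
        b = summaries.loc[summaries["group"] == g2, col].to_numpy(dtype=float)
        row = {
            "measure": label,
            f"{g1}_mean": float(np.nanmean(a)),
            f"{g1}_sem": sem(a),
            f"{g2}_mean": float(np.nanmean(b)),
            f"{g2}_sem": sem(b),
        }
        if min(a.size, b.size) >= 2:
            res = pooled_ttest(b, a)  # second group relative to the first
            row.update(p=res.p, t=res.t, df=res.df)
        else:
            row.update(p=float("nan"), t=float("nan"), df=0)
        rows.append(row)
    return pd.DataFrame(rows)


def _identity(x):
    return x


def _sqrt_abs(x):
    return np.sqrt(np.abs(x))


_TRANSFORMS = {"none": _identity, "sqrt": np.sqrt, "abs_sqrt": _sqrt_abs}


def fit_group_model(
    df: pd.DataFrame,
    value_col: str,
    kind: str = "gamma",
    transform: str = "none",
    measure: str | None = None,
) -> GroupModelResult:
    """Fit the group effect for one metric with an animal-level random term.

    ``df`` needs columns ``group``, ``animal`` and ``value_col`` (one row per
    transition x channel).  ``kind='gamma'`` fits a gamma-family log-link
    model by GEE with exchangeable within-animal correlation (bias-reduced
    covariance); ``kind='lmm'`` fits a linear mixed model with a random animal
    intercept on the transformed values.  The group-effect p-value uses a t
    distribution with ``n_animals - 2`` degrees of freedom.

    Raises
    ------
    ValueError
        If non-positive values reach the gamma family (the offending records
        are named).
    """
    data = df.dropna(subset=[value_col]).copy()
    if data.empty:
        raise ValueError(f"no finite values for {value_col}")
    levels = _group_levels(data)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    data["group"] = pd.Categorical(data["group"], categories=levels)
    n_animals = data["animal"].nunique()
    df_t = max(1, n_animals - 2)
    fn = _TRANSFORMS[transform]
    data["_y"] = fn(data[value_col].to_numpy(dtype=float))

    if kind == "gamma":
        bad = data[data["_y"] <= 0]
        if len(bad):
            idx = bad.index.tolist()[:10]
            raise ValueError(
                f"gamma family requires positive values; offending records "
                f"(index): {idx}"
            )
        model = smf.gee(
            "_y ~ C(group)",
            groups="animal",
            data=data,
            family=sm.families.Gamma(link=sm.families.links.Log()),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(cov_type="bias_reduced")
        name = model.exog_names[1]
        eff, se = float(res.params[name]), float(res.bse[name])
        model_name = "gamma GEE (log link, exchangeable)"
    elif kind == "lmm":
        md = smf.mixedlm("_y ~ C(group)", data, groups=data["animal"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True)
        name = md.exog_names[1]
        eff, se = float(res.params[name]), float(res.bse[name])
        model_name = "linear mixed model (random animal intercept)"
    else:
        raise ValueError("kind must be 'gamma' or 'lmm'")

    t = eff / se if se > 0 else float("nan")
    p = float(2.0 * sps.t.sf(abs(t), df_t)) if np.isfinite(t) else float("nan")
    return GroupModelResult(
        measure=measure or value_col,
        effect=eff,
        se=se,
        t=float(t),
        df=df_t,
        p=p,
        model=model_name,
        transform=transform,
        n_obs=len(data),
    )


def _animal_means(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return (
        df.dropna(subset=[value_col])
        .groupby(["group", "animal"], observed=True)[value_col]
        .mean()
        .reset_index()
    )


def transition_metric_models(
    speed: pd.DataFrame,
    variance_peaks: pd.DataFrame | None = None,
    direction: str = "TO_WAKE",
    bands: list[str] | None = None,
) -> pd.DataFrame:
    """Per-band group comparisons of the three speed metrics for one direction.

    Durations get the gamma-family model (no transform); gradients and
    variance peaks get the linear mixed model on sqrt-transformed values,
    with an absolute value first so that all-negative metrics (to-wake
    gradients) stay in the domain.  Group means +/- SEM are computed over
    animals (each animal contributes one mean), matching the
    animal-as-experimental-unit convention.
    """
    sel = speed[speed["direction"] == direction]
    if "channel" in sel.columns:  # models use per-channel rows, not the mean
        sel = sel[sel["channel"] != "mean"]
    bands = bands or list(pd.unique(sel["band"]))
    g1, g2 = _group_levels(sel)[:2]
    rows = []
    for band in bands:
        bsel = sel[sel["band"] == band]
        for value_col, kind, transform, label in (
            ("duration_min", "gamma", "none", "duration_min"),
            ("gradient_power_per_min", "lmm", "abs_sqrt", "gradient_power_per_min"),
        ):
            data = bsel.dropna(subset=[value_col])
            if data.empty or data["animal"].nunique() < 4:
                continue
            res = fit_group_model(
                data, value_col, kind=kind, transform=transform,
                measure=f"{band}:{label}",
            )
            am = _animal_means(data, value_col)
            rows.append(
                {
                    "direction": direction,
                    "band": band,
                    "measure": label,
                    f"{g1}_mean": am.loc[am["group"] == g1, value_col].mean(),
                    f"{g1}_sem": sem(am.loc[am["group"] == g1, value_col]),
                    f"{g2}_mean": am.loc[am["group"] == g2, value_col].mean(),
                    f"{g2}_sem": sem(am.loc[am["group"] == g2, value_col]),
                    "p": res.p,
                    "t": res.t,
                    "model": res.model,
                    "transform": res.transform,
                }
            )
    if variance_peaks is not None and not variance_peaks.empty:
        vsel = variance_peaks[variance_peaks["direction"] == direction]
        if "channel" in vsel.columns:
            vsel = vsel[vsel["channel"] != "mean"]
        data = vsel.dropna(subset=["variance_peak"])
        if not data.empty and data["animal"].nunique() >= 4:
            res = fit_group_model(
                data, "variance_peak", kind="lmm", transform="abs_sqrt",
                measure="variance_peak",
            )
            am = _animal_means(data, "variance_peak")
            rows.append(
                {
                    "direction": direction,
                    "band": "all",
                    "measure": "variance_peak",
                    f"{g1}_mean": am.loc[am["group"] == g1, "variance_peak"].mean(),
                    f"{g1}_sem": sem(am.loc[am["group"] == g1, "variance_peak"]),
                    f"{g2}_mean": am.loc[am["group"] == g2, "variance_peak"].mean(),
                    f"{g2}_sem": sem(am.loc[am["group"] == g2, "variance_peak"]),
                    "p": res.p,
                    "t": res.t,
                    "model": res.model,
                    "transform": res.transform,
                }
            )
    return pd.DataFrame(rows)


def permutation_calibration(
    df: pd.DataFrame,
    value_col: str,
    kind: str = "lmm",
    transform: str = "abs_sqrt",
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """False-positive rate of the group test under permuted animal labels.

    Animal-level group labels are shuffled ``n_perm`` times (preserving group
    sizes); the model is refit each time and the fraction of p < 0.05 is
    returned.  For a calibrated test on null data this fraction is ~5% within
    binomial error.
    """
    rng = np.random.default_rng(rng)
    animals = df[["animal", "group"]].drop_duplicates().reset_index(drop=True)
    labels = animals["group"].to_numpy()
    pvals = []
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        mapping = dict(zip(animals["animal"], perm))
        shuffled = df.copy()
        shuffled["group"] = shuffled["animal"].map(mapping)
        try:
            res = fit_group_model(shuffled, value_col, kind=kind, transform=transform)
            pvals.append(res.p)
        except (ValueError, np.linalg.LinAlgError):
            continue
    pvals = np.asarray(pvals, dtype=float)
    frac = float(np.mean(pvals < 0.05)) if pvals.size else float("nan")
    return {"fraction_significant": frac, "n_fits": int(pvals.size), "pvalues": pvals}
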