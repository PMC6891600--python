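"""Dose-response LD50 estimation for venom injection assays.

The assay design: groups of eight female fruit flies are injected in
triplicate at each venom dose (micrograms of venom per gram of body mass) and
mortality is scored at a fixed time point. Mortality is modelled with a
two-parameter log-logistic curve with fixed asymptotes at 0 and 1,

    p(d) = 1 / (1 + exp(-(b0 + b1 * ln d))),

which is a binomial GLM with logit link on log-dose. The LD50 is the dose at
50% mortality, exp(-b0 / b1), and its standard error follows from the
observed-information covariance of (b0, b1) by the delta method. The slope
b1 controls the steepness of the kill curve on the log-dose axis. The
headline fit pools flies across replicate groups; between-group dispersion
is summarised separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "NonIdentifiableError",
    "Ld50Fit",
    "fit_ld50",
    "log_logistic_mortality",
    "read_dose_response_tsv",
]


class NonIdentifiableError(ValueError):
    """Mortality does not bracket 50%, so the LD50 is not identifiable."""


def log_logistic_mortality(dose, ld50: float, slope: float):
    """Expected mortality fraction under the two-parameter log-logistic model.

    Zero dose has zero expected mortality (the curve's lower asymptote).
    """
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    eta = slope * (logd - math.log(ld50))
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.where(d > 0, p, 0.0)
    return float(p) if p.ndim == 0 else p


@dataclass
class Ld50Fit:
    """Fitted log-logistic dose-response summary."""

    ld50: float  # ug venom per g body mass
    slope: float  # on the natural-log dose axis
    se_ld50: float
    se_slope: float
    log_ld50: float
    se_log_ld50: float
    n_flies: int
    n_doses: int
    quasi_separation: bool = False
    time_point: Optional[float] = None
    between_group_sd: Optional[pd.DataFrame] = None  # per-dose replicate SD
    overdispersion: float = float("nan")  # Pearson chi2 / residual df

    def predicted(self, dose):
        return log_logistic_mortality(dose, self.ld50, self.slope)


def _per_dose(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby("dose", sort=True).agg(
        n_injected=("n_injected", "sum"), n_dead=("n_dead", "sum")
    )
    g["mortality"] = g["n_dead"] / g["n_injected"]
    return g.reset_index()


def fit_ld50(data: pd.DataFrame, time_point: Optional[float] = None) -> Ld50Fit:
    """Maximum-likelihood LD50 from grouped dose-survival records.

    ``data`` needs columns dose, n_injected, n_dead and optionally group and
    time_point (the latter selects one time point when several are present).
    Requires at least three distinct positive doses and mortality on both
    sides of 50%. Perfectly separating data (no dose with intermediate
    mortality) yields a quasi-separation fit: the LD50 is the geometric
    midpoint of the bracketing doses, with undefined standard errors.
    """
    df = data.copy()
    if time_point is not None and "time_point" in df.columns:
        df = df[df["time_point"] == time_point]
    if np.any(df["dose"] <= 0):
        raise ValueError("doses must be positive")
    if np.any((df["n_dead"] < 0) | (df["n_dead"] > df["n_injected"])):
        raise ValueError("0 <= n_dead <= n_injected violated")
    per_dose = _per_dose(df)
    if len(per_dose) < 3:
        raise ValueError("need at least 3 distinct doses")
    mort = per_dose["mortality"].to_numpy()
    if mort.max() <= 0.5 or mort.min() >= 0.5:
        raise NonIdentifiableError(
            "mortality does not bracket 50%: observed range "
            f"[{mort.min():.2f}, {mort.max():.2f}]"
        )

    intermediate = (mort > 0) & (mort < 1)
    if not intermediate.any():
        # Quasi-separation: likelihood is maximised on the boundary; report
        # the geometric midpoint of the steepest all-alive/all-dead bracket.
        below = per_dose.loc[mort == 0, "dose"].max()
        above = per_dose.loc[mort == 1, "dose"].min()
        ld50 = math.sqrt(below * above)
        return Ld50Fit(
            ld50=ld50, slope=math.inf, se_ld50=math.nan, se_slope=math.nan,
            log_ld50=math.log(ld50), se_log_ld50=math.nan,
            n_flies=int(per_dose["n_injected"].sum()), n_doses=len(per_dose),
            quasi_separation=True, time_point=time_point,
            between_group_sd=_group_dispersion(df),
        )

    endog = per_dose[["n_dead"]].copy()
    endog["n_alive"] = per_dose["n_injected"] - per_dose["n_dead"]
    exog = sm.add_constant(np.log(per_dose["dose"].to_numpy()))
    model = sm.GLM(endog.to_numpy(), exog, family=sm.families.Binomial())
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-boundary fits are legitimate here; full separation is handled above
        _warnings.simplefilter("ignore")
        fit = model.fit()
    b0, b1 = fit.params
    cov = fit.cov_params()
    ld50 = math.exp(-b0 / b1)
    # Delta method on g(b) = -b0/b1 (the log LD50).
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var_log = float(grad @ cov @ grad)
    se_log = math.sqrt(max(var_log, 0.0))
    return Ld50Fit(
        ld50=ld50,
        slope=float(b1),
        se_ld50=ld50 * se_log,
        se_slope=float(math.sqrt(cov[1, 1])),
        log_ld50=math.log(ld50),
        se_log_ld50=se_log,
        n_flies=int(per_dose["n_injected"].sum()),
        n_doses=len(per_dose),
        quasi_separation=False,
        time_point=time_point,
        between_group_sd=_group_dispersion(df),
        overdispersion=float(fit.pearson_chi2 / fit.df_resid) if fit.df_resid > 0 else float("nan"),
    )


def _group_dispersion(df: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Per-dose standard deviation of replicate-group mortality fractions."""
    if "group" not in df.columns or df.groupby("dose")["group"].nunique().max() < 2:
        return None
    frac = df.assign(mortality=df["n_dead"] / df["n_injected"])
    out = frac.groupby("dose", sort=True)["mortality"].agg(["mean", "std", "count"])
    return out.reset_index().rename(columns={"std": "sd_between_groups"})


def read_dose_response_tsv(path) -> pd.DataFrame:
    """Read a dose-survival table (dose, n_injected, n_dead, group, time_point)."""
    return pd.read_csv(path, sep="\t")
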