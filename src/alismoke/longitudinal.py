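"""Adjusted-AUC summaries and the paired repeated-measures model.

Longitudinal endpoints (TEER, qPCR delta-Ct, cilia metrics) measured at
several days are condensed to a single *adjusted AUC* per culture: the
trapezoidal area under the time course divided by the length of the time
interval, i.e. the time-averaged level of the endpoint.  Because both
treatments (cigarette smoke and air control) are applied to cultures from
the same donor, the adjusted AUCs are analyzed with a repeated-measurement
model with fixed factors donor status (HC/COPD), treatment, and their
interaction, assuming compound symmetry within donor.  Treatment effects
within each donor status are tested with one-sided t-type contrasts
``mu_{group,CS} - mu_{group,Air}`` whose direction is fixed a priori per
endpoint; p-values are not adjusted for multiplicity.

qPCR endpoints use the comparative-Ct convention
``dCt = Ct(target) - Ct(endogenous control)`` (lower dCt means higher
expression), so a fold change between two adjusted dCt AUCs is
``2 ** |AUC_air - AUC_smoke|``.

Estimation uses the closed-form balanced-design (split-plot) moment
estimators, which coincide with REML on the balanced paired two-treatment
designs this model targets; the within-group treatment contrast is then
numerically identical to the paired t-test on that group's CS-Air
differences when a single group is analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LongitudinalSeries",
    "AdjustedAUC",
    "FoldChange",
    "HypothesisSpec",
    "ContrastResult",
    "RepeatedMeasuresFit",
    "DIRECTION_REGISTRY",
    "hypothesis_for",
    "adjusted_auc",
    "auc_table",
    "fold_change_from_auc",
    "fit_repeated_measures",
    "test_one_sided",
]


@dataclass(frozen=True)
class LongitudinalSeries:
    """One endpoint measured on one culture (subject x treatment) over days."""

    subject: str
    group: str  # HC | COPD
    treatment: str  # CS | Air
    endpoint: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if days.shape != values.shape or days.ndim != 1:
            raise ValueError("days and values must be 1-D arrays of equal length")
        if not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class AdjustedAUC:
    """Trapezoidal AUC divided by the length of the time interval."""

    value: float
    span_days: float
    log_transformed: bool = False


@dataclass(frozen=True)
class FoldChange:
    fold: float
    direction: str  # increase | decrease | no_change


@dataclass(frozen=True)
class HypothesisSpec:
    """One-sided alternative for a treatment contrast within a group.

    ``direction="lower"`` tests H1: mu_{group,CS} - mu_{group,Air} < 0;
    ``"upper"`` tests the reverse.  ``transform`` records whether the
    endpoint's adjusted AUC is analyzed on the log scale.
    """

    endpoint: str
    group: str
    direction: str  # lower | upper
    transform: str = "identity"  # identity | log

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "upper"):
            raise ValueError(f"direction must be 'lower' or 'upper', got {self.direction!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"transform must be 'identity' or 'log', got {self.transform!r}")


#: a priori expected direction of the smoke effect per endpoint
#: (decrease-expected endpoints test "lower", increase-expected "upper")
DIRECTION_REGISTRY: dict[str, HypothesisSpec] = {
    "active_area": HypothesisSpec("active_area", "*", "lower", "log"),
    "cbf": HypothesisSpec("cbf", "*", "lower", "identity"),
    "teer": HypothesisSpec("teer", "*", "lower", "log"),
    "KRT5_dCt": HypothesisSpec("KRT5_dCt", "*", "lower", "identity"),
    "KRT14_dCt": HypothesisSpec("KRT14_dCt", "*", "lower", "identity"),
    "MUC5AC_dCt": HypothesisSpec("MUC5AC_dCt", "*", "lower", "identity"),
    "SCGB1A1_dCt": HypothesisSpec("SCGB1A1_dCt", "*", "upper", "identity"),
    "FOXJ1_dCt": HypothesisSpec("FOXJ1_dCt", "*", "upper", "identity"),
}


def hypothesis_for(endpoint: str, group: str) -> HypothesisSpec:
    """Registry lookup; unknown endpoints are rejected."""
    try:
        template = DIRECTION_REGISTRY[endpoint]
    except KeyError:
        raise KeyError(
            f"endpoint {endpoint!r} not in the direction registry; "
            f"known endpoints: {sorted(DIRECTION_REGISTRY)}"
        ) from None
    return HypothesisSpec(endpoint, group, template.direction, template.transform)


def adjusted_auc(series: LongitudinalSeries, log_transform: bool = False) -> AdjustedAUC:
    """Adjusted AUC of a series: trapezoid area / (last day - first day).

    For a constant series this equals the constant.  When ``log_transform``
    is set the natural logarithm is applied to the adjusted AUC itself
    (not pointwise to the values), which requires a positive AUC.
    """
    if series.days.size < 2:
        raise ValueError("adjusted AUC needs at least two time points")
    span = float(series.days[-1] - series.days[0])
    value = float(np.trapezoid(series.values, series.days)) / span
    if log_transform:
        if value <= 0:
            raise ValueError(f"cannot log-transform non-positive adjusted AUC {value}")
        value = math.log(value)
    return AdjustedAUC(value=value, span_days=span, log_transformed=log_transform)


def auc_table(data: pd.DataFrame, log_endpoints: set[str] | None = None) -> pd.DataFrame:
    """Adjusted AUC per (subject, group, treatment, endpoint) from a tidy table.

    ``data`` columns: subject, group, treatment, endpoint, day, value.
    """
    log_endpoints = log_endpoints or set()
    rows = []
    keys = ["subject", "group", "treatment", "endpoint"]
    for (subject, group, treatment, endpoint), sub in data.groupby(keys, sort=True):
        sub = sub.sort_values("day")
        series = LongitudinalSeries(
            subject, group, treatment, endpoint, sub["day"].to_numpy(), sub["value"].to_numpy()
        )
        auc = adjusted_auc(series, log_transform=endpoint in log_endpoints)
        rows.append((subject, group, treatment, endpoint, auc.value))
    return pd.DataFrame(rows, columns=keys + ["auc"])


def fold_change_from_auc(auc_air: float, auc_smoke: float) -> FoldChange:
    """Comparative-Ct fold change between two adjusted dCt AUCs.

    ``fold = 2 ** |auc_air - auc_smoke|``; expression *increases* under
    smoke when the smoke dCt AUC is lower (fewer cycles to threshold).
    """
    fold = 2.0 ** abs(auc_air - auc_smoke)
    if auc_smoke < auc_air:
        direction = "increase"
    elif auc_smoke > auc_air:
        direction = "decrease"
    else:
        direction = "no_change"
    return FoldChange(fold=fold, direction=direction)


@dataclass(frozen=True)
class ContrastResult:
    estimate: float  # mu_{group,CS} - mu_{group,Air}
    standard_error: float
    df: float  # within-subject residual degrees of freedom
    t_statistic: float
    p_one_sided: float
    direction: str


@dataclass(frozen=True)
class RepeatedMeasuresFit:
    """Fitted cell means and compound-symmetry variance components.

    ``cell_means`` maps (group, treatment) to the estimated mean; the
    residual degrees of freedom are partitioned into a between-subject part
    (used for the group main effect) and a within-subject part (used for
    treatment and interaction contrasts, since treatment varies within
    every subject).
    """

    cell_means: dict[tuple[str, str], float]
    group_sizes: dict[str, int]
    sigma2_within: float  # residual (within-subject) variance
    sigma2_subject: float  # between-subject variance component
    df_within: int
    df_between: int
    exposed: str
    control: str

    @property
    def within_subject_correlation(self) -> float:
        total = self.sigma2_subject + self.sigma2_within
        return self.sigma2_subject / total if total > 0 else 0.0


def fit_repeated_measures(
    data: pd.DataFrame, exposed: str = "CS", control: str = "Air"
) -> RepeatedMeasuresFit:
    """Fit the paired repeated-measures model to per-series adjusted AUCs.

    ``data`` columns: subject, group, treatment, and a value column named
    either ``auc`` or ``value``.  Every subject must contribute both
    treatment arms (no imputation); subjects are nested in groups.  The
    compound-symmetry variance components come from the balanced split-plot
    decomposition: the within-subject mean square is estimated from the
    per-subject treatment differences pooled across groups, with
    N - n_groups within-subject degrees of freedom.
    """
    value_col = "auc" if "auc" in data.columns else "value"
    pivot = data.pivot_table(
        index=["group", "subject"], columns="treatment", values=value_col, aggfunc="mean"
    )
    for arm in (exposed, control):
        if arm not in pivot.columns:
            raise ValueError(f"treatment arm {arm!r} absent from the data")
    missing = pivot.index[pivot[[exposed, control]].isna().any(axis=1)]
    if len(missing):
        subjects = ", ".join(str(s) for _, s in missing)
        raise ValueError(f"subjects missing a treatment arm: {subjects}")

    groups = pivot.index.get_level_values("group").unique().tolist()
    n_total = len(pivot)
    n_groups = len(groups)
    if n_total <= n_groups:
        raise ValueError("need more subjects than groups to estimate variance components")

    cell_means: dict[tuple[str, str], float] = {}
    group_sizes: dict[str, int] = {}
    ss_within = 0.0
    ss_between = 0.0
    for g in groups:
        block = pivot.loc[g]
        group_sizes[g] = len(block)
        cell_means[(g, exposed)] = float(block[exposed].mean())
        cell_means[(g, control)] = float(block[control].mean())
        d = (block[exposed] - block[control]).to_numpy()
        ss_within += float(((d - d.mean()) ** 2).sum()) / 2.0
        m = block[[exposed, control]].mean(axis=1).to_numpy()
        ss_between += 2.0 * float(((m - m.mean()) ** 2).sum())

    df_within = n_total - n_groups
    df_between = n_total - n_groups
    ms_within = ss_within / df_within
    ms_between = ss_between / df_between
    sigma2_subject = max((ms_between - ms_within) / 2.0, 0.0)
    return RepeatedMeasuresFit(
        cell_means=cell_means,
        group_sizes=group_sizes,
        sigma2_within=ms_within,
        sigma2_subject=sigma2_subject,
        df_within=df_within,
        df_between=df_between,
        exposed=exposed,
        control=control,
    )


def test_one_sided(fit: RepeatedMeasuresFit, spec: HypothesisSpec) -> ContrastResult:
    """One-sided t-type test of the treatment contrast within one group.

    The estimate is ``mu_{group,CS} - mu_{group,Air}``; its standard error
    uses the pooled within-subject mean square on the within-subject
    degrees of freedom.  ``direction="lower"`` accumulates probability to
    the left (alternative: smoke decreases the endpoint).  No multiplicity
    adjustment is applied.
    """
    key = (spec.group, fit.exposed)
    if key not in fit.cell_means:
        raise ValueError(f"group {spec.group!r} not present in the fitted model")
    estimate = fit.cell_means[(spec.group, fit.exposed)] - fit.cell_means[(spec.group, fit.control)]
    n_g = fit.group_sizes[spec.group]
    se = math.sqrt(2.0 * fit.sigma2_within / n_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = estimate / se if se > 0 else (0.0 if estimate == 0 else math.copysign(math.inf, estimate))
    if spec.direction == "lower":
        p = float(sps.t.cdf(t_stat, fit.df_within))
    else:
        p = float(sps.t.sf(t_stat, fit.df_within))
    return ContrastResult(
        estimate=float(estimate),
        standard_error=se,
        df=fit.df_within,
        t_statistic=float(t_stat),
        p_one_sided=p,
        direction=spec.direction,
    )
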