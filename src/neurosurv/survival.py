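"""Survival-record assembly and the statistical models of the pipeline.

Single-neuron survival data are hierarchical: neurons share a well
(cluster — transfection conditions are common to a well) and wells sit
on plates (strata — baseline toxicity varies between replicate plates).
Accordingly the Cox models here report well-cluster-robust sandwich
standard errors and stratify the baseline hazard by plate.

Event coding: a death observed during follow-up is the event; a neuron
still alive at the last frame is right-censored at the end of follow-up.
(The source protocol's prose swaps the words "censored"/"uncensored" for
these two cases; the reported hazard-ratio directions are only consistent
with the standard coding used here.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _cox

__all__ = [
    "LayoutError",
    "DataError",
    "AssignmentError",
    "ModelError",
    "CoxFit",
    "QuartileAssignment",
    "build_survival_records",
    "records_from_truth",
    "nelson_aalen",
    "fit_cox",
    "schoenfeld_ph_test",
    "normalize_reporter",
    "assign_quartiles",
    "quartile_hazard_model",
]


class LayoutError(KeyError):
    """A fate row refers to a well/plate absent from the layout."""


class DataError(ValueError):
    """Malformed survival input (negative times, bad flags)."""


class AssignmentError(ValueError):
    """Quartile assignment is impossible (too few measured neurons)."""


class ModelError(ValueError):
    """A model cannot be fitted on the supplied records."""


# ---------------------------------------------------------------------------
# record assembly

def reporter_column(reference_time: float) -> str:
    return f"green_{reference_time:g}h"


def build_survival_records(
    fates: pd.DataFrame,
    layout: pd.DataFrame,
    end_of_followup: float,
    reporter: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble one analysis row per neuron from fate, layout and
    (optionally) reporter tables.

    ``fates`` needs track_id/neuron_id, plate, well, survival_time_h, died;
    ``layout`` maps (plate, well) -> group.  ``reporter`` is a long table
    (track_id, time_h, mean_green [, mean_red]) whose green levels are
    attached as one column per measurement time (``green_{t}h``).

    Neurons never confirmed alive after the first frame (survival time 0)
    carry no at-risk time and are dropped with a warning; negative times
    raise :class:`DataError`.
    """
    f = fates.copy()
    id_col = "track_id" if "track_id" in f.columns else "neuron_id"
    if (f["survival_time_h"] < 0).any():
        raise DataError("negative survival time in fates")

    lay = layout.drop_duplicates(subset=["plate", "well"]).set_index(["plate", "well"])
    keys = list(zip(f["plate"], f["well"]))
    missing = sorted({k for k in keys if k not in lay.index})
    if missing:
        raise LayoutError(f"wells missing from layout: {missing[:5]}")
    group = [lay.loc[k, "group"] for k in keys]

    records = pd.DataFrame({
        "neuron_id": f[id_col].to_numpy(),
        "time": f["survival_time_h"].to_numpy(dtype=float),
        "event": f["died"].to_numpy(dtype=bool),
        "group": group,
        "well": [f"P{p}W{w}" for p, w in keys],
        "plate": [f"P{p}" for p, _ in keys],
    })
    n_zero = int((records["time"] == 0).sum())
    if n_zero:
        warnings.warn(
            f"dropping {n_zero} neuron(s) never confirmed alive after the first "
            "frame (no at-risk time)", stacklevel=2,
        )
        records = records[records["time"] > 0].reset_index(drop=True)
    if (~records["event"] & (records["time"] != end_of_followup)).any():
        raise DataError("censored record with time != end_of_followup")

    if reporter is not None:
        rid = "track_id" if "track_id" in reporter.columns else "neuron_id"
        wide = reporter.pivot_table(index=rid, columns="time_h",
                                    values="mean_green", aggfunc="first")
        wide.columns = [reporter_column(t) for t in wide.columns]
        records = records.merge(wide, left_on="neuron_id", right_index=True,
                                how="left")
    return records


def records_from_truth(truth, attach_reporter: bool = True) -> pd.DataFrame:
    """Survival records straight from simulator ground truth, keeping the
    exact continuous death times (no imaging-grid coarsening).

    Used for statistics-only runs and parameter-recovery studies where
    the estimand is the programmed hazard model itself.
    """
    f = truth.fates
    end = truth.design.end_of_followup
    records = pd.DataFrame({
        "neuron_id": f["neuron_id"].to_numpy(),
        "time": np.where(f["censored"], end, f["death_time_h"]),
        "event": (~f["censored"]).to_numpy(),
        "group": f["group"].to_numpy(),
        "well": [f"P{p}W{w}" for p, w in zip(f["plate"], f["well"])],
        "plate": [f"P{p}" for p in f["plate"]],
    })
    if attach_reporter and len(truth.trajectories):
        wide = truth.trajectories.pivot_table(index="neuron_id", columns="time_h",
                                              values="green_true", aggfunc="first")
        wide.columns = [reporter_column(t) for t in wide.columns]
        records = records.merge(wide, left_on="neuron_id", right_index=True,
                                how="left")
    return records


# ---------------------------------------------------------------------------
# Nelson-Aalen

def nelson_aalen(records: pd.DataFrame, by_group: bool = True,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Nelson–Aalen cumulative hazard H(t) = sum d_i/n_i per group.

    Subjects censored at an event time count as at risk at that time.
    Variance is sum d_i/n_i^2 with linear pointwise CIs clipped at 0.
    """
    if len(records) == 0:
        raise DataError("no records")
    z = stats.norm.ppf(1 - alpha / 2)
    frames = []
    groups = records.groupby("group") if by_group else [("all", records)]
    for gname, g in groups:
        t = g["time"].to_numpy(dtype=float)
        e = g["event"].to_numpy(dtype=bool)
        et = np.unique(t[e])
        h = var = 0.0
        rows = []
        for ti in et:
            n_risk = int((t >= ti).sum())
            d = int(((t == ti) & e).sum())
            h += d / n_risk
            var += d / n_risk**2
            rows.append((gname, ti, n_risk, d, h, var,
                         max(h - z * np.sqrt(var), 0.0), h + z * np.sqrt(var)))
        frames.append(pd.DataFrame(rows, columns=[
            "group", "time", "n_risk", "n_events", "H", "var", "ci_lo", "ci_hi"
        ]))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "time", "n_risk", "n_events", "H", "var", "ci_lo", "ci_hi"]
    )


# ---------------------------------------------------------------------------
# Cox model

@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, sandwich variance, and the arrays
    needed for downstream diagnostics."""

    terms: list[str]
    beta: np.ndarray
    var_model: np.ndarray
    var_robust: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_clusters: int
    strata_label: str
    ties: str
    converged: bool
    message: str
    n_iter: int
    reference: dict = field(default_factory=dict)  # covariate -> reference level
    _X: np.ndarray | None = None
    _time: np.ndarray | None = None
    _event: np.ndarray | None = None
    _entry: np.ndarray | None = None
    _strata: np.ndarray | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.var_robust))

    @property
    def model_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.var_model))

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.robust_se
        zstat = self.beta / se
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.beta,
            "hr": self.hr,
            "robust_se": se,
            "ci_lo": np.exp(self.beta - z * se),
            "ci_hi": np.exp(self.beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(zstat)),
            "n": self.n,
            "n_events": self.n_events,
            "n_clusters": self.n_clusters,
        })

    def hr_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Summary with explicit HR-1 reference rows (Table-style output)."""
        s = self.summary(alpha=alpha)
        ref_rows = [
            {"term": f"{cov}[{lvl}]", "beta": 0.0, "hr": 1.0, "robust_se": 0.0,
             "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
             "n": self.n, "n_events": self.n_events, "n_clusters": self.n_clusters}
            for cov, lvl in self.reference.items()
        ]
        return pd.concat([pd.DataFrame(ref_rows), s], ignore_index=True)


def _design_matrix(records: pd.DataFrame, covariates: list[str]):
    """Numeric columns pass through; object/categorical columns are
    dummy-coded against their first (sorted) level."""
    cols = []
    names: list[str] = []
    reference: dict[str, str] = {}
    for cov in covariates:
        col = records[cov]
        if col.isna().any():
            raise DataError(f"missing values in covariate {cov!r}")
        if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            reference[cov] = levels[0]
            for lvl in levels[1:]:
                cols.append((col.astype(str) == lvl).to_numpy(dtype=float))
                names.append(f"{cov}[{lvl}]")
    if not cols:
        raise ModelError("empty covariate specification")
    return np.column_stack(cols), names, reference


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str] | str = ("group",),
    cluster_by: str | None = "well",
    strata_by: str | None = "plate",
    ties: str = "breslow",
    entry_col: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Cox proportional-hazards fit with well-cluster-robust variance and
    plate stratification.

    Categorical covariates (e.g. ``group``) are expanded against their
    first sorted level, which carries no coefficient (HR 1 by
    construction).  ``entry_col`` enables delayed entry (left truncation).
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    covariates = list(covariates)
    if len(records) == 0:
        raise DataError("no records")
    X, names, reference = _design_matrix(records, covariates)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    entry = records[entry_col].to_numpy(dtype=float) if entry_col else None
    strata = records[strata_by].to_numpy() if strata_by else None
    if not event.any():
        raise ModelError("no events: partial likelihood undefined")

    res = _cox.newton_fit(X, time, event, entry=entry, strata=strata,
                          ties=ties, tol=tol, max_iter=max_iter)
    var_model = np.linalg.inv(res.information)

    if cluster_by:
        clusters = records[cluster_by].to_numpy()
    else:
        clusters = np.arange(len(records))
    resid = _cox.score_residuals(X, time, event, res.beta, entry=entry,
                                 strata=strata)
    _, inv = np.unique(clusters, return_inverse=True)
    n_clusters = inv.max() + 1
    if not event.any() or n_clusters == 0:
        raise ModelError("no clusters with events: robust variance undefined")
    u = np.zeros((n_clusters, X.shape[1]))
    np.add.at(u, inv, resid)
    meat = u.T @ u
    # finite-sample factor G/(G-1) * (N-1)/(N-p), the convention of Stata's
    # vce(cluster); counters the downward bias of the sandwich with few wells
    n_rec, p = X.shape
    if n_clusters > 1 and n_rec > p:
        meat = meat * (n_clusters / (n_clusters - 1)) * ((n_rec - 1) / (n_rec - p))
    var_robust = var_model @ meat @ var_model

    fit = CoxFit(
        terms=names, beta=res.beta, var_model=var_model, var_robust=var_robust,
        loglik=res.loglik, n=len(records), n_events=int(event.sum()),
        n_clusters=int(n_clusters),
        strata_label=strata_by or "(none)", ties=ties,
        converged=res.converged, message=res.message, n_iter=res.n_iter,
        reference=reference,
        _X=X, _time=time, _event=event, _entry=entry, _strata=strata,
    )
    if not res.converged:
        warnings.warn(f"Cox fit did not converge: {res.message}", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics

def schoenfeld_ph_test(fit: CoxFit, transform: str = "identity") -> pd.DataFrame:
    """Grambsch–Therneau test for a time trend in scaled Schoenfeld
    residuals; one chi-square(1) row per covariate plus a global row."""
    if fit._X is None:
        raise ValueError("fit is missing its training arrays")
    if fit._event.sum() < 2:
        raise ModelError("PH test undefined with fewer than 2 events")
    t, s = _cox.schoenfeld_residuals(fit._X, fit._time, fit._event, fit.beta,
                                     entry=fit._entry, strata=fit._strata)
    kw = {}
    if transform == "km":
        km_t, km_s = _km_curve(fit._time, fit._event)
        kw = {"km_times": km_t, "km_survival": km_s}
    # recompute information at beta for the test scale
    info = np.linalg.inv(fit.var_model)
    chi, p, chi_g, p_g = _cox.ph_test_statistics(t, s, info, transform=transform, **kw)
    rows = [{"term": term, "chi2": c, "df": 1, "p": pv}
            for term, c, pv in zip(fit.terms, chi, p)]
    rows.append({"term": "GLOBAL", "chi2": chi_g, "df": len(fit.terms), "p": p_g})
    return pd.DataFrame(rows)


def _km_curve(time, event):
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    et = np.unique(t[e])
    surv = []
    s = 1.0
    for ti in et:
        n_risk = (t >= ti).sum()
        d = ((t == ti) & e).sum()
        s *= 1.0 - d / n_risk
        surv.append(s)
    return et, np.asarray(surv)


# ---------------------------------------------------------------------------
# reporter normalization and quartile analysis

def normalize_reporter(
    series: pd.DataFrame,
    control_group: str,
    reference_time: float,
    value_col: str = "mean_green",
    group_col: str = "group",
    time_col: str = "time_h",
) -> pd.DataFrame:
    """Express reporter levels relative to the control group's mean at the
    reference time (control mean at reference maps to 1.0)."""
    at_ref = series[(series[group_col] == control_group)
                    & (series[time_col] == reference_time)]
    if len(at_ref) == 0:
        raise DataError(
            f"control group {control_group!r} has no measurement at t={reference_time}"
        )
    denom = at_ref[value_col].mean()
    if not denom > 0:
        raise DataError(f"control mean at reference time is {denom}, cannot normalize")
    out = series.copy()
    out[value_col] = out[value_col] / denom
    return out


@dataclass
class QuartileAssignment:
    """Quartile labels of the reporter level at one reference time."""

    reference_time: float
    value_col: str
    boundaries: np.ndarray          # 25/50/75 percentiles
    labels: pd.Series               # neuron_id -> "Q1".."Q4"

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(
            ["Q1", "Q2", "Q3", "Q4"], fill_value=0)


def assign_quartiles(
    records: pd.DataFrame,
    reference_time: float,
    value_col: str | None = None,
) -> QuartileAssignment:
    """Split neurons alive and measured at the reference time into quartiles
    of the reporter level there.

    Boundaries are the empirical 25/50/75 percentiles (linear
    interpolation); a value tied with a boundary goes to the lower
    quartile.  Neurons dead before the reference time are excluded.
    """
    value_col = value_col or reporter_column(reference_time)
    if value_col not in records.columns:
        raise AssignmentError(f"no reporter column {value_col!r} in records")
    eligible = records[(records["time"] >= reference_time)
                       & records[value_col].notna()]
    vals = eligible[value_col].to_numpy(dtype=float)
    if len(vals) < 4:
        raise AssignmentError(
            f"only {len(vals)} neurons measured at t={reference_time}; need >= 4"
        )
    q = np.percentile(vals, [25, 50, 75])  # linear interpolation
    if q[0] == q[2]:
        warnings.warn("degenerate reporter distribution: all quartile "
                      "boundaries equal; every neuron assigned Q1", stacklevel=2)
    labels = np.where(vals <= q[0], "Q1",
                      np.where(vals <= q[1], "Q2",
                               np.where(vals <= q[2], "Q3", "Q4")))
    return QuartileAssignment(
        reference_time=reference_time, value_col=value_col, boundaries=q,
        labels=pd.Series(labels, index=eligible["neuron_id"].to_numpy(),
                         name="quartile"),
    )


def quartile_hazard_model(
    records: pd.DataFrame,
    assignment: QuartileAssignment,
    adjust_by_group: bool = False,
    ties: str = "breslow",
) -> CoxFit:
    """Cox model of reporter quartiles (Q1 reference) on survival, clustered
    by well and stratified by plate.

    Follow-up is left-truncated at the reference time: a neuron enters the
    risk set only after its reporter level was measured, so early deaths
    cannot create immortal-time bias.  ``adjust_by_group`` adds the group
    indicator (second-step adjustment)."""
    t0 = assignment.reference_time
    sub = records[records["neuron_id"].isin(assignment.labels.index)].copy()
    sub["quartile"] = assignment.labels.loc[sub["neuron_id"]].to_numpy()
    sub = sub[sub["time"] > t0].copy()
    present = set(sub["quartile"].unique())
    assigned = set(assignment.labels.unique())
    for q in sorted(assigned):
        if q not in present:
            raise ModelError(f"quartile {q} has no neuron under observation after "
                             f"t={t0}")
    sub["entry"] = t0
    covs = ["quartile"] + (["group"] if adjust_by_group else [])
    return fit_cox(sub, covariates=covs, cluster_by="well", strata_by="plate",
                   ties=ties, entry_col="entry")
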