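"""Bounded-outcome trial analysis.

Implements the trial's analytic plan: bounded scores are shifted to a
binomial successes/trials scale (successes = score minus the scale minimum,
trials = the scale range), longitudinal measures are fit with marginal
binomial-logit estimating equations (saturated arm x timepoint mean
structure, participant clusters, classical sandwich covariance), sixteen
orthogonal contrasts in three families are tested with step-down Holm
adjustment at familywise alpha .05, and end-of-study measures get a single
two-group binomial-logit comparison.  Effect sizes are standardized mean
differences on the raw score scale.

Percent-scaled scores yield non-integer successes; these are handled as
quasi-binomial proportions, which the sandwich covariance makes valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

import statsmodels.api as sm

from .measures import LONGITUDINAL_MEASURES, REGISTRY, MeasureSpec
from .synth import ARMS, TIMEPOINTS, TrialDataset

__all__ = [
    "BinomialOutcome",
    "Contrast",
    "ContrastSet",
    "GEEResult",
    "EndpointResult",
    "AnalysisReport",
    "rescale_to_binomial",
    "fit_marginal_binomial",
    "build_contrasts",
    "holm_adjust",
    "cohens_d",
    "analyze_trial",
    "analyze_endpoint",
]

DEFAULT_CHANGES = (("T1", "T0"), ("T2", "T1"), ("T3", "T1"), ("T3", "T2"))


@dataclass(frozen=True)
class BinomialOutcome:
    """A bounded score re-expressed as successes out of trials."""

    successes: float
    trials: float

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError(
                f"successes {self.successes} outside [0, {self.trials}]"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def rescale_to_binomial(score: float, spec: MeasureSpec) -> BinomialOutcome:
    """Shift a bounded score to zero-minimum successes over range-many trials."""
    if not spec.total_min <= score <= spec.total_max:
        raise ValueError(
            f"{spec.name}: score {score} outside "
            f"[{spec.total_min}, {spec.total_max}]"
        )
    return BinomialOutcome(successes=score - spec.total_min, trials=spec.trials)


# ------------------------------------------------------------------ contrasts

@dataclass(frozen=True)
class Contrast:
    """One labelled linear contrast over the arm x timepoint cell parameters."""

    label: str
    family: str  # within_change | cross_sectional | change_difference
    vector: tuple[float, ...]
    arm: Optional[str] = None
    timepoint: Optional[str] = None
    change: Optional[tuple[str, str]] = None  # (later, earlier)
    arms: Optional[tuple[str, str]] = None  # (first, second) for arm differences


@dataclass(frozen=True)
class ContrastSet:
    cells: tuple[str, ...]
    contrasts: tuple[Contrast, ...]

    def __post_init__(self) -> None:
        for c in self.contrasts:
            if len(c.vector) != len(self.cells):
                raise ValueError(f"contrast {c.label}: wrong vector length")
            if abs(sum(c.vector)) > 1e-12:
                raise ValueError(f"contrast {c.label}: vector does not sum to 0")

    def family(self, name: str) -> list[Contrast]:
        return [c for c in self.contrasts if c.family == name]

    def __len__(self) -> int:
        return len(self.contrasts)


def cell_label(arm: str, timepoint: str) -> str:
    return f"{arm}:{timepoint}"


def build_contrasts(
    timepoints: Sequence[str] = TIMEPOINTS,
    arms: Sequence[str] = ARMS,
    changes: Sequence[tuple[str, str]] = DEFAULT_CHANGES,
) -> ContrastSet:
    """The default 16-hypothesis contrast set in its three families.

    Families: per-arm within-condition changes (2 arms x 4 change
    definitions = 8), arm differences at each timepoint cross-sectionally
    (4), and arm differences in each change definition (4).
    """
    if len(arms) != 2:
        raise ValueError("contrast set is defined for exactly 2 arms")
    cells = tuple(cell_label(a, t) for a in arms for t in timepoints)
    index = {c: i for i, c in enumerate(cells)}

    def vec(entries: dict[str, float]) -> tuple[float, ...]:
        v = [0.0] * len(cells)
        for cell, w in entries.items():
            v[index[cell]] += w
        return tuple(v)

    a1, a2 = arms
    out: list[Contrast] = []
    for arm in arms:
        for later, earlier in changes:
            out.append(
                Contrast(
                    label=f"{arm}:{later}-{earlier}",
                    family="within_change",
                    vector=vec({cell_label(arm, later): 1.0,
                                cell_label(arm, earlier): -1.0}),
                    arm=arm,
                    change=(later, earlier),
                )
            )
    for tp in timepoints:
        out.append(
            Contrast(
                label=f"{a1}-{a2}:{tp}",
                family="cross_sectional",
                vector=vec({cell_label(a1, tp): 1.0, cell_label(a2, tp): -1.0}),
                timepoint=tp,
                arms=(a1, a2),
            )
        )
    for later, earlier in changes:
        out.append(
            Contrast(
                label=f"{a1}-{a2}:{later}-{earlier}",
                family="change_difference",
                vector=vec(
                    {
                        cell_label(a1, later): 1.0,
                        cell_label(a1, earlier): -1.0,
                        cell_label(a2, later): -1.0,
                        cell_label(a2, earlier): 1.0,
                    }
                ),
                change=(later, earlier),
                arms=(a1, a2),
            )
        )
    return ContrastSet(cells=cells, contrasts=tuple(out))


# ------------------------------------------------------------------ GEE fit

@dataclass(frozen=True)
class GEEResult:
    """Saturated marginal binomial fit: cell logits plus sandwich covariance."""

    measure: str
    cells: tuple[str, ...]
    params: np.ndarray  # logit-scale cell estimates, in `cells` order
    cov: np.ndarray  # robust (sandwich) covariance of params
    n_clusters: int
    working_correlation: str
    converged: bool
    spec: MeasureSpec

    def cell_proportions(self) -> pd.Series:
        return pd.Series(expit(self.params), index=list(self.cells))

    def cell_table(self, confidence: float = 0.95) -> pd.DataFrame:
        """Model cell means with Wald CIs back-transformed to the score scale."""
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        se = np.sqrt(np.diag(self.cov))
        rows = []
        for i, cell in enumerate(self.cells):
            arm, tp = cell.split(":")
            p, lo, hi = (
                expit(self.params[i]),
                expit(self.params[i] - z * se[i]),
                expit(self.params[i] + z * se[i]),
            )
            rows.append(
                {
                    "arm": arm,
                    "timepoint": tp,
                    "mean": self.spec.total_min + self.spec.trials * p,
                    "ci_low": self.spec.total_min + self.spec.trials * lo,
                    "ci_high": self.spec.total_min + self.spec.trials * hi,
                }
            )
        return pd.DataFrame(rows)


def _continuity_adjust(df: pd.DataFrame, spec: MeasureSpec) -> pd.Series:
    """Successes with a 0.5 adjustment applied to degenerate (all-0/all-max) cells."""
    successes = df["score"].astype(float) - spec.total_min
    for (_, _), idx in df.groupby(["arm", "timepoint"]).groups.items():
        cell = successes.loc[idx]
        if (cell == 0).all():
            successes.loc[idx] = 0.5
        elif (cell == spec.trials).all():
            successes.loc[idx] = spec.trials - 0.5
    return successes


def fit_marginal_binomial(
    data: Union[TrialDataset, pd.DataFrame],
    measure: str,
    working_correlation: str = "independence",
) -> GEEResult:
    """Fit the saturated marginal binomial-logit model for one measure.

    One mean parameter per arm x timepoint cell on the logit scale;
    participants are the correlation clusters; the returned covariance is the
    classical robust sandwich.  Degenerate cells (every score at a bound)
    receive a 0.5 continuity adjustment on successes before fitting.
    """
    df = data.data if isinstance(data, TrialDataset) else data
    df = df[df["measure"] == measure].copy()
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    spec = REGISTRY[measure]
    arms = tuple(dict.fromkeys(df["arm"]))
    timepoints = tuple(dict.fromkeys(df["timepoint"]))
    cells = tuple(cell_label(a, t) for a in arms for t in timepoints)

    df = df.sort_values(["participant_id", "timepoint"], kind="stable")
    df["_prop"] = _continuity_adjust(df, spec) / spec.trials
    exog = pd.DataFrame(0.0, index=df.index, columns=list(cells))
    for cell in cells:
        arm, tp = cell.split(":")
        exog.loc[(df["arm"] == arm) & (df["timepoint"] == tp), cell] = 1.0
    if (exog.sum(axis=1) != 1.0).any():
        raise ValueError("each observation must fall in exactly one design cell")

    cov_struct = {
        "independence": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
    }
    if working_correlation not in cov_struct:
        raise ValueError(
            f"working_correlation must be one of {sorted(cov_struct)}"
        )
    model = sm.GEE(
        endog=df["_prop"].to_numpy(),
        exog=exog.to_numpy(),
        groups=df["participant_id"].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=cov_struct[working_correlation](),
    )
    res = model.fit()
    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
        raise RuntimeError(f"{measure}: estimating equations did not converge")
    return GEEResult(
        measure=measure,
        cells=cells,
        params=params,
        cov=cov,
        n_clusters=df["participant_id"].nunique(),
        working_correlation=working_correlation,
        converged=bool(getattr(res, "converged", True)),
        spec=spec,
    )


# ------------------------------------------------------------------ inference

def holm_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity, cap at 1.  Equals Bonferroni for the smallest p value.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_p must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _contrast_test(
    result: GEEResult,
    contrast: Contrast,
    dist: str = "normal",
    df: Optional[float] = None,
    confidence: float = 0.95,
) -> dict:
    c = np.asarray(contrast.vector, dtype=float)
    est = float(c @ result.params)
    var = float(c @ result.cov @ c)
    if var <= 0:
        raise RuntimeError(f"contrast {contrast.label}: non-positive variance")
    se = var ** 0.5
    stat = est / se
    if dist == "normal":
        p = 2.0 * stats.norm.sf(abs(stat))
        q = stats.norm.ppf(0.5 + confidence / 2.0)
    elif dist == "t":
        if df is None or df <= 0:
            raise ValueError("t reference distribution requires positive df")
        p = 2.0 * stats.t.sf(abs(stat), df)
        q = stats.t.ppf(0.5 + confidence / 2.0, df)
    else:
        raise ValueError("dist must be 'normal' or 't'")
    return {
        "label": contrast.label,
        "family": contrast.family,
        "estimate": est,
        "se": se,
        "statistic": stat,
        "p_raw": p,
        "ci_low": est - q * se,
        "ci_high": est + q * se,
    }


def _wide_scores(df: pd.DataFrame) -> pd.DataFrame:
    return df.pivot_table(
        index=["participant_id", "arm"], columns="timepoint", values="score"
    ).reset_index()


def cohens_d(data: Union[TrialDataset, pd.DataFrame], measure: str,
             contrast: Contrast) -> float:
    """Standardized effect size on the raw score scale for one contrast.

    Within-condition change: mean change / SD of changes in that arm.
    Cross-sectional: arm mean difference / pooled SD at that timepoint.
    Change difference: arm difference in mean change / pooled SD of changes.
    Raises on zero variance.
    """
    df = data.data if isinstance(data, TrialDataset) else data
    df = df[df["measure"] == measure]
    wide = _wide_scores(df)

    def pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        return float(
            np.sqrt(((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2))
        )

    if contrast.family == "within_change":
        later, earlier = contrast.change
        sub = wide[wide["arm"] == contrast.arm]
        diffs = (sub[later] - sub[earlier]).to_numpy(dtype=float)
        sd = float(np.std(diffs, ddof=1))
        if sd == 0:
            raise ZeroDivisionError(
                f"{contrast.label}: zero variance in change scores"
            )
        return float(np.mean(diffs)) / sd
    if contrast.family == "cross_sectional":
        first, second = contrast.arms
        x = wide.loc[wide["arm"] == first, contrast.timepoint].to_numpy(float)
        y = wide.loc[wide["arm"] == second, contrast.timepoint].to_numpy(float)
        sd = pooled_sd(x, y)
        if sd == 0:
            raise ZeroDivisionError(f"{contrast.label}: zero pooled variance")
        return float(np.mean(x) - np.mean(y)) / sd
    if contrast.family == "change_difference":
        later, earlier = contrast.change
        first, second = contrast.arms
        dx = wide.loc[wide["arm"] == first]
        dy = wide.loc[wide["arm"] == second]
        x = (dx[later] - dx[earlier]).to_numpy(dtype=float)
        y = (dy[later] - dy[earlier]).to_numpy(dtype=float)
        sd = pooled_sd(x, y)
        if sd == 0:
            raise ZeroDivisionError(f"{contrast.label}: zero pooled variance")
        return float(np.mean(x) - np.mean(y)) / sd
    raise ValueError(f"unknown contrast family {contrast.family!r}")


# ------------------------------------------------------------------ reports

@dataclass(frozen=True)
class MeasureAnalysis:
    measure: str
    gee: GEEResult
    cells: pd.DataFrame  # empirical + model summaries per cell
    contrasts: pd.DataFrame  # 16 hypothesis rows


@dataclass(frozen=True)
class AnalysisReport:
    """Full longitudinal analysis: one 16-row hypothesis table per measure."""

    measures: dict
    alpha: float = 0.05

    def contrast_frame(self) -> pd.DataFrame:
        frames = []
        for name, ma in self.measures.items():
            f = ma.contrasts.copy()
            f.insert(0, "measure", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def cell_frame(self) -> pd.DataFrame:
        frames = []
        for name, ma in self.measures.items():
            f = ma.cells.copy()
            f.insert(0, "measure", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.contrast_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "measures": {
                name: {
                    "working_correlation": ma.gee.working_correlation,
                    "n_clusters": ma.gee.n_clusters,
                    "converged": ma.gee.converged,
                    "cells": ma.cells.to_dict(orient="records"),
                    "contrasts": ma.contrasts.to_dict(orient="records"),
                }
                for name, ma in self.measures.items()
            },
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _empirical_cells(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby(["arm", "timepoint"], sort=False)["score"]
    out = g.agg(n="count", empirical_mean="mean", sd="std").reset_index()
    return out


def analyze_trial(
    data: Union[TrialDataset, pd.DataFrame],
    measures: Optional[Sequence[str]] = None,
    working_correlation: str = "independence",
    dist: str = "normal",
    df: Optional[float] = None,
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run the full longitudinal analysis.

    Per measure: saturated marginal binomial fit, the 16-contrast set with
    raw p values, one Holm family spanning those 16 hypotheses, unadjusted
    95% CIs, and standardized effect sizes; cell summaries combine empirical
    means/SDs with model means and back-transformed CIs.
    """
    frame = data.data if isinstance(data, TrialDataset) else data
    if measures is None:
        present = list(dict.fromkeys(frame["measure"]))
        measures = [m for m in LONGITUDINAL_MEASURES if m in present] or present
    out: dict[str, MeasureAnalysis] = {}
    for measure in measures:
        sub = frame[frame["measure"] == measure]
        gee = fit_marginal_binomial(sub, measure, working_correlation)
        arms = tuple(dict.fromkeys(sub["arm"]))
        timepoints = tuple(dict.fromkeys(sub["timepoint"]))
        cset = build_contrasts(timepoints=timepoints, arms=arms)
        rows = [
            _contrast_test(gee, c, dist=dist, df=df) for c in cset.contrasts
        ]
        table = pd.DataFrame(rows)
        table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
        table["cohens_d"] = [
            cohens_d(sub, measure, c) for c in cset.contrasts
        ]
        cells = _empirical_cells(sub).merge(
            gee.cell_table(), on=["arm", "timepoint"]
        )
        out[measure] = MeasureAnalysis(
            measure=measure, gee=gee, cells=cells, contrasts=table
        )
    return AnalysisReport(measures=out, alpha=alpha)


# -------------------------------------------------------------- endpoint GLM

@dataclass(frozen=True)
class EndpointResult:
    """Single-hypothesis two-group binomial-logit comparison at one timepoint."""

    measure: str
    arms: tuple[str, str]
    group_means: pd.DataFrame
    estimate: float  # arm logit difference (first arm minus second)
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float

    def hypothesis_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": self.measure,
                    "label": f"{self.arms[0]}-{self.arms[1]}",
                    "estimate": self.estimate,
                    "se": self.se,
                    "statistic": self.statistic,
                    "p_raw": self.p_value,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                }
            ]
        )


def analyze_endpoint(
    data: pd.DataFrame, measure: str, confidence: float = 0.95
) -> EndpointResult:
    """Two-group binomial-logit comparison with sandwich covariance.

    One score per participant; a single unadjusted hypothesis (the arm
    difference on the logit scale) is tested against the standard normal.
    """
    df = data[data["measure"] == measure].copy()
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    spec = REGISTRY[measure]
    arms = tuple(dict.fromkeys(df["arm"]))
    if len(arms) != 2:
        raise ValueError(f"endpoint comparison needs exactly 2 arms, got {arms}")
    prop = _continuity_adjust(df, spec) / spec.trials
    exog = np.column_stack(
        [np.ones(len(df)), (df["arm"] == arms[0]).to_numpy(dtype=float)]
    )
    model = sm.GLM(prop.to_numpy(), exog, family=sm.families.Binomial())
    res = model.fit(cov_type="HC0")
    est = float(res.params[1])
    se = float(np.sqrt(res.cov_params()[1, 1]))
    stat = est / se
    p = 2.0 * stats.norm.sf(abs(stat))
    q = stats.norm.ppf(0.5 + confidence / 2.0)
    means = (
        df.groupby("arm", sort=False)["score"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    return EndpointResult(
        measure=measure,
        arms=arms,
        group_means=means,
        estimate=est,
        se=se,
        statistic=stat,
        p_value=p,
        ci_low=est - q * se,
        ci_high=est + q * se,
    )
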