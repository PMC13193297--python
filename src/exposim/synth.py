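"""Synthetic trial-data generator.

Emulates the trial design — two arms (20 head-mounted-display, 21 desktop),
four timepoints, three bounded longitudinal measures plus end-of-study
ratings — with a logit-normal-binomial generating model: each participant
carries a latent normal effect on the logit scale, inducing within-
participant correlation across cells, and each cell score is a binomial
draw over the measure's range.  Data are always complete (no attrition, no
missing cells).

Default cell means are realistic group-by-timepoint values for this kind
of training trial; they are generator defaults, not estimation targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .measures import REGISTRY, LONGITUDINAL_MEASURES, MeasureSpec

__all__ = [
    "ARMS",
    "TIMEPOINTS",
    "DEFAULT_CELL_MEANS",
    "DEFAULT_ENDPOINT_MEANS",
    "GeneratorConfig",
    "TrialDataset",
    "generate_trial",
    "generate_endpoint_scores",
]

ARMS = ("hmd", "desktop")
TIMEPOINTS = ("T0", "T1", "T2", "T3")

# Default generating means by arm and timepoint.
DEFAULT_CELL_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "knowledge": {
        "hmd": {"T0": 34.17, "T1": 45.83, "T2": 45.42, "T3": 45.83},
        "desktop": {"T0": 42.46, "T1": 50.79, "T2": 51.98, "T3": 53.57},
    },
    "self_efficacy": {
        "hmd": {"T0": 72.35, "T1": 100.45, "T2": 110.70, "T3": 114.00},
        "desktop": {"T0": 87.52, "T1": 108.52, "T2": 117.29, "T3": 120.38},
    },
    "tbes": {
        "hmd": {"T0": 30.90, "T1": 21.20, "T2": 16.65, "T3": 15.95},
        "desktop": {"T0": 28.76, "T1": 21.19, "T2": 16.33, "T3": 14.71},
    },
}

# Default end-of-study measure means per arm (T2 only).
DEFAULT_ENDPOINT_MEANS: dict[str, dict[str, float]] = {
    "sus": {"hmd": 86.2, "desktop": 93.4},
    "vp_eval": {"hmd": 50.9, "desktop": 50.8},
    "tars_acceptability": {"hmd": 31.0, "desktop": 31.2},
    "tars_utility": {"hmd": 29.5, "desktop": 31.0},
}

# fixed sub-stream ids so each endpoint measure gets an independent,
# reproducible stream from one root seed
_STREAM_IDS = {"trial": 0, "sus": 1, "vp_eval": 2, "tars_acceptability": 3,
               "tars_utility": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and generating-model parameters for one synthetic trial."""

    n_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {"hmd": 20, "desktop": 21}
    )
    timepoints: tuple[str, ...] = TIMEPOINTS
    measures: tuple[str, ...] = LONGITUDINAL_MEASURES
    cell_means: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_CELL_MEANS
    )
    endpoint_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ENDPOINT_MEANS
    )
    subject_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        for arm, n in self.n_per_arm.items():
            if n < 1:
                raise ValueError(f"n_per_arm[{arm!r}] must be >= 1")
        for measure in self.measures:
            spec = REGISTRY[measure]
            for arm in self.n_per_arm:
                for tp in self.timepoints:
                    mu = self.cell_means[measure][arm][tp]
                    if not spec.total_min <= mu <= spec.total_max:
                        raise ValueError(
                            f"cell mean {mu} for {measure}/{arm}/{tp} outside "
                            f"[{spec.total_min}, {spec.total_max}]"
                        )

    @property
    def n_total(self) -> int:
        return sum(self.n_per_arm.values())

    def to_dict(self) -> dict:
        return {
            "n_per_arm": dict(self.n_per_arm),
            "timepoints": list(self.timepoints),
            "measures": list(self.measures),
            "cell_means": {
                m: {a: dict(tps) for a, tps in arms.items()}
                for m, arms in self.cell_means.items()
            },
            "endpoint_means": {m: dict(a) for m, a in self.endpoint_means.items()},
            "subject_sd": self.subject_sd,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrialDataset:
    """Long-format bounded trial scores plus generation provenance."""

    data: pd.DataFrame  # participant_id, arm, timepoint, measure, score
    provenance: dict

    def validate(self) -> None:
        df = self.data
        required = {"participant_id", "arm", "timepoint", "measure", "score"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataset missing columns {required - set(df.columns)}")
        arms_per_pid = df.groupby("participant_id")["arm"].nunique()
        if (arms_per_pid > 1).any():
            raise ValueError("a participant appears in more than one arm")
        for measure, sub in df.groupby("measure"):
            spec = REGISTRY[str(measure)]
            if (sub["score"] < spec.total_min).any() or (
                sub["score"] > spec.total_max
            ).any():
                raise ValueError(f"{measure}: score outside measure bounds")
            cells = sub.groupby("participant_id")["timepoint"].nunique()
            if cells.nunique() > 1:
                raise ValueError(f"{measure}: incomplete timepoint coverage")

    def to_csv(self, path: Union[str, Path], sidecar: bool = True) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        if sidecar:
            side = path.with_suffix(".provenance.json")
            side.write_text(json.dumps(self.provenance, indent=2) + "\n",
                            encoding="utf-8")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TrialDataset":
        path = Path(path)
        data = pd.read_csv(path)
        side = path.with_suffix(".provenance.json")
        provenance = (
            json.loads(side.read_text(encoding="utf-8")) if side.exists() else {}
        )
        ds = cls(data=data, provenance=provenance)
        ds.validate()
        return ds


def _participants(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    out = []
    i = 0
    for arm in cfg.n_per_arm:
        for _ in range(cfg.n_per_arm[arm]):
            i += 1
            out.append((f"P{i:03d}", arm))
    return out


def _draw_cell(
    rng: np.random.Generator, spec: MeasureSpec, mean: float, offset: float
) -> float:
    """One bounded score: binomial over the measure range on the shifted logit.

    Knowledge is drawn on its 12-item correct-count grid and converted to
    percent; everything else is drawn directly on the total-score range.
    """
    if spec.scoring == "percent_correct":
        trials = spec.n_items
        p = (mean - spec.total_min) / spec.trials
    else:
        trials = int(round(spec.trials))
        p = (mean - spec.total_min) / spec.trials
    p = min(max(p, 1e-9), 1 - 1e-9)
    p_i = expit(logit(p) + offset)
    draw = rng.binomial(trials, p_i)
    if spec.scoring == "percent_correct":
        return 100.0 * draw / spec.n_items
    return spec.total_min + float(draw)


def generate_trial(cfg: GeneratorConfig = GeneratorConfig()) -> TrialDataset:
    """Generate one complete longitudinal trial dataset.

    Per participant a latent effect ``b ~ Normal(0, subject_sd^2)`` is drawn
    once and shared across all cells, then each arm x timepoint x measure
    score is an independent binomial draw at inverse-logit(logit(cell mean
    proportion) + b).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM_IDS["trial"]])
    )
    records = []
    for pid, arm in _participants(cfg):
        b = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd > 0 else 0.0
        for measure in cfg.measures:
            spec = REGISTRY[measure]
            for tp in cfg.timepoints:
                mean = cfg.cell_means[measure][arm][tp]
                score = _draw_cell(rng, spec, mean, b)
                records.append(
                    {
                        "participant_id": pid,
                        "arm": arm,
                        "timepoint": tp,
                        "measure": measure,
                        "score": score,
                    }
                )
    ds = TrialDataset(
        data=pd.DataFrame.from_records(records),
        provenance={"generator": "exposim.synth.generate_trial",
                    "config": cfg.to_dict()},
    )
    ds.validate()
    return ds


def generate_endpoint_scores(
    cfg: GeneratorConfig, measure: str, timepoint: str = "T2"
) -> pd.DataFrame:
    """One bounded end-of-study score per participant (post-experiential only).

    Uses the same logit-normal-binomial mechanism as the longitudinal
    generator, on an independent random stream derived from ``cfg.seed``.
    """
    if measure not in cfg.endpoint_means:
        raise ValueError(
            f"no endpoint means configured for {measure!r}; "
            f"available: {sorted(cfg.endpoint_means)}"
        )
    spec = REGISTRY[measure]
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM_IDS.get(measure, 99)])
    )
    records = []
    for pid, arm in _participants(cfg):
        b = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd > 0 else 0.0
        mean = cfg.endpoint_means[measure][arm]
        if not spec.total_min <= mean <= spec.total_max:
            raise ValueError(
                f"endpoint mean {mean} for {measure}/{arm} outside bounds"
            )
        score = _draw_cell(rng, spec, mean, b)
        records.append(
            {
                "participant_id": pid,
                "arm": arm,
                "timepoint": timepoint,
                "measure": measure,
                "score": score,
            }
        )
    return pd.DataFrame.from_records(records)
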