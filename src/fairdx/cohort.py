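"""Synthetic cohort and prediction-table generation.

Stands in for a small remote mental-health interview cohort (~73 adults,
aged 18-65) whose subject table carries demographics (gender, race, age,
years of education), self-rated scale scores (PHQ-9, 0-27; GAD-7, 0-21)
and a clinician-assigned binary label (control vs. mental health
condition, MHC). Every downstream stage — composition audit, fairness
metrics, cross-validation harness, threshold mitigation — is exercised
against cohorts produced here with *known* group structure:

- group sizes are exact (specified counts, not multinomial draws);
- the clinical label is Bernoulli with a per-(attribute, group) base
  rate, so label-demographic dependence is a configuration knob;
- each "modality" is a block of spherical Gaussian features whose
  class-mean separation can differ by group, so a classifier trained on
  them exhibits controllable TPR/FPR disparities (within-group Bayes
  accuracy is the closed form ``Phi(separation / (2 * noise_sd))``);
- scale scores are label-conditional discretized Gaussians clipped to
  the instrument range, giving a controllable overlap at the >10 cutoff.

:func:`generate_prediction_fixture` additionally builds long-format
prediction tables whose per-group confusion counts are constructed
*exactly* (a target TPR of 0.9 with 10 positives yields exactly 9 true
positives), which makes them machine-precision oracles for the metric
formulas; a ``sampled`` mode replaces exact placement with Bernoulli
draws for stochastic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ModalitySpec",
    "CohortConfig",
    "GroupFixture",
    "RateFixtureConfig",
    "generate_cohort",
    "generate_prediction_fixture",
    "bayes_accuracy",
    "default_cohort_config",
]

SUBJECT_COLUMNS = [
    "subject_id", "gender", "race", "age_years", "education_years",
    "phq9", "gad7", "clinical_label",
]

_SCALE_RANGES = {"phq9": (0, 27), "gad7": (0, 21)}

# label-conditional (mean, sd) defaults chosen so the positive class mostly
# clears the >10 cutoff and the negative class mostly does not, with overlap
_DEFAULT_SCALE_PARAMS = {
    "phq9": {0: (5.0, 3.0), 1: (14.0, 4.0)},
    "gad7": {0: (4.0, 3.0), 1: (12.0, 4.0)},
}


@dataclass(frozen=True)
class ModalitySpec:
    """One synthetic feature modality.

    ``separation`` is the Euclidean distance between the positive- and
    negative-class feature means; a mapping gives per-group values keyed
    by the levels of ``attribute`` (required in that case).
    """

    name: str
    n_features: int
    separation: float | Mapping[str, float]
    noise_sd: float = 1.0
    attribute: str | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if isinstance(self.separation, Mapping) and self.attribute is None:
            raise ValueError(
                f"modality {self.name!r}: per-group separation requires 'attribute'")

    def separation_for(self, group: str) -> float:
        if isinstance(self.separation, Mapping):
            return float(self.separation[group])
        return float(self.separation)


def bayes_accuracy(separation: float, noise_sd: float = 1.0) -> float:
    """Optimal within-group accuracy of the spherical-Gaussian generator
    at equal class priors: Phi(separation / (2 * noise_sd))."""
    return float(norm.cdf(separation / (2.0 * noise_sd)))


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    groups : mapping attribute -> sequence of (level, count)
        Exact group sizes per demographic attribute. Counts must sum to
        the same total for every attribute (each subject has exactly one
        level per attribute).
    base_rate : mapping attribute -> {level: P(label = 1)}
        Per-group probability of the positive clinical label. When more
        than one attribute carries base rates, a subject's probability
        is the mean of the rates applicable to its group memberships.
    scale_params : {"phq9"|"gad7": {label: (mean, sd)}}
        Label-conditional Gaussian parameters for the scale scores.
    modalities : sequence of ModalitySpec
    age_range, education_range : (low, high) integer covariate supports
    seed : master seed for all sampling
    """

    groups: Mapping[str, Sequence[tuple[str, int]]]
    base_rate: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    scale_params: Mapping[str, Mapping[int, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_SCALE_PARAMS)
    modalities: Sequence[ModalitySpec] = field(default_factory=tuple)
    age_range: tuple[int, int] = (18, 65)
    education_range: tuple[int, int] = (8, 22)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = set()
        for attr, levels in self.groups.items():
            if not levels:
                raise ValueError(f"attribute {attr!r} has no groups")
            for level, count in levels:
                if count < 0:
                    raise ValueError(f"negative count for {attr}={level}")
            sizes.add(sum(c for _, c in levels))
        if len(sizes) > 1:
            raise ValueError(
                "inconsistent group definitions: per-attribute counts sum to "
                f"{sorted(sizes)}; a subject must have exactly one group per attribute")
        if not sizes or sizes == {0}:
            raise ValueError("cohort is empty")
        for attr, rates in self.base_rate.items():
            if attr not in self.groups:
                raise ValueError(f"base_rate references unknown attribute {attr!r}")
            known = {level for level, _ in self.groups[attr]}
            for level, p in rates.items():
                if level not in known:
                    raise ValueError(f"base_rate references unknown group {attr}={level}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"base rate for {attr}={level} not in [0, 1]")
        for scale, per_label in self.scale_params.items():
            if scale not in _SCALE_RANGES:
                raise ValueError(f"unknown scale {scale!r}")

    @property
    def n_subjects(self) -> int:
        first = next(iter(self.groups.values()))
        return sum(c for _, c in first)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """A demo cohort approximating the emulated study frame: n = 73 with
    a ~22 control / 51 MHC split, small race/gender minorities below the
    n >= 5 retention threshold, and one moderately informative modality."""
    return CohortConfig(
        groups={
            "gender": [("female", 38), ("male", 33), ("nonbinary", 2)],
            "race": [("white", 41), ("black", 17), ("asian", 9),
                     ("hispanic", 2), ("other", 4)],
        },
        base_rate={"gender": {"female": 0.70, "male": 0.70, "nonbinary": 0.70}},
        modalities=(
            ModalitySpec("facial", 8, 1.8),
            ModalitySpec("acoustic", 8, 1.4),
        ),
        seed=seed,
    )


def _assign_groups(rng: np.random.Generator, n: int,
                   levels: Sequence[tuple[str, int]]) -> np.ndarray:
    values = np.repeat([lv for lv, _ in levels], [c for _, c in levels])
    return rng.permutation(values)


def _draw_scale(rng: np.random.Generator, labels: np.ndarray, scale: str,
                params: Mapping[int, tuple[float, float]]) -> np.ndarray:
    lo, hi = _SCALE_RANGES[scale]
    out = np.empty(len(labels), dtype=int)
    for lab in (0, 1):
        mask = labels == lab
        mean, sd = params[lab]
        draws = rng.normal(mean, sd, size=int(mask.sum()))
        out[mask] = np.clip(np.rint(draws), lo, hi).astype(int)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate the subject table and per-modality feature blocks.

    Returns ``(subjects, features)`` where ``subjects`` has one row per
    subject (columns: subject_id, the configured attributes, age_years,
    education_years, phq9, gad7, clinical_label) and ``features`` maps
    modality name to a numeric block indexed by subject_id. Deterministic
    for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})

    for attr, levels in config.groups.items():
        subjects[attr] = _assign_groups(rng, n, levels)

    # label probability: mean of the applicable per-attribute base rates
    if config.base_rate:
        probs = np.zeros(n)
        weight = np.zeros(n)
        for attr, rates in config.base_rate.items():
            col = subjects[attr].to_numpy()
            for level, p in rates.items():
                mask = col == level
                probs[mask] += p
                weight[mask] += 1
        probs = np.where(weight > 0, probs / np.maximum(weight, 1), 0.7)
    else:
        probs = np.full(n, 0.7)
    subjects["clinical_label"] = (rng.random(n) < probs).astype(int)

    labels = subjects["clinical_label"].to_numpy()
    lo_a, hi_a = config.age_range
    subjects["age_years"] = np.clip(
        np.rint(rng.normal(38.0, 12.0, size=n)), lo_a, hi_a).astype(int)
    lo_e, hi_e = config.education_range
    subjects["education_years"] = np.clip(
        np.rint(rng.normal(16.0, 2.5, size=n)), lo_e, hi_e).astype(int)
    subjects["phq9"] = _draw_scale(rng, labels, "phq9", config.scale_params["phq9"])
    subjects["gad7"] = _draw_scale(rng, labels, "gad7", config.scale_params["gad7"])

    features: dict[str, pd.DataFrame] = {}
    for spec in config.modalities:
        d = spec.n_features
        unit = np.ones(d) / np.sqrt(d)
        if isinstance(spec.separation, Mapping):
            sep = subjects[spec.attribute].map(spec.separation_for).to_numpy(float)
        else:
            sep = np.full(n, float(spec.separation))
        signs = np.where(labels == 1, 0.5, -0.5)
        means = np.outer(signs * sep, unit)
        block = means + rng.normal(0.0, spec.noise_sd, size=(n, d))
        features[spec.name] = pd.DataFrame(
            block, index=pd.Index(subjects["subject_id"], name="subject_id"),
            columns=[f"{spec.name}_{j}" for j in range(d)])

    cols = ["subject_id", *config.groups.keys(), "age_years", "education_years",
            "phq9", "gad7", "clinical_label"]
    return subjects[cols], features


# ---------------------------------------------------------------------------
# exact-count prediction fixtures


@dataclass(frozen=True)
class GroupFixture:
    """Exact target composition of one group's confusion matrix."""

    group: str
    n_positive: int
    n_negative: int
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be >= 0")
        for name, rate in (("tpr", self.tpr), ("fpr", self.fpr)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class RateFixtureConfig:
    """A prediction table with per-group confusion counts fixed by design."""

    groups: Sequence[GroupFixture]
    attribute: str = "group"
    seed: int = 0
    sampled: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")


def _exact_count(rate: float, n: int, what: str, group: str) -> int:
    if n == 0:
        return 0
    k = rate * n
    k_round = round(k)
    if abs(k - k_round) > 1e-9:
        nearest = k_round / n
        raise ValueError(
            f"target {what} {rate} is not representable with n={n} in group "
            f"{group!r}; nearest representable rate is {nearest}")
    return int(k_round)


def generate_prediction_fixture(
    config: RateFixtureConfig,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Build a long-format prediction table realizing the configured rates.

    In exact mode (default) the number of true/false positives per group
    is ``rate * n`` exactly, so metrics computed downstream have zero
    sampling noise; a non-integer target raises a ``ValueError`` naming
    the nearest representable rate. In ``sampled`` mode predicted labels
    are Bernoulli draws at the target rates instead.

    Scores are drawn consistent with the predicted labels under the
    strictly-greater-than-0.5 decision rule: predicted positives get
    scores in (0.5, 1], predicted negatives in [0, 0.5].
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    sid = 0
    for rep in range(1, n_repeats + 1):
        sid = 0
        for gf in config.groups:
            if config.sampled:
                pred_pos = rng.random(gf.n_positive) < gf.tpr
                pred_neg = rng.random(gf.n_negative) < gf.fpr
            else:
                n_tp = _exact_count(gf.tpr, gf.n_positive, "TPR", gf.group)
                n_fp = _exact_count(gf.fpr, gf.n_negative, "FPR", gf.group)
                pred_pos = np.zeros(gf.n_positive, dtype=bool)
                pred_pos[:n_tp] = True
                pred_neg = np.zeros(gf.n_negative, dtype=bool)
                pred_neg[:n_fp] = True
            for y, preds in ((1, pred_pos), (0, pred_neg)):
                for p in preds:
                    score = (rng.uniform(0.5, 1.0) + 1e-9 if p
                             else rng.uniform(0.0, 0.5))
                    rows.append({
                        "subject_id": f"S{sid:05d}",
                        "repeat": rep,
                        "fold": 1,
                        "y_true": y,
                        "score": min(score, 1.0),
                        "y_pred": int(p),
                        config.attribute: gf.group,
                    })
                    sid += 1
    return pd.DataFrame(rows)
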