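"""Behavior-Metabolome Age (BMAge) composite scoring.

Every raw behavioral metric and biomarker intensity is standardized
against the young reference group (Z = (x - mean_young) / sd_young,
sample SD with the n-1 denominator). The sub-scores are:

* motor score — arithmetic mean of the six kinematic Z's
  (frame distance, movement speed/energy of the back, running, center
  time ratio, body length);
* characteristic score — mean of the seven behavioral-sequence Z's
  with the pausing-followed-by-sniffing term negated (it rises with
  age while the others fall): (Z1 + ... + Z6 - Z_pausing) / 7;
* behavioral total — (motor + characteristic) / 2;
* metabolomic score — (sum of Z over up-regulated biomarkers - sum of
  Z over down-regulated biomarkers) / total biomarker count.

A simple linear regression of the metabolomic on the behavioral score
tests whether the two domains move together, and Spearman correlation
relates scores to external covariates (taxa abundances, SM/Cer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError

__all__ = [
    "ZReference",
    "BmageResult",
    "fit_reference",
    "motor_score",
    "characteristic_score",
    "metabolome_score",
    "score_regression",
    "spearman_corr",
    "BmageScorer",
    "DEFAULT_KINEMATIC_METRICS",
    "DEFAULT_SEQUENCE_METRICS",
]

DEFAULT_KINEMATIC_METRICS: tuple[str, ...] = (
    "frame_distance",
    "movement_speed_back",
    "movement_energy_back",
    "running",
    "center_time_ratio",
    "body_length",
)

#: pausing-followed-by-sniffing must stay last: it enters with a minus sign
DEFAULT_SEQUENCE_METRICS: tuple[str, ...] = (
    "falling_right_turn",
    "rearing",
    "trotting_exploring",
    "walking_sniffing_head_down",
    "walking_sniffing_left_turn",
    "walking_sniffing_right_turn",
    "pausing_sniffing",
)


@dataclass
class ZReference:
    """Per-metric young-group mean and SD used for standardization."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        bad = self.sd.index[(self.sd <= 0) | self.sd.isna()]
        if len(bad):
            raise DomainError(f"zero or undefined reference SD for metric {bad[0]!r}")

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        """Z-scores of ``values`` (columns = metrics) vs this reference."""
        cols = self.mean.index
        missing = [c for c in cols if c not in values.columns]
        if missing:
            raise DomainError(f"metrics absent from data: {missing}")
        return (values[cols] - self.mean) / self.sd


def fit_reference(young_rows: pd.DataFrame) -> ZReference:
    """Reference mean/SD per metric from the young group (ddof=1).

    Raises ``DomainError`` (naming the metric) when fewer than 3 young
    animals are available or a metric has zero spread.
    """
    if len(young_rows) < 3:
        raise DomainError(f"need at least 3 young animals, got {len(young_rows)}")
    numeric = young_rows.select_dtypes(include=[np.number])
    return ZReference(mean=numeric.mean(), sd=numeric.std(ddof=1))


def _check_arity(z: Sequence[float], arity: int, label: str) -> np.ndarray:
    arr = np.asarray(z, dtype=float)
    if arr.shape != (arity,):
        raise DomainError(f"{label} expects exactly {arity} values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{label} requires finite values")
    return arr


def motor_score(z6: Sequence[float]) -> float:
    """Mean of the six kinematic Z-values."""
    return float(_check_arity(z6, 6, "motor_score").mean())


def characteristic_score(z7: Sequence[float]) -> float:
    """(Z1 + ... + Z6 - Z_pausing) / 7, pausing given last."""
    arr = _check_arity(z7, 7, "characteristic_score")
    return float((arr[:6].sum() - arr[6]) / 7.0)


def metabolome_score(
    z_values: Sequence[float], directions: Sequence[str]
) -> float:
    """(sum Z over 'up' biomarkers - sum Z over 'down') / n biomarkers.

    Directions come from the treatment-vs-vehicle differential table;
    NaN Z-values (biomarker missing in a sample) contribute zero while
    the denominator stays the total biomarker count.
    """
    z = np.asarray(z_values, dtype=float)
    dirs = np.asarray(directions, dtype=object)
    if z.size == 0:
        raise DomainError("empty biomarker set")
    if z.shape != dirs.shape:
        raise DomainError("z_values and directions must align")
    unknown = set(dirs) - {"up", "down"}
    if unknown:
        raise DomainError(f"unknown directions {sorted(unknown)}")
    signs = np.where(dirs == "up", 1.0, -1.0)
    contrib = np.where(np.isnan(z), 0.0, signs * z)
    return float(contrib.sum() / z.size)


def score_regression(
    behavior_scores: Sequence[float], metabolome_scores: Sequence[float]
) -> dict[str, float]:
    """OLS of metabolomic on behavioral score; two-sided slope p."""
    x = np.asarray(behavior_scores, dtype=float)
    y = np.asarray(metabolome_scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("need >= 3 paired scores")
    if np.std(x) == 0:
        raise DomainError("behavioral scores are constant; slope undefined")
    with np.errstate(invalid="ignore"):
        res = stats.linregress(x, y)
    r_squared = float(res.rvalue**2)
    if not np.isfinite(r_squared):  # constant response: nothing to explain
        r_squared = 0.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": r_squared,
        "p_value": float(res.pvalue),
    }


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with two-sided t-approx p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 4:
        raise DomainError("need >= 4 pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DomainError("constant vector; rank correlation undefined")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


@dataclass
class BmageResult:
    """Per-animal scores plus the cross-domain regression summary."""

    scores: pd.DataFrame  # animal_id index; z_motor, z_char, z_behavior_total, z_metabolome, group
    regression: dict[str, float]
    group_means: pd.DataFrame  # per-group mean of every z column (radar-ready)


class BmageScorer(BaseEstimator):
    """Young-referenced composite ageing score.

    ``fit`` learns the young reference for the 13 behavioral metrics;
    ``score_cohort`` standardizes a cohort, forms the sub-scores, adds
    the biomarker-based metabolomic score and regresses one domain on
    the other.

    Parameters
    ----------
    kinematic_metrics, sequence_metrics :
        Column names of the six kinematic and seven sequence metrics
        (pausing-type metric last in ``sequence_metrics``).
    young_group :
        Label of the reference group in the ``group`` column.
    """

    def __init__(
        self,
        kinematic_metrics: tuple[str, ...] = DEFAULT_KINEMATIC_METRICS,
        sequence_metrics: tuple[str, ...] = DEFAULT_SEQUENCE_METRICS,
        young_group: str = "Young",
    ) -> None:
        self.kinematic_metrics = kinematic_metrics
        self.sequence_metrics = sequence_metrics
        self.young_group = young_group

    @property
    def _metrics(self) -> list[str]:
        return list(self.kinematic_metrics) + list(self.sequence_metrics)

    def fit(self, behavior: pd.DataFrame, y=None) -> "BmageScorer":
        """Learn the young-group reference from a behavior table.

        ``behavior`` needs a ``group`` column and the 13 metric columns.
        """
        if "group" not in behavior.columns:
            raise DomainError("behavior table needs a 'group' column")
        young = behavior.loc[behavior["group"] == self.young_group, self._metrics]
        if young.empty:
            raise DomainError(f"no rows for young group {self.young_group!r}")
        self.reference_ = fit_reference(young)
        return self

    def behavior_scores(self, behavior: pd.DataFrame) -> pd.DataFrame:
        """Per-animal z_motor, z_char and z_behavior_total."""
        check_is_fitted(self, "reference_")
        z = self.reference_.transform(behavior[self._metrics])
        k = list(self.kinematic_metrics)
        s = list(self.sequence_metrics)
        z_motor = z[k].mean(axis=1)
        z_char = (z[s[:-1]].sum(axis=1) - z[s[-1]]) / 7.0
        out = pd.DataFrame(
            {
                "z_motor": z_motor,
                "z_char": z_char,
                "z_behavior_total": (z_motor + z_char) / 2.0,
            },
            index=behavior.index,
        )
        if "group" in behavior.columns:
            out.insert(0, "group", behavior["group"])
        return out

    def metabolome_scores(
        self,
        biomarker_values: pd.DataFrame,
        directions: Mapping[str, str],
        groups: pd.Series,
    ) -> pd.Series:
        """Per-animal metabolomic score from biomarker intensities.

        ``biomarker_values`` is animals x biomarkers (normalized
        intensities); its young rows provide the Z reference.
        """
        check_is_fitted(self, "reference_")
        young_rows = biomarker_values.loc[groups == self.young_group]
        ref = fit_reference(young_rows)
        z = ref.transform(biomarker_values)
        dir_list = [directions[c] for c in z.columns]
        return z.apply(
            lambda row: metabolome_score(row.to_numpy(), dir_list), axis=1
        ).rename("z_metabolome")

    def score_cohort(
        self,
        behavior: pd.DataFrame,
        biomarker_values: pd.DataFrame,
        directions: Mapping[str, str],
    ) -> BmageResult:
        """Full per-animal scoring plus the cross-domain regression."""
        b_scores = self.behavior_scores(behavior)
        m_scores = self.metabolome_scores(
            biomarker_values.loc[behavior.index],
            directions,
            behavior["group"],
        )
        scores = b_scores.join(m_scores)
        regression = score_regression(
            scores["z_behavior_total"].to_numpy(), scores["z_metabolome"].to_numpy()
        )
        group_means = scores.groupby("group").mean(numeric_only=True)
        return BmageResult(scores=scores, regression=regression, group_means=group_means)
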