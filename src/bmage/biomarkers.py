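"""ROC/AUC biomarker selection from differential metabolites.

The AUC of a single feature as a classifier of treated vs control
samples equals the Mann-Whitney probability that a random treated
sample outranks a random control (ties count 1/2). Selection keeps
significant features whose orientation-free AUC ``max(a, 1-a)``
strictly exceeds a threshold (0.85 by default), carrying the up/down
direction from the differential table so the composite score can sign
each biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .errors import DomainError
from .metabolomics import DiffTable, MetaboliteMatrix, normalize_log_median

__all__ = ["BiomarkerSet", "auc_mann_whitney", "select_biomarkers", "BiomarkerSelector"]


@dataclass
class BiomarkerSet:
    """Selected biomarkers: feature, organ, orientation-free AUC, direction."""

    entries: pd.DataFrame  # columns: feature_id, organ, auc, direction

    def __post_init__(self) -> None:
        required = {"feature_id", "organ", "auc", "direction"}
        missing = required - set(self.entries.columns)
        if missing:
            raise DomainError(f"biomarker table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return self.entries["feature_id"].tolist()


def auc_mann_whitney(
    scores_pos: Sequence[float] | np.ndarray,
    scores_neg: Sequence[float] | np.ndarray,
) -> float:
    """AUC = (#pairs pos>neg + 0.5 * #ties) / (n_pos * n_neg).

    Equals the area under the empirical ROC curve of the score.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both score lists must be non-empty")
    u_stat = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u_stat) / (pos.size * neg.size)


def select_biomarkers(
    diff: DiffTable,
    m: MetaboliteMatrix,
    group_treated: str,
    group_control: str,
    auc_thresh: float = 0.85,
    normalized: pd.DataFrame | None = None,
) -> BiomarkerSet:
    """Keep significant features discriminating treated from control.

    For each significant feature of ``diff`` the treated-vs-control AUC
    ``a`` is made orientation-free as ``max(a, 1-a)`` — biomarkers may
    be either up- or down-regulated, so discriminative ability must not
    depend on sign — and features with AUC strictly above
    ``auc_thresh`` are retained with the direction label from ``diff``.
    """
    missing = [f for f in diff.significant_features if f not in set(m.feature_ids)]
    if missing:
        raise DomainError(f"diff features absent from matrix: {missing[:5]}")
    norm = normalize_log_median(m) if normalized is None else normalized
    treated = norm.loc[m.groups == group_treated]
    control = norm.loc[m.groups == group_control]
    rows = []
    for feature in diff.significant_features:
        pos = treated[feature].to_numpy()
        neg = control[feature].to_numpy()
        if np.all(np.isnan(pos)) or np.all(np.isnan(neg)):
            continue
        a = auc_mann_whitney(pos, neg)
        auc = max(a, 1.0 - a)
        if auc > auc_thresh:
            rows.append(
                {
                    "feature_id": feature,
                    "organ": m.organ,
                    "auc": auc,
                    "direction": diff.direction_of(feature),
                }
            )
    entries = pd.DataFrame(rows, columns=["feature_id", "organ", "auc", "direction"])
    return BiomarkerSet(entries=entries)


class BiomarkerSelector(BaseEstimator):
    """Estimator form of :func:`select_biomarkers`.

    Attributes
    ----------
    biomarkers_ : BiomarkerSet
    """

    def __init__(
        self,
        group_treated: str = "Nico50",
        group_control: str = "Saccharin",
        auc_thresh: float = 0.85,
    ) -> None:
        self.group_treated = group_treated
        self.group_control = group_control
        self.auc_thresh = auc_thresh

    def fit(self, X: MetaboliteMatrix, y: DiffTable = None) -> "BiomarkerSelector":
        if y is None:
            raise DomainError("pass the DiffTable of the contrast as y")
        self.biomarkers_ = select_biomarkers(
            y, X, self.group_treated, self.group_control, self.auc_thresh
        )
        return self
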