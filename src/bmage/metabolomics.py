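"""Metabolite screening: filtering, differential tests, overlaps, SM/Cer.

The substrate is a samples x features intensity matrix per organ
(zero intensity encodes a missing ion, following LC-MS convention).
The screening chain is:

1. drop ions missing in more than half the samples (strict ">");
2. log2-transform positive intensities and median-center each sample
   (the concrete, invertible realization of "normalized peak areas");
3. per feature, a two-sample Student t-test (equal variance by default)
   between groups plus the log2 fold change of geometric means; a
   feature is *significant* when ``p < p_thresh`` and
   ``|log2FC| > lfc_thresh`` (defaults 0.05 and 0.26, i.e. about a
   1.2-fold difference);
4. confound exclusion (features responsive to the vehicle are removed
   from treatment contrasts) and direction-consistent overlap between
   contrasts (the "rejuvenation set");
5. Benjamini-Hochberg FDR for families of tests, and SM/Cer ratio
   comparisons across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

__all__ = [
    "MetaboliteMatrix",
    "DiffTable",
    "SharedSet",
    "normalize_log_median",
    "filter_missing",
    "differential",
    "exclude_confounded",
    "direction_consistent_overlap",
    "bh_fdr",
    "sm_cer_ratio",
    "DifferentialScreen",
]


@dataclass
class MetaboliteMatrix:
    """Samples x features intensity table with group labels.

    ``intensities`` is indexed by sample id with one column per feature
    id; values are non-negative and 0 encodes a missing ion.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    organ: str = ""

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            raise DomainError("duplicate sample ids")
        if self.intensities.columns.duplicated().any():
            raise DomainError("duplicate feature ids")
        self.groups = pd.Series(self.groups).reindex(idx)
        if self.groups.isna().any():
            raise DomainError("group labels missing for some samples")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise DomainError("intensities must be non-negative (0 = missing)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def group_samples(self, group: str) -> pd.DataFrame:
        return self.intensities.loc[self.groups == group]

    def to_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, organ: str = "") -> "MetaboliteMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        groups = df.pop("group")
        return cls(intensities=df.astype(float), groups=groups, organ=organ)


@dataclass
class DiffTable:
    """Per-feature differential test results for one B-vs-A contrast.

    ``table`` columns: feature_id (index), log2fc (log2 of the B/A
    geometric-mean ratio), p_value, q_value, direction ('up' means
    higher in ``group_b``), significant.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    organ: str = ""
    p_thresh: float = 0.05
    lfc_thresh: float = 0.26

    @property
    def significant_features(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()

    def direction_of(self, feature: str) -> str:
        return str(self.table.loc[feature, "direction"])


@dataclass
class SharedSet:
    """Direction-stratified overlap between two contrasts."""

    same_direction: list[str]
    opposite_direction: list[str]

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.same_direction), len(self.opposite_direction)


def normalize_log_median(m: MetaboliteMatrix) -> pd.DataFrame:
    """log2 intensities, median-centered per sample; zeros become NaN.

    Median centering uses each sample's observed (non-missing) features,
    which makes samples comparable under global intensity drift while
    remaining invertible given the medians.
    """
    arr = m.intensities.to_numpy(dtype=float).copy()
    arr[arr <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        logged = np.log2(arr)
    medians = np.nanmedian(logged, axis=1, keepdims=True)
    return pd.DataFrame(
        logged - medians, index=m.intensities.index, columns=m.intensities.columns
    )


def filter_missing(m: MetaboliteMatrix, max_missing_frac: float = 0.5) -> MetaboliteMatrix:
    """Drop features whose missing fraction strictly exceeds the cutoff.

    A value of exactly ``max_missing_frac`` is retained ("more than
    50%" is a strict inequality). Feature order is preserved.
    """
    if not 0 <= max_missing_frac <= 1:
        raise DomainError(f"max_missing_frac must be in [0,1], got {max_missing_frac}")
    if m.n_features == 0 or m.n_samples == 0:
        warnings.warn("empty metabolite matrix; nothing to filter", stacklevel=2)
        return m
    missing_frac = (m.intensities <= 0).mean(axis=0)
    keep = missing_frac.index[missing_frac <= max_missing_frac]
    return MetaboliteMatrix(
        intensities=m.intensities[keep], groups=m.groups, organ=m.organ
    )


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column t-test with NaN = missing.

    Columns where both groups have zero variance get p=1 for equal
    means and p=0 otherwise; columns with fewer than 2 observations in
    either group get p=NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    n_a = np.sum(~np.isnan(a), axis=0)
    n_b = np.sum(~np.isnan(b), axis=0)
    mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=0)
    mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var_a = np.nanvar(a, axis=0, ddof=1)
        var_b = np.nanvar(b, axis=0, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0) & (n_a >= 2) & (n_b >= 2)
    equal_means = np.isclose(mean_a, mean_b)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    p = np.where((n_a < 2) | (n_b < 2), np.nan, p)
    return p, mean_b - mean_a


def differential(
    m: MetaboliteMatrix,
    group_a: str,
    group_b: str,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.26,
    equal_var: bool = True,
    normalized: pd.DataFrame | None = None,
) -> DiffTable:
    """Per-feature B-vs-A screening on normalized log2 intensities.

    log2FC is the difference of group means of log2 intensities, i.e.
    the log2 ratio of back-transformed geometric means; zeros are
    treated as missing, not imputed. ``q_value`` is the BH-adjusted p
    over the tested features (significance itself uses the raw p, as in
    the source screening rule).

    Raises
    ------
    DomainError
        If either group is absent or has fewer than 3 samples.
    """
    for g in (group_a, group_b):
        n_g = int((m.groups == g).sum())
        if n_g < 3:
            raise DomainError(f"group {g!r} has {n_g} samples; need at least 3")
    norm = normalize_log_median(m) if normalized is None else normalized
    a = norm.loc[m.groups == group_a].to_numpy(dtype=float)
    b = norm.loc[m.groups == group_b].to_numpy(dtype=float)
    p, log2fc = _two_sample_t(a, b, equal_var=equal_var)
    finite = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = bh_fdr(p[finite])
    direction = np.where(log2fc > 0, "up", "down")
    significant = finite & (p < p_thresh) & (np.abs(log2fc) > lfc_thresh)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    return DiffTable(
        table=table,
        group_a=group_a,
        group_b=group_b,
        organ=m.organ,
        p_thresh=p_thresh,
        lfc_thresh=lfc_thresh,
    )


def exclude_confounded(diff_nico: DiffTable, diff_vehicle: DiffTable) -> DiffTable:
    """Remove features significant in the vehicle contrast.

    Features the vehicle (saccharin-vs-water) screen flags are dropped
    from the treatment table so that remaining hits are
    treatment-specific. A feature-universe mismatch warns and the
    removal applies on the intersection.
    """
    nico_features = set(diff_nico.table.index)
    veh_features = set(diff_vehicle.table.index)
    if not nico_features <= veh_features:
        warnings.warn(
            "treatment contrast has features absent from the vehicle contrast; "
            "excluding on the intersection",
            stacklevel=2,
        )
    confounded = set(diff_vehicle.significant_features) & nico_features
    kept = diff_nico.table.drop(index=sorted(confounded))
    return DiffTable(
        table=kept,
        group_a=diff_nico.group_a,
        group_b=diff_nico.group_b,
        organ=diff_nico.organ,
        p_thresh=diff_nico.p_thresh,
        lfc_thresh=diff_nico.lfc_thresh,
    )


def direction_consistent_overlap(diff_ref: DiffTable, diff_test: DiffTable) -> SharedSet:
    """Split shared significant features by agreement of direction.

    ``same_direction`` features are significant in both contrasts with
    equal 'up'/'down' labels (e.g. a treatment moving a metabolite the
    same way the young phenotype differs from the old); the remainder
    of the shared set is ``opposite_direction``. One table holding a
    subset of the other's features (confound exclusion) is expected;
    a two-sided mismatch warns.
    """
    ref_features = set(diff_ref.table.index)
    test_features = set(diff_test.table.index)
    if not (ref_features <= test_features or test_features <= ref_features):
        warnings.warn("feature universes differ; overlap on the intersection", stacklevel=2)
    shared = sorted(
        set(diff_ref.significant_features) & set(diff_test.significant_features)
    )
    same = [f for f in shared if diff_ref.direction_of(f) == diff_test.direction_of(f)]
    opposite = [f for f in shared if f not in set(same)]
    return SharedSet(same_direction=same, opposite_direction=opposite)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sm_cer_ratio(
    panel: pd.DataFrame,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample SM/Cer ratios and per-tissue group tests with FDR.

    ``panel`` is long-format with columns sample_id, group, tissue, sm,
    cer (dhcer optional). Per tissue, a two-tailed two-sample t-test
    compares ratios between ``group_b`` and ``group_a``; q-values apply
    BH across tissues (multiple unpaired t-tests with FDR correction).

    Returns ``(ratios, tests)``; ``tests`` has one row per tissue with
    mean ratios, log2 ratio fold change, p and q.
    """
    required = {"sample_id", "group", "tissue", "sm", "cer"}
    missing = required - set(panel.columns)
    if missing:
        raise DomainError(f"sphingolipid panel missing columns {sorted(missing)}")
    bad = panel.loc[panel["cer"] <= 0, "sample_id"]
    if len(bad):
        raise DomainError(f"non-positive Cer concentration for sample {bad.iloc[0]!r}")
    if (panel["sm"] <= 0).any():
        raise DomainError("non-positive SM concentration")
    ratios = panel.copy()
    ratios["sm_cer_ratio"] = ratios["sm"] / ratios["cer"]

    rows = []
    for tissue, sub in ratios.groupby("tissue", sort=True):
        r_a = sub.loc[sub["group"] == group_a, "sm_cer_ratio"].to_numpy()
        r_b = sub.loc[sub["group"] == group_b, "sm_cer_ratio"].to_numpy()
        if len(r_a) < 2 or len(r_b) < 2:
            raise DomainError(f"tissue {tissue!r}: need >= 2 samples per group")
        if np.var(r_a, ddof=1) == 0 and np.var(r_b, ddof=1) == 0:
            p = 1.0 if np.isclose(r_a.mean(), r_b.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(r_b, r_a, equal_var=equal_var).pvalue)
        rows.append(
            {
                "tissue": tissue,
                f"mean_{group_a}": float(r_a.mean()),
                f"mean_{group_b}": float(r_b.mean()),
                "log2_ratio_fc": float(np.log2(r_b.mean() / r_a.mean())),
                "p_value": p,
            }
        )
    tests = pd.DataFrame(rows).set_index("tissue")
    tests["q_value"] = bh_fdr(tests["p_value"].to_numpy())
    return ratios, tests


class DifferentialScreen(BaseEstimator):
    """Estimator wrapper around :func:`differential`.

    Parameters mirror the screening thresholds; ``fit`` runs the
    contrast on a :class:`MetaboliteMatrix` and exposes the results.

    Attributes
    ----------
    diff_ : DiffTable
    n_significant_ : int
    """

    def __init__(
        self,
        group_a: str = "Old",
        group_b: str = "Young",
        p_thresh: float = 0.05,
        lfc_thresh: float = 0.26,
        equal_var: bool = True,
        max_missing_frac: float = 0.5,
    ) -> None:
        self.group_a = group_a
        self.group_b = group_b
        self.p_thresh = p_thresh
        self.lfc_thresh = lfc_thresh
        self.equal_var = equal_var
        self.max_missing_frac = max_missing_frac

    def fit(self, X: MetaboliteMatrix, y=None) -> "DifferentialScreen":
        filtered = filter_missing(X, self.max_missing_frac)
        self.diff_ = differential(
            filtered,
            self.group_a,
            self.group_b,
            p_thresh=self.p_thresh,
            lfc_thresh=self.lfc_thresh,
            equal_var=self.equal_var,
        )
        self.n_significant_ = int(self.diff_.table["significant"].sum())
        return self
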