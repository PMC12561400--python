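"""Microbiome summaries: normalization, alpha diversity, Fir/Bac, Mantel.

Genus-level count tables are normalized to the smallest library size,
low-abundance taxa (< 0.1% within a sample by default) are zeroed, and
the remaining proportions are re-closed to sum to one. Alpha diversity
uses the bias-corrected Chao1 richness estimator and the Simpson
diversity index (1 - sum p_i^2). The Firmicutes/Bacteroidetes ratio is
computed per sample from a genus -> phylum map. The Mantel test relates
two subject-level distance matrices by rank (Spearman) correlation of
their upper triangles under joint row/column permutations of the
second matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import DomainError

__all__ = [
    "TaxaTimeSeries",
    "normalize_and_filter",
    "chao1",
    "simpson",
    "fir_bac_ratio",
    "mantel_test",
    "bray_curtis",
    "group_mean_log_profiles",
    "validate_distance_matrix",
]

_META_COLS = ("subject_id", "group", "timepoint")


@dataclass
class TaxaTimeSeries:
    """Per-subject genus-level counts over repeated timepoints.

    ``counts`` holds one row per subject x timepoint with metadata
    columns ``subject_id``, ``group``, ``timepoint`` followed by integer
    taxa counts. ``phylum_map`` assigns each taxon to a phylum.
    ``ground_truth`` is a generator sidecar (injected trend templates);
    analysis code never reads it.
    """

    counts: pd.DataFrame
    phylum_map: pd.Series
    ground_truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.counts.columns]
        if missing:
            raise DomainError(f"counts table missing metadata columns {missing}")
        taxa = self.taxa
        arr = self.counts[taxa].to_numpy()
        if (arr < 0).any():
            raise DomainError("taxa counts must be non-negative")
        unmapped = set(taxa) - set(self.phylum_map.index)
        if unmapped:
            raise DomainError(f"phylum map does not cover taxa: {sorted(unmapped)[:5]}")

    @property
    def taxa(self) -> list[str]:
        return [c for c in self.counts.columns if c not in _META_COLS]

    @property
    def timepoints(self) -> list:
        return sorted(self.counts["timepoint"].unique())

    def sample_counts(self) -> pd.DataFrame:
        """Taxa counts indexed by (subject_id, timepoint)."""
        return self.counts.set_index(["subject_id", "timepoint"])[self.taxa]


def normalize_and_filter(
    counts: pd.DataFrame, min_rel_abund: float = 0.001
) -> pd.DataFrame:
    """Depth-normalize counts and zero out rare taxa per sample.

    Counts are scaled so every sample matches the minimum library size
    (deterministic scaling, not subsampling), taxa with within-sample
    relative abundance strictly below ``min_rel_abund`` are set to zero,
    and rows are re-closed to sum to 1.

    Parameters
    ----------
    counts : samples x taxa count table (numeric columns only).

    Returns
    -------
    Relative-abundance table of the same shape, rows summing to 1.
    """
    arr = counts.to_numpy(dtype=float)
    depths = arr.sum(axis=1)
    zero = depths <= 0
    if zero.any():
        bad = counts.index[zero][0]
        raise DomainError(f"sample {bad!r} has zero total count")
    # scaling to min depth leaves proportions unchanged; it is the
    # proportions that the rare-taxon filter and closure act on
    rel = arr / depths[:, None]
    rel[rel < min_rel_abund] = 0.0
    totals = rel.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0][0]
        raise DomainError(f"sample {bad!r} lost all taxa at threshold {min_rel_abund}")
    rel /= totals[:, None]
    return pd.DataFrame(rel, index=counts.index, columns=counts.columns)


def chao1(counts: Sequence[int] | np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of singleton and doubleton taxa. Equals
    observed richness when there are no singletons; always >= S_obs.
    """
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        as_int = np.asarray(arr, dtype=float)
        if not np.allclose(as_int, np.round(as_int)):
            raise DomainError("chao1 requires integer counts")
        arr = np.round(as_int).astype(int)
    if (arr < 0).any():
        raise DomainError("counts must be non-negative")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def simpson(rel_abund: Sequence[float] | np.ndarray) -> float:
    """Simpson diversity ``1 - sum(p_i^2)`` (higher = more diverse)."""
    p = np.asarray(rel_abund, dtype=float)
    if (p < 0).any():
        raise DomainError("proportions must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise DomainError(f"proportions must sum to 1 (got {total:g})")
    return float(1.0 - np.sum(p**2))


def simpson_dominance(rel_abund: Sequence[float] | np.ndarray) -> float:
    """Dominance form ``sum(p_i^2)`` for callers preferring that convention."""
    return 1.0 - simpson(rel_abund)


def fir_bac_ratio(
    rel_abund: pd.Series | Mapping[str, float],
    phylum_map: pd.Series | Mapping[str, str],
) -> float:
    """Firmicutes-to-Bacteroidetes abundance ratio for one sample."""
    abund = pd.Series(rel_abund, dtype=float)
    phyla = pd.Series(phylum_map).reindex(abund.index)
    fir = float(abund[phyla == "Firmicutes"].sum())
    bac = float(abund[phyla == "Bacteroidetes"].sum())
    if bac <= 0:
        raise DomainError("Bacteroidetes total is zero; Fir/Bac ratio undefined")
    return fir / bac


def validate_distance_matrix(d: pd.DataFrame | np.ndarray, name: str = "d") -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DomainError(f"{name} must be square")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise DomainError(f"{name} must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-8):
        raise DomainError(f"{name} must have a zero diagonal")
    if (arr < -1e-12).any():
        raise DomainError(f"{name} must be non-negative")
    return arr


def _upper(arr: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return arr[iu]


def mantel_test(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int | None = None,
) -> tuple[float, float]:
    """One-tailed Mantel test between two distance matrices.

    The statistic is the Spearman (default) or Pearson correlation of
    the upper-triangle entries. The null permutes subject labels of the
    second matrix jointly on rows and columns;
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`` (positive
    association).

    Matrices given as DataFrames must share labels in the same order.
    """
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            raise DomainError("distance matrices must share subject labels")
    a = validate_distance_matrix(d1, "d1")
    b = validate_distance_matrix(d2, "d2")
    if a.shape != b.shape:
        raise DomainError("distance matrices must have equal dimensions")
    n = a.shape[0]
    if n < 4:
        raise DomainError(f"need at least 4 subjects, got {n}")
    if method not in ("spearman", "pearson"):
        raise DomainError(f"unknown method {method!r}")

    iu = np.triu_indices(n, k=1)
    x = _upper(a, iu)
    if method == "spearman":
        x = rankdata(x)
    x = x - x.mean()
    x_norm = np.linalg.norm(x)
    if x_norm == 0:
        raise DomainError("d1 upper triangle is constant")

    def corr_with(y_raw: np.ndarray) -> float:
        y = rankdata(y_raw) if method == "spearman" else y_raw
        y = y - y.mean()
        denom = x_norm * np.linalg.norm(y)
        if denom == 0:
            return 0.0
        return float(np.dot(x, y) / denom)

    r_obs = corr_with(_upper(b, iu))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += corr_with(b[np.ix_(perm, perm)][iu]) >= r_obs - 1e-12
    p_value = (1 + hits) / (1 + n_perm)
    return r_obs, float(p_value)


def bray_curtis(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples (rows)."""
    arr = rel_abund.to_numpy(dtype=float)
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=rel_abund.index, columns=rel_abund.index)


def group_mean_log_profiles(
    ts: TaxaTimeSeries,
    group: str,
    min_rel_abund: float = 0.0,
    pseudocount: float = 1e-6,
    center: str = "median",
) -> pd.DataFrame:
    """Taxa x timepoints log group-mean relative-abundance profiles.

    The trend unit of the miner: per timepoint, relative abundances are
    averaged over the group's subjects and logged (pseudocount guards
    taxa that drop out entirely at one timepoint).

    Because relative abundances are closed to 1, a genuine trend in a
    subset of taxa renormalizes every other taxon, imprinting a shared
    spurious drift in log space. ``center="median"`` (default) removes
    it median-of-ratios style: each taxon's log profile is first
    centered on its own time average; the per-timepoint median of
    those deviations estimates the shared drift, refined by one
    trimming step that drops taxa with residuals beyond 3 MAD (the
    strongly trending ones, which would otherwise tilt even the
    median) before re-taking the median over the quiet majority. When
    most taxa trend (balanced template designs) the trimmed set is
    unreliable and the plain median — unbiased there by symmetry — is
    kept. ``center="none"`` returns raw log profiles.
    """
    sub = ts.counts[ts.counts["group"] == group]
    if sub.empty:
        raise DomainError(f"group {group!r} absent from taxa table")
    taxa = ts.taxa
    rel = normalize_and_filter(sub[taxa], min_rel_abund) if min_rel_abund > 0 else (
        sub[taxa].div(sub[taxa].sum(axis=1), axis=0)
    )
    rel = rel.assign(timepoint=sub["timepoint"].to_numpy())
    means = rel.groupby("timepoint").mean().T  # taxa x timepoints
    means = means[sorted(means.columns)]
    if center not in ("median", "none"):
        raise DomainError(f"unknown centering {center!r}")
    logged = np.log(means + pseudocount)
    if center == "median":
        deviations = logged.sub(logged.mean(axis=1), axis=0)
        drift = deviations.median(axis=0)
        resid = deviations - drift
        scale = 1.4826 * resid.abs().median(axis=0)
        if (scale > 0).all():
            quiet = ~(resid.abs() > 3.0 * scale).any(axis=1)
            if quiet.mean() > 0.5 and quiet.sum() >= 4:
                drift = deviations.loc[quiet].median(axis=0)
        logged = logged - drift
    return logged


def alpha_diversity_table(ts: TaxaTimeSeries, min_rel_abund: float = 0.001) -> pd.DataFrame:
    """Per-sample Chao1 (raw counts) and Simpson (filtered proportions)."""
    taxa = ts.taxa
    rel = normalize_and_filter(ts.counts[taxa], min_rel_abund)
    rows = []
    for i, (_, row) in enumerate(ts.counts.iterrows()):
        rows.append(
            {
                "subject_id": row["subject_id"],
                "group": row["group"],
                "timepoint": row["timepoint"],
                "chao1": chao1(row[taxa].to_numpy()),
                "simpson": simpson(rel.iloc[i].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def fir_bac_table(ts: TaxaTimeSeries, min_rel_abund: float = 0.001) -> pd.DataFrame:
    """Per-sample Firmicutes/Bacteroidetes ratio."""
    taxa = ts.taxa
    rel = normalize_and_filter(ts.counts[taxa], min_rel_abund)
    out = ts.counts[list(_META_COLS)].copy()
    ratios = []
    for i in range(len(rel)):
        try:
            ratios.append(fir_bac_ratio(rel.iloc[i], ts.phylum_map))
        except DomainError:
            warnings.warn("sample with zero Bacteroidetes; ratio set to NaN", stacklevel=2)
            ratios.append(float("nan"))
    out["fir_bac_ratio"] = ratios
    return out
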