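"""Short time-series trend mining for longitudinal taxa abundances.

Each taxon's group-mean log-abundance profile over T timepoints is
matched against four canonical trend templates — continuous increase,
continuous decrease, increase-then-decrease, decrease-then-increase —
by Pearson correlation (computed as the dot product of centered,
unit-norm vectors). Significance of the count of taxa assigned to each
template is assessed against an exhaustive timepoint-permutation null:
every profile is re-assigned under every permutation of the timepoint
order and template counts are tallied, and the observed count is
referred to a hypergeometric tail over the pooled assignment events.

This mirrors the classic short time-series expression miner applied to
genus-level microbiota trajectories, restricted to the four-shape
template set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

from .errors import DomainError

__all__ = [
    "TEMPLATE_ORDER",
    "FLAT_LABEL",
    "template_shapes",
    "assign_trend",
    "assign_trends",
    "permutation_null",
    "trend_enrichment",
    "trend_clusters",
    "TrendAssignment",
    "TrendMiner",
]

logger = logging.getLogger(__name__)

#: fixed template order; also the tie-break order for equal similarities
TEMPLATE_ORDER: tuple[str, ...] = ("increase", "decrease", "up_down", "down_up")

#: label for profiles that are constant after centering (excluded from enrichment)
FLAT_LABEL = "flat"

#: centered-profile norm below which a profile counts as flat
_FLAT_NORM = 1e-9

#: above this many timepoints the T! null is sampled instead of enumerated
_MAX_EXACT_T = 6


@dataclass(frozen=True)
class TrendAssignment:
    """Best-matching template for one taxon profile."""

    taxon_id: str
    best_template: str
    similarity: float


def template_shapes(n_timepoints: int) -> dict[str, np.ndarray]:
    """Centered, unit-norm template shape vectors of length T.

    ``increase`` is a centered linear ramp (for T=4 proportional to
    (-3, -1, 1, 3)); ``up_down`` is a centered tent (for T=4 proportional
    to (-1, 1, 1, -1)); the other two are their negations.
    """
    t_count = int(n_timepoints)
    if t_count < 3:
        raise DomainError(f"templates undefined for fewer than 3 timepoints, got {t_count}")
    idx = np.arange(t_count, dtype=float)
    ramp = idx - idx.mean()
    ramp /= np.linalg.norm(ramp)
    tent = -np.abs(idx - (t_count - 1) / 2.0)
    tent -= tent.mean()
    tent /= np.linalg.norm(tent)
    return {
        "increase": ramp,
        "decrease": -ramp,
        "up_down": tent,
        "down_up": -tent,
    }


def _template_matrix(n_timepoints: int) -> np.ndarray:
    shapes = template_shapes(n_timepoints)
    return np.vstack([shapes[label] for label in TEMPLATE_ORDER])


def _normalize_profiles(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-norm each row; returns (unit rows, flat mask)."""
    if not np.all(np.isfinite(profiles)):
        raise DomainError("profiles contain non-finite values")
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms < _FLAT_NORM
    safe = np.where(flat, 1.0, norms)
    return centered / safe[:, None], flat


def _assign_matrix(profiles: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized assignment: returns (template index, similarity, flat mask)."""
    unit, flat = _normalize_profiles(profiles)
    sims = unit @ templates.T  # taxa x 4, equals Pearson r with each shape
    best = np.argmax(sims, axis=1)  # argmax keeps first max -> fixed-order tie-break
    best_sim = sims[np.arange(sims.shape[0]), best]
    return best, best_sim, flat


def assign_trend(profile: np.ndarray | list[float], taxon_id: str = "") -> TrendAssignment:
    """Assign one profile to its best-matching template.

    Similarity is the Pearson correlation between the profile and the
    template shape. Constant profiles get the label ``flat`` with
    similarity 0 and are excluded from enrichment counts.
    """
    arr = np.asarray(profile, dtype=float)[None, :]
    if arr.shape[1] < 3:
        raise DomainError("profile needs at least 3 timepoints")
    templates = _template_matrix(arr.shape[1])
    best, sim, flat = _assign_matrix(arr, templates)
    if flat[0]:
        return TrendAssignment(taxon_id, FLAT_LABEL, 0.0)
    return TrendAssignment(taxon_id, TEMPLATE_ORDER[best[0]], float(sim[0]))


def assign_trends(profiles: pd.DataFrame) -> pd.DataFrame:
    """Assign every row of a taxa x timepoints profile table.

    Returns a frame indexed like ``profiles`` with columns
    ``best_template`` and ``similarity``.
    """
    arr = profiles.to_numpy(dtype=float)
    templates = _template_matrix(arr.shape[1])
    best, sim, flat = _assign_matrix(arr, templates)
    labels = np.asarray(TEMPLATE_ORDER, dtype=object)[best]
    labels[flat] = FLAT_LABEL
    sim = np.where(flat, 0.0, sim)
    return pd.DataFrame(
        {"best_template": labels, "similarity": sim}, index=profiles.index
    )


def permutation_null(
    profiles: pd.DataFrame,
    n_sampled: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Template assignment counts under every timepoint permutation.

    For T <= 6 all T! permutations (identity included, lexicographic
    order) are enumerated; above that, ``n_sampled`` random permutations
    are drawn with the stated seed and a log message records the
    fallback. Flat profiles are excluded from the tallies.

    Returns a permutations x templates count table.
    """
    arr = profiles.to_numpy(dtype=float)
    if arr.shape[0] < 1:
        raise DomainError("need at least one profile")
    t_count = arr.shape[1]
    templates = _template_matrix(t_count)
    if t_count <= _MAX_EXACT_T:
        perms = list(itertools.permutations(range(t_count)))
    else:
        rng = np.random.default_rng(seed)
        logger.info(
            "T=%d > %d: sampling %d timepoint permutations (seed=%s)",
            t_count, _MAX_EXACT_T, n_sampled, seed,
        )
        perms = [tuple(rng.permutation(t_count)) for _ in range(n_sampled)]
    counts = np.zeros((len(perms), len(TEMPLATE_ORDER)), dtype=int)
    for row, perm in enumerate(perms):
        best, _, flat = _assign_matrix(arr[:, perm], templates)
        kept = best[~flat]
        counts[row] = np.bincount(kept, minlength=len(TEMPLATE_ORDER))
    return pd.DataFrame(counts, columns=list(TEMPLATE_ORDER))


def trend_enrichment(
    observed: Mapping[str, int],
    null_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric enrichment p-value per template.

    Pooling assignment events over all P permutations gives a population
    of size ``M = n * P`` (n profiles assigned per permutation) of which
    ``K`` events fall on template t. Drawing the n observed (identity
    permutation) assignments without replacement, the p-value is the
    upper tail ``P[X >= k]`` with ``X ~ Hypergeometric(M, K, n)``.
    """
    n_draws = int(sum(observed.get(t, 0) for t in TEMPLATE_ORDER))
    n_perms = len(null_counts)
    if n_perms < 1:
        raise DomainError("empty permutation null")
    population = n_draws * n_perms
    rows = []
    for template in TEMPLATE_ORDER:
        k_obs = int(observed.get(template, 0))
        k_null = int(null_counts[template].sum())
        if k_obs > k_null or n_draws > population:
            raise DomainError(
                f"inconsistent tallies for {template}: k={k_obs} > K={k_null} "
                f"or n={n_draws} > M={population}"
            )
        p_value = float(hypergeom.sf(k_obs - 1, population, k_null, n_draws))
        rows.append(
            {
                "template": template,
                "observed": k_obs,
                "null_events": k_null,
                "population": population,
                "draws": n_draws,
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows).set_index("template")


def trend_clusters(
    assignments: Mapping[str, pd.DataFrame],
    enrichments: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group taxa into (treatment group, significant template) clusters.

    ``assignments`` / ``enrichments`` map treatment-group label to the
    outputs of :func:`assign_trends` / :func:`trend_enrichment` computed
    over the same taxa. Only templates with enrichment p < ``alpha``
    form clusters. The second frame lists taxa belonging to more than
    one cluster (the cross-group overlap, e.g. a taxon trending in both
    treatment arms).
    """
    cluster_rows = []
    membership: dict[str, list[str]] = {}
    for group, assign in assignments.items():
        enrich = enrichments[group]
        for template in TEMPLATE_ORDER:
            if float(enrich.loc[template, "p_value"]) >= alpha:
                continue
            taxa = assign.index[assign["best_template"] == template].tolist()
            cluster_name = f"{group}:{template}"
            cluster_rows.append(
                {
                    "group": group,
                    "template": template,
                    "n_taxa": len(taxa),
                    "taxa": ",".join(map(str, taxa)),
                }
            )
            for taxon in taxa:
                membership.setdefault(str(taxon), []).append(cluster_name)
    clusters = pd.DataFrame(
        cluster_rows, columns=["group", "template", "n_taxa", "taxa"]
    )
    overlap_rows = [
        {"taxon": taxon, "clusters": ",".join(names)}
        for taxon, names in sorted(membership.items())
        if len(names) > 1
    ]
    overlap = pd.DataFrame(overlap_rows, columns=["taxon", "clusters"])
    return clusters, overlap


class TrendMiner(BaseEstimator):
    """Template assignment + permutation-null enrichment in one fit.

    Parameters
    ----------
    alpha : float
        Enrichment significance threshold used by downstream cluster
        building (raw p, no multiplicity correction, matching the
        source procedure).
    n_sampled_permutations : int
        Sample size for the permutation null when T! is not enumerable.
    random_state : int or None
        Seed for the sampled fallback.

    Attributes
    ----------
    assignments_ : pd.DataFrame
        Per-taxon best template and similarity.
    null_counts_ : pd.DataFrame
        Permutations x templates assignment tallies.
    enrichment_ : pd.DataFrame
        Per-template observed count and hypergeometric p-value.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_sampled_permutations: int = 10_000,
        random_state: int | None = None,
    ) -> None:
        self.alpha = alpha
        self.n_sampled_permutations = n_sampled_permutations
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "TrendMiner":
        """Mine trends from a taxa x timepoints profile table."""
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")
        profiles = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if profiles.shape[1] < 3:
            raise DomainError("need at least 3 timepoints")
        self.n_timepoints_ = profiles.shape[1]
        self.assignments_ = assign_trends(profiles)
        self.null_counts_ = permutation_null(
            profiles, self.n_sampled_permutations, self.random_state
        )
        observed = (
            self.assignments_["best_template"].value_counts().to_dict()
        )
        observed.pop(FLAT_LABEL, None)
        self.enrichment_ = trend_enrichment(observed, self.null_counts_)
        return self

    def significant_templates_(self) -> list[str]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "enrichment_")
        mask = self.enrichment_["p_value"] < self.alpha
        return self.enrichment_.index[mask].tolist()
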