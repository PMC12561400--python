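"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates a five-arm lifelong-exposure mouse study: a
young reference arm, an aged water arm, an aged vehicle (saccharin)
arm, and two aged treatment arms (low / high oral nicotine dose). It
emits, per cohort:

* one log-normal metabolite intensity matrix per organ, with a subset
  of "aging" features shifted between young and aged animals and a
  dose-dependent fraction of those shifts reversed by the treatment
  (full reversal at the high dose, half at the low dose);
* a behavioral table (six kinematic metrics, seven behavioral-sequence
  frequencies, open-field/rotarod endpoints, novel-object exploration
  times and a Y-maze arm-entry string) whose age-sensitive metrics are
  correlated (r ~ 0.5) with a per-animal latent biological-age factor
  shared with the metabolome — this coupling is what makes the
  cross-domain score regression recoverable;
* a sphingolipid concentration panel (SM, Cer, DHCer per tissue) with
  an elevated SM/Cer ratio in treated animals in the responsive
  tissues (gut, plasma, muscle);
* a ground-truth sidecar table listing which features and metrics
  carry effects. Analysis stages never read it.

Longitudinal genus-level taxa tables with injected trend templates are
generated separately by :func:`generate_taxa_series`.

All randomness flows from a single integer seed through named
``numpy`` seed-sequence streams, so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .metabolomics import MetaboliteMatrix
from .microbiome import TaxaTimeSeries
from .trends import TEMPLATE_ORDER, template_shapes

__all__ = [
    "CohortDesign",
    "TrendSpec",
    "SyntheticStudy",
    "generate_cohort",
    "generate_taxa_series",
    "write_study",
    "write_taxa_series",
    "read_taxa_series",
]

SPHINGO_TISSUES = ("gut", "plasma", "liver", "pancreas", "wat", "muscle")
SPHINGO_RESPONSIVE = ("gut", "plasma", "muscle")

_PHYLA_CYCLE = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")

#: behavioral aging-severity multiplier per group role
#: (young, aged water, vehicle, low dose, high dose)
_BEHAVIOR_SEVERITY = (0.0, 1.0, 1.0, 2.0 / 3.0, 1.0 / 3.0)

_ARMS = np.array(list("ABC"))


@dataclass(frozen=True)
class CohortDesign:
    """Study design and effect sizes for one synthetic cohort.

    ``groups`` are interpreted positionally as (young reference, aged
    water control, aged vehicle, low dose, high dose). ``aging_effect``
    is the standardized log2-scale mean shift of aged vs young animals
    for each affected metabolite feature; ``behavior_effect`` the
    analogous shift for age-sensitive behavioral metrics (motor decline
    in aged rodents is typically larger than single-metabolite shifts,
    hence the larger default). ``latent_coupling`` is the correlation
    between an affected readout's residual and the animal's latent
    biological-age factor.
    """

    groups: tuple[str, ...] = ("Young", "Old", "Saccharin", "Nico25", "Nico50")
    n_per_group: int = 10
    organs: tuple[str, ...] = ("plasma", "liver", "pancreas", "wat", "muscle")
    n_features_per_organ: int = 50
    aging_effect: float = 1.5
    aging_fraction: float = 0.4
    reversal_fraction: float = 0.6
    behavior_effect: float = 2.0
    latent_coupling: float = 0.5
    pathway_coupling: float = 0.65
    smcer_effect: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) != len(set(self.groups)) or not self.groups:
            raise ConfigurationError("groups: labels must be non-empty and unique")
        if len(self.groups) != 5:
            raise ConfigurationError(
                "groups: need 5 labels (young, aged water, vehicle, low dose, high dose)"
            )
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group: need at least 3 animals per group")
        if not self.organs or len(self.organs) != len(set(self.organs)):
            raise ConfigurationError("organs: labels must be non-empty and unique")
        if self.n_features_per_organ < 1:
            raise ConfigurationError("n_features_per_organ: must be positive")
        if not 0 <= self.reversal_fraction <= 1:
            raise ConfigurationError("reversal_fraction: must lie in [0, 1]")
        if not 0 <= self.aging_fraction <= 1:
            raise ConfigurationError("aging_fraction: must lie in [0, 1]")
        if not 0 <= self.latent_coupling < 1:
            raise ConfigurationError("latent_coupling: must lie in [0, 1)")
        if not 0 <= self.pathway_coupling < 1:
            raise ConfigurationError("pathway_coupling: must lie in [0, 1)")
        if self.latent_coupling**2 + self.pathway_coupling**2 > 0.95:
            raise ConfigurationError(
                "latent_coupling/pathway_coupling: squared couplings must sum below 0.95"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate: must lie in [0, 1)")

    # role accessors -------------------------------------------------
    @property
    def young(self) -> str:
        return self.groups[0]

    @property
    def aged_water(self) -> str:
        return self.groups[1]

    @property
    def vehicle(self) -> str:
        return self.groups[2]

    @property
    def low_dose(self) -> str:
        return self.groups[3]

    @property
    def high_dose(self) -> str:
        return self.groups[4]

    def behavior_severity(self) -> dict[str, float]:
        return dict(zip(self.groups, _BEHAVIOR_SEVERITY))


@dataclass(frozen=True)
class TrendSpec:
    """Injected temporal trends for the longitudinal taxa generator.

    ``assigned_template`` holds one label per taxon from the four trend
    patterns or ``"null"``; ``trend_group`` optionally restricts each
    taxon's trend to a single treatment group (None = all groups).
    ``amplitude`` scales the unit-norm template shape in log-abundance
    units; ``overdispersion`` is the per-subject-and-timepoint residual
    SD of log abundance. ``trend_baseline_offset`` shifts the baseline
    log abundance of trending taxa (default -3: trends sit on rare
    genera, clear of the abundance range that determines the
    median-log centering reference and contributing little total mass,
    so compositional renormalization of the non-trending majority
    stays below the noise floor; when every taxon trends the common
    offset cancels out).
    """

    n_taxa: int
    timepoints: int = 4
    assigned_template: tuple[str, ...] | None = None
    amplitude: float = 2.0
    overdispersion: float = 0.3
    trend_group: tuple[str | None, ...] | None = None
    trend_baseline_offset: float = -3.0

    def validate(self) -> None:
        if self.timepoints < 3:
            raise ConfigurationError("timepoints: templates undefined below 3")
        if self.n_taxa < 1:
            raise ConfigurationError("n_taxa: must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude: must be non-negative")
        if self.overdispersion < 0:
            raise ConfigurationError("overdispersion: must be non-negative")
        labels = self.templates()
        allowed = set(TEMPLATE_ORDER) | {"null"}
        bad = set(labels) - allowed
        if bad:
            raise ConfigurationError(f"assigned_template: unknown labels {sorted(bad)}")
        if self.trend_group is not None and len(self.trend_group) != self.n_taxa:
            raise ConfigurationError("trend_group: length must equal n_taxa")

    def templates(self) -> tuple[str, ...]:
        if self.assigned_template is None:
            return ("null",) * self.n_taxa
        if len(self.assigned_template) != self.n_taxa:
            raise ConfigurationError("assigned_template: length must equal n_taxa")
        return tuple(self.assigned_template)


@dataclass
class SyntheticStudy:
    """One generated cohort plus its ground-truth annotation."""

    design: CohortDesign
    metabolites: dict[str, MetaboliteMatrix]
    behavior: pd.DataFrame
    sphingolipids: pd.DataFrame
    ground_truth: pd.DataFrame
    latent_age: pd.Series = field(repr=False, default=None)


def _animal_ids(design: CohortDesign) -> tuple[list[str], pd.Series]:
    ids, groups = [], []
    for group in design.groups:
        for k in range(design.n_per_group):
            ids.append(f"{group}_{k + 1:02d}")
            groups.append(group)
    return ids, pd.Series(groups, index=ids, name="group")


def _coupled_noise(
    rng: np.random.Generator, u: np.ndarray, coupling: float, sd: float, size: int
) -> np.ndarray:
    """Residual c*u + sqrt(1-c^2)*eps with total SD = sd, columns iid."""
    eps = rng.standard_normal((u.size, size))
    return sd * (coupling * u[:, None] + np.sqrt(1.0 - coupling**2) * eps)


def _generate_organ(
    design: CohortDesign,
    organ: str,
    groups: pd.Series,
    u: np.ndarray,
    rng: np.random.Generator,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    n_feat = design.n_features_per_organ
    n_samp = len(groups)
    feature_ids = [f"{organ}_f{j + 1:03d}" for j in range(n_feat)]

    base = rng.uniform(14.0, 24.0, size=n_feat)  # log2 LC-MS intensity scale
    n_aging = int(round(design.aging_fraction * n_feat))
    aging_idx = rng.choice(n_feat, size=n_aging, replace=False)
    directions = rng.choice([-1.0, 1.0], size=n_feat)
    n_rev = int(round(design.reversal_fraction * n_aging))
    reversed_idx = rng.choice(aging_idx, size=n_rev, replace=False) if n_aging else np.array([], dtype=int)

    is_aging = np.zeros(n_feat, dtype=bool)
    is_aging[aging_idx] = True
    is_reversed = np.zeros(n_feat, dtype=bool)
    is_reversed[reversed_idx] = True

    # per-group aging-severity multiplier per feature
    severity = np.zeros((n_samp, n_feat))
    grp = groups.to_numpy()
    aged = np.isin(grp, [design.aged_water, design.vehicle])
    severity[np.ix_(aged, is_aging)] = 1.0
    low = grp == design.low_dose
    high = grp == design.high_dose
    restore = np.where(is_reversed, 1.0, 0.0)
    severity[low] = np.where(is_aging, 1.0 - 0.5 * restore, 0.0)
    severity[high] = np.where(is_aging, 1.0 - restore, 0.0)

    log2x = base[None, :] + directions[None, :] * design.aging_effect * severity

    # Aging features co-vary through the animal's latent biological-age
    # factor u and a per-organ pathway factor (metabolites of one
    # pathway rise and fall together); the independent remainder keeps
    # the total residual SD at noise_sd so realized standardized shifts
    # converge to aging_effect. Signs follow each feature's direction.
    c_u, c_p = design.latent_coupling, design.pathway_coupling
    pathway = rng.standard_normal(n_samp)
    eps = rng.standard_normal((n_samp, n_feat))
    shared = c_u * u[:, None] + c_p * pathway[:, None]
    resid_aging = design.noise_sd * (
        directions[None, :] * shared + np.sqrt(1.0 - c_u**2 - c_p**2) * eps
    )
    resid_null = design.noise_sd * eps
    log2x = log2x + np.where(is_aging[None, :], resid_aging, resid_null)

    intensities = np.exp2(log2x)
    if design.missing_rate > 0:
        mask = rng.random((n_samp, n_feat)) < design.missing_rate
        intensities[mask] = 0.0

    matrix = MetaboliteMatrix(
        intensities=pd.DataFrame(intensities, index=groups.index, columns=feature_ids),
        groups=groups,
        organ=organ,
    )
    truth = pd.DataFrame(
        {
            "kind": "metabolite",
            "organ": organ,
            "item": feature_ids,
            "is_aging": is_aging,
            "direction": np.where(directions > 0, "up", "down"),
            "reversed": is_reversed,
        }
    )
    return matrix, truth


def _ymaze_sequence(rng: np.random.Generator, p_alt: float, length: int) -> str:
    entries = [rng.choice(_ARMS)]
    entries.append(rng.choice(_ARMS[_ARMS != entries[0]]))
    for _ in range(length - 2):
        prev2, prev1 = entries[-2], entries[-1]
        others = _ARMS[_ARMS != prev1]
        alternating = others[others != prev2]
        if len(alternating) and rng.random() < p_alt:
            entries.append(alternating[0])
        else:
            entries.append(prev2)
    return "".join(entries)


def _generate_behavior(
    design: CohortDesign, groups: pd.Series, u: np.ndarray, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    severity = groups.map(design.behavior_severity()).to_numpy()
    n = len(groups)

    metric_base = {
        "frame_distance": (320.0, 32.0),
        "movement_speed_back": (42.0, 4.5),
        "movement_energy_back": (15.0, 1.8),
        "running": (8.0, 1.2),
        "center_time_ratio": (0.25, 0.035),
        "body_length": (7.4, 0.45),
        "falling_right_turn": (4.0, 0.7),
        "rearing": (22.0, 3.0),
        "trotting_exploring": (11.0, 1.6),
        "walking_sniffing_head_down": (16.0, 2.2),
        "walking_sniffing_left_turn": (9.0, 1.4),
        "walking_sniffing_right_turn": (9.0, 1.4),
        "pausing_sniffing": (12.0, 1.8),
        "oft_total_distance": (2600.0, 300.0),
        "rotarod_latency_25rpm": (180.0, 28.0),
    }
    # pausing-followed-by-sniffing rises with age; everything else falls
    rising = {"pausing_sniffing"}

    table = pd.DataFrame(index=groups.index)
    table["group"] = groups
    truth_rows = []
    for metric, (base, scale) in metric_base.items():
        sign = 1.0 if metric in rising else -1.0
        resid = _coupled_noise(rng, u, design.latent_coupling, 1.0, 1)[:, 0]
        signal = sign * (design.behavior_effect * severity + resid)
        table[metric] = base + scale * signal
        truth_rows.append(
            {
                "kind": "behavior_metric",
                "organ": "",
                "item": metric,
                "is_aging": True,
                "direction": "up" if metric in rising else "down",
                "reversed": True,
            }
        )

    # NOR exploration times: discrimination declines with age
    di_true = np.clip(
        0.35 - 0.28 * severity - 0.04 * u + 0.08 * rng.standard_normal(n), -0.9, 0.9
    )
    t_total = 40.0 + 8.0 * np.abs(rng.standard_normal(n))
    table["nor_t_new"] = t_total * (1.0 + di_true) / 2.0
    table["nor_t_old"] = t_total - table["nor_t_new"]
    table["nor_t_total"] = t_total

    # Y-maze arm entries: alternation propensity declines with age
    p_alt = np.clip(0.75 - 0.25 * severity + 0.05 * rng.standard_normal(n), 0.05, 0.95)
    lengths = rng.integers(20, 30, size=n)
    table["ymaze_entries"] = [
        _ymaze_sequence(rng, p_alt[i], int(lengths[i])) for i in range(n)
    ]
    truth = pd.DataFrame(truth_rows)
    return table, truth


def _generate_sphingolipids(
    design: CohortDesign, groups: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    severity = groups.map(design.behavior_severity()).to_numpy()
    youthfulness = 1.0 - severity
    rows = []
    for tissue in SPHINGO_TISSUES:
        mu_sm = rng.uniform(2.0, 3.5)
        mu_cer = rng.uniform(1.0, 2.5)
        responsive = tissue in SPHINGO_RESPONSIVE
        shift = design.smcer_effect * youthfulness if responsive else np.zeros_like(youthfulness)
        log_sm = mu_sm + 0.5 * shift + 0.3 * rng.standard_normal(len(groups))
        log_cer = mu_cer - 0.5 * shift + 0.3 * rng.standard_normal(len(groups))
        log_dhcer = (mu_sm - 1.0) + 0.3 * shift + 0.3 * rng.standard_normal(len(groups))
        for i, animal in enumerate(groups.index):
            rows.append(
                {
                    "sample_id": animal,
                    "group": groups.iloc[i],
                    "tissue": tissue,
                    "sm": float(np.exp(log_sm[i])),
                    "cer": float(np.exp(log_cer[i])),
                    "dhcer": float(np.exp(log_dhcer[i])),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign) -> SyntheticStudy:
    """Generate one full synthetic cohort from a validated design.

    Raises :class:`ConfigurationError` naming the offending field for
    invalid designs. Fixed seed implies byte-identical output.
    """
    design.validate()
    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(3 + len(design.organs))
    latent_rng = np.random.default_rng(streams[0])

    ids, groups = _animal_ids(design)
    u = latent_rng.standard_normal(len(ids))  # latent biological-age deviation
    latent = pd.Series(
        groups.map(design.behavior_severity()).to_numpy() + u,
        index=groups.index,
        name="latent_age",
    )

    metabolites: dict[str, MetaboliteMatrix] = {}
    truths = []
    for k, organ in enumerate(design.organs):
        rng = np.random.default_rng(streams[3 + k])
        matrix, truth = _generate_organ(design, organ, groups, u, rng)
        metabolites[organ] = matrix
        truths.append(truth)

    behavior, behavior_truth = _generate_behavior(
        design, groups, u, np.random.default_rng(streams[1])
    )
    sphingo = _generate_sphingolipids(design, groups, np.random.default_rng(streams[2]))
    truths.append(behavior_truth)
    ground_truth = pd.concat(truths, ignore_index=True)

    return SyntheticStudy(
        design=design,
        metabolites=metabolites,
        behavior=behavior,
        sphingolipids=sphingo,
        ground_truth=ground_truth,
        latent_age=latent,
    )


def generate_taxa_series(
    spec: TrendSpec,
    n_subjects_per_group: int,
    seed: int,
    groups: Sequence[str] = ("Saccharin", "Nico50"),
    subject_ids: dict[str, Sequence[str]] | None = None,
    depth: int = 50_000,
    sampling: str = "expected",
) -> TaxaTimeSeries:
    """Longitudinal genus-level counts with injected trend templates.

    Per subject and timepoint, each taxon's log abundance is its
    baseline plus ``amplitude`` times its (unit-norm) template shape —
    applied only in its ``trend_group`` if one is set — plus
    ``N(0, overdispersion)`` noise. Abundances close to proportions and
    convert to counts at fixed ``depth``; the default deterministic
    ``"expected"`` sampling rounds expected counts so that the
    noise-free limit is exactly monotone, while ``"multinomial"`` adds
    read-sampling noise.
    """
    spec.validate()
    if n_subjects_per_group < 3:
        raise ConfigurationError("n_subjects_per_group: need at least 3")
    if sampling not in ("expected", "multinomial"):
        raise ConfigurationError(f"sampling: unknown mode {sampling!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_count = spec.timepoints
    shapes = template_shapes(t_count)
    labels = spec.templates()
    trend_groups = spec.trend_group or (None,) * spec.n_taxa

    taxa = [f"g{j + 1:03d}" for j in range(spec.n_taxa)]
    phylum_map = pd.Series(
        [_PHYLA_CYCLE[j % len(_PHYLA_CYCLE)] for j in range(spec.n_taxa)],
        index=taxa,
        name="phylum",
    )
    baseline = rng.normal(0.0, 1.0, size=spec.n_taxa)
    baseline += np.where(
        np.array([lab != "null" for lab in labels]), spec.trend_baseline_offset, 0.0
    )

    rows = []
    for group in groups:
        if subject_ids is not None:
            subjects = list(subject_ids[group])
            if len(subjects) < 3:
                raise ConfigurationError(f"subject_ids[{group!r}]: need at least 3")
        else:
            subjects = [f"{group}_s{k + 1:02d}" for k in range(n_subjects_per_group)]
        trend_on = np.array(
            [
                labels[j] != "null" and (trend_groups[j] is None or trend_groups[j] == group)
                for j in range(spec.n_taxa)
            ]
        )
        shape_matrix = np.zeros((spec.n_taxa, t_count))
        for j in range(spec.n_taxa):
            if trend_on[j]:
                shape_matrix[j] = spec.amplitude * shapes[labels[j]]
        for subject in subjects:
            noise = rng.normal(0.0, spec.overdispersion, size=(spec.n_taxa, t_count))
            log_abund = baseline[:, None] + shape_matrix + noise
            props = np.exp(log_abund)
            props /= props.sum(axis=0, keepdims=True)
            for t in range(t_count):
                if sampling == "multinomial":
                    counts = rng.multinomial(depth, props[:, t])
                else:
                    counts = np.rint(depth * props[:, t]).astype(int)
                rows.append(
                    {"subject_id": subject, "group": group, "timepoint": t + 1}
                    | dict(zip(taxa, counts.tolist()))
                )

    counts_df = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "taxon": taxa,
            "template": labels,
            "trend_group": [g if g is not None else "all" for g in trend_groups],
        }
    )
    return TaxaTimeSeries(counts=counts_df, phylum_map=phylum_map, ground_truth=truth)


# ---------------------------------------------------------------- I/O


def write_study(study: SyntheticStudy, out_dir: str | Path) -> list[Path]:
    """Write the cohort as TSV files; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for organ, matrix in study.metabolites.items():
        path = out / f"{organ}_metabolites.tsv"
        matrix.to_tsv(path)
        written.append(path)
    behavior_path = out / "behavior.tsv"
    study.behavior.to_csv(
        behavior_path, sep="\t", index_label="animal_id", float_format="%.10g"
    )
    written.append(behavior_path)
    sphingo_path = out / "sphingolipids.tsv"
    study.sphingolipids.to_csv(sphingo_path, sep="\t", index=False, float_format="%.10g")
    written.append(sphingo_path)
    truth_path = out / "ground_truth.tsv"
    study.ground_truth.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    return written


def write_taxa_series(ts: TaxaTimeSeries, out_dir: str | Path) -> list[Path]:
    """Write per-timepoint count tables, the phylum map and the sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for t in ts.timepoints:
        sub = ts.counts[ts.counts["timepoint"] == t].drop(columns="timepoint")
        path = out / f"taxa_counts_t{t}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        written.append(path)
    phylum_path = out / "phylum_map.tsv"
    ts.phylum_map.rename_axis("taxon").to_csv(phylum_path, sep="\t")
    written.append(phylum_path)
    if ts.ground_truth is not None:
        truth_path = out / "taxa_ground_truth.tsv"
        ts.ground_truth.to_csv(truth_path, sep="\t", index=False)
        written.append(truth_path)
    return written


def read_taxa_series(in_dir: str | Path) -> TaxaTimeSeries:
    """Load taxa tables written by :func:`write_taxa_series`."""
    in_path = Path(in_dir)
    frames = []
    for path in sorted(in_path.glob("taxa_counts_t*.tsv")):
        t = int(path.stem.rsplit("t", 1)[1])
        df = pd.read_csv(path, sep="\t")
        df.insert(2, "timepoint", t)
        frames.append(df)
    if not frames:
        raise DomainError(f"no taxa_counts_t<k>.tsv files under {in_path}")
    counts = pd.concat(frames, ignore_index=True)
    phylum_map = pd.read_csv(in_path / "phylum_map.tsv", sep="\t", index_col="taxon")[
        "phylum"
    ]
    return TaxaTimeSeries(counts=counts, phylum_map=phylum_map)
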