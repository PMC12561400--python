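"""End-to-end orchestration: synth -> behavior -> diff -> biomarkers ->
network -> trends -> microbiome -> bmage.

A single :class:`RunConfig` drives every stage; all randomness flows
from one root seed through named substreams (one per stage), so a
rerun with the same config reproduces identical output checksums.
The run report records seeds, thresholds, per-stage summaries and a
SHA-256 checksum of every written table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import metabolomics as metab
from . import microbiome as micro
from .biomarkers import BiomarkerSet, select_biomarkers
from .errors import ConfigurationError, DomainError, PipelineError
from .network import correlation_network, organ_hub_summary, write_edge_list
from .scoring import BmageResult, BmageScorer, spearman_corr
from .synthdata import (
    CohortDesign,
    SyntheticStudy,
    TrendSpec,
    generate_cohort,
    generate_taxa_series,
    write_study,
    write_taxa_series,
)
from .trends import TrendMiner, trend_clusters

__all__ = ["RunConfig", "Thresholds", "TaxaGenConfig", "run_pipeline", "run_bmage_replicate"]

STAGES = (
    "synth",
    "behavior",
    "diff",
    "biomarkers",
    "network",
    "trends",
    "microbiome",
    "bmage",
)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Thresholds:
    """Screening and testing thresholds used across stages."""

    p: float = 0.05
    lfc: float = 0.26
    auc: float = 0.85
    r: float = 0.8
    network_p: float = 0.05
    alpha: float = 0.05
    min_rel_abund: float = 0.001
    mantel_permutations: int = 999

    def validate(self) -> None:
        for name in ("p", "network_p", "alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ConfigurationError(f"{name}: must lie in (0, 1), got {value}")
        if self.lfc < 0:
            raise ConfigurationError(f"lfc: must be non-negative, got {self.lfc}")
        if not 0.5 <= self.auc <= 1:
            raise ConfigurationError(f"auc: must lie in [0.5, 1], got {self.auc}")
        if not 0 <= self.r <= 1:
            raise ConfigurationError(f"r: must lie in [0, 1], got {self.r}")
        if not 0 <= self.min_rel_abund < 1:
            raise ConfigurationError("min_rel_abund: must lie in [0, 1)")
        if self.mantel_permutations < 9:
            raise ConfigurationError("mantel_permutations: need at least 9")


@dataclass(frozen=True)
class TaxaGenConfig:
    """Longitudinal taxa generation block of the run config.

    Default: 120 genera over 4 timepoints; 20 decreasing in the vehicle
    arm, 20 increasing and 20 decreasing in the high-dose arm (the
    three Gera-style clusters), plus one taxon decreasing in both arms
    (the cluster-overlap analogue); the rest carry no trend.
    """

    n_taxa: int = 120
    timepoints: int = 4
    amplitude: float = 2.0
    overdispersion: float = 0.3
    n_per_cluster: int = 20

    def validate(self) -> None:
        if self.n_taxa < 3 * self.n_per_cluster + 1:
            raise ConfigurationError(
                "n_taxa: must fit three trend clusters plus the overlap taxon"
            )
        if self.timepoints < 3:
            raise ConfigurationError("timepoints: need at least 3")

    def to_trend_spec(self, vehicle: str, high_dose: str) -> TrendSpec:
        labels: list[str] = []
        groups: list[str | None] = []
        k = self.n_per_cluster
        labels += ["decrease"] * k
        groups += [vehicle] * k
        labels += ["increase"] * k
        groups += [high_dose] * k
        labels += ["decrease"] * k
        groups += [high_dose] * k
        labels += ["decrease"]  # trends in both arms -> cluster overlap
        groups += [None]
        n_null = self.n_taxa - len(labels)
        labels += ["null"] * n_null
        groups += [None] * n_null
        return TrendSpec(
            n_taxa=self.n_taxa,
            timepoints=self.timepoints,
            assigned_template=tuple(labels),
            amplitude=self.amplitude,
            overdispersion=self.overdispersion,
            trend_group=tuple(groups),
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    design: CohortDesign = field(default_factory=CohortDesign)
    taxa: TaxaGenConfig = field(default_factory=TaxaGenConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        self.design.validate()
        self.taxa.validate()
        self.thresholds.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"stages: unknown stage names {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "design": asdict(self.design),
            "taxa": asdict(self.taxa),
            "thresholds": asdict(self.thresholds),
            "seed": self.seed,
            "stages": list(self.stages),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        design_kw = dict(data.get("design", {}))
        for key in ("groups", "organs"):
            if key in design_kw and design_kw[key] is not None:
                design_kw[key] = tuple(design_kw[key])
        return cls(
            design=CohortDesign(**design_kw),
            taxa=TaxaGenConfig(**data.get("taxa", {})),
            thresholds=Thresholds(**data.get("thresholds", {})),
            seed=int(data.get("seed", 0)),
            stages=tuple(data.get("stages", STAGES)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


# ------------------------------------------------------------------ helpers


def _stage_seed(root: np.random.SeedSequence, index: int) -> int:
    """Derive a small deterministic integer seed for stage ``index``."""
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> Path:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format="%.10g")
    return path


# ------------------------------------------------------ analysis building blocks


def screen_cohort(study: SyntheticStudy, thresholds: Thresholds) -> dict[str, Any]:
    """Run the full differential chain on every organ.

    Returns per-organ filtered matrices, normalized values, and the
    aging / vehicle / dose DiffTables (dose tables confound-excluded),
    plus direction-consistent overlaps against the aging contrast.
    """
    design = study.design
    out: dict[str, Any] = {"filtered": {}, "norm": {}, "diff": {}, "shared": {}}
    for organ, matrix in study.metabolites.items():
        filtered = metab.filter_missing(matrix, 0.5)
        norm = metab.normalize_log_median(filtered)
        kwargs = dict(p_thresh=thresholds.p, lfc_thresh=thresholds.lfc, normalized=norm)
        aging = metab.differential(filtered, design.aged_water, design.young, **kwargs)
        vehicle = metab.differential(filtered, design.aged_water, design.vehicle, **kwargs)
        doses = {}
        shared = {}
        for dose in (design.low_dose, design.high_dose):
            raw = metab.differential(filtered, design.vehicle, dose, **kwargs)
            doses[dose] = metab.exclude_confounded(raw, vehicle)
            shared[dose] = metab.direction_consistent_overlap(aging, doses[dose])
        out["filtered"][organ] = filtered
        out["norm"][organ] = norm
        out["diff"][organ] = {"aging": aging, "vehicle": vehicle, **doses}
        out["shared"][organ] = shared
    return out


def pick_biomarkers(
    study: SyntheticStudy, screen: dict[str, Any], thresholds: Thresholds
) -> dict[str, BiomarkerSet]:
    """ROC-select biomarkers per dose contrast, pooled over organs."""
    design = study.design
    result = {}
    for dose in (design.low_dose, design.high_dose):
        frames = []
        for organ, filtered in screen["filtered"].items():
            marker_set = select_biomarkers(
                screen["diff"][organ][dose],
                filtered,
                group_treated=dose,
                group_control=design.vehicle,
                auc_thresh=thresholds.auc,
                normalized=screen["norm"][organ],
            )
            frames.append(marker_set.entries)
        non_empty = [f for f in frames if len(f)]
        combined = (
            pd.concat(non_empty, ignore_index=True) if non_empty else frames[0]
        )
        result[dose] = BiomarkerSet(entries=combined)
    return result


def biomarker_value_table(
    screen: dict[str, Any], biomarkers: Mapping[str, BiomarkerSet]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Animals x biomarkers normalized-intensity table plus directions.

    Biomarkers appearing in both dose sets enter once (low dose first,
    keeping its direction label).
    """
    values: dict[str, pd.Series] = {}
    directions: dict[str, str] = {}
    for marker_set in biomarkers.values():
        for _, row in marker_set.entries.iterrows():
            node = f"{row['organ']}::{row['feature_id']}"
            if node in values:
                continue
            values[node] = screen["norm"][row["organ"]][row["feature_id"]]
            directions[node] = row["direction"]
    table = pd.DataFrame(values)
    return table, directions


def run_bmage_replicate(
    design: CohortDesign, thresholds: Thresholds | None = None
) -> dict[str, Any]:
    """One cohort -> screening -> biomarkers -> composite scores.

    A compact in-memory replicate of the scoring arm of the pipeline,
    used for replicate studies of the score's qualitative behavior.
    Returns the group ordering check (young > high dose > low dose >
    aged control on the behavioral score), the cross-domain regression
    and the biomarker count.
    """
    thresholds = thresholds or Thresholds()
    study = generate_cohort(design)
    screen = screen_cohort(study, thresholds)
    biomarkers = pick_biomarkers(study, screen, thresholds)
    values, directions = biomarker_value_table(screen, biomarkers)
    if values.shape[1] == 0:
        return {"ordering_ok": False, "n_biomarkers": 0, "slope": np.nan, "slope_p": np.nan}
    scorer = BmageScorer(young_group=design.young).fit(study.behavior)
    result = scorer.score_cohort(study.behavior, values, directions)
    means = result.group_means["z_behavior_total"]
    ordering_ok = bool(
        means[design.young] > means[design.high_dose] > means[design.low_dose] > means[design.aged_water]
    )
    return {
        "ordering_ok": ordering_ok,
        "n_biomarkers": int(values.shape[1]),
        "slope": result.regression["slope"],
        "slope_p": result.regression["p_value"],
        "r_squared": result.regression["r_squared"],
        "result": result,
        "study": study,
    }


# ------------------------------------------------------------------ stages


class _Run:
    """Mutable context threaded through the pipeline stages."""

    def __init__(self, config: RunConfig, out_dir: Path) -> None:
        self.config = config
        self.out = out_dir
        self.root = np.random.SeedSequence(config.seed)
        self.study: SyntheticStudy | None = None
        self.taxa = None
        self.screen: dict[str, Any] | None = None
        self.biomarkers: dict[str, BiomarkerSet] | None = None
        self.bmage: BmageResult | None = None
        self.files: list[Path] = []
        self.report: dict[str, Any] = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": config.seed,
            "thresholds": asdict(config.thresholds),
            "stages": {},
        }

    def record(self, stage: str, summary: dict, files: list[Path]) -> None:
        self.files.extend(files)
        self.report["stages"][stage] = summary | {
            "outputs": {f.name: _sha256(f) for f in sorted(files)}
        }


def _stage_synth(run: _Run) -> None:
    config = run.config
    design = replace(config.design, seed=_stage_seed(run.root, 0))
    study = generate_cohort(design)
    spec = config.taxa.to_trend_spec(design.vehicle, design.high_dose)
    subject_ids = {
        group: study.behavior.index[study.behavior["group"] == group].tolist()
        for group in (design.vehicle, design.high_dose)
    }
    taxa = generate_taxa_series(
        spec,
        n_subjects_per_group=design.n_per_group,
        seed=_stage_seed(run.root, 1),
        groups=(design.vehicle, design.high_dose),
        subject_ids=subject_ids,
    )
    files = write_study(study, run.out) + write_taxa_series(taxa, run.out)
    run.study, run.taxa = study, taxa
    run.record(
        "synth",
        {
            "n_animals": len(study.behavior),
            "organs": list(design.organs),
            "n_features_per_organ": design.n_features_per_organ,
            "n_taxa": spec.n_taxa,
        },
        files,
    )


def _stage_behavior(run: _Run) -> None:
    table = run.study.behavior
    rows = []
    for animal, row in table.iterrows():
        rows.append(
            {
                "animal_id": animal,
                "group": row["group"],
                "discrimination_index": beh.discrimination_index(
                    row["nor_t_new"], row["nor_t_old"], row["nor_t_total"]
                ),
                "spontaneous_alternation": beh.spontaneous_alternation(
                    row["ymaze_entries"]
                ),
            }
        )
    indices = pd.DataFrame(rows)
    path = _write_tsv(indices, run.out / "behavior_indices.tsv")
    summary = {
        "group_mean_di": indices.groupby("group")["discrimination_index"].mean().round(4).to_dict(),
        "group_mean_sab": indices.groupby("group")["spontaneous_alternation"].mean().round(2).to_dict(),
    }
    run.record("behavior", summary, [path])


def _stage_diff(run: _Run) -> None:
    config = run.config
    study = run.study
    screen = screen_cohort(study, config.thresholds)
    run.screen = screen
    files = []
    counts: dict[str, dict[str, int]] = {}
    contrast_names = {
        "aging": "aging",
        "vehicle": "vehicle",
        study.design.low_dose: "nico_low",
        study.design.high_dose: "nico_high",
    }
    for organ in study.design.organs:
        counts[organ] = {}
        for key, diff in screen["diff"][organ].items():
            name = contrast_names[key]
            path = run.out / f"diff_{organ}_{name}.tsv"
            _write_tsv(diff.table, path, index=True)
            files.append(path)
            counts[organ][name] = int(diff.table["significant"].sum())
        for dose, shared in screen["shared"][organ].items():
            rows = [{"feature_id": f, "relation": "same"} for f in shared.same_direction]
            rows += [{"feature_id": f, "relation": "opposite"} for f in shared.opposite_direction]
            path = run.out / f"shared_{organ}_{contrast_names[dose]}.tsv"
            _write_tsv(pd.DataFrame(rows, columns=["feature_id", "relation"]), path)
            files.append(path)
            counts[organ][f"shared_{contrast_names[dose]}"] = shared.counts[0]
    ratios, tests = metab.sm_cer_ratio(
        study.sphingolipids, study.design.vehicle, study.design.high_dose
    )
    files.append(_write_tsv(ratios, run.out / "smcer.tsv"))
    files.append(_write_tsv(tests, run.out / "smcer_tests.tsv", index=True))
    run.smcer = (ratios, tests)
    run.record(
        "diff",
        {
            "significant_counts": counts,
            "smcer_q": tests["q_value"].round(5).to_dict(),
        },
        files,
    )


def _stage_biomarkers(run: _Run) -> None:
    study = run.study
    biomarkers = pick_biomarkers(study, run.screen, run.config.thresholds)
    run.biomarkers = biomarkers
    files = []
    summary = {}
    names = {study.design.low_dose: "nico_low", study.design.high_dose: "nico_high"}
    for dose, marker_set in biomarkers.items():
        path = run.out / f"biomarkers_{names[dose]}.tsv"
        _write_tsv(marker_set.entries, path)
        files.append(path)
        summary[names[dose]] = len(marker_set)
    run.record("biomarkers", {"n_selected": summary}, files)


def _stage_network(run: _Run) -> None:
    study = run.study
    screen = run.screen
    thresholds = run.config.thresholds
    features = {}
    directions = {}
    for organ in study.design.organs:
        diffs = screen["diff"][organ]
        selected: list[str] = []
        dirs: dict[str, str] = {}
        for key in ("aging", study.design.low_dose, study.design.high_dose):
            for feat in diffs[key].significant_features:
                if feat not in dirs:
                    selected.append(feat)
                    dirs[feat] = diffs[key].direction_of(feat)
        features[organ] = selected
        directions[organ] = dirs
    graph = correlation_network(
        screen["filtered"],
        features,
        r_thresh=thresholds.r,
        p_thresh=thresholds.network_p,
        directions=directions,
    )
    summary = organ_hub_summary(graph)
    edge_path = run.out / "network_edges.tsv"
    write_edge_list(graph, edge_path)
    graphml_path = run.out / "network.graphml"
    nx.write_graphml(graph, graphml_path)
    summary_path = _write_tsv(summary, run.out / "network_organ_summary.tsv", index=True)
    run.record(
        "network",
        {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "hub_organ": summary.index[0] if len(summary) else None,
        },
        [edge_path, graphml_path, summary_path],
    )


def _stage_trends(run: _Run) -> None:
    config = run.config
    design = run.study.design
    files = []
    assignments = {}
    enrichments = {}
    significant = {}
    for group in (design.vehicle, design.high_dose):
        profiles = micro.group_mean_log_profiles(run.taxa, group)
        miner = TrendMiner(alpha=config.thresholds.alpha).fit(profiles)
        assignments[group] = miner.assignments_
        enrichments[group] = miner.enrichment_
        significant[group] = miner.significant_templates_()
        files.append(
            _write_tsv(miner.assignments_, run.out / f"trend_assignments_{group}.tsv", index=True)
        )
        files.append(
            _write_tsv(miner.enrichment_, run.out / f"trend_enrichment_{group}.tsv", index=True)
        )
    clusters, overlap = trend_clusters(assignments, enrichments, config.thresholds.alpha)
    files.append(_write_tsv(clusters, run.out / "trend_clusters.tsv"))
    files.append(_write_tsv(overlap, run.out / "trend_overlap.tsv"))
    run.trend_clusters = clusters
    run.trend_overlap = overlap
    run.record(
        "trends",
        {
            "significant_templates": significant,
            "n_clusters": len(clusters),
            "n_overlap_taxa": len(overlap),
        },
        files,
    )


def _stage_microbiome(run: _Run) -> None:
    config = run.config
    taxa = run.taxa
    min_abund = config.thresholds.min_rel_abund
    alpha_table = micro.alpha_diversity_table(taxa, min_abund)
    firbac = micro.fir_bac_table(taxa, min_abund)
    files = [
        _write_tsv(alpha_table, run.out / "alpha_diversity.tsv"),
        _write_tsv(firbac, run.out / "firbac.tsv"),
    ]

    last = taxa.timepoints[-1]
    sub = taxa.counts[taxa.counts["timepoint"] == last].set_index("subject_id")
    rel = micro.normalize_and_filter(sub[taxa.taxa], min_abund)
    d_taxa = micro.bray_curtis(rel)
    run.last_timepoint_rel = rel

    plasma = run.screen["norm"][run.study.design.organs[0]]
    plasma = plasma.loc[rel.index]
    plasma = plasma.fillna(plasma.mean())
    from scipy.spatial.distance import pdist, squareform

    d_metab = pd.DataFrame(
        squareform(pdist(plasma.to_numpy())), index=rel.index, columns=rel.index
    )
    scorer = BmageScorer(young_group=run.study.design.young).fit(run.study.behavior)
    b_scores = scorer.behavior_scores(run.study.behavior).loc[rel.index]
    z = b_scores[["z_motor", "z_char"]].to_numpy()
    d_behav = pd.DataFrame(
        squareform(pdist(z)), index=rel.index, columns=rel.index
    )
    seed = _stage_seed(run.root, 6)
    rows = []
    for name, d2 in (("metabolome", d_metab), ("behavior", d_behav)):
        r, p = micro.mantel_test(
            d_taxa, d2, n_perm=config.thresholds.mantel_permutations, seed=seed
        )
        rows.append({"comparison": f"taxa_vs_{name}", "mantel_r": r, "p_value": p})
    mantel = pd.DataFrame(rows)
    files.append(_write_tsv(mantel, run.out / "mantel.tsv"))
    run.record(
        "microbiome",
        {
            "mean_chao1": round(float(alpha_table["chao1"].mean()), 3),
            "mean_simpson": round(float(alpha_table["simpson"].mean()), 4),
            "group_mean_firbac": firbac.groupby("group")["fir_bac_ratio"].mean().round(3).to_dict(),
            "mantel": {row["comparison"]: [round(row["mantel_r"], 4), row["p_value"]] for _, row in mantel.iterrows()},
        },
        files,
    )


def _stage_bmage(run: _Run) -> None:
    study = run.study
    design = study.design
    values, directions = biomarker_value_table(run.screen, run.biomarkers)
    if values.shape[1] == 0:
        raise PipelineError("[bmage] no biomarkers selected; cannot build metabolomic score")
    scorer = BmageScorer(young_group=design.young).fit(study.behavior)
    result = scorer.score_cohort(study.behavior, values, directions)
    run.bmage = result
    files = [
        _write_tsv(result.scores, run.out / "bmage_scores.tsv", index=True, index_label="animal_id")
    ]

    # external covariates: SM/Cer ratios and the overlap taxon, within the
    # vehicle + high-dose arms (the arms the covariates are defined for)
    covariates = {}
    arms = [design.vehicle, design.high_dose]
    arm_scores = result.scores[result.scores["group"].isin(arms)]
    ratios, _ = run.smcer
    for tissue, sub in ratios[ratios["group"].isin(arms)].groupby("tissue"):
        merged = sub.set_index("sample_id").join(arm_scores["z_behavior_total"], how="inner")
        try:
            rho, p = spearman_corr(
                merged["sm_cer_ratio"].to_numpy(), merged["z_behavior_total"].to_numpy()
            )
            covariates[f"smcer_{tissue}"] = {"rho": round(rho, 4), "p": round(p, 5)}
        except Exception:  # constant covariate in a degenerate draw
            covariates[f"smcer_{tissue}"] = {"rho": None, "p": None}
    if getattr(run, "trend_overlap", None) is not None and len(run.trend_overlap):
        taxon = str(run.trend_overlap["taxon"].iloc[0])
        rel = run.last_timepoint_rel
        common = rel.index.intersection(arm_scores.index)
        if len(common) >= 4 and taxon in rel.columns:
            try:
                rho, p = spearman_corr(
                    rel.loc[common, taxon].to_numpy(),
                    arm_scores.loc[common, "z_behavior_total"].to_numpy(),
                )
                covariates[f"overlap_taxon_{taxon}"] = {"rho": round(rho, 4), "p": round(p, 5)}
            except DomainError:  # taxon zeroed by the abundance filter
                covariates[f"overlap_taxon_{taxon}"] = {"rho": None, "p": None}

    summary = {
        "regression": {k: round(v, 6) for k, v in result.regression.items()},
        "group_mean_scores": {
            col: result.group_means[col].round(4).to_dict()
            for col in ("z_motor", "z_char", "z_behavior_total", "z_metabolome")
        },
        "covariate_correlations": covariates,
        "n_biomarkers": int(values.shape[1]),
    }
    summary_path = run.out / "bmage_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    files.append(summary_path)
    run.record("bmage", summary, files)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "behavior": _stage_behavior,
    "diff": _stage_diff,
    "biomarkers": _stage_biomarkers,
    "network": _stage_network,
    "trends": _stage_trends,
    "microbiome": _stage_microbiome,
    "bmage": _stage_bmage,
}

_DEPENDENCIES = {
    "behavior": ("synth",),
    "diff": ("synth",),
    "biomarkers": ("diff",),
    "network": ("diff",),
    "trends": ("synth",),
    "microbiome": ("synth", "diff"),
    "bmage": ("diff", "biomarkers", "trends", "microbiome"),
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all enabled stages in dependency order; returns the report.

    The report (also written to ``report.json``) contains one section
    per executed stage with its summary numbers and the SHA-256
    checksum of every output file. Rerunning with the same config
    yields identical checksums. On stage failure the stage's partial
    outputs are renamed with a ``.partial`` suffix and a
    :class:`PipelineError` tagged with the stage name is raised.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out)
    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        missing = [d for d in _DEPENDENCIES.get(stage, ()) if d not in enabled]
        if missing:
            raise ConfigurationError(
                f"stage {stage!r} requires disabled stage(s) {missing}"
            )
    for stage in enabled:
        before = set(out.iterdir())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _STAGE_FUNCS[stage](run)
        except Exception as exc:
            for path in sorted(set(out.iterdir()) - before):
                if path.is_file() and path.suffix != ".partial":
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(f"[{stage}] {exc}") from exc
    report_path = out / "report.json"
    report_path.write_text(
        json.dumps(run.report, indent=2, sort_keys=True, default=_json_default)
    )
    return run.report
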