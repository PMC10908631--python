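"""End-to-end orchestration: simulate/ingest → label → graph → CN → stats.

The pipeline mirrors a typical multiplexed-imaging workflow: cells are
typed by gating plus classification, per-sample spatial graphs are built,
neighbor-composition profiles are pooled cohort-wide and clustered into
cellular neighborhoods, type-pair interactions are counted, mean signal
intensities are summarized from rendered (or supplied) images, and the
group statistics are compiled into a tidy report.

A single pipeline seed fans out into per-stage seeds (derived by hashing
the stage name into a ``SeedSequence``) so every stage is independently
reproducible; identical configuration and seed reproduce all CSV outputs
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gating import (ClassifierModel, GatingRules, assign_cell_types,
                     default_gating_rules)
from .graphs import SpatialGraph, build_expansion_graph, build_knn_graph
from .intensity import (compare_group_msi, sample_msi_summary, save_channels,
                        save_mask, load_mask, load_channels)
from .interactions import compare_interactions, count_pair_interactions
from .neighborhoods import (CNModel, aggregate_neighbor_fractions,
                            cluster_neighborhoods, cn_composition_zscores,
                            cn_frequencies)
from .stats import (kaplan_meier, log_rank, normalized_frequencies,
                    pearson_correlation, summarize_tests, tissue_nlr,
                    two_way_anova, unpaired_t_test)
from .synthetic import (CELL_TYPES, Cohort, GeneratorConfig,
                        render_sample_images, sample_background_levels,
                        simulate_cohort)

__all__ = ["PipelineConfig", "CohortAnalysis", "stage_seed", "build_graph",
           "analyze_cells", "analyze_cohort", "cohort_statistics",
           "directional_recovery", "run_pipeline"]

DEFAULT_MSI_MARKERS = ("E-Cadherin", "DNA", "TGFb1", "SMAD4", "Slug")
INTERACTION_PAIRS = (("neutrophil", "neutrophil"),
                     ("neutrophil", "tumor"),
                     ("cd8t", "neutrophil"))


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_graph(coords, cell_ids, method: str = "expansion",
                parameter: float = 15.0, sample_id: str = "sample") -> SpatialGraph:
    if method == "expansion":
        return build_expansion_graph(coords, cell_ids, threshold=parameter,
                                     sample_id=sample_id)
    if method == "knn":
        return build_knn_graph(coords, cell_ids, k=int(parameter),
                               sample_id=sample_id)
    raise ValueError("graph method must be 'expansion' or 'knn'")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"                  # "synthetic" | "files"
    outdir: str = "spatialtme_run"
    seed: int = 0
    n_per_group: int = 3
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cells_path: str | None = None            # files mode
    metadata_path: str | None = None
    images_dir: str | None = None
    gating_rules_path: str | None = None
    graph_method: str = "expansion"
    graph_parameter: float = 15.0
    n_cns: int = 8
    n_init: int = 10
    probability_threshold: float = 0.5
    regularization_c: float = 1.0
    render_images: bool = True
    msi_markers: tuple[str, ...] = DEFAULT_MSI_MARKERS

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.n_cns < 2:
            raise ValueError("n_cns must be >= 2")
        if self.mode == "files":
            for p in (self.cells_path, self.metadata_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        d["msi_markers"] = list(self.msi_markers)
        return d

    @classmethod
    def from_dict(cls, d) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "msi_markers" in d:
            d["msi_markers"] = tuple(d["msi_markers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CohortAnalysis:
    """In-memory results of one cohort analysis."""

    cells: pd.DataFrame
    metadata: pd.DataFrame
    graphs: dict[str, SpatialGraph]
    profiles: pd.DataFrame
    cn_model: CNModel
    cn_zscores: pd.DataFrame
    cn_freqs: pd.DataFrame
    type_freqs: pd.DataFrame
    tnlr: pd.DataFrame
    interactions: pd.DataFrame
    classifier: ClassifierModel
    gated: pd.Series
    msi_summaries: pd.DataFrame | None = None

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.metadata["sample_id"], self.metadata["group"]))

    def neutrophil_rich_cn(self) -> int:
        """The CN with the highest neutrophil z-score (composition-defined)."""
        return int(self.cn_zscores["neutrophil"].idxmax())


def _pooled_index(cells: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(cells[["sample_id", "cell_id"]])


def analyze_cells(cells: pd.DataFrame, metadata: pd.DataFrame, *,
                  graph_method: str = "expansion", graph_parameter: float = 15.0,
                  n_cns: int = 8, n_init: int = 10, seed: int = 0,
                  rules: GatingRules | None = None,
                  probability_threshold: float = 0.5,
                  regularization_c: float = 1.0) -> CohortAnalysis:
    """Run the tabular pipeline on a cohort cell table.

    ``cells`` must carry ``sample_id, cell_id, x, y`` plus marker columns;
    ``metadata`` one row per sample with ``sample_id, group`` (and,
    optionally, survival and serum columns used by the statistics stage).
    """
    cells = cells.sort_values(["sample_id", "cell_id"]).reset_index(drop=True)
    if rules is None:
        rules = default_gating_rules()
    final, gated, model = assign_cell_types(
        cells, rules, seed=stage_seed(seed, "classify"),
        probability_threshold=probability_threshold,
        regularization_c=regularization_c)
    cells = cells.copy()
    cells["gated_label"] = gated.to_numpy()
    cells["final_label"] = final.to_numpy()

    idx = _pooled_index(cells)
    graphs: dict[str, SpatialGraph] = {}
    profile_parts = []
    interaction_parts = []
    for sid, sub in cells.groupby("sample_id", sort=True):
        g = build_graph(sub[["x", "y"]].to_numpy(), sub["cell_id"].to_numpy(),
                        method=graph_method, parameter=graph_parameter,
                        sample_id=str(sid))
        graphs[str(sid)] = g
        labels = pd.Series(sub["final_label"].to_numpy(), index=sub["cell_id"].to_numpy())
        prof = aggregate_neighbor_fractions(g, labels)
        prof.index = pd.MultiIndex.from_product([[sid], prof.index],
                                                names=["sample_id", "cell_id"])
        profile_parts.append(prof)
        interaction_parts.append(count_pair_interactions(g, labels))
    profiles = pd.concat(profile_parts).sort_index()
    interactions = pd.concat(interaction_parts, ignore_index=True)

    cn_model = cluster_neighborhoods(profiles, k=n_cns,
                                     seed=stage_seed(seed, "cluster"),
                                     n_init=n_init)
    cn_series = cn_model.labels
    cells = cells.set_index(idx)
    cells["cn"] = cn_series
    cells = cells.reset_index(drop=True)

    final_by_idx = pd.Series(cells["final_label"].to_numpy(), index=cn_series.index)
    zscores = cn_composition_zscores(cn_series, final_by_idx)
    cn_freqs = cn_frequencies(cn_series,
                              pd.Series([i[0] for i in cn_series.index],
                                        index=cn_series.index),
                              k=n_cns)

    type_counts = (cells.groupby(["sample_id", "final_label"], observed=False)
                        .size().unstack(fill_value=0)
                        .reindex(columns=list(CELL_TYPES), fill_value=0))
    type_freqs = normalized_frequencies(type_counts)

    tnlr_rows = []
    group_of = dict(zip(metadata["sample_id"], metadata["group"]))
    for sid, row in type_counts.iterrows():
        tnlr_rows.append({"sample_id": sid, "group": group_of.get(sid),
                          "tnlr": tissue_nlr(int(row["neutrophil"]),
                                             int(row["cd4t"]), int(row["cd8t"]))})
    tnlr = pd.DataFrame(tnlr_rows)

    return CohortAnalysis(cells=cells, metadata=metadata.reset_index(drop=True),
                          graphs=graphs, profiles=profiles, cn_model=cn_model,
                          cn_zscores=zscores, cn_freqs=cn_freqs,
                          type_freqs=type_freqs, tnlr=tnlr,
                          interactions=interactions, classifier=model,
                          gated=gated)


def analyze_cohort(cohort: Cohort, *, render_markers=DEFAULT_MSI_MARKERS,
                   graph_method: str = "expansion", graph_parameter: float = 15.0,
                   n_cns: int = 8, n_init: int = 10, seed: int = 0,
                   rules: GatingRules | None = None,
                   probability_threshold: float = 0.5,
                   regularization_c: float = 1.0) -> CohortAnalysis:
    """Analyze a synthetic cohort, including rendered-image MSI summaries."""
    analysis = analyze_cells(cohort.cells, cohort.metadata,
                             graph_method=graph_method,
                             graph_parameter=graph_parameter, n_cns=n_cns,
                             n_init=n_init, seed=seed, rules=rules,
                             probability_threshold=probability_threshold,
                             regularization_c=regularization_c)
    if render_markers:
        cfg = cohort.config
        parts = []
        for s in sorted(cohort.samples, key=lambda r: r.metadata.sample_id):
            bg = sample_background_levels(s.cells, render_markers,
                                          cfg.background_fraction)
            mask, channels = render_sample_images(
                s.cells, cfg.roi_width, cfg.roi_height,
                markers=list(render_markers), background=bg)
            parts.append(sample_msi_summary(mask, channels,
                                            s.metadata.sample_id,
                                            s.metadata.group))
        analysis.msi_summaries = pd.concat(parts, ignore_index=True)
    return analysis


def cohort_statistics(analysis: CohortAnalysis) -> dict:
    """Compile the group statistics for one analyzed cohort.

    Returns a dict with a tidy two-sample test table, the two-way ANOVA
    tables for the cell-type and CN frequency panels, and per-group KM
    curves.
    """
    meta = analysis.metadata
    groups = sorted(meta["group"].unique())
    if len(groups) != 2:
        raise ValueError("cohort statistics require exactly two groups")
    by_group = {g: meta.loc[meta["group"] == g, "sample_id"].tolist()
                for g in groups}
    entries = []

    # per-type frequency t-tests
    for t in CELL_TYPES:
        x = analysis.type_freqs.loc[by_group[groups[0]], t]
        y = analysis.type_freqs.loc[by_group[groups[1]], t]
        entries.append({"test": "t_test_frequency", "comparison": t,
                        "result": unpaired_t_test(x, y)})

    # tissue NLR
    tn = analysis.tnlr.set_index("sample_id")["tnlr"]
    entries.append({"test": "t_test_tnlr", "comparison": "tnlr",
                    "result": unpaired_t_test(tn[by_group[groups[0]]],
                                              tn[by_group[groups[1]]])})

    # interactions
    for pair in INTERACTION_PAIRS:
        res = compare_interactions(analysis.interactions, pair,
                                   analysis.groups)
        entries.append({"test": "t_test_interaction",
                        "comparison": f"{res['pair'][0]}-{res['pair'][1]}",
                        "result": res["test"]})

    # MSI comparisons
    if analysis.msi_summaries is not None:
        for marker in analysis.msi_summaries["marker"].unique():
            for region in ("cell", "intercellular"):
                res = compare_group_msi(analysis.msi_summaries, marker, region)
                entries.append({"test": "t_test_msi",
                                "comparison": f"{marker}/{region}",
                                "result": res["test"]})

    # survival
    km_curves = {}
    if "survival_time" in meta.columns:
        for g in groups:
            sub = meta[meta["group"] == g]
            km_curves[g] = kaplan_meier(sub["survival_time"], sub["event"])
        entries.append({"test": "log_rank", "comparison": "-".join(groups),
                        "result": log_rank(meta["survival_time"], meta["event"],
                                           meta["group"])})
    if "serum_ne_dna" in meta.columns:
        entries.append({"test": "pearson_serum_survival",
                        "comparison": "serum_ne_dna~survival_time",
                        "result": pearson_correlation(meta["serum_ne_dna"],
                                                      meta["survival_time"])})

    # two-way ANOVA panels (category x treatment group)
    tf_long = analysis.type_freqs.reset_index().melt(
        id_vars="sample_id", var_name="cell_type", value_name="freq")
    tf_long["group"] = tf_long["sample_id"].map(analysis.groups)
    anova_types = two_way_anova(tf_long["freq"], tf_long["cell_type"],
                                tf_long["group"])
    cf_long = analysis.cn_freqs.reset_index().melt(
        id_vars="sample_id", var_name="cn", value_name="freq")
    cf_long["group"] = cf_long["sample_id"].map(analysis.groups)
    anova_cns = two_way_anova(cf_long["freq"], cf_long["cn"], cf_long["group"])

    return {"tests": summarize_tests(entries),
            "anova_type_frequencies": anova_types,
            "anova_cn_frequencies": anova_cns,
            "km_curves": km_curves}


def directional_recovery(config: GeneratorConfig | None = None,
                         n_cohorts: int = 100, n_per_group: int = 3,
                         seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Planted-effect recovery over replicate synthetic cohorts.

    For each replicate cohort the full pipeline is run and four directional
    findings are scored against the planted effects:

    - ``neut_freq``: neutrophil frequency higher in NT with t-test p < alpha;
    - ``neut_cn``: the CN with maximal neutrophil z-score more frequent in NT;
    - ``neut_neut``: more neutrophil–neutrophil interactions in NT;
    - ``ecad_msi``: E-Cadherin MSI lower in NT in both the cell and the
      intercellular region.

    Returns one row per cohort with boolean columns plus the neutrophil
    t-test p-value; column means are the recovery rates.
    """
    if config is None:
        config = GeneratorConfig()
    children = np.random.SeedSequence(seed).spawn(n_cohorts)
    rows = []
    for i, child in enumerate(children):
        cseed = int(child.generate_state(1)[0] % (2 ** 31))
        cohort = simulate_cohort(config, n_per_group, seed=cseed)
        an = analyze_cohort(cohort, render_markers=("E-Cadherin",), seed=cseed)
        nt = an.metadata.loc[an.metadata["group"] == "NT", "sample_id"]
        it = an.metadata.loc[an.metadata["group"] == "IT", "sample_id"]

        x = an.type_freqs.loc[nt, "neutrophil"]
        y = an.type_freqs.loc[it, "neutrophil"]
        tt = unpaired_t_test(x, y)
        neut_freq = bool(tt.pvalue < alpha and tt.mean_diff > 0)

        cn = an.neutrophil_rich_cn()
        neut_cn = bool(an.cn_freqs.loc[nt, cn].mean() > an.cn_freqs.loc[it, cn].mean())

        res = compare_interactions(an.interactions, ("neutrophil", "neutrophil"),
                                   an.groups)
        neut_neut = bool(res["means"]["NT"] > res["means"]["IT"])

        ecad = True
        for region in ("cell", "intercellular"):
            r = compare_group_msi(an.msi_summaries, "E-Cadherin", region)
            ecad &= bool(r["means"]["NT"] < r["means"]["IT"])

        rows.append({"cohort": i, "neut_freq": neut_freq, "neut_cn": neut_cn,
                     "neut_neut": neut_neut, "ecad_msi": ecad,
                     "neut_freq_pvalue": tt.pvalue})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all stage outputs to a run directory.

    Returns the run directory.  A ``manifest.json`` records the config hash,
    seeds and package version; re-running with an identical config and seed
    reproduces all CSV outputs bit-exactly.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        if config.mode == "synthetic":
            stage = "simulate"
            cohort = simulate_cohort(config.generator, config.n_per_group,
                                     seed=stage_seed(config.seed, "simulate"))
            cells, metadata = cohort.cells, cohort.metadata
            cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
            config.generator.to_yaml(out / "generator_config.yaml")
        else:
            stage = "load"
            cohort = None
            cells = pd.read_csv(config.cells_path, float_precision="round_trip")
            metadata = pd.read_csv(config.metadata_path, float_precision="round_trip")

        stage = "gate/classify/graph/neighborhoods/interactions"
        rules = (GatingRules.from_yaml(config.gating_rules_path)
                 if config.gating_rules_path else default_gating_rules())
        analysis = analyze_cells(cells, metadata,
                                 graph_method=config.graph_method,
                                 graph_parameter=config.graph_parameter,
                                 n_cns=config.n_cns, n_init=config.n_init,
                                 seed=config.seed, rules=rules,
                                 probability_threshold=config.probability_threshold,
                                 regularization_c=config.regularization_c)

        stage = "intensity"
        if config.mode == "synthetic" and config.render_images:
            parts = []
            gcfg = config.generator
            for s in sorted(cohort.samples, key=lambda r: r.metadata.sample_id):
                bg = sample_background_levels(s.cells, config.msi_markers,
                                              gcfg.background_fraction)
                mask, channels = render_sample_images(
                    s.cells, gcfg.roi_width, gcfg.roi_height,
                    markers=list(config.msi_markers), background=bg)
                img_dir = out / "images" / s.metadata.sample_id
                img_dir.mkdir(parents=True, exist_ok=True)
                save_mask(mask, img_dir / "mask.tiff")
                save_channels(channels, img_dir)
                parts.append(sample_msi_summary(mask, channels,
                                                s.metadata.sample_id,
                                                s.metadata.group))
            analysis.msi_summaries = pd.concat(parts, ignore_index=True)
        elif config.mode == "files" and config.images_dir is not None:
            parts = []
            group_of = dict(zip(metadata["sample_id"], metadata["group"]))
            for sdir in sorted(Path(config.images_dir).iterdir()):
                if not sdir.is_dir():
                    continue
                mask = load_mask(sdir / "mask.tiff")
                channels = load_channels(sdir)
                parts.append(sample_msi_summary(mask, channels, sdir.name,
                                                group_of.get(sdir.name)))
            if parts:
                analysis.msi_summaries = pd.concat(parts, ignore_index=True)

        stage = "stats"
        report = cohort_statistics(analysis)

        stage = "write"
        analysis.cells.to_csv(out / "cells.csv", index=False)
        analysis.metadata.to_csv(out / "metadata.csv", index=False)
        edges_dir = out / "edges"
        edges_dir.mkdir(exist_ok=True)
        for sid, g in analysis.graphs.items():
            g.save(edges_dir / f"{sid}.csv", edges_dir / f"{sid}.json")
        analysis.profiles.reset_index().to_csv(out / "profiles.csv", index=False)
        analysis.cn_model.centroids.to_csv(out / "cn_centroids.csv")
        analysis.cn_zscores.to_csv(out / "cn_zscores.csv")
        analysis.cn_freqs.to_csv(out / "cn_frequencies.csv")
        analysis.type_freqs.to_csv(out / "type_frequencies.csv")
        analysis.tnlr.to_csv(out / "tnlr.csv", index=False)
        analysis.interactions.to_csv(out / "interactions.csv", index=False)
        if analysis.msi_summaries is not None:
            analysis.msi_summaries.to_csv(out / "msi_summary.csv", index=False)
        analysis.classifier.to_json(out / "classifier.json")
        rules.to_yaml(out / "gating_rules.yaml")
        report["tests"].to_csv(out / "stats_report.csv", index=False)
        report["anova_type_frequencies"].table.to_csv(out / "anova_type_frequencies.csv")
        report["anova_cn_frequencies"].table.to_csv(out / "anova_cn_frequencies.csv")
        if report["km_curves"]:
            km_all = pd.concat([t.assign(group=g)
                                for g, t in report["km_curves"].items()],
                               ignore_index=True)
            km_all.to_csv(out / "km_curves.csv", index=False)
        manifest = {
            "package": "spatialtme",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("simulate", "classify", "cluster")},
            "mode": config.mode,
            "outputs": sorted(str(p.relative_to(out))
                              for p in out.rglob("*") if p.is_file()
                              and p.name != "manifest.json"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return out
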