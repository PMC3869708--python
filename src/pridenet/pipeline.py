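"""End-to-end orchestration: observations -> matrices -> metrics -> inference.

``run_analysis`` performs the full dual analysis a field study of this kind
reports: for the whole group *and* for the roster with a designated subset
(typically the cubs) excluded, it builds the association network and the
four directed interaction networks, computes every network report (density,
strong transitivity, cliques, degrees, betweenness), runs the Mantel panel
against attribute and random matrices, the rank-correlation suite among
node metrics, and a keystone-candidate ranking; it can write the whole
bundle (CSV tables, GraphML sociograms, clique maps, JSON manifest) to an
output directory.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import export
from .matrices import (
    ALL_SOCIAL,
    AssociationMatrix,
    InteractionMatrix,
    LabeledMatrix,
    build_association_matrix,
    build_attribute_matrices,
    build_interaction_matrices,
)
from .metrics import NetworkReport, network_report
from .observations import (
    BEHAVIORS,
    ObservationSet,
    data_point_accounting,
    deduplicate_bouts,
    read_observations,
)
from .observations import subset_observations
from .stats import mantel_panel, panel_blocks, rank_correlation

logger = logging.getLogger(__name__)

ATTRIBUTE_KINDS_DEFAULT = ("gender_similarity", "half_sibling", "full_sibling", "age_similarity", "kinship")


@dataclass
class RunConfig:
    """Options of one full analysis run."""

    scans_path: str | None = None
    events_path: str | None = None
    roster_path: str | None = None
    kinship_path: str | None = None
    exclude_ids: tuple[str, ...] = ()          # e.g. the cubs; () = infer cubs from roster
    infer_cub_exclusion: bool = True
    behaviors: tuple[str, ...] = BEHAVIORS
    transitivity_rule: str = "min"
    weighted_betweenness: bool = False
    clique_symmetrization: str = "union"
    mantel_symmetrization: str = "sum"
    attribute_kinds: tuple[str, ...] = ATTRIBUTE_KINDS_DEFAULT
    drop_unaccepted: bool = False
    dedup_gap_seconds: float = 60.0
    n_permutations: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        for key in ("exclude_ids", "behaviors", "attribute_kinds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class VariantResult:
    """Everything computed for one roster variant."""

    label: str
    observations: ObservationSet
    networks: dict[str, LabeledMatrix]
    attributes: dict[str, LabeledMatrix]
    reports: dict[str, NetworkReport]
    degree_table: pd.DataFrame
    betweenness_table: pd.DataFrame
    mantel: pd.DataFrame
    correlations: pd.DataFrame
    keystone: pd.DataFrame


@dataclass
class AnalysisBundle:
    variants: dict[str, VariantResult]
    manifest: dict


def _analyze_variant(
    obs: ObservationSet, label: str, config: RunConfig, seed: int
) -> VariantResult:
    ids = obs.ids
    events = deduplicate_bouts(obs.events, dt.timedelta(seconds=config.dedup_gap_seconds))
    if config.drop_unaccepted:
        events = tuple(e for e in events if e.accepted)

    assoc = build_association_matrix(obs.scans, ids)
    inter = build_interaction_matrices(events, ids)
    networks: dict[str, LabeledMatrix] = {b: inter[b] for b in (*config.behaviors, ALL_SOCIAL)}
    networks["composition"] = assoc

    reference = obs.scans[len(obs.scans) // 2].timestamp.date() if obs.scans else None
    attributes = build_attribute_matrices(
        obs.roster,
        obs.kinship_full(),
        kinds=config.attribute_kinds,
        reference_date=reference,
    )

    reports = {}
    for name, mat in networks.items():
        directed = name != "composition"
        reports[name] = network_report(
            mat,
            directed=directed,
            name=name,
            transitivity_rule=config.transitivity_rule,
            weighted_betweenness=config.weighted_betweenness,
            clique_symmetrization=config.clique_symmetrization,
        )

    degree_cols, btw_cols = {}, {}
    for name, rep in reports.items():
        nm = rep.node_metrics
        if "indegree_norm" in nm:
            degree_cols[(name, "indegree")] = nm["indegree_norm"]
            degree_cols[(name, "outdegree")] = nm["outdegree_norm"]
        else:
            degree_cols[(name, "degree")] = nm["degree_norm"]
        if "betweenness_norm" in nm:
            btw_cols[name] = nm["betweenness_norm"]
    degree_table = pd.DataFrame(degree_cols)
    degree_table.columns = pd.MultiIndex.from_tuples(degree_table.columns, names=["network", "metric"])
    betweenness_table = pd.DataFrame(btw_cols)

    panel = mantel_panel(
        networks,
        attributes,
        n_permutations=config.n_permutations,
        seed=seed,
        symmetrization=config.mantel_symmetrization,
    )
    correlations = correlation_suite(reports)
    keystone = summarize_keystone(list(reports.values()))

    return VariantResult(
        label=label,
        observations=obs,
        networks=networks,
        attributes=attributes,
        reports=reports,
        degree_table=degree_table,
        betweenness_table=betweenness_table,
        mantel=panel,
        correlations=correlations,
        keystone=keystone,
    )


def correlation_suite(reports: Mapping[str, NetworkReport]) -> pd.DataFrame:
    """Spearman among in/outdegree vectors; Kendall of betweenness vs degree.

    Covers, for every directed network, the indegree-vs-outdegree Spearman
    correlations within and across networks, and Kendall's tau-b between
    each network's betweenness and every in/outdegree vector.
    """
    vectors: dict[str, pd.Series] = {}
    btw: dict[str, pd.Series] = {}
    for name, rep in reports.items():
        nm = rep.node_metrics
        if "indegree" in nm:
            vectors[f"{name}_indegree"] = nm["indegree"]
            vectors[f"{name}_outdegree"] = nm["outdegree"]
        if "betweenness" in nm:
            btw[f"{name}_betweenness"] = nm["betweenness"]
    rows = []
    names = list(vectors)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                res = rank_correlation(vectors[a], vectors[b], "spearman", names=(a, b))
            except ValueError:
                continue
            rows.append(res.to_dict())
    for bn, bv in btw.items():
        for a in names:
            try:
                res = rank_correlation(bv, vectors[a], "kendall_tau", names=(bn, a))
            except ValueError:
                continue
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def summarize_keystone(reports: Sequence[NetworkReport], tol: float = 1e-9) -> pd.DataFrame:
    """Rank individuals as keystone candidates across networks.

    For every report, individuals are ranked (1 = most central, ties get
    average ranks) on betweenness, and on the number of cliques they belong
    to. The composite score is the mean of all those ranks; the lowest
    composite is flagged keystone, with ties flagged jointly rather than
    broken silently.
    """
    if not reports:
        raise ValueError("need at least one network report")
    rank_cols = {}
    ids = list(reports[0].node_metrics.index)
    for rep in reports:
        nm = rep.node_metrics
        if "betweenness" in nm:
            rank_cols[f"{rep.network_name}_betweenness_rank"] = nm["betweenness"].rank(
                ascending=False
            )
        counts = pd.Series(
            {i: sum(1 for c in rep.cliques if i in c) for i in nm.index}, dtype=float
        )
        rank_cols[f"{rep.network_name}_clique_rank"] = counts.rank(ascending=False)
    df = pd.DataFrame(rank_cols, index=ids)
    df["composite_rank"] = df.mean(axis=1)
    best = df["composite_rank"].min()
    df["keystone"] = df["composite_rank"] <= best + tol
    if df["keystone"].sum() == len(df):
        # complete symmetry: everyone tied, nobody stands out
        df["keystone"] = False
    df.index.name = "id"
    return df.sort_values("composite_rank")


def run_analysis(
    config: RunConfig, observations: ObservationSet | None = None
) -> AnalysisBundle:
    """Run the dual (full roster / subset-excluded) analysis.

    ``observations`` may be passed directly (e.g. straight from the
    simulator); otherwise the four logs named in the config are read. When
    ``config.out_dir`` is set the bundle is also written to disk; a failure
    at any stage removes partial outputs and re-raises with a stage tag.
    """
    stage = "ingest"
    try:
        if observations is None:
            if not all((config.scans_path, config.events_path, config.roster_path)):
                raise ValueError("either observations or input paths are required")
            observations = read_observations(
                config.scans_path, config.events_path, config.roster_path, config.kinship_path
            )
        accounting = data_point_accounting(observations)
        logger.info("ingested records: %s", accounting)

        exclude = tuple(config.exclude_ids)
        if not exclude and config.infer_cub_exclusion:
            exclude = observations.cub_ids
        rng = np.random.default_rng(config.seed)
        variants: dict[str, VariantResult] = {}
        stage = "analysis:all"
        variants["all"] = _analyze_variant(
            observations, "all", config, seed=int(rng.integers(0, 2**31 - 1))
        )
        if exclude:
            stage = "analysis:excluded"
            reduced = subset_observations(observations, exclude)
            variants["excluded"] = _analyze_variant(
                reduced, "excluded", config, seed=int(rng.integers(0, 2**31 - 1))
            )

        manifest = {
            "config": {
                k: (list(getattr(config, k)) if isinstance(getattr(config, k), tuple) else getattr(config, k))
                for k in config.__dataclass_fields__
            },
            "excluded_ids": list(exclude),
            "data_points": accounting,
            "variants": {
                label: data_point_accounting(v.observations) for label, v in variants.items()
            },
            "n_individuals": {label: len(v.observations.ids) for label, v in variants.items()},
        }
        bundle = AnalysisBundle(variants=variants, manifest=manifest)
        if config.out_dir:
            stage = "write"
            write_bundle(bundle, config.out_dir)
        return bundle
    except Exception as exc:
        if config.out_dir and stage == "write":
            shutil.rmtree(config.out_dir, ignore_errors=True)
        raise RuntimeError(f"analysis failed at stage '{stage}': {exc}") from exc


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> Path:
    """Write every table, sociogram and the manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, v in bundle.variants.items():
        vdir = out / label
        vdir.mkdir(exist_ok=True)
        for name, mat in v.networks.items():
            mat.to_csv(vdir / f"matrix_{name}.csv")
            export.to_graphml(mat, vdir / f"sociogram_{name}.graphml", directed=name != "composition")
        for name, attr in v.attributes.items():
            attr.to_csv(vdir / f"attribute_{name}.csv")
        group_rows = {
            name: {"density": rep.density, "strong_transitivity": rep.strong_transitivity}
            for name, rep in v.reports.items()
        }
        pd.DataFrame(group_rows).to_csv(vdir / "group_metrics.csv", index_label="metric")
        v.betweenness_table.to_csv(vdir / "betweenness.csv", index_label="id")
        v.degree_table.to_csv(vdir / "degrees.csv", index_label="id")
        v.mantel.to_csv(vdir / "mantel_panel.csv", index=False)
        p_block, r_block = panel_blocks(v.mantel)
        p_block.to_csv(vdir / "mantel_p_values.csv")
        r_block.to_csv(vdir / "mantel_coefficients.csv")
        v.correlations.to_csv(vdir / "correlations.csv", index=False)
        v.keystone.to_csv(vdir / "keystone_ranking.csv")
        cliques = pd.concat(
            [
                export.clique_bipartite(rep.cliques, network_name=name)
                for name, rep in v.reports.items()
            ],
            ignore_index=True,
        )
        cliques.to_csv(vdir / "clique_membership.csv", index=False)
        for name, rep in v.reports.items():
            rep.to_json(vdir / f"report_{name}.json")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))
    return out
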