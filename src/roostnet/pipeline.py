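"""Year-stratified analysis pipeline.

Runs, per colony-year: network construction and metrics, ER null tests,
roost-removal simulations, individual BRB foraging UDs with the
UDOI-thresholded foraging network, colony roosting/foraging kernel UDs,
and telemetry summaries; then cross-year comparisons (Bhattacharyya
affinity of colony UDs, roosting-centroid shift) and the congruence
between foraging overlap and social proximity.  All stages draw from
named substreams of one global seed, so disabling a stage never perturbs
another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import metrics as M
from . import nulls as N
from . import removal as R
from . import spatial as S
from . import summaries as T
from .networks import attach_node_attributes, build_bipartite, project
from .synthetic import Colony, ColonyConfig, generate_colony, read_colony_csvs

__all__ = ["PipelineConfig", "run_pipeline", "analyze_year", "social_foraging_congruence"]

_STAGE_KEYS = {"nulls_roost": 0, "nulls_social": 1, "removal": 2, "spatial": 3}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one report (round-trips via YAML)."""

    #: year label -> synthetic ColonyConfig; or year label -> input directory
    years: dict = field(default_factory=dict)
    input_dirs: dict = field(default_factory=dict)
    n_null_sims: int = 500
    null_link_prob: float | None = None  # None: match observed density
    brb_tmax_min: float = 60.0
    brb_lmin_m: float = 50.0
    brb_hmin_m: float = 88.0
    grid_cell_m: float = 30.0
    isopleth_level: float = 0.95
    udoi_threshold: float = 1.0
    min_fixes: int = 40
    removal_reps: int = 1000
    removal_max_fraction: float = 0.70
    removal_step: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not self.years and not self.input_dirs:
            raise ValueError("configure at least one year")
        for v in (
            self.n_null_sims, self.brb_tmax_min, self.brb_lmin_m, self.brb_hmin_m,
            self.grid_cell_m, self.isopleth_level, self.udoi_threshold,
            self.min_fixes, self.removal_reps, self.removal_max_fraction,
            self.removal_step,
        ):
            if v <= 0:
                raise ValueError("all thresholds must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["years"] = {
            y: dataclasses.asdict(c) if isinstance(c, ColonyConfig) else c
            for y, c in self.years.items()
        }
        for y in d["years"]:
            td = d["years"][y].get("tracking_days_per_bat")
            if td is not None:
                d["years"][y]["tracking_days_per_bat"] = dict(td)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        years = {y: ColonyConfig(**c) for y, c in (d.get("years") or {}).items()}
        d["years"] = years
        return cls(**d)


def _year_seed(seed: int, year: str, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence(
        seed, spawn_key=(zlib.crc32(str(year).encode()), _STAGE_KEYS[stage])
    )
    return int(ss.generate_state(1)[0] % (2**31))


def social_foraging_congruence(
    social: nx.Graph, overlap: nx.Graph
) -> tuple[int, int, float]:
    """Count foraging-overlap dyads that are also socially close.

    A dyad is "close" when its geodesic distance in the social network is
    strictly below the social network's mean shortest path length.
    Returns (n overlap dyads, n also close, colony mean path).
    """
    shared = set(social.nodes) & set(overlap.nodes)
    if not shared:
        raise ValueError("social and overlap networks share no bat identifiers")
    mean_path = M.mean_shortest_path(social)
    n_overlap = overlap.number_of_edges()
    n_close = 0
    for u, v in overlap.edges:
        if u not in social or v not in social:
            continue
        try:
            d = nx.shortest_path_length(social, u, v)
        except nx.NetworkXNoPath:
            continue
        if d < mean_path:
            n_close += 1
    return n_overlap, n_close, mean_path


def _null_metrics_roost() -> dict:
    return {
        "density": M.density_two_mode,
        "clustering": M.clustering_two_mode,
        "degree_centralization": M.degree_centralization_two_mode,
    }


def _null_metrics_social(attribute: str | None) -> dict:
    out = {
        "density": M.density,
        "clustering": M.clustering,
        "degree_centralization": M.degree_centralization,
        "modularity_Q": lambda g: M.modularity_leading_eigenvector(g)[0],
        "mean_shortest_path": M.mean_shortest_path,
    }
    if attribute:
        out["homophily_r"] = lambda g: M.nominal_assortativity(g, attribute)
    return out


def analyze_year(colony: Colony, config: PipelineConfig, year: str) -> dict:
    """All within-year stages for one colony; returns a result bundle."""
    out: dict = {"year": year}

    bnet = build_bipartite(colony.relocations)
    social = project(bnet, "bats")
    roost_proj = project(bnet, "roosts")
    attach_node_attributes(social, colony.bats, "bat_id", ["age_class", "sex"])
    out["bipartite"] = bnet
    out["social"] = social
    out["roost_projection"] = roost_proj
    out["roost_report"] = M.roost_network_report(bnet, f"roost_{year}")
    out["social_report"] = M.social_network_report(social, "age_class", f"social_{year}")

    er = N.ERConfig(
        n_sims=config.n_null_sims,
        link_prob=config.null_link_prob,
        seed=_year_seed(config.seed, year, "nulls_roost"),
    )
    out["roost_nulls"] = N.run_null_suite(bnet, _null_metrics_roost(), er)
    er_s = dataclasses.replace(er, seed=_year_seed(config.seed, year, "nulls_social"))
    has_classes = colony.bats["age_class"].nunique() > 1
    out["social_nulls"] = N.run_null_suite(
        social, _null_metrics_social("age_class" if has_classes else None), er_s
    )

    out["removal_curve"] = R.random_removal_curve(
        roost_proj,
        max_removed_fraction=config.removal_max_fraction,
        step=config.removal_step,
        n_reps=config.removal_reps,
        seed=_year_seed(config.seed, year, "removal"),
    )
    out["targeted_removal"] = R.targeted_removal(roost_proj, k=1)
    out["baseline_components"] = R.count_components(roost_proj)

    out["summaries"] = T.roost_switching_stats(colony.relocations)
    out["glm"] = T.poisson_glm_roosts_vs_relocs(T.per_bat_effort(colony.relocations))
    days_used = colony.relocations.groupby("roost_id").size()
    max_counts = colony.exit_counts.groupby("roost_id")["count"].max()
    joint = pd.concat([days_used, max_counts], axis=1, join="inner")
    joint.columns = ["days", "max_count"]
    try:
        out["emergence_correlation"] = T.emergence_correlation(
            joint["days"].to_numpy(), joint["max_count"].to_numpy()
        )
    except ValueError as err:
        out["emergence_correlation"] = None
        out["emergence_correlation_skipped"] = str(err)

    # --- individual foraging UDs and the overlap network
    params = S.BRBParams(config.brb_tmax_min, config.brb_lmin_m, config.brb_hmin_m)
    fix_counts = colony.fixes.groupby("bat_id").size()
    eligible = sorted(fix_counts[fix_counts >= config.min_fixes].index)
    out["ud_eligible"] = eligible
    if len(eligible) < 2:
        out["overlap_skipped"] = (
            f"only {len(eligible)} bat(s) with >= {config.min_fixes} fixes"
        )
        return out
    tracks, diffusions = {}, {}
    for bat in eligible:
        tr = S.segment_track(colony.fixes[colony.fixes["bat_id"] == bat], params)
        tracks[bat] = tr
        diffusions[bat] = S.estimate_diffusion_plugin(tr, params)
    max_sd = max(
        np.sqrt(
            params.hmin_m**2
            + 2.0 * d * params.tmax_min * 0.25
        )
        for d in diffusions.values()
    )
    pts = colony.fixes.loc[
        colony.fixes["bat_id"].isin(eligible), ["x_m", "y_m"]
    ].to_numpy()
    spec = S.GridSpec.from_points(pts, config.grid_cell_m, buffer_m=4.0 * max_sd)
    uds = {}
    for bat in eligible:
        p = dataclasses.replace(params, diffusion=diffusions[bat])
        uds[bat] = S.brb_ud(tracks[bat], p, spec)
    out["foraging_uds"] = uds
    out["diffusions"] = diffusions
    graph, dyads, fraction = S.foraging_overlap_network(
        uds, threshold=config.udoi_threshold, level=config.isopleth_level
    )
    out["overlap_network"] = graph
    out["dyad_table"] = dyads
    out["overlap_fraction"] = fraction
    areas = {
        bat: S.isopleth(ud, config.isopleth_level)[1] for bat, ud in uds.items()
    }
    out["foraging_range_ha"] = areas
    out["congruence"] = social_foraging_congruence(social, graph)
    return out


def _colony_uds_across_years(
    colonies: dict[str, Colony], config: PipelineConfig
) -> dict:
    """Colony-level roosting (roost-day-weighted) and foraging (pooled,
    unweighted) kernel UDs on grids shared across years."""
    roost_pts, roost_w, forage_pts = {}, {}, {}
    for year, colony in colonies.items():
        days = colony.relocations.groupby("roost_id").size()
        coords = colony.roosts.set_index("roost_id").loc[days.index, ["x_m", "y_m"]]
        roost_pts[year] = coords.to_numpy(dtype=float)
        roost_w[year] = days.to_numpy(dtype=float)
        forage_pts[year] = colony.fixes[["x_m", "y_m"]].to_numpy(dtype=float)

    out: dict = {"roosting": {}, "foraging": {}}
    all_roost = np.vstack(list(roost_pts.values()))
    bw = max(
        (S.href_weighted(roost_pts[y], roost_w[y]) for y in colonies), default=0.0
    )
    spec_r = S.GridSpec.from_points(
        all_roost, config.grid_cell_m, buffer_m=max(4.0 * bw, 10 * config.grid_cell_m)
    )
    all_forage = np.vstack(list(forage_pts.values()))
    bw_f = max(
        (S.href_weighted(forage_pts[y], np.ones(len(forage_pts[y]))) for y in colonies),
        default=0.0,
    )
    spec_f = S.GridSpec.from_points(
        all_forage, config.grid_cell_m, buffer_m=max(4.0 * bw_f, 10 * config.grid_cell_m)
    )
    for year in colonies:
        ud_r = S.weighted_kernel_ud(roost_pts[year], roost_w[year], spec_r)
        ud_f = S.weighted_kernel_ud(forage_pts[year], None, spec_f)
        out["roosting"][year] = {
            "ud": ud_r,
            "area_ha": S.isopleth(ud_r, config.isopleth_level)[1],
            "centroid": S.ud_centroid(roost_pts[year], roost_w[year]),
        }
        out["foraging"][year] = {
            "ud": ud_f,
            "area_ha": S.isopleth(ud_f, config.isopleth_level)[1],
        }
    years = sorted(colonies)
    out["pairwise"] = {}
    for i in range(len(years) - 1):
        a, b = years[i], years[i + 1]
        out["pairwise"][f"{a}->{b}"] = {
            "ba_roosting": S.bhattacharyya_affinity(
                out["roosting"][a]["ud"], out["roosting"][b]["ud"]
            ),
            "ba_foraging": S.bhattacharyya_affinity(
                out["foraging"][a]["ud"], out["foraging"][b]["ud"]
            ),
            "centroid_shift_m": S.centroid_shift(
                out["roosting"][a]["centroid"], out["roosting"][b]["centroid"]
            ),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full year-stratified analysis; optionally write a report tree."""
    config.validate()
    colonies: dict[str, Colony] = {}
    for year, cc in config.years.items():
        colonies[year] = generate_colony(cc)
    for year, path in config.input_dirs.items():
        colonies[year] = read_colony_csvs(path)

    report: dict = {"years": {}, "config": config}
    for year in sorted(colonies):
        report["years"][year] = analyze_year(colonies[year], config, year)
    report["colony_space_use"] = _colony_uds_across_years(colonies, config)
    report["colonies"] = colonies
    if config.outdir:
        write_report(report, config)
    return report


def _null_rows(results) -> list[dict]:
    return [r.as_row() for r in results]


def write_report(report: dict, config: PipelineConfig) -> None:
    """Persist tables, networks and rasters under ``config.outdir``."""
    from .networks import write_graphml

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "settings": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "years"
        },
        "years": sorted(report["years"]),
    }
    metric_rows, null_rows, summary_rows = [], [], []
    for year, res in report["years"].items():
        ydir = out / year
        ydir.mkdir(exist_ok=True)
        metric_rows.append(res["roost_report"].as_row())
        metric_rows.append(res["social_report"].as_row())
        for r in res["roost_nulls"]:
            null_rows.append({"year": year, "network": "roost", **r.as_row()})
        for r in res["social_nulls"]:
            null_rows.append({"year": year, "network": "social", **r.as_row()})
        summary_rows.append({"year": year, **res["summaries"].as_row()})
        res["removal_curve"].as_frame().to_csv(ydir / "removal_curve.csv", index=False)
        write_graphml(res["bipartite"].graph, ydir / "bipartite.graphml")
        write_graphml(res["social"], ydir / "social.graphml")
        write_graphml(res["roost_projection"], ydir / "roost_projection.graphml")
        if "dyad_table" in res:
            res["dyad_table"].to_csv(ydir / "overlap_dyads.csv", index=False)
        glm = res["glm"]
        with open(ydir / "glm.json", "w") as fh:
            json.dump(
                {
                    "beta": glm.beta,
                    "ci_95": list(glm.ci_95),
                    "intercept": glm.intercept,
                    "D2": glm.D2,
                    "adj_D2": glm.adj_D2,
                    "n": glm.n,
                    **glm.meta,
                },
                fh,
                indent=1,
            )
    pd.DataFrame(metric_rows).to_csv(out / "network_metrics.csv", index=False)
    pd.DataFrame(null_rows).to_csv(out / "null_tests.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "summaries.csv", index=False)
    space = report["colony_space_use"]
    space_json = {
        "roosting": {
            y: {"area_ha": v["area_ha"], "centroid": list(v["centroid"])}
            for y, v in space["roosting"].items()
        },
        "foraging": {y: {"area_ha": v["area_ha"]} for y, v in space["foraging"].items()},
        "pairwise": space["pairwise"],
    }
    with open(out / "colony_space_use.json", "w") as fh:
        json.dump(space_json, fh, indent=1)
    for y, v in space["roosting"].items():
        S.write_asc(v["ud"], out / y / "roosting_ud.asc")
        with open(out / y / "roosting_isopleth.geojson", "w") as fh:
            json.dump(S.isopleth_geojson(v["ud"], config.isopleth_level), fh)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
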