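"""End-to-end pipeline: filter -> prevalence -> networks -> metrics -> comparisons.

Produces a reproducible report bundle: cohort characteristics, subgroup
prevalence-difference tables, network structure summaries, top-PageRank tables,
abundant-connection lists, and a JSON manifest carrying the configuration,
seeds and filter log. The pipeline is a pure function of (input, config, seed).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .emr_io import Cohort, write_cohort, write_filter_log, write_network
from .filters import comorbidity_universe, filter_cohort, stratify
from .metrics import abundant_connections, pagerank_importance, summarize_network
from .network import build_pcn
from .prevalence import (
    age_profiles,
    cluster_age_profiles,
    compare_subgroups,
    mean_comorbidity_trend,
    prevalence_with_ci,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    min_codes: int = 2
    min_prevalence: float = 0.02
    subgroup_axes: tuple[str, ...] = ("sex", "disease_type")
    rare_filter_per_subgroup: bool = False
    alpha: float = 0.05
    d_threshold: float = 0.1
    enrichment_fold: float = 1.5
    abundant_threshold: float = 0.05
    include_td_nodes: bool = True
    kmeans_k: Optional[int] = None
    seed: int = 0
    top_k_pagerank: int = 5

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["subgroup_axes"] = list(self.subgroup_axes)
        return d


def _quantiles(values) -> dict:
    arr = np.asarray(list(values), dtype=float)
    # linear-interpolation quantiles: the convention behind median (IQR) tables
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
    }


def _characteristics(cohort: Cohort, universe: Sequence[str],
                     strata: dict[str, dict[str, Cohort]]) -> dict:
    uni = set(universe)

    def block(c: Cohort) -> dict:
        ages = [r.age for r in c.records]
        ncom = [len(r.codes & uni) for r in c.records]
        return {
            "n": len(c.records),
            "age": _quantiles(ages),
            "comorbidities": _quantiles(ncom),
        }

    out = {"overall": block(cohort)}
    for axis, groups in strata.items():
        out[axis] = {label: block(c) for label, c in groups.items() if c.records}
        labels = [l for l, c in groups.items() if c.records]
        if axis in ("sex", "disease_type") and len(labels) == 2:
            a, b = (groups[l] for l in labels)
            x = [len(r.codes & uni) for r in a.records]
            y = [len(r.codes & uni) for r in b.records]
            if x and y:
                # Mann-Whitney U backs the median-comorbidity contrast: a
                # nonparametric choice consistent with median/IQR reporting.
                u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                out[axis]["comorbidity_count_test"] = {
                    "test": "mann-whitney-u", "U": float(u), "p": float(p),
                    "groups": labels,
                }
    return out


def run_pipeline(cohort: Cohort, cfg: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis and write the report bundle under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "filter"
    try:
        filtered = filter_cohort(
            cohort, cfg.min_codes, cfg.min_prevalence,
            subgroup_axes=cfg.subgroup_axes if cfg.rare_filter_per_subgroup else (),
        )
        write_cohort(filtered, out / "filtered.csv")
        write_filter_log(filtered, out / "filter_log.json")
        universe = comorbidity_universe(filtered)
        strata = {axis: stratify(filtered, axis) for axis in cfg.subgroup_axes}

        stage = "characteristics"
        characteristics = _characteristics(filtered, universe, strata)
        (out / "table1_characteristics.json").write_text(
            json.dumps(characteristics, indent=2))

        stage = "prevalence"
        N = len(filtered.records)
        counts = filtered.prevalence_counts()
        prev_rows = []
        for code in universe:
            est = prevalence_with_ci(counts.get(code, 0), N, code=code)
            prev_rows.append({
                "code": code, "n": est.n, "N": est.N,
                "prevalence": est.prevalence,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
        prev_df = pd.DataFrame(prev_rows)
        prev_df.to_csv(out / "prevalence.csv", index=False)

        diff_tables = {}
        for axis in cfg.subgroup_axes:
            groups = {l: c for l, c in strata[axis].items() if c.records}
            labels = sorted(groups)
            if len(labels) != 2:
                continue
            a, b = labels
            diffs = compare_subgroups(groups[a], groups[b], universe,
                                      cfg.d_threshold, cfg.enrichment_fold,
                                      cfg.alpha)
            rows = [{
                "code": d.code, f"p_{a}": d.p_a, f"p_{b}": d.p_b,
                "absolute_difference": d.absolute_difference,
                "relative_difference": d.relative_difference,
                "z": d.z, "p_value": d.p_value,
                "classification": d.classification.value,
            } for d in diffs]
            diff_tables[axis] = rows
            pd.DataFrame(rows).to_csv(out / f"table2_diff_{axis}.csv", index=False)

        stage = "age_profiles"
        profiles = age_profiles(filtered, universe)
        means, trend_rho, trend_p = mean_comorbidity_trend(filtered, universe)
        profiles, chosen_k, inertias = cluster_age_profiles(
            profiles, k=cfg.kmeans_k, seed=cfg.seed)
        pd.DataFrame([{
            "code": p.code,
            **{f"prev_{b}": v for b, v in zip(p.bins, p.prevalence)},
            "spearman_rho": p.spearman_rho, "spearman_p": p.spearman_p,
            "cluster": p.cluster_id,
        } for p in profiles]).to_csv(out / "age_profiles.csv", index=False)

        stage = "networks"
        nets = {"all": build_pcn(filtered, universe, cfg.include_td_nodes,
                                 cfg.alpha, label="all")}
        for axis in cfg.subgroup_axes:
            for label, sub in strata[axis].items():
                if len(sub.records) >= 3:
                    nets[f"{axis}={label}"] = build_pcn(
                        sub, universe, cfg.include_td_nodes, cfg.alpha,
                        label=f"{axis}={label}")
        net_summaries = {}
        pagerank_rows = []
        for name, net in nets.items():
            if len(net.nodes) >= 2 and net.edges:
                prefix = name.replace("=", "_")
                write_network(net, out / f"net_{prefix}_nodes.csv",
                              out / f"net_{prefix}_edges.csv",
                              out / f"net_{prefix}.graphml")
                s = summarize_network(net)
                net_summaries[name] = {
                    "nodes": s.node_count, "edges": s.edge_count,
                    "density": s.density, "mean_degree": s.mean_degree,
                    "degree_median": s.degree_median,
                    "degree_iqr": list(s.degree_iqr),
                    "neighbor_degree_median": s.neighbor_degree_median,
                    "neighbor_degree_iqr": list(s.neighbor_degree_iqr),
                    "cutoff": net.cutoff,
                    "significant_pairs": net.provenance["significant_pairs"],
                }
                top, _ = pagerank_importance(net, top_k=cfg.top_k_pagerank)
                pagerank_rows += [{"network": name, "rank": i + 1,
                                   "code": c, "pagerank": v}
                                  for i, (c, v) in enumerate(top)]
        (out / "table3_networks.json").write_text(json.dumps(net_summaries, indent=2))
        pd.DataFrame(pagerank_rows).to_csv(out / "pagerank_top.csv", index=False)

        stage = "comparisons"
        comparison_files = []
        for axis in cfg.subgroup_axes:
            names = [n for n in nets if n.startswith(f"{axis}=")]
            if len(names) == 2:
                comp = abundant_connections(nets[names[0]], nets[names[1]],
                                            cfg.abundant_threshold)
                rows = [{
                    "code_a": e.code_a, "code_b": e.code_b,
                    f"cosine_{names[0].split('=')[1]}": e.cosine_in_a,
                    f"cosine_{names[1].split('=')[1]}": e.cosine_in_b,
                    "status": e.status.value, "mode": e.mode.value,
                } for e in comp]
                fname = f"abundant_{axis}.csv"
                pd.DataFrame(rows).to_csv(out / fname, index=False)
                comparison_files.append(fname)
    except Exception as err:  # preserve partial outputs, name the stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": cfg.to_dict(),
        "filter_log": [{"filter": n, "before": b, "after": a}
                       for n, b, a in filtered.filter_log],
        "n_records": len(filtered.records),
        "n_comorbidities": len(universe),
        "age_trend": {"mean_per_bin": [None if np.isnan(m) else float(m)
                                       for m in means],
                      "spearman_rho": trend_rho, "spearman_p": trend_p},
        "kmeans": {"k": chosen_k, "inertia": [float(x) for x in inertias]},
        "networks": net_summaries,
        "comparisons": comparison_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
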