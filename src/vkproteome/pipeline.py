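"""End-to-end orchestration: simulate/load -> normalize -> analyses -> tables.

A single YAML (or dict) config drives a full run:

.. code-block:: yaml

    seed: 17
    simulate: {}                 # SimConfig overrides; omit to read inputs
    # inputs:
    #   subjects: subjects.tsv
    #   abundance: abundance.tsv
    #   normalized: false
    #   subject_column_map: {pivka2_ugL: PIVKA2}   # optional SD1-style maps
    analysis: {q_primary: 0.10, q_relaxed: 0.20, min_children: 50}
    cohort_table:
      covariates: {age_y: normal, triglyceride_mmolL: skewed, sex: categorical}
    network: {min_pairs_per_experiment: 3, eps: 0.01, heatmap: false}

Outputs written to the run directory: ``table1.tsv`` (cohort comparison),
``table2.tsv`` (PIVKA-II association), ``table3.tsv`` (group difference),
``rmatrix.tsv`` (averaged correlation matrix, display-thresholded) and
``manifest.json`` (config snapshot, input checksums, seed, package version,
per-stage row counts and timings, aggregated warnings). Given fixed inputs
and seed, the four tables are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import AnalysisConfig, AssociationScan, \
    GroupDifferenceScan, build_cohort_table
from .io import CohortDataset, read_cohort, write_cohort, \
    write_correlation_matrix, write_results_table
from .network import averaged_correlation, display_threshold, plot_heatmap, \
    select_network_proteins
from .preprocess import dichotomize_vk, log2_median_normalize
from .simulate import BlockConfig, PivkaTarget, SimConfig, generate_cohort

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config_from_dict(d: dict, seed: int | None) -> SimConfig:
    d = dict(d or {})
    if "pivka_target" in d:
        d["pivka_target"] = PivkaTarget(**d["pivka_target"])
    if "correlated_block" in d:
        d["correlated_block"] = BlockConfig(**d["correlated_block"])
    if "driver_slopes" in d:
        d["driver_slopes"] = tuple(d["driver_slopes"])
    if seed is not None:
        d.setdefault("seed", seed)
    return SimConfig(**d)


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def run_full_analysis(config, out_dir) -> Path:
    """Run the whole analysis; returns the output directory.

    ``config`` is a YAML path or a dict (see module docstring). Any stage
    failure raises, with the stage named in the log.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    manifest: dict = {"package": "vkproteome", "version": __version__,
                      "seed": seed, "config": cfg, "inputs": {},
                      "stages": [], "warnings": []}

    def stage(name):
        t0 = time.perf_counter()

        def done(rows):
            manifest["stages"].append(
                {"stage": name, "rows": int(rows),
                 "seconds": round(time.perf_counter() - t0, 3)})
        return done

    # ---- load or simulate ---------------------------------------------------
    done = stage("load")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        subj_path, abund_path = Path(inputs["subjects"]), Path(inputs["abundance"])
        dataset = read_cohort(
            subj_path, abund_path,
            normalized=bool(inputs.get("normalized", False)),
            subject_column_map=inputs.get("subject_column_map"),
            abundance_column_map=inputs.get("abundance_column_map"))
        manifest["inputs"] = {str(subj_path): _sha256(subj_path),
                              str(abund_path): _sha256(abund_path)}
        truth = None
    else:
        sim_config = _sim_config_from_dict(cfg.get("simulate", {}), seed)
        dataset, truth = generate_cohort(sim_config)
        manifest["inputs"] = {"simulated": dataclasses.asdict(sim_config)}
        write_cohort(dataset, out / "subjects.tsv", out / "abundance.tsv")
    done(len(dataset.observations))

    # ---- normalize ----------------------------------------------------------
    if not dataset.normalized:
        done = stage("normalize")
        dataset, report = log2_median_normalize(dataset)
        done(report.n_observations)

    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    subjects = dichotomize_vk(dataset.subjects, analysis.vkd_cutoff_ugL)

    # ---- table 1: cohort comparison ----------------------------------------
    done = stage("cohort_table")
    covariates = (cfg.get("cohort_table", {}) or {}).get("covariates") or \
        {"pivka2_ugL": "skewed"}
    table1 = build_cohort_table(subjects, covariates, analysis)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False,
                  float_format="%.6g")
    done(len(table1))

    # ---- table 2: association scan ------------------------------------------
    done = stage("associate")
    assoc = AssociationScan(dataset, analysis).fit()
    write_results_table(assoc.results, out / "table2.tsv", "association")
    manifest["warnings"] += [f"association: skipped {gi}: {why}"
                             for gi, why in assoc.skipped]
    done(len(assoc.results))

    # ---- table 3: group difference scan --------------------------------------
    done = stage("diffabund")
    group = GroupDifferenceScan(dataset, analysis,
                                subjects_with_status=subjects).fit()
    write_results_table(group.results, out / "table3.tsv", "group_diff")
    manifest["warnings"] += [f"group_diff: skipped {gi}: {why}"
                             for gi, why in group.skipped]
    done(len(group.results))

    # ---- correlation network -------------------------------------------------
    done = stage("correlate")
    net_cfg = cfg.get("network", {}) or {}
    selected = select_network_proteins(assoc.results, group.results,
                                       analysis.q_relaxed)
    if len(selected) >= 2:
        matrix = averaged_correlation(
            dataset, selected,
            min_pairs_per_experiment=int(net_cfg.get("min_pairs_per_experiment",
                                                     3)))
        shown = display_threshold(matrix, eps=float(net_cfg.get("eps", 0.01)))
        write_correlation_matrix(shown, out / "rmatrix.tsv")
        if net_cfg.get("heatmap"):
            plot_heatmap(matrix, out / "rmatrix.png",
                         eps=float(net_cfg.get("eps", 0.01)))
    else:
        # a single selected protein has no pairwise structure; emit the
        # trivial matrix so downstream consumers still find the file
        pd.DataFrame([[1.0]], index=selected, columns=selected).to_csv(
            out / "rmatrix.tsv", sep="\t")
        manifest["warnings"].append(
            "network: only one protein passed q < "
            f"{analysis.q_relaxed}; correlation matrix is trivial")
    done(len(selected))

    manifest["discoveries"] = {
        "association": {str(k): v["count"]
                        for k, v in assoc.threshold_report().items()},
        "group_diff": {str(k): v["count"]
                       for k, v in group.threshold_report().items()},
        "network_proteins": len(selected),
    }
    if truth is not None:
        manifest["simulation_truth"] = {
            "n_drivers": int(truth.protein_table["is_driver"].sum()),
            "driver_gis": list(truth.drivers["gi_accession"]),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
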