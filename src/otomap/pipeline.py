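"""End-to-end orchestration: ingest → geometry → tuning → development →
clustering → machine-readable report.

The run config is a single YAML mapping. Every analysis knob whose value
is genuinely a choice (thresholds, bin widths, weighting modes, iteration
counts) lives here with documented defaults; stages whose inputs are
missing are skipped with a log entry, and the report is marked incomplete.
All outputs are pure functions of their declared inputs and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import run_null_model
from .core import DegeneratePolarityError
from .development import (
    all_afferent_fractions,
    divergence_counts,
    myelination_position_summary,
    pathway_composition,
    ribbon_count_by_class,
)
from .hair_cells import MaturityThresholds, hair_cell_table, polarity_vector
from .io import (
    axis_map_from_config,
    load_config,
    read_cells_csv,
    read_cilia_csv,
    read_connectivity_csv,
    read_skeleton_swc,
)
from .tuning import (
    TuningPropagator,
    convergence_divergence,
    position_correlation,
    tuning_similarity_curve,
)

log = logging.getLogger("otomap")

CENTRAL_POPULATIONS = ("mauthner", "commissural_escape", "svn", "tangential", "vs",
                       "vs_med", "vs_vent")


def _config_hash(cfg: dict) -> str:
    # hash the analysis parameters, not where outputs are written
    cfg = {k: v for k, v in cfg.items() if k != "run_dir"}
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config, run_dir=None) -> dict:
    """Run all stages whose inputs exist; return (and write) the report.

    ``config`` is a path to a YAML file or an already-loaded mapping with
    keys ``inputs`` (paths to cells/cilia/connectivity/skeletons),
    ``thresholds``, ``tuning``, ``development``, ``clustering``, ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    t0 = time.time()
    inputs = config.get("inputs", {})
    base = Path(config.get("base_dir", "."))
    run_dir = Path(run_dir or config.get("run_dir", "otomap_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "otomap_version": __version__,
        },
        "stages": {},
        "outputs": {},
        "headline": {},
        "incomplete": False,
    }

    def _path(key):
        p = inputs.get(key)
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    def skip(stage, why):
        log.info("skipping %s: %s", stage, why)
        report["stages"][stage] = {"status": "skipped", "reason": why}
        report["incomplete"] = True

    # ---- ingest -----------------------------------------------------------
    cells_path, cilia_path, conn_path = map(_path, ("cells", "cilia", "connectivity"))
    cells_meta = read_cells_csv(cells_path) if cells_path and cells_path.exists() else None
    conn = read_connectivity_csv(conn_path) if conn_path and conn_path.exists() else None
    hair_cells = None
    if cilia_path and cilia_path.exists():
        ribbon_counts = None
        if conn is not None:
            ribbon_counts = (
                conn.aggregated.query("kind == 'ribbon'")
                .groupby("pre_id")["count"].sum().to_dict()
            )
        hair_cells = read_cilia_csv(cilia_path, ribbon_counts=ribbon_counts)
    report["stages"]["ingest"] = {
        "status": "ok",
        "n_cells_meta": 0 if cells_meta is None else len(cells_meta),
        "n_hair_cells": 0 if hair_cells is None else len(hair_cells),
        "n_contacts": 0 if conn is None else conn.total_count,
    }

    # ---- hair-cell geometry ----------------------------------------------
    hc_table = None
    if hair_cells is None:
        skip("geometry", "cilia.csv missing")
    else:
        tcfg = config.get("thresholds", {})
        thresholds = MaturityThresholds(
            kino_min_established=tcfg.get("kino_min_established", 4.8),
            stereo_min_striolar=tcfg.get("stereo_min_striolar", 4.8),
            kino_immature_max=tcfg.get("kino_immature_max", 5.0),
            ks_ratio_striolar_max=tcfg.get("ks_ratio_striolar_max", 1.7),
        )
        hc_table = hair_cell_table(hair_cells, thresholds=thresholds)
        out = run_dir / "hair_cells.csv"
        hc_table.to_csv(out, index=False)
        report["outputs"]["hair_cells"] = str(out)
        report["stages"]["geometry"] = {
            "status": "ok",
            "n_degenerate": int(hc_table["degenerate"].sum()),
            "class_counts": hc_table["maturity"].value_counts().to_dict(),
        }

    # ---- tuning -----------------------------------------------------------
    propagator = None
    if hair_cells is None or conn is None:
        skip("tuning", "needs cilia.csv and connectivity.csv")
    else:
        tun = config.get("tuning", {})
        hc_vectors = {}
        for cid, hc in hair_cells.items():
            try:
                hc_vectors[cid] = polarity_vector(hc)
            except DegeneratePolarityError:
                pass
        propagator = TuningPropagator(
            central_weighting=tun.get("weighting", "uniform")
        ).fit(conn, hc_vectors)
        aff_table = propagator.afferent_table()
        aff_out = run_dir / "afferent_tuning.csv"
        aff_table.to_csv(aff_out, index=False)
        report["outputs"]["afferent_tuning"] = str(aff_out)

        central_table = None
        if cells_meta is not None:
            central_ids = cells_meta.loc[
                cells_meta["population"].isin(CENTRAL_POPULATIONS), "cell_id"
            ]
            central_table = propagator.central_table(central_ids)
            cen_out = run_dir / "central_tuning.csv"
            central_table.to_csv(cen_out, index=False)
            report["outputs"]["central_tuning"] = str(cen_out)

        # similarity curve over the requested LPR-side subset of hair cells
        subset = tun.get("subset", "medial")
        sub = hc_table[~hc_table["degenerate"]]
        if subset in ("medial", "lateral"):
            sub = sub[sub["lpr_side"] == subset]
        curve = None
        if len(sub) >= 2:
            curve = tuning_similarity_curve(
                sub[["ml", "rc", "dv"]].to_numpy(),
                sub["tuning_angle"].to_numpy(),
                bin_width=float(tun.get("bin_width", 10.0)),
            )
            curve_out = run_dir / "similarity_curve.csv"
            curve.to_csv(curve_out, index=False)
            report["outputs"]["similarity_curve"] = str(curve_out)

        corr = {}
        if cells_meta is not None:
            hc_pos = {
                r["cell_id"]: np.array([r["ml"], r["rc"], r["dv"]])
                for _, r in hc_table.iterrows()
            }
            aff_pos = {
                r["cell_id"]: np.array([r["ml"], r["rc"], r["dv"]])
                for _, r in cells_meta[cells_meta["population"] == "afferent"].iterrows()
            }
            try:
                r, p, n = position_correlation(
                    conn, hc_pos, aff_pos,
                    axis=tun.get("correlation_axis", "rc"),
                    weighting=tun.get("correlation_weighting", "per_pair"),
                )
                corr = {"axis": tun.get("correlation_axis", "rc"), "r": r, "p": p, "n": n}
                (run_dir / "correlations.json").write_text(json.dumps(corr, indent=2))
                report["outputs"]["correlations"] = str(run_dir / "correlations.json")
            except Exception as e:  # degenerate geometry: report, don't fail the run
                corr = {"error": str(e)}
        cd = convergence_divergence(conn)
        report["headline"].update(cd)
        report["headline"]["position_correlation"] = corr
        report["stages"]["tuning"] = {
            "status": "ok",
            "n_afferents_tuned": len(aff_table),
            "n_degenerate_afferents": len(propagator.degenerate_),
        }

    # ---- development ------------------------------------------------------
    if conn is None or hc_table is None or cells_meta is None:
        skip("development", "needs connectivity.csv, cilia.csv and cells.csv")
    else:
        dev = config.get("development", {})
        basis = dev.get("basis", "ribbon_weighted")
        hc_classes = dict(zip(hc_table["cell_id"], hc_table["maturity"]))
        fractions = all_afferent_fractions(conn, hc_classes, basis=basis)
        comp_rows = [
            {"cell_id": k, "striolar": f.striolar, "extrastriolar": f.extrastriolar,
             "immature": f.immature, "basis": f.basis}
            for k, f in fractions.items()
        ]
        comp_out = run_dir / "afferent_composition.csv"
        pd.DataFrame(comp_rows).to_csv(comp_out, index=False)
        report["outputs"]["afferent_composition"] = str(comp_out)

        myelin = dict(
            zip(cells_meta["cell_id"], cells_meta["myelinated"])
        )
        pop_of = dict(zip(cells_meta["cell_id"], cells_meta["population"]))
        pops = {}
        for pop in CENTRAL_POPULATIONS:
            ids = cells_meta.loc[cells_meta["population"] == pop, "cell_id"].tolist()
            if ids:
                pops[pop] = ids
        if dev.get("pool_escape", True):
            esc = pops.pop("mauthner", []) + pops.pop("commissural_escape", [])
            if esc:
                pops["escape"] = esc
        path_rows = []
        for pop, ids in pops.items():
            try:
                pc = pathway_composition(pop, ids, conn, fractions, myelin)
                path_rows.append(vars(pc))
            except Exception as e:
                log.info("pathway %s: %s", pop, e)
        path_out = run_dir / "pathway_composition.csv"
        pd.DataFrame(path_rows).to_csv(path_out, index=False)
        report["outputs"]["pathway_composition"] = str(path_out)

        aff_meta = cells_meta[cells_meta["population"] == "afferent"]
        stats_report = {
            "myelination_position": myelination_position_summary(aff_meta),
            "ribbon_by_class": ribbon_count_by_class(hc_table),
        }
        try:
            per_aff, crosstab = divergence_counts(conn, pop_of, myelin)
            div_out = run_dir / "divergence.csv"
            per_aff.to_csv(div_out, index=False)
            report["outputs"]["divergence"] = str(div_out)
            if crosstab is not None:
                stats_report["divergence_crosstab"] = {
                    str(k): v for k, v in crosstab.to_dict(orient="index").items()
                }
        except Exception as e:
            log.info("divergence: %s", e)
        stats_out = run_dir / "stats_report.json"
        stats_out.write_text(json.dumps(stats_report, indent=2, default=float))
        report["outputs"]["stats_report"] = str(stats_out)
        report["headline"]["myelinated_fraction"] = float(aff_meta["myelinated"].mean())
        report["headline"]["pathway_composition"] = path_rows
        report["stages"]["development"] = {"status": "ok", "n_pathways": len(path_rows)}

    # ---- clustering -------------------------------------------------------
    skel_dir = _path("skeletons")
    syn_path = _path("synapse_locations")
    if not (skel_dir and skel_dir.exists() and syn_path and syn_path.exists()):
        skip("clustering", "needs skeleton folder and synapse_locations.csv")
    else:
        clu = config.get("clustering", {})
        syn_df = pd.read_csv(syn_path)
        axis_map = axis_map_from_config(config)
        neurons = []
        for swc in sorted(skel_dir.glob("*.swc")):
            skel = read_skeleton_swc(swc, axis_map=axis_map)
            sub = syn_df[syn_df["neuron"] == skel.label]
            neurons.append((skel, sub[["ml", "rc", "dv"]].to_numpy(dtype=float)))
        aff_path = _path("afferent_nodes")
        afferent_xyz = (
            pd.read_csv(aff_path)[["ml", "rc", "dv"]].to_numpy(dtype=float)
            if aff_path and aff_path.exists()
            else None
        )
        result = run_null_model(
            neurons,
            afferent_xyz,
            model=clu.get("model", "unweighted"),
            iterations=int(clu.get("iterations", 100_000)),
            seed=int(clu.get("seed", seed)),
            spacing=float(clu.get("spacing", 1.0)),
        )
        clu_out = run_dir / "clustering_result.json"
        clu_out.write_text(json.dumps(result.to_dict(), indent=2, default=float))
        report["outputs"]["clustering"] = str(clu_out)
        report["headline"]["clustering"] = {
            "model": result.model,
            "observed_um": result.observed,
            "ci": [result.ci_low, result.ci_high],
            "empirical_p": result.empirical_p,
        }
        report["stages"]["clustering"] = {
            "status": "ok",
            "n_neurons": len(result.per_neuron),
            "n_excluded": len(result.excluded),
        }

    report["elapsed_s"] = round(time.time() - t0, 3)
    (run_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
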