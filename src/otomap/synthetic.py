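"""Synthetic maculae, ganglia, central populations, and test arbors.

Every analysis stage in this package is testable without any download:
the generators here emit data with the same structure as the reconstructed
utricular circuit — a 2-D macula sheet with a smoothly rotating polarity
field and a lateral line of polarity reversal (LPR), a radial
center→periphery maturity gradient in ciliary lengths and ribbon counts,
a ganglion with rostrocaudal topography and mediolateral birth-order
layering (myelinated afferents lateral), convergent/divergent connectivity
with integer ribbon weights, class-biased central populations, and
branched skeletons with plantable synapse clustering — together with
ground-truth tables sufficient to score every inference stage.

Default scale mirrors the reconstructed circuit (91 hair cells, 105
afferents, ~45 central neurons, convergence 3.0 ± 1.5); all counts are
configurable. Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .clustering import resample_skeleton
from .core import ConnectivityTable, HairCell, Skeleton, ValidationError
from .hair_cells import MaturityClassifier

CLASSES = ("striolar", "extrastriolar", "immature")


def _default_central_populations() -> dict:
    # striolar_target: planted contact-weighted striolar input fraction.
    # side restricts eligible afferents by the LPR side they innervate:
    # the ipsilateral Mauthner draws on medial-side afferents, the
    # commissural escape neurons on lateral-side afferents.
    return {
        "mauthner": {"n": 1, "events_mean": 45.0, "striolar_target": 0.65, "side": "medial"},
        "commissural_escape": {"n": 4, "events_mean": 6.0, "striolar_target": 0.65, "side": "lateral"},
        "svn": {"n": 12, "events_mean": 8.0, "striolar_target": 0.30, "side": None},
        "tangential": {"n": 11, "events_mean": 8.0, "striolar_target": 0.30, "side": None},
        "vs": {"n": 19, "events_mean": 16.0, "striolar_target": 0.30, "side": None},
    }


@dataclass
class MaculaConfig:
    """Generative parameters of the synthetic utricular macula (µm, deg)."""

    n_hair_cells: int = 91
    extent_rc: float = 60.0
    extent_ml: float = 45.0
    lpr_ml: float = 34.0
    lpr_tilt: float = 0.0  # ml drift of the LPR per unit normalized rc (curved option)
    sweep_deg: float = 140.0  # rostrocaudal rotation of the polarity field
    noise_kappa: float | None = 20.0  # von Mises concentration; None = no noise
    bundle_length_um: float = 1.6  # horizontal magnitude of the polarity vector
    dv_tilt_frac: float = 0.3  # dv component as a fraction of the horizontal magnitude
    n_stereocilia: int = 6  # bases per cell (kept even so the centroid is exact)
    # per-class ciliary length distributions: (mean, sd) in µm, consistent
    # with the default MaturityThresholds so generated classes are recoverable
    striolar_stereo: tuple = (6.0, 0.4)
    striolar_ratio: tuple = (1.4, 0.1)
    extrastriolar_stereo: tuple = (3.4, 0.5)
    extrastriolar_ratio: tuple = (2.4, 0.3)
    immature_kino: tuple = (3.4, 0.6)
    immature_stereo: tuple = (2.4, 0.5)
    # Poisson ribbon-count mean: decreasing from macula center to periphery
    ribbon_lambda_center: float = 14.0
    ribbon_lambda_edge: float = 3.0
    ribbon_radial_scale: float = 0.5
    striola_width: float = 0.57  # radial scale of the striolar class zone
    immature_gain: float = 0.30  # peripheral immature-class probability gain
    seed: int = 0


@dataclass
class CircuitConfig:
    """Generative parameters of the synthetic ganglion and central circuit."""

    n_afferents: int = 105
    convergence_mean: float = 3.0
    convergence_sd: float = 1.5
    neighborhood_um: float = 10.0  # spatial scale of afferent input sampling
    rc_jitter_um: float = 4.0  # ganglion rostrocaudal topography jitter
    soma_ml_base: float = 10.0
    myelin_offset_um: float = 6.0  # lateral shift of early-born (myelinated) somata
    soma_ml_jitter_um: float = 2.5
    soma_dv_jitter_um: float = 2.0
    myelin_base_p: float = 0.05
    myelin_striolar_gain: float = 0.45  # myelination probability gain per unit striolar fraction
    contact_mean: float = 2.0  # mean central contacts per (afferent, neuron) event
    central_populations: dict = field(default_factory=_default_central_populations)
    seed: int = 1


# ---------------------------------------------------------------------------
# macula
# ---------------------------------------------------------------------------


def lpr_position(cfg: MaculaConfig, rc) -> np.ndarray:
    """Generative LPR ml position as a (monotone) function of rc."""
    rc = np.asarray(rc, dtype=float)
    return cfg.lpr_ml + cfg.lpr_tilt * (rc / cfg.extent_rc - 0.5)


def polarity_field(cfg: MaculaConfig, rc, side) -> np.ndarray:
    """Generative tuning angle θ(rc, side) in degrees.

    On the medial side the field rotates smoothly from caudal-leaning to
    rostral-leaning directions with increasing rc while always pointing
    laterally (positive ml component); lateral-side cells point the
    opposite way (reversal across the LPR).
    """
    rc = np.asarray(rc, dtype=float)
    theta = 90.0 + cfg.sweep_deg * (0.5 - rc / cfg.extent_rc)
    theta = np.where(np.asarray(side) == "lateral", theta + 180.0, theta)
    return theta % 360.0


def _radial_coord(cfg: MaculaConfig, ml, rc) -> np.ndarray:
    """Normalized distance from the striola center (on the LPR, mid-rc)."""
    dml = (ml - lpr_position(cfg, rc)) / (cfg.extent_ml / 2.0)
    drc = (rc - cfg.extent_rc / 2.0) / (cfg.extent_rc / 2.0)
    return np.hypot(dml, drc)


def _class_probabilities(cfg: MaculaConfig, r: np.ndarray) -> np.ndarray:
    p_str = np.exp(-((r / cfg.striola_width) ** 2))
    p_imm = cfg.immature_gain * np.minimum(1.0, r) ** 2
    p_ext = np.clip(1.0 - p_str - p_imm, 0.0, None)
    P = np.stack([p_str, p_ext, p_imm], axis=1)
    return P / P.sum(axis=1, keepdims=True)


def _polyline(rng, base: np.ndarray, length: float, n_seg: int = 8) -> np.ndarray:
    """A mostly-dorsal polyline of exactly the given summed length."""
    pts = [base]
    d = np.array([0.0, 0.0, 1.0])
    for _ in range(n_seg):
        d = d + rng.normal(0.0, 0.15, size=3)
        d = d / np.linalg.norm(d)
        pts.append(pts[-1] + d * (length / n_seg))
    return np.asarray(pts)


def _draw_lengths(rng, cls: str, cfg: MaculaConfig) -> tuple[float, float]:
    """(kinocilium, tallest stereocilium) lengths consistent with the class."""
    if cls == "striolar":
        s = np.clip(rng.normal(*cfg.striolar_stereo), 5.05, None)
        k = s * np.clip(rng.normal(*cfg.striolar_ratio), 1.12, 1.65)
    elif cls == "extrastriolar":
        s = np.clip(rng.normal(*cfg.extrastriolar_stereo), 2.0, 4.6)
        k = np.clip(s * np.clip(rng.normal(*cfg.extrastriolar_ratio), 1.8, 3.2), 5.1, None)
    else:  # immature
        k = np.clip(rng.normal(*cfg.immature_kino), 1.5, 4.7)
        s = np.clip(rng.normal(*cfg.immature_stereo), 1.0, 4.6)
    return float(k), float(s)


def generate_macula(cfg: MaculaConfig | None = None):
    """Generate hair cells plus a ground-truth table.

    Returns ``(cells, truth)``: ``cells`` maps cell_id -> HairCell with
    full cilia geometry; ``truth`` records true class, true field angle,
    realized (noisy) angle, LPR side, radial coordinate and the provisional
    ribbon-count draw for every cell.
    """
    cfg = cfg or MaculaConfig()
    if cfg.n_hair_cells < 1:
        raise ValidationError("n_hair_cells must be positive")
    if cfg.n_stereocilia % 2 or cfg.n_stereocilia < 2:
        raise ValidationError("n_stereocilia must be even and >= 2")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_hair_cells
    ml = rng.uniform(0.0, cfg.extent_ml, size=n)
    rc = rng.uniform(0.0, cfg.extent_rc, size=n)
    dv = rng.normal(0.0, 0.5, size=n)  # near-planar epithelium
    side = np.where(ml < lpr_position(cfg, rc), "medial", "lateral")
    theta_true = polarity_field(cfg, rc, side)
    if cfg.noise_kappa is None or np.isinf(cfg.noise_kappa):
        theta = theta_true.copy()
    else:
        theta = (
            theta_true + np.degrees(rng.vonmises(0.0, cfg.noise_kappa, size=n))
        ) % 360.0

    r = _radial_coord(cfg, ml, rc)
    P = _class_probabilities(cfg, r)
    cls_idx = np.array([rng.choice(3, p=P[i]) for i in range(n)])
    classes = np.array(CLASSES)[cls_idx]
    lam = cfg.ribbon_lambda_edge + (
        cfg.ribbon_lambda_center - cfg.ribbon_lambda_edge
    ) * np.exp(-((r / cfg.ribbon_radial_scale) ** 2))
    ribbons = np.maximum(1, rng.poisson(lam))

    # consistency check: drawn class lengths must land in their class
    clf = MaturityClassifier().fit()

    cells: dict[str, HairCell] = {}
    rows = []
    for i in range(n):
        cid = f"hc{i:03d}"
        klen, slen = _draw_lengths(rng, classes[i], cfg)
        if str(clf.predict([[klen, slen]])[0]) != classes[i]:
            raise ValidationError(
                f"infeasible config: class length draw ({klen:.2f}, {slen:.2f}) "
                f"violates thresholds for {classes[i]}"
            )
        base = np.array([ml[i], rc[i], dv[i]])
        a = np.radians(theta[i])
        horiz = np.array([np.sin(a), np.cos(a), 0.0])  # (ml, rc, dv)
        mag = cfg.bundle_length_um
        centroid = base - mag * horiz - np.array(
            [0.0, 0.0, cfg.dv_tilt_frac * mag]
        )
        # symmetric +/- offset pairs keep the centroid exact
        half = rng.normal(0.0, 0.5, size=(cfg.n_stereocilia // 2, 3))
        half[:, 2] *= 0.1
        bases = centroid + np.concatenate([half, -half])
        kino = _polyline(rng, base, klen)
        stereo = _polyline(rng, bases[0], slen)
        cells[cid] = HairCell(
            cell_id=cid,
            kinocilium=kino,
            tallest_stereocilium=stereo,
            stereocilia_bases=bases,
            ribbon_count=int(ribbons[i]),
        )
        rows.append(
            {
                "cell_id": cid,
                "ml": ml[i],
                "rc": rc[i],
                "dv": dv[i],
                "true_side": side[i],
                "true_class": classes[i],
                "true_angle": theta_true[i],
                "realized_angle": theta[i],
                "radial_coord": r[i],
                "kino_length": klen,
                "stereo_length": slen,
                "ribbon_count": int(ribbons[i]),
            }
        )
    return cells, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# circuit
# ---------------------------------------------------------------------------


def _solve_tilt(values: np.ndarray, target: float) -> np.ndarray:
    """Exponential-tilt weights w ∝ exp(γ v) with Σwv/Σw = target."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.ones_like(v)
    target = float(np.clip(target, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)))

    def mean_at(gamma):
        w = np.exp(gamma * (v - v.mean()))
        return float(np.sum(w * v) / np.sum(w)) - target

    span = 200.0 / max(hi - lo, 1e-6)
    gamma = brentq(mean_at, -span, span)
    w = np.exp(gamma * (v - v.mean()))
    return w / w.sum()


def generate_circuit(cells: dict[str, HairCell], truth: pd.DataFrame,
                     cfg: CircuitConfig | None = None):
    """Generate afferents, central neurons, connectivity and ground truth.

    Each afferent draws hair cells from a spatial neighborhood strictly on
    one side of the LPR; ribbon counts per edge are >= 1 and sum, per hair
    cell, to its ribbon_count (the HairCell objects are updated in place
    when a cell's divergence exceeds its provisional draw). Central
    contacts are drawn per-event with exponential-tilt afferent weights so
    the contact-weighted expected class composition of each pathway equals
    its planted target; the exact expectation is recorded in the ground
    truth.

    Returns ``(cells_meta, connectivity, aff_truth, pathway_truth)``.
    """
    cfg = cfg or CircuitConfig()
    rng = np.random.default_rng(cfg.seed)
    truth_in = truth
    truth = truth.set_index("cell_id", drop=False)
    hc_ids = truth["cell_id"].to_numpy()
    pos = truth[["ml", "rc"]].to_numpy(dtype=float)
    side = truth["true_side"].to_numpy()

    # --- afferent -> hair-cell sampling, one LPR side each -----------------
    aff_inputs: dict[str, list[str]] = {}
    aff_side: dict[str, str] = {}
    frac_medial = float(np.mean(side == "medial"))
    for a in range(cfg.n_afferents):
        aid = f"aff{a:03d}"
        s = "medial" if rng.random() < frac_medial else "lateral"
        pool = np.flatnonzero(side == s)
        if pool.size == 0:
            s = "medial" if s == "lateral" else "lateral"
            pool = np.flatnonzero(side == s)
        k = int(np.clip(round(rng.normal(cfg.convergence_mean, cfg.convergence_sd)),
                        1, pool.size))
        anchor = rng.choice(pool)
        d = np.linalg.norm(pos[pool] - pos[anchor], axis=1)
        w = np.exp(-(d**2) / (2.0 * cfg.neighborhood_um**2))
        w /= w.sum()
        chosen = rng.choice(pool, size=k, replace=False, p=w)
        aff_inputs[aid] = [hc_ids[c] for c in chosen]
        aff_side[aid] = s
    # every hair cell must reach at least one afferent
    covered = {h for hs in aff_inputs.values() for h in hs}
    for i, hid in enumerate(hc_ids):
        if hid not in covered:
            same = [a for a in aff_inputs if aff_side[a] == side[i]]
            anchors = np.array(
                [pos[np.flatnonzero(hc_ids == aff_inputs[a][0])[0]] for a in same]
            )
            nearest = same[int(np.argmin(np.linalg.norm(anchors - pos[i], axis=1)))]
            aff_inputs[nearest].append(hid)

    # --- ribbon counts per edge -------------------------------------------
    hc_affs: dict[str, list[str]] = {h: [] for h in hc_ids}
    for aid, hs in aff_inputs.items():
        for h in hs:
            hc_affs[h].append(aid)
    ribbon_rows = []
    for hid, affs in hc_affs.items():
        deg = len(affs)
        total = max(int(truth.loc[hid, "ribbon_count"]), deg)
        extra = rng.multinomial(total - deg, np.full(deg, 1.0 / deg))
        cells[hid].ribbon_count = total
        truth.loc[hid, "ribbon_count"] = total
        hc_pos = cells[hid].apical_position
        for aid, cnt in zip(affs, 1 + extra):
            ribbon_rows.append(
                {
                    "pre_id": hid, "post_id": aid, "count": int(cnt),
                    "kind": "ribbon",
                    "ml": hc_pos[0], "rc": hc_pos[1], "dv": hc_pos[2],
                }
            )
    ribbon_df = pd.DataFrame(ribbon_rows)

    # --- afferent class composition, myelination, soma position -----------
    cls_of = dict(zip(truth["cell_id"], truth["true_class"]))
    aff_rows = []
    for aid in aff_inputs:
        sub = ribbon_df[ribbon_df["post_id"] == aid]
        w = sub["count"].to_numpy(dtype=float)
        F = np.stack(
            [np.array([cls_of[h] == c for c in CLASSES], dtype=float)
             for h in sub["pre_id"]]
        )
        frac = (F * w[:, None]).sum(axis=0) / w.sum()
        p_myel = float(np.clip(cfg.myelin_base_p + cfg.myelin_striolar_gain * frac[0],
                               0.0, 0.95))
        myel = bool(rng.random() < p_myel)
        mean_rc = float(truth.loc[sub["pre_id"], "rc"].mean())
        soma_rc = mean_rc + rng.normal(0.0, cfg.rc_jitter_um)
        soma_ml = (
            cfg.soma_ml_base
            + (cfg.myelin_offset_um if myel else 0.0)
            + rng.normal(0.0, cfg.soma_ml_jitter_um)
        )
        soma_dv = rng.normal(0.0, cfg.soma_dv_jitter_um)
        aff_rows.append(
            {
                "cell_id": aid,
                "side": aff_side[aid],
                "striolar_frac": frac[0],
                "extrastriolar_frac": frac[1],
                "immature_frac": frac[2],
                "myelinated": myel,
                "mean_input_rc": mean_rc,
                "ml": soma_ml, "rc": soma_rc, "dv": soma_dv,
            }
        )
    aff_truth = pd.DataFrame(aff_rows).set_index("cell_id", drop=False)

    # --- central populations ----------------------------------------------
    central_rows = []
    pathway_rows = []
    cell_meta_rows = []
    s_frac = aff_truth["striolar_frac"].to_numpy()
    F_aff = aff_truth[["striolar_frac", "extrastriolar_frac", "immature_frac"]].to_numpy()
    aff_arr = aff_truth["cell_id"].to_numpy()
    for pop, spec_ in cfg.central_populations.items():
        if spec_["side"] is None:
            eligible = np.arange(aff_arr.size)
        else:
            eligible = np.flatnonzero(aff_truth["side"].to_numpy() == spec_["side"])
        if eligible.size == 0:
            raise ValidationError(f"population {pop}: no eligible afferents")
        w = _solve_tilt(s_frac[eligible], spec_["striolar_target"])
        expected = (F_aff[eligible] * w[:, None]).sum(axis=0)
        pathway_rows.append(
            {
                "population": pop,
                "expected_striolar": expected[0],
                "expected_extrastriolar": expected[1],
                "expected_immature": expected[2],
                "planted_target": spec_["striolar_target"],
            }
        )
        for j in range(spec_["n"]):
            nid = f"{pop}{j:02d}"
            n_events = max(2, int(rng.poisson(spec_["events_mean"])))
            events = rng.choice(eligible, size=n_events, p=w)
            counts = pd.Series(events).value_counts()
            for idx, cnt in counts.items():
                central_rows.append(
                    {
                        "pre_id": aff_arr[idx], "post_id": nid, "count": int(cnt),
                        "kind": "central",
                        "ml": np.nan, "rc": np.nan, "dv": np.nan,
                    }
                )
            cell_meta_rows.append(
                {
                    "cell_id": nid, "population": pop,
                    "ml": rng.normal(20.0, 4.0),
                    "rc": rng.normal(30.0, 10.0),
                    "dv": rng.normal(-20.0, 4.0),
                    "myelinated": False,
                }
            )
    pathway_truth = pd.DataFrame(pathway_rows)

    # --- assemble ----------------------------------------------------------
    for hid in hc_ids:
        p = cells[hid].apical_position
        cell_meta_rows.append(
            {"cell_id": hid, "population": "hair_cell",
             "ml": p[0], "rc": p[1], "dv": p[2], "myelinated": False}
        )
    for _, row in aff_truth.iterrows():
        cell_meta_rows.append(
            {"cell_id": row["cell_id"], "population": "afferent",
             "ml": row["ml"], "rc": row["rc"], "dv": row["dv"],
             "myelinated": bool(row["myelinated"])}
        )
    # keep the caller's ground-truth ribbon counts consistent with the
    # realized connectivity (divergence can raise a cell's total)
    truth_in["ribbon_count"] = truth_in["cell_id"].map(truth["ribbon_count"])
    cells_meta = pd.DataFrame(cell_meta_rows)
    connectivity = ConnectivityTable(
        pd.concat([ribbon_df, pd.DataFrame(central_rows)], ignore_index=True)
    )
    return cells_meta, connectivity, aff_truth.reset_index(drop=True), pathway_truth


# ---------------------------------------------------------------------------
# test skeletons
# ---------------------------------------------------------------------------


def _grow_tree(rng, cable_length: float, step: float, branch_prob: float,
               origin: np.ndarray) -> Skeleton:
    xyz = [origin.astype(float)]
    parent = [-1]
    d0 = rng.normal(size=3)
    tips = [(0, d0 / np.linalg.norm(d0))]
    total = 0.0
    while total < cable_length:
        t = int(rng.integers(len(tips)))
        node, d = tips[t]
        d = d + rng.normal(0.0, 0.35, size=3)
        d = d / np.linalg.norm(d)
        xyz.append(xyz[node] + d * step)
        parent.append(node)
        new = len(xyz) - 1
        total += step
        tips[t] = (new, d)
        if rng.random() < branch_prob and total < cable_length:
            d2 = d + rng.normal(0.0, 1.0, size=3)
            tips.append((new, d2 / np.linalg.norm(d2)))
    return Skeleton(np.arange(len(xyz)), np.array(parent), np.asarray(xyz))


def _sample_on_cable(rng, skel: Skeleton, n: int) -> np.ndarray:
    """n points uniform by arc length over the skeleton's cable."""
    child, par = skel.edges
    w = skel.edge_lengths
    e = rng.choice(child.size, size=n, p=w / w.sum())
    frac = rng.random(n)
    return skel.xyz[par[e]] + frac[:, None] * (skel.xyz[child[e]] - skel.xyz[par[e]])


def generate_test_skeletons(
    n_neurons: int = 5,
    cable_length: float = 300.0,
    step: float = 2.0,
    branch_prob: float = 0.12,
    n_synapses: int = 10,
    placement: str = "uniform",
    cluster_scale: float = 3.0,
    n_afferent_points: int = 4,
    spacing: float = 1.0,
    seed: int = 0,
):
    """Random branched arbors with planted synapse placement.

    ``placement='uniform'`` scatters synapses uniformly over the arbor
    nodes of the ``spacing``-regularized skeleton (the same placement law
    as the unweighted null model, so calibration experiments are exact);
    ``'clustered'`` gathers them around randomly chosen afferent-apposition
    points with 3-D Gaussian scatter of the stated scale (µm). Arbors are
    spatially separated so proximity scores do not mix neurons.

    Returns ``(neurons, afferent_xyz)`` with ``neurons`` a list of
    ``(Skeleton, synapse_xyz)`` and ``afferent_xyz`` the pooled afferent
    synapse-node cloud used by the weighted null models.
    """
    if placement not in ("uniform", "clustered"):
        raise ValidationError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    neurons = []
    afferent_pts = []
    for i in range(n_neurons):
        origin = np.array([500.0 * i, 0.0, 0.0])
        skel = _grow_tree(rng, cable_length, step, branch_prob, origin)
        skel.label = f"vn{i:02d}"
        aff = _sample_on_cable(rng, skel, n_afferent_points)
        aff = aff + rng.normal(0.0, 0.5, size=aff.shape)
        afferent_pts.append(aff)
        if placement == "uniform":
            rs = resample_skeleton(skel, spacing)
            syn = rs.xyz[rng.integers(rs.n_nodes, size=n_synapses)]
        else:
            centers = aff[rng.integers(aff.shape[0], size=n_synapses)]
            syn = centers + rng.normal(
                0.0, cluster_scale / np.sqrt(3.0), size=(n_synapses, 3)
            )
        neurons.append((skel, syn))
    return neurons, np.concatenate(afferent_pts, axis=0)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(outdir, macula_cfg: MaculaConfig | None = None,
                    circuit_cfg: CircuitConfig | None = None,
                    skeleton_kwargs: dict | None = None):
    """Generate and write a full input bundle into a directory.

    Emits cells.csv, cilia.csv, connectivity.csv, ground-truth tables, and
    an SWC folder of test arbors with synapse/afferent-node tables, so the
    whole pipeline can run from files alone.
    """
    from pathlib import Path

    from .io import write_cilia_csv, write_connectivity_csv, write_skeleton_swc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mcfg = macula_cfg or MaculaConfig()
    ccfg = circuit_cfg or CircuitConfig()
    cells, truth = generate_macula(mcfg)
    cells_meta, conn, aff_truth, pathway_truth = generate_circuit(cells, truth, ccfg)
    cells_meta.to_csv(outdir / "cells.csv", index=False)
    write_cilia_csv(cells, outdir / "cilia.csv")
    write_connectivity_csv(conn, outdir / "connectivity.csv")
    truth.to_csv(outdir / "ground_truth_hair_cells.csv", index=False)
    aff_truth.to_csv(outdir / "ground_truth_afferents.csv", index=False)
    pathway_truth.to_csv(outdir / "ground_truth_pathways.csv", index=False)

    skw = dict(seed=ccfg.seed)
    skw.update(skeleton_kwargs or {})
    neurons, afferent_xyz = generate_test_skeletons(**skw)
    swc_dir = outdir / "skeletons"
    swc_dir.mkdir(exist_ok=True)
    syn_rows = []
    for skel, syn in neurons:
        write_skeleton_swc(skel, swc_dir / f"{skel.label}.swc")
        for p in syn:
            syn_rows.append({"neuron": skel.label, "ml": p[0], "rc": p[1], "dv": p[2]})
    pd.DataFrame(syn_rows).to_csv(outdir / "synapse_locations.csv", index=False)
    pd.DataFrame(afferent_xyz, columns=["ml", "rc", "dv"]).to_csv(
        outdir / "afferent_nodes.csv", index=False
    )
    config = {
        "macula": dataclasses.asdict(mcfg),
        "circuit": {
            k: v for k, v in dataclasses.asdict(ccfg).items()
        },
    }
    import yaml

    (outdir / "generator_config.yaml").write_text(yaml.safe_dump(config))
    return outdir
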