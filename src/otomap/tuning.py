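"""Synapse-weighted propagation of directional tuning through the circuit.

Each hair cell contributes a horizontal unit polarity vector. An afferent's
anatomically inferred tuning is the resultant of its convergent hair-cell
vectors weighted by ribbon-synapse counts; central neurons inherit tuning
as the (by default unweighted) mean of their afferents' unit vectors. The
resultant length divided by the total weight — the circular coherence —
measures how aligned a neuron's inputs are.

Angle convention: degrees in [0, 360), 0° = rostral (+rc), 90° = lateral
(+ml), counterclockwise in the (rc, ml) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .core import (
    ConnectivityTable,
    MissingInputError,
    UndefinedTuningError,
    ValidationError,
)

HALF_PLANES = {
    "rostral": lambda rc, ml: rc > 0,
    "caudal": lambda rc, ml: rc < 0,
    "ipsilateral": lambda rc, ml: ml > 0,
    "contralateral": lambda rc, ml: ml < 0,
}


def angle_from_components(rc: float, ml: float) -> float:
    """Angle in degrees of an (rc, ml) vector, in [0, 360)."""
    a = float(np.degrees(np.arctan2(ml, rc)) % 360.0)
    return 0.0 if a >= 360.0 else a  # tiny negative atan2 results wrap to 360.


def components_from_angle(angle_deg):
    """(rc, ml) unit components of an angle in degrees."""
    a = np.radians(angle_deg)
    return np.cos(a), np.sin(a)


@dataclass(frozen=True)
class TuningVector:
    """A horizontal-plane tuning direction with its input statistics.

    ``coherence`` = resultant length / total weight, in [0, 1]; it is 1
    exactly when all contributing inputs share one direction.
    """

    unit_rc: float
    unit_ml: float
    coherence: float
    total_weight: float
    horizontal_magnitude: float = np.nan
    dv_component: float = np.nan

    @property
    def angle(self) -> float:
        return angle_from_components(self.unit_rc, self.unit_ml)

    @property
    def unit(self) -> np.ndarray:
        return np.array([self.unit_rc, self.unit_ml])


def _resultant(units: np.ndarray, weights: np.ndarray, who: str) -> TuningVector:
    weights = np.asarray(weights, dtype=float)
    if units.shape[0] == 0:
        raise MissingInputError(f"{who}: no inputs")
    R = (units * weights[:, None]).sum(axis=0)
    total = float(weights.sum())
    norm = float(np.linalg.norm(R))
    if norm < 1e-12 * max(total, 1.0):
        raise UndefinedTuningError(f"{who}: zero resultant vector")
    return TuningVector(
        unit_rc=R[0] / norm,
        unit_ml=R[1] / norm,
        coherence=norm / total,
        total_weight=total,
    )


def circular_mean_deg(angles_deg, weights=None) -> float:
    """Resultant-vector circular mean of angles in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    rc = float(np.sum(w * np.cos(a)))
    ml = float(np.sum(w * np.sin(a)))
    if np.hypot(rc, ml) < 1e-12:
        raise UndefinedTuningError("circular mean undefined: zero resultant")
    return angle_from_components(rc, ml)


def angular_difference_deg(a: float, b: float) -> float:
    """Unsigned circular difference between two angles, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class TuningPropagator(BaseEstimator):
    """Propagate hair-cell polarity vectors to afferents and central neurons.

    ``fit`` consumes a connectivity table plus per-hair-cell unit vectors
    and computes every afferent's ribbon-weighted resultant; ``central``
    then averages afferent vectors onto any downstream neuron. Afferents
    whose resultant vanishes are excluded and listed in ``degenerate_``.

    Parameters
    ----------
    central_weighting : {"uniform", "synapse_count"}
        How central neurons average their afferents: plain mean of unit
        vectors (default) or contact-count-weighted resultant. The two
        modes are never mixed within one fit.
    """

    def __init__(self, central_weighting: str = "uniform"):
        self.central_weighting = central_weighting

    def fit(self, connectivity: ConnectivityTable, hair_cell_vectors: dict[str, TuningVector]):
        """hair_cell_vectors maps hair-cell id -> unit TuningVector."""
        if self.central_weighting not in ("uniform", "synapse_count"):
            raise ValidationError(
                f"unknown central weighting {self.central_weighting!r}"
            )
        self.connectivity_ = connectivity
        self.hair_cell_vectors_ = dict(hair_cell_vectors)
        ribbon = connectivity.aggregated.query("kind == 'ribbon'")
        self.afferent_vectors_: dict[str, TuningVector] = {}
        self.degenerate_: list[str] = []
        for aff_id, grp in ribbon.groupby("post_id"):
            units, weights = [], []
            for _, row in grp.iterrows():
                tv = self.hair_cell_vectors_.get(row["pre_id"])
                if tv is None:
                    continue  # degenerate hair cell: excluded upstream
                units.append([tv.unit_rc, tv.unit_ml])
                weights.append(row["count"])
            if not units:
                self.degenerate_.append(aff_id)
                continue
            try:
                self.afferent_vectors_[aff_id] = _resultant(
                    np.asarray(units), np.asarray(weights), f"afferent {aff_id}"
                )
            except UndefinedTuningError:
                self.degenerate_.append(aff_id)
        return self

    def afferent(self, aff_id: str) -> TuningVector:
        try:
            return self.afferent_vectors_[str(aff_id)]
        except KeyError:
            if str(aff_id) in self.degenerate_:
                raise UndefinedTuningError(
                    f"afferent {aff_id}: zero resultant vector"
                ) from None
            raise MissingInputError(
                f"afferent {aff_id}: no ribbon input with defined tuning"
            ) from None

    def central(self, neuron_id: str) -> TuningVector:
        """Inferred tuning of a central neuron from its afferent inputs."""
        central = self.connectivity_.aggregated.query("kind == 'central'")
        grp = central[central["post_id"] == str(neuron_id)]
        units, weights = [], []
        for _, row in grp.iterrows():
            tv = self.afferent_vectors_.get(row["pre_id"])
            if tv is None:
                continue
            units.append([tv.unit_rc, tv.unit_ml])
            weights.append(
                row["count"] if self.central_weighting == "synapse_count" else 1.0
            )
        return _resultant(np.asarray(units).reshape(-1, 2), np.asarray(weights),
                          f"central neuron {neuron_id}")

    def afferent_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": k,
                "angle": tv.angle,
                "coherence": tv.coherence,
                "total_weight": tv.total_weight,
            }
            for k, tv in self.afferent_vectors_.items()
        ]
        return pd.DataFrame(rows, columns=["cell_id", "angle", "coherence", "total_weight"])

    def central_table(self, neuron_ids) -> pd.DataFrame:
        rows = []
        for nid in neuron_ids:
            try:
                tv = self.central(nid)
                rows.append(
                    {
                        "cell_id": str(nid),
                        "angle": tv.angle,
                        "coherence": tv.coherence,
                        "total_weight": tv.total_weight,
                    }
                )
            except (MissingInputError, UndefinedTuningError):
                rows.append(
                    {"cell_id": str(nid), "angle": np.nan, "coherence": np.nan,
                     "total_weight": 0.0}
                )
        return pd.DataFrame(rows, columns=["cell_id", "angle", "coherence", "total_weight"])


def afferent_tuning(
    aff_id: str, connectivity: ConnectivityTable, hair_cell_vectors: dict[str, TuningVector]
) -> TuningVector:
    """Ribbon-weighted resultant tuning of one afferent."""
    prop = TuningPropagator().fit(connectivity, hair_cell_vectors)
    return prop.afferent(aff_id)


def central_tuning(
    neuron_id: str,
    connectivity: ConnectivityTable,
    afferent_vectors: dict[str, TuningVector],
    weighting: str = "uniform",
) -> TuningVector:
    """Average the tuning of the afferents contacting one central neuron."""
    if weighting not in ("uniform", "synapse_count"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    grp = connectivity.aggregated.query("kind == 'central'")
    grp = grp[grp["post_id"] == str(neuron_id)]
    units, weights = [], []
    for _, row in grp.iterrows():
        tv = afferent_vectors.get(row["pre_id"])
        if tv is None:
            continue
        units.append([tv.unit_rc, tv.unit_ml])
        weights.append(row["count"] if weighting == "synapse_count" else 1.0)
    return _resultant(np.asarray(units).reshape(-1, 2), np.asarray(weights),
                      f"central neuron {neuron_id}")


# ---------------------------------------------------------------------------
# topographic statistics
# ---------------------------------------------------------------------------


def tuning_similarity_curve(
    positions: np.ndarray,
    angles_deg: np.ndarray,
    bin_edges: np.ndarray | None = None,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Pairwise tuning similarity (cosine of the angle difference) versus
    3-D Euclidean distance, binned.

    Positions are kinocilium positions for hair cells and soma centers for
    afferents; the caller applies any LPR-side subset first. Returns a
    frame with bin_lo, bin_hi, n_pairs, mean_cos, sd_cos; empty bins carry
    n_pairs 0 and NaN means. Every unordered pair within the bin range is
    counted exactly once.
    """
    P = np.asarray(positions, dtype=float)
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if P.shape[0] < 2:
        raise ValidationError("need at least two cells for a similarity curve")
    d = pdist(P)
    i, j = np.triu_indices(P.shape[0], k=1)
    cos = np.cos(a[i] - a[j])
    if bin_edges is None:
        hi = np.quantile(d, 0.99)
        bin_edges = np.arange(0.0, hi + bin_width, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(bin_edges.size - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": bin_edges[b],
                "bin_hi": bin_edges[b + 1],
                "n_pairs": n,
                "mean_cos": float(cos[sel].mean()) if n else np.nan,
                "sd_cos": float(cos[sel].std(ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def position_correlation(
    connectivity: ConnectivityTable,
    hc_positions: dict[str, np.ndarray],
    aff_positions: dict[str, np.ndarray],
    axis: str = "rc",
    weighting: str = "per_pair",
):
    """Pearson correlation of soma-axis position across connected pairs.

    For every ribbon-connected (hair cell, afferent) pair, correlate the
    chosen axis coordinate of the hair cell with that of the afferent soma.
    ``weighting='ribbon_count'`` replicates each pair by its contact count
    (the effective n is then the replicate count). Returns ``(r, p, n)``.
    """
    ax = {"ml": 0, "rc": 1, "dv": 2}[axis]
    if weighting not in ("per_pair", "ribbon_count"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    ribbon = connectivity.aggregated.query("kind == 'ribbon'")
    xs, ys = [], []
    for _, row in ribbon.iterrows():
        hc, aff = row["pre_id"], row["post_id"]
        if hc not in hc_positions or aff not in aff_positions:
            continue
        rep = int(row["count"]) if weighting == "ribbon_count" else 1
        xs.extend([float(np.asarray(hc_positions[hc])[ax])] * rep)
        ys.extend([float(np.asarray(aff_positions[aff])[ax])] * rep)
    if len(xs) < 3:
        raise ValidationError("need at least three connected pairs")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValidationError("constant coordinate vector: correlation undefined")
    r, p = pearsonr(xs, ys)
    return float(r), float(p), len(xs)


def population_polar_summary(
    vectors: dict[str, TuningVector], half_plane: str | None = None
):
    """Per-neuron tuning table plus population circular mean.

    Returns ``(table, circ_mean_deg, n_in_half_plane)``; the half-plane
    count is over named half-planes ("ipsilateral" = positive ml component,
    etc.), or None when no half-plane is requested.
    """
    if not vectors:
        raise MissingInputError("no neurons with defined tuning")
    table = pd.DataFrame(
        [
            {"neuron_id": k, "angle": tv.angle, "coherence": tv.coherence}
            for k, tv in vectors.items()
        ]
    )
    mean = circular_mean_deg(table["angle"].to_numpy())
    n_half = None
    if half_plane is not None:
        try:
            pred = HALF_PLANES[half_plane]
        except KeyError:
            raise ValidationError(f"unknown half-plane {half_plane!r}") from None
        n_half = int(
            sum(pred(tv.unit_rc, tv.unit_ml) for tv in vectors.values())
        )
    return table, mean, n_half


def convergence_divergence(connectivity: ConnectivityTable) -> dict:
    """Convergence/divergence bookkeeping over the ribbon bipartite graph.

    convergence = distinct hair cells per afferent; divergence = distinct
    afferents per hair cell. Satisfies
    n_hc * mean_div == n_aff * mean_conv == number of connected pairs.
    """
    ribbon = connectivity.aggregated.query("kind == 'ribbon'")
    pairs = ribbon[["pre_id", "post_id"]].drop_duplicates()
    conv = pairs.groupby("post_id").size()
    div = pairs.groupby("pre_id").size()
    return {
        "n_pairs": len(pairs),
        "n_hair_cells": int(div.size),
        "n_afferents": int(conv.size),
        "convergence_mean": float(conv.mean()),
        "convergence_sd": float(conv.std(ddof=1)) if conv.size > 1 else 0.0,
        "divergence_mean": float(div.mean()),
        "divergence_sd": float(div.std(ddof=1)) if div.size > 1 else 0.0,
    }
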