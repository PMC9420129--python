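"""Hair-cell apical geometry: ciliary lengths, polarity vectors, maturity
classes, and the line of polarity reversal (LPR).

A hair cell depolarizes maximally for head tilt toward its kinocilium, so
its anatomical tuning direction is the vector from the centroid of its
stereocilia bases to the kinocilium base, projected into the horizontal
(ml, rc) plane. Ciliary lengths distinguish striolar (long stereocilia,
kinocilium/stereocilium ratio ≈ 1.1–1.7), extrastriolar (short stereocilia,
higher ratio) and immature (short kinocilium) cells. The LPR is the curve
across the macula where polarity flips by ~180°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.isotonic import IsotonicRegression

from .core import DegeneratePolarityError, HairCell, ValidationError
from .tuning import TuningVector, angle_from_components

MATURITY_CLASSES = ("striolar", "extrastriolar", "immature")


# ---------------------------------------------------------------------------
# ciliary geometry
# ---------------------------------------------------------------------------


def cilium_length(points: np.ndarray) -> float:
    """Polyline length: the sum of Euclidean point-to-point distances, µm.

    A single point has length 0. Consecutive duplicate points contribute
    nothing (the trace is deduplicated implicitly by the zero segment).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 1:
        raise ValidationError("empty cilia trace")
    if pts.shape[0] == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def polarity_vector(hc: HairCell) -> TuningVector:
    """Anatomical tuning vector of one hair cell.

    The 3-D vector runs from the center of mass of the stereocilia bases to
    the kinocilium base; only its horizontal (ml, rc) projection defines the
    tuning direction. The pre-normalization horizontal magnitude and the
    dorsoventral component are recorded for QC (hair-bundle vectors are
    expected to be short dorsoventrally on a near-horizontal macula).

    Raises
    ------
    DegeneratePolarityError
        If the horizontal projection is (numerically) zero.
    """
    centroid = hc.stereocilia_bases.mean(axis=0)
    v3 = hc.kinocilium_base - centroid
    ml, rc, dv = float(v3[0]), float(v3[1]), float(v3[2])
    mag = float(np.hypot(ml, rc))
    if mag < 1e-12:
        raise DegeneratePolarityError(
            f"{hc.cell_id}: polarity vector has no horizontal component"
        )
    return TuningVector(
        unit_rc=rc / mag,
        unit_ml=ml / mag,
        coherence=1.0,
        total_weight=1.0,
        horizontal_magnitude=mag,
        dv_component=dv,
    )


# ---------------------------------------------------------------------------
# maturity classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaturityThresholds:
    """Length thresholds (µm) separating hair-cell maturity classes.

    ``kino_min_established`` and ``kino_immature_max`` bracket the short-
    kinocilium criterion; ``stereo_min_striolar`` is the minimum tallest-
    stereocilium length of striolar cells; ``ks_ratio_striolar_max`` caps
    the kinocilium/stereocilium ratio of striolar cells.
    """

    kino_min_established: float = 4.8
    stereo_min_striolar: float = 4.8
    kino_immature_max: float = 5.0
    ks_ratio_striolar_max: float = 1.7

    def __post_init__(self):
        vals = (
            self.kino_min_established,
            self.stereo_min_striolar,
            self.kino_immature_max,
            self.ks_ratio_striolar_max,
        )
        if any(v <= 0 for v in vals):
            raise ValidationError("maturity thresholds must be positive")
        if self.kino_min_established > self.kino_immature_max:
            raise ValidationError(
                "kino_min_established must be <= kino_immature_max"
            )


class MaturityClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based maturity classifier on (kinocilium, stereocilium) lengths.

    A cell is *immature* when both cilia are short (kinocilium below
    ``kino_immature_max`` AND tallest stereocilium at or below
    ``stereo_min_striolar``); otherwise *striolar* when the stereocilium is
    long and the K/S ratio at or below ``ks_ratio_striolar_max``; otherwise
    *extrastriolar*. The rule is total and deterministic, and is scale-
    consistent: scaling both lengths and both length thresholds by c > 0
    preserves the class.

    Follows the sklearn estimator API; ``fit`` only records classes_
    (there are no free parameters to estimate).
    """

    def __init__(
        self,
        kino_min_established: float = 4.8,
        stereo_min_striolar: float = 4.8,
        kino_immature_max: float = 5.0,
        ks_ratio_striolar_max: float = 1.7,
    ):
        self.kino_min_established = kino_min_established
        self.stereo_min_striolar = stereo_min_striolar
        self.kino_immature_max = kino_immature_max
        self.ks_ratio_striolar_max = ks_ratio_striolar_max

    def _thresholds(self) -> MaturityThresholds:
        return MaturityThresholds(
            self.kino_min_established,
            self.stereo_min_striolar,
            self.kino_immature_max,
            self.ks_ratio_striolar_max,
        )

    def fit(self, X=None, y=None):
        self._thresholds()  # validate
        self.classes_ = np.array(MATURITY_CLASSES)
        return self

    def predict(self, X) -> np.ndarray:
        """Classify (n, 2) rows of [kinocilium length, stereocilium length]."""
        if not hasattr(self, "classes_"):
            self.fit()
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        if np.any(X <= 0) or not np.all(np.isfinite(X)):
            raise ValidationError("ciliary lengths must be positive and finite")
        t = self._thresholds()
        kino, stereo = X[:, 0], X[:, 1]
        immature = (kino < t.kino_immature_max) & (stereo <= t.stereo_min_striolar)
        striolar = (
            ~immature
            & (stereo > t.stereo_min_striolar)
            & (kino / stereo <= t.ks_ratio_striolar_max)
        )
        out = np.full(X.shape[0], "extrastriolar", dtype=object)
        out[immature] = "immature"
        out[striolar] = "striolar"
        return out.astype(str)


def classify_maturity(
    kino_len: float, stereo_len: float, thresholds: MaturityThresholds | None = None
) -> str:
    """Classify a single hair cell from its two ciliary lengths (µm)."""
    t = thresholds or MaturityThresholds()
    clf = MaturityClassifier(
        t.kino_min_established,
        t.stereo_min_striolar,
        t.kino_immature_max,
        t.ks_ratio_striolar_max,
    )
    return str(clf.predict([[kino_len, stereo_len]])[0])


# ---------------------------------------------------------------------------
# line of polarity reversal
# ---------------------------------------------------------------------------


class PolarityReversalBoundary(BaseEstimator):
    """Fit the LPR as a monotone mediolateral boundary over rostrocaudal bins.

    Cells whose polarity vector points laterally (positive ml component)
    sit medial to the LPR, and vice versa. The boundary is estimated by
    choosing, within each rc bin, the ml split minimizing provisional-side
    misassignments, then smoothing the per-bin splits with an isotonic
    (monotone) regression weighted by bin occupancy. Deterministic and
    seedless.

    Parameters
    ----------
    n_bins : number of rc bins (reduced automatically for small samples).
    ml_tol : |ml component| below which a vector is flagged ambiguous
        (purely rostrocaudal polarity); such cells get no provisional side
        and are labeled purely by the fitted boundary.

    Attributes
    ----------
    boundary_rc_, boundary_ml_ : support points of the fitted boundary.
    n_disagreements_ : provisional labels that flipped at the boundary step.
    ambiguous_ : boolean mask of cells without a provisional side.
    single_side_ : True when all provisional labels agreed (no boundary
        could be estimated; a warning is issued).
    """

    def __init__(self, n_bins: int = 6, ml_tol: float = 1e-9):
        self.n_bins = n_bins
        self.ml_tol = ml_tol

    def fit(self, positions, vectors):
        """Fit from (n, 2+) positions [ml, rc, ...] and (n, 2) unit vectors
        given as [rc component, ml component]."""
        P = np.asarray(positions, dtype=float)
        V = np.asarray(vectors, dtype=float)
        ml, rc = P[:, 0], P[:, 1]
        vml = V[:, 1]
        self.ambiguous_ = np.abs(vml) <= self.ml_tol
        provisional = np.where(vml > 0, "medial", "lateral").astype(object)
        provisional[self.ambiguous_] = None
        known = ~self.ambiguous_
        sides = set(provisional[known])
        self.single_side_ = len(sides) < 2
        if self.single_side_:
            warnings.warn(
                "all polarity vectors lie on one side; LPR boundary undefined",
                stacklevel=2,
            )
            only = sides.pop() if sides else "medial"
            self.labels_ = np.full(P.shape[0], only, dtype=object).astype(str)
            self.boundary_rc_ = np.array([rc.min(), rc.max()])
            fill = ml.max() + 1.0 if only == "medial" else ml.min() - 1.0
            self.boundary_ml_ = np.array([fill, fill])
            self.n_disagreements_ = 0
            return self

        n_bins = max(1, min(self.n_bins, max(1, known.sum() // 4)))
        edges = np.quantile(rc[known], np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-9
        centers, splits, weights = [], [], []
        for b in range(n_bins):
            sel = known & (rc >= edges[b]) & (rc < edges[b + 1])
            if sel.sum() == 0:
                continue
            centers.append(rc[sel].mean())
            splits.append(_best_split(ml[sel], provisional[sel]))
            weights.append(sel.sum())
        centers = np.asarray(centers)
        splits = np.asarray(splits)
        order = np.argsort(centers)
        centers, splits = centers[order], splits[order]
        weights = np.asarray(weights, dtype=float)[order]
        if centers.size >= 2:
            iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
            with warnings.catch_warnings():
                # a flat boundary makes the monotone direction ambiguous,
                # which is fine: any direction fits equally well
                warnings.simplefilter("ignore", UserWarning)
                splits = iso.fit(centers, splits, sample_weight=weights).predict(centers)
        self.boundary_rc_ = centers
        self.boundary_ml_ = splits
        self.labels_ = self.predict(P)
        self.n_disagreements_ = int(
            np.sum(self.labels_[known] != provisional[known].astype(str))
        )
        return self

    def boundary_at(self, rc) -> np.ndarray:
        """Interpolated boundary ml position at given rc coordinates."""
        return np.interp(np.asarray(rc, dtype=float), self.boundary_rc_, self.boundary_ml_)

    def predict(self, positions) -> np.ndarray:
        """Side-of-boundary label for (n, 2+) positions [ml, rc, ...]."""
        P = np.asarray(positions, dtype=float)
        b = self.boundary_at(P[:, 1])
        return np.where(P[:, 0] < b, "medial", "lateral").astype(str)


def _best_split(ml: np.ndarray, side: np.ndarray) -> float:
    """The ml threshold minimizing misassignment: medial cells below it."""
    order = np.argsort(ml)
    mls, sides = ml[order], side[order]
    cands = np.concatenate(
        [[mls[0] - 1.0], (mls[:-1] + mls[1:]) / 2.0, [mls[-1] + 1.0]]
    )
    best_t, best_cost = cands[0], np.inf
    for t in cands:
        cost = np.sum((sides == "medial") & (mls >= t)) + np.sum(
            (sides == "lateral") & (mls < t)
        )
        if cost < best_cost:
            best_t, best_cost = t, cost
    return float(best_t)


def assign_lpr_side(cells: dict[str, HairCell] | list[HairCell], n_bins: int = 6):
    """Assign an LPR side to every hair cell and fit the boundary.

    Returns ``(labels, boundary)`` where ``labels`` is a DataFrame with
    cell_id, provisional and final side, and the ambiguity flag, and
    ``boundary`` is the fitted :class:`PolarityReversalBoundary`. Cells with
    degenerate polarity are excluded from the fit but still receive a
    boundary-based side.
    """
    hcs = list(cells.values()) if isinstance(cells, dict) else list(cells)
    ids, positions, vec, degenerate = [], [], [], []
    for hc in hcs:
        ids.append(hc.cell_id)
        positions.append(hc.apical_position[:2])  # (ml, rc)
        try:
            tv = polarity_vector(hc)
            vec.append([tv.unit_rc, tv.unit_ml])
            degenerate.append(False)
        except DegeneratePolarityError:
            vec.append([0.0, 0.0])
            degenerate.append(True)
    positions = np.asarray(positions)
    vec = np.asarray(vec)
    degenerate = np.asarray(degenerate)

    boundary = PolarityReversalBoundary(n_bins=n_bins)
    ok = ~degenerate
    boundary.fit(positions[ok], vec[ok])
    final = boundary.predict(positions)
    provisional = np.where(vec[:, 1] > 0, "medial", "lateral").astype(object)
    ambiguous = degenerate | (np.abs(vec[:, 1]) <= boundary.ml_tol)
    provisional[ambiguous] = None
    for hc, side in zip(hcs, final):
        hc.lpr_side = str(side)
    labels = pd.DataFrame(
        {
            "cell_id": ids,
            "provisional_side": provisional,
            "final_side": final,
            "ambiguous": ambiguous,
        }
    )
    return labels, boundary


# ---------------------------------------------------------------------------
# per-cell summary
# ---------------------------------------------------------------------------


def hair_cell_table(
    cells: dict[str, HairCell],
    thresholds: MaturityThresholds | None = None,
    n_bins: int = 6,
) -> pd.DataFrame:
    """Full per-cell geometry table: lengths, K/S, class, side, tuning angle.

    Sets ``maturity`` and ``lpr_side`` on each HairCell in place and returns
    a tidy frame (one row per cell; degenerate-polarity cells carry NaN
    angle and a ``degenerate`` flag).
    """
    t = thresholds or MaturityThresholds()
    clf = MaturityClassifier(
        t.kino_min_established,
        t.stereo_min_striolar,
        t.kino_immature_max,
        t.ks_ratio_striolar_max,
    ).fit()
    sides, _ = assign_lpr_side(cells, n_bins=n_bins)
    side_of = dict(zip(sides["cell_id"], sides["final_side"]))
    rows = []
    for cid, hc in cells.items():
        klen = cilium_length(hc.kinocilium)
        slen = cilium_length(hc.tallest_stereocilium)
        maturity = str(clf.predict([[klen, slen]])[0]) if klen > 0 and slen > 0 else None
        hc.maturity = maturity
        try:
            tv = polarity_vector(hc)
            angle = tv.angle
            dv_comp = tv.dv_component
            hmag = tv.horizontal_magnitude
            degenerate = False
        except DegeneratePolarityError:
            angle, dv_comp, hmag, degenerate = np.nan, np.nan, np.nan, True
        rows.append(
            {
                "cell_id": cid,
                "kino_length": klen,
                "stereo_length": slen,
                "ks_ratio": klen / slen if slen > 0 else np.nan,
                "maturity": maturity,
                "lpr_side": side_of[cid],
                "tuning_angle": angle,
                "horizontal_magnitude": hmag,
                "dv_component": dv_comp,
                "ribbon_count": hc.ribbon_count,
                "ml": hc.apical_position[0],
                "rc": hc.apical_position[1],
                "dv": hc.apical_position[2],
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def tuning_angle(hc: HairCell) -> float:
    """Tuning angle in degrees (0° = rostral, 90° = lateral)."""
    tv = polarity_vector(hc)
    return angle_from_components(tv.unit_rc, tv.unit_ml)
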