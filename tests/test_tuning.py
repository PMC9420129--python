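"""Synapse-weighted tuning propagation and topography statistics."""

import numpy as np
import pandas as pd
import pytest

from otomap.core import (
    ConnectivityTable,
    MissingInputError,
    UndefinedTuningError,
)
from otomap.hair_cells import polarity_vector
from otomap.synthetic import CircuitConfig, MaculaConfig, generate_circuit, generate_macula
from otomap.tuning import (
    TuningPropagator,
    TuningVector,
    afferent_tuning,
    central_tuning,
    circular_mean_deg,
    convergence_divergence,
    population_polar_summary,
    position_correlation,
    tuning_similarity_curve,
)


def tv(angle_deg: float) -> TuningVector:
    a = np.radians(angle_deg)
    return TuningVector(unit_rc=np.cos(a), unit_ml=np.sin(a), coherence=1.0,
                        total_weight=1.0)


def table(rows) -> ConnectivityTable:
    return ConnectivityTable(
        pd.DataFrame(rows, columns=["pre_id", "post_id", "count", "kind"])
    )


def brute_force_weighted_mean(angles_deg, weights):
    """Independent oracle: weighted resultant by plain trigonometric sums."""
    x = sum(w * np.cos(np.radians(a)) for a, w in zip(angles_deg, weights))
    y = sum(w * np.sin(np.radians(a)) for a, w in zip(angles_deg, weights))
    return np.degrees(np.arctan2(y, x)) % 360


class TestAfferentTuning:
    def test_single_input_passes_through(self):
        conn = table([("hc1", "a1", 7, "ribbon")])
        out = afferent_tuning("a1", conn, {"hc1": tv(33.0)})
        assert out.angle == pytest.approx(33.0)
        assert out.coherence == pytest.approx(1.0)
        assert out.total_weight == 7

    def test_orthogonal_equal_weights_bisect(self):
        conn = table([("hc1", "a1", 1, "ribbon"), ("hc2", "a1", 1, "ribbon")])
        out = afferent_tuning("a1", conn, {"hc1": tv(0.0), "hc2": tv(90.0)})
        assert out.angle == pytest.approx(45.0)
        assert out.coherence == pytest.approx(np.sqrt(2) / 2)

    def test_weighted_sum_matches_oracle(self):
        conn = table([("hc1", "a1", 3, "ribbon"), ("hc2", "a1", 1, "ribbon")])
        out = afferent_tuning("a1", conn, {"hc1": tv(0.0), "hc2": tv(90.0)})
        assert out.angle == pytest.approx(np.degrees(np.arctan2(1, 3)))
        assert out.angle == pytest.approx(brute_force_weighted_mean([0, 90], [3, 1]))

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            angles = rng.uniform(0, 360, size=k)
            weights = rng.integers(1, 20, size=k)
            conn = table(
                [(f"hc{i}", "a1", int(w), "ribbon") for i, w in enumerate(weights)]
            )
            vecs = {f"hc{i}": tv(a) for i, a in enumerate(angles)}
            got = afferent_tuning("a1", conn, vecs).angle
            want = brute_force_weighted_mean(angles, weights)
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    def test_opposed_inputs_are_undefined(self):
        conn = table([("hc1", "a1", 1, "ribbon"), ("hc2", "a1", 1, "ribbon")])
        with pytest.raises(UndefinedTuningError):
            afferent_tuning("a1", conn, {"hc1": tv(0.0), "hc2": tv(180.0)})

    def test_no_input_is_missing(self):
        conn = table([("hc1", "a1", 1, "ribbon")])
        with pytest.raises(MissingInputError):
            afferent_tuning("a2", conn, {"hc1": tv(0.0)})


class TestCentralTuning:
    def test_single_afferent_identical(self):
        conn = table([("a1", "m1", 4, "central")])
        out = central_tuning("m1", conn, {"a1": tv(200.0)})
        assert out.angle == pytest.approx(200.0)

    def test_symmetric_pair_averages_to_zero(self):
        conn = table([("a1", "m1", 1, "central"), ("a2", "m1", 9, "central")])
        out = central_tuning("m1", conn, {"a1": tv(10.0), "a2": tv(350.0)},
                             weighting="uniform")
        assert out.angle % 360 == pytest.approx(0.0, abs=1e-9)

    def test_synapse_count_weighting_differs(self):
        conn = table([("a1", "m1", 1, "central"), ("a2", "m1", 3, "central")])
        uni = central_tuning("m1", conn, {"a1": tv(0.0), "a2": tv(90.0)}, "uniform")
        wtd = central_tuning("m1", conn, {"a1": tv(0.0), "a2": tv(90.0)}, "synapse_count")
        assert uni.angle == pytest.approx(45.0)
        assert wtd.angle == pytest.approx(np.degrees(np.arctan2(3, 1)))


class TestInvariants:
    def _random_circuit_vectors(self, seed=0):
        rng = np.random.default_rng(seed)
        rows, vecs = [], {}
        for i in range(12):
            vecs[f"hc{i}"] = tv(rng.uniform(0, 360))
        for a in range(6):
            for i in rng.choice(12, size=3, replace=False):
                rows.append((f"hc{i}", f"a{a}", int(rng.integers(1, 9)), "ribbon"))
            rows.append((f"a{a}", "m1", int(rng.integers(1, 4)), "central"))
        return table(rows), vecs

    def test_rotation_equivariance(self):
        """Rotating all hair-cell vectors by phi rotates every inferred
        vector by exactly phi and leaves coherence unchanged."""
        conn, vecs = self._random_circuit_vectors()
        phi = 77.3
        rotated = {k: tv((v.angle + phi) % 360) for k, v in vecs.items()}
        base = TuningPropagator().fit(conn, vecs)
        rot = TuningPropagator().fit(conn, rotated)
        for aff in base.afferent_vectors_:
            b, r = base.afferent(aff), rot.afferent(aff)
            assert abs((r.angle - b.angle - phi + 180) % 360 - 180) < 1e-9
            assert r.coherence == pytest.approx(b.coherence, abs=1e-12)
        bm, rm = base.central("m1"), rot.central("m1")
        assert abs((rm.angle - bm.angle - phi + 180) % 360 - 180) < 1e-9

    def test_weight_homogeneity(self):
        """Scaling all ribbon counts by a constant changes no angle or
        coherence."""
        conn, vecs = self._random_circuit_vectors(seed=3)
        scaled_df = conn.df.copy()
        ribbon = scaled_df["kind"] == "ribbon"
        scaled_df.loc[ribbon, "count"] *= 5
        scaled = ConnectivityTable(scaled_df)
        base = TuningPropagator().fit(conn, vecs)
        big = TuningPropagator().fit(scaled, vecs)
        for aff in base.afferent_vectors_:
            assert big.afferent(aff).angle == pytest.approx(base.afferent(aff).angle)
            assert big.afferent(aff).coherence == pytest.approx(
                base.afferent(aff).coherence
            )

    def test_convergence_divergence_bookkeeping(self, circuit):
        _, _, _, conn, _, _ = circuit
        cd = convergence_divergence(conn)
        assert cd["n_hair_cells"] * cd["divergence_mean"] == pytest.approx(
            cd["n_pairs"]
        )
        assert cd["n_afferents"] * cd["convergence_mean"] == pytest.approx(
            cd["n_pairs"]
        )


class TestSimilarityCurve:
    def test_identical_angles_give_unit_similarity(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 50, size=(20, 3))
        curve = tuning_similarity_curve(pos, np.full(20, 123.0))
        populated = curve[curve["n_pairs"] > 0]
        assert np.allclose(populated["mean_cos"], 1.0)
        assert curve["n_pairs"].sum() == 20 * 19 // 2

    def test_single_pair_bin(self):
        curve = tuning_similarity_curve(
            [[0, 0, 0], [7, 0, 0]], [0.0, 90.0], bin_edges=[0, 10, 20]
        )
        assert curve.loc[0, "n_pairs"] == 1
        assert curve.loc[0, "mean_cos"] == pytest.approx(0.0, abs=1e-12)
        assert curve.loc[1, "n_pairs"] == 0 and np.isnan(curve.loc[1, "mean_cos"])

    def test_isotropic_angles_average_to_zero(self):
        """Under uniform angles the per-bin mean cosine shrinks as 3/sqrt(n)."""
        rng = np.random.default_rng(5)
        n = 200
        pos = rng.uniform(0, 30, size=(n, 3))
        angles = rng.uniform(0, 360, size=n)
        curve = tuning_similarity_curve(pos, angles, bin_edges=[0, 60])
        assert curve.loc[0, "n_pairs"] > 1000
        assert abs(curve.loc[0, "mean_cos"]) < 3 / np.sqrt(curve.loc[0, "n_pairs"])


class TestPositionCorrelation:
    def test_identity_line(self):
        conn = table([(f"hc{i}", f"a{i}", 1, "ribbon") for i in range(5)])
        pos = {f"hc{i}": np.array([0.0, float(i), 0.0]) for i in range(5)}
        aff = {f"a{i}": np.array([0.0, float(i), 0.0]) for i in range(5)}
        r, p, n = position_correlation(conn, pos, aff, axis="rc")
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_ribbon_replication_changes_n(self):
        conn = table(
            [("hc0", "a0", 5, "ribbon"), ("hc1", "a1", 1, "ribbon"),
             ("hc2", "a2", 1, "ribbon")]
        )
        pos = {f"hc{i}": np.array([0.0, float(i), 0.0]) for i in range(3)}
        aff = {f"a{i}": np.array([0.0, float(i) + 0.1, 0.0]) for i in range(3)}
        _, _, n_pair = position_correlation(conn, pos, aff, weighting="per_pair")
        _, _, n_rib = position_correlation(conn, pos, aff, weighting="ribbon_count")
        assert n_pair == 3 and n_rib == 7

    def test_permutation_calibration(self):
        """Permuted pairings exceed the 5% significance level rarely."""
        rng = np.random.default_rng(2)
        n = 40
        rc = rng.uniform(0, 60, size=n)
        pos = {f"hc{i}": np.array([0.0, rc[i], 0.0]) for i in range(n)}
        false_pos = 0
        reps = 400
        for _ in range(reps):
            perm = rng.permutation(n)
            aff = {f"a{i}": np.array([0.0, rc[perm[i]], 0.0]) for i in range(n)}
            conn = table([(f"hc{i}", f"a{i}", 1, "ribbon") for i in range(n)])
            _, p, _ = position_correlation(conn, pos, aff)
            false_pos += p < 0.05
        assert false_pos / reps < 0.09


class TestPolarSummary:
    def test_single_neuron(self):
        t, mean, _ = population_polar_summary({"n1": tv(30.0)})
        assert mean == pytest.approx(30.0)
        assert len(t) == 1

    def test_symmetric_pair_half_plane(self):
        t, mean, n = population_polar_summary(
            {"n1": tv(45.0), "n2": tv(315.0)}, half_plane="rostral"
        )
        assert mean % 360 == pytest.approx(0.0, abs=1e-9)
        assert n == 2

    def test_circular_mean_wraps(self):
        assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)


class TestOnSyntheticCircuit:
    def test_afferent_angles_match_brute_force(self, circuit):
        """Propagated tuning equals the independent ribbon-weighted oracle."""
        cells, truth, _, conn, _, _ = circuit
        vecs = {cid: polarity_vector(hc) for cid, hc in cells.items()}
        prop = TuningPropagator().fit(conn, vecs)
        ribbon = conn.aggregated.query("kind == 'ribbon'")
        for aff_id, grp in list(ribbon.groupby("post_id"))[:30]:
            want = brute_force_weighted_mean(
                [vecs[h].angle for h in grp["pre_id"]], grp["count"].to_numpy()
            )
            got = prop.afferent(aff_id).angle
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    def test_escape_pathways_oppose(self, circuit):
        """Mauthner vs commissural-escape population tuning is near-opposite
        (the two pools draw from opposite LPR sides)."""
        cells, truth, meta, conn, _, _ = circuit
        vecs = {cid: polarity_vector(hc) for cid, hc in cells.items()}
        prop = TuningPropagator().fit(conn, vecs)
        mau = prop.central("mauthner00")
        comm_ids = meta.loc[meta["population"] == "commissural_escape", "cell_id"]
        comm = circular_mean_deg([prop.central(c).angle for c in comm_ids])
        diff = abs((mau.angle - comm + 180) % 360 - 180)
        assert diff > 120.0
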