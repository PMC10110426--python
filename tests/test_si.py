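"""Spreading Index, laterality and symmetry metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ckcnet as ck
from ckcnet.connectivity import FidelityMask, InteractionMatrix
from ckcnet.errors import (
    DegenerateSignalError,
    InvalidParameterError,
    MissingControlError,
    UndefinedMetricError,
)
from ckcnet.si import (
    edge_zscores,
    laterality,
    reference_distribution,
    spreading_index,
    spreading_index_from_matrices,
    symmetry,
)


def antisym_matrix(n=12, seed=0, sd=0.02, labels=None):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, (n, n))
    d = 0.5 + (a - a.T) / 2.0
    np.fill_diagonal(d, np.nan)
    return InteractionMatrix(
        dpte=d, mask=FidelityMask.all_valid(n),
        labels=labels or tuple(f"p{i:02d}" for i in range(n)),
        band=(3.26, 3.86),
    )


class TestReferenceDistribution:
    def test_null_control_centres_on_half(self):
        ref = reference_distribution(antisym_matrix(n=20, seed=1))
        assert ref.mu == pytest.approx(0.5, abs=0.01)
        assert ref.sigma > 0

    def test_matches_direct_mean_sd_oracle(self):
        m = antisym_matrix(n=10, seed=2)
        ref = reference_distribution(m)
        vals = m.dpte[m.mask.valid]
        assert ref.mu == pytest.approx(float(np.mean(vals)), abs=1e-12)
        assert ref.sigma == pytest.approx(float(np.std(vals)), abs=1e-12)
        assert ref.n_pooled == vals.size

    def test_degenerate_control_raises(self):
        m = antisym_matrix(n=10, sd=0.0)
        with pytest.raises(DegenerateSignalError):
            reference_distribution(m)

    def test_missing_control_raises(self):
        with pytest.raises(MissingControlError):
            reference_distribution(None)


class TestEdgeZscores:
    def test_mean_value_maps_to_zero(self):
        m = antisym_matrix(seed=3)
        ref = reference_distribution(m)
        z, sig = edge_zscores(m, ref)
        v = m.mask.valid
        i, j = np.argwhere(np.isclose(m.dpte, ref.mu, atol=1e-3) & v)[0]
        assert abs(z[i, j]) < 0.1 and not sig[i, j]

    def test_three_sigma_edge_is_significant(self):
        m = antisym_matrix(seed=4)
        ref = reference_distribution(m)
        m.dpte[2, 5] = ref.mu + 3 * ref.sigma
        z, sig = edge_zscores(m, ref, alpha=0.01)
        assert z[2, 5] == pytest.approx(3.0)
        assert sig[2, 5]  # threshold z ~ 2.326

    def test_antisymmetric_pair_identity(self):
        m = antisym_matrix(seed=5)
        ref = reference_distribution(m)
        z, _ = edge_zscores(m, ref)
        v = m.mask.valid
        expected = (1.0 - 2.0 * ref.mu) / ref.sigma
        pair_sums = z[v] + z.T[v]
        assert np.allclose(pair_sums, expected, atol=1e-9)


class TestSpreadingIndex:
    def _toy(self, z_edges, n=6, hemi=None):
        """z-matrix with planted significant edges, all else z=0."""
        labels = tuple(f"p{i}" for i in range(n))
        m = antisym_matrix(n=n, seed=6, labels=labels)
        z = np.zeros((n, n))
        sig = np.zeros((n, n), dtype=bool)
        for i, j in z_edges:
            z[i, j] = 4.0
            sig[i, j] = True
        z[~m.mask.valid] = np.nan
        hemi = hemi or ["left"] * n
        return m, z, sig, hemi

    def test_hand_enumerated_toy_case(self):
        # 6 parcels, left hemisphere: sources ranked by significant
        # outbound counts; chosen 4 sources have 20 valid outbound edges,
        # 12 significant -> SI = 60
        edges = [(0, j) for j in (1, 2, 3, 4, 5)] + \
                [(1, j) for j in (0, 2, 3, 4)] + \
                [(2, j) for j in (0, 1)] + [(3, 4)]
        m, z, sig, hemi = self._toy(edges)
        res = spreading_index(z, sig, m, "left", parcel_hemisphere=hemi)
        assert res.source_parcels == ("p0", "p1", "p2", "p3")
        assert res.n_possible_from_sources == 20
        assert res.n_significant_from_sources == 12
        assert res.si == pytest.approx(60.0)

    def test_all_edges_significant_gives_100(self):
        edges = [(i, j) for i in range(6) for j in range(6) if i != j]
        m, z, sig, hemi = self._toy(edges)
        res = spreading_index(z, sig, m, "left", parcel_hemisphere=hemi)
        assert res.si == 100.0

    def test_no_significant_edges_gives_0(self):
        m, z, sig, hemi = self._toy([])
        res = spreading_index(z, sig, m, "left", parcel_hemisphere=hemi)
        assert res.si == 0.0

    def test_sources_restricted_to_requested_hemisphere(self):
        hemi = ["left", "right"] * 4
        edges = [(1, j) for j in range(8) if j != 1]  # strongest is right
        m, z, sig, _ = self._toy(edges, n=8)
        res = spreading_index(z, sig, m, "left", parcel_hemisphere=hemi)
        assert all(int(p[1:]) % 2 == 0 for p in res.source_parcels)

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_parameter_recovery_of_planted_edge_fraction(self, f):
        # plant significant outbound edges on 4 known left-hemisphere
        # parcels at edge fraction f; SI must recover 100 f within 10
        from ckcnet.containers import default_parcel_metadata

        labels, hemis, _ = default_parcel_metadata(58)
        left = [i for i, h in enumerate(hemis) if h == "left"]
        sources = left[:4]
        sis = []
        for seed in range(20):
            rng = np.random.default_rng(1700 + seed)
            m = antisym_matrix(n=58, seed=1800 + seed, labels=labels)
            z = rng.normal(0.0, 1.0, (58, 58))
            sig = z > 5.0  # background: nothing significant
            for s in sources:
                cols = [j for j in range(58) if j != s]
                chosen = rng.choice(cols, size=int(round(f * len(cols))),
                                    replace=False)
                z[s, chosen] = 5.0
                sig[s, chosen] = True
            z[~m.mask.valid] = np.nan
            res = spreading_index(z, sig, m, "left",
                                  parcel_hemisphere=list(hemis))
            assert set(res.source_parcels) == {labels[i] for i in sources}
            sis.append(res.si)
        assert abs(np.mean(sis) - 100.0 * f) <= 10.0

    def test_end_to_end_recovery_from_signals(self):
        # 4 left sources drive 10 targets; SI machinery run on actual
        # dPTE matrices referenced against an uncoupled control
        from ckcnet.connectivity import dpte_matrix

        n = 16
        from ckcnet.containers import default_parcel_metadata

        labels, hemis, _ = default_parcel_metadata(n)
        left = [i for i, h in enumerate(hemis) if h == "left"][:4]
        others = [i for i in range(n) if i not in left]
        edges = tuple(
            (s, t, 5, 0.95) for k, s in enumerate(left)
            for t in others[2 * k : 2 * k + 3]
        )
        stim = ck.generate_parcel_signals(ck.SynthParcelConfig(
            n_parcels=n, duration=60.0, seed=21, coupling_edges=edges))
        ctrl = ck.generate_parcel_signals(ck.SynthParcelConfig(
            n_parcels=n, duration=60.0, seed=22))
        res = spreading_index_from_matrices(
            dpte_matrix(stim), dpte_matrix(ctrl), "left")
        assert res.si > 0
        assert len(set(res.source_parcels) & {labels[i] for i in left}) >= 2


class TestLateralityAndSymmetry:
    def test_limit_cases(self):
        assert laterality(0.3, 0.3) == 50.0
        assert laterality(0.3, 0.0) == 100.0
        assert laterality(0.3, 0.1) == 75.0
        assert symmetry(0.2, 0.2) == 100.0
        assert symmetry(0.2, 0.4) == 50.0
        assert symmetry(0.0, 0.4) == 0.0

    def test_undefined_cases_raise(self):
        with pytest.raises(UndefinedMetricError):
            laterality(0.0, 0.0)
        with pytest.raises(UndefinedMetricError):
            symmetry(0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            laterality(-0.1, 0.5)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_laterality_complementarity(self, a, b):
        assert laterality(a, b) + laterality(b, a) == pytest.approx(100.0)

    def test_hemispheric_ckc_summary(self, csd_epochs):
        res = ck.detect_ckc(csd_epochs)
        left = ck.hemispheric_ckc(res, "left")
        right = ck.hemispheric_ckc(res, "right")
        assert laterality(left, right) + laterality(right, left) == pytest.approx(100.0)
        assert ck.hemispheric_ckc(res, "left", mode="mean") <= left
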