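import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mvi import ecology as eco
from mvi.io_model import SampleMeta, ValidationError


# -- brute-force oracles ----------------------------------------------------


def chao1_oracle(counts):
    tally = Counter(c for c in counts if c > 0)
    s0 = sum(tally.values())
    a1 = tally.get(1, 0)
    a2 = tally.get(2, 0)
    if a2 > 0:
        return s0 + a1 * a1 / (2 * a2)
    return s0 + a1 * (a1 - 1) / 2


def shannon_oracle(counts):
    total = sum(counts)
    if total == 0:
        return float("nan")
    acc = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            acc -= p * math.log(p)
    return acc


def bray_curtis_oracle(u, v):
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den


# -- rarefaction ------------------------------------------------------------


class TestRarefy:
    def test_depth_equal_to_total_unchanged(self):
        counts = pd.DataFrame({"s": [3, 5, 2]}, index=list("abc"))
        out = eco.rarefy(counts, depth=10, seed=1)
        pd.testing.assert_frame_equal(out, counts, check_dtype=False)

    def test_column_sums_equal_depth(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 200, size=(30, 4)),
            index=[f"c{i}" for i in range(30)],
            columns=list("wxyz"),
        )
        depth = int(counts.sum(axis=0).min())
        out = eco.rarefy(counts, depth=depth, seed=3)
        assert (out.sum(axis=0) == depth).all()

    def test_deterministic(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 3)))
        a = eco.rarefy(counts, depth=100, seed=9)
        b = eco.rarefy(counts, depth=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_depth_rejected(self):
        counts = pd.DataFrame({"s": [1]})
        with pytest.raises(ValidationError):
            eco.rarefy(counts, depth=0)

    def test_shallow_samples_dropped_with_warning(self, caplog):
        counts = pd.DataFrame({"deep": [50, 50], "shallow": [1, 1]})
        with caplog.at_level("WARNING"):
            out = eco.rarefy(counts, depth=50, seed=0)
        assert list(out.columns) == ["deep"]
        assert "shallow" in caplog.text


# -- alpha diversity --------------------------------------------------------


class TestChao1:
    def test_no_singletons_collapses_to_s0(self):
        assert eco.chao1([3, 4, 2, 2]) == 4

    def test_hand_evaluated(self):
        # S0=4, a1=2, a2=1 -> 4 + 4/2 = 6
        assert eco.chao1([1, 1, 2, 5]) == pytest.approx(6.0)

    def test_bias_corrected_fallback(self):
        # a2 == 0: S0 + a1(a1-1)/2
        assert eco.chao1([1, 1, 1, 5]) == pytest.approx(4 + 3 * 2 / 2)

    def test_empty_vector_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert eco.chao1([]) == 0.0
        assert "empty" in caplog.text

    def test_always_at_least_s0(self, rng):
        for _ in range(50):
            v = rng.integers(0, 6, size=rng.integers(1, 30))
            s0 = int((v > 0).sum())
            c = eco.chao1(v)
            assert c >= s0
            if (v == 1).sum() == 0:
                assert c == s0

    def test_oracle_equivalence(self, rng):
        for _ in range(100):
            v = rng.integers(0, 8, size=rng.integers(1, 40)).tolist()
            assert eco.chao1(v) == pytest.approx(chao1_oracle(v), abs=1e-12)


class TestShannon:
    def test_single_species_zero(self):
        assert eco.shannon([42]) == 0.0

    def test_uniform_is_log_s(self):
        assert eco.shannon([5] * 7) == pytest.approx(math.log(7), abs=1e-12)

    def test_hand_evaluated(self):
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert eco.shannon([2, 2, 4]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_undefined(self):
        assert np.isnan(eco.shannon([0, 0]))

    def test_oracle_equivalence(self, rng):
        for _ in range(100):
            v = rng.integers(0, 20, size=rng.integers(1, 40)).tolist()
            got, want = eco.shannon(v), shannon_oracle(v)
            if math.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestPopulationVariance:
    def test_even_community_zero(self):
        assert eco.population_variance([0.25] * 4) == 0.0

    def test_dominant_profile_closed_form(self):
        # one entry at ~1, the rest sharing epsilon: var -> (n-1)/n^2
        n = 10
        eps = 1e-9
        profile = [1 - eps] + [eps / (n - 1)] * (n - 1)
        assert eco.population_variance(profile) == pytest.approx((n - 1) / n**2, rel=1e-6)

    def test_order_invariant(self, rng):
        v = rng.random(12)
        shuffled = v[rng.permutation(12)]
        assert eco.population_variance(v) == pytest.approx(
            eco.population_variance(shuffled), abs=1e-15
        )

    def test_fewer_than_two_detected_undefined(self):
        assert np.isnan(eco.population_variance([1.0, 0.0, 0.0]))


# -- beta diversity ---------------------------------------------------------


def _samples():
    out = []
    for participant in ("U1", "U2"):
        for site in ("PC", "DC", "STL"):
            out.append(
                SampleMeta(f"{participant}_{site}", participant, site, "MV")
            )
    return out


class TestBrayCurtis:
    def test_identical_profiles_distance_zero(self):
        prof = pd.DataFrame({"U1_PC": [0.5, 0.5], "U1_DC": [0.5, 0.5]})
        d = eco.bray_curtis_matrix(prof)
        assert d.at["U1_PC", "U1_DC"] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        prof = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert eco.bray_curtis_matrix(prof).at["a", "b"] == pytest.approx(1.0)

    def test_bounds_and_symmetry(self, rng):
        prof = pd.DataFrame(rng.random((15, 5)), columns=list("abcde"))
        d = eco.bray_curtis_matrix(prof).to_numpy()
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T, atol=1e-15)

    def test_oracle_equivalence(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 20))
            u, v = rng.random(n), rng.random(n)
            prof = pd.DataFrame({"u": u, "v": v})
            got = eco.bray_curtis_matrix(prof).at["u", "v"]
            assert got == pytest.approx(bray_curtis_oracle(u, v), abs=1e-12)

    def test_contrasts_structure(self, rng):
        profiles = pd.DataFrame(
            rng.random((40, 6)), columns=[s.sample_id for s in _samples()]
        )
        out = eco.bray_curtis_contrasts(profiles, _samples())
        pairs = out["pairs"]
        assert set(pairs["comparison"]) == {"intra", "inter"}
        assert len(pairs) == 15  # 6 choose 2
        assert out["pcoa"].shape == (6, 2)
        assert "intra_vs_inter" in out and "pcdc_vs_mlistl" in out

    def test_two_sample_minimum(self):
        with pytest.raises(ValidationError):
            eco.bray_curtis_contrasts(pd.DataFrame({"only": [1.0]}), _samples())


class TestSharedVCSets:
    def test_triple_overlap_counted(self):
        detection = pd.DataFrame(
            {
                "U1_PC": [True, True, False],
                "U1_DC": [True, False, False],
                "U1_STL": [True, False, True],
            },
            index=["v1", "v2", "v3"],
        )
        samples = [
            SampleMeta("U1_PC", "U1", "PC", "MV"),
            SampleMeta("U1_DC", "U1", "DC", "MV"),
            SampleMeta("U1_STL", "U1", "STL", "MV"),
        ]
        out = eco.shared_vc_sets(detection, samples).set_index("participant")
        assert out.at["U1", "PC|DC|STL"] == 1
        assert out.at["U1", "PC"] == 1  # v2 only in PC
        assert out.at["U1", "STL"] == 1  # v3 only in STL

    def test_regions_sum_to_total(self, rng):
        cols = ["U1_PC", "U1_DC", "U1_STL"]
        detection = pd.DataFrame(
            rng.random((200, 3)) < 0.5, columns=cols, index=[f"v{i}" for i in range(200)]
        )
        samples = [SampleMeta(c, "U1", c.split("_")[1], "MV") for c in cols]
        out = eco.shared_vc_sets(detection, samples).iloc[0]
        region_cols = ["PC", "DC", "STL", "PC|DC", "PC|STL", "DC|STL", "PC|DC|STL"]
        assert sum(out[c] for c in region_cols) == out["n_total"]

    def test_missing_site_reduced_partition(self):
        detection = pd.DataFrame({"U1_PC": [True], "U1_DC": [True]}, index=["v1"])
        samples = [
            SampleMeta("U1_PC", "U1", "PC", "MV"),
            SampleMeta("U1_DC", "U1", "DC", "MV"),
        ]
        out = eco.shared_vc_sets(detection, samples).iloc[0]
        assert bool(out["reduced"])
        assert np.isnan(out["PC|DC|STL"])

    def test_planted_triple_share_recovered(self, rng):
        n = 500
        triple = rng.random(n) < 0.30
        cols = ["U1_PC", "U1_DC", "U1_STL"]
        data = {}
        for c in cols:
            site_only = rng.random(n) < 0.4
            data[c] = triple | site_only
        detection = pd.DataFrame(data, index=[f"v{i}" for i in range(n)])
        samples = [SampleMeta(c, "U1", c.split("_")[1], "MV") for c in cols]
        out = eco.shared_vc_sets(detection, samples).iloc[0]
        frac = out["PC|DC|STL"] / out["n_total"]
        # 0.30 planted plus the small chance of random triple co-detection
        expected = (0.30 + 0.70 * 0.4**3) / (1 - 0.70 * 0.6**3)
        assert frac == pytest.approx(expected, abs=0.05)


class TestHostPairCorrelations:
    def _profiles(self, rng, n_pairs=10, coupled=True):
        cols = [f"U{p}_{s}" for p in (1, 2, 3) for s in ("PC", "DC", "STL")]
        vc_rows, host_rows, pairs = {}, {}, []
        for i in range(n_pairs):
            host = rng.lognormal(0, 1, len(cols))
            vc = host * np.exp(rng.normal(0, 0.2, len(cols))) if coupled else rng.lognormal(0, 1, len(cols))
            vc_rows[f"v{i}"] = vc
            host_rows[f"h{i}"] = host
            pairs.append((f"v{i}", f"h{i}"))
        nra_vc = pd.DataFrame(vc_rows, index=cols).T
        nra_host = pd.DataFrame(host_rows, index=cols).T
        sample_pairs = [(c, c) for c in cols]
        return nra_vc, nra_host, pairs, sample_pairs

    def test_identical_profiles_rho_one(self, rng):
        nra_vc, nra_host, pairs, sample_pairs = self._profiles(rng, n_pairs=3)
        nra_vc.loc["v0"] = nra_host.loc["h0"].to_numpy()
        out = eco.host_pair_correlations(nra_vc, nra_host, pairs, sample_pairs, n_null=50, seed=0)
        assert max(out["matched_rho"]) == pytest.approx(1.0)

    def test_null_median_near_zero(self, rng):
        nra_vc, nra_host, pairs, sample_pairs = self._profiles(rng, n_pairs=30, coupled=False)
        out = eco.host_pair_correlations(
            nra_vc, nra_host, pairs, sample_pairs, n_null=1000, seed=1
        )
        assert abs(out["median_null"]) < 0.1

    def test_matched_above_null_when_coupled(self, rng):
        nra_vc, nra_host, pairs, sample_pairs = self._profiles(rng, n_pairs=20, coupled=True)
        out = eco.host_pair_correlations(nra_vc, nra_host, pairs, sample_pairs, n_null=300, seed=2)
        assert out["median_matched"] > out["median_null"]
        assert out["p_value"] < 0.01

    def test_too_few_pairs_rejected(self, rng):
        nra_vc, nra_host, pairs, sample_pairs = self._profiles(rng, n_pairs=1)
        with pytest.raises(ValidationError):
            eco.host_pair_correlations(nra_vc, nra_host, pairs, sample_pairs)

    def test_too_few_samples_rejected(self, rng):
        nra_vc, nra_host, pairs, _ = self._profiles(rng, n_pairs=5)
        with pytest.raises(ValidationError):
            eco.host_pair_correlations(nra_vc, nra_host, pairs, [("U1_PC", "U1_PC")])
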