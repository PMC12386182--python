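"""Differential-expression stage: filters, TMM, dispersion, exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import binom

from lightmeta.datamodel import ValidationError
from lightmeta.de import (
    Contrast,
    bh_adjust,
    build_contrasts,
    call_degs,
    cpm,
    estimate_common_dispersion,
    exact_nb_pvalue,
    filter_low_expression,
    nb_exact_test,
    tmm_factors,
)
from tests.conftest import make_sample


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_exact_pvalue(y_a, y_b, n_a, n_b, phi):
    """Enumerate the conditional two-group NB pmf directly.

    P(Y_b = k | Y_a + Y_b = s) for Y_g ~ NB(mean n_g mu, dispersion phi/n_g);
    p-value sums probabilities <= that of the observed split.
    """
    s = y_a + y_b
    if s == 0:
        return 1.0
    ks = np.arange(s + 1)
    if phi == 0:
        pmf = binom.pmf(ks, s, n_b / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        # joint product of the two NB pmfs; mean-dependent factors are common
        logw = (gammaln(ks + r_b) - gammaln(ks + 1)
                + gammaln(s - ks + r_a) - gammaln(s - ks + 1))
        logw -= logw.max()
        w = np.exp(logw)
        pmf = w / w.sum()
    obs = pmf[y_b]
    return min(1.0, float(pmf[pmf <= obs * (1 + 1e-10)].sum()))


def oracle_tmm_pair(y_k, y_r, trim_m=0.3, trim_a=0.05):
    """Step-by-step trimmed weighted mean of M-values for one library pair."""
    y_k, y_r = np.asarray(y_k, float), np.asarray(y_r, float)
    n_k, n_r = y_k.sum(), y_r.sum()
    ok = (y_k > 0) & (y_r > 0)
    yk, yr = y_k[ok], y_r[ok]
    m = np.log2((yk / n_k) / (yr / n_r))
    a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
    w = 1.0 / ((n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr))
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


# ---------------------------------------------------------------------------
# low-expression filter
# ---------------------------------------------------------------------------

class TestFilterLowExpression:
    def _mat(self, low_in):
        """4-sample matrix where the test gene is below 1 CPM in `low_in` samples."""
        base = np.full((1, 4), 2_000_000, dtype=float)  # sets library size ~2e6
        gene = np.full(4, 10.0)          # 10/2e6*1e6 = 5 CPM
        gene[:low_in] = 1.0              # 0.5 CPM -> below threshold
        return np.vstack([gene, base])

    def test_all_zero_gene_dropped(self):
        mat = np.vstack([np.zeros(4), np.full(4, 100.0)])
        assert not filter_low_expression(mat)[0]

    @pytest.mark.parametrize("low_in,kept", [(0, True), (2, True), (3, False), (4, False)])
    def test_more_than_half_boundary(self, low_in, kept):
        mask = filter_low_expression(self._mat(low_in))
        assert mask[0] == kept

    def test_zero_library_named(self):
        mat = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValidationError, match="sB"):
            filter_low_expression(mat, sample_ids=["sA", "sB"])


# ---------------------------------------------------------------------------
# TMM and CPM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_libraries_factor_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, size=50).astype(float)
        mat = np.column_stack([col, col, col])
        assert np.allclose(tmm_factors(mat), 1.0, atol=1e-12)

    def test_pure_depth_scaling_factor_one(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 500, size=50).astype(float)
        mat = np.column_stack([col, 10 * col])
        assert np.allclose(tmm_factors(mat), 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 300, size=(200, 5)).astype(float)
        f = tmm_factors(mat)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_composition_bias_matches_hand_oracle(self):
        # library B equals A except one gene carrying ~30% of B's reads
        rng = np.random.default_rng(4)
        a = rng.integers(50, 150, size=20).astype(float)
        b = a.copy()
        b[0] = 0.45 * a.sum()  # dominant transcript
        mat = np.column_stack([a, b])
        f = tmm_factors(mat)
        ref = int(np.argmin(np.abs(
            np.array([np.quantile(mat[:, j], .75) for j in range(2)]) / mat.sum(0)
            - (np.array([np.quantile(mat[:, j], .75) for j in range(2)]) / mat.sum(0)).mean()
        )))
        other = 1 - ref
        raw = oracle_tmm_pair(mat[:, other], mat[:, ref])
        expected = np.array([1.0, 1.0])
        expected[other] = raw
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f, expected, rtol=1e-10)
        assert f[1] < f[0]  # composition-biased library is scaled down

    def test_cpm_arithmetic(self):
        counts = np.array([[5.0], [10.0], [0.0]])
        out = cpm(counts, np.array([1e6]), np.array([1.0]))
        assert out[0, 0] == pytest.approx(5.0)
        out2 = cpm(np.array([[10.0]]), np.array([2e6]), np.array([2.0]))
        assert out2[0, 0] == pytest.approx(2.5)
        assert out[2, 0] == 0.0


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def _simulate(self, phi, n_genes=2000, n=6, seed=0):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(4, 1, size=n_genes))[:, None] * np.ones(n)
        if phi == 0:
            counts = rng.poisson(mu)
        else:
            r = 1 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
        return counts.astype(float)

    def test_poisson_counts_estimate_near_zero(self):
        counts = self._simulate(0.0)
        est = estimate_common_dispersion(counts, ["g"] * 6)
        assert est <= 0.01

    def test_nb_dispersion_recovered(self):
        counts = self._simulate(0.4, seed=1)
        est = estimate_common_dispersion(counts, ["g"] * 6)
        assert 0.25 <= est <= 0.6

    def test_degenerate_input_hits_floor(self):
        counts = np.full((1, 4), 7.0)
        assert estimate_common_dispersion(counts, ["g"] * 4) == pytest.approx(1e-6)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_symmetric_case_p_one(self):
        assert exact_nb_pvalue(10, 10, 2, 2, 0.1) == pytest.approx(1.0)

    def test_binomial_limit_0_vs_10(self):
        # 1v1 samples, phi ~ 0: reduces to a fair binomial two-tail
        p = exact_nb_pvalue(0, 10, 1, 1, 1e-9)
        assert p == pytest.approx(2 * 0.5 ** 10, rel=1e-6)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5, 2.0])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(5)
        for _ in range(60):
            s = int(rng.integers(1, 201))
            y_b = int(rng.integers(0, s + 1))
            n_a, n_b = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            ours = exact_nb_pvalue(s - y_b, y_b, n_a, n_b, phi)
            oracle = oracle_exact_pvalue(s - y_b, y_b, n_a, n_b, phi)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_zero_total_p_one_lfc_zero(self):
        res = nb_exact_test(
            np.zeros((1, 2)), np.zeros((1, 2)),
            np.full(4, 1e6), np.ones(4), 0.1,
        )
        assert res["pvalue"].iloc[0] == 1.0
        assert res["logFC"].iloc[0] == 0.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            exact_nb_pvalue(1, 2, 1, 1, -0.5)

    def test_depth_doubling_preserves_logfc(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 200, size=(50, 3)).astype(float)
        b = rng.integers(0, 200, size=(50, 3)).astype(float)
        lib = np.full(6, 1e5)
        r1 = nb_exact_test(a, b, lib, np.ones(6), 0.1)
        r2 = nb_exact_test(2 * a, 2 * b, 2 * lib, np.ones(6), 0.1)
        assert np.allclose(r1["logFC"], r2["logFC"], atol=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment and DEG calling
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        out = bh_adjust([0.005, 0.011, 0.02, 0.04])
        assert np.allclose(out, [0.02, 0.022, 0.0266667, 0.04], atol=1e-6)

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, np.nan])


class TestCallDegs:
    @pytest.mark.parametrize("lfc,fdr_like,expected", [
        (0.6, 0.04, "up"),
        (0.4, 0.001, "ns"),       # fold-change gate fails despite tiny FDR
        (-0.5, 0.05, "down"),     # thresholds are inclusive
    ])
    def test_threshold_rules(self, lfc, fdr_like, expected):
        res = pd.DataFrame({"pvalue": [fdr_like], "logFC": [lfc], "logCPM": [5.0]})
        recs = call_degs(res, "c1", ["g1"])
        assert recs[0].direction == expected
        assert recs[0].FDR >= recs[0].pvalue


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

class TestContrasts:
    def test_time_matched_strategy(self):
        samples = [
            make_sample("c6", cond="E1_CTRL_6", duration=360.0, control=True),
            make_sample("c12", cond="E1_CTRL_12", duration=720.0, control=True),
            make_sample("s6", cond="E1_HL_6", duration=360.0),
            make_sample("s12", cond="E1_HL_12", duration=720.0),
        ]
        contrasts = {c.condition_id: c for c in build_contrasts(samples)}
        assert len(contrasts) == 2
        assert contrasts["E1_HL_6"].strategy == "time_matched"
        assert contrasts["E1_HL_6"].control_sample_ids == ["c6"]
        assert contrasts["E1_HL_12"].control_sample_ids == ["c12"]

    def test_common_control_strategy(self):
        samples = [make_sample("c", cond="E1_CTRL", duration=0.0, control=True)]
        for i, dur in enumerate((30.0, 60.0, 360.0)):
            samples.append(make_sample(f"s{i}", cond=f"E1_HL_{i}", duration=dur))
        contrasts = build_contrasts(samples)
        assert len(contrasts) == 3
        assert all(c.strategy == "common_control" for c in contrasts)
        assert all(c.control_sample_ids == ["c"] for c in contrasts)

    def test_no_controls_is_error(self):
        with pytest.raises(ValidationError):
            build_contrasts([make_sample("s1")])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            Contrast("c", ["a"], ["a"], "common_control")
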