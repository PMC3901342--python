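import math
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnaforge.quantify import (
    build_counts,
    call_de,
    de_test,
    normalize,
    tmm_factor,
    tmm_pair_factors,
)


def direct_tmm(a, b, trim_m=0.30, trim_a=0.05):
    """Straight transcription of the TMM definition, no shared code paths."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.sum(), b.sum()
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    m = np.log2((a / na) / (b / nb))
    avg = 0.5 * np.log2((a / na) * (b / nb))
    w = 1.0 / ((na - a) / (na * a) + (nb - b) / (nb * b))
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    lo_a = math.floor(n * trim_a) + 1
    rm = stats.rankdata(m)
    ra = stats.rankdata(avg)
    keep2 = (
        (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    )
    return 2.0 ** ((w[keep2] * m[keep2]).sum() / w[keep2].sum())


class TestBuildCounts:
    def test_isomir_counts_sum_per_product(self):
        assignments = pd.DataFrame(
            [
                {"product_id": "g1|mature", "count_f3": 2, "count_f4": 0},
                {"product_id": "g1|mature", "count_f3": 7, "count_f4": 1},
                {"product_id": "g1|star", "count_f3": 1, "count_f4": 5},
            ]
        )
        counts, lib = build_counts(assignments)
        assert counts.loc["g1|mature", "raw_f3"] == 9
        assert counts.loc["g1|star", "raw_f3"] == 1  # star independent
        assert (lib["F3"], lib["F4"]) == (10, 6)

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            build_counts(pd.DataFrame(columns=["product_id", "count_f3", "count_f4"]))


class TestTmm:
    def test_identical_libraries_give_unit_factor(self):
        c = np.array([100, 50, 3, 800, 20])
        assert tmm_factor(c, c) == pytest.approx(1.0)

    def test_pure_depth_difference_gives_unit_factor(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 1000, size=200)
        assert tmm_factor(a, 2 * a) == pytest.approx(1.0)

    def test_composition_bias_recovered_vs_direct_formula(self):
        rng = np.random.default_rng(2)
        a = rng.integers(10, 500, size=300).astype(float)
        b = a.copy()
        b[:30] *= 8  # 10% of genes inflated in library b
        f = tmm_factor(a, b)
        assert f == pytest.approx(direct_tmm(a, b), rel=0.05)
        assert f != pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_matrices_match_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.poisson(rng.uniform(5, 300, size=150)) + 1
        b = rng.poisson(rng.uniform(5, 300, size=150)) + 1
        assert tmm_factor(a, b) == pytest.approx(direct_tmm(a, b), rel=0.05)

    def test_pair_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 500, size=100)
        b = rng.integers(1, 500, size=100)
        f3, f4 = tmm_pair_factors(a, b)
        assert f3 * f4 == pytest.approx(1.0)

    def test_no_shared_genes_gives_unit_factor(self):
        assert tmm_factor([0, 5, 0], [3, 0, 2]) == 1.0

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent cross-check against the reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(4)
        a = rng.poisson(rng.uniform(5, 400, size=200)) + 1
        b = (rng.poisson(rng.uniform(5, 400, size=200)) + 1)
        b[:20] *= 6
        mat = tmp_path / "counts.tsv"
        pd.DataFrame({"a": a, "b": b}).to_csv(mat, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.delim('{mat}'))\n"
            "f <- calcNormFactors(x, method='TMM')\n"
            "cat(f[1]/f[2])\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        edger_ratio = float(out.stdout.strip())
        ours = tmm_factor(a, b)
        f3, f4 = tmm_pair_factors(a, b)
        assert f3 / f4 == pytest.approx(edger_ratio, rel=0.05)
        assert ours == pytest.approx(edger_ratio, rel=0.05)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,size,factor,expected",
        [(500, 1e6, 1.0, 500.0), (500, 2e6, 1.0, 250.0), (100, 1e6, 0.8, 125.0)],
    )
    def test_formula(self, raw, size, factor, expected):
        assert normalize(raw, size, factor) == pytest.approx(expected)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            normalize(10, 0, 1.0)


class TestDeTest:
    def test_symmetric_counts_give_p_one(self):
        assert de_test(100, 100, 1e6, 1e6) == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        assert de_test(3, 10, 1e6, 1e6) == pytest.approx(de_test(10, 3, 1e6, 1e6))

    def test_extreme_zero_vs_large_is_significant(self):
        # the printed miR-21 contrast: 0 vs 83,244 reads
        assert de_test(0, 83_244, 1e6, 1e6) < 0.001

    def test_equals_full_enumeration(self):
        k1, k2 = 3, 10
        n, p0 = k1 + k2, 0.5
        p_obs = stats.binom.pmf(k1, n, p0)
        expected = sum(
            stats.binom.pmf(k, n, p0)
            for k in range(n + 1)
            if stats.binom.pmf(k, n, p0) <= p_obs * (1 + 1e-9)
        )
        assert de_test(k1, k2, 1e6, 1e6) == pytest.approx(expected)

    def test_unequal_library_sizes_shift_the_null(self):
        # 200 vs 100 reads is exactly proportional to 2:1 library sizes
        assert de_test(200, 100, 2e6, 1e6) > 0.5

    def test_normal_approximation_agrees_at_switch_boundary(self):
        from srnaforge import quantify

        for k1 in (4_700, 4_900, 5_000, 5_150):
            n = 10_000
            exact = float(stats.binomtest(k1, n, 0.5).pvalue)
            mu, sd = n * 0.5, math.sqrt(n * 0.25)
            z = (abs(k1 - mu) - 0.5) / sd
            approx = min(1.0, 2 * stats.norm.sf(max(z, 0.0)))
            if exact > 1e-6:
                assert approx == pytest.approx(exact, rel=5e-3)

    def test_double_zero_is_one_by_convention(self):
        assert de_test(0, 0, 1e6, 1e6) == 1.0

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k1, k2 = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            if k1 + k2 == 0:
                continue
            p = de_test(k1, k2, 1e6, 1.3e6)
            assert 0 < p <= 1


class TestCallDe:
    def _frame(self, rows):
        return pd.DataFrame(rows).set_index("product_id")

    def test_exact_twofold_is_not_called(self):
        # fold change must strictly exceed 2-fold, however small the p-value
        counts = self._frame(
            [{"product_id": "a", "raw_f3": 20_000, "raw_f4": 10_000},
             # balancer equalises column sums so the TMM factor is exactly 1
             {"product_id": "bal", "raw_f3": 0, "raw_f4": 10_000}]
            + [
                {"product_id": f"bg{i}", "raw_f3": 1000, "raw_f4": 1000}
                for i in range(50)
            ]
        )
        de = call_de(counts, pd.Series({"F3": 10**6, "F4": 10**6}))
        row = de.loc["a"]
        assert row["log2fc"] == pytest.approx(1.0, abs=1e-9)
        assert row["pvalue"] < 1e-9 and row["call"] == "ns"

    def test_strong_fold_and_p_called_up(self):
        counts = self._frame(
            [{"product_id": "a", "raw_f3": 4_960, "raw_f4": 1_000},
             {"product_id": "bal", "raw_f3": 0, "raw_f4": 3_960}]
            + [
                {"product_id": f"bg{i}", "raw_f3": 1000, "raw_f4": 1000}
                for i in range(50)
            ]
        )
        de = call_de(counts, pd.Series({"F3": 10**6, "F4": 10**6}))
        row = de.loc["a"]
        assert row["log2fc"] == pytest.approx(math.log2(4.96), abs=1e-6)
        assert row["call"] == "up"

    def test_weak_p_not_called(self):
        counts = self._frame(
            [{"product_id": "a", "raw_f3": 12, "raw_f4": 4}]
            + [
                {"product_id": f"bg{i}", "raw_f3": 1000, "raw_f4": 1000}
                for i in range(20)
            ]
        )
        de = call_de(counts, pd.Series({"F3": 10**6, "F4": 10**6}))
        assert de.loc["a", "call"] == "ns" and de.loc["a", "pvalue"] > 0.001

    def test_zero_count_uses_pseudocount_display_but_exact_test(self):
        counts = self._frame(
            [{"product_id": "a", "raw_f3": 0, "raw_f4": 5_000}]
            + [
                {"product_id": f"bg{i}", "raw_f3": 1000, "raw_f4": 1000}
                for i in range(20)
            ]
        )
        de = call_de(counts, pd.Series({"F3": 10**6, "F4": 10**6}))
        row = de.loc["a"]
        assert row["call"] == "down" and math.isfinite(row["log2fc"])


class TestCalibrationAndPower:
    def test_null_rate_within_binomial_interval(self):
        """With no true effect, p < 0.001 should fire at its nominal rate."""
        rng = np.random.default_rng(17)
        n = 5_000
        means = rng.uniform(500, 3000, size=n)
        hits = 0
        for m in means:
            k1, k2 = rng.poisson(m), rng.poisson(m)
            if de_test(int(k1), int(k2), 1e6, 1e6) < 0.001:
                hits += 1
        lo = stats.binom.ppf(0.005, n, 0.001)
        hi = stats.binom.ppf(0.995, n, 0.001)
        assert lo <= hits <= hi

    def test_planted_fourfold_changes_recovered(self):
        """|log2FC| = 2 at mean >= 200 reads: >= 95% called, right direction."""
        rng = np.random.default_rng(23)
        rows = []
        truth = {}
        for i in range(200):
            base = rng.uniform(200, 2000)
            direction = 1 if rng.random() < 0.5 else -1
            m3, m4 = base * 2.0**direction, base / 2.0**direction
            rows.append(
                {"product_id": f"p{i}", "raw_f3": rng.poisson(m3),
                 "raw_f4": rng.poisson(m4)}
            )
            truth[f"p{i}"] = "up" if direction > 0 else "down"
        for i in range(800):  # null background keeps TMM honest
            m = rng.uniform(50, 2000)
            rows.append(
                {"product_id": f"n{i}", "raw_f3": rng.poisson(m),
                 "raw_f4": rng.poisson(m)}
            )
        counts = pd.DataFrame(rows).set_index("product_id")
        de = call_de(counts)
        planted = de.loc[list(truth)]
        called = planted[planted["call"] != "ns"]
        assert len(called) / len(planted) >= 0.95
        assert all(called.loc[pid, "call"] == truth[pid] for pid in called.index)
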