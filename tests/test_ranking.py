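import math

import numpy as np
import pandas as pd
import pytest

from tftea.io import CountMatrix
from tftea.ranking import (RankedList, differential_rank, normalize, read_rank,
                           tmm_factors, welch_t, write_rank)


def brute_tmm(counts: np.ndarray, ref_idx: int,
              log_ratio_trim: float = 0.30, sum_trim: float = 0.05) -> np.ndarray:
    """Scalar-loop transcription of the trim-and-weight definition of the
    trimmed mean of M-values, independent of the vectorized route."""
    lib = counts.sum(axis=0).astype(float)
    factors = []
    for j in range(counts.shape[1]):
        pairs = [(float(o), float(r))
                 for o, r in zip(counts[:, j], counts[:, ref_idx])
                 if o > 0 and r > 0]
        m_vals = [math.log2((o / lib[j]) / (r / lib[ref_idx])) for o, r in pairs]
        a_vals = [0.5 * math.log2((o / lib[j]) * (r / lib[ref_idx]))
                  for o, r in pairs]
        var = [(lib[j] - o) / (lib[j] * o) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
               for o, r in pairs]
        if all(abs(m) < 1e-10 for m in m_vals):
            factors.append(1.0)
            continue
        n = len(m_vals)

        def midranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            out = [0.0] * n
            i = 0
            while i < n:
                j2 = i
                while j2 + 1 < n and vals[order[j2 + 1]] == vals[order[i]]:
                    j2 += 1
                for k in range(i, j2 + 1):
                    out[order[k]] = (i + j2) / 2 + 1
                i = j2 + 1
            return out

        rm, ra = midranks(m_vals), midranks(a_vals)
        lo_m = math.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                w = 1.0 / var[i]
                num += w * m_vals[i]
                den += w
        factors.append(2.0 ** (num / den) if den else 1.0)
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5], [40]]), (1, 2))
        cm = CountMatrix(["g1", "g2", "g3", "g4"], ["a", "b"], counts)
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0)

    def test_uniform_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 200, size=30)
        counts = np.column_stack([base, 2 * base])
        cm = CountMatrix([f"g{i}" for i in range(30)], ["a", "b"], counts)
        f = tmm_factors(cm)
        assert f["b"] / f["a"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_with_amplified_genes(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(4, 1, 50)
        counts = rng.negative_binomial(5, 5 / (5 + mu[:, None]), size=(50, 4))
        counts[:10, 2] *= 8  # one sample with 10 strongly amplified genes
        cm = CountMatrix([f"g{i}" for i in range(50)], list("abcd"), counts)
        lib = counts.sum(axis=0)
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                        for j in range(4)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(),
                                   brute_tmm(counts, ref), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_equivalence_random_nb(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(3.5, 1.3, 120)
        counts = rng.negative_binomial(4, 4 / (4 + mu[:, None]), size=(120, 5))
        cm = CountMatrix([f"g{i}" for i in range(120)], list("abcde"), counts)
        lib = counts.sum(axis=0)
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                        for j in range(5)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(),
                                   brute_tmm(counts, ref), atol=1e-8)

    def test_zero_library_rejected_with_name(self):
        counts = np.array([[5, 0], [3, 0]])
        cm = CountMatrix(["g1", "g2"], ["ok", "empty"], counts)
        with pytest.raises(ValueError, match="empty"):
            tmm_factors(cm)


class TestNormalize:
    def test_all_zero_gene_constant_row(self, small_counts):
        counts = small_counts.counts.copy()
        counts[0, :] = 0
        cm = CountMatrix(small_counts.gene_ids, small_counts.sample_ids, counts)
        norm = normalize(cm)
        lib = counts.sum(axis=0) * tmm_factors(cm).to_numpy()
        expected = np.log2(0.5 / (lib + 1) * 1e6)
        np.testing.assert_allclose(norm.iloc[0].to_numpy(), expected)

    def test_scale_invariance_under_doubling(self, small_counts):
        doubled = CountMatrix(small_counts.gene_ids, small_counts.sample_ids,
                              2 * small_counts.counts)
        a = normalize(small_counts).to_numpy()
        b = normalize(doubled).to_numpy()
        # exact only without the prior count; the 0.5 prior shifts
        # low-count cells by up to ~0.1 log2 units at these depths
        np.testing.assert_allclose(a, b, atol=0.15)
        high = small_counts.counts >= 20
        np.testing.assert_allclose(a[high], b[high], atol=2e-2)

    def test_spot_value_formula(self, small_counts):
        norm = normalize(small_counts)
        f = tmm_factors(small_counts)
        lib_eff = small_counts.counts.sum(axis=0) * f.to_numpy()
        g, s = 7, 2
        expected = np.log2((small_counts.counts[g, s] + 0.5)
                           / (lib_eff[s] + 1.0) * 1e6)
        assert norm.iloc[g, s] == pytest.approx(expected, rel=1e-12)


class TestDifferentialRank:
    def _norm(self, seed=4, n=40):
        rng = np.random.default_rng(seed)
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        return pd.DataFrame(rng.normal(5, 1, (n, 6)),
                            index=[f"g{i:02d}" for i in range(n)], columns=cols)

    def test_identical_groups_statistic_zero(self):
        norm = self._norm()
        norm.iloc[5] = 3.0  # constant everywhere
        ranked = differential_rank(norm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        idx = ranked.gene_ids.index("g05")
        assert ranked.statistic[idx] == 0.0

    def test_label_reversal_negates_and_reverses(self):
        norm = self._norm()
        fwd = differential_rank(norm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        rev = differential_rank(norm, ["b0", "b1", "b2"], ["a0", "a1", "a2"])
        np.testing.assert_allclose(np.sort(rev.statistic),
                                   np.sort(-fwd.statistic), atol=1e-12)
        # statistics are all distinct here, so order exactly reverses
        assert rev.gene_ids == list(reversed(fwd.gene_ids))

    def test_planted_genes_take_top_ranks(self):
        rng = np.random.default_rng(8)
        norm = pd.DataFrame(rng.normal(5, 0.05, (100, 8)),
                            index=[f"g{i:03d}" for i in range(100)],
                            columns=[f"a{i}" for i in range(4)]
                                    + [f"b{i}" for i in range(4)])
        planted = [f"g{i:03d}" for i in range(10)]
        norm.loc[planted, ["a0", "a1", "a2", "a3"]] += 2.0
        ranked = differential_rank(norm, [f"a{i}" for i in range(4)],
                                   [f"b{i}" for i in range(4)])
        assert set(ranked.gene_ids[:10]) == set(planted)

    def test_sample_order_within_groups_irrelevant(self):
        norm = self._norm()
        r1 = differential_rank(norm, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        r2 = differential_rank(norm, ["a2", "a0", "a1"], ["b1", "b2", "b0"])
        assert r1.gene_ids == r2.gene_ids
        np.testing.assert_allclose(r1.statistic, r2.statistic)

    def test_small_group_rejected(self):
        norm = self._norm()
        with pytest.raises(ValueError, match=">=2"):
            welch_t(norm, ["a0"], ["b0", "b1", "b2"])


class TestRankedList:
    def test_tie_break_is_lexicographic(self):
        ranked = RankedList.from_statistics({"z": 1.0, "a": 1.0, "m": 2.0})
        assert ranked.gene_ids == ["m", "a", "z"]

    def test_non_monotone_input_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            RankedList(["a", "b"], np.array([1.0, 2.0]))

    def test_rank_file_round_trip(self, tmp_path):
        ranked = RankedList.from_statistics({"a": 2.5, "b": -1.0, "c": 0.0})
        path = tmp_path / "rank.tsv"
        write_rank(ranked, path)
        back = read_rank(path)
        assert back.gene_ids == ranked.gene_ids
        np.testing.assert_allclose(back.statistic, ranked.statistic)
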