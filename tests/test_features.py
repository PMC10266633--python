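import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcwgbs import Methylome
from rcwgbs.features import (
    CHAIN_K,
    PAD_LEVEL,
    WINDOW_LENGTH,
    assemble_features,
    encode_2mer,
    encode_onehot,
    neighbor_average,
    neighbor_chain,
)


def _bits(code):
    return [(code >> 3) & 1, (code >> 2) & 1, (code >> 1) & 1, code & 1]


class TestTwoMerEncoding:
    def test_all_sixteen_codes_match_lexicographic_enumeration(self):
        """Brute-force oracle: sorted dinucleotides enumerate codes 0..15."""
        dinucs = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        assert dinucs == sorted(dinucs)  # lexicographic by construction
        seen = set()
        for code, dinuc in enumerate(dinucs):
            window = dinuc + "A" * (WINDOW_LENGTH - 2)
            col = encode_2mer(window)[:, 0].tolist()
            assert col == _bits(code), f"{dinuc} -> {col}"
            seen.add(tuple(col))
        assert len(seen) == 16  # injective

    @pytest.mark.parametrize(
        "dinuc,col",
        [("AA", [0, 0, 0, 0]), ("TT", [1, 1, 1, 1]), ("GA", [1, 0, 0, 0])],
    )
    def test_printed_examples(self, dinuc, col):
        window = dinuc + "C" * (WINDOW_LENGTH - 2)
        assert encode_2mer(window)[:, 0].tolist() == col

    def test_overlapping_step_one(self):
        window = "ACGT" + "A" * (WINDOW_LENGTH - 4)
        m = encode_2mer(window)
        assert m.shape == (4, 100)
        assert m[:, 0].tolist() == _bits(1)   # AC
        assert m[:, 1].tolist() == _bits(6)   # CG
        assert m[:, 2].tolist() == _bits(11)  # GT

    def test_n_column_zeroed(self):
        window = "AN" + "A" * (WINDOW_LENGTH - 2)
        m = encode_2mer(window)
        assert m[:, 0].tolist() == [0, 0, 0, 0]
        assert m[:, 1].tolist() == [0, 0, 0, 0]  # NA also contains the N
        assert m[:, 2].tolist() == [0, 0, 0, 0]  # AA

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="101"):
            encode_2mer("ACGT")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=WINDOW_LENGTH, max_size=WINDOW_LENGTH))
    def test_columns_decode_back_to_dinucleotides(self, window):
        m = encode_2mer(window)
        order = "ACGT"
        for i in range(100):
            code = int("".join(str(b) for b in m[:, i]), 2)
            assert order[code // 4] + order[code % 4] == window[i : i + 2]


class TestOneHot:
    @pytest.mark.parametrize(
        "base,col",
        [("A", [0, 0, 0, 1]), ("C", [0, 0, 1, 0]), ("G", [0, 1, 0, 0]),
         ("T", [1, 0, 0, 0]), ("N", [0, 0, 0, 0])],
    )
    def test_per_base_mapping(self, base, col):
        assert encode_onehot(base)[:, 0].tolist() == col

    def test_non_n_columns_sum_to_one(self):
        m = encode_onehot("ACGTACGT")
        assert np.all(m.sum(axis=0) == 1)

    def test_unknown_base_rejected(self):
        with pytest.raises(ValueError):
            encode_onehot("ACGX")


class TestNeighborChain:
    def _methylome(self, pos, meth, unmeth):
        return Methylome({"chr1": (np.array(pos), np.array(meth), np.array(unmeth))})

    def test_first_site_pads_upstream_half(self):
        pos = list(range(10, 10 + 4 * 60, 4))  # 60 covered sites
        m = self._methylome(pos, [1] * 60, [1] * 60)
        chain, mask = neighbor_chain(m, "chr1", 10, return_mask=True)
        assert np.all(chain[:CHAIN_K] == PAD_LEVEL)
        assert not mask[:CHAIN_K].any()
        assert mask[CHAIN_K:].all()

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(10, 5000), size=300, replace=False))
        cov = rng.integers(0, 5, size=300)
        meth = rng.binomial(cov, 0.5)
        m = self._methylome(pos, meth, cov - meth)
        covered = [(int(p), mm / c) for p, mm, c in zip(pos, meth, cov) if c > 0]
        for target in [int(pos[0]), int(pos[150]), int(pos[-1]), 2501]:
            chain = neighbor_chain(m, "chr1", target)
            left = [lv for p, lv in covered if p < target][-CHAIN_K:]
            right = [lv for p, lv in covered if p > target][:CHAIN_K]
            expected = (
                [PAD_LEVEL] * (CHAIN_K - len(left)) + left
                + right + [PAD_LEVEL] * (CHAIN_K - len(right))
            )
            np.testing.assert_allclose(chain, expected)

    def test_target_level_never_leaks_into_chain(self):
        # the target has a unique level; it must not appear in its own chain
        pos = list(range(100, 100 + 4 * 120, 4))
        meth = [1] * 120
        meth[60] = 9  # unique level 0.9 at the target
        unmeth = [9] * 120
        unmeth[60] = 1
        m = self._methylome(pos, meth, unmeth)
        chain = neighbor_chain(m, "chr1", pos[60])
        assert not np.any(np.isclose(chain, 0.9))

    def test_uncovered_sites_skipped(self):
        pos = [10, 20, 30, 40, 50]
        m = self._methylome(pos, [1, 0, 5, 0, 1], [0, 0, 5, 0, 0])
        chain = neighbor_chain(m, "chr1", 30, k=2)
        # covered neighbors are 10 (level 1.0) and 50 (level 1.0); 20/40 uncovered
        np.testing.assert_allclose(chain, [PAD_LEVEL, 1.0, 1.0, PAD_LEVEL])


class TestNeighborAverage:
    def test_constant_and_simple_means(self):
        assert neighbor_average(np.full(100, 0.5)) == 0.5
        assert neighbor_average(np.array([0.0, 1.0])) == 0.5

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        chain = rng.random(100)
        assert neighbor_average(chain) == pytest.approx(chain.sum() / 100, abs=1e-12)

    def test_all_padding_is_undefined(self):
        chain = np.full(4, PAD_LEVEL)
        assert np.isnan(neighbor_average(chain, mask=np.zeros(4, dtype=bool)))


class TestAssembleFeatures:
    def test_shape_and_composition(self, small_dataset):
        genome, _, methylome = small_dataset
        sites = [("chrSim", int(p)) for p in methylome.positions("chrSim")[100:105]]
        X, n_bad = assemble_features(genome, methylome, sites)
        assert X.shape == (5, 5, 100, 1)
        assert n_bad.shape == (5,)
        for i, (chrom, pos) in enumerate(sites):
            window = genome.window(chrom, pos, 50)
            np.testing.assert_array_equal(X[i, :4, :, 0], encode_2mer(window))
            np.testing.assert_allclose(
                X[i, 4, :, 0], neighbor_chain(methylome, chrom, pos), atol=1e-7
            )

    def test_binary_rows_and_level_row_ranges(self, small_dataset):
        genome, _, methylome = small_dataset
        sites = [("chrSim", int(p)) for p in methylome.positions("chrSim")[:50]]
        X, _ = assemble_features(genome, methylome, sites)
        assert set(np.unique(X[:, :4])) <= {0.0, 1.0}
        assert np.all((X[:, 4] >= 0) & (X[:, 4] <= 1))

    def test_repeated_assembly_is_bit_identical(self, small_dataset):
        genome, _, methylome = small_dataset
        sites = [("chrSim", int(p)) for p in methylome.positions("chrSim")[:20]]
        X1, _ = assemble_features(genome, methylome, sites)
        X2, _ = assemble_features(genome, methylome, sites)
        assert np.array_equal(X1, X2)

    def test_non_cpg_site_rejected(self, small_dataset):
        genome, _, methylome = small_dataset
        cpg = set(genome.cpg_positions("chrSim").tolist())
        not_cpg = next(p for p in range(60, 200) if p not in cpg)
        with pytest.raises(ValueError, match="CpG"):
            assemble_features(genome, methylome, [("chrSim", not_cpg)])

    def test_fully_methylated_flanks_give_unit_chain(self, toy_genome):
        m = Methylome({"chrT": (np.array([3, 9, 15, 21]),
                                np.array([0, 4, 4, 4]),
                                np.array([0, 0, 0, 0]))})
        X, _ = assemble_features(toy_genome, m, [("chrT", 3)])
        chain = X[0, 4, :, 0]
        observed = chain[(chain != PAD_LEVEL)]
        assert np.all(observed == 1.0)

    def test_onehot_scheme_keeps_shape(self, small_dataset):
        genome, _, methylome = small_dataset
        # interior sites: windows contain no off-chromosome N padding
        sites = [("chrSim", int(p)) for p in methylome.positions("chrSim")[200:205]]
        X, _ = assemble_features(genome, methylome, sites, scheme="onehot")
        assert X.shape == (5, 5, 100, 1)
        seq_cols = X[:, :4, :, 0].sum(axis=1)
        assert np.all(seq_cols == 1)  # every non-center base one-hot
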