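"""Featurization: per-residue vectors, cumulative operators, spatial
encoding, subsequence windows and global features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepccs import (
    FeaturizationConfig,
    SubsequenceLayoutConfig,
    Window,
    cumulative,
    encode_peptides,
    feature_matrix,
    global_features,
    global_length,
    parse_peptide,
    residue_features,
    spatial_encoding,
    subsequence_windows,
)
from pepccs.chemistry import Residue
from pepccs.errors import EncodingLengthError
from pepccs.features import (
    CH_ACETYL,
    CH_CHARGE,
    CH_CTERM,
    CH_DIST_C,
    CH_DIST_N,
    CH_FBLOCK,
    CH_NTERM,
    CH_RELPOS,
    CH_RESIDUE,
    CUMULATIVE_BLOCK,
    N_RESIDUE_FEATURES,
    PAD_FEATURE,
    SPATIAL_CHANNELS,
    layout_manifest,
    padding_features,
)


def naive_cumulative(F, kind, w):
    """Independent brute-force implementation of the three operators."""
    out = np.zeros(F.shape[1])
    for i in range(F.shape[1]):
        s = sum(F[j, i] for j in range(w.j_start, w.j_end + 1))
        if kind == 1:
            out[i] = s / 100.0
        elif kind == 2:
            total = sum(F[j, i] for j in range(F.shape[0]))
            out[i] = 0.0 if total == 0 else s / total
        else:
            out[i] = s / (w.j_end - w.j_start + 1)
    return out


class TestResidueFeatures:
    def test_padding_vector(self):
        v = padding_features()
        assert v[PAD_FEATURE] == 1.0
        assert np.count_nonzero(v) == 1

    def test_one_hot_exactly_one(self, chem):
        for sym in "ACDEFGHIKLMNPQRSTVWYm":
            v = residue_features(Residue(sym, sym == "m"), chem)
            assert v[:21].sum() == 1.0
            assert set(np.unique(v[:21])) <= {0.0, 1.0}
            assert v[PAD_FEATURE] == 0.0

    def test_aspartate_flags(self, chem):
        v = residue_features(Residue("D"), chem)
        assert v[26] == 1.0  # acidic
        assert v[36] == 1.0  # {N, D} pair
        assert v[37] == 0.0

    def test_oxidized_met_class_membership(self, chem):
        v = residue_features(Residue("m", is_oxidized_met=True), chem)
        assert v[20] == 1.0  # 21st one-hot slot
        assert v[27] == 1.0  # modified (non-standard)
        assert v[31] == 1.0  # uncharged polar
        # composition: Met plus one O
        vm = residue_features(Residue("M"), chem)
        assert v[24] == vm[24] + 1  # O count


class TestFeatureMatrix:
    def test_identical_residues_identical_rows(self):
        F = feature_matrix(parse_peptide("GG", 2))
        assert F.shape == (2, N_RESIDUE_FEATURES)
        np.testing.assert_array_equal(F[0], F[1])

    def test_single_residue_matrix(self):
        assert feature_matrix(parse_peptide("G", 2)).shape == (1, 45)

    def test_oxidized_met_row(self, chem):
        F = feature_matrix(parse_peptide("GM(ox)K", 2), chem)
        assert F[1, 20] == 1.0
        assert F[1, 24] == chem["M"].composition.O + 1


class TestCumulative:
    def test_full_window_kind2_normalizes_to_one(self, random_peptides):
        p = random_peptides[0]
        F = feature_matrix(p)
        w = Window(0, len(p) - 1)
        c2 = cumulative(F, 2, w)
        total = F.sum(axis=0)
        np.testing.assert_allclose(c2[total > 0], 1.0, atol=1e-12)
        np.testing.assert_array_equal(c2[total == 0], 0.0)

    def test_single_residue_kind3_identity(self, random_peptides):
        p = random_peptides[1]
        F = feature_matrix(p)
        for j in (0, len(p) - 1):
            np.testing.assert_allclose(cumulative(F, 3, Window(j, j)), F[j], atol=0)

    def test_triple_glycine_kind1(self, chem):
        F = feature_matrix(parse_peptide("GGG", 2), chem)
        c1 = cumulative(F, 1, Window(0, 2))
        g_idx = chem["G"].one_hot_index
        assert c1[g_idx] == pytest.approx(0.03, abs=1e-15)

    def test_matches_naive_oracle(self, random_peptides, rng):
        for p in random_peptides:
            F = feature_matrix(p)
            n = F.shape[0]
            a, b = sorted(rng.integers(0, n, size=2))
            w = Window(int(a), int(b))
            for kind in (1, 2, 3):
                np.testing.assert_allclose(
                    cumulative(F, kind, w), naive_cumulative(F, kind, w), atol=1e-12
                )

    def test_c1_additivity(self, random_peptides):
        for p in random_peptides[:50]:
            n = len(p)
            if n < 2:
                continue
            F = feature_matrix(p)
            full = cumulative(F, 1, Window(0, n - 1))
            for j in (0, n // 2, n - 2):
                left = cumulative(F, 1, Window(0, j))
                right = cumulative(F, 1, Window(j + 1, n - 1))
                np.testing.assert_allclose(left + right, full, atol=1e-12)

    def test_c2_bounded_c3_within_feature_range(self, random_peptides, rng):
        for p in random_peptides[:50]:
            F = feature_matrix(p)
            a, b = sorted(rng.integers(0, len(p), size=2))
            w = Window(int(a), int(b))
            c2 = cumulative(F, 2, w)
            assert np.all((c2 >= -1e-12) & (c2 <= 1 + 1e-12))
            c3 = cumulative(F, 3, w)
            seg = F[w.j_start : w.j_end + 1]
            assert np.all(c3 >= seg.min(axis=0) - 1e-12)
            assert np.all(c3 <= seg.max(axis=0) + 1e-12)

    def test_out_of_bounds_window_rejected(self):
        F = feature_matrix(parse_peptide("AAK", 2))
        with pytest.raises(ValueError):
            cumulative(F, 1, Window(0, 3))
        with pytest.raises(ValueError):
            Window(2, 1)


class TestSubsequenceWindows:
    def test_default_layout_has_36_windows_for_any_length(self):
        for n in (1, 2, 7, 16, 17, 30, 45):
            assert len(subsequence_windows(n)) == 36

    def test_single_residue_peptide_all_windows_degenerate(self):
        assert all(w == Window(0, 0) for w in subsequence_windows(1))

    def test_fractional_tilings_partition_the_peptide(self):
        cfg = SubsequenceLayoutConfig()
        for n in (16, 23, 45):
            ws = subsequence_windows(n, cfg)[2 * len(cfg.fixed_lengths) :]
            pos = 0
            for level in cfg.fractional_levels:
                tile, ws = ws[:level], ws[level:]
                covered = []
                for w in tile:
                    covered.extend(range(w.j_start, w.j_end + 1))
                assert covered == list(range(n)), f"level {level}, n {n}"

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(1, 60), level=st.sampled_from([2, 4, 8, 16]))
    def test_fractional_windows_cover_and_stay_in_bounds(self, n, level):
        cfg = SubsequenceLayoutConfig(fixed_lengths=(), fractional_levels=(level,))
        ws = subsequence_windows(n, cfg)
        assert len(ws) == level
        assert ws[0].j_start == 0 and ws[-1].j_end == n - 1
        for w in ws:
            assert 0 <= w.j_start <= w.j_end <= n - 1
        if n >= level:  # a true tiling once every window can hold a residue
            covered = [j for w in ws for j in range(w.j_start, w.j_end + 1)]
            assert covered == list(range(n))

    def test_fixed_windows_clamped_for_short_peptides(self):
        ws = subsequence_windows(7)
        assert ws[0] == Window(0, 4)  # N-terminal 5-mer
        assert ws[1] == Window(2, 6)  # C-terminal 5-mer
        assert ws[4] == Window(0, 6)  # 20-mer clamped to whole peptide
        assert ws[5] == Window(0, 6)


class TestSpatialEncoding:
    def test_channel_count(self):
        M = spatial_encoding(parse_peptide("AAK", 2), L=96)
        assert M.shape == (96, SPATIAL_CHANNELS)
        assert SPATIAL_CHANNELS == 4 + CUMULATIVE_BLOCK + 3 + 1 == 323

    def test_terminus_flags(self):
        p = parse_peptide("AAGGK", 3)
        M = spatial_encoding(p, L=96)
        assert M[0, CH_NTERM] == 1.0 and M[:, CH_NTERM].sum() == 1.0
        assert M[4, CH_CTERM] == 1.0 and M[:, CH_CTERM].sum() == 1.0
        assert M[:, CH_ACETYL].sum() == 0.0
        acet = spatial_encoding(parse_peptide("*AAGGK", 3), L=96)
        assert acet[0, CH_ACETYL] == 1.0

    def test_padding_rows(self):
        p = parse_peptide("AAK", 2)
        M = spatial_encoding(p, L=96)
        pad = M[3:]
        assert np.all(pad[:, CH_RESIDUE] == 0.0)
        assert np.all(pad[:, CH_FBLOCK + PAD_FEATURE] == 1.0)
        # everything else in the pad rows is zero except the charge channel
        other = pad.copy()
        other[:, CH_FBLOCK + PAD_FEATURE] = 0.0
        other[:, CH_CHARGE] = 0.0
        assert np.all(other == 0.0)

    def test_position_channels(self):
        p = parse_peptide("AAGGK", 4)
        M = spatial_encoding(p, L=96)
        np.testing.assert_allclose(M[:5, CH_RELPOS], np.arange(5) / 4)
        np.testing.assert_array_equal(M[:5, CH_DIST_N], np.arange(5))
        np.testing.assert_array_equal(M[:5, CH_DIST_C], np.arange(4, -1, -1))
        assert np.all(M[:, CH_CHARGE] == 4.0)

    def test_single_residue_relative_position_is_zero(self):
        M = spatial_encoding(parse_peptide("K", 2), L=96)
        assert M[0, CH_RELPOS] == 0.0

    def test_encoding_independent_of_length_beyond_padding(self):
        p = parse_peptide("AAGGKLLR", 2)
        M1 = spatial_encoding(p, L=49)
        M2 = spatial_encoding(p, L=96)
        np.testing.assert_array_equal(M1, M2[:49])

    def test_too_long_peptide_rejected(self):
        p = parse_peptide("A" * 10 + "K", 2)
        with pytest.raises(EncodingLengthError):
            spatial_encoding(p, L=51)


class TestGlobalFeatures:
    def test_reduced_vector_is_six_scalars(self):
        g = global_features(parse_peptide("AAK", 3), reduced=True)
        np.testing.assert_array_equal(g, [3, 3, 0, 1, 0, 0])

    def test_full_vector_length(self):
        g = global_features(parse_peptide("AAK", 2))
        assert g.shape == (6 + 45 * 36,) == (1626,)
        assert global_length() == 1626

    def test_charge_one_hot(self):
        for z, onehot in ((2, (1, 0, 0)), (3, (0, 1, 0)), (4, (0, 0, 1))):
            g = global_features(parse_peptide("AAK", z), reduced=True)
            assert tuple(g[2:5]) == onehot
            assert g[1] == z

    def test_windowed_block_matches_cumulative(self):
        p = parse_peptide("AAGGKLLMR", 2)
        g = global_features(p)
        F = feature_matrix(p)
        ws = subsequence_windows(len(p))
        first = cumulative(F, 1, ws[0])
        np.testing.assert_allclose(g[6:51], first, atol=0)


class TestEncodedDataset:
    def test_determinism_bit_identical(self, random_peptides):
        peps = random_peptides[:20]
        e1 = encode_peptides(peps)
        e2 = encode_peptides(peps)
        np.testing.assert_array_equal(e1.spatial, e2.spatial)
        np.testing.assert_array_equal(e1.glob, e2.glob)
        assert e1.feature_hash == e2.feature_hash

    def test_hash_distinguishes_configs(self):
        a = FeaturizationConfig(L=96)
        b = FeaturizationConfig(L=90)
        c = FeaturizationConfig(L=96, reduced=True)
        from pepccs import featurization_hash

        assert len({featurization_hash(x) for x in (a, b, c)}) == 3

    def test_layout_manifest_covers_all_channels(self):
        man = layout_manifest()
        assert len(man["spatial_channels"]) == SPATIAL_CHANNELS
        assert man["global_dim"] == 1626
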