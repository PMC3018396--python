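import numpy as np
import pytest

from pinhub.io_formats import AMINO_ACIDS, AA_INDEX
from pinhub.sequence_features import (
    HARALICK_NAMES,
    aac,
    cooccurrence_matrix,
    dipeptide_comp,
    gapped_pair_comp,
    haralick_features,
    length_feature,
    load_property_table,
    physicochemical_comp,
)


def naive_pair_counts(sequence, k):
    """Independent double-loop oracle for gapped-pair composition."""
    counts = np.zeros(400)
    for i in range(len(sequence) - 1 - k):
        a, b = sequence[i], sequence[i + k + 1]
        if a in AA_INDEX and b in AA_INDEX:
            counts[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    return counts / (len(sequence) - 1 - k)


class TestCompositions:
    def test_aac_examples(self):
        v = aac("AAAC")
        assert v[AA_INDEX["A"]] == 0.75
        assert v[AA_INDEX["C"]] == 0.25
        assert v.sum() == pytest.approx(1.0)
        assert aac("M")[AA_INDEX["M"]] == 1.0

    def test_dipeptide_examples(self):
        v = dipeptide_comp("AAA")
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == 1.0
        v = dipeptide_comp("ACAC")  # adjacent pairs: AC, CA, AC
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == pytest.approx(2 / 3)
        assert v[AA_INDEX["C"] * 20 + AA_INDEX["A"]] == pytest.approx(1 / 3)
        assert len(v) == 400

    def test_gapped_examples(self):
        v = gapped_pair_comp("ACA", 1)
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == 1.0
        v = gapped_pair_comp("ACDCA", 1)  # windows: A.D, C.C, D.A
        for a, b in (("A", "D"), ("C", "C"), ("D", "A")):
            assert v[AA_INDEX[a] * 20 + AA_INDEX[b]] == pytest.approx(1 / 3)

    def test_gap_zero_equals_dipeptides(self, random_sequences):
        for seq in random_sequences:
            np.testing.assert_array_equal(gapped_pair_comp(seq, 0), dipeptide_comp(seq))

    @pytest.mark.parametrize("k", [0, 1, 2, 4])
    def test_oracle_equivalence(self, random_sequences, k):
        """All composition ops equal a naive double-loop counter."""
        for seq in random_sequences:
            if len(seq) < k + 2:
                continue
            np.testing.assert_allclose(
                gapped_pair_comp(seq, k), naive_pair_counts(seq, k), atol=1e-12
            )
            counts = np.zeros(20)
            for c in seq:
                counts[AA_INDEX[c]] += 1
            np.testing.assert_allclose(aac(seq), counts / len(seq), atol=1e-12)

    def test_normalization_standard_sequences(self, random_sequences):
        for seq in random_sequences:
            assert aac(seq).sum() == pytest.approx(1.0, abs=1e-9)
            assert dipeptide_comp(seq).sum() == pytest.approx(1.0, abs=1e-9)
            if len(seq) >= 4:
                assert gapped_pair_comp(seq, 2).sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonstandard_residues_excluded_from_numerators(self):
        # X contributes to N but to no count: sums fall below 1
        v = aac("AXA")
        assert v[AA_INDEX["A"]] == pytest.approx(2 / 3)
        assert v.sum() == pytest.approx(2 / 3)
        v = dipeptide_comp("AXA")  # pairs AX, XA contain X -> no counts
        assert v.sum() == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            aac("")
        with pytest.raises(ValueError):
            dipeptide_comp("A")
        with pytest.raises(ValueError):
            gapped_pair_comp("AC", 1)


class TestCooccurrence:
    def test_single_mass(self):
        m = cooccurrence_matrix("ACA", 1)
        assert m.shape == (20, 20)
        assert m[AA_INDEX["A"], AA_INDEX["A"]] == 1.0
        assert m.sum() == 1.0

    def test_row_major_reshape_consistency(self, random_sequences):
        for seq in random_sequences[:20]:
            if len(seq) < 3:
                continue
            np.testing.assert_array_equal(
                cooccurrence_matrix(seq, 1).ravel(), gapped_pair_comp(seq, 1)
            )

    def test_directional(self):
        # "AC" with k=0: mass at (A,C) only, not (C,A)
        m = cooccurrence_matrix("AC", 0)
        assert m[AA_INDEX["A"], AA_INDEX["C"]] == 1.0
        assert m[AA_INDEX["C"], AA_INDEX["A"]] == 0.0


def haralick_oracle(p):
    """Direct-summation reference looping over all (i, j) pairs, 1-based."""
    p = p / p.sum()
    ng = p.shape[0]

    def log2_(x):
        return np.log2(x) if x > 0 else 0.0

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    energy = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    if var_x > 0 and var_y > 0:
        corr = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
        corr = (corr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        corr = 0.0
    inertia = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    entropy = -sum(p[i, j] * log2_(p[i, j]) for i in range(ng) for j in range(ng))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0) + p[i, j]
    sa = sum(k * v for k, v in p_sum.items())
    sv = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    se = -sum(v * log2_(v) for v in p_sum.values())
    da = sum(k * v for k, v in p_diff.items())
    dv = sum((k - da) ** 2 * v for k, v in p_diff.items())
    de = -sum(v * log2_(v) for v in p_diff.values())

    hx = -sum(px[i] * log2_(px[i]) for i in range(ng))
    hy = -sum(py[j] * log2_(py[j]) for j in range(ng))
    hxy1 = -sum(
        p[i, j] * log2_(px[i] * py[j])
        for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    return np.array([energy, corr, inertia, entropy, idm, sa, sv, se, da, dv, de, imc1])


class TestHaralick:
    def test_single_cell(self):
        m = np.zeros((20, 20))
        m[0, 0] = 1.0
        f = dict(zip(HARALICK_NAMES, haralick_features(m)))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["inertia"] == 0.0
        assert f["inverse_difference_moment"] == 1.0

    def test_uniform_matrix(self):
        f = dict(zip(HARALICK_NAMES, haralick_features(np.ones((20, 20)))))
        assert f["energy"] == pytest.approx(1 / 400)
        assert f["entropy"] == pytest.approx(np.log2(400))

    def test_random_matrix_matches_direct_summation_oracle(self, rng):
        for _ in range(10):
            m = np.zeros((20, 20))
            idx = rng.integers(0, 4, size=(8, 2))  # support on a 4x4 corner
            for i, j in idx:
                m[i, j] += rng.uniform(0.1, 1.0)
            np.testing.assert_allclose(
                haralick_features(m), haralick_oracle(m), atol=1e-10
            )

    def test_value_ranges_on_real_sequences(self, random_sequences):
        for seq in random_sequences[:30]:
            if len(seq) < 3:
                continue
            f = dict(zip(HARALICK_NAMES, haralick_features(cooccurrence_matrix(seq, 1))))
            assert 0 < f["energy"] <= 1
            assert 0 <= f["entropy"] <= np.log2(400)
            assert 0 < f["inverse_difference_moment"] <= 1

    def test_contrast_correlation_agree_with_skimage(self, rng):
        """Cross-check shared statistics against the image-texture library."""
        graycoprops = pytest.importorskip("skimage.feature").graycoprops
        m = rng.uniform(0, 1, size=(20, 20))
        ours = dict(zip(HARALICK_NAMES, haralick_features(m)))
        glcm = (m / m.sum())[:, :, None, None]
        assert ours["inertia"] == pytest.approx(
            float(graycoprops(glcm, "contrast")[0, 0])
        )
        assert ours["correlation"] == pytest.approx(
            float(graycoprops(glcm, "correlation")[0, 0])
        )
        assert ours["energy"] == pytest.approx(
            float(graycoprops(glcm, "ASM")[0, 0])
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.zeros((20, 20)))


class TestPhysicochemical:
    def test_default_table_has_48_groups_with_aromatic_hfwy(self):
        table = load_property_table()
        assert len(table) == 48
        aromatic = table.groups[table.names.index("aromatic")]
        assert aromatic == frozenset("HFWY")

    def test_aromaticity(self):
        table = load_property_table()
        v = physicochemical_comp("HFWY", table)
        assert v[table.names.index("aromatic")] == 1.0
        assert physicochemical_comp("HAAA", table)[table.names.index("aromatic")] == 0.25

    def test_absent_group_zero(self):
        table = load_property_table()
        # sulfur-containing group (C, M) absent from an A-only sequence
        assert physicochemical_comp("AAAA", table)[table.names.index("sulfur_containing")] == 0.0


class TestLength:
    def test_examples(self):
        assert length_feature("ACDE")[0] == 4
        assert length_feature("M")[0] == 1

    def test_consistent_with_aac_denominator(self):
        seq = "AAAC"
        n = length_feature(seq)[0]
        counts = aac(seq) * n
        np.testing.assert_allclose(counts, np.round(counts))
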