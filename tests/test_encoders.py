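import collections
import math

import numpy as np
import pytest

from stacktide.encoders import (
    EncoderSpec,
    encode_aac,
    encode_apaac,
    encode_ctd,
    encode_dataset,
    encode_dpc,
    encode_paac,
    encode_property_mean,
    encode_reduced,
    encoder_registry,
    RS_SCHEDULES,
)
from stacktide.encoders.tables import (
    CTD_GROUPS,
    paac_standardize,
    HYDROPHOBICITY,
    pcp_matrix,
    reduced_map,
    synthetic_aaindex_table,
)
from stacktide.sequence_io import ALPHABET, Peptide, PeptideDataset

RNG = np.random.default_rng(2024)


def random_peptide(rng=RNG, lo=5, hi=30) -> str:
    return "".join(rng.choice(list(ALPHABET), size=rng.integers(lo, hi + 1)))


EXPECTED_DIMS = {
    "AAC": 20, "AAI": 531, "APAAC": 22, "CTD": 147, "DPC": 400, "PCP": 11,
    "PAAC": 21, "RSacid": 32, "RScharge": 50, "RSDHP": 32, "RSpolar": 32,
    "RSsecond": 40,
}


class TestRegistry:
    def test_twelve_encoders_with_contract_dimensions(self):
        regs = encoder_registry()
        assert len(regs) == 12
        assert {r.name: r.dimension for r in regs} == EXPECTED_DIMS
        assert len({r.name for r in regs}) == 12

    def test_dimension_multiset(self):
        dims = sorted(r.dimension for r in encoder_registry())
        assert dims == sorted([20, 531, 22, 147, 400, 11, 21, 32, 50, 32, 32, 40])

    @pytest.mark.parametrize("spec", encoder_registry(), ids=lambda s: s.name)
    def test_output_matches_declared_dimension(self, spec):
        for _ in range(5):
            v = spec.encode(random_peptide())
            assert v.shape == (spec.dimension,)
            assert np.isfinite(v).all()
        assert len(spec.column_names()) == spec.dimension


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("AAAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_mixed(self):
        v = encode_aac("ACACD")
        assert v[ALPHABET.index("A")] == pytest.approx(0.4)
        assert v[ALPHABET.index("C")] == pytest.approx(0.4)
        assert v[ALPHABET.index("D")] == pytest.approx(0.2)

    def test_against_counting_oracle(self):
        for _ in range(1000):
            seq = random_peptide()
            counts = collections.Counter(seq)
            expected = np.array([counts[a] / len(seq) for a in ALPHABET])
            np.testing.assert_allclose(encode_aac(seq), expected, atol=1e-12)


class TestDPC:
    def test_homopolymer(self):
        v = encode_dpc("AAAAA")
        assert v[0] == 1.0 and v.sum() == pytest.approx(1.0)

    def test_alternating(self):
        v = encode_dpc("ACACA")
        ac = ALPHABET.index("A") * 20 + ALPHABET.index("C")
        ca = ALPHABET.index("C") * 20 + ALPHABET.index("A")
        assert v[ac] == pytest.approx(0.5) and v[ca] == pytest.approx(0.5)

    def test_against_pair_counting_oracle(self):
        for _ in range(200):
            seq = random_peptide()
            pairs = collections.Counter(seq[i:i + 2] for i in range(len(seq) - 1))
            for i, a in enumerate(ALPHABET):
                for j, b in enumerate(ALPHABET):
                    assert encode_dpc(seq)[i * 20 + j] == pytest.approx(
                        pairs[a + b] / (len(seq) - 1))
            break  # one full 400-cell check; remaining iterations spot-check sums
        for _ in range(100):
            assert encode_dpc(random_peptide()).sum() == pytest.approx(1.0)


def ctd_oracle(seq: str) -> np.ndarray:
    """Independent straight-loop CTD implementation (no shared code)."""
    out = []
    L = len(seq)
    for attr, groups in CTD_GROUPS.items():
        gidx = []
        for a in seq:
            for gi, grp in enumerate(groups):
                if a in grp:
                    gidx.append(gi)
                    break
        for g in range(3):
            out.append(gidx.count(g) / L)
        pairs = list(zip(gidx, gidx[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            out.append(sum(1 for x, y in pairs if {x, y} == {a, b}) / (L - 1))
        for g in range(3):
            pos = [i + 1 for i, c in enumerate(gidx) if c == g]
            if not pos:
                out.extend([0.0] * 5)
                continue
            n = len(pos)
            picks = [pos[0]]
            for q in (0.25, 0.5, 0.75, 1.0):
                picks.append(pos[math.ceil(q * n) - 1])
            out.extend(100.0 * p / L for p in picks)
    return np.array(out)


class TestCTD:
    def test_homopolymer_composition_and_transitions(self):
        v = encode_ctd("AAAAA")
        for block in range(7):
            comp = v[block * 21: block * 21 + 3]
            trans = v[block * 21 + 3: block * 21 + 6]
            assert comp.sum() == pytest.approx(1.0)
            assert comp.max() == pytest.approx(1.0)  # single occupied group
            assert trans.sum() == 0.0

    def test_homopolymer_distribution_frozen_values(self):
        # hand computation for AAAAA (n_g = 5, L = 5): first occurrence at
        # position 1 -> 20%; ceil(q*5) for q=25/50/75/100% -> positions
        # 2, 3, 4, 5 -> 40, 60, 80, 100%
        v = encode_ctd("AAAAA")
        for attr_i, (attr, groups) in enumerate(CTD_GROUPS.items()):
            g = next(gi for gi, grp in enumerate(groups) if "A" in grp)
            d = v[attr_i * 21 + 6 + g * 5: attr_i * 21 + 6 + g * 5 + 5]
            np.testing.assert_allclose(d, [20, 40, 60, 80, 100])

    def test_against_independent_oracle(self):
        for _ in range(100):
            seq = random_peptide()
            np.testing.assert_allclose(encode_ctd(seq), ctd_oracle(seq), atol=1e-12)

    def test_distribution_range_and_absent_groups(self):
        v = encode_ctd("AAAAAAA")  # most groups absent
        for attr_i in range(7):
            for g in range(3):
                d = v[attr_i * 21 + 6 + g * 5: attr_i * 21 + 6 + g * 5 + 5]
                assert ((d == 0).all() or ((d > 0) & (d <= 100)).all())


class TestPAACFamily:
    def test_paac_homopolymer_theta_zero(self):
        v = encode_paac("AAAAA")
        assert v[20] == pytest.approx(0.0)  # identical residues: no correlation
        np.testing.assert_allclose(v[:20], encode_aac("AAAAA"))

    def test_paac_normalization_and_sign(self):
        for _ in range(50):
            v = encode_paac(random_peptide())
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert (v >= 0).all()

    def test_paac_hand_computed_dipeptide(self):
        # "ACACA": theta1 = mean of squared standardized property diffs A<->C
        h1 = paac_standardize(HYDROPHOBICITY)
        from stacktide.encoders.tables import HYDROPHILICITY, SIDE_CHAIN_MASS
        h2 = paac_standardize(HYDROPHILICITY)
        m = paac_standardize(SIDE_CHAIN_MASS)
        iA, iC = ALPHABET.index("A"), ALPHABET.index("C")
        corr = ((h1[iA] - h1[iC]) ** 2 + (h2[iA] - h2[iC]) ** 2 + (m[iA] - m[iC]) ** 2) / 3
        theta = corr  # every adjacent pair is A<->C
        w = 0.05
        denom = 1.0 + w * theta
        v = encode_paac("ACACA")
        assert v[20] == pytest.approx(w * theta / denom)
        assert v[iA] == pytest.approx(0.6 / denom)

    def test_apaac_homopolymer_nonzero_correlation(self):
        v = encode_apaac("AAAAA")
        assert v.shape == (22,)
        assert v[20] != 0.0 and v[21] != 0.0  # self-products of property values
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_must_exceed_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            encode_paac("ACDEF", lam=5)


class TestPropertyMeans:
    def test_homopolymer_equals_property_value(self):
        m, _ = pcp_matrix()
        v = encode_property_mean("DDDDD", m)
        np.testing.assert_allclose(v, m[:, ALPHABET.index("D")])

    def test_panel_dimensions(self):
        aai, names = synthetic_aaindex_table()
        assert aai.shape == (531, 20) and len(names) == 531
        m, pnames = pcp_matrix()
        assert m.shape == (11, 20) and len(pnames) == 11

    def test_aai_panel_standardized_and_reproducible(self):
        a, _ = synthetic_aaindex_table()
        b, _ = synthetic_aaindex_table()
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(a.std(axis=1), 1, atol=1e-12)


class TestReducedSchemes:
    @pytest.mark.parametrize("scheme", list(RS_SCHEDULES))
    def test_blocks_sum_to_one(self, scheme):
        for _ in range(20):
            v = encode_reduced(random_peptide(), scheme)
            offset = 0
            k = len(reduced_map(scheme).values()) and max(reduced_map(scheme).values()) + 1
            for block in RS_SCHEDULES[scheme]:
                width = k * k if block.startswith("di") else k
                assert v[offset:offset + width].sum() == pytest.approx(1.0)
                offset += width
            assert offset == len(v)

    def test_reduced_homopolymer_one_hot_blocks(self):
        # all-K sequence maps to a single class under every scheme
        for scheme in RS_SCHEDULES:
            v = encode_reduced("KKKKKK", scheme)
            k = max(reduced_map(scheme).values()) + 1
            offset = 0
            for block in RS_SCHEDULES[scheme]:
                width = k * k if block.startswith("di") else k
                blk = v[offset:offset + width]
                assert (blk == 1.0).sum() == 1 and blk.sum() == pytest.approx(1.0)
                offset += width

    def test_unknown_scheme_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            encode_reduced("ACDEF", "RSbogus")


class TestEncodeDataset:
    def _ds(self, seqs):
        return PeptideDataset(peptides=[Peptide(id=f"p{i}", sequence=s)
                                        for i, s in enumerate(seqs)])

    def test_shape_and_row_order(self):
        spec = encoder_registry()[0]  # AAC
        fm = encode_dataset(self._ds(["AAAAA", "CCCCC", "ACACD"]), spec)
        assert fm.values.shape == (3, 20)
        np.testing.assert_allclose(fm.values[0], encode_aac("AAAAA"))
        assert fm.row_ids == ["p0", "p1", "p2"]

    def test_deterministic(self):
        ds = self._ds([random_peptide() for _ in range(10)])
        spec = next(e for e in encoder_registry() if e.name == "CTD")
        a = encode_dataset(ds, spec).values
        b = encode_dataset(ds, spec).values
        np.testing.assert_array_equal(a, b)

    def test_permutation_covariance(self):
        seqs = [random_peptide() for _ in range(12)]
        ds = self._ds(seqs)
        perm = np.random.default_rng(5).permutation(12)
        spec = next(e for e in encoder_registry() if e.name == "DPC")
        direct = encode_dataset(ds.subset(perm), spec).values
        reordered = encode_dataset(ds, spec).values[perm]
        np.testing.assert_array_equal(direct, reordered)

    def test_empty_dataset(self):
        spec = encoder_registry()[0]
        fm = encode_dataset(self._ds([]), spec)
        assert fm.values.shape == (0, 20)


class TestCompositionProperties:
    """Property-based checks over arbitrary valid peptides."""

    from hypothesis import given, settings, strategies as st

    peptides = st.text(alphabet=list(ALPHABET), min_size=5, max_size=40)

    @given(seq=peptides)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_composition_blocks_sum_to_one(self, seq):
        assert encode_aac(seq).sum() == pytest.approx(1.0)
        assert encode_dpc(seq).sum() == pytest.approx(1.0)
        assert encode_paac(seq).sum() == pytest.approx(1.0, abs=1e-9)
        assert encode_apaac(seq).sum() == pytest.approx(1.0, abs=1e-9)

    @given(seq=peptides)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_aac_matches_counter_oracle(self, seq):
        counts = collections.Counter(seq)
        expected = np.array([counts[a] / len(seq) for a in ALPHABET])
        np.testing.assert_allclose(encode_aac(seq), expected, atol=1e-12)

    @given(seq=peptides)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_ctd_distribution_components_bounded(self, seq):
        v = encode_ctd(seq)
        for attr_i in range(7):
            for g in range(3):
                d = v[attr_i * 21 + 6 + g * 5: attr_i * 21 + 6 + g * 5 + 5]
                assert ((d == 0) | ((d > 0) & (d <= 100))).all()
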