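"""Cascade calculus: receptive fields, gap recursion, validity, design search."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghdcnet.design import (
    CascadeSpec,
    DilatedLayerSpec,
    coverage_oracle,
    design_cascade,
    gap_profile,
    hdc_reference_gap,
    layer_offsets,
    receptive_field,
    validate_cascade,
)

STANDARD_CASCADES = {
    # the four default skip-block cascades plus the reference HDC configuration
    "block1": ((1, 2, 5, 7, 9), (3, 3, 3, 5, 5), 81),
    "block2": ((1, 2, 5, 7), (3, 3, 3, 5), 45),
    "block3": ((1, 2, 5), (3, 3, 3), 17),
    "block4": ((1, 2), (3, 3), 7),
    "hdc": ((1, 2, 5, 9), (3, 3, 3, 3), 35),
}


def cascade(rates, kernels) -> CascadeSpec:
    return CascadeSpec.from_lists(rates, kernels)


class TestTypes:
    @pytest.mark.parametrize("k,r", [(2, 1), (4, 1), (0, 1), (3, 0), (3, -2)])
    def test_layer_invariants_rejected(self, k, r):
        with pytest.raises(ValueError):
            DilatedLayerSpec(k, r)

    def test_empty_cascade_rejected(self):
        with pytest.raises(ValueError):
            CascadeSpec(())

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            CascadeSpec.from_lists([1, 2], [3])


class TestReceptiveField:
    @pytest.mark.parametrize("rates,kernels,expected",
                             list(STANDARD_CASCADES.values()),
                             ids=list(STANDARD_CASCADES))
    def test_standard_cascades(self, rates, kernels, expected):
        assert receptive_field(cascade(rates, kernels)) == expected

    def test_identity_kernel(self):
        assert receptive_field(cascade([1], [1])) == 1

    @given(
        st.lists(
            st.tuples(st.sampled_from([1, 3, 5, 7]), st.integers(1, 9)),
            min_size=1,
            max_size=5,
        ),
        st.sampled_from([1, 3, 5]),
        st.integers(1, 9),
    )
    def test_additivity_of_appended_layer(self, layers, k, r):
        base = CascadeSpec(tuple(DilatedLayerSpec(kk, rr) for kk, rr in layers))
        extended = CascadeSpec(base.layers + (DilatedLayerSpec(k, r),))
        assert receptive_field(extended) == receptive_field(base) + r * (k - 1)


class TestLayerOffsets:
    def test_worked_example(self):
        # M_3 = 5, k_2 = 3, r_2 = 2 -> offsets {±(2m+5n)} and gap M_2 = 2
        off = layer_offsets(k_l=3, r_l=2, k_up=3, M_up=5)
        assert off.offsets == (-7, -5, -3, -2, 0, 2, 3, 5, 7)
        assert off.max_gap == 2

    def test_degenerate_1x1(self):
        off = layer_offsets(1, 1, 1, 1)
        assert off.offsets == (0,)
        assert off.gaps == ()
        assert off.max_gap == 1

    def test_enumerated_5x5_case(self):
        # brute force over 7m + 9n, m,n in {0,±1,±2}
        sums = sorted({7 * m + 9 * n for m in range(-2, 3) for n in range(-2, 3)})
        expected_gap = max(b - a for a, b in zip(sums, sums[1:]))
        off = layer_offsets(5, 7, 5, 9)
        assert list(off.offsets) == sums
        assert off.max_gap == expected_gap == 7

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            layer_offsets(4, 1, 3, 1)
        with pytest.raises(ValueError):
            layer_offsets(3, 1, 2, 1)

    @given(st.sampled_from([1, 3, 5, 7]), st.integers(1, 9),
           st.sampled_from([1, 3, 5, 7]), st.integers(1, 30))
    def test_offsets_symmetric_about_zero(self, k, r, k_up, m_up):
        off = layer_offsets(k, r, k_up, m_up)
        assert tuple(-x for x in reversed(off.offsets)) == off.offsets
        assert all(a <= b for a, b in zip(off.gaps, off.gaps[1:]))


class TestGapProfile:
    def test_block1_gap_sequence(self):
        profile = gap_profile(cascade((1, 2, 5, 7, 9), (3, 3, 3, 5, 5)))
        assert [profile.M(l) for l in range(2, 6)] == [2, 5, 7, 9]
        assert profile.M(6) == 1  # boundary convention
        assert profile.valid

    def test_all_even_rates_invalid(self):
        profile = gap_profile(cascade((2, 4, 8), (3, 3, 3)))
        assert profile.M(2) == 4
        assert not profile.valid

    def test_single_dense_layer_valid(self):
        assert gap_profile(cascade([1], [3])).valid

    def test_single_dilated_layer_invalid(self):
        assert not gap_profile(cascade([2], [3])).valid

    def test_receptive_field_always_odd(self):
        for rates in itertools.product([1, 2, 3], repeat=2):
            profile = gap_profile(cascade(rates, (3, 5)))
            assert profile.receptive_field % 2 == 1

    def test_reflection_invariance_of_max_gap(self):
        # negating all taps (kernel reflection) cannot change gap structure:
        # the offset set is already symmetric, so the profile is reflection-invariant
        p = gap_profile(cascade((1, 3, 5), (3, 3, 5)))
        assert p.max_gaps == gap_profile(cascade((1, 3, 5), (3, 3, 5))).max_gaps


class TestValidateCascade:
    @pytest.mark.parametrize("rates,kernels,expected",
                             list(STANDARD_CASCADES.values()),
                             ids=list(STANDARD_CASCADES))
    def test_standard_cascades_gridding_free(self, rates, kernels, expected):
        profile = validate_cascade(cascade(rates, kernels))
        assert profile.valid
        assert "gridding-free" in profile.diagnostic

    def test_invalid_diagnostic_names_layer(self):
        profile = validate_cascade(cascade((2, 4, 8), (3, 3, 3)))
        assert not profile.valid
        assert "layer 1" in profile.diagnostic
        assert "M2" in profile.diagnostic.replace("M2=4", "M2")


class TestCoverageOracle:
    def test_block1_no_holes(self):
        report = coverage_oracle(cascade((1, 2, 5, 7, 9), (3, 3, 3, 5, 5)))
        assert report.receptive_field == 81
        assert not report.has_holes

    def test_even_cascade_has_parity_holes(self):
        report = coverage_oracle(cascade((2, 4, 8), (3, 3, 3)))
        assert report.has_holes
        assert all(x % 2 == 0 for x in report.covered)

    def test_single_dilated_layer_holes(self):
        report = coverage_oracle(cascade([2], [3]))
        assert set(report.covered) == {-2, 0, 2}
        assert report.holes == (-1, 1)

    def test_bound_enforced(self):
        with pytest.raises(ValueError):
            coverage_oracle(cascade([600], [3]), max_receptive_field=1001)


class TestHdcReferenceGap:
    @pytest.mark.parametrize("r,m,expected", [(9, 1, 9), (2, 5, 2), (5, 9, 5)])
    def test_printed_and_intermediate_cases(self, r, m, expected):
        assert hdc_reference_gap(r, m) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            hdc_reference_gap(0, 1)
        with pytest.raises(ValueError):
            hdc_reference_gap(1, 0)

    def test_agreement_with_enumeration(self):
        """The closed form vs the exact k=3 enumeration, r in 1..9, M in 1..30.

        On the M_up > 2r branch the two are identical.  The 0 < M_up < r branch
        is a conservative upper bound on the exact gap (it is exact at the top
        of a cascade where the layer above collapses to one read position), so
        it may only over-estimate — never under-estimate — the gap.
        """
        for r in range(1, 10):
            for m in range(1, 31):
                exact = layer_offsets(3, r, 3, m).max_gap
                closed = hdc_reference_gap(r, m)
                if m > 2 * r:
                    assert closed == exact, (r, m)
                elif m < r:
                    assert closed == r >= exact, (r, m)
                else:  # intermediate case delegates to the enumeration
                    assert closed == exact, (r, m)

    def test_hdc_recursion_reproduces_reference_design(self):
        # top-down through rates [1,2,5,9]: M_4=r_4=9 (top), then 5, 2, 1
        rates = (1, 2, 5, 9)
        m = 1  # boundary above the top layer
        gaps = []
        for r in reversed(rates):
            m = hdc_reference_gap(r, m)
            gaps.append(m)
        assert gaps == [9, 5, 2, 1]


class TestDesignCascade:
    def test_two_layer_search_contains_default(self):
        designs = design_cascade(2, {3}, max_rate=2, min_receptive_field=7)
        assert (1, 2) in {c.rates for c in designs}

    def test_trivial_single_layer(self):
        designs = design_cascade(1, {3}, max_rate=1, min_receptive_field=3)
        assert len(designs) == 1
        assert designs[0].rates == (1,)

    def test_excludes_gridding_cascades(self):
        designs = design_cascade(3, {3}, max_rate=8, min_receptive_field=1)
        assert (2, 4, 8) not in {c.rates for c in designs}
        # every returned design must also pass the brute-force oracle check
        # when it starts dense (r1 == 1)
        for c in designs[:20]:
            if c.rates[0] == 1:
                assert not coverage_oracle(c).has_holes

    def test_deterministic_ordering(self):
        a = design_cascade(2, {3, 5}, max_rate=3, min_receptive_field=1)
        b = design_cascade(2, {5, 3}, max_rate=3, min_receptive_field=1)
        assert [(c.rates, c.kernels) for c in a] == [(c.rates, c.kernels) for c in b]
        fields = [receptive_field(c) for c in a]
        assert fields == sorted(fields, reverse=True)

    def test_empty_result_is_not_an_error(self):
        assert design_cascade(1, {3}, max_rate=1, min_receptive_field=99) == []


@settings(deadline=None, max_examples=60)
@given(
    st.lists(st.tuples(st.sampled_from([1, 3, 5]), st.integers(1, 4)),
             min_size=1, max_size=3)
)
def test_validity_implies_coverage_when_first_layer_dense(layers):
    """Soundness: a validator-accepted cascade starting at r1=1 has no holes."""
    layers = [(layers[0][0], 1)] + layers[1:]
    c = CascadeSpec(tuple(DilatedLayerSpec(k, r) for k, r in layers))
    if gap_profile(c).valid and receptive_field(c) <= 1001:
        assert not coverage_oracle(c).has_holes
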