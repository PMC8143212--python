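"""Rate laws, variant mapping and parameter-set contracts."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atgdyn import (
    MitophagyParams,
    ModelVariant,
    NonselectiveParams,
    rate_accumulation,
    rate_removal,
)

EXPECTED_VARIANTS = {
    1: (True, "accumulation"),
    2: (True, "removal"),
    3: (True, "both"),
    4: (False, "accumulation"),
    5: (False, "removal"),
    6: (False, "both"),
}


class TestVariantMapping:
    def test_bijection_event_flag_and_target(self):
        seen = set()
        for vid, (event, target) in EXPECTED_VARIANTS.items():
            v = ModelVariant(vid)
            assert v.event_based is event
            assert v.wortmannin_target == target
            seen.add((v.event_based, v.wortmannin_target))
        assert len(seen) == 6

    @pytest.mark.parametrize("vid", [0, 7, -1])
    def test_invalid_id_rejected(self, vid):
        with pytest.raises(ValueError):
            ModelVariant(vid)

    def test_serialization_round_trip(self):
        for vid in range(1, 7):
            v = ModelVariant(vid)
            assert ModelVariant.from_json(v.to_json()) == v


class TestRateLaws:
    @pytest.mark.parametrize(
        "A,kprod,m,kwrtm,wtm,vid,expected",
        [
            # published accumulation constant at unit aggregate
            (1.0, 0.0082, 1.01365, 1.0, False, 3, 0.0082),
            (0.0, 0.01, 1.0, 1.0, False, 3, 0.0),
            # hand-computed: 0.01 * 2**2 * 0.5
            (2.0, 0.01, 2.0, 0.5, True, 3, 0.02),
            # variant 2 does not target accumulation
            (2.0, 0.01, 2.0, 0.5, True, 2, 0.04),
        ],
    )
    def test_accumulation(self, A, kprod, m, kwrtm, wtm, vid, expected):
        p = NonselectiveParams(kprodATG13=kprod, m=m, kwrtm=kwrtm)
        assert rate_accumulation(A, p, wtm, ModelVariant(vid)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "A,krem,kwrtm,wtm,vid,expected",
        [
            # published removal constant at unit aggregate
            (1.0, 0.0029, 1.0, False, 3, 0.0029),
            (0.0, 0.1, 1.0, False, 3, 0.0),
            # hand-computed: 0.1 * 3 * 0.2, variant 2 targets removal
            (3.0, 0.1, 0.2, True, 2, 0.06),
            # variant 1 leaves removal untouched by wortmannin
            (3.0, 0.1, 0.2, True, 1, 0.3),
        ],
    )
    def test_removal(self, A, krem, kwrtm, wtm, vid, expected):
        p = NonselectiveParams(kremATG13=krem, kwrtm=kwrtm)
        assert rate_removal(A, p, wtm, ModelVariant(vid)) == pytest.approx(expected)

    def test_negative_aggregate_rejected(self):
        p = NonselectiveParams()
        with pytest.raises(ValueError):
            rate_accumulation(-0.1, p)
        with pytest.raises(ValueError):
            rate_removal(-0.1, p)

    @settings(max_examples=50, deadline=None)
    @given(
        a1=st.floats(0.0, 50.0),
        a2=st.floats(0.0, 50.0),
        m=st.floats(0.0, 4.0),
        vid=st.integers(1, 6),
    )
    def test_accumulation_monotone_in_aggregate(self, a1, a2, m, vid):
        p = NonselectiveParams(m=m)
        lo, hi = sorted([a1, a2])
        v = ModelVariant(vid)
        assert rate_accumulation(lo, p, False, v) <= rate_accumulation(hi, p, False, v) + 1e-12

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0.0, 50.0),
        vid=st.integers(1, 6),
        wtm=st.booleans(),
    )
    def test_kwrtm_one_is_control_equivalence(self, a, vid, wtm):
        p = NonselectiveParams(kwrtm=1.0)
        v = ModelVariant(vid)
        assert rate_accumulation(a, p, wtm, v) == rate_accumulation(a, p, False, v)
        assert rate_removal(a, p, wtm, v) == rate_removal(a, p, False, v)

    def test_removal_linear_in_aggregate(self):
        p = NonselectiveParams(kremATG13=0.25)
        assert rate_removal(4.0, p) == pytest.approx(4 * rate_removal(1.0, p))


class TestParameterSets:
    def test_nonselective_json_round_trip(self):
        p = NonselectiveParams(kprodATG13=0.0082, kremATG13=0.0029, m=1.01365, kwrtm=0.4, t=150.0)
        q = NonselectiveParams.from_json(p.to_json())
        assert q == p
        assert set(json.loads(p.to_json())) >= {"kprodATG13", "kremATG13", "m", "kwrtm", "t"}

    def test_mitophagy_json_round_trip(self):
        p = MitophagyParams(kprodLC3=0.2, kpeak=1.0, p=2.5, Tau=5.0)
        assert MitophagyParams.from_json(p.to_json()) == p

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kprodATG13=-1e-3),
            dict(kwrtm=0.0),
            dict(kwrtm=1.5),
            dict(t=-5.0),
            dict(atg13_seed=0.0),
            dict(m=-0.1),
        ],
    )
    def test_nonselective_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            NonselectiveParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(p=-0.5), dict(engulf_coeff=0.0), dict(t_sd=-1.0), dict(kpeak=-0.1)],
    )
    def test_mitophagy_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            MitophagyParams(**kwargs)
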