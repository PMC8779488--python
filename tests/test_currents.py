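"""Conductance-scaling algebra and the AF remodeling set."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrialsim.currents import (AF_REMODELING, CURRENT_ORDER,
                                ConductanceScaling, CurrentID, af_variant)

ALL_IDS = list(CurrentID)


class TestConductanceScaling:
    def test_default_is_identity(self):
        sc = ConductanceScaling()
        assert all(sc[c] == 1.0 for c in ALL_IDS)
        assert np.array_equal(sc.as_vector(), np.ones(9))

    def test_exactly_nine_scalable_currents(self):
        assert len(CURRENT_ORDER) == 9
        assert {c.value for c in CURRENT_ORDER} == {
            "INa", "Ito", "ICaL", "IKur", "IKr", "IKs", "IK1", "INCX", "INaK"}

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_rejects_invalid_multipliers(self, bad):
        with pytest.raises(ValueError):
            ConductanceScaling({CurrentID.INa: bad})

    def test_rejects_unknown_current(self):
        with pytest.raises(ValueError):
            ConductanceScaling({"IFunny": 1.0})

    @given(a=st.floats(0.0, 4.0), b=st.floats(0.0, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_composition_is_elementwise_product(self, a, b):
        sa = ConductanceScaling({CurrentID.IKr: a})
        sb = ConductanceScaling({CurrentID.IKr: b, CurrentID.INa: 0.5})
        sc = sa.compose(sb)
        assert sc[CurrentID.IKr] == pytest.approx(a * b)
        assert sc[CurrentID.INa] == 0.5
        # commutative
        assert sb.compose(sa).to_dict() == sc.to_dict()

    def test_zero_is_full_block(self):
        sc = ConductanceScaling({CurrentID.ICaL: 0.0})
        assert sc.as_vector()[2] == 0.0

    def test_with_current_replaces_not_composes(self):
        sc = ConductanceScaling({CurrentID.Ito: 0.2})
        assert sc.with_current(CurrentID.Ito, 1.0)[CurrentID.Ito] == 1.0


class TestAFRemodeling:
    def test_published_remodeling_multipliers(self):
        sc = af_variant()
        expected = {"INa": 0.90, "Ito": 0.20, "ICaL": 0.50, "IKur": 0.45,
                    "IKr": 1.0, "IKs": 2.0, "IK1": 2.0, "INCX": 1.4,
                    "INaK": 1.0}
        assert sc.to_dict() == pytest.approx(expected)

    def test_applying_twice_squares_the_multipliers(self):
        twice = af_variant(af_variant())
        assert twice[CurrentID.INa] == pytest.approx(0.90 ** 2)
        assert twice[CurrentID.IK1] == pytest.approx(4.0)
        assert twice.to_dict() != af_variant().to_dict()

    def test_recovering_ito_restores_baseline_entry_only(self):
        sc = af_variant().with_current(CurrentID.Ito, 1.0)
        assert sc[CurrentID.Ito] == 1.0
        for c in (CurrentID.INa, CurrentID.ICaL, CurrentID.IKur,
                  CurrentID.IKs, CurrentID.IK1, CurrentID.INCX):
            assert sc[c] == af_variant()[c]

    def test_ikr_and_inak_not_remodeled(self):
        assert CurrentID.IKr not in AF_REMODELING
        assert CurrentID.INaK not in AF_REMODELING
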