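"""Activity map assembly and positional / Y-paralogue permutation tests."""

import numpy as np
import pytest

from xescape.chrommap import (
    build_map,
    polarity_test,
    y_paralogue_association,
)
from xescape.escape import EscapeEstimate
from xescape.locus_model import LocusMeta, YParalogue


def _estimate(lid, e, n=500):
    return EscapeEstimate(
        locus_id=lid, f2=e, f1=1 - e, f0=0.0, e_raw=e, e_corrected=e,
        ci_low=max(e - 0.05, 0), ci_high=min(e + 0.05, 1), n=n, d_used=1.0,
    )


def _panel(values, y_status=None, n=500):
    metas, ests = [], []
    for i, v in enumerate(values):
        lid = f"L{i:02d}"
        status = YParalogue.NONE if y_status is None else y_status[i]
        metas.append(
            LocusMeta(lid, (lid,), x_position=(i + 1) * 1_000_000, y_paralogue=status)
        )
        ests.append(_estimate(lid, v, n))
    return metas, ests


def _sampled(rng, e, n=500):
    """e_raw with multinomial sampling noise at perfect detection."""
    return rng.binomial(n, e) / n


class TestBuildMap:
    def test_orders_by_position_regardless_of_input_order(self):
        metas, ests = _panel([0.1, 0.2, 0.3, 0.4, 0.5])
        amap1 = build_map(metas, ests)
        amap2 = build_map(metas[::-1], ests[::-1])
        assert [m.locus_id for m, _ in amap1.entries] == [
            m.locus_id for m, _ in amap2.entries
        ]
        assert list(amap1.positions) == sorted(amap1.positions)

    def test_unmapped_locus_dropped_with_warning(self):
        metas, ests = _panel([0.1, 0.2, 0.3])
        metas[1] = LocusMeta("L01", ("L01",), x_position=None)
        with pytest.warns(UserWarning, match="no position"):
            amap = build_map(metas, ests)
        assert len(amap.entries) == 2

    def test_single_locus_map_refuses_polarity_test(self):
        metas, ests = _panel([0.3])
        amap = build_map(metas, ests)
        with pytest.raises(ValueError, match=">= 5"):
            polarity_test(amap, n_permutations=99, seed=0)


class TestPolarityTest:
    def test_linear_gradient_detected(self):
        rng = np.random.default_rng(13)
        grad = np.linspace(0.05, 0.7, 20)
        metas, ests = _panel([_sampled(rng, e) for e in grad])
        res = polarity_test(build_map(metas, ests), n_permutations=9999, seed=13)
        assert res["trend"].p_value < 0.01

    def test_null_rejection_rate_near_alpha(self):
        # constant true e; variation is pure sampling noise -> exchangeable
        rng = np.random.default_rng(7)
        rej = 0
        reps = 500
        for _ in range(reps):
            metas, ests = _panel([_sampled(rng, 0.3) for _ in range(20)])
            res = polarity_test(
                build_map(metas, ests),
                n_permutations=999,
                seed=int(rng.integers(2**31)),
            )
            rej += res["trend"].p_value < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_invariant_to_monotone_position_rescaling(self):
        rng = np.random.default_rng(3)
        vals = [_sampled(rng, 0.3) for _ in range(10)]
        metas, ests = _panel(vals)
        squared = [
            LocusMeta(m.locus_id, m.genes, x_position=(m.x_position // 1_000_000) ** 2)
            for m in metas
        ]
        r1 = polarity_test(build_map(metas, ests), n_permutations=999, seed=5)
        r2 = polarity_test(build_map(squared, ests), n_permutations=999, seed=5)
        assert r1["trend"].statistic_value == pytest.approx(
            r2["trend"].statistic_value
        )
        assert r1["trend"].p_value == r2["trend"].p_value

    def test_permutation_p_reproducible_and_positive(self):
        rng = np.random.default_rng(19)
        metas, ests = _panel([_sampled(rng, 0.3) for _ in range(12)])
        amap = build_map(metas, ests)
        r1 = polarity_test(amap, n_permutations=999, seed=11)
        r2 = polarity_test(amap, n_permutations=999, seed=11)
        assert r1["trend"].p_value == r2["trend"].p_value > 0.0
        assert r1["adjacency"].p_value == r2["adjacency"].p_value > 0.0


class TestYParalogueAssociation:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(17)
        status = [YParalogue.EXPRESSED] * 7 + [YParalogue.NONE] * 13
        values = [
            _sampled(rng, 0.2 + (0.4 if s is YParalogue.EXPRESSED else 0.0))
            for s in status
        ]
        metas, ests = _panel(values, y_status=status)
        res = y_paralogue_association(build_map(metas, ests), seed=17)
        assert res.p_value < 0.01
        assert res.group_sizes == {"none": 13, "expressed": 7}

    def test_single_group_refused(self):
        metas, ests = _panel([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            y_paralogue_association(build_map(metas, ests), seed=0)

    def test_null_association_not_rejected(self):
        rng = np.random.default_rng(29)
        status = ([YParalogue.EXPRESSED] * 5 + [YParalogue.SILENT] * 5
                  + [YParalogue.NONE] * 10)
        values = [_sampled(rng, 0.3) for _ in status]
        metas, ests = _panel(values, y_status=status)
        res = y_paralogue_association(
            build_map(metas, ests), n_permutations=1999, seed=29
        )
        assert res.p_value > 0.05
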