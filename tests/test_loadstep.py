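"""Load-step summaries, histograms and rank correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trabdvc import build_grid, correlate_morphometry, histogram, spearman, summarize
from trabdvc.morphometry import MorphometryResult
from trabdvc.strainfield import StrainField


def strain_field_with_ep3(ep3_values, ns=16):
    """Minimal StrainField whose included nodes carry prescribed ep3 (µε)."""
    grid = build_grid((64, 64, 64), 39.0, ns)
    shape = grid.shape
    n = int(np.prod(shape))
    vals = np.zeros(n)
    included = np.zeros(n, dtype=bool)
    vals[: len(ep3_values)] = ep3_values
    included[: len(ep3_values)] = True
    principal = np.zeros(shape + (3,))
    principal[..., 2] = vals.reshape(shape)
    eps = np.zeros(shape + (6,))
    eps[..., 2] = vals.reshape(shape)
    return StrainField(
        grid=grid,
        eps=eps,
        principal=principal,
        eqv=np.abs(vals).reshape(shape),
        included=included.reshape(shape),
        boundary=np.zeros(shape, dtype=bool),
    )


class TestSummarize:
    def test_uniform_beyond_yield(self):
        strain = strain_field_with_ep3([-12000.0] * 8)
        s = summarize(strain)
        assert s.percent_above_yield == 100.0
        assert s.med_ep3_magnitude == pytest.approx(12000.0)

    def test_half_and_half_midpoint_median(self):
        strain = strain_field_with_ep3([-12000.0] * 4 + [-2000.0] * 4)
        s = summarize(strain)
        assert s.percent_above_yield == 50.0
        assert s.med_ep3_magnitude == pytest.approx(7000.0)

    def test_min_median_max_ordering(self):
        rng = np.random.default_rng(3)
        strain = strain_field_with_ep3(list(rng.normal(-3000, 2000, 20)))
        s = summarize(strain)
        for comp, d in s.stats.items():
            assert d["min"] <= d["median"] <= d["max"]

    def test_yield_fraction_nondecreasing_with_load(self):
        # stepwise loading analogue: the same field scaled by rising load
        rng = np.random.default_rng(4)
        base = rng.normal(-5000, 4000, 50)
        pcts = []
        for scale in (0.5, 1.0, 2.0):
            s = summarize(strain_field_with_ep3(list(base * scale)))
            pcts.append(s.percent_above_yield)
        assert pcts == sorted(pcts)

    def test_empty_field_rejected(self):
        strain = strain_field_with_ep3([1.0])
        strain.included[:] = False
        with pytest.raises(ValueError):
            summarize(strain)


class TestHistogram:
    def test_all_zero_single_bin(self):
        strain = strain_field_with_ep3([0.0] * 10)
        edges, counts = histogram(strain, "ep3", bin_width=500.0)
        assert counts.sum() == 10
        assert (counts > 0).sum() == 1

    def test_counts_conserved_under_bin_width(self):
        rng = np.random.default_rng(5)
        strain = strain_field_with_ep3(list(rng.normal(0, 3000, 40)))
        for w in (100.0, 750.0, 5000.0):
            edges, counts = histogram(strain, "ep3", bin_width=w)
            assert counts.sum() == 40
            assert len(edges) == len(counts) + 1

    def test_two_level_field_two_bins(self):
        strain = strain_field_with_ep3([-12000.0] * 3 + [-2000.0] * 5)
        _, counts = histogram(strain, "ep3", bin_width=1000.0)
        assert (counts > 0).sum() == 2
        assert sorted(counts[counts > 0]) == [3, 5]


class TestSpearman:
    def test_thickness_vs_connectivity_reference_columns(self):
        # five-specimen morphometry: Tb.Th against Conn.D
        tb_th = [243.0, 250.0, 271.0, 269.0, 304.0]
        conn = [8.26, 6.41, 5.23, 5.06, 3.20]
        res = spearman(tb_th, conn)
        assert res.r_s == pytest.approx(-0.90, abs=1e-9)

    def test_t_approximation_p_value(self):
        # rank-correlation 0.9 at n=5 under the t convention
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 5.0, 4.0]
        res = spearman(x, y)
        assert res.r_s == pytest.approx(0.90)
        assert res.p_two_tailed == pytest.approx(0.037, abs=5e-4)
        # exact permutation test disagrees with the t convention here
        assert res.p_exact == pytest.approx(2 * 5 / 120, abs=1e-9)

    def test_perfect_monotone_exact_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 20.0, 30.0, 40.0, 50.0]
        res = spearman(x, y)
        assert res.r_s == pytest.approx(1.0)
        assert res.p_exact == pytest.approx(2.0 / 120.0)
        assert res.p_two_tailed == 0.0  # t statistic diverges

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.integers(min_value=-10_000, max_value=10_000),
            min_size=4, max_size=7, unique=True,
        ),
        st.lists(
            st.integers(min_value=-10_000, max_value=10_000),
            min_size=7, max_size=7, unique=True,
        ),
    )
    def test_symmetry_and_monotone_invariance(self, xs, ys):
        xs = [float(v) for v in xs]
        ys = [float(v) for v in ys[: len(xs)]]
        res_xy = spearman(xs, ys)
        res_yx = spearman(ys, xs)
        assert res_xy.r_s == pytest.approx(res_yx.r_s, abs=1e-12)
        # strictly monotone transform of either vector leaves r_s unchanged
        res_t = spearman([3.0 * v + 7.0 for v in xs], ys)
        assert res_t.r_s == pytest.approx(res_xy.r_s, abs=1e-12)


def summary_with(med_ep3, pct):
    return type(
        "S", (), {"med_ep3_magnitude": med_ep3, "percent_above_yield": pct}
    )()


def morpho_result(**kw):
    defaults = dict(
        tb_bvtv=20.0, tb_th=250.0, tb_sp=900.0, tb_n=0.8, conn_d=5.0,
        region_volume=40.0,
    )
    defaults.update(kw)
    return MorphometryResult(**defaults)


class TestCorrelateMorphometry:
    def test_monotone_association_gives_unit_correlation(self):
        th = [200.0, 230.0, 260.0, 290.0, 320.0]
        morph = [
            morpho_result(tb_th=t, tb_bvtv=18 + i, tb_sp=900 - 7 * i,
                          tb_n=0.7 + 0.01 * i, conn_d=8 - i)
            for i, t in enumerate(th)
        ]
        sums = {"LS2": [summary_with(1000 + 10 * t, 10.0 + i) for i, t in enumerate(th)]}
        df = correlate_morphometry(sums, morph)
        cell = df[(df.strain_param == "med_ep3") & (df.morpho_param == "tb_th")]
        assert cell.r_s.iloc[0] == pytest.approx(1.0)

    def test_grid_shape_per_load_step(self):
        rng = np.random.default_rng(6)
        morph = [
            morpho_result(tb_th=250 + 10 * rng.standard_normal(),
                          tb_bvtv=20 + rng.standard_normal(),
                          tb_sp=900 + 10 * rng.standard_normal(),
                          tb_n=0.8 + 0.05 * rng.standard_normal(),
                          conn_d=5 + rng.standard_normal())
            for _ in range(5)
        ]
        sums = {
            ls: [summary_with(2000 + 100 * rng.standard_normal(),
                              rng.uniform(5, 40)) for _ in range(5)]
            for ls in ("LS2", "LS3")
        }
        df = correlate_morphometry(sums, morph)
        # 2 strain parameters x 5 morphometric columns per load step
        assert len(df) == 2 * 2 * 5
        assert set(df.load_step) == {"LS2", "LS3"}

    def test_p_values_match_spearman_cellwise(self):
        rng = np.random.default_rng(7)
        morph = [
            morpho_result(tb_th=240 + 15 * i + rng.standard_normal(),
                          tb_bvtv=18 + rng.uniform(0, 8),
                          tb_sp=800 + rng.uniform(0, 300),
                          tb_n=0.7 + rng.uniform(0, 0.2),
                          conn_d=8 - i + 0.1 * rng.standard_normal())
            for i in range(5)
        ]
        vals = [1500.0, 2100.0, 1900.0, 2600.0, 2300.0]
        sums = {"LS3": [summary_with(v, 10.0 + 2 * i) for i, v in enumerate(vals)]}
        df = correlate_morphometry(sums, morph)
        row = df[(df.strain_param == "med_ep3") & (df.morpho_param == "tb_th")].iloc[0]
        direct = spearman(vals, [m.tb_th for m in morph])
        assert row.r_s == pytest.approx(direct.r_s)
        assert row.p_t_approx == pytest.approx(direct.p_two_tailed)

    def test_too_few_specimens(self):
        with pytest.raises(ValueError, match="3"):
            correlate_morphometry(
                {"LS2": [summary_with(1.0, 1.0)] * 2},
                [morpho_result(), morpho_result()],
            )
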