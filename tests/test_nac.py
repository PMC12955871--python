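"""Reaction-coordinate geometry, NAC classification and site statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from omtkit.errors import DegenerateGeometryError, SelectionError
from omtkit.nac import (
    GeometryRecord,
    ReactiveRegion,
    SiteSpec,
    angle_deg,
    classify,
    kde2d,
    measure_site,
    rank_sites,
    records_to_frame,
    site_stats,
)
from omtkit.structio import Ensemble, Selector
from omtkit.synth import SiteDistribution, embed_geometry, generate_ensemble, site_spec_for_chain

from conftest import make_frame


class TestAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0, 0], [-1, 0, 0], 180.0),  # collinear
            ([1, 0, 0], [0, 1, 0], 90.0),    # orthogonal
            ([1, 0, 0], [0.5, np.sqrt(3) / 2, 0], 60.0),  # equilateral triangle
        ],
    )
    def test_reference_angles(self, a, b, expected):
        assert angle_deg(a, [0, 0, 0], b) == pytest.approx(expected, abs=1e-10)

    def test_zero_length_arm(self):
        with pytest.raises(DegenerateGeometryError):
            angle_deg([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_clamped_against_rounding(self):
        # nearly collinear vectors can push the cosine past +/-1 in floats
        v = np.array([1.0, 1e-9, 0.0])
        assert 0.0 <= angle_deg(v, [0, 0, 0], v * 3.0) <= 180.0


class TestMeasureSite:
    def _frame(self, n_coords):
        coords = [[0, 0, 0], [-2, 0, 0], [-3.8, 0, 0]] + n_coords
        names = ["O", "C1", "S"] + [f"NE{i}" for i in range(len(n_coords))]
        return make_frame(coords, names=names)

    def _site(self, n_names):
        return SiteSpec(
            label="t",
            o_sel=Selector(atom_names=["O"]),
            n_sels=[Selector(atom_names=[n]) for n in n_names],
            c1_sel=Selector(atom_names=["C1"]),
            s_sel=Selector(atom_names=["S"]),
        )

    def test_constructed_collinear_case(self):
        rec = measure_site(self._frame([[3.3, 0, 0]]), self._site(["NE0"]))
        assert rec.d == pytest.approx(3.3, abs=1e-12)
        assert rec.theta == pytest.approx(180.0, abs=1e-6)

    def test_minimum_over_acceptor_nitrogens(self):
        rec = measure_site(self._frame([[3.3, 0, 0], [5.0, 0, 0]]), self._site(["NE0", "NE1"]))
        assert rec.d == pytest.approx(3.3, abs=1e-12)

    def test_ambiguous_selector_reports_site(self):
        frame = self._frame([[3.3, 0, 0]])
        site = self._site(["NE0"])
        site.o_sel = Selector(resname="GLY")  # matches every atom
        with pytest.raises(SelectionError, match="'t'"):
            measure_site(frame, site)

    @pytest.mark.parametrize("d,theta", [(3.3, 155.0), (1.0, 90.0), (6.2, 25.0)])
    def test_round_trip_against_embedding(self, d, theta):
        frame = embed_geometry(d, theta)
        rec = measure_site(frame, site_spec_for_chain("x", "A"))
        assert rec.d == pytest.approx(d, abs=1e-6)
        assert rec.theta == pytest.approx(theta, abs=1e-6)


class TestClassify:
    # printed model geometries of the gallacetophenone hydroxyls: only the
    # 3'-OH pair lies inside the default reactive box
    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (3.3, 155.0, True),    # 3'-OH: both criteria met
            (5.8, 110.0, False),   # 2'-OH: both fail
            (4.0, 160.0, False),   # 4'-OH: distance fails
            (3.5, 150.0, False),   # strict '<' at the distance boundary
            (3.4, 125.0, True),    # inclusive theta window, lower edge
            (3.4, 170.0, True),    # inclusive theta window, upper edge
        ],
    )
    def test_reactive_region_membership(self, d, theta, expected):
        rec = GeometryRecord(frame_index=1, site_label="s", d=d, theta=theta)
        assert classify(rec, ReactiveRegion()) is expected

    @given(
        d=st.floats(0.6, 8.0),
        theta=st.floats(0.0, 180.0),
        shrink_d=st.floats(0.1, 3.0),
        lo=st.floats(0.0, 40.0),
        hi=st.floats(0.0, 40.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_shrinking_region_is_monotone(self, d, theta, shrink_d, lo, hi):
        """A conformation outside a region stays outside any smaller region."""
        big = ReactiveRegion(d_max=4.5, theta_min=100.0, theta_max=175.0)
        small = ReactiveRegion(
            d_max=max(big.d_max - shrink_d, 0.2),
            theta_min=min(big.theta_min + lo, 174.0),
            theta_max=max(big.theta_max - hi, min(big.theta_min + lo, 174.0) + 0.5),
        )
        rec = GeometryRecord(frame_index=1, site_label="s", d=d, theta=theta)
        if classify(rec, small):
            assert classify(rec, big)


class TestSiteStats:
    def test_fraction_by_construction(self):
        """Region cut so exactly the 4 smallest-d draws of 10 are reactive."""
        dist = SiteDistribution("s", 3.3, 0.4, 150.0, 12.0)
        ens, truth = generate_ensemble([dist], 10, seed=7)
        d_sorted = np.sort(truth.table["d_angstrom"].to_numpy())
        cut = 0.5 * (d_sorted[3] + d_sorted[4])
        region = ReactiveRegion(d_max=cut, theta_min=0.0, theta_max=180.0)
        st_ = site_stats(ens, truth.site_specs["s"], region)
        assert st_.fraction == pytest.approx(0.4)
        assert st_.n_reactive == 4

    def test_fraction_is_exact_integer_arithmetic(self):
        dist = SiteDistribution("s", 3.3, 0.3, 155.0, 10.0)
        ens, truth = generate_ensemble([dist], 37, seed=3)
        st_ = site_stats(ens, truth.site_specs["s"], truth.region)
        brute = sum(
            classify(r, truth.region) for r in st_.records
        )
        assert st_.fraction == brute / 37

    def test_identical_frames_kde_peaks_at_the_point(self):
        frame = embed_geometry(3.0, 150.0)
        frames = [embed_geometry(3.0, 150.0, frame_index=i + 1) for i in range(5)]
        ens = Ensemble(frames=frames)
        st_ = site_stats(ens, site_spec_for_chain("s", "A"), ReactiveRegion())
        imax, jmax = np.unravel_index(np.argmax(st_.kde), st_.kde.shape)
        assert st_.d_axis[imax] == pytest.approx(3.0, abs=np.diff(st_.d_axis)[0])
        assert st_.theta_axis[jmax] == pytest.approx(150.0, abs=np.diff(st_.theta_axis)[0])

    def test_fraction_matches_cdf_product_oracle(self):
        """Empirical reactive fraction converges to the closed-form product of
        the marginal probabilities (independent d and theta); small-n variant
        of the full-scale check, 3-sigma binomial bound."""
        n = 4000
        dist = SiteDistribution("s", 3.3, 0.3, 155.0, 10.0)
        ens, truth = generate_ensemble([dist], n, seed=11)
        st_ = site_stats(ens, truth.site_specs["s"], truth.region)
        p_d = norm.cdf((3.5 - 3.3) / 0.3)
        p_t = (norm.cdf((170 - 155) / 10) - norm.cdf((125 - 155) / 10)) / (
            norm.cdf((180 - 155) / 10) - norm.cdf((0 - 155) / 10)
        )
        p = p_d * p_t
        assert abs(st_.fraction - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_kde_riemann_sum_near_unity(self):
        dist = SiteDistribution("s", 3.3, 0.3, 155.0, 10.0)
        ens, truth = generate_ensemble([dist], 500, seed=5)
        st_ = site_stats(ens, truth.site_specs["s"], truth.region)
        dd = np.diff(st_.d_axis)[0]
        dt = np.diff(st_.theta_axis)[0]
        assert 0.95 <= st_.kde.sum() * dd * dt <= 1.05

    def test_records_table_columns(self):
        dist = SiteDistribution("s", 3.3, 0.3, 155.0, 10.0)
        ens, truth = generate_ensemble([dist], 5, seed=1)
        st_ = site_stats(ens, truth.site_specs["s"], truth.region)
        df = records_to_frame(st_.records)
        assert list(df.columns) == ["frame", "site", "d_angstrom", "theta_deg", "reactive"]
        assert len(df) == 5


def test_kde_equals_bruteforce_kernel_sum(rng):
    """Vectorised KDE equals the explicit double-loop kernel sum to 1e-12."""
    d_vals = rng.normal(3.3, 0.3, size=60)
    t_vals = rng.normal(155.0, 10.0, size=60)
    d_axis = np.linspace(0, 8, 20)
    t_axis = np.linspace(0, 180, 20)
    grid = kde2d(d_vals, t_vals, d_axis, t_axis)

    from omtkit.nac import scott_bandwidth

    hd, ht = scott_bandwidth(d_vals), scott_bandwidth(t_vals)
    brute = np.zeros((20, 20))
    for i, x in enumerate(d_axis):
        for j, y in enumerate(t_axis):
            s = 0.0
            for dv, tv in zip(d_vals, t_vals):
                s += (
                    np.exp(-0.5 * ((x - dv) / hd) ** 2) / (hd * np.sqrt(2 * np.pi))
                    * np.exp(-0.5 * ((y - tv) / ht) ** 2) / (ht * np.sqrt(2 * np.pi))
                )
            brute[i, j] = s / len(d_vals)
    np.testing.assert_allclose(grid, brute, atol=1e-12)


class TestRankSites:
    def _stats(self, label, frac):
        from omtkit.nac import SiteStats

        return SiteStats(site_label=label, n_frames=1000, n_reactive=int(frac * 1000),
                         fraction=frac, records=[], kde=np.zeros((2, 2)),
                         d_axis=np.zeros(2), theta_axis=np.zeros(2))

    def test_published_fractions_force_ordering(self):
        ranking = rank_sites([
            self._stats("2'-OH", 0.0001),
            self._stats("3'-OH", 0.319),
            self._stats("4'-OH", 0.003),
        ])
        assert [lab for lab, _ in ranking.ordered] == ["3'-OH", "4'-OH", "2'-OH"]
        assert ranking.top_site == "3'-OH"
        assert not ranking.tied_labels

    def test_tie_flagged_and_alphabetical(self):
        ranking = rank_sites([self._stats("B", 0.2), self._stats("A", 0.2)])
        assert [lab for lab, _ in ranking.ordered] == ["A", "B"]
        assert ranking.tied_labels == {"A", "B"}

    def test_single_site(self):
        ranking = rank_sites([self._stats("only", 0.5)])
        assert ranking.top_site == "only"
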