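import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nephrospan.kidney_classify import classify_person
from nephrospan.person import Person, Sex
from nephrospan.persontime import (
    AgeBandScheme,
    StratumCounts,
    aggregate_counts,
    exposure_matrix,
    read_counts_csv,
    split_exposure,
    write_counts_csv,
)


class TestAgeBandScheme:
    def test_default_bands(self, scheme):
        assert scheme.n_bands == 9
        np.testing.assert_allclose(
            scheme.edges, [40, 45, 50, 55, 60, 65, 70, 75, 80]
        )
        assert scheme.labels()[0] == "40-45"
        assert scheme.labels()[-1] == "80+"

    def test_band_index(self, scheme):
        assert scheme.band_index(40.0) == 0
        assert scheme.band_index(44.999) == 0
        assert scheme.band_index(45.0) == 1  # boundary goes up
        assert scheme.band_index(79.999) == 7
        assert scheme.band_index(80.0) == 8
        assert scheme.band_index(120.0) == 8

    def test_misaligned_scheme_rejected(self):
        with pytest.raises(ValueError):
            AgeBandScheme(start_age=40, band_width=5, open_band_start=82)


class TestSplitExposure:
    def test_mid_band_death(self, scheme):
        py, death = split_exposure(43.0, 47.5, True, scheme)
        assert py[0] == pytest.approx(2.0)
        assert py[1] == pytest.approx(2.5)
        assert py[2:].sum() == 0
        assert death == 1

    def test_all_before_40(self, scheme):
        py, death = split_exposure(30.0, 38.0, True, scheme)
        assert py.sum() == 0
        assert death is None

    def test_open_band(self, scheme):
        py, death = split_exposure(78.0, 85.0, False, scheme)
        assert py[7] == pytest.approx(2.0)
        assert py[8] == pytest.approx(5.0)
        assert death is None

    def test_death_at_exact_boundary_goes_up(self, scheme):
        _, death = split_exposure(43.0, 45.0, True, scheme)
        assert death == 1

    def test_exit_before_entry_rejected(self, scheme):
        with pytest.raises(ValueError):
            split_exposure(50.0, 49.0, False, scheme)

    @given(
        entry=st.floats(20.0, 95.0),
        dur=st.floats(0.0, 40.0),
        died=st.booleans(),
        cut=st.floats(0.0, 1.0),
    )
    def test_subinterval_additivity(self, entry, dur, died, cut):
        """Cutting follow-up into abutting pieces and summing is a no-op."""
        exit_age = entry + dur
        mid = entry + dur * cut
        whole, death_whole = split_exposure(entry, exit_age, died)
        first, _ = split_exposure(entry, mid, False)
        second, death_second = split_exposure(mid, exit_age, died)
        np.testing.assert_allclose(whole, first + second, atol=1e-9)
        assert death_whole == death_second

    def test_matches_vectorized(self, scheme, rng):
        entry = rng.uniform(20, 95, size=200)
        exit_ = entry + rng.uniform(0, 30, size=200)
        died = rng.uniform(size=200) < 0.5
        py_mat, death_band = exposure_matrix(entry, exit_, died, scheme)
        for i in range(200):
            py, death = split_exposure(entry[i], exit_[i], died[i], scheme)
            np.testing.assert_allclose(py_mat[i], py, atol=1e-12)
            assert death_band[i] == (-1 if death is None else death)


def _classified_person(i, sex, index_age, exit_age, died, scr=0.9, acr=10.0):
    p = Person(
        id=f"p{i}",
        sex=sex,
        index_age=index_age,
        serum_creatinine=scr,
        acr_values=[acr],
        exit_age=exit_age,
        died=died,
    )
    return p, classify_person(p)


class TestAggregateCounts:
    def test_singleton_stratum_equals_split(self, scheme):
        pair = _classified_person(0, Sex.MALE, 43.0, 47.5, True)
        (sc,) = aggregate_counts([pair], scheme=scheme)
        py, death = split_exposure(43.0, 47.5, True, scheme)
        np.testing.assert_allclose(sc.person_years, py)
        assert sc.deaths[death] == 1
        assert sc.deaths.sum() == 1
        assert sc.key == "male|GE60|NORMAL"

    def test_duplication_doubles_counts(self, scheme, rng):
        pairs = [
            _classified_person(
                i, Sex.FEMALE, a, a + d, bool(z), scr=0.7, acr=50.0
            )
            for i, (a, d, z) in enumerate(
                zip(
                    rng.uniform(35, 85, 50),
                    rng.uniform(0, 20, 50),
                    rng.uniform(size=50) < 0.5,
                )
            )
        ]
        (single,) = aggregate_counts(pairs, scheme=scheme)
        (doubled,) = aggregate_counts(pairs + pairs, scheme=scheme)
        np.testing.assert_allclose(
            doubled.person_years, 2 * single.person_years, atol=1e-9
        )
        np.testing.assert_allclose(doubled.deaths, 2 * single.deaths)

    def test_kdigo_low_equals_ge60_normal_cell(self, scheme, rng):
        pairs = []
        i = 0
        for scr, acr in [(0.9, 10.0), (0.9, 100.0), (1.6, 10.0)]:
            for _ in range(20):
                a = rng.uniform(35, 85)
                pairs.append(
                    _classified_person(
                        i, Sex.MALE, a, a + rng.uniform(0, 15),
                        bool(rng.uniform() < 0.4), scr=scr, acr=acr,
                    )
                )
                i += 1
        by_cell = {
            sc.stratum: sc
            for sc in aggregate_counts(
                pairs, grouping="egfr_x_albuminuria", scheme=scheme
            )
        }
        by_risk = {
            sc.stratum: sc
            for sc in aggregate_counts(pairs, grouping="kdigo", scheme=scheme)
        }
        np.testing.assert_allclose(
            by_risk["LOW"].person_years,
            by_cell["GE60|NORMAL"].person_years,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            by_risk["LOW"].deaths, by_cell["GE60|NORMAL"].deaths
        )

    def test_conservation(self, scheme, rng):
        pairs = [
            _classified_person(
                i, Sex.MALE, a, a + d, bool(z),
                scr=[0.9, 1.4, 2.0][i % 3], acr=[5.0, 60.0, 400.0][i % 3],
            )
            for i, (a, d, z) in enumerate(
                zip(
                    rng.uniform(30, 88, 300),
                    rng.uniform(0, 25, 300),
                    rng.uniform(size=300) < 0.5,
                )
            )
        ]
        counts = aggregate_counts(pairs, scheme=scheme)
        total_py = sum(sc.person_years.sum() for sc in counts)
        expected = sum(
            max(0.0, p.exit_age - max(p.index_age, 40.0)) for p, _ in pairs
        )
        assert total_py == pytest.approx(expected, abs=1e-9)
        total_deaths = sum(sc.deaths.sum() for sc in counts)
        expected_deaths = sum(
            1 for p, _ in pairs if p.died and p.exit_age >= 40.0
        )
        assert total_deaths == expected_deaths

    def test_excluded_person_rejected(self):
        p = Person(
            id="x", sex=Sex.MALE, index_age=50.0, serum_creatinine=6.0,
            acr_values=[10.0], exit_age=55.0, died=False,
        )
        prof = classify_person(p)
        with pytest.raises(ValueError, match="excluded"):
            aggregate_counts([(p, prof)])

    def test_missing_profile_rejected(self):
        p = Person(
            id="x", sex=Sex.MALE, index_age=50.0, serum_creatinine=0.9,
            acr_values=[10.0], exit_age=55.0, died=False,
        )
        with pytest.raises(ValueError, match="profile"):
            aggregate_counts([(p, None)])


class TestCountsInvariants:
    def test_death_without_exposure_rejected(self, scheme):
        deaths = np.zeros(9)
        py = np.ones(9)
        deaths[3] = 1.0
        py[3] = 0.0
        with pytest.raises(ValueError):
            StratumCounts("x", Sex.MALE, deaths, py, scheme)

    def test_csv_roundtrip(self, tmp_path, rng):
        counts = [
            StratumCounts(
                "GE60|NORMAL", Sex.MALE,
                rng.integers(1, 50, 9).astype(float),
                rng.uniform(100, 5000, 9),
            ),
            StratumCounts(
                "LOW", Sex.FEMALE,
                rng.integers(1, 50, 9).astype(float),
                rng.uniform(100, 5000, 9),
            ),
        ]
        path = tmp_path / "counts.csv"
        write_counts_csv(counts, path)
        back = read_counts_csv(path)
        assert len(back) == 2
        for orig, rt in zip(counts, back):
            assert rt.stratum == orig.stratum
            assert rt.sex == orig.sex
            np.testing.assert_allclose(rt.deaths, orig.deaths)
            np.testing.assert_allclose(
                rt.person_years, orig.person_years, rtol=1e-9
            )
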