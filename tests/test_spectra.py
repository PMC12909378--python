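"""Spectrum I/O, cleaning, averaging, quality filtering, and labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edscreen import spectra as sp
from conftest import make_spectrum

MSP_TWO_RECORDS = """\
NAME: compoundA
PRECURSORMZ: 250.1200
IONMODE: positive
Num Peaks: 3
100.0 10
150.5 5
200.1 1

NAME: compoundB
PRECURSORMZ: 300.2000
Num Peaks: 3
90.0 100
120.0 50
299.9 20
"""

MGF_ONE_RECORD = """\
BEGIN IONS
TITLE=compoundC
PEPMASS=180.0500
100.0 1.0
150.0 0.4
END IONS
"""


class TestReadWrite:
    def test_msp_record_and_peak_counts(self, tmp_path):
        f = tmp_path / "two.msp"
        f.write_text(MSP_TWO_RECORDS)
        out = sp.read_spectra(f)
        assert len(out) == 2
        assert [len(s) for s in out] == [3, 3]
        assert out[0].compound_id == "compoundA"
        assert out[0].precursor_mz == pytest.approx(250.12)

    def test_mgf_parsing(self, tmp_path):
        f = tmp_path / "one.mgf"
        f.write_text(MGF_ONE_RECORD)
        (s,) = sp.read_spectra(f)
        assert s.compound_id == "compoundC"
        assert s.precursor_mz == pytest.approx(180.05)
        assert len(s) == 2

    def test_missing_precursor_is_absent_not_error(self, tmp_path):
        f = tmp_path / "noprec.msp"
        f.write_text("NAME: x\nNum Peaks: 1\n100.0 1.0\n")
        (s,) = sp.read_spectra(f)
        assert s.precursor_mz is None

    def test_malformed_record_names_index(self, tmp_path):
        f = tmp_path / "bad.msp"
        f.write_text("NAME: ok\nNum Peaks: 1\n100.0 1.0\n\nNAME: bad\n100.0\n")
        with pytest.raises(ValueError, match="record 1"):
            sp.read_spectra(f)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        f = tmp_path / "empty.msp"
        f.write_text("")
        with pytest.warns(UserWarning):
            assert sp.read_spectra(f) == []

    @pytest.mark.parametrize("fmt", ["msp", "mgf"])
    def test_round_trip(self, tmp_path, fmt):
        s = make_spectrum([(100.123456, 1.0), (200.5, 0.25), (300.9, 0.0625)],
                          precursor=301.5, cid="rt")
        path = tmp_path / f"rt.{fmt}"
        sp.write_spectra([s], path)
        (back,) = sp.read_spectra(path)
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-6)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-5)
        assert back.precursor_mz == pytest.approx(301.5, abs=1e-6)


class TestNormalizeClean:
    def test_scaling(self):
        s = sp.normalize_peaks(make_spectrum([(1.0, 10), (2.0, 5), (3.0, 1)]))
        assert list(s.intensities) == pytest.approx([1.0, 0.5, 0.1])

    def test_single_peak(self):
        s = sp.normalize_peaks(make_spectrum([(100.0, 42.0)]))
        assert s.intensities[0] == 1.0

    def test_idempotent(self):
        s = sp.normalize_peaks(make_spectrum([(1.0, 3), (2.0, 7)]))
        assert sp.normalize_peaks(s) == s

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            sp.normalize_peaks(make_spectrum([(1.0, 0.0)]))

    def test_clean_drops_zero_and_superprecursor_peaks(self):
        s = make_spectrum([(50.0, 0.0), (100.0, 1.0), (400.0, 0.5)],
                          precursor=300.0)
        out = sp.clean_peaks(s)
        assert [mz for mz, _ in out.peaks] == [100.0]


class TestAverage:
    def test_single_spectrum_identity(self):
        s = make_spectrum([(100.0, 2.0), (200.0, 1.0)])
        out = sp.average_spectra([s])
        assert list(out.intensities) == pytest.approx([1.0, 0.5])

    def test_two_identical(self):
        s = make_spectrum([(100.0, 1.0), (200.0, 0.5)])
        out = sp.average_spectra([s, s])
        np.testing.assert_allclose(out.mz, s.mz)
        np.testing.assert_allclose(out.intensities, [1.0, 0.5])

    def test_disjoint_peaks_average_to_half(self):
        # hand-computed: each peak present in one of two spectra at 1.0,
        # averaged intensity 0.5, then renormalized back to 1.0
        a = make_spectrum([(100.0, 1.0)])
        b = make_spectrum([(200.0, 1.0)])
        out = sp.average_spectra([a, b], mz_tolerance=0.01)
        assert len(out) == 2
        np.testing.assert_allclose(out.intensities, [1.0, 1.0])

    def test_merge_within_tolerance_weighted_mz(self):
        a = make_spectrum([(100.00, 1.0)])
        b = make_spectrum([(100.10, 1.0)])
        out = sp.average_spectra([a, b], mz_tolerance=0.2)
        assert len(out) == 1
        assert out.mz[0] == pytest.approx(100.05)

    def test_order_invariance(self, rng):
        group = [make_spectrum([(m, i) for m, i in
                                zip(np.sort(rng.uniform(50, 500, 5)),
                                    rng.uniform(0.1, 1, 5))])
                 for _ in range(4)]
        fwd = sp.average_spectra(group, 0.1)
        rev = sp.average_spectra(group[::-1], 0.1)
        np.testing.assert_allclose(fwd.mz, rev.mz)
        np.testing.assert_allclose(fwd.intensities, rev.intensities)

    def test_errors(self):
        with pytest.raises(ValueError):
            sp.average_spectra([])
        with pytest.raises(ValueError, match="mixed"):
            sp.average_spectra([make_spectrum([(1, 1)], cid="a"),
                                make_spectrum([(1, 1)], cid="b")])


class TestQualityFilter:
    def test_case_study_rule_five_peaks(self):
        s = make_spectrum([(100, 1.0), (110, 0.6), (120, 0.3),
                           (130, 0.1), (140, 0.06)])
        assert sp.quality_filter(s) is True

    def test_four_above_threshold_fails(self):
        s = make_spectrum([(100, 1.0), (110, 0.6), (120, 0.3), (130, 0.1),
                           (140, 0.01), (150, 0.01), (160, 0.01)])
        assert sp.quality_filter(s) is False

    def test_min_peaks_one_always_passes_normalized(self):
        assert sp.quality_filter(make_spectrum([(100, 1.0)]), min_peaks=1)

    @given(st.integers(1, 8), st.floats(0.01, 0.5), st.integers(0, 6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_both_arguments(self, min_peaks, min_rel, bump):
        s = make_spectrum([(100 + k, v) for k, v in
                           enumerate([1.0, 0.8, 0.4, 0.2, 0.07, 0.03])])
        base = sp.quality_filter(s, min_peaks, min_rel)
        stricter = sp.quality_filter(s, min_peaks + bump, min_rel + 0.1)
        assert not (stricter and not base)


class TestLabels:
    def test_precautionary_active_wins(self):
        out = sp.clean_labels([("AAAAAAAAAAAAAA", "A", "active"),
                               ("AAAAAAAAAAAAAA", "A", "inactive")])
        assert out[0].labels["A"] == "active"

    def test_only_inactive(self):
        out = sp.clean_labels([("B" * 14, "A", "inactive")])
        assert out[0].labels["A"] == "inactive"

    def test_absent_assay_absent_label(self):
        out = sp.clean_labels([("C" * 14, "A", "active")])
        assert "B" not in out[0].labels

    def test_output_size_is_unique_id_blocks(self):
        rows = [("ID%02d" % (i % 7) + "X" * 10, "A", "inactive")
                for i in range(25)]
        assert len(sp.clean_labels(rows)) == 7

    def test_long_ids_grouped_by_14char_block(self):
        out = sp.clean_labels([("D" * 14 + "-SUFFIX1", "A", "active"),
                               ("D" * 14 + "-SUFFIX2", "A", "inactive")])
        assert len(out) == 1
        assert out[0].labels["A"] == "active"


class TestStratifiedSplit:
    def _compounds(self, n_active=10, n_inactive=90):
        mk = lambda i, lab: sp.LabeledCompound(f"C{i:03d}", labels={"A": lab})
        return ([mk(i, "active") for i in range(n_active)]
                + [mk(100 + i, "inactive") for i in range(n_inactive)])

    def test_proportions(self):
        train, test = sp.stratified_split(self._compounds(), 0.2, "A", seed=0)
        test_active = sum(c.labels["A"] == "active" for c in test)
        assert test_active == 2
        assert len(test) == 20

    def test_deterministic(self):
        c = self._compounds()
        s1 = sp.stratified_split(c, 0.2, "A", seed=5)
        s2 = sp.stratified_split(c, 0.2, "A", seed=5)
        assert [x.compound_id for x in s1[1]] == [x.compound_id for x in s2[1]]

    def test_exclusions_never_in_test(self):
        c = self._compounds()
        excl = {x.compound_id for x in c[:30]}
        _, test = sp.stratified_split(c, 0.2, "A", seed=1, exclude_ids=excl)
        assert not excl & {x.compound_id for x in test}

    def test_small_class_raises(self):
        with pytest.raises(ValueError):
            sp.stratified_split(self._compounds(n_active=1), 0.2, "A", seed=0)
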