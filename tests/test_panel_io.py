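import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixlr
from mixlr._alleles import allele_key, parse_allele, stutter_target
from mixlr.panel_io import (
    AnalysisConfig,
    EPGProfile,
    FormatError,
    PanelMismatchError,
    PeakRecord,
    apply_analytical_threshold,
    read_allele_frequencies,
    read_config,
    read_peak_table,
    write_allele_frequencies,
    write_config,
    write_peak_table,
)


def make_profile(panel, heights_by_locus, sample="s1", at=30.0):
    peaks = {
        l.name: [
            PeakRecord(sample, l.name, a, l.fragment_size(a), h)
            for a, h in heights_by_locus.get(l.name, {}).items()
        ]
        for l in panel.loci
    }
    return EPGProfile(sample, at, peaks)


class TestAlleleLabels:
    def test_microvariant_parsing_and_stutter(self):
        assert parse_allele("9.3") == (9, 3)
        assert stutter_target("9.3") == "8.3"
        assert stutter_target("12") == "11"
        assert allele_key("9.3") < allele_key("10")

    @given(rep=st.integers(2, 40), frac=st.integers(0, 3))
    @settings(deadline=None, max_examples=50)
    def test_stutter_is_one_repeat_down(self, rep, frac):
        label = f"{rep}.{frac}" if frac else str(rep)
        tgt = stutter_target(label)
        r, f = parse_allele(tgt)
        assert (r, f) == (rep - 1, frac)


class TestPeakTables:
    def test_threshold_removes_subthreshold_peaks(self, panel8, tmp_path):
        l0, l1 = panel8.locus_names[:2]
        profile = make_profile(
            panel8, {l0: {"12": 49.0, "13": 300.0}, l1: {"10": 51.0}}, at=1.0
        )
        path = tmp_path / "peaks.tsv"
        write_peak_table(profile, path)
        out = read_peak_table(path, panel8, at=50.0)
        assert out.alleles(l0) == ["13"]
        assert out.alleles(l1) == ["10"]
        # loci absent from the file appear with empty peak lists
        assert set(out.loci) == set(panel8.locus_names)
        assert out.alleles(panel8.locus_names[2]) == []

    def test_round_trip_identity(self, panel8, tmp_path):
        l0, l1 = panel8.locus_names[:2]
        profile = make_profile(
            panel8, {l0: {"12": 120.5, "13": 300.25}, l1: {"10": 51.125}}, at=30.0
        )
        p1 = tmp_path / "a.tsv"
        write_peak_table(profile, p1)
        back = read_peak_table(p1, panel8, at=30.0)
        p2 = tmp_path / "b.tsv"
        write_peak_table(back, p2)
        assert p1.read_text() == p2.read_text()
        for l in profile.loci:
            assert back.heights(l) == pytest.approx(profile.heights(l))

    def test_empty_file_is_format_error(self, panel8, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_peak_table(path, panel8, at=30.0)

    def test_missing_column_and_unknown_marker(self, panel8, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SampleName\tMarker\tAllele\tSize\n")
        with pytest.raises(FormatError, match="Height"):
            read_peak_table(path, panel8, at=30.0)
        path2 = tmp_path / "marker.tsv"
        path2.write_text(
            "SampleName\tMarker\tAllele\tSize\tHeight\ns\tNOSUCH\t12\t100\t200\n"
        )
        with pytest.raises(PanelMismatchError, match="NOSUCH"):
            read_peak_table(path2, panel8, at=30.0)

    def test_non_numeric_height_reports_line(self, panel8, tmp_path):
        path = tmp_path / "nan.tsv"
        l0 = panel8.locus_names[0]
        path.write_text(
            f"SampleName\tMarker\tAllele\tSize\tHeight\ns\t{l0}\t12\t100\toops\n"
        )
        with pytest.raises(FormatError, match="line 2"):
            read_peak_table(path, panel8, at=30.0)


class TestThresholding:
    def test_strict_threshold_and_idempotence(self, panel8):
        l0 = panel8.locus_names[0]
        profile = make_profile(panel8, {l0: {"12": 49.0, "13": 50.0}}, at=1.0)
        out = apply_analytical_threshold(profile, 50.0)
        assert out.alleles(l0) == ["13"]
        again = apply_analytical_threshold(out, 50.0)
        assert again.heights(l0) == out.heights(l0)

    def test_count_after_filtering(self, panel8):
        rng = np.random.default_rng(0)
        l0 = panel8.locus_names[0]
        heights = dict(zip([str(a) for a in range(12, 22)],
                           [10.0, 20.0, 25.0, 29.0, 31.0, 40.0, 100.0, 500.0, 35.0, 60.0]))
        profile = make_profile(panel8, {l0: heights}, at=1.0)
        out = apply_analytical_threshold(profile, 30.0)
        assert len(out.alleles(l0)) == 6

    def test_nonpositive_at_rejected(self, panel8):
        profile = make_profile(panel8, {}, at=30.0)
        with pytest.raises(ValueError):
            apply_analytical_threshold(profile, 0.0)


class TestFrequencies:
    def test_read_back_identity_when_normalized(self, panel8, freqs8, tmp_path):
        path = tmp_path / "freqs.csv"
        write_allele_frequencies(freqs8, path)
        back = read_allele_frequencies(path, panel8)
        for pop in freqs8.populations:
            for locus in panel8.locus_names:
                for a, f in freqs8.freqs[pop][locus].items():
                    assert back.freqs[pop][locus][a] == pytest.approx(f, abs=1e-9)

    def test_unseen_allele_inserted_at_minimum(self, freqs8, panel8):
        locus = panel8.locus_names[0]
        table = mixlr.AlleleFrequencyTable(freqs8.freqs, n_pop=500)
        out = table.ensure_alleles(locus, ["99"])
        # inserted at 5/(2*500) = 0.005 before renormalization
        col = out.freqs["All"][locus]
        total_before = sum(freqs8.freqs["All"][locus].values()) + 0.005
        assert col["99"] == pytest.approx(0.005 / total_before)
        assert sum(col.values()) == pytest.approx(1.0, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_rebasing_sums_to_one(self, panel8, seed):
        rng = np.random.default_rng(seed)
        raw = {
            "pop": {
                l.name: {
                    a: float(f)
                    for a, f in zip(l.alleles, rng.random(len(l.alleles)))
                }
                for l in panel8.loci
            }
        }
        out = mixlr.AlleleFrequencyTable(raw).rebased()
        for locus, col in out.freqs["pop"].items():
            assert sum(col.values()) == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_frequency_rejected(self, panel8, tmp_path):
        path = tmp_path / "bad.csv"
        l0 = panel8.locus_names[0]
        rows = ["locus,allele,All"]
        for a in panel8.loci[0].alleles:
            rows.append(f"{l0},{a},0.1")
        rows[1] = f"{l0},{panel8.loci[0].alleles[0]},1.5"
        for l in panel8.loci[1:]:
            for a in l.alleles:
                rows.append(f"{l.name},{a},{1.0 / len(l.alleles)}")
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="outside"):
            read_allele_frequencies(path, panel8)


class TestGenotypeFiles:
    def test_round_trip(self, panel8, tmp_path):
        from mixlr.panel_io import read_genotypes, write_genotypes

        profiles = {
            "s1": {l.name: (l.alleles[2], l.alleles[4]) for l in panel8.loci},
            "s2": {l.name: (l.alleles[0], l.alleles[0]) for l in panel8.loci},
        }
        path = tmp_path / "g.csv"
        write_genotypes(profiles, path)
        assert read_genotypes(path) == profiles

    def test_spreadsheet_float_labels_normalized(self, tmp_path):
        from mixlr.panel_io import read_genotypes

        path = tmp_path / "g.csv"
        path.write_text("sample,locus,allele1,allele2\ns,TH01,9.3,15.0\n")
        assert read_genotypes(path)["s"]["TH01"] == ("9.3", "15")


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = AnalysisConfig(chains=4, theta=0.03, at=50.0, seed=7)
        path = tmp_path / "c.yaml"
        write_config(config, path)
        assert read_config(path) == config

    def test_defaults_match_protocol(self):
        c = AnalysisConfig()
        assert (c.chains, c.burn_in_fraction, c.thin_n) == (8, 0.20, 1)
        assert (c.preprocessing_steps, c.drop_in_coefficient) == (10000, 1.0)
        assert (c.degradation_mode, c.popgen_model, c.theta) == ("none", "NRC4.1", 0.01)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(burn_in_fraction=1.5)
        with pytest.raises(ValueError):
            AnalysisConfig(thin_n=0)
        with pytest.raises(ValueError):
            AnalysisConfig(popgen_model="bogus")
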