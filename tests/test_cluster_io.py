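import io

import numpy as np
import pytest

from hdxkit import cluster_io
from hdxkit.cluster_io import (PROTON_MASS, ClusterCSVError, ClusterRecord,
                               Species, UptakeCurve, assign_replicates,
                               deconvolute_neutral,
                               deconvolute_uptake, parse_cluster_csv,
                               write_cluster_csv)


def _record(**kw):
    base = dict(protein="p", start=1, end=5, sequence="KLSAM", modification="",
                fragment="", max_uptake=4, mono_mass=500.0, state="apo",
                exposure_s=1.0, file="f_01", charge=2, rt=1.0,
                intensity=100.0, centroid=251.007276466)
    base.update(kw)
    return ClusterRecord(**base)


class TestParsing:
    def test_time_unit_conversion(self, tiny_csv_buffer):
        records = parse_cluster_csv(tiny_csv_buffer, time_unit="ms")
        assert records[0].exposure_s == pytest.approx(0.05)

    def test_unknown_time_unit_rejected(self, tiny_csv_buffer):
        with pytest.raises(ClusterCSVError, match="time unit"):
            parse_cluster_csv(tiny_csv_buffer, time_unit="h")

    def test_invariant_violation_names_line_and_column(self):
        bad = "p,10,5,ABCDEF,,,4,500.0,apo,1,f,1,1.0,10,400.0\n"
        with pytest.raises(ClusterCSVError, match="line 1") as exc:
            parse_cluster_csv(io.StringIO(bad), "s")
        assert "end" in str(exc.value) or "sequence" in str(exc.value)

    def test_empty_file_rejected(self):
        with pytest.raises(ClusterCSVError, match="empty"):
            parse_cluster_csv(io.StringIO(""), "s")

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ClusterCSVError, match="columns"):
            parse_cluster_csv(io.StringIO("a,b,c\n"), "s")

    def test_toy_csv_groups_into_two_species(self, tiny_csv_buffer):
        records = parse_cluster_csv(tiny_csv_buffer, "ms")
        assert len(records) == 3
        species = {r.species().key for r in records}
        assert len(species) == 2  # two charge states collapse, fragment apart

    def test_header_detected_and_mapped(self, tiny_csv_buffer):
        text = ",".join(cluster_io.COLUMNS) + "\n" + tiny_csv_buffer.read()
        records = parse_cluster_csv(io.StringIO(text), "ms")
        assert len(records) == 3

    def test_bad_fragment_label(self):
        row = "p,1,5,ABCDE,,q3,4,500.0,apo,1,f,1,1.0,10,400.0\n"
        with pytest.raises(ClusterCSVError, match="fragment"):
            parse_cluster_csv(io.StringIO(row), "s")

    def test_roundtrip_identical(self, small_dataset):
        records = parse_cluster_csv(io.StringIO(small_dataset.csv_text), "s")
        buf = io.StringIO()
        write_cluster_csv(records, buf, "s")
        buf.seek(0)
        again = parse_cluster_csv(buf, "s")
        assert again == records


class TestSpecies:
    def test_covered_interval_for_fragments(self):
        sp_c = Species("p", 10, 17, "KLSAMGTR", fragment="c3", max_uptake=2)
        assert sp_c.covered_interval == (10, 12)
        sp_z = Species("p", 10, 17, "KLSAMGTR", fragment="z4", max_uptake=3)
        assert sp_z.covered_interval == (14, 17)
        sp = Species("p", 10, 17, "KLSAMGTR", max_uptake=7)
        assert sp.covered_interval == (10, 17)

    def test_exchangeable_residues_skip_nterm_and_prolines(self):
        sp = Species("p", 1, 8, "KPLSAMPR", max_uptake=5)
        assert sp.exchangeable_residues() == [3, 4, 5, 6, 8]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Species("p", 5, 3, "ABC")


class TestReplicates:
    def test_lexicographic_default(self):
        recs = [_record(file="a_02"), _record(file="a_01")]
        out = assign_replicates(recs)
        by_file = {r.file: r.replicate for r in out}
        assert by_file == {"a_01": 1, "a_02": 2}

    def test_explicit_mapping_overrides(self):
        recs = [_record(file="a_01"), _record(file="a_02")]
        mapping = {"a_01": ("apo", 2), "a_02": ("apo", 1)}
        out = assign_replicates(recs, mapping)
        assert {r.file: r.replicate for r in out} == {"a_01": 2, "a_02": 1}

    def test_mapping_unknown_file_rejected(self):
        with pytest.raises(ClusterCSVError, match="unknown"):
            assign_replicates([_record()], {"nope": ("apo", 1), "f_01": ("apo", 2)})

    def test_mapping_collision_rejected(self):
        recs = [_record(file="a"), _record(file="b")]
        with pytest.raises(ClusterCSVError, match="both map"):
            assign_replicates(recs, {"a": ("apo", 1), "b": ("apo", 1)})

    def test_missing_replicate_flagged(self):
        recs = [_record(file="a_01", exposure_s=1.0),
                _record(file="a_02", exposure_s=1.0),
                _record(file="a_01", exposure_s=10.0)]
        out = assign_replicates(recs)
        report = cluster_io.missing_replicate_report(out)
        assert len(report) == 1
        assert report.iloc[0]["time_s"] == 10.0
        assert report.iloc[0]["missing_replicate"] == 2


class TestDeconvolution:
    def test_single_charge_state_arithmetic(self):
        rec = _record(charge=2, centroid=500.0)
        assert deconvolute_neutral([rec]) == pytest.approx(
            2 * 500.0 - 2 * 1.007276466, abs=1e-9)

    def test_charge_state_invariance(self):
        m = 997.0
        recs = [_record(charge=z, centroid=(m + z * PROTON_MASS) / z,
                        intensity=w)
                for z, w in ((1, 5.0), (2, 1.0), (3, 17.0))]
        assert deconvolute_neutral(recs) == pytest.approx(m, abs=1e-9)

    def test_intensity_weighted_mean(self):
        # oracle: hand formula for 3:1 weighting of two charge states
        r1 = _record(charge=1, centroid=999.0, intensity=3.0)
        r2 = _record(charge=2, centroid=500.0035, intensity=1.0)
        m1 = 999.0 - 1.007276466
        m2 = 2 * 500.0035 - 2 * 1.007276466
        expected = (3 * m1 + m2) / 4
        assert deconvolute_neutral([r1, r2]) == pytest.approx(expected, abs=1e-12)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ClusterCSVError, match="intensity"):
            deconvolute_neutral([_record(intensity=0.0)])

    def test_missing_reference_rejected(self):
        with pytest.raises(ClusterCSVError, match="reference"):
            deconvolute_uptake([_record()], None)


class TestUptakeTable:
    def test_undeuterated_control_uptake_zero(self, noiseless_table):
        t0 = noiseless_table[noiseless_table["time_s"] == 0.0]
        assert np.allclose(t0["uptake"], 0.0, atol=1e-9)

    def test_noiseless_uptake_matches_ground_truth(self, noiseless_dataset,
                                                   noiseless_table):
        truth = noiseless_dataset.species_truth
        merged = noiseless_table.merge(
            truth, on=["protein", "start", "end", "sequence", "modification",
                       "fragment", "state", "time_s"])
        assert len(merged) == len(noiseless_table)
        assert np.allclose(merged["uptake"], merged["true_uptake_observed"],
                           atol=1e-8)

    def test_curve_extraction(self, small_table, small_dataset):
        sp = small_dataset.species[0]
        curve = UptakeCurve.from_table(small_table, sp, "State_A")
        assert curve.n_replicates == 3
        assert set(curve.unique_times()) == {0.1, 1.0, 10.0, 100.0, 1000.0}
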