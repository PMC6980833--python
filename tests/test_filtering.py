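"""Read filtering, taxonomic reassignment, presence calling and burn-in
exclusion, including the synthetic round-trip recovery of detections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scatdiet as sd
from scatdiet.exceptions import ConfigurationError, MissingControlError
from scatdiet.studydata import CONSUMER_TAXON


def _reads(rows):
    return pd.DataFrame(rows, columns=["subsample_id", "control_id", "taxon",
                                       "read_count", "sequence_length"])


class TestFilterReads:
    def test_threshold_application(self):
        t = _reads([("s1", "c1", "x", 5, 100),
                    ("s1", "c1", "y", 12, 100),
                    ("s1", "c1", "z", 50, 70)])
        out = sd.filter_reads(t)
        assert out["taxon"].tolist() == ["y"]

    def test_all_rows_failing_yields_empty_table(self):
        t = _reads([("s1", "c1", "x", 5, 70)])
        out = sd.filter_reads(t)
        assert out.empty and list(out.columns) == list(t.columns)

    @pytest.mark.parametrize("count,length,kept", [
        (10, 80, True),   # both exactly at threshold: retained
        (9, 80, False),
        (10, 79, False),
    ])
    def test_boundary_pinning(self, count, length, kept):
        out = sd.filter_reads(_reads([("s1", "c1", "x", count, length)]))
        assert (len(out) == 1) is kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.filter_reads(_reads([]), min_length=-1)


TARGETS = ["Oryctolagus cuniculus", "Cervus spp", "Equus caballus"]


class TestReassignTaxa:
    def test_family_reassigned_to_species(self):
        t = _reads([("sub1", "c1", "Leporidae", 40, 100)])
        out, _ = sd.reassign_taxa(t, target_species=TARGETS)
        assert out.iloc[0]["taxon"] == "Oryctolagus cuniculus"
        assert out.iloc[0]["read_count"] == 40

    def test_merge_sums_read_counts(self):
        t = _reads([("sub1", "c1", "Cervidae", 10, 100),
                    ("sub1", "c1", "Cervus spp", 30, 105)])
        out, _ = sd.reassign_taxa(t, target_species=TARGETS)
        assert len(out) == 1
        assert out.iloc[0]["read_count"] == 40

    def test_non_target_dropped_and_counted(self):
        t = _reads([("sub1", "c1", "Homo sapiens", 500, 100),
                    ("sub1", "c1", "Cervus spp", 10, 100)])
        out, report = sd.reassign_taxa(t, target_species=TARGETS)
        assert "Homo sapiens" not in set(out["taxon"])
        assert report["dropped_rows"] == 1
        assert report["dropped_reads"] == 500

    def test_reads_conserved_up_to_reported_drops(self):
        t = _reads([("s1", "c1", "Leporidae", 7, 90),
                    ("s1", "c1", "Homo sapiens", 3, 90),
                    ("s2", "c1", "Cervus spp", 11, 90)])
        out, report = sd.reassign_taxa(t, target_species=TARGETS)
        assert out["read_count"].sum() + report["dropped_reads"] == t["read_count"].sum()

    def test_unknown_mapping_target_rejected(self):
        mapping = [sd.TaxonMapping("Suidae", "Sus scrofa")]
        with pytest.raises(ConfigurationError):
            sd.reassign_taxa(_reads([]), mapping, target_species=TARGETS)


class TestCallPresence:
    def _controls(self, rows):
        return pd.DataFrame(rows, columns=["control_id", "taxon", "read_count"])

    @pytest.mark.parametrize("sample,control,expected", [
        (50, 0, 1),
        (50, 9, 1),    # control just under the cutoff still counts as clean
        (50, 10, 0),   # control at the cutoff suppresses the call
        (0, 0, 0),
    ])
    def test_presence_rule(self, sample, control, expected):
        t = _reads([("s1", "c1", "Cervus spp", sample, 100),
                    ("s1", "c1", CONSUMER_TAXON, 500, 100)])
        ctrl = self._controls([("c1", "Cervus spp", control)] if control else [])
        out = sd.call_presence(t, ctrl, target_species=["Cervus spp"])
        assert out.iloc[0]["detected"] == expected

    def test_consumer_never_emitted_as_prey(self):
        t = _reads([("s1", "c1", CONSUMER_TAXON, 500, 100)])
        out = sd.call_presence(t, self._controls([]),
                               target_species=["Cervus spp", CONSUMER_TAXON])
        assert CONSUMER_TAXON not in set(out["species"])

    def test_every_pair_has_explicit_call(self):
        t = _reads([("s1", "c1", "Cervus spp", 20, 100)])
        out = sd.call_presence(t, self._controls([]), target_species=TARGETS)
        assert len(out) == len(TARGETS)
        assert set(out["detected"]) <= {0, 1}

    def test_missing_control_is_an_error_naming_the_subsample(self):
        info = pd.DataFrame({"subsample_id": ["ghost"]})
        t = _reads([("s1", "c1", "Cervus spp", 20, 100)])
        with pytest.raises(MissingControlError, match="ghost"):
            sd.call_presence(t, self._controls([]), target_species=TARGETS,
                             sample_info=info)

    @given(s1=st.integers(0, 30), s2=st.integers(0, 30),
           c1=st.integers(0, 30), c2=st.integers(0, 30))
    def test_monotonicity(self, s1, s2, c1, c2):
        """Raising a sample count never flips 1->0; raising a control
        count never flips 0->1."""
        def call(s, c):
            t = _reads([("x", "cc", "Cervus spp", s, 100),
                        ("x", "cc", CONSUMER_TAXON, 5, 100)])
            ctrl = self._controls([("cc", "Cervus spp", c)])
            return sd.call_presence(t, ctrl, target_species=["Cervus spp"]).iloc[0]["detected"]

        lo_s, hi_s = sorted((s1, s2))
        assert call(lo_s, c1) <= call(hi_s, c1)
        lo_c, hi_c = sorted((c1, c2))
        assert call(s1, hi_c) <= call(s1, lo_c)


class TestExcludeBurnin:
    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=["scat_id", "individual_id",
                                           "defecation_date", "species", "detected"])

    def _schedule(self):
        return pd.DataFrame({
            "date": pd.to_datetime(["2017-11-03", "2017-11-04", "2017-11-05", "2017-11-06"]),
            "individual_id": ["Jura"] * 4,
            "species": ["Deer"] * 4,
            "proportion": [1.0] * 4,
        })

    def test_first_days_scats_removed(self):
        m = self._matrix([("s1", "Jura", "2017-11-04", "Deer", 1),   # trial day 2
                          ("s2", "Jura", "2017-11-06", "Deer", 1)])
        out, report = sd.exclude_burnin_scats(m, self._schedule())
        assert out["scat_id"].tolist() == ["s2"]
        assert report["burnin_rows_dropped"] == 1

    def test_excluded_species_removed_everywhere(self):
        m = self._matrix([("s2", "Jura", "2017-11-10", "Meleagris gallopavo", 1),
                          ("s2", "Jura", "2017-11-10", "Deer", 0)])
        out, _ = sd.exclude_burnin_scats(m, self._schedule())
        assert "Meleagris gallopavo" not in set(out["species"])
        assert "Deer" in set(out["species"])

    def test_zero_burnin_empty_exclusions_is_identity(self):
        m = self._matrix([("s1", "Jura", "2017-11-03", "Deer", 1)])
        out, _ = sd.exclude_burnin_scats(m, self._schedule(), burnin_days=0,
                                         excluded_species=())
        pd.testing.assert_frame_equal(out, m.assign(
            defecation_date=pd.to_datetime(m["defecation_date"])))


class TestRoundTrip:
    def test_read_simulation_then_presence_calling_recovers_detections(
            self, schedule, species, true_params):
        """With no contamination, ample depth and full-length sequences,
        filter -> reassign -> call reproduces the generating detection
        matrix exactly."""
        det = sd.simulate_detections(schedule, true_params,
                                     scat_days=["2017-11-08", "2017-11-10"],
                                     degradation_days=[0, 5], seed=30)
        reads, controls = sd.simulate_read_table(
            det, consumer_fraction=0.54, mean_depth=20_000,
            control_contamination_rate=0.0, short_read_fraction=0.0, seed=31,
        )
        assert (reads["sequence_length"] >= 80).all()
        filtered = sd.filter_reads(reads)
        # no higher-rank labels in the synthetic table: identity mapping
        reassigned, report = sd.reassign_taxa(filtered, mapping=[],
                                              target_species=species)
        assert report["dropped_rows"] == 0
        matrix = sd.call_presence(reassigned, controls, target_species=species,
                                  sample_info=det)
        key = ["subsample_id", "species"]
        merged = det.merge(matrix[key + ["detected"]], on=key,
                           suffixes=("_true", "_called"))
        assert len(merged) == len(det)
        assert (merged["detected_true"] == merged["detected_called"]).all()
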