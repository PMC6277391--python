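"""Tryptic digestion, emPAI, identification filters, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limnodigest import proteomics as pq
from limnodigest import synth


class TestTrypticDigest:
    def test_cleaves_after_k_r_but_not_before_proline(self):
        assert pq.tryptic_digest("AKRPGKMR", 0) == ["AK", "RPGK", "MR"]

    def test_no_internal_site(self):
        assert pq.tryptic_digest("MR", 0) == ["MR"]

    def test_one_missed_cleavage_adds_joined_products(self):
        peps = pq.tryptic_digest("AKRPGKMR", 1)
        assert set(peps) == {"AK", "RPGK", "MR", "AKRPGK", "RPGKMR"}

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            pq.tryptic_digest("AKBGR")


class TestObservablePeptides:
    def test_small_peptide_excluded_by_default_window(self):
        # GK is ~203 Da, far below the low-mass bound of the window
        assert pq.peptide_mass("GK") == pytest.approx(203.127, abs=0.01)
        assert pq.observable_peptides("GK") == 0

    def test_unbounded_window_counts_whole_digest(self):
        seq = "AKRPGKMRLLLK"
        assert pq.observable_peptides(seq, (0.0, np.inf)) == len(
            pq.tryptic_digest(seq, 0)
        )

    def test_protein_without_cleavage_sites_is_one_peptide(self):
        seq = "MLLAVGLNHQTW"
        assert pq.tryptic_digest(seq, 0) == [seq]
        inside = pq.DEFAULT_MASS_WINDOW[0] <= pq.peptide_mass(seq) <= pq.DEFAULT_MASS_WINDOW[1]
        assert pq.observable_peptides(seq) == int(inside)

    def test_carbamidomethyl_fixed_modification(self):
        assert pq.peptide_mass("CK") == pytest.approx(
            pq.peptide_mass("SK") + pq.CARBAMIDOMETHYL_MASS - (87.03203 - 103.00919),
            abs=0.01,
        )


class TestEmpai:
    def test_reference_value(self):
        assert pq.empai(4, 20) == pytest.approx(0.58489, abs=1e-5)

    def test_zero_observed(self):
        assert pq.empai(0, 10) == 0.0

    def test_full_coverage(self):
        assert pq.empai(20, 20) == pytest.approx(9.0)

    def test_observed_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert pq.empai(25, 20) == pytest.approx(9.0)

    def test_zero_observable_is_an_error(self):
        with pytest.raises(ValueError):
            pq.empai(1, 0)

    @given(
        observable=st.integers(1, 60),
        obs_a=st.integers(0, 60),
        obs_b=st.integers(0, 60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_observed(self, observable, obs_a, obs_b):
        lo, hi = sorted([min(obs_a, observable), min(obs_b, observable)])
        assert pq.empai(lo, observable) <= pq.empai(hi, observable)

    @given(observed=st.integers(1, 30), extra=st.integers(0, 30))
    @settings(max_examples=200, derandomize=True)
    def test_decreasing_in_observable(self, observed, extra):
        assert pq.empai(observed, observed + extra) >= pq.empai(
            observed, observed + extra + 1
        )


def _evidence(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "peptide", "expect", "sample", "compartment", "replicate"]
    )


class TestFilters:
    def test_expect_cutoff_drops_match_before_protein_counting(self):
        ev = _evidence(
            [
                ("P1", "AAAK", 0.01, "s1", "gut_fluid", 1),
                ("P1", "CCCK", 0.06, "s1", "gut_fluid", 1),  # fails the cutoff
            ]
        )
        out, report = pq.filter_identifications(ev)
        assert out.empty  # only one surviving peptide -> protein dropped
        assert not report.set_index("protein_id").loc["P1", "retained"]

    def test_min_two_peptides_in_some_sample(self):
        ev = _evidence(
            [
                ("P1", "AAAK", 0.01, "s1", "gut_fluid", 1),
                ("P1", "DDDK", 0.01, "s2", "gut_fluid", 2),  # never 2 in one sample
                ("P2", "EEEK", 0.01, "s1", "gut_fluid", 1),
                ("P2", "FFFK", 0.01, "s1", "gut_fluid", 1),
            ]
        )
        out, _ = pq.filter_identifications(ev, scope="any_sample")
        assert set(out["protein_id"]) == {"P2"}
        out_global, _ = pq.filter_identifications(ev, scope="global")
        assert set(out_global["protein_id"]) == {"P1", "P2"}

    def test_empty_table_passes_through(self):
        out, report = pq.filter_identifications(_evidence([]))
        assert out.empty and report.empty

    def test_idempotent(self, digestome):
        _, evidence, _ = digestome
        once, _ = pq.filter_identifications(evidence)
        twice, _ = pq.filter_identifications(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMolarPercentages:
    def test_shares(self):
        q = pd.DataFrame(
            {
                "protein_id": ["P1", "P2"],
                "compartment": ["gut_fluid"] * 2,
                "replicate": [1, 1],
                "empai": [1.0, 3.0],
            }
        )
        out = pq.molar_percentages(q)
        assert out["mol_pct"].tolist() == pytest.approx([25.0, 75.0])

    def test_single_protein_is_100(self):
        q = pd.DataFrame(
            {"protein_id": ["P1"], "compartment": ["gut_fluid"], "replicate": [1],
             "empai": [2.5]}
        )
        assert pq.molar_percentages(q)["mol_pct"].iloc[0] == 100.0

    def test_equal_empais_split_evenly(self):
        n = 7
        q = pd.DataFrame(
            {"protein_id": [f"P{i}" for i in range(n)], "compartment": ["c"] * n,
             "replicate": [1] * n, "empai": [0.4] * n}
        )
        assert pq.molar_percentages(q)["mol_pct"].tolist() == pytest.approx([100.0 / n] * n)

    def test_groups_sum_to_100(self, digestome):
        _, evidence, sequences = digestome
        filtered, _ = pq.filter_identifications(evidence)
        quants = pq.molar_percentages(pq.quantify(filtered, sequences))
        sums = quants.groupby(["compartment", "replicate"])["mol_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)


class TestReplicateNormalization:
    def _quants(self, totals):
        rows = []
        organs = ["gut_fluid", "gut_tissue", "hepatopancreas"]
        for rep, total in enumerate(totals, start=1):
            for organ in organs:
                rows.append(
                    {"protein_id": "P1", "compartment": organ, "replicate": rep,
                     "empai": total / len(organs)}
                )
        return pd.DataFrame(rows)

    def test_totals_equalized_to_mean(self):
        q = pq.normalize_replicates(self._quants([80.0, 100.0, 120.0]),
                                    ("gut_fluid", "gut_tissue", "hepatopancreas"))
        totals = q.groupby("replicate")["empai"].sum()
        assert np.allclose(totals, 100.0, atol=1e-9)

    def test_identical_replicates_unchanged(self):
        raw = self._quants([90.0, 90.0])
        out = pq.normalize_replicates(raw, ("gut_fluid", "gut_tissue", "hepatopancreas"))
        pd.testing.assert_frame_equal(raw, out)

    def test_rescaling_one_replicate_leaves_molar_shares_unchanged(self):
        # the normalization absorbs any overall per-replicate loading factor
        raw = self._quants([80.0, 100.0])
        doubled = raw.copy()
        doubled.loc[doubled["replicate"] == 1, "empai"] *= 2
        organs = ("gut_fluid", "gut_tissue", "hepatopancreas")
        a = pq.molar_percentages(pq.normalize_replicates(raw, organs))
        b = pq.molar_percentages(pq.normalize_replicates(doubled, organs))
        assert np.allclose(a["mol_pct"], b["mol_pct"])
        # and per-replicate cross-organ totals are equal after normalization
        ta = pq.normalize_replicates(doubled, organs).groupby("replicate")["empai"].sum()
        assert np.allclose(ta, ta.iloc[0])

    def test_missing_organ_is_an_error(self):
        q = self._quants([100.0])
        q = q[q["compartment"] != "gut_tissue"]
        with pytest.raises(ValueError, match="missing organs"):
            pq.normalize_replicates(q, ("gut_fluid", "gut_tissue", "hepatopancreas"))


class TestFamilySummary:
    def test_gh_shares_renormalized_within_gh_subset(self):
        q = pd.DataFrame(
            {
                "protein_id": ["A", "B", "C", "D"],
                "compartment": ["gut_fluid"] * 4,
                "replicate": [1] * 4,
                "mol_pct": [30.0, 25.0, 45.0, 10.0],  # D is not a GH
            }
        )
        ann = {"A": "GH7", "B": "GH9", "C": "GH5", "D": "hemocyanin"}
        gh, _ = pq.family_summary(q, ann)
        share = pq.gh7_gh9_share(gh)
        assert share.iloc[0] == pytest.approx(55.0)

    def test_single_family_is_100(self):
        q = pd.DataFrame(
            {"protein_id": ["A", "B"], "compartment": ["gut_fluid"] * 2,
             "replicate": [1, 1], "mol_pct": [60.0, 40.0]}
        )
        gh, _ = pq.family_summary(q, {"A": "GH7", "B": "GH7"})
        assert gh["gh_share_pct"].tolist() == [100.0]

    def test_no_gh_proteins_flagged_empty(self):
        q = pd.DataFrame(
            {"protein_id": ["A"], "compartment": ["gut_fluid"], "replicate": [1],
             "mol_pct": [100.0]}
        )
        with pytest.warns(UserWarning, match="no GH"):
            gh, _ = pq.family_summary(q, {"A": "hemocyanin"})
        assert gh.empty

    def test_digestome_round_trip_gh7_gh9_majority(self, digestome):
        preset, evidence, sequences = digestome
        filtered, _ = pq.filter_identifications(evidence)
        quants = pq.molar_percentages(pq.quantify(filtered, sequences))
        gh, _ = pq.family_summary(quants, synth.annotations_of(preset))
        shares = pq.gh7_gh9_share(gh, "gut_fluid")
        assert len(shares) == 3
        assert (shares > 50.0).all()

    def test_hemocyanin_enriched_in_fluid_over_tissue(self, digestome):
        preset, evidence, sequences = digestome
        filtered, _ = pq.filter_identifications(evidence)
        quants = pq.molar_percentages(pq.quantify(filtered, sequences))
        _, contrasts = pq.family_summary(quants, synth.annotations_of(preset))
        hc = contrasts[contrasts["family"] == "hemocyanin"].set_index("compartment")
        assert hc.loc["gut_fluid", "mean"] > hc.loc["gut_tissue", "mean"]
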