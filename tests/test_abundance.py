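"""Protein quantification, responsive-protein calling, concordance."""

import numpy as np
import pandas as pd
import pytest

from triadpipe import (
    PdrpCallConfig,
    SimulationSpec,
    ValidationError,
    call_pdrps,
    concordance,
    generate_subgenome_proteome,
    index_proteome,
    map_peptide_table,
    normalize_channels,
    quantify_proteins,
    simulate_itraq_experiment,
    volcano_coordinates,
)
from triadpipe.mapping import PeptideMatch

CHANNELS = ["CK1", "CK2", "CK3", "NP1", "NP2", "NP3"]


def _table(rows):
    return pd.DataFrame(rows, columns=["peptide", "protein_id"] + CHANNELS)


def _unique(pep, locus):
    return PeptideMatch(pep, frozenset({locus}), "locus_unique")


class TestNormalizeChannels:
    def test_equal_sum_channels_unchanged(self):
        t = _table([["PEPA", "L1", 1, 1, 1, 1, 1, 1], ["PEPB", "L1", 2, 2, 2, 2, 2, 2]])
        out = normalize_channels(t, "total_sum")
        assert np.allclose(out[CHANNELS], t[CHANNELS])

    def test_rescaled_channel_recovered(self):
        # doubling one channel must be undone exactly by normalization
        t = _table([["PEPA", "L1", 1, 2, 3, 4, 5, 6], ["PEPB", "L2", 2, 3, 4, 5, 6, 7]])
        skew = t.copy()
        skew["CK2"] = skew["CK2"] * 2
        out_skew = normalize_channels(skew, "total_sum")
        out_ref = normalize_channels(t, "total_sum")
        # identical up to one global scale factor: all ratios recovered
        factor = out_skew[CHANNELS].to_numpy() / out_ref[CHANNELS].to_numpy()
        assert np.allclose(factor, factor[0, 0])

    def test_none_is_identity(self):
        t = _table([["PEPA", "L1", 1, 2, 3, 4, 5, 6]])
        assert normalize_channels(t, "none").equals(t)

    def test_all_zero_channel_rejected(self):
        t = _table([["PEPA", "L1", 0, 1, 1, 1, 1, 1]])
        with pytest.raises(ValidationError):
            normalize_channels(t, "total_sum")


class TestQuantifyProteins:
    def test_single_unique_peptide_ratio(self):
        t = _table([["PEPA", "L1", 1, 1, 1, 2, 2, 2]])
        q = quantify_proteins(t, {"PEPA": _unique("PEPA", "L1")})
        assert q.loc["L1", "ratio"] == pytest.approx(2.0)

    def test_shared_peptides_do_not_quantify(self):
        t = _table([["PEPA", "L1", 1, 1, 1, 2, 2, 2]])
        shared = PeptideMatch("PEPA", frozenset({"L1", "L2"}), "family_shared")
        q = quantify_proteins(t, {"PEPA": shared})
        assert not q.loc["L1", "quantified"]

    def test_unique_peptide_areas_are_additive(self):
        t = _table(
            [["PEPA", "L1", 1, 1, 1, 3, 3, 3], ["PEPC", "L1", 2, 2, 2, 3, 3, 3]]
        )
        q = quantify_proteins(
            t, {"PEPA": _unique("PEPA", "L1"), "PEPC": _unique("PEPC", "L1")}
        )
        assert q.loc["L1", "CK1"] == 3 and q.loc["L1", "NP1"] == 6

    def test_missing_specificity_record_rejected(self):
        t = _table([["PEPA", "L1", 1, 1, 1, 1, 1, 1]])
        with pytest.raises(ValidationError):
            quantify_proteins(t, {})


class TestCallPdrps:
    def _quants(self, ratio):
        ck = np.array([1.0, 1.0, 1.0])
        t = _table([["PEPA", "L1", *ck, *(ck * ratio)]])
        return quantify_proteins(t, {"PEPA": _unique("PEPA", "L1")})

    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.20, "up"), (1.199, "unchanged"), (1.0, "unchanged"),
         (0.83, "down"), (0.831, "unchanged"), (2.5, "up"), (0.4, "down")],
    )
    def test_inclusive_fold_thresholds(self, ratio, expected):
        calls = call_pdrps(self._quants(ratio))
        assert calls.loc["L1", "reg_class"] == expected

    def test_class_conservation(self):
        spec = SimulationSpec(seed=6, n_families=10, cv=0.1)
        db = generate_subgenome_proteome(spec)
        table = simulate_itraq_experiment(db, spec)
        matches = map_peptide_table(table["peptide"], index_proteome(db))
        calls = call_pdrps(quantify_proteins(table, matches))
        counts = calls["reg_class"].value_counts()
        assert counts.sum() == len(calls)
        assert set(counts.index) <= {"up", "down", "unchanged", "not_quantified"}

    def test_global_rescaling_leaves_classes_unchanged(self):
        spec = SimulationSpec(seed=8, n_families=8, cv=0.1)
        db = generate_subgenome_proteome(spec)
        table = simulate_itraq_experiment(db, spec)
        matches = map_peptide_table(table["peptide"], index_proteome(db))
        calls = call_pdrps(quantify_proteins(table, matches))
        scaled = table.copy()
        scaled[CHANNELS] = scaled[CHANNELS] * 37.5
        calls2 = call_pdrps(quantify_proteins(scaled, matches))
        assert calls["reg_class"].equals(calls2["reg_class"])
        assert np.allclose(calls["ratio"], calls2["ratio"])

    def test_null_calibration_with_p_filter(self):
        # Planted fold change 1 everywhere: with the p-filter on, the
        # flagged fraction must stay near the nominal alpha.
        spec = SimulationSpec(seed=9, n_families=67, cv=0.05,
                              singleton_fraction=0.0)
        db = generate_subgenome_proteome(spec)
        table = simulate_itraq_experiment(db, spec)
        matches = map_peptide_table(table["peptide"], index_proteome(db))
        cfg = PdrpCallConfig(p_filter_enabled=True)
        calls = call_pdrps(quantify_proteins(table, matches), cfg)
        flagged = calls["reg_class"].isin(["up", "down"]).mean()
        assert flagged <= cfg.alpha + 0.03


class TestConcordance:
    def _calls(self, ratios, classes):
        return pd.DataFrame(
            {"ratio": ratios, "reg_class": classes},
            index=[f"P{i}" for i in range(len(ratios))],
        )

    def test_identical_calls_fully_concordant(self):
        a = self._calls([2.0, 0.5, 1.0], ["up", "down", "unchanged"])
        assert concordance(a, a).fraction == 1.0

    def test_flipped_directions_zero_concordant(self):
        a = self._calls([2.0, 0.5], ["up", "down"])
        b = self._calls([0.5, 2.0], ["down", "up"])
        assert concordance(a, b).n_concordant == 0

    def test_nine_of_eleven_agreement(self):
        # Discovery vs targeted validation: 11 shared proteins, 9 agree.
        a = self._calls([2.0] * 11, ["up"] * 11)
        b = self._calls([2.0] * 9 + [0.5, 0.5], ["up"] * 9 + ["down", "down"])
        rep = concordance(a, b)
        assert (rep.n_shared, rep.n_concordant) == (11, 9)

    def test_disjoint_ids_rejected(self):
        a = self._calls([2.0], ["up"])
        b = self._calls([2.0], ["up"])
        b.index = ["other"]
        with pytest.raises(ValidationError):
            concordance(a, b)


class TestVolcano:
    def test_closed_form_coordinates(self):
        q = pd.DataFrame(
            {
                "quantified": [True, True, True],
                "ratio": [1.0, 2.0, 0.5],
                "p_value": [1.0, 0.5, 0.01],
            },
            index=["P1", "P2", "P3"],
        )
        v = volcano_coordinates(q)
        assert v.loc["P1"].tolist() == [0.0, 0.0]
        assert v.loc["P2", "log2_ratio"] == pytest.approx(1.0)
        assert v.loc["P3", "log2_ratio"] == pytest.approx(-1.0)
        assert v.loc["P3", "neg_log10_p"] == pytest.approx(2.0)

    def test_zero_p_clipped_to_finite(self):
        q = pd.DataFrame(
            {"quantified": [True], "ratio": [2.0], "p_value": [0.0]}, index=["P1"]
        )
        assert np.isfinite(volcano_coordinates(q)).all().all()
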