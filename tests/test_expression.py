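"""Comparative-Ct arithmetic, response calling, panel set algebra."""

import numpy as np
import pandas as pd
import pytest

from wrkykit.expression import (
    CT_COLUMNS,
    ResponseCall,
    call_response,
    call_responses,
    read_ct_table,
    relative_quantity,
    summarize_panel,
)
from wrkykit.synthetic_data import (
    PATHOGEN_REPRESSED,
    PATHOGEN_UNCHANGED,
    SA_UNCHANGED,
    STUDY_PANEL_GENES,
    PanelDesign,
    build_study_panel,
    make_panel_ct,
)


def _table(rows):
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def _flat(gene="g", treatment="x", ct=24.0, ref=20.0):
    return [
        (gene, treatment, t, r, ct, ref) for t in (0, 9, 12, 24, 48) for r in (1, 2, 3)
    ]


class TestRelativeQuantity:
    def test_flat_cts_give_unit_rq(self):
        rq = relative_quantity(_table(_flat()))
        assert np.allclose(rq["rq"], 1.0)

    def test_one_cycle_drop_doubles(self):
        rows = _flat()
        rows = [
            (g, tr, t, r, ct - 1.0 if t == 24 else ct, ref)
            for g, tr, t, r, ct, ref in rows
        ]
        rq = relative_quantity(_table(rows)).set_index("timepoint_h")["rq"]
        assert rq.loc[24] == pytest.approx(2.0, abs=1e-12)
        assert rq.loc[0] == 1.0

    def test_reference_shift_cancels(self):
        rows = [
            (g, tr, t, r, ct - 1.0 if t == 24 else ct, ref - 1.0 if t == 24 else ref)
            for g, tr, t, r, ct, ref in _flat()
        ]
        rq = relative_quantity(_table(rows)).set_index("timepoint_h")["rq"]
        assert rq.loc[24] == pytest.approx(1.0, abs=1e-12)

    def test_scale_free_in_ct_offset(self):
        rng = np.random.default_rng(0)
        rows = [
            (g, tr, t, r, ct + rng.normal(0, 0.3), ref + rng.normal(0, 0.3))
            for g, tr, t, r, ct, ref in _flat()
        ]
        base = _table(rows)
        shifted = base.copy()
        shifted["ct_target"] += 3.7
        shifted["ct_reference"] += 3.7
        a = relative_quantity(base)["rq"].to_numpy()
        b = relative_quantity(shifted)["rq"].to_numpy()
        assert np.allclose(a, b)

    def test_missing_calibrator_names_gene(self):
        rows = [r for r in _flat() if r[2] != 0]
        with pytest.raises(ValueError, match="calibrator.*'g'"):
            relative_quantity(_table(rows))

    def test_ct_out_of_range_rejected(self):
        rows = _flat() + [("g", "x", 9, 4, 50.0, 20.0)]
        with pytest.raises(ValueError, match="out of range"):
            relative_quantity(_table(rows))

    def test_per_replicate_mode_matches_at_zero_noise(self):
        design = PanelDesign(genes=("g",), profiles={("g", "x"): {24: 4.0}}, noise_sd=0.0)
        ct = make_panel_ct(design)
        a = relative_quantity(ct, aggregate="ct_mean")
        b = relative_quantity(ct, aggregate="per_replicate")
        assert np.allclose(a["rq"], b["rq"])

    def test_control_normalization(self):
        rows = _flat("g", "x") + _flat("g", "control")
        rows = [
            (g, tr, t, r, ct - (2.0 if t == 24 else 0.0), ref)
            for g, tr, t, r, ct, ref in rows
        ]  # both series 4-fold up at 24 h -> control-normalized rq back to 1
        rq = relative_quantity(_table(rows), normalize_by_control=True)
        treated = rq[(rq["treatment"] == "x") & (rq["timepoint_h"] == 24)]["rq"].iloc[0]
        assert treated == pytest.approx(1.0, abs=1e-12)

    def test_read_ct_table_round_trip(self, tmp_path):
        p = tmp_path / "ct.tsv"
        _table(_flat()).to_csv(p, sep="\t", index=False)
        df = read_ct_table(p)
        assert list(df.columns) == CT_COLUMNS and len(df) == 15


class TestCallResponse:
    def test_flat_profile_unchanged(self):
        assert call_response({9: 1.1, 12: 0.9, 24: 1.0, 48: 1.0})[0] == "unchanged"

    def test_single_high_timepoint_induced(self):
        call, trigger = call_response({9: 1.0, 12: 1.0, 24: 4.0, 48: 1.0})
        assert call == "induced" and trigger == 24

    def test_single_low_timepoint_repressed(self):
        call, trigger = call_response({9: 1.0, 12: 0.25, 24: 1.0, 48: 1.0})
        assert call == "repressed" and trigger == 12

    def test_both_crossed_larger_log_fold_wins(self):
        assert call_response({9: 8.0, 12: 0.4})[0] == "induced"
        assert call_response({9: 2.5, 12: 0.1})[0] == "repressed"

    def test_exact_tie_goes_to_induced(self):
        assert call_response({9: 4.0, 12: 0.25})[0] == "induced"

    def test_thresholds_inclusive(self):
        assert call_response({9: 2.0})[0] == "induced"
        assert call_response({9: 0.5})[0] == "repressed"

    def test_calibrator_ignored(self):
        assert call_response({0: 10.0})[0] == "unchanged"


class TestPanel:
    def test_study_arithmetic(self):
        """28-gene panel: 3 flat + 2 repressed under pathogen leaves 25
        altered of which 23 induced; 5 flat under SA leaves 23 induced."""
        design = build_study_panel(seed=5)
        rq = relative_quantity(make_panel_ct(design))
        calls = call_responses(rq)
        pathogen = [c for c in calls if c.treatment == "pathogen"]
        sa = [c for c in calls if c.treatment == "SA"]
        s = summarize_panel(pathogen, sa, list(STUDY_PANEL_GENES))
        assert s.n_assayed == 28
        p = s.per_treatment["pathogen"]
        assert p == {"induced": 23, "repressed": 2, "unchanged": 3}
        assert p["induced"] + p["repressed"] == 25  # altered
        assert s.per_treatment["SA"] == {"induced": 23, "repressed": 0, "unchanged": 5}
        # honest set algebra: the intersection excludes every gene flat or
        # repressed under either treatment
        expected_both = set(STUDY_PANEL_GENES) - set(
            PATHOGEN_UNCHANGED + PATHOGEN_REPRESSED + SA_UNCHANGED
        )
        assert set(s.both_induced_genes) == expected_both
        assert s.n_both_induced == len(expected_both) == 19

    def test_counts_sum_to_panel_size(self):
        design = build_study_panel(seed=6)
        rq = relative_quantity(make_panel_ct(design))
        calls = call_responses(rq)
        s = summarize_panel(
            [c for c in calls if c.treatment == "pathogen"],
            [c for c in calls if c.treatment == "SA"],
            list(STUDY_PANEL_GENES),
        )
        for counts in s.per_treatment.values():
            assert sum(counts.values()) == s.n_assayed

    def test_empty_panel(self):
        s = summarize_panel([], [], [])
        assert s.n_assayed == 0 and s.n_both_induced == 0
        assert all(v == 0 for counts in s.per_treatment.values() for v in counts.values())

    def test_single_treatment_gene_excluded_from_intersection(self, caplog):
        calls_p = [ResponseCall("g1", "pathogen", {24: 4.0}, "induced", 24)]
        calls_s = []
        with caplog.at_level("WARNING"):
            s = summarize_panel(calls_p, calls_s, ["g1"])
        assert s.per_treatment["pathogen"]["induced"] == 1
        assert s.n_both_induced == 0
        assert "g1" in caplog.text

    def test_permutation_invariant(self):
        design = build_study_panel(seed=7)
        rq = relative_quantity(make_panel_ct(design))
        calls = call_responses(rq)
        p = [c for c in calls if c.treatment == "pathogen"]
        s = [c for c in calls if c.treatment == "SA"]
        a = summarize_panel(p, s, list(STUDY_PANEL_GENES))
        b = summarize_panel(p[::-1], s[::-1], list(STUDY_PANEL_GENES))
        assert a.per_treatment == b.per_treatment
        assert set(a.both_induced_genes) == set(b.both_induced_genes)

    def test_call_recovery_under_noise(self):
        """Programmed folds >= 4 (or <= 0.25) are always recovered at
        technical noise sd 0.15 with triplicate wells."""
        design = build_study_panel(seed=11, noise_sd=0.15)
        truth = design.truth_calls()
        rq = relative_quantity(make_panel_ct(design))
        for c in call_responses(rq):
            assert c.call == truth[(c.gene, c.treatment)], (c.gene, c.treatment)
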