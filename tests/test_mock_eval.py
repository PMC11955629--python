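"""Mock-control scoring: confusion counts, performance, O/E ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mockbench.mock_eval import (ConfusionCounts, MockReference,
                                 aggregate_controls, confusion,
                                 evaluate_control, match_species, oe_ratios,
                                 percent_correct, performance, round_half_up)
from mockbench.profiles import AbundanceTable, format_lineage
from mockbench.synthetic import species_lineage


def _profile(percents: dict[str, float], control_id: str = "c1") -> AbundanceTable:
    """Build a one-column relative table from species-label -> percent."""
    rows = {format_lineage(species_lineage(k)): v / 100.0
            for k, v in percents.items()}
    return AbundanceTable(pd.DataFrame({control_id: rows}), mode="relative")


def _perfect(ref) -> dict[str, float]:
    return dict(ref.entries)


class TestMatchSpecies:
    def test_perfect_profile(self, zymo8):
        t = _profile(_perfect(zymo8))
        detected, spurious, rescues = match_species(t, zymo8, "c1")
        assert detected == set(zymo8.species)
        assert spurious == set() and rescues == set()

    def test_genus_rescue_not_detected(self, zymo8):
        percents = _perfect(zymo8)
        pct = percents.pop("Bacillus subtilis")
        rows = {format_lineage(species_lineage(k)): v / 100.0
                for k, v in percents.items()}
        rows["k__;p__;c__;o__;f__;g__Bacillus;s__"] = pct / 100.0
        t = AbundanceTable(pd.DataFrame({"c1": rows}), mode="relative")
        detected, spurious, rescues = match_species(t, zymo8, "c1")
        assert "Bacillus subtilis" not in detected
        assert rescues == {"Bacillus subtilis"}
        assert spurious == set()

    def test_extra_taxon_is_spurious_at_floor_zero(self, zymo8):
        percents = _perfect(zymo8)
        percents["Limosilactobacillus fermentum"] -= 0.3
        percents["Cutibacterium acnes"] = 0.3
        t = _profile(percents)
        detected, spurious, _ = match_species(t, zymo8, "c1", floor=0.0)
        assert detected == set(zymo8.species)
        assert spurious == {format_lineage(species_lineage("Cutibacterium acnes"))}

    def test_floor_suppresses_rare_spurious(self, zymo8):
        percents = _perfect(zymo8)
        percents["Limosilactobacillus fermentum"] -= 0.3
        percents["Cutibacterium acnes"] = 0.3
        t = _profile(percents)
        _, spurious, _ = match_species(t, zymo8, "c1", floor=0.5)
        assert spurious == set()

    def test_alias_resolution(self, zymo8):
        percents = _perfect(zymo8)
        pct = percents.pop("Limosilactobacillus fermentum")
        percents["Lactobacillus fermentum"] = pct
        t = _profile(percents)
        detected, spurious, _ = match_species(t, zymo8, "c1")
        assert "Limosilactobacillus fermentum" in detected and not spurious

    def test_unknown_control_id(self, zymo8):
        t = _profile(_perfect(zymo8))
        with pytest.raises(KeyError):
            match_species(t, zymo8, "nope")


class TestConfusionAndPerformance:
    @pytest.mark.parametrize("tp, fp, fn, expected", [
        (7, 15, 1, (0.32, 0.88, 0.47)),
        (8, 0, 0, (1.00, 1.00, 1.00)),
        (8, 8, 0, (0.50, 1.00, 0.67)),
    ])
    def test_scores_round_to_printed_values(self, tp, fp, fn, expected):
        scores = performance(ConfusionCounts(tp, fp, fn))
        got = tuple(round_half_up(x) for x in
                    (scores.precision, scores.sensitivity, scores.f_score))
        assert got == expected

    def test_counts_from_sets(self, zymo8):
        detected = set(zymo8.species) - {"Bacillus subtilis"}
        counts = confusion(detected, {f"sp{i}" for i in range(15)}, zymo8)
        assert (counts.tp, counts.fp, counts.fn) == (7, 15, 1)
        assert counts.tp + counts.fn == len(zymo8)

    def test_total_miss(self, zymo8):
        counts = confusion(set(), {"a", "b", "c"}, zymo8)
        assert (counts.tp, counts.fp, counts.fn) == (0, 3, 8)
        assert performance(counts).f_score == 0.0

    def test_undefined_precision_flagged(self):
        scores = performance(ConfusionCounts(0, 0, 8))
        assert scores.precision == 0.0 and scores.precision_undefined

    @given(st.integers(1, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(2, 5))
    def test_scale_free(self, tp, fp, fn, k):
        a = performance(ConfusionCounts(tp, fp, fn))
        b = performance(ConfusionCounts(k * tp, k * fp, k * fn))
        assert np.isclose(a.precision, b.precision)
        assert np.isclose(a.f_score, b.f_score)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_harmonic_mean_relation_and_bounds(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        s = performance(ConfusionCounts(tp, fp, fn))
        if s.precision + s.sensitivity > 0:
            assert np.isclose(
                s.f_score,
                2 * s.precision * s.sensitivity / (s.precision + s.sensitivity),
                atol=1e-12)
        assert min(s.precision, s.sensitivity) - 1e-12 <= s.f_score
        assert s.f_score <= max(s.precision, s.sensitivity) + 1e-12


class TestOERatios:
    def test_identity_species_has_unit_ratio(self, zymo8):
        tables = {c: _profile(_perfect(zymo8), c) for c in ("c1", "c2")}
        recs = oe_ratios(tables, zymo8)
        for rec in recs:
            assert np.isclose(rec.median, 1.0) and np.isclose(rec.max, 1.0)

    def test_zero_inflated_median_and_range(self, zymo8, extraction_observed):
        tables = {c: extraction_observed for c in extraction_observed.sample_ids}
        recs = {r.species_label: r for r in oe_ratios(tables, zymo8)}
        lm = recs["Listeria monocytogenes"]
        assert round_half_up(lm.median) == 0.32
        assert (round_half_up(lm.min), round_half_up(lm.max)) == (0.00, 0.35)
        bs = recs["Bacillus subtilis"]
        assert bs.formatted() == "1.07 (0.00–1.13)"

    def test_ratio_weighted_sum_equals_percent_correct(self, zymo8):
        # unrounded synthetic profile: sum over species of ratio*theoretical
        # telescopes back to the percent correctly classified
        rng = np.random.default_rng(0)
        percents = {k: v * rng.uniform(0.5, 1.5) for k, v in zymo8.entries}
        other = 100.0 - sum(percents.values())
        rows = {format_lineage(species_lineage(k)): v / 100.0
                for k, v in percents.items()}
        rows["k__;p__;c__;o__;f__;g__;s__"] = other / 100.0
        t = AbundanceTable(pd.DataFrame({"c1": rows}), mode="relative")
        recs = oe_ratios({"c1": t}, zymo8)
        total = sum(r.per_control[0][2] * r.theoretical_percent for r in recs)
        assert np.isclose(total, percent_correct(t, zymo8, "c1"), atol=1e-9)


class TestPercentCorrectAndAggregate:
    def test_published_extraction_column(self, zymo8, extraction_observed):
        assert np.isclose(
            percent_correct(extraction_observed, zymo8, "R1P1Zymoex"), 80.84)

    def test_published_sequencing_column(self, zymo8, sequencing_observed):
        assert np.isclose(
            percent_correct(sequencing_observed, zymo8, "R1P1Zymoseq"), 99.58)

    def test_perfect_profile_is_100(self, zymo8):
        t = _profile(_perfect(zymo8))
        assert np.isclose(percent_correct(t, zymo8, "c1"), 100.0)

    def test_percent_correct_plus_other_is_100(self, zymo8, extraction_observed):
        for cid in extraction_observed.sample_ids:
            pc = percent_correct(extraction_observed, zymo8, cid)
            other = extraction_observed.data.at["k__;p__;c__;o__;f__;g__;s__", cid]
            assert abs(pc + other - 100.0) <= 0.02

    def test_aggregate_single_report(self, zymo8):
        t = _profile(_perfect(zymo8))
        rep = evaluate_control(t, zymo8, "c1")
        summary = aggregate_controls([rep])
        assert summary.f_median == rep.scores.f_score == 1.0

    def test_aggregate_median_from_confusion_triples(self, extraction_confusion_path):
        df = pd.read_csv(extraction_confusion_path, sep="\t", index_col=0)
        fs = [performance(ConfusionCounts(
            int(df.at["true_positives", c]), int(df.at["false_positives", c]),
            int(df.at["false_negatives", c]))).f_score for c in df.columns]
        assert round_half_up(float(np.median(fs))) == 0.84
        assert round_half_up(float(np.min(fs))) == 0.47
        assert round_half_up(float(np.max(fs))) == 1.00


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.665) == 0.67
    assert round_half_up(1.0661) == 1.07
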