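"""Sequencing metrics: matching rules, curves and their invariants."""

import numpy as np
import pytest

from tcnovo import chem, evaluation
from tcnovo.decoding import SequencingResult
from tcnovo.evaluation import (choose_cutoff_for_precision,
                               filtered_peptide_accuracy, peptide_accuracy,
                               peptide_correct, positional_accuracy,
                               positional_matches, precision_coverage)


def result(sid, pep, score, ppm=0.0):
    return SequencingResult(spectrum_id=sid, peptide=pep,
                            positional_probs=[score] if pep else [],
                            quality_score=score, theoretical_mass=0.0,
                            ppm_to_precursor=ppm)


class TestPeptideCorrect:
    def test_identical(self):
        assert peptide_correct("ACK", "ACK")

    def test_leu_ile_collapsed(self):
        assert peptide_correct("LKE", "IKE")

    def test_length_mismatch(self):
        assert not peptide_correct("ACK", "ACKK")

    def test_substitution(self):
        assert not peptide_correct("GCK", "ACK")


class TestPositionalMatches:
    def test_identical_all_matched(self):
        assert positional_matches("PEPTIDE", "PEPTIDE") == 7

    def test_disjoint_zero(self):
        assert positional_matches("GGGG", "WWWW") == 0

    def test_resync_after_mass_balanced_error(self):
        # N (114.043) vs GG (57.021*2 = 114.043): prefix masses re-align
        # after the error so downstream residues count again
        pred, truth = "ANK", "AGGK"
        assert positional_matches(pred, truth) == 2  # A and K

    def test_matches_brute_force_prefix_oracle(self, rng):
        # oracle: direct double loop over all (i, j) prefix pairs
        from conftest import random_peptides
        preds = random_peptides(rng, 50, lengths=(3, 12))
        truths = random_peptides(rng, 50, lengths=(3, 12))
        for pred, truth in zip(preds, truths):
            pm_p = np.cumsum([0.0] + [chem.RESIDUE_MASS[c] for c in pred])
            pm_t = np.cumsum([0.0] + [chem.RESIDUE_MASS[c] for c in truth])
            expected = 0
            i = j = 0
            while i < len(pred) and j < len(truth):
                if abs(pm_p[i] - pm_t[j]) <= 0.5:
                    expected += chem.residues_equivalent(pred[i], truth[j])
                    i, j = i + 1, j + 1
                elif pm_p[i] < pm_t[j]:
                    i += 1
                else:
                    j += 1
            assert positional_matches(pred, truth) == expected

    def test_by_index_mode(self):
        assert positional_matches("ANK", "AGGK", by_index=True) == 1  # A only

    def test_peptide_correct_implies_full_match(self, rng):
        from conftest import random_peptides
        for pep in random_peptides(rng, 30, lengths=(2, 15)):
            swapped = pep.replace("I", "L")
            assert peptide_correct(swapped, pep)
            assert positional_matches(swapped, pep) == len(pep)


class TestAccuracies:
    def test_all_perfect(self):
        assert positional_accuracy(["ACK", "GDE"], ["ACK", "GDE"]) == 1.0
        assert peptide_accuracy(["ACK"], ["ACK"]) == 1.0

    def test_all_empty_decodes(self):
        assert positional_accuracy(["", ""], ["ACK", "GDE"]) == 0.0

    def test_hand_counted_mixture(self):
        # spectrum 1: fully correct (3 residues); spectrum 2: "GKE" vs
        # "AKE" first residue wrong, prefixes re-align nowhere (57 vs 71
        # then 185.1 vs 199.1 ... offset 14 forever) -> 0 matches
        acc = positional_accuracy(["ACK", "GKE"], ["ACK", "AKE"])
        assert acc == pytest.approx(3 / 6)

    def test_filtered_accuracy(self):
        truths = {"a": "ACK", "b": "GDE", "c": "WW"}
        results = [result("a", "ACK", 0.9, ppm=1.0),
                   result("b", "GDE", 0.8, ppm=50.0),   # filtered out
                   result("c", "AA", 0.7, ppm=2.0)]
        acc, n = filtered_peptide_accuracy(results, truths, tol_ppm=10)
        assert n == 2
        assert acc == pytest.approx(0.5)

    def test_filtered_accuracy_empty_set_convention(self):
        truths = {"a": "ACK"}
        acc, n = filtered_peptide_accuracy([result("a", "ACK", 0.9, ppm=99)],
                                           truths)
        assert (acc, n) == (0.0, 0)


class TestPrecisionCoverage:
    def fixture_results(self, rng):
        truths = {}
        results = []
        for i in range(20):
            sid = f"s{i}"
            truth = "ACDEFK"
            correct = i % 3 != 0
            truths[sid] = truth
            results.append(result(sid, truth if correct else "GGK",
                                  score=float(rng.uniform(0, 1))))
        return results, truths

    def test_brute_force_recount(self, rng):
        results, truths = self.fixture_results(rng)
        thresholds = [0.0, 0.25, 0.5, 0.75, 0.99]
        curve = precision_coverage(results, truths, thresholds)
        for t, prec, cov in curve:
            above = [r for r in results if r.quality_score >= t]
            ncorr = sum(peptide_correct(r.peptide, truths[r.spectrum_id])
                        for r in above)
            assert cov == pytest.approx(ncorr / len(truths))
            assert prec == pytest.approx(ncorr / len(above) if above else 1.0)

    def test_coverage_non_increasing_and_sets_nested(self, rng):
        results, truths = self.fixture_results(rng)
        thresholds = np.linspace(0, 1, 11)
        curve = precision_coverage(results, truths, thresholds)
        coverages = [c for _, _, c in curve]
        assert all(a >= b - 1e-12 for a, b in zip(coverages, coverages[1:]))
        prev = None
        for t in thresholds:
            above = {r.spectrum_id for r in results if r.quality_score >= t}
            if prev is not None:
                assert above <= prev
            prev = above

    def test_threshold_above_all_scores(self):
        truths = {"a": "ACK"}
        curve = precision_coverage([result("a", "ACK", 0.5)], truths, [0.9])
        assert curve[0][1] == 1.0  # documented empty-set convention
        assert curve[0][2] == 0.0


class TestCutoffChoice:
    def test_separable_scores(self):
        truths = {f"s{i}": "ACK" for i in range(6)}
        # correct results score >= 0.8; wrong ones score <= 0.3
        results = [result(f"s{i}", "ACK", 0.8 + 0.02 * i) for i in range(3)]
        results += [result(f"s{i}", "GGK", 0.1 * i) for i in range(3, 6)]
        cut = choose_cutoff_for_precision(results, truths, 0.95)
        assert 0.3 < cut <= 0.8

    def test_target_zero_gives_minimum_score(self):
        truths = {"a": "ACK", "b": "ACK"}
        results = [result("a", "ACK", 0.4), result("b", "GGK", 0.2)]
        assert choose_cutoff_for_precision(results, truths, 0.0) == 0.2

    def test_unreachable_target_returns_sentinel(self):
        truths = {"a": "ACK"}
        results = [result("a", "GGK", 0.9)]
        assert choose_cutoff_for_precision(results, truths, 0.95) is None


class TestEvaluateReport:
    def test_report_fields_and_serialization(self, tmp_path, rng):
        truths = {"a": "ACK", "b": "GDEK"}
        results = [result("a", "ACK", 0.9, ppm=1.0),
                   result("b", "GDEK", 0.5, ppm=20.0)]
        report = evaluation.evaluate(results, truths)
        assert report.n_spectra == 2
        assert report.peptide_accuracy == 1.0
        assert report.n_filtered == 1
        assert 0 <= report.positional_accuracy <= 1
        out = tmp_path / "report.json"
        report.to_json(out)
        import json
        payload = json.loads(out.read_text())
        assert payload["peptide_accuracy"] == 1.0
        assert len(payload["precision_coverage"]) == 21
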