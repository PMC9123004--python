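import math

import numpy as np
import pytest

from panelprof import synth
from panelprof.msi_signature import (
    CANONICAL_CLASSES,
    N_TRIPLET_POSITIONS,
    PwmModel,
    SubstitutionEvent,
    TRIPLET_INDEX,
    canonicalize,
    classify_msi,
    fit_boundary,
    reverse_complement,
    score_sample_signature,
    score_substitution,
    train_pwm,
)
from panelprof.msi_tract import MsiTractResult


def flat_model(value=0.0):
    return PwmModel(
        {c: np.full((N_TRIPLET_POSITIONS, 64), value) for c in CANONICAL_CLASSES}
    )


class TestCanonicalize:
    def test_purine_ref_is_reverse_complemented(self):
        w = "ACGTTGAACCT"  # centre (index 5) = G
        ev = canonicalize("G", "A", w)
        assert ev.canonical_class == "C>T"
        assert ev.window11 == reverse_complement(w)

    def test_pyrimidine_ref_unchanged(self):
        w = "ACGTTCAACCT"
        ev = canonicalize("C", "T", w)
        assert ev.canonical_class == "C>T" and ev.window11 == w

    def test_idempotence(self):
        w = "ACGTTGAACCT"
        once = canonicalize("G", "A", w)
        twice = canonicalize(once.ref, once.alt, once.window11)
        assert once == twice

    def test_non_acgt_base_rejected(self):
        with pytest.raises(ValueError):
            canonicalize("N", "T", "A" * 5 + "N" + "A" * 5)

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            canonicalize("C", "C", "A" * 5 + "C" + "A" * 5)


class TestTrainPwm:
    def test_identical_catalogs_give_zero_matrices(self):
        events, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=300, signature="flat", rng_seed=1)
        )
        model = train_pwm(events, events)
        for cls in CANONICAL_CLASSES:
            assert np.allclose(model.matrices[cls], 0.0)

    def test_doubled_probability_gives_log2_entry(self):
        # one triplet at one position occurs at exactly double the pMMR
        # probability; zero-pseudocount limit recovers log(2)
        w_a = "AAAAACAAAAA"  # triplets all AAA except those touching centre C
        w_b = "TTTTTCTTTTT"
        dmmr = [SubstitutionEvent("C", "T", w_a)] * 2 + [
            SubstitutionEvent("C", "T", w_b)
        ] * 2
        pmmr = [SubstitutionEvent("C", "T", w_a)] * 1 + [
            SubstitutionEvent("C", "T", w_b)
        ] * 3
        model = train_pwm(dmmr, pmmr, pseudocount=1e-9)
        grid = model.matrices["C>T"]
        # position 0 triplet AAA: P_d = 2/4, P_p = 1/4
        assert grid[0, TRIPLET_INDEX["AAA"]] == pytest.approx(math.log(2), abs=1e-6)
        assert grid[0, TRIPLET_INDEX["TTT"]] == pytest.approx(
            math.log(2 / 3), abs=1e-6
        )

    def test_pseudocount_must_be_positive(self):
        with pytest.raises(ValueError):
            train_pwm([], [], pseudocount=0.0)

    @staticmethod
    def _position0_errors(n, seed_pair):
        mmr, truth_m = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=n, signature="mmr",
                                    rng_seed=seed_pair[0])
        )
        flat, truth_f = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=n, signature="flat",
                                    rng_seed=seed_pair[1])
        )
        model = train_pwm(mmr, flat, pseudocount=0.5)
        pm = synth.analytic_triplet_probs(truth_m["base_probs"], 0, "C")
        pf = synth.analytic_triplet_probs(truth_f["base_probs"], 0, "C")
        grid = model.matrices["C>T"]
        errs = {}
        for trip, idx in TRIPLET_INDEX.items():
            if pm[trip] > 0.005 and pf[trip] > 0.005:  # estimable triplets
                errs[trip] = grid[0, idx] - math.log(pm[trip] / pf[trip])
        return errs

    def test_recovers_analytic_log_ratios_on_synthetic_catalogs(self):
        errs = self._position0_errors(20000, (5, 6))
        # sampling noise is dominated by the rarer catalog's triplet counts
        # (tens of observations), so ~0.15 log-units of scatter is expected
        rmse = np.sqrt(np.mean([e**2 for e in errs.values()]))
        assert rmse < 0.3
        assert max(abs(e) for e in errs.values()) < 0.6

    def test_recovery_error_shrinks_with_catalog_size(self):
        rmse_small = np.sqrt(
            np.mean([e**2 for e in self._position0_errors(1000, (20, 21)).values()])
        )
        rmse_large = np.sqrt(
            np.mean([e**2 for e in self._position0_errors(20000, (5, 6)).values()])
        )
        assert rmse_large < rmse_small

    def test_json_round_trip(self, tmp_path):
        events, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=200, signature="mmr", rng_seed=2)
        )
        flat, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=200, signature="flat", rng_seed=3)
        )
        model = train_pwm(events, flat)
        path = tmp_path / "pwm.json"
        model.to_json(path)
        back = PwmModel.from_json(path)
        for cls in CANONICAL_CLASSES:
            assert np.allclose(model.matrices[cls], back.matrices[cls])


class TestScoring:
    def test_all_zero_matrices_score_zero(self):
        ev = SubstitutionEvent("C", "T", "ACGTTCAACCT")
        assert score_substitution(flat_model(0.0), ev) == 0.0

    def test_constant_log2_matrices_score_9_log2(self):
        ev = SubstitutionEvent("C", "T", "ACGTTCAACCT")
        score = score_substitution(flat_model(math.log(2)), ev)
        assert score == pytest.approx(9 * math.log(2))

    def test_matches_brute_force_position_loop(self, rng):
        events, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=50, signature="mmr", rng_seed=7)
        )
        flat, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=50, signature="flat", rng_seed=8)
        )
        model = train_pwm(events, flat)
        for ev in events[:20]:
            brute = 0.0
            for p in range(9):
                trip = ev.window11[p : p + 3]
                brute += model.matrices[ev.canonical_class][p, TRIPLET_INDEX[trip]]
            assert score_substitution(model, ev) == pytest.approx(brute)

    def test_strand_symmetry(self):
        events, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=100, signature="mmr", rng_seed=9)
        )
        flat, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=100, signature="flat", rng_seed=10)
        )
        model = train_pwm(events, flat)
        for ev in events[:20]:
            flipped = canonicalize(
                ev.ref.translate(str.maketrans("ACGT", "TGCA")),
                ev.alt.translate(str.maketrans("ACGT", "TGCA")),
                reverse_complement(ev.window11),
            )
            assert score_substitution(model, flipped) == pytest.approx(
                score_substitution(model, ev)
            )

    def test_sample_total_is_exact_sum_and_doubles(self):
        events, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=40, signature="mmr", rng_seed=11)
        )
        model = flat_model(0.1)
        one = score_sample_signature(model, events)
        two = score_sample_signature(model, events + events)
        assert one.n_substitutions == 40
        assert two.total == pytest.approx(2 * one.total)

    def test_empty_catalog_scores_zero(self):
        s = score_sample_signature(flat_model(1.0), [])
        assert (s.total, s.n_substitutions) == (0.0, 0)

    def test_mmr_sample_outscores_flat_sample(self):
        train_m, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=5000, signature="mmr", rng_seed=12)
        )
        train_f, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=5000, signature="flat", rng_seed=13)
        )
        model = train_pwm(train_m, train_f)
        sample_m, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=100, signature="mmr", rng_seed=14)
        )
        sample_f, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=100, signature="flat", rng_seed=15)
        )
        assert (
            score_sample_signature(model, sample_m).total
            > score_sample_signature(model, sample_f).total
        )

    def test_pole_like_hypermutator_scores_negative(self):
        """High mutation count outside MMR contexts must not look like MSI."""
        train_m, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=5000, signature="mmr", rng_seed=16)
        )
        train_f, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=5000, signature="flat", rng_seed=17)
        )
        model = train_pwm(train_m, train_f)
        pole, _ = synth.simulate_mutation_catalog(
            synth.MutationSimConfig(n_mutations=2000, signature="pole_like",
                                    rng_seed=18)
        )
        assert score_sample_signature(model, pole).total < 0


class TestBoundary:
    def test_separated_clusters_classified_correctly(self):
        pts = [(0.5, 100.0)] * 5 + [(0.0, -100.0)] * 5
        labels = ["MSI-H"] * 5 + ["MSS"] * 5
        b = fit_boundary(pts, labels)
        assert b.combined_score(0.5, 100.0) > 0
        assert b.combined_score(0.0, -100.0) < 0

    def test_two_points_boundary_is_perpendicular_bisector(self):
        # single point per class: the max-margin line is their bisector
        p_h, p_s = (0.4, 80.0), (0.1, -40.0)
        b = fit_boundary([p_h, p_s], ["MSI-H", "MSS"])
        mid = ((p_h[0] + p_s[0]) / 2, (p_h[1] + p_s[1]) / 2)
        assert b.combined_score(*mid) == pytest.approx(0.0, abs=1e-6)
        assert b.combined_score(*p_h) == pytest.approx(-b.combined_score(*p_s),
                                                       rel=1e-3)

    def test_synthetic_cohort_fully_separated(self, rng):
        n = 360
        frac_h = rng.uniform(0.2, 0.8, n // 2)
        sig_h = rng.uniform(50, 300, n // 2)
        frac_s = rng.uniform(0.0, 0.1, n // 2)
        sig_s = rng.uniform(-300, -50, n // 2)
        pts = list(zip(frac_h, sig_h)) + list(zip(frac_s, sig_s))
        labels = ["MSI-H"] * (n // 2) + ["MSS"] * (n // 2)
        b = fit_boundary(pts, labels)
        calls = [
            "MSI-H" if b.combined_score(x, y) > 0 else "MSS" for x, y in pts
        ]
        assert calls == labels

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            fit_boundary([(0, 1), (0, 2)], ["MSS", "MSS"])

    def test_non_separable_warns_and_names_violators(self):
        # an MSS point sitting inside the MSI-H cluster cannot be separated
        pts = [(0.5, 100.0), (0.45, 95.0), (0.55, 105.0),
               (0.0, -100.0), (0.05, -95.0), (0.5, 100.0)]
        labels = ["MSI-H", "MSI-H", "MSI-H", "MSS", "MSS", "MSS"]
        with pytest.warns(UserWarning, match="violators.*5"):
            fit_boundary(pts, labels)

    def test_mmr_flag_relabels_near_boundary(self):
        # one mislabelled point close to the boundary, flagged by MMR status
        pts = [(0.5, 100.0)] * 4 + [(0.0, -100.0)] * 4 + [(0.24, 1.0)]
        labels = ["MSI-H"] * 4 + ["MSS"] * 4 + ["MSS"]
        flags = [True] * 4 + [False] * 4 + [True]
        b = fit_boundary(pts, labels, mmr_deleterious=flags, relabel_band=2.0)
        assert b.combined_score(0.24, 1.0) > 0


class TestClassifyMsi:
    def _boundary(self):
        pts = [(0.3, 50.0)] * 3 + [(0.02, -50.0)] * 3
        return fit_boundary(pts, ["MSI-H"] * 3 + ["MSS"] * 3)

    def test_score_zero_is_mss(self):
        from panelprof.msi_signature import MsiResult

        assert MsiResult(0.1, 0.0, 0.0).call == "MSS"

    def test_high_fraction_positive_signature_is_msih(self):
        b = self._boundary()
        res = classify_msi(
            MsiTractResult(68, 11),
            type("S", (), {"total": 80.0})(),
            b,
        )
        assert res.call == "MSI-H"

    def test_zero_fraction_negative_signature_is_mss(self):
        b = self._boundary()
        res = classify_msi(
            MsiTractResult(68, 0),
            type("S", (), {"total": -120.0})(),
            b,
        )
        assert res.call == "MSS"
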