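"""Synthetic generators: determinism, planted-structure construction,
and closed-form calibration of the planted effects."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from discosig import (
    CohortSimSpec,
    ConsensusSignature,
    PerturbationSimSpec,
    SignatureEntry,
    SignatureParams,
    SynergySimSpec,
    ValidationError,
    hsa_score,
    logrank_test,
    simulate_cohort,
    simulate_dependency_table,
    simulate_dose_response,
    simulate_perturbation_set,
)


def toy_signature(n_up=10, n_down=10):
    entries = {}
    for i in range(n_up):
        entries[f"UP{i:03d}"] = SignatureEntry(2.0 + i * 0.3, "up", 1.0)
    for i in range(n_down):
        entries[f"DN{i:03d}"] = SignatureEntry(-(2.0 + i * 0.3), "down", 1.0)
    return ConsensusSignature(entries=entries, params=SignatureParams(0.3, 2.0))


class TestPerturbation:
    def test_truth_size_by_construction(self):
        _, truth = simulate_perturbation_set(
            PerturbationSimSpec(n_genes=100, n_up=10, n_down=10)
        )
        assert len(truth) == 20
        assert sum(1 for d in truth.values() if d == "up") == 10

    def test_seed_determinism(self):
        spec = PerturbationSimSpec(n_genes=50, n_up=5, n_down=5, seed=42)
        t1, tr1 = simulate_perturbation_set(spec)
        t2, tr2 = simulate_perturbation_set(spec)
        assert t1 == t2 and tr1 == tr2

    def test_overfull_planting_rejected(self):
        with pytest.raises(ValidationError):
            PerturbationSimSpec(n_genes=10, n_up=8, n_down=8)

    def test_columns_cover_lines_and_timepoints(self):
        spec = PerturbationSimSpec(
            n_genes=20, n_up=2, n_down=2, n_cell_lines=4, timepoints=["6 h", "24 h"]
        )
        table, _ = simulate_perturbation_set(spec)
        assert len(table.col_ids) == 8
        tps = {table.col_meta[c]["timepoint"] for c in table.col_ids}
        assert tps == {"6 h", "24 h"}

    def test_responder_fraction_matches_normal_tail(self):
        """For a planted up gene (effect 4, responder fraction 0.5, unit
        noise) the per-line exceedance P(z >= 2) has closed form
        0.5*P(N(4,1)>=2) + 0.5*P(N(0,1)>=2) ~ 0.50; check by simulation
        over 1000 planted genes."""
        spec = PerturbationSimSpec(
            n_genes=1000, n_up=1000, n_down=0, planted_effect=4.0,
            responder_fraction=0.5, noise_sd=1.0, seed=11,
        )
        table, truth = simulate_perturbation_set(spec)
        frac = float(np.mean(table.values >= 2.0))
        expected = 0.5 * norm.sf(2.0, loc=4.0) + 0.5 * norm.sf(2.0)
        assert frac == pytest.approx(expected, abs=0.02)


class TestCohort:
    def test_no_censoring_means_all_events(self):
        cohort, _ = simulate_cohort(
            CohortSimSpec(n_genes=50, n_patients=40, censor_rate=0.0, n_markers_per_subgroup=5)
        )
        assert all(r.os_event == 1 for r in cohort.survival.values())

    def test_seed_determinism(self):
        spec = CohortSimSpec(n_genes=60, n_patients=30, seed=3, n_markers_per_subgroup=5)
        (c1, t1), (c2, t2) = simulate_cohort(spec), simulate_cohort(spec)
        assert c1.expr == c2.expr
        assert c1.survival == c2.survival
        assert t1.markers == t2.markers

    def test_subgroup_proportions_respected(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n_genes=30, n_patients=76, n_markers_per_subgroup=0))
        counts = {s: len(cohort.patients_in(s)) for s in cohort.subgroup_levels()}
        assert sum(counts.values()) == 76
        # largest-remainder apportionment of the default proportions
        assert counts == {"WNT": 8, "SHH": 23, "G3": 19, "G4": 26}

    def test_discordant_markers_oppose_signature(self):
        sig = toy_signature()
        _, truth = simulate_cohort(
            CohortSimSpec(n_genes=200, discordant_subgroup="G3"), drug_signature=sig
        )
        for g, shift in truth.markers["G3"].items():
            assert math.copysign(1, shift) == -math.copysign(1, sig.entries[g].consensus_z)

    def test_discordant_without_signature_rejected(self):
        with pytest.raises(ValidationError, match="drug_signature"):
            simulate_cohort(CohortSimSpec(discordant_subgroup="G3"))

    def test_unknown_discordant_subgroup_rejected(self):
        with pytest.raises(ValidationError):
            CohortSimSpec(discordant_subgroup="NOPE")

    def test_null_hazard_ratio_is_calibrated(self):
        """With no planted hazard effect the Q4-vs-Q1 log-rank test must
        reject at its nominal rate (5% +/- 2% over 500 seeds)."""
        rejections = 0
        n_seeds = 500
        genes = [f"GENE{i:05d}" for i in range(10)]
        for seed in range(n_seeds):
            cohort, truth = simulate_cohort(
                CohortSimSpec(
                    n_genes=20, n_patients=120, n_markers_per_subgroup=0, survival_geneset=genes,
                    survival_hazard_ratio=1.0, censor_rate=0.2, seed=seed,
                )
            )
            q4 = [p for p, q in truth.quartile.items() if q == "Q4"]
            q1 = [p for p, q in truth.quartile.items() if q == "Q1"]
            chi2, p = logrank_test(
                [(cohort.survival[p].os_time, cohort.survival[p].os_event) for p in q4],
                [(cohort.survival[p].os_time, cohort.survival[p].os_event) for p in q1],
            )
            rejections += p < 0.05
        assert abs(rejections / n_seeds - 0.05) <= 0.02

    def test_planted_quartile_hazard_ordering(self):
        cohort, truth = simulate_cohort(
            CohortSimSpec(
                n_genes=40, n_patients=200, censor_rate=0.0, n_markers_per_subgroup=0,
                survival_geneset=[f"GENE{i:05d}" for i in range(10)],
                survival_hazard_ratio=4.0, seed=5,
            )
        )
        mean_time = {}
        for q in ("Q1", "Q4"):
            pts = [p for p in truth.quartile if truth.quartile[p] == q]
            mean_time[q] = np.mean([cohort.survival[p].os_time for p in pts])
        assert mean_time["Q4"] < mean_time["Q1"]


class TestDependency:
    def test_essential_gene_mean_below_minus_one(self):
        hits = 0
        for seed in range(100):
            dep = simulate_dependency_table(["ESS"], n_genes=30, n_cell_lines=20, seed=seed)
            hits += dep.values[0].mean() < -1.0
        assert hits == 100  # N(-1.5, 0.3/sqrt(20)): tail beyond -1 is ~1e-13

    def test_background_gene_mean_near_zero(self):
        hits = 0
        for seed in range(100):
            dep = simulate_dependency_table(["ESS"], n_genes=30, n_cell_lines=20, seed=seed)
            hits += abs(dep.values[5].mean()) < 0.3
        assert hits == 100

    def test_determinism(self):
        a = simulate_dependency_table(["x"], 20, 5, seed=9)
        b = simulate_dependency_table(["x"], 20, 5, seed=9)
        assert a == b


class TestDoseResponseSim:
    def test_zero_excess_zero_score(self):
        s = simulate_dose_response(SynergySimSpec(planted_excess=0.0, noise_sd=0.0))
        assert hsa_score(s).hsa_score == 0.0

    def test_margins_follow_4pl(self):
        spec = SynergySimSpec(noise_sd=0.0)
        s = simulate_dose_response(spec)
        d = np.asarray(spec.doses_a[1:])
        expected = 100.0 / (1.0 + (spec.ec50_a / d) ** spec.hill_a)
        assert s.response[1:, 0] == pytest.approx(expected)
        assert s.response[0, 0] == 0.0

    def test_determinism_with_noise(self):
        spec = SynergySimSpec(planted_excess=10.0, noise_sd=3.0, seed=21)
        a, b = simulate_dose_response(spec), simulate_dose_response(spec)
        assert np.array_equal(a.response, b.response)

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValidationError):
            SynergySimSpec(doses_a=[1.0, 2.0])
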