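"""Synthetic cohort generator: round trips, noise calibration, determinism."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from clonefish import (
    SubcloneCode,
    SyntheticCohortSpec,
    filter_cells,
    generate_cohort,
    generate_matched_pairs,
    sample_cells,
    shannon_entropy,
    simulate_clone_tree,
    tabulate_clones,
)
from clonefish.evolution import REPLACEMENT, SHARED, classify_evolution, match_pairs
from clonefish.simulate import generate_patient_sample


SMALL = dict(n_favorable=4, n_unfavorable=3, cells_per_sample=150)


class TestCloneTree:
    def test_zero_cin_single_founder(self, rng):
        spec = SyntheticCohortSpec(cin_rate=0.0, **SMALL)
        clones, parents = simulate_clone_tree(spec, rng)
        assert len(set(clones)) == 1 and parents[0] == -1

    def test_depth_one_full_cin_on_one_chromosome(self):
        cin = [0.0] * 8
        cin[3] = 1.0  # chromosome 10
        spec = SyntheticCohortSpec(cin_rate=cin, tree_depth=1, n_subclones=2, **SMALL)
        rng = np.random.default_rng(0)
        clones, _ = simulate_clone_tree(spec, rng)
        founder, child = clones
        diffs = [a - b for a, b in zip(child.gains, founder.gains)]
        assert sorted(np.nonzero(diffs)[0].tolist()) == [3]
        assert abs(diffs[3]) == 1

    def test_degenerate_full_cin_deep_tree_rejected(self):
        spec = SyntheticCohortSpec(cin_rate=1.0, tree_depth=9, **SMALL)
        with pytest.raises(ValueError, match="degenerate"):
            simulate_clone_tree(spec, np.random.default_rng(0))

    def test_chr21_gained_in_nearly_all_clones(self):
        spec = SyntheticCohortSpec(**SMALL)
        j21 = spec.panel.index("21")
        j4, j6 = spec.panel.index("4"), spec.panel.index("6")
        with21 = with_late = total = 0
        for seed in range(50):
            clones, _ = simulate_clone_tree(spec, np.random.default_rng(seed))
            total += len(clones)
            with21 += sum(c.gains[j21] >= 1 for c in clones)
            with_late += sum(c.gains[j4] >= 1 or c.gains[j6] >= 1 for c in clones)
        assert with21 / total >= 0.95
        assert with_late / total < 0.5


class TestSampleCells:
    def test_zero_noise_cells_equal_source_clones(self, rng):
        clones = [SubcloneCode.from_string(s) for s in ("10001002", "11111111")]
        cells, sources = sample_cells(
            clones, [0.6, 0.4], 200, "F", "s", rng
        )
        from clonefish import encode_subclone

        for cell, source in zip(cells, sources):
            assert encode_subclone(cell, "F") == source

    def test_planted_noise_rate_within_binomial_ci(self, rng):
        diploid = [SubcloneCode((0,) * 8)]
        n, p = 4000, 0.0037
        cells, _ = sample_cells(
            diploid, [1.0], n, "M", "s", rng, false_gain_rate=p
        )
        gains = sum(c.counts[1] > 2 for c in cells)  # chromosome 4 channel
        lo, hi = binom.ppf([0.0025, 0.9975], n, p)
        assert lo <= gains <= hi

    def test_admixture_fraction_filtered_as_no_gain(self, rng):
        clones = [SubcloneCode.from_string("11111111")]
        n = 2000
        cells, _ = sample_cells(clones, [1.0], n, "M", "s", rng, admixture=0.3)
        no_gain = sum(
            1 for _, reason in filter_cells(cells, "M").excluded if reason == "no-gain"
        )
        lo, hi = binom.ppf([0.0025, 0.9975], n, 0.3)
        assert lo <= no_gain <= hi

    def test_frequencies_must_sum_to_one(self, rng):
        with pytest.raises(ValueError):
            sample_cells([SubcloneCode((0,) * 8)], [0.5], 10, "M", "s", rng)


class TestCohort:
    def test_fixed_seed_identical_regeneration(self):
        spec = SyntheticCohortSpec(seed=42, **SMALL)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a.clinical.equals(b.clinical)
        for pid in a.cells:
            assert [c.counts for c in a.cells[pid]] == [c.counts for c in b.cells[pid]]
        assert a.truth == b.truth

    def test_group_sizes_and_outcome_consistency(self):
        spec = SyntheticCohortSpec(seed=1, **SMALL)
        clin = generate_cohort(spec).clinical
        assert (clin.group == "favorable").sum() == 4
        assert ((clin.outcome == "REL") == (clin.group == "unfavorable")).all()
        assert (clin.time_years > 0).all()

    def test_contradictory_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(mean_p18=(150.0, 25.0))

    def test_entropy_estimate_converges_with_cells(self):
        errors = []
        for n_cells in (200, 2000, 20000):
            errs = []
            for seed in range(5):
                spec = SyntheticCohortSpec(
                    seed=seed, cells_per_sample=n_cells,
                    false_gain_rate=0.0, false_loss_rate=0.0, admixture=0.0,
                )
                rng = np.random.default_rng(seed)
                sample = generate_patient_sample(spec, "favorable", "F", "s", rng)
                blasts = [c for _, c in filter_cells(sample["cells"], "F").blasts]
                est = tabulate_clones(blasts).entropy_bits
                errs.append(abs(est - sample["true_entropy_bits"]))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]

    def test_gain_rate_estimates_unbiased(self):
        errs = []
        for seed in range(40):
            spec = SyntheticCohortSpec(
                seed=seed, cells_per_sample=400,
                false_gain_rate=0.0, false_loss_rate=0.0, admixture=0.0,
            )
            rng = np.random.default_rng(1000 + seed)
            sample = generate_patient_sample(spec, "favorable", "M", "s", rng)
            blasts = [c for _, c in filter_cells(sample["cells"], "M").blasts]
            j18 = spec.panel.index("18")
            est = 100 * np.mean([c.gains[j18] >= 1 for c in blasts])
            errs.append(est - sample["true_p18"])
        se = np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 3 * se + 0.5

    def test_pmc_entropy_negative_rank_correlation_across_cohort(self):
        spec = SyntheticCohortSpec(seed=7, n_favorable=15, n_unfavorable=10,
                                   cells_per_sample=200)
        cohort = generate_cohort(spec)
        truth = cohort.truth["patients"]
        pmcs = [100 * max(t["clone_frequencies"].values()) for t in truth.values()]
        ents = [t["true_entropy_bits"] for t in truth.values()]
        rho, _ = spearmanr(pmcs, ents)
        assert rho < -0.5


class TestMatchedPairs:
    def _patterns(self, scenario, seed=5):
        spec = SyntheticCohortSpec(seed=seed, cells_per_sample=200)
        out = generate_matched_pairs(spec, n_patients=6, scenario=scenario)
        sexes = {r.patient_id: r.sex for r in out["meta"].itertuples()}
        samples = []
        for sid, cells in out["cells"].items():
            pid, tp = sid.rsplit("_", 1)
            blasts = [c for _, c in filter_cells(cells, sexes[pid]).blasts]
            samples.append((pid, tp, tabulate_clones(blasts)))
        pairs, _ = match_pairs(samples)
        return [classify_evolution(dx, rel, pid).pattern for pid, dx, rel in pairs]

    def test_persistent_scenario_always_shared(self):
        assert set(self._patterns("persistent")) == {SHARED}

    def test_sweep_scenario_always_replacement(self):
        assert set(self._patterns("sweep")) == {REPLACEMENT}

    def test_unknown_scenario_rejected(self):
        spec = SyntheticCohortSpec(**SMALL)
        with pytest.raises(ValueError):
            generate_matched_pairs(spec, scenario="mystery")
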