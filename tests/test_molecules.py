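"""Molecule-population simulator: limits, conservation, ground-truth audit."""

import numpy as np
import pytest

import dualaav as da
from dualaav.constructs import FIVE_PRIME, THREE_PRIME
from dualaav.molecules import (
    HEAD_TO_HEAD,
    HEAD_TO_TAIL,
    TAIL_TO_TAIL,
    MoleculeSpecies,
    PopulationError,
    SamplePopulation,
    read_species_tsv,
    write_species_tsv,
)

from conftest import make_pop, random_sim_params


class TestSpeciesModel:
    def test_hr_junction_requires_plus_five_to_plus_three(self):
        with pytest.raises(PopulationError):
            MoleculeSpecies(((THREE_PRIME, 1), (FIVE_PRIME, 1)), ("HR",))
        with pytest.raises(PopulationError):
            MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, -1)), ("HR",))

    def test_itr_junction_type_must_match_orientations(self):
        # same orientation is head-to-tail; a flip with an exposed head is
        # head-to-head, with an exposed tail tail-to-tail
        with pytest.raises(PopulationError):
            MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)), (HEAD_TO_HEAD,))
        with pytest.raises(PopulationError):
            MoleculeSpecies(((FIVE_PRIME, -1), (THREE_PRIME, 1)), (HEAD_TO_HEAD,))
        MoleculeSpecies(((FIVE_PRIME, -1), (THREE_PRIME, 1)), (TAIL_TO_TAIL,))

    def test_junction_count_matches_topology(self):
        with pytest.raises(PopulationError):
            MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)), ())
        MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)),
                        (HEAD_TO_TAIL, HEAD_TO_TAIL), topology="circular")

    def test_structure_string_roundtrip(self, ht_dimer):
        for sp in (
            ht_dimer,
            MoleculeSpecies.hr_product(),
            MoleculeSpecies.monomer(FIVE_PRIME, -1),
            MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)),
                            (HEAD_TO_TAIL, HEAD_TO_TAIL), topology="circular"),
        ):
            assert MoleculeSpecies.from_structure(sp.structure) == sp


class TestSimulateSample:
    def test_no_hr_no_concat_gives_pure_monomers(self):
        pop, gt = da.simulate_sample(
            da.SimParams(hr_fraction=0.0, concat_fraction=0.0, host_genomes=50, seed=3)
        )
        assert all(sp.n_units == 1 for sp in pop.species)
        assert gt.true_hr == 0.0 and gt.true_concat == 0.0

    def test_full_hr_with_balanced_vectors(self):
        pop, gt = da.simulate_sample(
            da.SimParams(u5=6, u3=6, hr_fraction=1.0, concat_fraction=0.0,
                         host_genomes=100, seed=4)
        )
        assert gt.true_hr == 1.0
        assert gt.R == min(gt.T5, gt.T3)

    def test_seeded_determinism(self):
        p = da.SimParams(host_genomes=100, seed=11)
        pop1, _ = da.simulate_sample(p)
        pop2, _ = da.simulate_sample(p)
        assert pop1.species == pop2.species

    def test_ground_truth_audit_matches_emitted(self):
        for seed in range(5):
            p = da.SimParams(host_genomes=300, concat_fraction=0.2, seed=seed)
            pop, gt = da.simulate_sample(p)
            audit = da.ground_truth_metrics(pop)
            assert (audit.T5, audit.T3, audit.R) == (gt.T5, gt.T3, gt.R)
            assert audit.junction_census == gt.junction_census
            assert audit.junction_detail == gt.junction_detail

    def test_unit_conservation_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = random_sim_params(rng)
            pop, gt = da.simulate_sample(p)
            # independent recount: monomers + concatemer members + HR partners
            n5 = n3 = 0
            for sp, count in pop.species.items():
                for ident, _ in sp.units:
                    if ident == FIVE_PRIME:
                        n5 += count
                    else:
                        n3 += count
            assert n5 == gt.T5 and n3 == gt.T3

    def test_true_hr_recovers_theta_across_seeds(self):
        # binomial SE of R/min(T5,T3) from an independent re-count
        theta, vals = 0.5, []
        for seed in range(50):
            p = da.SimParams(u5=8, u3=12, hr_fraction=theta, concat_fraction=0.08,
                             host_genomes=10_000, seed=seed)
            pop, _ = da.simulate_sample(p)
            audit = da.ground_truth_metrics(pop)
            vals.append(audit.true_hr)
        m = min(8, 12) * 10_000
        se = np.sqrt(theta * (1 - theta) / m) / np.sqrt(50)
        assert abs(np.mean(vals) - theta) < 3 * se + 1 / m  # + rounding slack

    def test_conditional_junction_type_frequencies_match_weights(self):
        # linear chains force flip junctions to alternate head-to-head /
        # tail-to-tail, so the testable form of the orientation_weights
        # contract is conditional: among junctions formed from an exposed
        # head, head-to-tail vs head-to-head splits as w_ht : w_hh.
        w = (0.5, 0.3, 0.2)
        p = da.SimParams(u5=10, u3=10, hr_fraction=0.0, concat_fraction=1.0,
                         chain_length_p=0.2, orientation_weights=w,
                         host_genomes=3000, seed=9)
        pop, _ = da.simulate_sample(p)
        from_head = {"ht": 0, "hh": 0}
        from_tail = {"ht": 0, "tt": 0}
        for sp, count in pop.species.items():
            for i, j in enumerate(sp.junctions):
                if sp.topology == "circular" and i == len(sp.junctions) - 1:
                    continue  # closing junction type is forced, not sampled
                prev_orient = sp.units[i][1]
                if prev_orient == +1:
                    from_head["hh" if j == HEAD_TO_HEAD else "ht"] += count
                else:
                    from_tail["tt" if j == TAIL_TO_TAIL else "ht"] += count
        n_head = sum(from_head.values())
        n_tail = sum(from_tail.values())
        assert n_head > 2000 and n_tail > 2000
        p_head = w[0] / (w[0] + w[1])
        p_tail = w[0] / (w[0] + w[2])
        for obs, n, prob in ((from_head["ht"], n_head, p_head),
                             (from_tail["ht"], n_tail, p_tail)):
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(obs / n - prob) < 3 * se

    def test_circular_dimer_accounting(self):
        sp = MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)),
                             (HEAD_TO_TAIL, HEAD_TO_TAIL), topology="circular")
        gt = da.ground_truth_metrics(make_pop({sp: 1}))
        assert gt.R == 0
        assert gt.total_itr_junctions == 2

    def test_pure_hr_population_accounting(self):
        gt = da.ground_truth_metrics(make_pop({MoleculeSpecies.hr_product(): 10}))
        assert (gt.T5, gt.T3, gt.R) == (10, 10, 10)
        assert gt.total_itr_junctions == 0


class TestTranscripts:
    def test_zero_leak_rate_gives_zero_leak(self):
        pop, _ = da.simulate_sample(da.SimParams(host_genomes=100, seed=1))
        tp = da.simulate_transcripts(pop, leak_rate=0.0, expr_rate=2.0, seed=0)
        assert tp.five_leak == 0

    def test_no_hr_gives_zero_recombined(self):
        pop, _ = da.simulate_sample(
            da.SimParams(hr_fraction=0.0, host_genomes=100, seed=1)
        )
        tp = da.simulate_transcripts(pop, leak_rate=0.1, expr_rate=2.0, seed=0)
        assert tp.recombined == 0

    def test_three_prime_never_expresses(self):
        pop, _ = da.simulate_sample(da.SimParams(host_genomes=100, seed=1))
        tp = da.simulate_transcripts(pop, leak_rate=0.1, expr_rate=2.0, seed=0)
        assert tp.three_aberrant == 0

    def test_recombined_mean_matches_poisson_rate(self):
        pop = make_pop({MoleculeSpecies.hr_product(): 1000})
        vals = [
            da.simulate_transcripts(pop, 0.0, 2.0, seed=s).recombined
            for s in range(100)
        ]
        se = np.sqrt(2000 / 100)  # Poisson mean=var
        assert abs(np.mean(vals) - 2000) < 3 * se


class TestConcatCalibration:
    def test_phi_for_4pct_junction_fraction(self):
        p = da.SimParams()
        phi = da.concat_fraction_for_target(0.04, p)
        truths = []
        for seed in range(30):
            _, gt = da.simulate_sample(
                da.SimParams(concat_fraction=phi, seed=seed)
            )
            truths.append(gt.true_concat)
        assert abs(np.mean(truths) - 0.04) < 0.004

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            da.concat_fraction_for_target(0.5, da.SimParams())


class TestSpeciesIO:
    def test_tsv_roundtrip(self, tmp_path):
        pop, _ = da.simulate_sample(
            da.SimParams(host_genomes=50, concat_fraction=0.3, seed=5)
        )
        path = tmp_path / "species.tsv"
        write_species_tsv(pop, path)
        back = read_species_tsv(path)
        assert back.species == pop.species
        assert back.host_genomes == pop.host_genomes
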