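"""Droplet partitioning, detection, amplitude gating and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dualaav as da
from dualaav.constructs import FIVE_PRIME, THREE_PRIME
from dualaav.digest import ALEI, SMAI, digest
from dualaav.droplets import (
    DdpcrRunConfig,
    EmptyRunError,
    GatingError,
    Occupancy,
    SaturationError,
    _convergent_pairs,
    amplifiable,
    default_thresholds,
    detect,
    gate,
    partition,
    read_droplets_csv,
    template_classes,
    write_droplets_csv,
)
from dualaav.molecules import TAIL_TO_TAIL, MoleculeSpecies

from conftest import make_pop

VCN = ("FIVE", "THREE", "REC", "TTN")


def one_fragment(pop_species, enzyme, constructs, panel, predicate):
    fp = digest(make_pop(pop_species), enzyme, *constructs, panel)
    frs = [fr for fr in fp.fragments if predicate(fr)]
    assert frs, "no fragment matched the predicate"
    return frs


class TestAmplifiable:
    def test_intact_hr_fragment_amplifies_rec(self, constructs, panel, hr_species):
        rec = panel.assay("REC")
        frs = one_fragment({hr_species: 1}, SMAI, constructs, panel,
                           lambda fr: any(s.name == "REC_F" for s in fr.sites))
        assert any(amplifiable(fr, rec) for fr in frs)

    def test_smai_cut_head_to_tail_fragment_does_not(self, constructs, panel, ht_dimer):
        rec = panel.assay("REC")
        fp = digest(make_pop({ht_dimer: 1}), SMAI, *constructs, panel)
        assert not any(amplifiable(fr, rec) for fr in fp.fragments)

    def test_undigested_head_to_tail_mimics_hr(self, constructs, panel, ht_dimer):
        # the bias SmaI pre-digestion exists to remove
        rec = panel.assay("REC")
        fp = digest(make_pop({ht_dimer: 1}), None, *constructs, panel)
        assert any(amplifiable(fr, rec) for fr in fp.fragments)

    def test_tail_to_tail_junction_via_primer_b_self_pair(self, constructs, panel):
        sp = MoleculeSpecies(((THREE_PRIME, -1), (THREE_PRIME, 1)), (TAIL_TO_TAIL,))
        fp = digest(make_pop({sp: 1}), ALEI, *constructs, panel)
        junc_b = panel.assay("JUNC_B")
        carriers = [fr for fr in fp.fragments if amplifiable(fr, junc_b)]
        assert len(carriers) == 1
        (f, r, _), = _convergent_pairs(carriers[0], set(junc_b.panel_primers),
                                       junc_b.max_amplicon)
        assert f.name == r.name == "B"

    def test_rt_assays_never_fire_on_dna(self, constructs, panel, hr_species):
        fp = digest(make_pop({hr_species: 1}), None, *constructs, panel)
        rt = panel.assay("REC_RT")
        assert not any(amplifiable(fr, rt) for fr in fp.fragments)

    def test_amplicon_size_limit_enforced(self, constructs, panel, hr_species):
        from dataclasses import replace

        small = replace(panel.assay("REC"), max_amplicon=500)
        fp = digest(make_pop({hr_species: 1}), SMAI, *constructs, panel)
        assert not any(amplifiable(fr, small) for fr in fp.fragments)


class TestPartition:
    def test_empty_population_all_droplets_empty(self):
        occ = partition({}, DdpcrRunConfig(n_droplets=1000, seed=0))
        assert occ.counts.shape == (1000, 0)

    def test_positive_fraction_matches_poisson(self):
        cfg = DdpcrRunConfig(n_droplets=20000, seed=1)
        # count/N = 0.693 -> expected positive fraction 1 - e^-0.693 = 0.5
        occ = partition({frozenset(["X"]): 13863}, cfg)
        frac = (occ.counts > 0).mean()
        p = 1 - np.exp(-13863 / 20000)
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(frac - p) < 3 * se

    def test_independent_classes_double_occupancy(self):
        cfg = DdpcrRunConfig(n_droplets=100_000, seed=2)
        n = int(0.1 * cfg.n_droplets)
        occ = partition({frozenset(["X"]): n, frozenset(["Y"]): n}, cfg)
        both = ((occ.counts > 0).all(axis=1)).mean()
        p = (1 - np.exp(-0.1)) ** 2
        se = np.sqrt(p * (1 - p) / cfg.n_droplets)
        assert abs(both - p) < 3 * se

    def test_saturated_class_rejected(self):
        cfg = DdpcrRunConfig(n_droplets=1000, seed=0)
        with pytest.raises(SaturationError):
            partition({frozenset(["X"]): 20000}, cfg)

    def test_zero_droplets_rejected(self):
        with pytest.raises(EmptyRunError):
            partition({frozenset(["X"]): 10}, DdpcrRunConfig(n_droplets=0))


def _manual_occupancy(panel, rows, cfg=None):
    """Occupancy with hand-set per-droplet template counts."""
    sigs = tuple(sorted({sig for row in rows for sig in row},
                        key=lambda s: sorted(s)))
    counts = np.array(
        [[row.get(sig, 0) for sig in sigs] for row in rows], dtype=int
    )
    cfg = cfg or DdpcrRunConfig(n_droplets=len(rows), noise_sd=0.0)
    return Occupancy(sigs, counts, np.zeros(len(sigs)), cfg)


class TestDetectAndGate:
    def test_amplitude_additivity_fam_levels(self, panel):
        sub = panel.subset(VCN)
        occ = _manual_occupancy(
            sub,
            [
                {frozenset(["FIVE"]): 1, frozenset(["THREE"]): 1},  # FAM 1+2
                {frozenset(["FIVE"]): 1},
                {frozenset(["THREE"]): 1},
                {},
            ],
        )
        ds = detect(occ, sub, mode="amplitude")
        fam = ds.df["Ch1 Amplitude"].to_numpy()
        base, unit = ds.baseline, ds.level_unit
        assert fam[0] == base + 3 * unit
        assert fam[1] == base + 1 * unit
        assert fam[2] == base + 2 * unit
        assert fam[3] == base  # empty droplet: baseline only

    def test_calls_mode_exact_against_occupancy(self, constructs, panel, hr_species):
        sub = panel.subset(VCN)
        fp = digest(make_pop({hr_species: 4000}, host_genomes=1000), SMAI,
                    *constructs, sub)
        templates = template_classes(fp, sub.assays)
        cfg = DdpcrRunConfig(n_droplets=20000, seed=5)
        occ = partition(templates, cfg)
        ds = detect(occ, sub, mode="calls")
        hr_col = occ.signatures.index(frozenset(["FIVE", "THREE", "REC"]))
        expected = (occ.counts[:, hr_col] > 0).astype(int)
        assert (ds.df["REC"].to_numpy() == expected).all()

    def test_noiseless_amplitude_gating_equals_calls(self, constructs, panel):
        sub = panel.subset(VCN)
        pop, _ = da.simulate_sample(da.SimParams(host_genomes=800, seed=6))
        fp = digest(pop, SMAI, *constructs, sub)
        templates = template_classes(fp, sub.assays)
        cfg = DdpcrRunConfig(n_droplets=8000, noise_sd=0.0, seed=7)
        occ = partition(templates, cfg)
        k_calls = gate(detect(occ, sub, mode="calls"))
        k_amp = gate(detect(occ, sub, mode="amplitude"))
        assert k_calls == k_amp

    def test_gate_raising_top_threshold_drops_top_cloud(self, panel):
        sub = panel.subset(VCN)
        occ = _manual_occupancy(
            sub, [{frozenset(["FIVE"]): 1, frozenset(["THREE"]): 1}] * 4
                 + [{frozenset(["FIVE"]): 1}] * 3,
        )
        ds = detect(occ, sub, mode="amplitude")
        th = default_thresholds(ds)
        k0 = gate(ds, th)
        # push the top FAM threshold above the level-3 cloud: those droplets
        # decode one level lower, so FIVE (level 1) loses them
        th_hi = {**th, "Ch1": [th["Ch1"][0], th["Ch1"][1], ds.baseline + 3.5 * ds.level_unit]}
        k1 = gate(ds, th_hi)
        assert k1["FIVE"][0] <= k0["FIVE"][0]
        assert k0["FIVE"][0] == 7 and k1["FIVE"][0] == 3

    def test_non_increasing_thresholds_rejected(self, panel):
        sub = panel.subset(VCN)
        occ = _manual_occupancy(sub, [{frozenset(["FIVE"]): 1}])
        ds = detect(occ, sub, mode="amplitude")
        with pytest.raises(GatingError):
            gate(ds, {"Ch1": [5000.0, 3000.0, 1000.0], "Ch2": [2000.0]})

    def test_undecodable_levels_rejected(self, panel):
        # four single-channel junction assays at the same level cannot be
        # amplitude-multiplexed
        sub = panel.subset(("JUNC_A", "JUNC_B", "JUNC_C", "JUNC_D"))
        occ = _manual_occupancy(sub, [{}])
        with pytest.raises(GatingError):
            detect(occ, sub, mode="amplitude")

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=60))
    def test_calls_gate_is_column_sum(self, panel, n_pos):
        sub = panel.subset(("FIVE",))
        rows = [{frozenset(["FIVE"]): 1}] * n_pos + [{}] * (60 - n_pos)
        ds = detect(_manual_occupancy(sub, rows), sub, mode="calls")
        assert gate(ds)["FIVE"] == (n_pos, 60)


class TestCsvRoundTrip:
    @pytest.mark.parametrize("mode", ["calls", "amplitude"])
    def test_roundtrip_preserves_gate_counts(self, constructs, panel, tmp_path, mode):
        sub = panel.subset(VCN)
        pop, _ = da.simulate_sample(da.SimParams(host_genomes=300, seed=8))
        fp = digest(pop, SMAI, *constructs, sub)
        occ = partition(template_classes(fp, sub.assays),
                        DdpcrRunConfig(n_droplets=4000, seed=9))
        ds = detect(occ, sub, mode=mode,
                    rng=np.random.default_rng(10))
        path = tmp_path / "droplets.csv"
        write_droplets_csv(ds, path)
        back = read_droplets_csv(path)
        assert gate(back) == gate(ds)
        assert back.mode == mode and back.n_droplets == ds.n_droplets

    def test_malformed_calls_csv_reports_row(self, panel, tmp_path):
        sub = panel.subset(("FIVE",))
        ds = detect(_manual_occupancy(sub, [{}, {frozenset(["FIVE"]): 1}]),
                    sub, mode="calls")
        path = tmp_path / "droplets.csv"
        write_droplets_csv(ds, path)
        text = path.read_text().splitlines()
        text[1] = "7"
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(GatingError, match="row 2"):
            read_droplets_csv(path)
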