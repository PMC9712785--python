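import json

import numpy as np
import pytest

from spongenet.records import Direction, RnaClass, ValidationError
from spongenet.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_all,
    simulate_counts,
    simulate_sequences,
    write_simulation,
)
from spongenet.targets import find_seed_sites


class TestConfigValidation:
    def test_triads_bounded_by_de_counts(self):
        with pytest.raises(ValidationError, match="n_triads"):
            SimulationConfig(n_de_circ=2, n_de_mirna=5, n_de_mrna=5, n_triads=3)

    def test_target_shorter_than_site_rejected(self):
        with pytest.raises(ValidationError, match="seed site"):
            SimulationConfig(circ_len=5)

    def test_de_bounded_by_feature_count(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_circ=5, n_de_circ=10, n_triads=0)


class TestSimulateCounts:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=1, n_mrna=200, dispersion=0.1,
                               baseline_mean=500, effect_log2fc=2)
        a, _ = simulate_counts(cfg)
        b, _ = simulate_counts(cfg)
        for rna_class in a:
            assert a[rna_class].to_csv() == b[rna_class].to_csv()

    def test_null_effect_centers_fold_changes_at_zero(self):
        cfg = SimulationConfig(seed=2, effect_log2fc=0.0, n_triads=0,
                               n_de_circ=0, n_de_mirna=0, n_de_mrna=0)
        mats, truth = simulate_counts(cfg)
        counts = mats[RnaClass.MRNA].to_numpy(dtype=float)
        lfc = np.log2((counts[:, :3].mean(axis=1) + 0.5) /
                      (counts[:, 3:].mean(axis=1) + 0.5))
        assert abs(lfc.mean()) < 0.05
        assert truth.de["mRNA"] == {}

    def test_zero_dispersion_is_poisson_limit(self):
        cfg = SimulationConfig(seed=3, dispersion=0.0, baseline_log2_sd=0.0,
                               n_mrna=4000, n_de_mrna=0, n_triads=0,
                               n_de_circ=0, n_de_mirna=0)
        mats, _ = simulate_counts(cfg)
        control = mats[RnaClass.MRNA].to_numpy(dtype=float)[:, 3:]
        # all features share mean 500; pooled variance must be ~ the mean
        ratio = control.var() / control.mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_planted_triads_are_direction_consistent(self):
        cfg = SimulationConfig(seed=4)
        _, truth = simulate_counts(cfg)
        assert len(truth.triads) == cfg.n_triads
        for circ, mirna, mrna in truth.triads:
            c = truth.direction(RnaClass.CIRC, circ)
            m = truth.direction(RnaClass.MIRNA, mirna)
            g = truth.direction(RnaClass.MRNA, mrna)
            assert c is g and m is c.opposite

    def test_case_group_mean_scaled_by_effect(self):
        cfg = SimulationConfig(seed=6, dispersion=0.01, n_per_group=50,
                               baseline_log2_sd=0.0, effect_log2fc=2.0)
        mats, truth = simulate_counts(cfg)
        counts = mats[RnaClass.CIRC]
        for feature, lfc in truth.de["circRNA"].items():
            case = counts.loc[feature][: cfg.n_per_group].mean()
            control = counts.loc[feature][cfg.n_per_group :].mean()
            assert np.log2(case / control) == pytest.approx(lfc, abs=0.2)


class TestSimulateSequences:
    def test_planted_sites_found_at_recorded_coordinates(self):
        cfg = SimulationConfig(seed=7, n_circ=10, n_mirna=10, n_mrna=10,
                               n_de_circ=4, n_de_mirna=4, n_de_mrna=4, n_triads=4)
        _, truth = simulate_counts(cfg)
        mirnas, targets = simulate_sequences(cfg, truth)
        assert len(truth.planted_sites) == 2 * cfg.n_triads
        for site in truth.planted_sites:
            found = find_seed_sites(
                mirnas[site["mirna_id"]], targets[site["target_id"]],
                circular=site["target_id"].startswith("circ"),
            )
            assert any(
                s.start == site["start"] and s.end == site["end"]
                and s.site_type.value == "8mer"
                for s in found
            )

    def test_zero_triads_plant_nothing(self):
        cfg = SimulationConfig(seed=8, n_triads=0, n_de_circ=2, n_de_mirna=2,
                               n_de_mrna=2, n_circ=10, n_mirna=10, n_mrna=10)
        _, truth = simulate_counts(cfg)
        simulate_sequences(cfg, truth)
        assert truth.planted_sites == []

    def test_background_7mer_rate_matches_closed_form(self):
        """Over 1000 random pairs, the count of exact 7mer (m8-extended)
        matches on length-L backgrounds is (L-6) * 4^-7 per pair within 3 SD."""
        rng = np.random.default_rng(123)
        alphabet = np.array(list("ACGT"))
        L, n_pairs = 500, 1000
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        total = 0
        for _ in range(n_pairs):
            mir = "".join(rng.choice(alphabet, size=22))
            target = "".join(rng.choice(alphabet, size=L))
            seven = "".join(comp[b] for b in reversed(mir[1:8]))
            sites = find_seed_sites(mir, target)
            total += sum(
                1 for s in sites if s.site_type.value in ("7mer_m8", "8mer")
            )
            # cross-check against plain substring counting
            assert sum(
                1 for i in range(L - 6) if target[i : i + 7] == seven
            ) == sum(1 for s in sites if s.site_type.value in ("7mer_m8", "8mer"))
        expected = n_pairs * (L - 6) * 4.0 ** -7
        sd = np.sqrt(expected)  # Poisson-scale fluctuation
        assert abs(total - expected) <= 3 * sd

    def test_scrubbed_background_has_recorded_collisions_only(self):
        cfg = SimulationConfig(seed=9, n_circ=30, n_mirna=20, n_mrna=60,
                               n_de_circ=5, n_de_mirna=5, n_de_mrna=5, n_triads=5)
        _, truth = simulate_counts(cfg)
        mirnas, targets = simulate_sequences(cfg, truth)
        planted = {
            (s["mirna_id"], s["target_id"], s["start"], s["end"])
            for s in truth.planted_sites
        }
        recorded = {
            (s["mirna_id"], s["target_id"], s["start"], s["end"])
            for s in truth.chance_sites
        }
        planted_pairs = {(m, t) for m, t, _, _ in planted}
        regions = {}
        for _, t, lo, hi in planted:
            regions.setdefault(t, []).append((lo, hi))
        for mid, mseq in mirnas.items():
            for tid, tseq in targets.items():
                for s in find_seed_sites(mseq, tseq, circular=tid.startswith("circ")):
                    key = (mid, tid, s.start, s.end)
                    nested = (mid, tid) in planted_pairs and any(
                        lo <= s.start and s.end <= hi for lo, hi in regions.get(tid, ())
                    )
                    assert key in planted or key in recorded or nested


class TestStreamsAndOutputs:
    def test_simulate_all_is_deterministic(self):
        cfg = SimulationConfig(seed=10, n_circ=20, n_mirna=15, n_mrna=30,
                               n_de_circ=4, n_de_mirna=4, n_de_mrna=4, n_triads=3)
        first = simulate_all(cfg)
        second = simulate_all(cfg)
        assert all(first[0][k].equals(second[0][k]) for k in first[0])
        assert first[1] == second[1] and first[2] == second[2]
        assert first[3] == second[3]

    def test_ground_truth_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_circ=10, n_mirna=10, n_mrna=10,
                               n_de_circ=3, n_de_mirna=3, n_de_mrna=3, n_triads=2)
        _, _, _, _, truth = simulate_all(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.de == truth.de
        assert back.triads == truth.triads
        assert back.planted_sites == truth.planted_sites

    def test_write_simulation_outputs_all_artifacts(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_circ=8, n_mirna=8, n_mrna=8,
                               n_de_circ=2, n_de_mirna=2, n_de_mrna=2, n_triads=2)
        out = write_simulation(cfg, tmp_path / "sim")
        names = {p.name for p in out.iterdir()}
        assert {
            "counts_circRNA.tsv", "counts_miRNA.tsv", "counts_mRNA.tsv",
            "mirna.fa", "targets.fa", "ct_table.tsv", "ground_truth.json",
            "config.json",
        } <= names
        config = json.loads((out / "config.json").read_text())
        assert config["seed"] == 13
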