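import numpy as np
import pytest

from spongenet.records import RnaClass, SiteType, ValidationError
from spongenet.targets import SITE_WEIGHTS, find_seed_sites, predict_interactions, score_duplex

from oracles import brute_seed_sites

ALPHABET = list("ACGT")


def random_seq(rng, n):
    return "".join(rng.choice(ALPHABET, size=n))


class TestFindSeedSites:
    def test_constructed_8mer_site(self):
        mirna = "UCGAAUGCAAAA"
        target = "GGG" + "GCATTCGA" + "GGG"  # rev-comp of positions 2-8 plus A1
        (site,) = find_seed_sites(mirna, target)
        assert site.site_type is SiteType.EIGHTMER
        assert (site.start, site.end) == (3, 11)

    def test_no_complementary_core_gives_empty(self):
        assert find_seed_sites("UCGAAUGCAAAA", "G" * 40) == []

    def test_t_u_equivalence(self):
        mirna = "UCGAAUGCAAAA"
        target = "GGGGCATTCGAGGG"
        as_rna = [ (s.start, s.end, s.site_type) for s in
                   find_seed_sites(mirna, target.replace("T", "U")) ]
        as_dna = [ (s.start, s.end, s.site_type) for s in
                   find_seed_sites(mirna.replace("U", "T"), target) ]
        assert as_rna == as_dna

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValidationError, match="ambiguity"):
            find_seed_sites("UCGAAUGCAAAN", "ACGT" * 10)

    def test_matches_brute_force_scan_on_random_pairs(self, rng):
        for _ in range(500):
            mirna = random_seq(rng, 22)
            target = random_seq(rng, int(rng.integers(30, 120)))
            got = [(s.start, s.end, s.site_type.value) for s in find_seed_sites(mirna, target)]
            assert got == brute_seed_sites(mirna, target)

    def test_circular_scan_finds_junction_spanning_site(self):
        mirna = "UCGAAUGCAAAA"
        site_seq = "GCATTCGA"
        tail, head = site_seq[:5], site_seq[5:]
        target = head + "G" * 30 + tail  # site crosses the back-splice junction
        assert find_seed_sites(mirna, target) == []
        (site,) = find_seed_sites(mirna, target, circular=True)
        assert site.site_type is SiteType.EIGHTMER
        assert site.end > len(target)  # wraps past the junction


class TestScoreDuplex:
    def test_6mer_without_3prime_pairing_is_minimum_weight(self):
        mirna = "ACGAAUGCAAAAGGGG"  # position 1 = A (no m8 partner match in target)
        target = "TTT" + "GCATTCG"[1:] + "TTT"  # core only
        (site,) = find_seed_sites(mirna, target)
        assert site.site_type is SiteType.SIXMER
        assert score_duplex(site, mirna, target) == SITE_WEIGHTS[SiteType.SIXMER]

    def test_deterministic(self):
        mirna = "UCGAAUGCAAAAUGCA"
        target = "AGGGCATTCGAGG"
        (site,) = find_seed_sites(mirna, target)
        assert score_duplex(site, mirna, target) == score_duplex(site, mirna, target)

    def test_bonus_equals_hand_count_over_all_flanks(self):
        """Enumerate all 4-nt target flanks opposite miRNA positions 13-16."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirna = "TCGAATGCAAAATGCACTGTT"  # positions 13-16 = GCAC
        site_seq = "GCATTCGA"
        from itertools import product

        for flank in product("ACGT", repeat=4):
            # miRNA position i pairs target coordinate core_start + 7 - i;
            # positions 13..16 therefore face the 4 nt just upstream, reversed
            target = "TT" + "".join(flank) + "TTT" + site_seq + "TT"
            (site,) = [s for s in find_seed_sites(mirna, target)
                       if s.site_type is SiteType.EIGHTMER]
            core_start = site.start + 1
            expected = sum(
                target[core_start + 7 - pos] == comp[mirna[pos - 1]]
                for pos in range(13, 17)
            )
            assert score_duplex(site, mirna, target) == SITE_WEIGHTS[SiteType.EIGHTMER] + expected


class TestPredictInteractions:
    @pytest.fixture()
    def planted(self):
        mirna = "TCGAATGCAAAATGCACTGTT"
        site = "GCATTCGA"
        mirnas = {"miR-x": mirna}
        targets = {"gene-hit": "TTTT" + site + "TTTT", "gene-miss": "T" * 20}
        return mirnas, targets

    def test_both_sources_agree_under_intersection(self, planted):
        mirnas, targets = planted
        (edge,) = predict_interactions(mirnas, targets, RnaClass.MRNA, policy="intersection")
        assert edge.pair == ("miR-x", "gene-hit")
        assert edge.sources == frozenset({"seed_count", "duplex_score"})

    def test_policy_contract_for_single_source_call(self, planted):
        mirnas, targets = planted
        # a score threshold above any possible score silences the score source
        assert predict_interactions(mirnas, targets, RnaClass.MRNA,
                                    policy="intersection", min_score=100.0) == []
        (edge,) = predict_interactions(mirnas, targets, RnaClass.MRNA,
                                       policy="union", min_score=100.0)
        assert edge.sources == frozenset({"seed_count"})

    def test_intersection_subset_of_union(self, rng):
        mirnas = {f"m{i}": random_seq(rng, 22) for i in range(8)}
        targets = {f"g{i}": random_seq(rng, 300) for i in range(20)}
        union = {e.pair for e in predict_interactions(mirnas, targets, RnaClass.MRNA, "union")}
        inter = {e.pair for e in
                 predict_interactions(mirnas, targets, RnaClass.MRNA, "intersection")}
        assert inter <= union

    def test_sponge_edges_are_circ_oriented(self, planted):
        mirnas, targets = planted
        (edge,) = predict_interactions(mirnas, targets, RnaClass.CIRC, policy="union")
        assert edge.source_class is RnaClass.CIRC and edge.target_id == "miR-x"

    def test_site_count_invariant_to_appended_tail(self, planted):
        mirnas, targets = planted
        base = find_seed_sites(mirnas["miR-x"], targets["gene-hit"])
        extended = find_seed_sites(mirnas["miR-x"], targets["gene-hit"] + "G" * 50)
        assert [(s.start, s.site_type) for s in base] == [
            (s.start, s.site_type) for s in extended
        ]

    def test_empty_fasta_warns(self):
        with pytest.warns(UserWarning, match="empty FASTA"):
            assert predict_interactions({}, {"g": "ACGT" * 10}, RnaClass.MRNA) == []

    def test_planted_pairs_recovered_exactly(self):
        from spongenet.simulate import SimulationConfig, simulate_all

        # the property holds for collision-free instances: take the first
        # seed whose scrubbed background has no recorded chance site
        for seed in range(11, 31):
            cfg = SimulationConfig(seed=seed, n_circ=20, n_mirna=15, n_mrna=40,
                                   n_de_circ=6, n_de_mirna=6, n_de_mrna=6, n_triads=6)
            _, mirnas, targets, _, truth = simulate_all(cfg)
            if not truth.chance_sites:
                break
        else:
            pytest.fail("no collision-free simulation among 20 seeds")
        circ = {t: s for t, s in targets.items() if t.startswith("circ")}
        mrna = {t: s for t, s in targets.items() if not t.startswith("circ")}
        for policy in ("union", "intersection"):
            sponge = {e.pair for e in predict_interactions(mirnas, circ, RnaClass.CIRC, policy)}
            targ = {e.pair for e in predict_interactions(mirnas, mrna, RnaClass.MRNA, policy)}
            assert sponge == {(c, m) for c, m, _ in truth.triads}
            assert targ == {(m, g) for _, m, g in truth.triads}
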