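"""NG86 Ka/Ks, duplication detection/classification, dating and summaries."""

import itertools
import math
import random
from fractions import Fraction

import pytest
from Bio.Seq import Seq

from ankfam.evolution import (SENSE_CODONS, STOP_CODONS, KaKsResult,
                              align_pair_stats, classify_duplication,
                              classify_selection, codon_differences,
                              codon_sites, count_sites_ng86, detect_paralogs,
                              estimate_divergence_time, jukes_cantor,
                              kaks_ng86, load_printed_pairs,
                              omega_consistent_with_rounding,
                              pair_table_summary)
from ankfam.genome_structure import GeneModel
from ankfam.simulate import CodonSimSpec, simulate_paralog_pair

# ---------------------------------------------------------------------------
# independent oracle helpers (Biopython translation, direct enumeration)
# ---------------------------------------------------------------------------

BASES = "ACGT"


def oracle_translate(codon):
    aa = str(Seq(codon).translate())
    return None if aa == "*" else aa


def oracle_sites(codon):
    syn = Fraction(0)
    aa = oracle_translate(codon)
    for pos, b in itertools.product(range(3), BASES):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if oracle_translate(alt) == aa and oracle_translate(alt) is not None:
            syn += Fraction(1, 3)
    return syn, 3 - syn


def oracle_differences(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return Fraction(0), Fraction(0)
    walks = []
    for order in itertools.permutations(positions):
        cur, syn, non, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if oracle_translate(nxt) is None or oracle_translate(cur) is None:
                blocked, non = True, non + 1
            elif oracle_translate(cur) == oracle_translate(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        walks.append((syn, non, blocked))
    usable = [w for w in walks if not w[2]] or walks
    return (Fraction(sum(w[0] for w in usable), len(usable)),
            Fraction(sum(w[1] for w in usable), len(usable)))


# ---------------------------------------------------------------------------


class TestSiteCounting:
    def test_tryptophan_has_no_synonymous_neighbour(self):
        assert codon_sites("TGG") == (Fraction(0), Fraction(3))

    def test_phenylalanine_partition(self):
        assert codon_sites("TTT") == (Fraction(1, 3), Fraction(8, 3))

    def test_every_sense_codon_partitions_three_sites(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == 3
            assert (s, n) == oracle_sites(codon)

    def test_sequence_counts_are_exact_sums(self):
        s, n = count_sites_ng86("TTTTGG")
        assert (s, n) == (Fraction(1, 3), Fraction(17, 3))

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            count_sites_ng86("TAATTT")

    def test_terminal_stop_tolerated_but_not_counted(self):
        assert count_sites_ng86("TTTTAA") == codon_sites("TTT")

    def test_ambiguous_codon_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            s, n = count_sites_ng86("TTTNNN")
        assert s + n == 3

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            count_sites_ng86("TTTT")


class TestPathwayAveraging:
    def test_all_codon_pairs_match_enumeration_oracle(self):
        for ca, cb in itertools.product(SENSE_CODONS[::3], SENSE_CODONS[::3]):
            assert codon_differences(ca, cb) == oracle_differences(ca, cb)

    def test_two_difference_codon_averages_both_pathways(self):
        # TTT (Phe) -> GTA: via GTT (Val, non+syn) or TTA (Leu, non+non)
        sd, nd = codon_differences("TTT", "GTA")
        assert sd + nd == 2
        assert (sd, nd) == oracle_differences("TTT", "GTA")


class TestKaKs:
    def test_identical_sequences(self):
        r = kaks_ng86("TTTGGG", "TTTGGG")
        assert r.ka == 0.0 and r.ks == 0.0 and r.omega is None

    def test_single_synonymous_change(self):
        r = kaks_ng86("TTAGGAGGA", "TTGGGAGGA")  # TTA->TTG: both leucine
        assert r.nd == 0 and r.sd == 1
        assert r.ka == 0.0 and r.ks > 0

    def test_gap_codons_dropped_pairwise(self):
        r = kaks_ng86("TTA---GGA", "TTGAAAGGA")
        assert r.n_codons == 2

    def test_matches_exhaustive_oracle_on_small_alignments(self):
        rng = random.Random(29)
        for _ in range(200):
            n = rng.randint(1, 3)
            codons_a = [rng.choice(SENSE_CODONS) for _ in range(n)]
            codons_b = []
            for ca in codons_a:
                cb = ca
                for pos in range(3):
                    if rng.random() < 0.25:
                        cand = cb[:pos] + rng.choice(BASES) + cb[pos + 1:]
                        if cand not in STOP_CODONS:
                            cb = cand
                codons_b.append(cb)
            a, b = "".join(codons_a), "".join(codons_b)

            s = n_sites = sd = nd = Fraction(0)
            for ca, cb in zip(codons_a, codons_b):
                sa, na = oracle_sites(ca)
                sb, nb = oracle_sites(cb)
                s += Fraction(sa + sb, 2)
                n_sites += Fraction(na + nb, 2)
                dsd, dnd = oracle_differences(ca, cb)
                sd += dsd
                nd += dnd
            ps, pn = float(sd / s) if s else 0.0, float(nd / n_sites)
            if ps >= 0.75 or pn >= 0.75:
                continue
            r = kaks_ng86(a, b)
            assert r.s_sites == pytest.approx(float(s))
            assert r.n_sites == pytest.approx(float(n_sites))
            assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * pn / 3))
            if s > 0:
                assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3))

    def test_saturated_divergence_raises(self):
        with pytest.raises(ValueError, match="saturat"):
            jukes_cantor(0.8)

    def test_sites_sum_to_three_per_codon(self):
        a, b, _ = simulate_paralog_pair(CodonSimSpec(n_codons=50, seed=3))
        r = kaks_ng86(a, b)
        assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons)


class TestSelectionAndDating:
    @pytest.mark.parametrize("omega,expected", [
        (1.05, "positive"), (0.85, "purifying"), (1.0, "neutral"), (0.0, "purifying"),
    ])
    def test_selection_rule(self, omega, expected):
        assert classify_selection(omega) == expected

    def test_neutral_band(self):
        assert classify_selection(1.05, neutral_band=0.1) == "neutral"

    def test_undefined_omega_rejected(self):
        with pytest.raises(ValueError):
            classify_selection(None)

    def test_zero_ks_dates_to_zero(self):
        assert estimate_divergence_time(0.0) == (0.0, 0.0)

    def test_printed_clock_formula(self):
        _, mya = estimate_divergence_time(0.33, 6.96e-9)
        assert mya == pytest.approx(23.71, abs=0.01)

    def test_doubling_the_clock_halves_the_age(self):
        for ks in (0.05, 0.33, 1.16):
            t1, _ = estimate_divergence_time(ks, 6.96e-9)
            t2, _ = estimate_divergence_time(ks, 2 * 6.96e-9)
            assert t1 == pytest.approx(2 * t2)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            estimate_divergence_time(-0.1)


class TestPairDetection:
    def test_identical_sequences_full_coverage_and_identity(self):
        seq = "MGDTPLHLAARNGHLEVVKLLLEHGADVNARDKDGDTPLHLAARNG"
        coverage, identity = align_pair_stats(seq, seq)
        assert coverage == 100.0 and identity == 100.0

    def test_component_rule_keeps_multi_edge_components_only(self):
        seq = "MGDTPLHLAARNGHLEVVKLLLEHGADVNARDKDGDTPLHLAARNG"
        other = "MWYQCKRNESTIVDPFGAHLMWYQCKRNESTIVDPFGAHLMWYQCK"
        pairs = detect_paralogs({"a": seq, "b": seq, "c": seq,
                                 "d": other, "e": other + "W"})
        names = {(p.gene_a, p.gene_b) for p in pairs}
        # a-b-c form a 3-edge component and survive; d-e is a single edge
        assert names == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_diverged_pair_rejected_by_identity(self):
        rng = random.Random(17)
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(120))
        mutated = list(base)
        for i in rng.sample(range(120), 48):  # ~60% identity remains
            mutated[i] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY"
                                     if a != mutated[i]])
        _, identity = align_pair_stats(base, "".join(mutated))
        assert identity < 70.0
        pairs = detect_paralogs({"a": base, "b": "".join(mutated),
                                 "c": base, "d": base})
        assert all("b" not in (p.gene_a, p.gene_b) for p in pairs)

    def test_order_invariance(self):
        seq = "MGDTPLHLAARNGHLEVVKLLLEHGADVNARDKD"
        forward = detect_paralogs({"a": seq, "b": seq, "c": seq})
        backward = detect_paralogs({"c": seq, "b": seq, "a": seq})
        assert [(p.gene_a, p.gene_b) for p in forward] == \
               [(p.gene_a, p.gene_b) for p in backward]


class TestDuplicationClass:
    def _models(self, positions, seq_id="chr5"):
        return {f"g{i}": GeneModel(gene_id=f"g{i}", seq_id=seq_id, strand="+",
                                   start=p, end=p + 999, exons=[(p, p + 999)])
                for i, p in enumerate(positions)}

    def test_adjacent_genes_are_tandem(self):
        from ankfam.evolution import ParalogPair

        models = self._models([1000, 5000, 9000])
        pair = ParalogPair("g0", "g1", 100.0, 100.0)
        assert classify_duplication(pair, models) == "tandem"

    def test_different_chromosomes_are_segmental(self):
        from ankfam.evolution import ParalogPair

        models = self._models([1000])
        models["h0"] = GeneModel(gene_id="h0", seq_id="chr1", strand="+",
                                 start=1000, end=1999, exons=[(1000, 1999)])
        pair = ParalogPair("g0", "h0", 100.0, 100.0)
        assert classify_duplication(pair, models) == "segmental"

    def test_many_intervening_family_genes_break_tandem(self):
        from ankfam.evolution import ParalogPair

        models = self._models([i * 10_000 for i in range(42)])
        pair = ParalogPair("g0", "g41", 100.0, 100.0)
        assert classify_duplication(pair, models, max_intervening_genes=5) == "segmental"

    def test_missing_model_raises(self):
        from ankfam.evolution import ParalogPair

        with pytest.raises(KeyError):
            classify_duplication(ParalogPair("x", "y", 90.0, 90.0), {})


class TestPairTable:
    def test_printed_table_selection_counts(self):
        df = load_printed_pairs()
        summary = pair_table_summary(df.to_dict("records"))
        assert summary.n_pairs == 23
        assert summary.selection_counts["purifying"] == 22
        assert summary.selection_counts["positive"] == 1

    def test_printed_table_duplication_times(self):
        summary = pair_table_summary(load_printed_pairs().to_dict("records"))
        assert round(summary.t_mean, 1) == 1.1
        assert summary.t_max == 5.87 and summary.t_min == 0.05

    def test_single_result_degenerates(self):
        summary = pair_table_summary([{"omega": 0.4, "t_mya": 2.0}])
        assert summary.omega_min == summary.omega_max == summary.omega_mean == 0.4
        assert summary.t_min == summary.t_max == summary.t_mean == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_table_summary([])

    def test_rounding_consistency_helper(self):
        assert omega_consistent_with_rounding(0.28, 0.33, 0.85)
        # 0.14/0.24 = 0.583 but the feasibility interval [0.551, 0.617]
        # still touches 0.60 +- 0.005, so rounding alone can explain it
        assert omega_consistent_with_rounding(0.14, 0.24, 0.60)
        assert not omega_consistent_with_rounding(0.50, 0.10, 2.0)
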