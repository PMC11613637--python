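import itertools
import math
import random

import pytest

from panfam.align import needleman_wunsch
from panfam.duplication_kaks import (DuplicationThresholds, classify_duplication,
                                     codon_align, detect_duplicates,
                                     duplication_time, gene_gap, kaks_ratio,
                                     ng86, analyze_duplicates)
from panfam.family_scan import FamilyMember
from panfam.genome_model import (GeneRecord, bundled_duplicate_table,
                                 bundled_family_table,
                                 gene_records_from_family_table)

# ---------------------------------------------------------------------------
# independent NG86 oracle: explicit enumeration with its own codon table
# ---------------------------------------------------------------------------

from Bio.Seq import Seq

CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
AA = {c: str(Seq(c).translate()) for c in CODONS}


def oracle_syn_sites(codon):
    total = 0.0
    for pos in range(3):
        syn = sum(1 for b in "ACGT" if b != codon[pos]
                  and AA[codon[:pos] + b + codon[pos + 1:]] == AA[codon]
                  and AA[codon[:pos] + b + codon[pos + 1:]] != "*")
        total += syn / 3
    return total


def oracle_diffs(c1, c2):
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = c1, 0, 0, False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if AA[nxt] == "*" and step < len(order) - 1:
                blocked = True
            sd, nd = (sd + 1, nd) if AA[nxt] == AA[cur] else (sd, nd + 1)
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in open_paths) / len(open_paths),
            sum(p[1] for p in open_paths) / len(open_paths))


def oracle_ng86(cds1, cds2):
    s1 = s2 = sd = nd = 0.0
    n = len(cds1) // 3
    for k in range(n):
        c1, c2 = cds1[3 * k: 3 * k + 3], cds2[3 * k: 3 * k + 3]
        s1 += oracle_syn_sites(c1)
        s2 += oracle_syn_sites(c2)
        d = oracle_diffs(c1, c2)
        sd, nd = sd + d[0], nd + d[1]
    S = (s1 + s2) / 2
    N = 3 * n - S
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else math.nan
    return jc(nd / N), jc(sd / S)


SENSE = [c for c in CODONS if AA[c] != "*"]


class TestNg86:
    def test_identical_sequences_zero(self):
        r = ng86("ATGCGT", "ATGCGT")
        assert r.ka == 0 and r.ks == 0

    def test_single_synonymous_difference(self):
        """One Phe codon difference (TTT vs TTC) in a 100-codon background:
        purely synonymous divergence, Ks fixed by the site counts + JC."""
        a = "TTT" * 100
        b = "TTC" + "TTT" * 99
        r = ng86(a, b)
        ka_o, ks_o = oracle_ng86(a, b)
        assert r.ka == 0
        assert r.ks == pytest.approx(ks_o)
        assert r.ks > 0

    def test_all_single_difference_codon_pairs_match_oracle(self):
        """Site and difference counts equal brute-force enumeration on every
        sense-codon pair differing at exactly one position."""
        for c1 in SENSE:
            for pos in range(3):
                for b in "ACGT":
                    c2 = c1[:pos] + b + c1[pos + 1:]
                    if c2 == c1 or AA[c2] == "*":
                        continue
                    r = ng86(c1, c2)
                    sd_o, nd_o = oracle_diffs(c1, c2)
                    assert (r.syn_diffs, r.nonsyn_diffs) == (sd_o, nd_o)
                    assert r.syn_sites == pytest.approx(
                        (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2)
                    assert r.syn_sites + r.nonsyn_sites == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_multi_difference_codons_match_pathway_enumeration(self, seed):
        rng = random.Random(seed)
        pairs = [(rng.choice(SENSE), rng.choice(SENSE)) for _ in range(60)]
        cds1 = "".join(p[0] for p in pairs)
        cds2 = "".join(p[1] for p in pairs)
        ka_o, ks_o = oracle_ng86(cds1, cds2)
        r = ng86(cds1, cds2)
        for mine, want in ((r.ka, ka_o), (r.ks, ks_o)):
            if math.isnan(want):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(want)

    def test_symmetric_in_arguments(self):
        rng = random.Random(3)
        a = "".join(rng.choice(SENSE) for _ in range(50))
        b = "".join(rng.choice(SENSE) for _ in range(50))
        r1, r2 = ng86(a, b), ng86(b, a)
        assert (r1.syn_diffs, r1.nonsyn_diffs) == (r2.syn_diffs, r2.nonsyn_diffs)
        assert r1.syn_sites == pytest.approx(r2.syn_sites)

    def test_site_conservation_three_per_codon(self):
        rng = random.Random(9)
        cds = "".join(rng.choice(SENSE) for _ in range(40))
        r = ng86(cds, cds)
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(3 * 40)

    def test_saturation_flagged_not_crashed(self):
        r = ng86("TTT" * 50, "TTC" * 50)
        assert r.saturated and math.isnan(r.ks)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86("ATGTAAAAA", "ATGTAAAAA")

    def test_agrees_with_independent_reference(self):
        """Cross-check against a second, externally maintained NG86."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = random.Random(21)
        from panfam.synthetic_data import evolve_codons, random_cds
        anc = random_cds(120, rng)
        der = evolve_codons(anc, 0.15, 0.8, 4)
        dn, ds = cal_dn_ds(CodonSeq(anc), CodonSeq(der), method="NG86")
        r = ng86(anc, der)
        assert r.ka == pytest.approx(dn, abs=1e-9)
        assert r.ks == pytest.approx(ds, abs=1e-9)


class TestRatioAndDating:
    @pytest.mark.parametrize("ka,ks,expected", [
        (0.0395, 0.0541, 0.73), (0.0528, 0.0273, 1.93), (0.0, 0.5, 0.0)])
    def test_ratio_reported_values(self, ka, ks, expected):
        assert round(kaks_ratio(ka, ks), 2) == expected

    def test_ratio_undefined_for_zero_ks(self):
        assert kaks_ratio(0.1, 0.0) is None
        assert kaks_ratio(0.1, math.nan) is None

    @pytest.mark.parametrize("ks,expected", [
        (0.0541, 1.80), (0.1522, 5.07), (0.0105, 0.35), (0.0, 0.0)])
    def test_dating_reported_values(self, ks, expected):
        assert round(duplication_time(ks), 2) == expected

    def test_dating_linear_in_ks(self):
        assert duplication_time(0.2) == pytest.approx(2 * duplication_time(0.1))

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            duplication_time(-0.1)


class TestCodonAlign:
    def test_identical_pair_returns_cds(self):
        cds = "ATGGTTAAA"
        aln = needleman_wunsch("MVK", "MVK")
        assert codon_align(aln, cds, cds) == (cds, cds)

    def test_gap_column_drops_exactly_three_bases(self):
        cds1, cds2 = "ATGGTTCCAAAA", "ATGGTTAAA"
        aln = needleman_wunsch("MVPK", "MVK")
        c1, c2 = codon_align(aln, cds1, cds2)
        assert len(c1) == len(c2) == len(cds1) - 3
        assert len(c1) % 3 == 0

    def test_mismatched_cds_named_residue(self):
        aln = needleman_wunsch("MVK", "MVK")
        with pytest.raises(ValueError, match="residue"):
            codon_align(aln, "ATGGGGAAA", "ATGGTTAAA")  # GGG = G, not V

    def test_simulated_pair_round_trips_through_backtranslation(self, study_sim):
        cfg, genomes, truth = study_sim
        row = truth.duplicate_pairs.iloc[0]
        seq = {g.gene_id: g for g in genomes[row["cultivar"]].genes}
        g1, g2 = seq[row["gene1"]], seq[row["gene2"]]
        aln = needleman_wunsch(g1.protein_sequence, g2.protein_sequence)
        c1, c2 = codon_align(aln, g1.cds_sequence, g2.cds_sequence)
        r = ng86(c1, c2)
        assert r.ka == pytest.approx(row["ka"], abs=1e-9)
        assert r.ks == pytest.approx(row["ks"], abs=1e-9)


def member_from(rec: GeneRecord, name=None) -> FamilyMember:
    return FamilyMember(name=name or rec.gene_id, gene=rec)


class TestDetectDuplicates:
    def test_identical_genes_retained_with_full_coverage(self):
        prot = "MVKWQERTLILVAT" * 5
        recs = [GeneRecord(f"g{i}", "cv", "Chr1", 100 + 5000 * i,
                           100 + 5000 * i + 300, "+", protein_sequence=prot)
                for i in range(2)]
        pairs = detect_duplicates([member_from(r) for r in recs])
        assert len(pairs) == 1
        assert pairs[0].coverage == 1.0 and pairs[0].similarity == 1.0

    def test_divergent_pair_rejected(self):
        rng = random.Random(5)
        a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(100))
        b = "".join(ch if rng.random() > 0.4 else
                    rng.choice("ACDEFGHIKLMNPQRSTVWY") for ch in a)  # ~60% id
        recs = [GeneRecord("g1", "cv", "Chr1", 100, 400, "+", protein_sequence=a),
                GeneRecord("g2", "cv", "Chr1", 9000, 9300, "+", protein_sequence=b)]
        pairs = detect_duplicates([member_from(r) for r in recs])
        assert pairs == []

    def test_simulated_tandem_cluster_all_pairs_retained(self, study_sim):
        """Every within-cluster pair of the simulated five-copy tandem
        cluster passes the 70/70 rule: C(5,2) = 10 pairs per cultivar."""
        cfg, genomes, truth = study_sim
        cv = cfg.cultivars[0]
        cluster = truth.duplicate_pairs.query("cultivar == @cv")
        cluster_genes = set(cluster["gene1"]) | set(cluster["gene2"])
        chr2_genes = [g for g in genomes[cv].genes
                      if g.gene_id in cluster_genes and g.chromosome == "Chr2"]
        assert len(chr2_genes) == 5
        pairs = detect_duplicates([member_from(g) for g in chr2_genes])
        assert len(pairs) == 10


@pytest.fixture(scope="module")
def printed_records():
    df = bundled_family_table()
    return {r.gene_id: r for r in gene_records_from_family_table(df)}


class TestClassifyDuplication:

    def test_all_printed_pairs_are_tandem(self, printed_records):
        """Published duplicate pairs, classified from the published
        coordinates, are all tandem (44 pairs; 14 in the Xg11 cultivar)."""
        dup = bundled_duplicate_table()
        labels = [classify_duplication(printed_records[a], printed_records[b])
                  for a, b in zip(dup["Gene 1"], dup["Gene 2"])]
        assert labels == ["tandem"] * 44
        xg11 = dup["Gene 1"].str.startswith("Xg11")
        assert int(xg11.sum()) == 14

    def test_cross_chromosome_is_segmental(self):
        g1 = GeneRecord("a", "cv", "Chr1", 100, 200, "+")
        g2 = GeneRecord("b", "cv", "Chr2", 100, 200, "+")
        assert classify_duplication(g1, g2) == "segmental"

    def test_boundary_gap_inclusive(self):
        g1 = GeneRecord("a", "cv", "Chr1", 100, 200, "+")
        g2 = GeneRecord("b", "cv", "Chr1", 200 + 100_000 + 1, 400_000, "+")
        assert gene_gap(g1, g2) == 100_000
        assert classify_duplication(g1, g2) == "tandem"
        g3 = GeneRecord("c", "cv", "Chr1", 200 + 100_001 + 1, 400_000, "+")
        assert classify_duplication(g1, g3) == "segmental"

    def test_overlapping_genes_gap_zero(self):
        g1 = GeneRecord("a", "cv", "Chr1", 100, 300, "+")
        g2 = GeneRecord("b", "cv", "Chr1", 200, 400, "+")
        assert gene_gap(g1, g2) == 0


class TestAnalyzeDuplicates:
    def test_full_analysis_on_simulated_cluster(self, study_sim):
        cfg, genomes, truth = study_sim
        cv = cfg.cultivars[0]
        fam = set(truth.members.query("cultivar == @cv")["gene_id"])
        members = [member_from(g) for g in genomes[cv].genes if g.gene_id in fam]
        pairs = analyze_duplicates(members)
        by_name = {frozenset((p.gene1.name, p.gene2.name)): p for p in pairs}
        for _, row in truth.duplicate_pairs.query("cultivar == @cv").iterrows():
            p = by_name[frozenset((row["gene1"], row["gene2"]))]
            assert p.dup_type == "tandem"
            assert p.ka == pytest.approx(row["ka"], abs=1e-9)
            assert p.ks == pytest.approx(row["ks"], abs=1e-9)
            assert p.time_mya == pytest.approx(row["ks"] / 3e-8 / 1e6)
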