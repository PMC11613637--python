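import pandas as pd
import pytest

from panfam.genome_model import (CultivarGenome, FastaError, GeneRecord,
                                 bundled_family_table, family_table_summary,
                                 read_family_table, read_fasta, read_gff3,
                                 write_family_table, write_fasta)


class TestFasta:
    def test_round_trip_preserves_content_and_order(self, tmp_path):
        seqs = {"geneA": "ACGTACGT", "geneB": "TTTTGGGG"}
        p = tmp_path / "x.fa"
        write_fasta(seqs, p)
        assert read_fasta(p, alphabet="dna") == seqs

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">s\nacgt\n")
        assert read_fasta(p)["s"] == "ACGT"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">s\nACGT\n>s\nACGT\n")
        with pytest.raises(FastaError, match="duplicate"):
            read_fasta(p)

    def test_bad_protein_residue_reported_with_position(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">s\nMKVJLT\n")
        with pytest.raises(FastaError, match="position 4"):
            read_fasta(p, alphabet="protein")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(FastaError):
            read_fasta(p)


class TestGeneRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "cv", "Chr1", 10, 5, "+")
        with pytest.raises(ValueError):
            GeneRecord("g", "cv", "Chr1", 1, 5, "forward")
        with pytest.raises(ValueError, match="does not match"):
            GeneRecord("g", "cv", "Chr1", 1, 6, "+",
                       cds_sequence="ATGAAA", protein_sequence="MF")

    def test_translation_consistency_accepted(self):
        GeneRecord("g", "cv", "Chr1", 1, 9, "+",
                   cds_sequence="ATGAAATAA", protein_sequence="MK")


class TestGff3:
    def _write(self, tmp_path, strand):
        chrom = "A" * 99 + "ATGGTT" + "G" * 10 + "AAATAA" + "C" * 50
        if strand == "-":
            from panfam.genome_model import reverse_complement
            chrom = reverse_complement(chrom)
            # segments mirrored: same intervals counted from the other end
            s1, e1 = len(chrom) - 104, len(chrom) - 99   # was 100-105
            s2, e2 = len(chrom) - 120, len(chrom) - 115  # was 116-121
            segs = [(s2, e2), (s1, e1)]
        else:
            segs = [(100, 105), (116, 121)]
        gff = tmp_path / "a.gff3"
        lines = ["##gff-version 3",
                 f"Chr1\tt\tgene\t{min(s for s, _ in segs)}\t{max(e for _, e in segs)}\t.\t{strand}\t.\tID=g1",
                 f"Chr1\tt\tmRNA\t{min(s for s, _ in segs)}\t{max(e for _, e in segs)}\t.\t{strand}\t.\tID=m1;Parent=g1"]
        for k, (s, e) in enumerate(sorted(segs)):
            lines.append(f"Chr1\tt\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID=c{k};Parent=m1")
        gff.write_text("\n".join(lines) + "\n")
        return chrom, gff

    def test_plus_strand_cds_concatenated(self, tmp_path):
        chrom, gff = self._write(tmp_path, "+")
        genome = read_gff3(gff, CultivarGenome("cv", {"Chr1": chrom}))
        assert genome.genes[0].cds_sequence == "ATGGTTAAATAA"
        assert genome.genes[0].protein_sequence == "MVK"

    def test_minus_strand_reverse_complemented(self, tmp_path):
        chrom, gff = self._write(tmp_path, "-")
        genome = read_gff3(gff, CultivarGenome("cv", {"Chr1": chrom}))
        assert genome.genes[0].cds_sequence == "ATGGTTAAATAA"
        assert genome.genes[0].strand == "-"

    def test_out_of_bounds_cds_skipped_not_fatal(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("##gff-version 3\n"
                       "Chr1\tt\tgene\t1\t999\t.\t+\t.\tID=g1\n"
                       "Chr1\tt\tmRNA\t1\t999\t.\t+\t.\tID=m1;Parent=g1\n"
                       "Chr1\tt\tCDS\t1\t999\t.\t+\t0\tID=c1;Parent=m1\n")
        genome = read_gff3(gff, CultivarGenome("cv", {"Chr1": "ACGT" * 10}))
        assert genome.genes == []

    def test_round_trip_on_simulated_genome(self, sim_bundle):
        """The GFF3 reader reproduces the simulator's truth coordinates and
        sequences exactly."""
        cfg, genomes, truth, outdir = sim_bundle
        cv = cfg.cultivars[0]
        loaded = read_gff3(outdir / f"{cv}.gff3",
                           CultivarGenome(cv, read_fasta(outdir / f"{cv}.genome.fa")))
        want = {g.gene_id: g for g in genomes[cv].genes}
        assert len(loaded.genes) == len(want)
        for g in loaded.genes:
            w = want[g.gene_id]
            assert (g.chromosome, g.start, g.end, g.strand) == \
                   (w.chromosome, w.start, w.end, w.strand)
            assert g.cds_sequence == w.cds_sequence
            assert g.protein_sequence == w.protein_sequence


class TestFamilyTable:
    def test_printed_table_dialect(self):
        df = bundled_family_table()
        row = df[df["Name"] == "Xg11_CBF11"].iloc[0]
        assert (row["Chr"], row["Start"], row["End"], row["Strand"]) == \
               ("Chr13", 3408292, 3408975, "+")
        assert len(df) == 59

    def test_summary_ranges(self):
        s = family_table_summary(bundled_family_table())
        assert s["n_members"] == 59
        assert s["AA_min"] == 171 and s["AA_max"] == 505

    def test_write_sorts_and_round_trips(self, tmp_path):
        from panfam.family_scan import FamilyMember
        mk = lambda name, chrom, start: FamilyMember(
            name=name, gene=GeneRecord(name, name.split("_")[0], chrom,
                                       start, start + 99, "+"))
        members = [mk("cvA_F2", "Chr10", 50), mk("cvA_F1", "Chr2", 100)]
        props = {m.name: {"AA": 100, "MW": 11000.5, "Ip": 6.2, "II": 40.1,
                          "AI": 70.0, "GRAVY": -0.55} for m in members}
        out = tmp_path / "fam.tsv"
        df = write_family_table(members, props, out)
        assert list(df.columns) == ["Name", "Gene", "Chr", "Start", "End",
                                    "Strand", "AA", "MW", "Ip", "II", "AI", "GRAVY"]
        # numeric chromosome order: Chr2 before Chr10
        assert list(df["Name"]) == ["cvA_F1", "cvA_F2"]
        back = read_family_table(out)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_missing_property_named(self, tmp_path):
        from panfam.family_scan import FamilyMember
        m = FamilyMember(name="cvA_F1",
                         gene=GeneRecord("cvA_F1", "cvA", "Chr1", 1, 10, "+"))
        with pytest.raises(ValueError, match="cvA_F1"):
            write_family_table([m], {}, tmp_path / "x.tsv")
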