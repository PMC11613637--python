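"""Synthetic multi-cultivar pan-genomes with a planted gene family.

The generator emulates the structure of a real pan-genome gene-family study:
several cultivar genomes carrying one transcription-factor family whose
members form ortho-groups (core groups present in every cultivar, dispensable
groups missing from designated cultivars, unique groups confined to one),
with tandem-duplicated clusters diverged at controlled synonymous divergence
and dN/dS, decoy genes of matching composition but no homology, promoters
seeded with known cis-elements, and negative-binomial read-count matrices.
Every run emits machine-readable truth tables, so each pipeline stage can be
scored against ground truth without any external data.

Sequence evolution is codon-wise: substitutions are proposed uniformly over
codon positions and alternative bases and accepted with probability
min(1, 1/ω) when synonymous and min(1, ω) when nonsynonymous (ω the target
dN/dS — the scaling keeps the nonsynonymous/synonymous rate ratio equal to ω
for ω above 1 as well); stops are rejected, and the process halts once the
realized NG86 synonymous divergence against the ancestor reaches the target. There is no transition/transversion bias and no
indel process — the simplest neutral-mutation model whose NG86 estimand is
controlled directly by the acceptance rule.

All randomness flows from a single integer seed; a fixed seed gives
byte-identical output bundles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .duplication_kaks import (BASES, CODON_TO_AA, jukes_cantor, ng86,
                               pathway_counts, syn_sites)
from .family_scan import bundled_ap2_profile
from .genome_model import (CultivarGenome, GeneRecord, reverse_complement,
                           translate_cds, write_fasta, write_gff3)
from .promoter_scan import read_element_dictionary

AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    if _aa != "*":
        AA_CODONS.setdefault(_aa, []).append(_codon)
for _aa in AA_CODONS:
    AA_CODONS[_aa].sort()


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def evolve_codons(ancestor: str, target_ks: float, dnds: float,
                  seed: int | random.Random = 0) -> str:
    """Evolve a CDS until its NG86 synonymous divergence from ``ancestor``
    reaches ``target_ks``. Returns the descendant CDS (same length).

    Raises if the target is unattainable (synonymous saturation).
    """
    if len(ancestor) % 3 or not ancestor:
        raise ValueError("ancestor length must be a positive multiple of 3")
    codons = [ancestor[i: i + 3] for i in range(0, len(ancestor), 3)]
    if any(CODON_TO_AA[c] == "*" for c in codons):
        raise ValueError("ancestor contains internal stop codons")
    if target_ks < 0:
        raise ValueError("target_ks must be nonnegative")
    if target_ks == 0:
        return ancestor
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    n = len(codons)
    s_anc = sum(syn_sites(c) for c in codons)
    s_desc = s_anc
    sd = nd = 0.0
    per_codon = [(0.0, 0.0)] * n
    max_proposals = 4000 * n
    for _ in range(max_proposals):
        k = rng.randrange(n)
        pos = rng.randrange(3)
        cur = codons[k]
        b = rng.choice([x for x in BASES if x != cur[pos]])
        nxt = cur[:pos] + b + cur[pos + 1:]
        if CODON_TO_AA[nxt] == "*":
            continue
        if CODON_TO_AA[nxt] != CODON_TO_AA[cur]:
            if rng.random() >= min(1.0, dnds):
                continue
        elif dnds > 1.0 and rng.random() >= 1.0 / dnds:
            continue
        # accept: update incremental NG86 bookkeeping against the ancestor
        anc = ancestor[3 * k: 3 * k + 3]
        old_sd, old_nd = per_codon[k]
        new_sd, new_nd = pathway_counts(anc, nxt)
        sd += new_sd - old_sd
        nd += new_nd - old_nd
        per_codon[k] = (new_sd, new_nd)
        s_desc += syn_sites(nxt) - syn_sites(cur)
        codons[k] = nxt
        ps = sd / ((s_anc + s_desc) / 2.0)
        if ps >= 0.70:
            raise ValueError("target_ks unattainable: synonymous saturation")
        if jukes_cantor(ps) >= target_ks:
            return "".join(codons)
    raise ValueError("target_ks not reached within the proposal budget")


def random_cds(n_codons: int, rng: random.Random, protein: str | None = None) -> str:
    """A random CDS; when ``protein`` is given, a random back-translation."""
    if protein is not None:
        return "".join(rng.choice(AA_CODONS[aa]) for aa in protein)
    aas = [aa for aa in AA_CODONS if aa != "M"]
    seq = "".join(rng.choice(AA_CODONS[rng.choice(aas)]) for _ in range(n_codons - 1))
    return AA_CODONS["M"][0] + seq


def codon_shuffle(cds: str, rng: random.Random) -> str:
    """Shuffle codon order (composition preserved, homology destroyed)."""
    codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    rng.shuffle(codons)
    return "".join(codons)


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class OrthoGroupSpec:
    n_core: int = 8
    n_dispensable: int = 5
    n_unique: int = 2
    dispensable_absent_from: int = 1  # cultivar index lacking dispensable groups
    unique_in: int = 3                # cultivar index carrying unique groups


@dataclass
class SimulationConfig:
    """Study-mirroring defaults: five cultivars; 8 core + 5 dispensable
    (absent from one cultivar) + 2 unique (one cultivar) ortho-groups; two
    tandem clusters with ~20-kb inter-gene gaps; moderate divergence."""

    seed: int = 0
    cultivars: tuple[str, ...] = ("cv1", "cv2", "cv3", "cv4", "cv5")
    chromosome_length: int = 120_000
    groups: OrthoGroupSpec = field(default_factory=OrthoGroupSpec)
    #: group index -> (chromosome, cluster id or None). Groups sharing a
    #: cluster id are laid out adjacently (tandem); others are isolated.
    n_decoys: int = 8
    protein_length: int = 210          # codons, domain included
    #: paralog-group divergence mirrors the Ks range observed between tandem
    #: duplicates (~0.01-0.15); orthologs of one species' cultivars are nearly
    #: identical, so their divergence sits an order of magnitude lower
    between_group_ks: float = 0.10
    within_group_ks: float = 0.01
    #: dN/dS for paralog-group divergence (post-duplication relaxation) vs the
    #: purifying regime of same-species ortholog divergence
    dnds: float = 0.5
    within_dnds: float = 0.1
    # adjacent-gene gaps; kept small enough that even the first-to-last pair of
    # a five-gene cluster stays within the 100-kb tandem distance cutoff
    tandem_gap_bp: tuple[int, int] = (12_000, 20_000)
    isolated_gap_bp: int = 35_000
    promoter_elements_per_gene: int = 4
    promoter_length: int = 2000

    def layout(self) -> list[tuple[int, str, str | None]]:
        """(group index, chromosome, cluster id) per group. Mirrors the study:
        two isolated core groups on Chr1, a five-group core tandem cluster on
        Chr2, one isolated core group on Chr3, the dispensable groups as a
        tandem cluster on Chr3, and the unique groups tandem on Chr3."""
        g = self.groups
        out = []
        idx = 0
        for k in range(g.n_core):
            if k < 2:
                out.append((idx, "Chr1", None))
            elif k < 7:
                out.append((idx, "Chr2", "clusterA"))
            else:
                out.append((idx, "Chr3", None))
            idx += 1
        for _ in range(g.n_dispensable):
            out.append((idx, "Chr3", "clusterB"))
            idx += 1
        for _ in range(g.n_unique):
            out.append((idx, "Chr3", "clusterC"))
            idx += 1
        return out


@dataclass
class TruthTables:
    """Ground truth emitted alongside the bundle, consistent with the files."""

    members: pd.DataFrame         # cultivar, gene_id, group, chrom, start, end, strand
    orthogroups: pd.DataFrame     # group, pan_class, presence per cultivar
    duplicate_pairs: pd.DataFrame # cultivar, gene1, gene2, gap, dup_type, ka, ks
    promoter_hits: pd.DataFrame   # gene_id, element, offset, strand
    decoys: pd.DataFrame          # cultivar, gene_id

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.members.to_csv(outdir / "truth_members.tsv", sep="\t", index=False)
        self.orthogroups.to_csv(outdir / "truth_orthogroups.tsv", sep="\t", index=False)
        self.duplicate_pairs.to_csv(outdir / "truth_duplicates.tsv", sep="\t", index=False)
        self.promoter_hits.to_csv(outdir / "truth_promoters.tsv", sep="\t", index=False)
        self.decoys.to_csv(outdir / "truth_decoys.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# pan-genome simulation
# ---------------------------------------------------------------------------

def _ancestor_cds(cfg: SimulationConfig, rng: random.Random) -> tuple[str, int]:
    """Ancestral family CDS embedding the domain consensus; returns the CDS
    and the domain's residue offset."""
    profile = bundled_ap2_profile()
    consensus = profile.consensus()
    flank_n = 40
    flank_c = cfg.protein_length - flank_n - len(consensus)
    if flank_c < 10:
        raise ValueError("protein_length too short for domain plus flanks")
    aas = [aa for aa in AA_CODONS if aa != "M"]
    protein = ("M" + "".join(rng.choice(aas) for _ in range(flank_n - 1))
               + consensus
               + "".join(rng.choice(aas) for _ in range(flank_c)))
    return random_cds(0, rng, protein=protein), flank_n


def _random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def simulate_pangenome(cfg: SimulationConfig, outdir: str | Path | None = None
                       ) -> tuple[dict[str, CultivarGenome], TruthTables]:
    """Generate the cultivar genomes and truth tables (optionally writing the
    per-cultivar genome FASTA, GFF3, protein FASTA and CDS FASTA plus truth
    TSVs under ``outdir``)."""
    rng = random.Random(cfg.seed)
    g = cfg.groups
    n_groups = g.n_core + g.n_dispensable + g.n_unique
    layout = cfg.layout()
    ancestor, _domain_off = _ancestor_cds(cfg, rng)

    # per-group ancestors, then per-cultivar orthologs
    group_cds = [evolve_codons(ancestor, cfg.between_group_ks / 2.0, cfg.dnds,
                               random.Random(rng.randrange(2 ** 31)))
                 for _ in range(n_groups)]
    presence: dict[int, list[str]] = {}
    for gi in range(n_groups):
        if gi < g.n_core:
            carriers = list(cfg.cultivars)
        elif gi < g.n_core + g.n_dispensable:
            carriers = [cv for i, cv in enumerate(cfg.cultivars)
                        if i != g.dispensable_absent_from]
        else:
            carriers = [cfg.cultivars[g.unique_in]]
        presence[gi] = carriers

    elements = {e.name: e for e in read_element_dictionary()}
    element_names = sorted(elements)

    genomes: dict[str, CultivarGenome] = {}
    member_rows, promoter_rows, decoy_rows, dup_rows = [], [], [], []
    cds_store: dict[str, dict[str, str]] = {}

    for ci, cv in enumerate(cfg.cultivars):
        crng = random.Random(rng.randrange(2 ** 31))
        genome = CultivarGenome(cultivar=cv)
        chrom_parts: dict[str, list[str]] = {c: [] for c in ("Chr1", "Chr2", "Chr3")}
        chrom_pos: dict[str, int] = {c: 0 for c in chrom_parts}
        cds_store[cv] = {}
        placed: dict[str, list[tuple[int, GeneRecord]]] = {}

        def append_seq(chrom: str, seq: str) -> int:
            """Append to a chromosome; returns 1-based start of the segment."""
            start = chrom_pos[chrom] + 1
            chrom_parts[chrom].append(seq)
            chrom_pos[chrom] += len(seq)
            return start

        prev_cluster = None
        gene_counter = 0
        for gi, chrom, cluster in layout:
            if cv not in presence[gi]:
                prev_cluster = cluster
                continue
            cds = evolve_codons(group_cds[gi], cfg.within_group_ks / 2.0,
                                cfg.within_dnds,
                                random.Random(crng.randrange(2 ** 31)))
            gene_counter += 1
            gene_id = f"{cv}_g{gene_counter:03d}"
            strand = "+" if crng.random() < 0.7 else "-"
            # spacer before the promoter+gene block
            if cluster is not None and cluster == prev_cluster:
                spacer = crng.randint(*cfg.tandem_gap_bp) - cfg.promoter_length
            else:
                spacer = cfg.isolated_gap_bp
            append_seq(chrom, _random_dna(max(100, spacer), crng))

            promoter = list(_random_dna(cfg.promoter_length, crng))
            chosen = crng.sample(element_names, cfg.promoter_elements_per_gene)
            used: list[tuple[int, int]] = []
            for name in chosen:
                pat = elements[name].pattern
                concrete = "".join(
                    crng.choice({"A": "A", "C": "C", "G": "G", "T": "T",
                                 "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
                                 "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
                                 "H": "ACT", "V": "ACG", "N": "ACGT"}[c])
                    for c in pat)
                for _ in range(50):
                    off = crng.randrange(1, cfg.promoter_length - len(pat))
                    if all(off + len(pat) <= s or off >= s + l for s, l in used):
                        break
                used.append((off, len(pat)))
                promoter[off - 1: off - 1 + len(concrete)] = concrete
                promoter_rows.append({"gene_id": gene_id, "element": name,
                                      "offset": off, "strand": "+"})
            promoter_seq = "".join(promoter)

            stop = crng.choice(["TAA", "TGA", "TAG"])
            body = cds + stop
            if strand == "+":
                append_seq(chrom, promoter_seq)
                start = append_seq(chrom, body)
                end = start + len(body) - 1
            else:
                start = append_seq(chrom, reverse_complement(body))
                end = start + len(body) - 1
                append_seq(chrom, reverse_complement(promoter_seq))
            rec = GeneRecord(gene_id=gene_id, cultivar=cv, chromosome=chrom,
                             start=start, end=end, strand=strand,
                             cds_sequence=body, protein_sequence=translate_cds(body))
            genome.genes.append(rec)
            cds_store[cv][gene_id] = body
            member_rows.append({"cultivar": cv, "gene_id": gene_id,
                                "group": f"FAM{gi + 1}", "chromosome": chrom,
                                "start": start, "end": end, "strand": strand})
            if cluster is not None:
                placed.setdefault(cluster, []).append((gi, rec))
            prev_cluster = cluster

        # decoys: codon-shuffled family sequences, no domain, no homology
        for d in range(cfg.n_decoys):
            gene_counter += 1
            gene_id = f"{cv}_g{gene_counter:03d}"
            chrom = crng.choice(["Chr1", "Chr2", "Chr3"])
            body = codon_shuffle(ancestor, crng) + "TAA"
            append_seq(chrom, _random_dna(2500, crng))
            start = append_seq(chrom, body)
            rec = GeneRecord(gene_id=gene_id, cultivar=cv, chromosome=chrom,
                             start=start, end=start + len(body) - 1, strand="+",
                             cds_sequence=body, protein_sequence=translate_cds(body))
            genome.genes.append(rec)
            cds_store[cv][gene_id] = body
            decoy_rows.append({"cultivar": cv, "gene_id": gene_id})

        for chrom in chrom_parts:
            tail = cfg.chromosome_length - chrom_pos[chrom]
            if tail > 0:
                append_seq(chrom, _random_dna(tail, crng))
            genome.chromosomes[chrom] = "".join(chrom_parts[chrom])
        genome.genes.sort(key=GeneRecord.sort_key)
        genomes[cv] = genome

        # truth duplicate pairs: within-cluster pairs in this cultivar
        for cluster, members in placed.items():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    (gi1, r1), (gi2, r2) = members[i], members[j]
                    first, second = (r1, r2) if r1.start <= r2.start else (r2, r1)
                    gap = second.start - first.end - 1
                    res = ng86(r1.cds_sequence[:-3], r2.cds_sequence[:-3])
                    dup_rows.append({
                        "cultivar": cv, "gene1": r1.gene_id, "gene2": r2.gene_id,
                        "gap": gap, "dup_type": "tandem",
                        "ka": res.ka, "ks": res.ks,
                    })

    og_rows = []
    for gi in range(n_groups):
        carriers = presence[gi]
        n = len(carriers)
        # unique takes precedence so the single-cultivar degenerate case is
        # labeled unique, not core
        pan = ("unique" if n == 1
               else "core" if n == len(cfg.cultivars) else "dispensable")
        row = {"group": f"FAM{gi + 1}", "pan_class": pan}
        for cv in cfg.cultivars:
            row[cv] = int(cv in carriers)
        og_rows.append(row)

    truth = TruthTables(
        members=pd.DataFrame(member_rows),
        orthogroups=pd.DataFrame(og_rows),
        duplicate_pairs=pd.DataFrame(dup_rows),
        promoter_hits=pd.DataFrame(promoter_rows),
        decoys=pd.DataFrame(decoy_rows),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cv, genome in genomes.items():
            write_fasta(genome.chromosomes, outdir / f"{cv}.genome.fa")
            write_gff3(genome, outdir / f"{cv}.gff3")
            write_fasta({g.gene_id: g.protein_sequence for g in genome.sorted_genes()},
                        outdir / f"{cv}.proteins.faa")
            write_fasta(cds_store[cv], outdir / f"{cv}.cds.fna")
        truth.write(outdir)
    return genomes, truth


def family_queries(cfg: SimulationConfig, n: int = 3) -> dict[str, str]:
    """Seed query proteins for the scan: independent descendants of the family
    ancestor (emulating homologs from related species)."""
    rng = random.Random(cfg.seed + 777)
    ancestor, _ = _ancestor_cds(cfg, random.Random(cfg.seed))
    out = {}
    for i in range(n):
        cds = evolve_codons(ancestor, 0.08, cfg.dnds,
                            random.Random(rng.randrange(2 ** 31)))
        out[f"query{i + 1}"] = translate_cds(cds)
    return out


# ---------------------------------------------------------------------------
# read-count simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionPlan:
    """Planned FPKM per gene per condition, replicate count, library sizes."""

    conditions: tuple[str, ...] = ("control", "cold", "heat")
    n_replicates: int = 3
    library_size: int = 20_000_000
    dispersion: float = 10.0  # NB size parameter; larger -> tighter counts
    base_fpkm: tuple[float, ...] = (5.0, 20.0, 80.0)
    fold_changes: tuple[float, ...] = (4.0, 1.0, 0.25)  # sampled per gene/condition


def simulate_counts(gene_lengths: dict[str, int], plan: ExpressionPlan, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts matrix, design table and truth FPKM means.

    Returns (counts genes × samples, design with sample/condition rows,
    truth table of planned FPKM per gene and condition).
    """
    rng = np.random.default_rng(seed)
    pyrng = random.Random(seed)
    genes = sorted(gene_lengths)
    planned: dict[str, dict[str, float]] = {}
    for gene in genes:
        base = pyrng.choice(plan.base_fpkm)
        planned[gene] = {}
        for ci, cond in enumerate(plan.conditions):
            fc = 1.0 if ci == 0 else pyrng.choice(plan.fold_changes)
            planned[gene][cond] = base * fc
    samples, cond_of = [], {}
    for cond in plan.conditions:
        for r in range(plan.n_replicates):
            s = f"{cond}_{r + 1}"
            samples.append(s)
            cond_of[s] = cond
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for i, gene in enumerate(genes):
        for j, s in enumerate(samples):
            mean = planned[gene][cond_of[s]] * gene_lengths[gene] * plan.library_size / 1e9
            if mean <= 0:
                continue
            p = plan.dispersion / (plan.dispersion + mean)
            counts[i, j] = rng.negative_binomial(plan.dispersion, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    design_df = pd.DataFrame({"sample": samples,
                              "condition": [cond_of[s] for s in samples]})
    truth_df = pd.DataFrame(planned).T.loc[genes]
    return counts_df, design_df, truth_df
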