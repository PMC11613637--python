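"""Domain types and file readers/writers for pan-genome gene-family analysis.

The in-memory model is deliberately small: a :class:`GeneRecord` per annotated
gene (1-based inclusive coordinates, GFF3 convention), a :class:`CultivarGenome`
holding chromosome sequences plus an ordered gene index, and pandas DataFrames
for the two tabular dialects used throughout — the per-gene "family table"
(name, coordinates, protein length and physicochemical properties) and the
duplicate-pair table (Ka, Ks, Ka/Ks, duplication time, duplication type).

Coordinates are 1-based inclusive everywhere in the public surface; any
half-open indexing is confined to implementation and never serialized.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("panfam")

DNA_ALPHABET = set("ACGTURYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXU*")

#: Column order of the family table (physicochemical properties per member).
FAMILY_TABLE_COLUMNS = [
    "Name", "Gene", "Chr", "Start", "End", "Strand",
    "AA", "MW", "Ip", "II", "AI", "GRAVY",
]

#: Column order of the duplicate-pair table.
DUPLICATE_TABLE_COLUMNS = [
    "Gene 1", "Gene 2", "Ka", "Ks", "Ka/Ks", "Time (MYA)", "Duplication Type",
]


class FastaError(ValueError):
    """Malformed FASTA input (duplicate id, bad alphabet, empty file)."""


def chromosome_sort_key(name: str) -> tuple:
    """Sort key for chromosome names: trailing integer if present ("Chr13" -> 13),
    non-numeric names sort lexicographically after all numeric ones."""
    m = re.search(r"(\d+)$", name)
    if m:
        return (0, int(m.group(1)), name)
    return (1, 0, name)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, trimming one trailing stop."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass
class GeneRecord:
    """One annotated gene: coordinates, strand, CDS, protein."""

    gene_id: str
    cultivar: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # inclusive, >= start
    strand: str  # "+" or "-"
    cds_sequence: str = ""
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.cds_sequence and self.protein_sequence:
            if translate_cds(self.cds_sequence) != self.protein_sequence:
                raise ValueError(
                    f"{self.gene_id}: translated CDS does not match protein sequence"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (chromosome_sort_key(self.chromosome), self.start, self.end, self.gene_id)


@dataclass
class CultivarGenome:
    """A cultivar's chromosome sequences and its ordered gene collection."""

    cultivar: str
    chromosomes: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def add_gene(self, gene: GeneRecord) -> None:
        if self.chromosomes.get(gene.chromosome):
            chrom_len = len(self.chromosomes[gene.chromosome])
            if gene.end > chrom_len:
                raise ValueError(
                    f"{gene.gene_id}: interval {gene.start}-{gene.end} exceeds "
                    f"{gene.chromosome} length {chrom_len}"
                )
        self.genes.append(gene)

    def sorted_genes(self) -> list[GeneRecord]:
        """Genes sorted by (chromosome order, start); ties by end then gene_id."""
        return sorted(self.genes, key=GeneRecord.sort_key)

    def gene_order_index(self) -> dict[str, int]:
        """Rank of each gene in chromosomal order, shared by duplication logic."""
        return {g.gene_id: i for i, g in enumerate(self.sorted_genes())}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str | None = None) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercased sequence map.

    Parameters
    ----------
    alphabet
        ``"dna"`` or ``"protein"`` to validate residues (rejecting with the
        offending position), or None to skip validation.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if alphabet is not None:
            allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
            for i, ch in enumerate(seq):
                if ch not in allowed:
                    raise FastaError(
                        f"{path}: record {rec.id!r} has non-IUPAC {alphabet} "
                        f"character {ch!r} at position {i + 1}"
                    )
        records[rec.id] = seq
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, genome: CultivarGenome) -> CultivarGenome:
    """Populate ``genome.genes`` from a GFF3 annotation.

    One GeneRecord per gene feature; when a gene has several mRNAs the one
    with the longest total CDS is taken. CDS segments are concatenated in
    transcription order and reverse-complemented on the minus strand before
    translation. Features whose CDS fall outside the chromosome are skipped
    with a logged warning rather than aborting the run.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    for gene in db.features_of_type("gene"):
        best_cds: list | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            if not segs:
                continue
            total = sum(f.end - f.start + 1 for f in segs)
            if best_cds is None or total > sum(f.end - f.start + 1 for f in best_cds):
                best_cds = segs
        if best_cds is None:
            best_cds = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
        chrom_seq = genome.chromosomes.get(gene.seqid, "")
        if chrom_seq and best_cds:
            if any(f.end > len(chrom_seq) or f.start < 1 for f in best_cds):
                logger.warning(
                    "gff3: skipping gene %s — CDS outside %s bounds", gene.id, gene.seqid
                )
                continue
        cds = ""
        if chrom_seq:
            cds = "".join(chrom_seq[f.start - 1 : f.end] for f in best_cds)
            if gene.strand == "-":
                cds = reverse_complement(cds)
        protein = translate_cds(cds) if cds else ""
        genome.add_gene(
            GeneRecord(
                gene_id=gene.id,
                cultivar=genome.cultivar,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_sequence=cds,
                protein_sequence=protein,
            )
        )
    genome.genes.sort(key=GeneRecord.sort_key)
    return genome


def write_gff3(genome: CultivarGenome, path: str | Path,
               cds_segments: Mapping[str, list[tuple[int, int]]] | None = None) -> None:
    """Write gene/mRNA/CDS features for every gene (single-mRNA gene models).

    ``cds_segments`` optionally maps gene_id to explicit CDS intervals
    (1-based inclusive); by default the whole gene span is one CDS.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.sorted_genes():
            segs = (cds_segments or {}).get(g.gene_id, [(g.start, g.end)])
            base = f"{g.chromosome}\tpanfam\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            # phase bookkeeping: CDS pieces in genomic order
            ordered = sorted(segs)
            pieces = ordered if g.strand == "+" else list(reversed(ordered))
            phase, phases = 0, {}
            for (s, e) in pieces:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for (s, e) in ordered:
                fh.write(f"{base}CDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                         f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n")


# ---------------------------------------------------------------------------
# Family table (Table-1 dialect) and duplicate-pair table (Table-2 dialect)
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> pd.DataFrame:
    """Read a family table TSV.

    Accepts the printed-table dialect: extra trailing columns (e.g. subcellular
    localization) are ignored, en-dash minus strands normalized, and sequences
    are optional (property recomputation is then unavailable).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FAMILY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing family-table columns {missing}")
    df = df[[c for c in df.columns if c in FAMILY_TABLE_COLUMNS]].copy()
    df["Strand"] = df["Strand"].str.replace("–", "-", regex=False).str.strip()
    for col in ("Start", "End", "AA"):
        df[col] = df[col].astype(int)
    for col in ("MW", "Ip", "II", "AI", "GRAVY"):
        df[col] = df[col].astype(float)
    if df["Name"].duplicated().any():
        dupes = df.loc[df["Name"].duplicated(), "Name"].tolist()
        raise ValueError(f"{path}: duplicate member names {dupes}")
    if (df["AA"] <= 0).any():
        raise ValueError(f"{path}: AA column must be positive")
    return df


def family_table_summary(df: pd.DataFrame) -> dict[str, float]:
    """Range summary of the family table's numeric columns (per-column min/max)."""
    out: dict[str, float] = {"n_members": int(len(df))}
    for col in ("AA", "MW", "Ip", "II", "AI", "GRAVY"):
        out[f"{col}_min"] = float(df[col].min())
        out[f"{col}_max"] = float(df[col].max())
    return out


def write_family_table(members: Iterable, properties: Mapping[str, Mapping[str, float]],
                       path: str | Path) -> pd.DataFrame:
    """Write family members + computed properties as a family-table TSV.

    ``members`` are FamilyMember-like objects (``name`` and a ``gene``
    GeneRecord); ``properties`` maps member name -> property mapping with keys
    AA, MW, Ip, II, AI, GRAVY. Rows are sorted by (cultivar, chromosome order,
    start); floats are written at full precision.
    """
    rows = []
    for m in sorted(members, key=lambda m: (m.gene.cultivar, *m.gene.sort_key())):
        if m.name not in properties:
            raise ValueError(f"missing computed properties for {m.name}")
        p = properties[m.name]
        rows.append({
            "Name": m.name, "Gene": m.gene.gene_id, "Chr": m.gene.chromosome,
            "Start": m.gene.start, "End": m.gene.end, "Strand": m.gene.strand,
            "AA": int(p["AA"]), "MW": p["MW"], "Ip": p["Ip"], "II": p["II"],
            "AI": p["AI"], "GRAVY": p["GRAVY"],
        })
    df = pd.DataFrame(rows, columns=FAMILY_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df


def read_duplicate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DUPLICATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing duplicate-table columns {missing}")
    df = df[DUPLICATE_TABLE_COLUMNS].copy()
    for col in ("Ka", "Ks", "Ka/Ks", "Time (MYA)"):
        df[col] = df[col].astype(float)
    return df


def bundled_family_table() -> pd.DataFrame:
    """The packaged family characterization table (59 members, 5 cultivars)."""
    from importlib import resources
    with resources.files("panfam.data").joinpath("table1.tsv").open() as fh:
        return read_family_table(fh)


def bundled_duplicate_table() -> pd.DataFrame:
    """The packaged duplicate-pair table (44 pairs with printed Ka/Ks/age)."""
    from importlib import resources
    with resources.files("panfam.data").joinpath("table2.tsv").open() as fh:
        return read_duplicate_table(fh)


def gene_records_from_family_table(df: pd.DataFrame) -> list[GeneRecord]:
    """GeneRecords (coordinates only) from a family table; cultivar is taken
    from the name prefix before the first underscore."""
    records = []
    for _, row in df.iterrows():
        records.append(GeneRecord(
            gene_id=row["Name"],
            cultivar=str(row["Name"]).split("_", 1)[0],
            chromosome=row["Chr"],
            start=int(row["Start"]),
            end=int(row["End"]),
            strand=row["Strand"],
        ))
    return records
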