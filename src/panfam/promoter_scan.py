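"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2-kb regions upstream of the transcription start, taken
strand-aware from the genome (minus-strand promoters are reverse-complemented
so that position 1 is the promoter's 5' end and the element nearest the gene
sits at the 3' end). Elements are short degenerate DNA motifs (IUPAC
alphabet) from a bundled, editable dictionary of plant cis-elements grouped
into light / hormone / stress / development categories. The dictionary ships
one documented consensus variant per element name; element databases host
several variants per name, so the chosen patterns are data, not code.

Scanning reports every match position on both strands, overlaps included;
minus-strand hits are reported at their leftmost plus-strand position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genome_model import CultivarGenome, GeneRecord, logger, reverse_complement

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

CATEGORIES = ("light", "hormone", "stress", "development", "other")


@dataclass(frozen=True)
class CisElement:
    """A named degenerate motif with its functional category."""

    name: str
    pattern: str  # IUPAC DNA
    category: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = [c for c in self.pattern if c not in IUPAC_DNA]
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {bad} in pattern")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC_DNA[c] for c in self.pattern))


@dataclass(frozen=True)
class CisElementHit:
    gene: str
    element: str
    category: str
    offset: int  # 1-based leftmost position within the promoter
    strand: str
    matched: str


def read_element_dictionary(path: str | Path | None = None) -> list[CisElement]:
    """Load the element dictionary TSV (columns: name, pattern, category);
    defaults to the bundled plant cis-element set."""
    if path is None:
        ref = resources.files("panfam.data").joinpath("cis_elements.tsv")
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [CisElement(r["name"], r["pattern"].upper(), r["category"])
            for _, r in df.iterrows()]


def extract_upstream(genome: CultivarGenome, gene: GeneRecord,
                     length: int = 2000) -> str:
    """The up-to-``length``-bp promoter upstream of ``gene``, strand-aware.

    Plus strand: bases [start-length, start-1]; minus strand: reverse
    complement of [end+1, end+length]. Regions truncated by a chromosome
    boundary are returned at their actual (logged) length; a gene starting at
    base 1 on the plus strand yields an empty promoter with a warning.
    """
    chrom = genome.chromosomes.get(gene.chromosome)
    if not chrom:
        raise ValueError(f"{gene.gene_id}: no sequence for {gene.chromosome}")
    if gene.strand == "+":
        lo = max(1, gene.start - length)
        promoter = chrom[lo - 1: gene.start - 1]
    else:
        hi = min(len(chrom), gene.end + length)
        promoter = reverse_complement(chrom[gene.end: hi])
    if len(promoter) < length:
        logger.warning("promoter of %s truncated to %d bp by chromosome boundary",
                       gene.gene_id, len(promoter))
    return promoter


def scan_elements(promoter: str, dictionary: Iterable[CisElement],
                  both_strands: bool = True, gene: str = "") -> list[CisElementHit]:
    """All element match positions in a promoter, overlapping hits included.

    Minus-strand hits are matches of the pattern on the reverse complement,
    reported at their leftmost position on the given (plus) sequence.
    """
    if not promoter:
        raise ValueError("scan_elements: empty promoter")
    promoter = promoter.upper()
    L = len(promoter)
    hits: list[CisElementHit] = []
    rc = reverse_complement(promoter) if both_strands else ""
    for elem in dictionary:
        rx = re.compile(f"(?=({elem.regex().pattern}))")
        for m in rx.finditer(promoter):
            hits.append(CisElementHit(gene, elem.name, elem.category,
                                      m.start() + 1, "+", m.group(1)))
        if both_strands:
            plen = len(elem.pattern)
            for m in rx.finditer(rc):
                # mirror: leftmost plus-strand offset of the rc match
                offset = L - (m.start() + plen) + 1
                hits.append(CisElementHit(gene, elem.name, elem.category, offset,
                                          "-", promoter[offset - 1: offset - 1 + plen]))
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def hits_table(hits: Iterable[CisElementHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": h.gene, "element": h.element, "category": h.category,
          "offset": h.offset, "strand": h.strand, "matched": h.matched}
         for h in hits],
        columns=["gene", "element", "category", "offset", "strand", "matched"])


def category_counts(hits: Iterable[CisElementHit]) -> pd.DataFrame:
    """Gene × category hit-count matrix (the promoter-landscape summary)."""
    df = hits_table(hits)
    if df.empty:
        return pd.DataFrame(columns=list(CATEGORIES))
    mat = df.pivot_table(index="gene", columns="category", values="element",
                         aggfunc="count", fill_value=0)
    return mat.reindex(columns=[c for c in CATEGORIES if c in mat.columns])


def scan_genome_promoters(genome: CultivarGenome, genes: Iterable[GeneRecord],
                          dictionary: Iterable[CisElement] | None = None,
                          length: int = 2000, both_strands: bool = True,
                          names: Mapping[str, str] | None = None) -> list[CisElementHit]:
    """Extract and scan the promoter of each gene; genes whose promoter is
    empty (gene at the chromosome edge) contribute no hits."""
    dictionary = list(dictionary) if dictionary is not None else read_element_dictionary()
    all_hits: list[CisElementHit] = []
    for gene in genes:
        promoter = extract_upstream(genome, gene, length)
        if not promoter:
            continue
        label = (names or {}).get(gene.gene_id, gene.gene_id)
        all_hits.extend(scan_elements(promoter, dictionary, both_strands, gene=label))
    return all_hits
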