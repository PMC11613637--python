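"""Duplicate-pair detection, tandem/segmental classification, NG86 Ka/Ks and
duplication dating.

Duplicate pairs within a cultivar are retained under the 70/70 rule: the
global protein alignment must cover at least 70% of the longer gene and show
at least 70% identity over aligned columns. A retained pair is *tandem* when
both genes sit on the same chromosome within a configurable distance
(default 100 kb between nearest gene ends), otherwise *segmental*.

Ka and Ks follow Nei & Gojobori (1986): per-codon synonymous site fractions
(stop-codon changes count as nonsynonymous, so synonymous + nonsynonymous
sites sum to exactly 3 per codon), observed differences partitioned by
equal-weight averaging over all minimal substitution pathways (pathways
passing through a stop codon are excluded), and the Jukes–Cantor correction
d = -(3/4)·ln(1 - 4p/3) applied to both proportions. Duplication age is
T = Ks / (2·λ) with λ = 1.5e-8 synonymous substitutions per site per year,
reported in million years (Mya).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .align import Alignment, needleman_wunsch
from .family_scan import FamilyMember
from .genome_model import GeneRecord, DUPLICATE_TABLE_COLUMNS, translate_cds

#: Synonymous substitution rate, substitutions / synonymous site / year.
DEFAULT_CLOCK_RATE = 1.5e-8

_table = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"
BASES = "ACGT"


@dataclass
class DuplicationThresholds:
    min_coverage: float = 0.70
    min_similarity: float = 0.70
    tandem_max_distance: int = 100_000  # bp between nearest gene ends


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of a codon: per position, the fraction of the 3
    alternative bases giving a synonymous (non-stop) codon. Nonsynonymous
    sites are 3 minus this, so sites always total 3 per codon."""
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TO_AA[alt] == aa and CODON_TO_AA[alt] != "*":
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged with equal weight over all minimal substitution pathways.

    Pathways whose intermediate codons are stops are excluded; if every
    pathway is blocked the average falls back to all pathways. The two counts
    always sum to the number of differing positions.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TO_AA[nxt] == "*" and step < len(order) - 1:
                through_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differences; NaN at saturation."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class NG86Result:
    ka: float
    ks: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def saturated(self) -> bool:
        return math.isnan(self.ka) or math.isnan(self.ks)


def ng86(cds1: str, cds2: str) -> NG86Result:
    """Nei–Gojobori Ka/Ks on an aligned, gap-free codon sequence pair."""
    if len(cds1) != len(cds2):
        raise ValueError("ng86 requires equal-length sequences")
    if len(cds1) < 3 or len(cds1) % 3:
        raise ValueError("ng86 requires length >= 3 and divisible by 3")
    s1 = s2 = sd = nd = 0.0
    n_codons = len(cds1) // 3
    for k in range(n_codons):
        c1, c2 = cds1[3 * k: 3 * k + 3], cds2[3 * k: 3 * k + 3]
        if CODON_TO_AA.get(c1) == "*" or CODON_TO_AA.get(c2) == "*":
            raise ValueError(f"internal stop codon at codon {k + 1}")
        if c1 not in CODON_TO_AA or c2 not in CODON_TO_AA:
            raise ValueError(f"ambiguous codon at codon {k + 1}")
        s1 += syn_sites(c1)
        s2 += syn_sites(c2)
        d = pathway_counts(c1, c2)
        sd += d[0]
        nd += d[1]
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    return NG86Result(ka=jukes_cantor(pn), ks=jukes_cantor(ps),
                      syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd)


def kaks_ratio(ka: float, ks: float) -> float | None:
    """Ka/Ks; undefined (None) when Ks is 0 or either rate is saturated."""
    if math.isnan(ka) or math.isnan(ks):
        return None
    if ks == 0:
        return None
    return ka / ks


def duplication_time(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Duplication age in Mya: T = Ks / (2·rate) · 1e-6."""
    if ks < 0 or math.isnan(ks):
        raise ValueError("Ks must be nonnegative and finite")
    return ks / (2.0 * rate) / 1e6


def codon_align(protein_alignment: Alignment, cds1: str, cds2: str) -> tuple[str, str]:
    """Expand an aligned protein pair to its codon alignment.

    Each aligned residue column becomes its source codon; columns with a gap
    or an ambiguous base are dropped, so the output length is divisible by 3.
    The translated CDSs (stop trimmed) must match the aligned proteins.
    """
    p1 = protein_alignment.aligned_a.replace("-", "")
    p2 = protein_alignment.aligned_b.replace("-", "")
    offsets = []
    for which, (prot, cds) in enumerate([(p1, cds1), (p2, cds2)], start=1):
        trans = translate_cds(cds)
        off = trans.find(prot)  # local alignments may start mid-protein
        if off < 0:
            for i, (x, y) in enumerate(zip(prot, trans)):
                if x != y:
                    raise ValueError(
                        f"sequence {which}: CDS translation differs from aligned "
                        f"protein at residue {i + 1} ({y!r} vs {x!r})")
            raise ValueError(f"sequence {which}: CDS/protein length mismatch")
        offsets.append(off)
    out1, out2 = [], []
    i, j = offsets
    for x, y in zip(protein_alignment.aligned_a, protein_alignment.aligned_b):
        cod1 = cds1[3 * i: 3 * i + 3] if x != "-" else None
        cod2 = cds2[3 * j: 3 * j + 3] if y != "-" else None
        if x != "-":
            i += 1
        if y != "-":
            j += 1
        if cod1 is None or cod2 is None:
            continue
        if any(b not in BASES for b in cod1 + cod2):
            continue
        out1.append(cod1)
        out2.append(cod2)
    return "".join(out1), "".join(out2)


@dataclass
class DuplicatePair:
    """Two family members retained by the 70/70 rule, with Ka/Ks and age."""

    gene1: FamilyMember
    gene2: FamilyMember
    coverage: float
    similarity: float
    dup_type: str = ""
    ka: float = math.nan
    ks: float = math.nan
    ratio: float | None = None
    time_mya: float = math.nan


def detect_duplicates(members: Sequence[FamilyMember],
                      thresholds: DuplicationThresholds | None = None,
                      scoring=None) -> list[DuplicatePair]:
    """All unordered within-cultivar member pairs passing the 70/70 rule.

    Coverage is (aligned residue columns) / (longer protein length) and
    similarity is identity over aligned columns, both from a global affine-gap
    alignment. Members without a protein sequence are excluded with a warning.
    Pairs are reported once, ordered lexicographically by name.
    """
    import logging
    thresholds = thresholds or DuplicationThresholds()
    usable = []
    for m in members:
        if not m.gene.protein_sequence:
            logging.getLogger("panfam").warning(
                "detect_duplicates: %s has no protein sequence, excluded", m.name)
            continue
        usable.append(m)
    usable = sorted(usable, key=lambda m: m.name)
    out = []
    for m1, m2 in itertools.combinations(usable, 2):
        if m1.gene.cultivar != m2.gene.cultivar:
            continue
        aln = needleman_wunsch(m1.gene.protein_sequence, m2.gene.protein_sequence,
                               scoring=scoring)
        longer = max(len(m1.gene.protein_sequence), len(m2.gene.protein_sequence))
        coverage = aln.aligned_pairs / longer
        if coverage >= thresholds.min_coverage and aln.identity >= thresholds.min_similarity:
            out.append(DuplicatePair(gene1=m1, gene2=m2,
                                     coverage=coverage, similarity=aln.identity))
    return out


def gene_gap(g1: GeneRecord, g2: GeneRecord) -> int | None:
    """Base pairs strictly between two genes' nearest ends (None if on
    different chromosomes; 0 when they touch or overlap)."""
    if g1.chromosome != g2.chromosome:
        return None
    first, second = (g1, g2) if g1.start <= g2.start else (g2, g1)
    return max(0, second.start - first.end - 1)


def classify_duplication(g1: GeneRecord, g2: GeneRecord,
                         tandem_max_distance: int = 100_000) -> str:
    """Tandem iff same chromosome and inter-gene gap <= the distance cutoff
    (inclusive boundary); segmental otherwise."""
    gap = gene_gap(g1, g2)
    if gap is not None and gap <= tandem_max_distance:
        return "tandem"
    return "segmental"


def analyze_duplicates(members: Sequence[FamilyMember],
                       thresholds: DuplicationThresholds | None = None,
                       rate: float = DEFAULT_CLOCK_RATE,
                       scoring=None) -> list[DuplicatePair]:
    """Full duplicate-pair analysis: 70/70 detection, tandem/segmental
    classification, NG86 Ka/Ks on the codon alignment, and dating."""
    thresholds = thresholds or DuplicationThresholds()
    pairs = detect_duplicates(members, thresholds, scoring=scoring)
    for p in pairs:
        p.dup_type = classify_duplication(p.gene1.gene, p.gene2.gene,
                                          thresholds.tandem_max_distance)
        if p.gene1.gene.cds_sequence and p.gene2.gene.cds_sequence:
            aln = needleman_wunsch(p.gene1.gene.protein_sequence,
                                   p.gene2.gene.protein_sequence, scoring=scoring)
            c1, c2 = codon_align(aln, p.gene1.gene.cds_sequence,
                                 p.gene2.gene.cds_sequence)
            res = ng86(c1, c2)
            p.ka, p.ks = res.ka, res.ks
            p.ratio = kaks_ratio(res.ka, res.ks)
            p.time_mya = duplication_time(res.ks, rate) if not math.isnan(res.ks) else math.nan
    return pairs


def duplicate_table(pairs: Iterable[DuplicatePair]) -> pd.DataFrame:
    """Duplicate pairs as the standard output table (Ka/Ks and time rounded
    to 2 decimals, Ka and Ks to 4; full precision stays on the objects)."""
    rows = []
    for p in pairs:
        rows.append({
            "Gene 1": p.gene1.name, "Gene 2": p.gene2.name,
            "Ka": round(p.ka, 4) if not math.isnan(p.ka) else math.nan,
            "Ks": round(p.ks, 4) if not math.isnan(p.ks) else math.nan,
            "Ka/Ks": round(p.ratio, 2) if p.ratio is not None else math.nan,
            "Time (MYA)": round(p.time_mya, 2) if not math.isnan(p.time_mya) else math.nan,
            "Duplication Type": p.dup_type.capitalize(),
        })
    return pd.DataFrame(rows, columns=DUPLICATE_TABLE_COLUMNS)
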