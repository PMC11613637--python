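"""Family membership scanning: local-alignment homology search against seed
queries, a domain-presence check, and chromosomal-order naming.

The search is an explicit Smith–Waterman scan (BLOSUM62, affine gaps) of every
proteome entry against every query; candidates must reach minimum identity and
query coverage. Membership is then decided by the domain check: a log-odds
position-specific scoring matrix (PSSM) built from a bundled seed alignment of
the family's DNA-binding domain, slid over the candidate protein. The bundled
AP2-like seed alignment is synthetic (see data/ap2_seed.synthetic.faa); the
profile is calibrated at build time so that all seed sequences pass and
shuffled versions of the consensus fail.

Accepted members are named ``<cultivar>_<FAM><k>`` by chromosomal order within
each cultivar (numeric chromosome order, then start coordinate).
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .align import Alignment, smith_waterman
from .genome_model import GeneRecord, chromosome_sort_key, read_fasta

logger = logging.getLogger("panfam")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

#: Default membership thresholds. Deliberately loose: the domain check is the
#: decisive filter, the alignment scan only pre-selects homologs.
DEFAULT_MIN_IDENTITY = 0.40
DEFAULT_MIN_COVERAGE = 0.50


@dataclass
class DomainProfile:
    """Log-odds PSSM over a seed alignment of a protein domain.

    ``matrix[k, a]`` is log2(p_k(a) / background) for alignment column k and
    residue index a in ``AA20``; a window passes when its summed score reaches
    ``threshold`` over the full ``min_span`` columns.
    """

    name: str
    matrix: np.ndarray  # (L, 20) log-odds
    threshold: float
    min_span: int

    @classmethod
    def from_seed_alignment(cls, sequences: list[str], name: str = "AP2",
                            pseudocount: float = 0.5,
                            calibration_shuffles: int = 1000,
                            seed: int = 0) -> "DomainProfile":
        """Build and calibrate a profile from an ungapped seed alignment.

        The acceptance threshold sits a quarter of the way from the highest
        score of ``calibration_shuffles`` shuffled consensus sequences up to
        the lowest-scoring seed sequence: every seed passes, every shuffle
        fails, and family members that have drifted somewhat further than the
        seed variants still clear the bar.
        """
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("seed alignment sequences must have equal length")
        L = lengths.pop()
        counts = np.full((L, 20), pseudocount)
        for s in sequences:
            for k, aa in enumerate(s):
                if aa in _AA_INDEX:
                    counts[k, _AA_INDEX[aa]] += 1.0
        probs = counts / counts.sum(axis=1, keepdims=True)
        matrix = np.log2(probs / 0.05)
        prof = cls(name=name, matrix=matrix, threshold=-math.inf, min_span=L)
        seed_scores = [prof._window_score(s, 0) for s in sequences]
        consensus = prof.consensus()
        rng = random.Random(seed)
        shuffle_scores = []
        for _ in range(calibration_shuffles):
            chars = list(consensus)
            rng.shuffle(chars)
            shuffle_scores.append(prof._window_score("".join(chars), 0))
        prof.threshold = float(max(shuffle_scores)
                               + 0.25 * (min(seed_scores) - max(shuffle_scores)))
        if prof.threshold >= min(seed_scores):
            raise ValueError("profile threshold not attainable by seed sequences")
        return prof

    def consensus(self) -> str:
        return "".join(AA20[int(i)] for i in self.matrix.argmax(axis=1))

    def _window_score(self, protein: str, offset: int) -> float:
        total = 0.0
        for k in range(self.min_span):
            aa = protein[offset + k]
            if aa in _AA_INDEX:
                total += self.matrix[k, _AA_INDEX[aa]]
            # unknown residues contribute 0 (background odds)
        return total

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# PSSM {self.name} log2-odds, threshold={float(self.threshold):.10g}, "
                     f"min_span={self.min_span}\n")
            fh.write("pos\t" + "\t".join(AA20) + "\n")
            for k in range(self.min_span):
                fh.write(str(k + 1) + "\t" +
                         "\t".join(f"{v:.6f}" for v in self.matrix[k]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "AP2") -> "DomainProfile":
        with open(path) as fh:
            header = fh.readline()
            threshold = float(header.split("threshold=")[1].split(",")[0])
            fh.readline()
            rows = [[float(x) for x in line.split("\t")[1:]] for line in fh if line.strip()]
        matrix = np.asarray(rows)
        return cls(name=name, matrix=matrix, threshold=threshold, min_span=len(rows))


def bundled_ap2_profile() -> DomainProfile:
    """The packaged (synthetic) AP2-like domain profile."""
    with resources.files("panfam.data").joinpath("ap2_seed.synthetic.faa").open() as fh:
        seqs, cur = {}, None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                cur = line[1:].split()[0]
                seqs[cur] = ""
            elif cur:
                seqs[cur] += line
    return DomainProfile.from_seed_alignment(list(seqs.values()), name="AP2")


def check_domain(protein: str, profile: DomainProfile) -> tuple[bool, tuple[int, int] | None]:
    """Slide the profile over ``protein``; present iff some full-length window
    scores at least the profile threshold. Returns the best window's 1-based
    inclusive span (best-scoring window even when absent, or None if the
    protein is shorter than the profile)."""
    L = profile.min_span
    if len(protein) < L:
        return False, None
    best_score, best_off = -math.inf, 0
    for off in range(len(protein) - L + 1):
        s = profile._window_score(protein, off)
        if s > best_score:
            best_score, best_off = s, off
    present = best_score >= profile.threshold
    return present, (best_off + 1, best_off + L)


@dataclass
class Candidate:
    """A proteome entry passing the alignment thresholds against some query."""

    subject_id: str
    alignment: Alignment
    query_coverage: float
    domain_present: bool = False
    domain_span: tuple[int, int] | None = None


def scan_family(queries: Mapping[str, str], proteome: Mapping[str, str],
                min_identity: float = DEFAULT_MIN_IDENTITY,
                min_coverage: float = DEFAULT_MIN_COVERAGE,
                scoring=None) -> list[Candidate]:
    """Find proteome entries homologous to any query.

    For each proteome entry the best-scoring local alignment over all queries
    is kept; the entry is a candidate when that alignment reaches both
    ``min_identity`` (over aligned columns) and ``min_coverage`` (aligned
    query span / query length). An empty proteome yields an empty list.
    """
    if not queries:
        raise ValueError("scan_family requires at least one query")
    out: list[Candidate] = []
    for sid, sseq in proteome.items():
        best: Alignment | None = None
        best_cov = 0.0
        for qid, qseq in queries.items():
            aln = smith_waterman(qseq, sseq, scoring=scoring)
            if best is None or aln.score > best.score:
                aln.query_id, aln.subject_id = qid, sid
                best = aln
                qlen = len(qseq)
                span = aln.query_span
                best_cov = (span[1] - span[0] + 1) / qlen if aln.score > 0 else 0.0
        if best is not None and best.score > 0 \
                and best.identity >= min_identity and best_cov >= min_coverage:
            out.append(Candidate(subject_id=sid, alignment=best, query_coverage=best_cov))
    return out


def apply_domain_filter(candidates: list[Candidate], proteome: Mapping[str, str],
                        profile: DomainProfile) -> list[Candidate]:
    """Keep candidates whose protein contains the complete domain."""
    kept = []
    for c in candidates:
        present, span = check_domain(proteome[c.subject_id], profile)
        c.domain_present, c.domain_span = present, span
        if present:
            kept.append(c)
    return kept


@dataclass
class FamilyMember:
    """A gene accepted into the family, with its chromosomal-order name."""

    name: str
    gene: GeneRecord
    alignment: Alignment | None = None
    domain_span: tuple[int, int] | None = None


def assign_names(candidates_by_cultivar: Mapping[str, list[GeneRecord]],
                 family: str = "FAM",
                 extras: Mapping[str, dict] | None = None) -> list[FamilyMember]:
    """Name members ``<cultivar>_<family><k>`` by chromosomal order.

    Within each cultivar, genes are sorted by numeric chromosome order then
    start (ties: end, then gene_id) and numbered densely from 1. Renaming is
    idempotent — names depend only on coordinates.
    """
    members: list[FamilyMember] = []
    for cultivar in sorted(candidates_by_cultivar):
        genes = sorted(candidates_by_cultivar[cultivar], key=GeneRecord.sort_key)
        for k, gene in enumerate(genes, start=1):
            info = (extras or {}).get(gene.gene_id, {})
            members.append(FamilyMember(
                name=f"{cultivar}_{family}{k}", gene=gene,
                alignment=info.get("alignment"),
                domain_span=info.get("domain_span"),
            ))
    return members
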