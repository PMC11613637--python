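"""Physicochemical protein properties: length, MW, pI, instability, aliphatic
index and GRAVY — the per-member columns of the family characterization table.

All calculators follow the classical definitions used by protein property
servers: average-isotope residue masses for molecular weight, the Bjellqvist
pKa set with bisection for the isoelectric point, the Guruprasad dipeptide
weight table for the instability index, Ikai's aliphatic index, and the
Kyte–Doolittle hydropathy scale for GRAVY. The published dipeptide and
hydropathy tables are taken from Bio.SeqUtils.ProtParamData; the summation
logic here is independent of Biopython's calculators.

Residue ``X`` (unknown) is excluded from the pI/AI/GRAVY sums and contributes
the mean residue mass to MW, with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV, kd as KYTE_DOOLITTLE

logger = logging.getLogger("panfam")

WATER_MW = 18.01524  # Da, lost per peptide bond

#: Average-isotope residue masses (free amino acid minus one water), Da.
RESIDUE_MASSES = {aa: w - WATER_MW for aa, w in protein_weights.items()}
MEAN_RESIDUE_MASS = sum(RESIDUE_MASSES[a] for a in "ACDEFGHIKLMNPQRSTVWY") / 20.0

#: Bjellqvist pKa values for the ionizable groups; the terminal pKas are
#: residue-specific where Bjellqvist measured them.
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
NTERM_PKS = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
             "V": 7.44, "E": 7.7}
CTERM_PKS = {"D": 4.55, "E": 4.75}

_warned_x = False


def _warn_x() -> None:
    global _warned_x
    if not _warned_x:
        _warned_x = True
        logger.warning("protein_props: residue X excluded from pI/AI/GRAVY, "
                       "mean residue mass used for MW")


@dataclass
class ProteinProperties:
    length: int
    molecular_weight: float
    isoelectric_point: float
    instability_index: float
    aliphatic_index: float
    gravy: float

    def as_table_row(self) -> dict[str, float]:
        return {"AA": self.length, "MW": self.molecular_weight,
                "Ip": self.isoelectric_point, "II": self.instability_index,
                "AI": self.aliphatic_index, "GRAVY": self.gravy}


def molecular_weight(seq: str) -> float:
    """Average-isotope molecular weight in Da: residue masses plus one water."""
    if not seq:
        raise ValueError("molecular_weight: empty sequence")
    total = WATER_MW
    for aa in seq:
        if aa == "X" or aa not in RESIDUE_MASSES:
            _warn_x()
            total += MEAN_RESIDUE_MASS
        else:
            total += RESIDUE_MASSES[aa]
    return total


def net_charge(seq: str, ph: float) -> float:
    """Net charge at ``ph`` from Henderson–Hasselbalch over ionizable groups
    (D, E, C, Y, H, K, R plus the two termini), Bjellqvist pKa set."""
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    pos = sum(n / (1.0 + 10.0 ** (ph - POSITIVE_PKS[aa]))
              for aa, n in counts.items() if aa in POSITIVE_PKS)
    nterm_pk = NTERM_PKS.get(seq[0], POSITIVE_PKS["Nterm"])
    pos += 1.0 / (1.0 + 10.0 ** (ph - nterm_pk))
    neg = sum(n / (1.0 + 10.0 ** (NEGATIVE_PKS[aa] - ph))
              for aa, n in counts.items() if aa in NEGATIVE_PKS)
    cterm_pk = CTERM_PKS.get(seq[-1], NEGATIVE_PKS["Cterm"])
    neg += 1.0 / (1.0 + 10.0 ** (cterm_pk - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so bisection converges; iteration
    stops when |charge| < ``tol``.
    """
    if not seq:
        raise ValueError("isoelectric_point: empty sequence")
    if "X" in seq:
        _warn_x()
        seq = seq.replace("X", "")
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(100):
        q = net_charge(seq, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
        ph = (lo + hi) / 2.0
    return ph


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) · Σ DIWV over the L−1 dipeptides."""
    if len(seq) < 2:
        raise ValueError("instability_index requires length >= 2")
    total = 0.0
    for i in range(len(seq) - 1):
        total += DIWV.get(seq[i], {}).get(seq[i + 1], 0.0)
    return 10.0 / len(seq) * total


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)),
    with X(·) the mole percent of the residue."""
    if not seq:
        raise ValueError("aliphatic_index: empty sequence")
    if "X" in seq:
        _warn_x()
        seq = seq.replace("X", "")
        if not seq:
            return 0.0
    n = len(seq)
    pct = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return pct["A"] + 2.9 * pct["V"] + 3.9 * (pct["I"] + pct["L"])


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over residues."""
    if not seq:
        raise ValueError("gravy: empty sequence")
    kept = [aa for aa in seq if aa in KYTE_DOOLITTLE]
    if len(kept) < len(seq):
        _warn_x()
        if not kept:
            return 0.0
    return sum(KYTE_DOOLITTLE[aa] for aa in kept) / len(kept)


def compute_properties(seq: str) -> ProteinProperties:
    """All family-table properties for one protein sequence."""
    return ProteinProperties(
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        isoelectric_point=isoelectric_point(seq),
        instability_index=instability_index(seq),
        aliphatic_index=aliphatic_index(seq),
        gravy=gravy(seq),
    )
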