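"""FPKM expression profiling and threshold-based stress-response labels.

FPKM[g, s] = counts[g, s] · 1e9 / (length[g] · total[s]) with gene length in
bp and total the sample's mapped-fragment count. Response classification is a
descriptive fold-change rule, not a differential-expression test: a gene is
*induced* in a contrast when log2((mean_treat + ε)/(mean_ctrl + ε)) reaches
the threshold and the treatment mean is expressed at all, *repressed*
symmetrically, *not_expressed* when both means sit below the expression
floor, and *unchanged* otherwise. ε defaults to 0.01 FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RESPONSE_LABELS = ("induced", "repressed", "unchanged", "not_expressed")


@dataclass
class ExpressionDesign:
    """Sample metadata: sample -> condition, plus (control, treatment)
    condition pairs defining the contrasts to classify."""

    condition: dict[str, str]
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.condition.items() if c == condition]


def fpkm(counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series,
         totals: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    lengths = pd.Series(lengths).reindex(counts.index)
    totals = pd.Series(totals).reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing lengths for {list(lengths[lengths.isna()].index)}")
    if totals.isna().any():
        raise ValueError(f"missing totals for {list(totals[totals.isna()].index)}")
    if (lengths <= 0).any() or (totals <= 0).any():
        raise ValueError("gene lengths and library totals must be positive")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def classify_response(matrix: pd.DataFrame, design: ExpressionDesign,
                      lfc_threshold: float = 1.0, min_expr: float = 1.0,
                      epsilon: float = 0.01) -> pd.DataFrame:
    """Per-gene response label for each (control, treatment) contrast.

    ``matrix`` is genes × samples in FPKM. Labels are invariant to sample
    order within a condition (only condition means enter the rule).
    """
    if not design.contrasts:
        raise ValueError("design defines no contrasts")
    out = {}
    for ctrl, treat in design.contrasts:
        ctrl_samples = design.samples_for(ctrl)
        treat_samples = design.samples_for(treat)
        if not ctrl_samples or not treat_samples:
            raise ValueError(f"contrast {ctrl} vs {treat}: empty sample set")
        mean_c = matrix[ctrl_samples].mean(axis=1)
        mean_t = matrix[treat_samples].mean(axis=1)
        lfc = np.log2((mean_t + epsilon) / (mean_c + epsilon))
        labels = pd.Series("unchanged", index=matrix.index)
        labels[(lfc >= lfc_threshold) & (mean_t >= min_expr)] = "induced"
        labels[(-lfc >= lfc_threshold) & (mean_c >= min_expr)] = "repressed"
        labels[(mean_c < min_expr) & (mean_t < min_expr)] = "not_expressed"
        out[f"{treat}_vs_{ctrl}"] = labels
    return pd.DataFrame(out)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_lengths_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_design_tsv(path) -> ExpressionDesign:
    """Design TSV: columns sample, condition; contrast rows are encoded in a
    '#contrast control treatment' comment header block."""
    contrasts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#contrast"):
                _, ctrl, treat = line.strip().split("\t")
                contrasts.append((ctrl, treat))
    df = pd.read_csv(path, sep="\t", comment="#")
    return ExpressionDesign(condition=dict(zip(df["sample"], df["condition"])),
                            contrasts=contrasts)
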