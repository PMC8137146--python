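"""Proximity-labelling (TMT) candidate selection.

A protein is a candidate lost interactor iff it is not a known contaminant,
is supported by at least 5 peptides, and its mean depletion/control abundance
ratio across replicates is strictly below 0.70.  Candidates are ranked most
depleted first; ties break lexicographically on protein id so output order
is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import AnalysisParams

__all__ = ["ProteinQuant", "load_quant_table", "filter_candidates", "write_quant_table"]


@dataclass
class ProteinQuant:
    protein_id: str
    peptide_count: int
    ratios: tuple[float, ...]  # per-replicate abundance ratios; NaN = missing
    contaminant: bool = False
    candidate: bool | None = None

    def __post_init__(self) -> None:
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be >= 0")
        for r in self.ratios:
            if not math.isnan(r) and r < 0:
                raise ValueError(f"{self.protein_id}: negative abundance ratio")

    @property
    def observed_ratios(self) -> tuple[float, ...]:
        return tuple(r for r in self.ratios if not math.isnan(r))

    @property
    def mean_ratio(self) -> float:
        obs = self.observed_ratios
        if not obs:
            return float("nan")
        if len(set(obs)) == 1:  # exact on ties so boundary values stay boundary
            return obs[0]
        return float(math.fsum(obs) / len(obs))


def load_quant_table(
    path: str | Path, contaminant_list: Iterable[str] = ()
) -> list[ProteinQuant]:
    """Read a TSV with protein_id, peptide_count and >= 1 ratio_* columns.

    Missing ratio cells stay NaN and are excluded from the mean but keep
    their column position.  Contaminants are flagged by exact identifier
    membership in the supplied list.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "peptide_count"}
    if not required <= set(df.columns):
        raise ValueError(f"quant table must have columns {sorted(required)}")
    ratio_cols = [c for c in df.columns if c.startswith("ratio")]
    if not ratio_cols:
        raise ValueError("quant table has no ratio columns")
    contaminants = set(contaminant_list)
    out: list[ProteinQuant] = []
    for row in df.itertuples(index=False):
        ratios = tuple(float(getattr(row, c)) for c in ratio_cols)
        out.append(
            ProteinQuant(
                protein_id=str(row.protein_id),
                peptide_count=int(row.peptide_count),
                ratios=ratios,
                contaminant=str(row.protein_id) in contaminants,
            )
        )
    return out


def filter_candidates(
    quants: Sequence[ProteinQuant],
    params: AnalysisParams | None = None,
    min_observed_ratios: int = 2,
) -> list[ProteinQuant]:
    """Apply the candidate filter and return candidates ranked by depletion.

    Gates, all strict as published: not a contaminant; peptide_count >= 5
    (< 5 discarded); mean abundance ratio < 0.70 (0.70 exactly is excluded);
    and at least ``min_observed_ratios`` replicate ratios observed.
    """
    params = params or AnalysisParams()
    candidates: list[ProteinQuant] = []
    for q in quants:
        ok = (
            not q.contaminant
            and q.peptide_count >= params.min_peptides
            and len(q.observed_ratios) >= min_observed_ratios
            and q.mean_ratio < params.ratio_threshold
        )
        q.candidate = ok
        if ok:
            candidates.append(q)
    return sorted(candidates, key=lambda q: (q.mean_ratio, q.protein_id))


def write_quant_table(quants: Sequence[ProteinQuant], path: str | Path) -> None:
    rows = [
        {
            "protein_id": q.protein_id,
            "peptide_count": q.peptide_count,
            "mean_ratio": q.mean_ratio,
            "n_observed": len(q.observed_ratios),
            "contaminant": q.contaminant,
            "candidate": bool(q.candidate),
        }
        for q in quants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
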