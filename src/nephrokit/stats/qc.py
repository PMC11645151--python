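"""Single-cell QC filtering.

Cells pass when 500 <= genes detected <= 5000 and the mitochondrial
fraction is below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

GENES_MIN = 500
GENES_MAX = 5000
MITO_MAX = 0.5


@dataclass(frozen=True)
class CellQCRecord:
    genes_detected: int
    mito_fraction: float

    def __post_init__(self):
        if self.genes_detected < 0:
            raise ValueError("gene count must be >= 0")
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValueError("mitochondrial fraction must lie in [0, 1]")


@dataclass(frozen=True)
class QCFilterSummary:
    n_input: int
    n_kept: int
    n_low_genes: int
    n_high_genes: int
    n_high_mito: int


def scrna_qc_filter(records: Sequence[CellQCRecord],
                    genes_min: int = GENES_MIN, genes_max: int = GENES_MAX,
                    mito_max: float = MITO_MAX):
    """Indices of cells passing QC plus per-reason exclusion counts.

    A cell can be excluded for more than one reason; each reason counter
    counts every cell failing that bound.
    """
    kept: list[int] = []
    low = high = mito = 0
    for i, rec in enumerate(records):
        ok = True
        if rec.genes_detected < genes_min:
            low += 1
            ok = False
        if rec.genes_detected > genes_max:
            high += 1
            ok = False
        if rec.mito_fraction >= mito_max:
            mito += 1
            ok = False
        if ok:
            kept.append(i)
    return kept, QCFilterSummary(len(records), len(kept), low, high, mito)
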