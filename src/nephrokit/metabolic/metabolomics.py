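"""Spatial-metabolomics matrix preprocessing.

Missing abundances are treated as below-detection-limit and imputed at
20% of the per-metabolite observed minimum; duplicate tissue sections of
the same participant are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites relative abundances (NaN = missing).

    ``abundances`` is a DataFrame indexed by section id with metabolite
    columns; ``participant`` maps each section to its participant so
    duplicate sections can be averaged.
    """

    abundances: pd.DataFrame
    participant: pd.Series

    def __post_init__(self):
        if not self.abundances.index.equals(self.participant.index):
            raise ValueError("participant map must cover exactly the sample index")
        observed = self.abundances.to_numpy(dtype=float)
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValueError("abundances must be nonnegative where present")


def impute_metabolites(matrix: MetaboliteMatrix,
                       fraction: float = 0.2) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Fill missing entries with ``fraction`` x per-metabolite observed minimum.

    Returns (imputed matrix, boolean imputation mask).  A metabolite with
    no observed value at all cannot be imputed and raises.
    """
    df = matrix.abundances
    mask = df.isna()
    fully_missing = [c for c in df.columns if mask[c].all()]
    if fully_missing:
        raise ValueError(f"metabolites with no observed values: {fully_missing}")
    fills = df.min(axis=0, skipna=True) * fraction
    imputed = df.fillna(fills)
    return MetaboliteMatrix(imputed, matrix.participant), mask


def average_duplicates(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Average duplicate sections per participant; singletons pass through."""
    grouped = matrix.abundances.groupby(matrix.participant).mean()
    participants = pd.Series(grouped.index, index=grouped.index)
    return MetaboliteMatrix(grouped, participants)


def atrophic_tubule_fraction(n_atrophic: int, n_total: int) -> float:
    """Percent of atrophic tubules among all tubules in an ROI."""
    if n_total <= 0:
        raise ValueError("total tubule count must be > 0")
    if not 0 <= n_atrophic <= n_total:
        raise ValueError("atrophic count must lie in [0, n_total]")
    return 100.0 * n_atrophic / n_total
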