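"""Character coding: outlier grouping and the binary cladistic matrix.

Two distinct codings live here.  First, raw near-two-valued counts are
grouped into 0/1 states by a per-character threshold (outliers and rare
values join their nearest common value) so they can be analysed as
binomial variables.  Second, the strains × characters matrix of estimated
per-strain means — significant characters only — is centred and scaled
per character, and the *sign* of each scaled mean becomes the cladistic
state: strains below the across-strain average get state 0, strains above
it state 1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .charstats import DivergenceTest, StrainProfile
from .data_io import BinaryTaxonMatrix, ThresholdRule, ValidationError

__all__ = [
    "ThresholdRule",
    "binarize",
    "strain_mean_frame",
    "scale_columns",
    "build_matrix",
]


def binarize(values: Sequence[int], rule: ThresholdRule) -> np.ndarray:
    """Group raw integer states into two states by a monotone threshold."""
    v = np.asarray(values)
    if (v < 0).any():
        raise ValidationError("raw states must be non-negative")
    return rule.apply(v)


def strain_mean_frame(profiles: Mapping[str, StrainProfile],
                      tests: Sequence[DivergenceTest]) -> pd.DataFrame:
    """Strains × significant-characters matrix of response-scale means.

    Every strain must have an estimate for every significant character
    (no silent imputation): a missing cell is an error naming it.
    """
    sig = sorted(t.character_id for t in tests if t.significant)
    if not sig:
        return pd.DataFrame()
    strains = sorted({s for cid in sig for s in profiles[cid].per_strain.index})
    data = {}
    for cid in sig:
        means = profiles[cid].per_strain["mean"]
        for s in strains:
            if s not in means.index:
                raise ValidationError(
                    f"strain {s} has no estimate for significant character {cid}"
                )
        data[cid] = [float(means[s]) for s in strains]
    return pd.DataFrame(data, index=strains)


def scale_columns(frame: pd.DataFrame, drop_constant: bool = False
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Centre each column to mean 0 and scale to sd 1 (n−1) over strains.

    Constant columns (sd 0) cannot be standardised; they are either
    dropped or kept as all-zero columns, and reported either way.
    """
    out = {}
    constant = []
    for cid in frame.columns:
        x = frame[cid].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0.0:
            constant.append(cid)
            if drop_constant:
                continue
            out[cid] = np.zeros_like(x)
        else:
            out[cid] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=frame.index), constant


def build_matrix(profiles: Mapping[str, StrainProfile],
                 tests: Sequence[DivergenceTest]) -> BinaryTaxonMatrix:
    """Code the cladistic 0/1 matrix from scaled per-strain means.

    Restricted to significant characters; per character the strain means
    are centred by their unweighted average and the state is 1 exactly
    where the scaled mean is strictly above 0 ("lower than the average
    mean" codes 0, and the boundary goes with not-greater).  Columns that
    are constant across strains are flagged uninformative.
    """
    means = strain_mean_frame(profiles, tests)
    if means.empty:
        raise ValidationError("no significant characters to code")
    scaled, constant = scale_columns(means, drop_constant=False)
    states = (scaled.to_numpy() > 0.0).astype(int)
    return BinaryTaxonMatrix(
        taxa=list(means.index),
        characters=list(means.columns),
        states=states,
        source_means=scaled.to_numpy(),
        uninformative=constant,
    )
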