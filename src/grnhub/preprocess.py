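"""Array preprocessing: flag filtering, loess normalization, z-panels.

The chain mirrors standard single-channel microarray practice: drop probes
that fail QC on too many arrays, loess-normalize each array against a
virtual reference (the per-gene median across arrays) in M-A space, then —
for the knockdown panel — express every array as within-array z-scores of
log2 ratios versus the virtual median array.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import DisruptantPanel, ExpressionMatrix


def filter_flags(
    matrix: ExpressionMatrix, min_good_fraction: float = 0.9
) -> ExpressionMatrix:
    """Keep genes flagged "Good" on at least ``min_good_fraction`` of arrays.

    Gene order is preserved.  Raises if the matrix carries no flags, so a
    caller who wants to skip QC must do so explicitly.
    """
    if matrix.flags is None:
        raise ValueError(
            "matrix has no quality flags; skip filter_flags explicitly if the "
            "data were already QC'd"
        )
    good_frac = (matrix.flags == "Good").mean(axis=1)
    keep = good_frac >= min_good_fraction
    return ExpressionMatrix(
        values=matrix.values.loc[keep].copy(),
        flags=matrix.flags.loc[keep].copy(),
    )


def loess_normalize(
    matrix: ExpressionMatrix,
    span: float = 0.4,
    min_genes: int = 50,
) -> ExpressionMatrix:
    """Remove intensity-dependent bias per array by M-A loess against a
    virtual reference array.

    For each array, with reference R = per-gene median across arrays,
    M = value - R and A = (value + R) / 2; the loess fit of M on A (degree 1,
    ``span`` fraction of points) is subtracted from the array.  After
    normalization the residual M-vs-A trend is ~0.

    Raises if fewer than ``min_genes`` genes are present (the local fit is
    unreliable on tiny matrices).
    """
    values = matrix.values
    if len(values) < min_genes:
        raise ValueError(
            f"loess normalization needs >= {min_genes} genes, got {len(values)}"
        )
    ref = values.median(axis=1).to_numpy()
    out = values.copy()
    for col in values.columns:
        v = values[col].to_numpy()
        m = v - ref
        a = 0.5 * (v + ref)
        trend = lowess(m, a, frac=span, it=2, return_sorted=False)
        out[col] = v - trend
    return ExpressionMatrix(values=out, flags=matrix.flags)


def to_zpanel(
    matrix: ExpressionMatrix,
    target_map: dict[str, str],
    ddof: int = 1,
) -> DisruptantPanel:
    """Within-array z-scores of log2 ratios versus the virtual median array.

    ratio = value - per-gene median across arrays; per array,
    z = (ratio - mean(ratio)) / sd(ratio) with the sample (n-1) standard
    deviation taken across genes within that array.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("need at least two arrays to form a virtual median array")
    unknown = [a for a in target_map if a not in set(values.columns)]
    if unknown:
        raise ValueError(f"target_map references unknown arrays: {unknown}")
    median = values.median(axis=1)
    ratios = values.sub(median, axis=0)
    sd = ratios.std(axis=0, ddof=ddof)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero ratio variance in array(s): {zero}")
    z = ratios.sub(ratios.mean(axis=0), axis=1).div(sd, axis=1)
    return DisruptantPanel(zvalues=z, target_map=dict(target_map))
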