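"""Concordant-regulation gene selection from a replicated time course.

For each replicate and timepoint, log2 ratios to a reference timepoint
(first or last) are standardized *across genes*, and a gene is selected when
its |z| clears a threshold at a run of adjacent timepoints with a consistent
direction.  The final list is the union of the first-reference and
last-reference selections.

Note on the criterion's sense: selection keeps transcripts with
|z| >= threshold (i.e. z <= -2 or z >= +2 at the default threshold).  The
alternative reading, keeping -2 <= z <= +2, would retain the *unchanged*
transcripts and cannot yield significantly regulated genes.
"""

from __future__ import annotations

import numpy as np

from .containers import TimecourseData, ZScoreCube

REPLICATE_RULES = ("all", "majority", "any")


def timecourse_zscores(tc: TimecourseData, reference: str = "first") -> ZScoreCube:
    """Cross-gene z-scores of log2 ratios to the reference timepoint.

    ratio(g, r, t) = x(g, r, t) - x(g, r, ref); within each (replicate,
    timepoint) slice the ratios are centred and scaled by the sample (n-1)
    standard deviation across genes.  The reference slice is identically
    zero and excluded from standardization.

    Raises if any non-reference slice has zero cross-gene variance, naming
    the replicate and timepoint.
    """
    if reference not in ("first", "last"):
        raise ValueError("reference must be 'first' or 'last'")
    ref_idx = 0 if reference == "first" else tc.n_timepoints - 1
    ratios = tc.cube - tc.cube[:, :, ref_idx][:, :, None]
    z = np.zeros_like(ratios)
    for r in range(tc.n_replicates):
        for t in range(tc.n_timepoints):
            if t == ref_idx:
                continue
            slice_ = ratios[:, r, t]
            sd = slice_.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"zero cross-gene variance in replicate "
                    f"{tc.replicate_ids[r]!r} at t={tc.timepoints[t]:g}h"
                )
            z[:, r, t] = (slice_ - slice_.mean()) / sd
    return ZScoreCube(
        z=z,
        gene_ids=list(tc.gene_ids),
        timepoints=tc.timepoints,
        replicate_ids=list(tc.replicate_ids),
        reference=reference,
    )


def _window_hits(
    z: np.ndarray, z_threshold: float, min_adjacent: int, same_sign: bool
) -> np.ndarray:
    """Boolean (genes, replicates, windows, signs): criterion holds over the
    window of ``min_adjacent`` consecutive timepoints for that sign."""
    n_t = z.shape[2]
    n_w = n_t - min_adjacent + 1
    if n_w <= 0:
        return np.zeros(z.shape[:2] + (0, 2), dtype=bool)
    pos = z >= z_threshold
    neg = z <= -z_threshold
    if not same_sign:
        both = pos | neg
        pos = neg = both
    out = np.empty(z.shape[:2] + (n_w, 2), dtype=bool)
    for w in range(n_w):
        sl = slice(w, w + min_adjacent)
        out[:, :, w, 0] = pos[:, :, sl].all(axis=2)
        out[:, :, w, 1] = neg[:, :, sl].all(axis=2)
    return out


def select_concordant(
    zcube: ZScoreCube,
    z_threshold: float = 2.0,
    min_adjacent: int = 2,
    replicate_rule: str = "all",
    same_sign: bool = True,
) -> set[str]:
    """Genes with |z| >= threshold over >= ``min_adjacent`` adjacent
    non-reference timepoints, consistently signed, under ``replicate_rule``.

    The per-replicate criterion is existential: a replicate satisfies it
    when *some* run of ``min_adjacent`` consecutive non-reference
    timepoints has |z| >= threshold with a consistent sign (runs need not
    be aligned across replicates, reflecting that replicate time courses
    peak at slightly different times).  ``replicate_rule`` controls how
    many replicates must satisfy it: "all" (default), "majority" (more
    than half), or "any".
    """
    if min_adjacent < 2:
        raise ValueError("min_adjacent must be >= 2")
    if replicate_rule not in REPLICATE_RULES:
        raise ValueError(f"replicate_rule must be one of {REPLICATE_RULES}")
    ref = zcube.reference_index
    keep = [t for t in range(len(zcube.timepoints)) if t != ref]
    z = zcube.z[:, :, keep]
    hits = _window_hits(z, z_threshold, min_adjacent, same_sign)
    n_rep = z.shape[1]
    rep_ok = hits.any(axis=(2, 3))  # genes x replicates: some run, either sign
    n_ok = rep_ok.sum(axis=1)
    if replicate_rule == "all":
        ok = n_ok == n_rep
    elif replicate_rule == "majority":
        ok = n_ok > n_rep / 2
    else:
        ok = n_ok >= 1
    return {g for g, flag in zip(zcube.gene_ids, ok) if flag}


def concordant_union(
    tc: TimecourseData,
    z_threshold: float = 2.0,
    min_adjacent: int = 2,
    replicate_rule: str = "all",
    same_sign: bool = True,
) -> set[str]:
    """Union of the first-reference and last-reference concordant selections."""
    out: set[str] = set()
    for reference in ("first", "last"):
        zc = timecourse_zscores(tc, reference=reference)
        out |= select_concordant(
            zc,
            z_threshold=z_threshold,
            min_adjacent=min_adjacent,
            replicate_rule=replicate_rule,
            same_sign=same_sign,
        )
    return out
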