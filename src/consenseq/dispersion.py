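"""Gene-wise negative-binomial dispersion by method of moments, with
shrinkage toward a common value.

For each replicate group (treatment, timepoint) the counts are first put on
a common library scale; the NB variance contract Var = mu + phi*mu^2 then
gives a per-group moment estimate phi = (s^2 - c*m) / m^2, where the factor
c corrects the Poisson term for the rescaling. Group estimates are pooled
across groups weighted by residual degrees of freedom, clamped at zero, and
shrunk toward the across-gene median with a fixed prior weight — small
per-gene residual degrees of freedom make raw tagwise estimates extremely
noisy, and the shrinkage mirrors the common-dispersion squeezing used by
count-based DE tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, SampleSheet, ValidationError

__all__ = ["estimate_dispersions"]


def estimate_dispersions(
    matrix: CountMatrix,
    sheet: SampleSheet,
    samples: list[str] | None = None,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-gene dispersion estimates.

    Returns a DataFrame indexed by gene with columns ``phi_raw``,
    ``phi_shrunk`` and ``common_phi``. Groups are the (treatment, timepoint)
    cells of ``samples`` (default: all samples); every group must have at
    least two replicates.
    """
    sheet.validate_against(matrix)
    if samples is None:
        samples = list(matrix.sample_ids)
    sub = sheet.table.loc[samples]
    libs = matrix.lib_sizes[samples].to_numpy(dtype=float)
    ref = np.exp(np.mean(np.log(libs)))  # geometric mean library
    y = matrix.counts[samples].to_numpy(dtype=float) * (ref / libs)

    num = np.zeros(matrix.counts.shape[0])
    den = np.zeros_like(num)
    total_df = 0.0
    for _, grp in sub.groupby(["treatment", "timepoint_h"], sort=True):
        idx = [samples.index(s) for s in grp.index]
        if len(idx) < 2:
            raise ValidationError(
                f"group {tuple(grp.iloc[0][['treatment', 'timepoint_h']])} has a single replicate"
            )
        yg = y[:, idx]
        m = yg.mean(axis=1)
        v = yg.var(axis=1, ddof=1)
        # E[var] = c*m + phi*m^2 with c the mean rescaling factor
        c = float(np.mean(ref / libs[idx]))
        w = len(idx) - 1
        ok = m > 0
        num[ok] += w * (v[ok] - c * m[ok]) / m[ok] ** 2
        den[ok] += w
        total_df += w

    phi_raw = np.full(num.shape, 0.0)
    has = den > 0
    phi_raw[has] = np.maximum(num[has] / den[has], 0.0)
    common = float(np.median(phi_raw[has])) if has.any() else 0.0
    phi_shrunk = (den * phi_raw + prior_df * common) / (den + prior_df)
    return pd.DataFrame(
        {"phi_raw": phi_raw, "phi_shrunk": phi_shrunk, "common_phi": common},
        index=matrix.gene_ids,
    )
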