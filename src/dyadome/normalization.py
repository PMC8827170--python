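"""Count normalization: GMPR size factors and fixed-depth rarefaction.

GMPR (geometric mean of pairwise ratios) estimates a per-sample size
factor that is robust to the heavy zero-inflation of amplicon counts: for
each pair of samples only the ASVs observed in *both* are compared, the
pairwise ratio is the median of those count ratios, and a sample's factor
is the geometric mean of its pairwise ratios. The self-ratio (always 1)
is included in the geometric mean, which makes the factors recover depth
ratios exactly on perfectly proportional tables.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a fixed depth; samples below the depth are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import UndefinedValueError, ValidationError

logger = logging.getLogger("dyadome")

__all__ = ["gmpr_size_factors", "gmpr_normalize", "rarefy"]


def gmpr_size_factors(counts: pd.DataFrame, min_shared: int = 1) -> pd.Series:
    """GMPR size factor per sample.

    For samples j, k let r_jk be the median of c_ij / c_ik over ASVs i
    with c_ij > 0 and c_ik > 0. With r_jj = 1, the factor of sample j is
    the geometric mean of {r_jk : k shares >= ``min_shared`` nonzero ASVs
    with j} together with r_jj.
    """
    if counts.shape[1] < 2:
        raise ValidationError("GMPR requires at least two samples")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if min_shared > counts.shape[0]:
        raise ValueError(
            f"min_shared={min_shared} exceeds the number of ASVs ({counts.shape[0]})"
        )
    x = counts.to_numpy(dtype=float)
    n_samples = x.shape[1]
    nonzero = x > 0
    log_factors = np.zeros(n_samples)
    isolated = []
    for j in range(n_samples):
        logs = [0.0]  # r_jj = 1
        partners = 0
        for k in range(n_samples):
            if k == j:
                continue
            shared = nonzero[:, j] & nonzero[:, k]
            if shared.sum() >= min_shared:
                r = np.median(x[shared, j] / x[shared, k])
                logs.append(np.log(r))
                partners += 1
        if partners == 0:
            isolated.append(counts.columns[j])
            continue
        log_factors[j] = np.mean(logs)
    if isolated:
        raise UndefinedValueError(
            "samples sharing no nonzero ASV with any other sample "
            f"(min_shared={min_shared}): {isolated}"
        )
    return pd.Series(np.exp(log_factors), index=counts.columns, name="gmpr_size_factor")


def gmpr_normalize(
    counts: pd.DataFrame, min_shared: int = 1
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts divided column-wise by their GMPR size factors.

    Normalized abundances are real-valued; downstream distance measures
    convert them to within-sample proportions anyway.
    """
    factors = gmpr_size_factors(counts, min_shared=min_shared)
    return counts / factors, factors


def rarefy(counts: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (and logged).
    ``seed`` may be an integer or a :class:`numpy.random.Generator`.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [c for c in counts.columns if c not in set(keep)]
    if dropped:
        logger.info(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    if len(keep) == 0:
        raise ValidationError(f"all samples fall below rarefaction depth {depth}")
    out = {}
    for col in keep:
        column = counts[col].to_numpy(dtype=np.int64)
        if column.sum() == depth:
            out[col] = column
        else:
            out[col] = rng.multivariate_hypergeometric(column, depth)
    result = pd.DataFrame(out, index=counts.index)
    result.index.name = "asv_id"
    return result
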