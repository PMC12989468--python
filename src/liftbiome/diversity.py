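"""Rarefaction, alpha diversity, and within-subject Bray-Curtis distances.

Diversity is computed on rarefied counts: every sample is subsampled
without replacement to a common depth (multivariate hypergeometric draw),
and samples shallower than that depth are dropped and logged.  Alpha
metrics are Shannon entropy in natural-log units, observed ASV richness
and Pielou evenness.  The within-subject community trajectory is the
Bray-Curtis distance between a participant's timepoint pairs
(W0-W4, W4-W8, W0-W8).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

PAIRS = (("W0", "W4"), ("W4", "W8"), ("W0", "W8"))


def default_depth(counts: pd.DataFrame, fraction: float = 0.9) -> int:
    """Default rarefaction depth: ``fraction`` of the minimum sample depth."""
    totals = counts.sum(axis=0)
    return max(int(np.floor(totals.min() * fraction)), 1)


def rarefy(
    counts: pd.DataFrame, depth: int, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Returns the rarefied table (shallow samples removed) and the list of
    dropped sample ids.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept_cols = []
    dropped: list[str] = []
    data = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        data[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    rarefied = pd.DataFrame(data, index=counts.index, columns=kept_cols)
    return rarefied, dropped


def shannon(p_or_counts: Sequence[float]) -> float:
    """Shannon entropy H = -sum p ln p (natural log) of a count vector."""
    x = np.asarray(p_or_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon (nats), observed ASVs, and Pielou evenness.

    Pielou J = H / ln(observed); undefined (NaN) for single-ASV samples.
    """
    rows = []
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        h = shannon(col)
        observed = int((col > 0).sum())
        pielou = h / np.log(observed) if observed > 1 else np.nan
        rows.append((sample, h, observed, pielou))
    return pd.DataFrame(
        rows, columns=["sample", "shannon", "observed_asvs", "pielou"]
    )


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_braycurtis(x, y))


def within_subject_distances(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    dropped: Iterable[str] = (),
) -> pd.DataFrame:
    """One Bray-Curtis distance record per participant per timepoint pair.

    ``metadata`` is indexed by sample id with ``participant`` and
    ``timepoint`` columns.  Pairs whose sample was dropped at rarefaction
    (or is otherwise absent from ``counts``) are omitted.
    """
    dropped = set(dropped)
    available = [s for s in counts.columns if s not in dropped]
    meta = metadata.loc[[s for s in available if s in metadata.index]]
    rows = []
    for participant, sub in meta.groupby("participant"):
        by_tp = dict(zip(sub["timepoint"], sub.index))
        for a, b in PAIRS:
            if a in by_tp and b in by_tp:
                d = bray_curtis(counts[by_tp[a]], counts[by_tp[b]])
                rows.append((participant, f"{a}-{b}", d))
    return pd.DataFrame(rows, columns=["participant", "pair", "distance"])


def beta_distance_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Square Bray-Curtis distance matrix over all samples."""
    samples = list(counts.columns)
    mat = counts.to_numpy(dtype=float).T
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _braycurtis(mat[i], mat[j])
    return pd.DataFrame(out, index=samples, columns=samples)
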