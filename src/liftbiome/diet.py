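"""Diet-stability analysis: RMS-scaled Euclidean distances, Sammon
nonlinear mapping, and responder-stratified within-participant diet shifts.

Survey diet records (8 food frequencies + 4 drink volumes) are centered by
the overall mean of each variable and scaled by the root-mean-square of the
centered values, making the Euclidean distance invariant to each
variable's raw units.  The resulting distance matrix is embedded in two
dimensions with Sammon's nonlinear mapping (pseudo-Newton iteration with
step halving, initialized from classical scaling); stress below ~0.2 is
conventionally read as a fair representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .responders import ResponderLabels
from .simulate import DRINK_VARS, FOOD_VARS
from .stats import TestResult, kruskal_dunn

DIET_VARS = (*FOOD_VARS, *DRINK_VARS)


@dataclass
class SammonResult:
    coordinates: np.ndarray  # n x dim
    stress: float
    iterations: int
    converged: bool


def diet_distances(
    records: pd.DataFrame, variables: Sequence[str] = DIET_VARS
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Euclidean distances on mean-centered, RMS-scaled variables.

    Returns the square distance matrix (indexed like ``records``) and the
    list of variables kept; zero-RMS (constant) variables are dropped with
    a warning.
    """
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise ValueError(f"missing diet variables: {missing}")
    data = records[list(variables)].astype(float)
    if data.isna().any().any():
        raise ValueError("diet records must be complete")
    centered = data - data.mean(axis=0)
    rms = np.sqrt((centered**2).mean(axis=0))
    kept = [v for v in variables if rms[v] > 0]
    dropped = [v for v in variables if rms[v] == 0]
    if dropped:
        warnings.warn(
            f"dropping zero-variance diet variables: {dropped}", stacklevel=2
        )
    scaled = centered[kept] / rms[kept]
    dist = squareform(pdist(scaled.to_numpy(), metric="euclidean"))
    return pd.DataFrame(dist, index=records.index, columns=records.index), kept


def sammon_stress(dist: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress E = (1/sum d) * sum (d - e)^2 / d over i < j pairs
    (d = input distances, e = embedded Euclidean distances)."""
    iu = np.triu_indices_from(dist, k=1)
    delta = dist[iu]
    embedded = squareform(
        pdist(coords, metric="euclidean"), checks=False
    )[iu]
    return float(((delta - embedded) ** 2 / delta).sum() / delta.sum())


def _classical_scaling(dist: np.ndarray, dim: int) -> np.ndarray:
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def sammon(
    dist,
    dim: int = 2,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: Optional[int] = None,
    init: str = "classical",
) -> SammonResult:
    """Sammon nonlinear mapping of a distance matrix into ``dim`` dimensions.

    Minimizes the Sammon stress by the diagonal pseudo-Newton update with
    step halving; initialization is deterministic classical scaling unless
    ``init='random'`` (then ``seed`` applies).  Exact duplicate points
    (zero off-diagonal distances) receive a deterministic 1e-9 jitter since
    the objective divides by the input distances.  Convergence: relative
    stress change below ``tol``.
    """
    d = np.asarray(dist, dtype=float).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    dup = off & (d == 0)
    if dup.any():
        d[dup] = 1e-9
    np.fill_diagonal(d, 0.0)

    if init == "classical":
        y = _classical_scaling(d, dim)
    elif init == "random":
        rng = np.random.default_rng(seed)
        y = rng.normal(scale=d[off].mean(), size=(n, dim))
    else:
        raise ValueError(f"unknown init {init!r}")

    c = d[off].sum() / 2.0  # sum over i < j
    stress = sammon_stress(d, y)
    iterations = 0
    converged = False
    eye = np.eye(n, dtype=bool)
    for iterations in range(1, max_iter + 1):
        diff = y[:, None, :] - y[None, :, :]  # n x n x dim
        e = np.sqrt((diff**2).sum(axis=2))
        e[eye] = 1.0
        e = np.where(e == 0, 1e-12, e)
        dm = d.copy()
        dm[eye] = 1.0
        ratio = (dm - e) / (dm * e)
        ratio[eye] = 0.0
        grad = -2.0 / c * (ratio[:, :, None] * diff).sum(axis=1)
        term = 1.0 / (dm * e)
        term[eye] = 0.0
        hess = (
            -2.0
            / c
            * (
                term[:, :, None]
                * (
                    (dm - e)[:, :, None]
                    - diff**2 / e[:, :, None]
                    * (1.0 + (dm - e)[:, :, None] / e[:, :, None])
                )
            ).sum(axis=1)
        )
        denom = np.abs(hess)
        denom = np.where(denom < 1e-12, 1e-12, denom)
        step = grad / denom
        alpha = 1.0
        new_stress = stress
        for _ in range(30):
            candidate = y - alpha * step
            new_stress = sammon_stress(d, candidate)
            if new_stress < stress:
                break
            alpha /= 2.0
        else:
            converged = True
            break
        y = candidate
        if stress - new_stress < tol * max(stress, 1e-30):
            stress = new_stress
            converged = True
            break
        stress = new_stress
    return SammonResult(
        coordinates=y, stress=float(sammon_stress(d, y)),
        iterations=iterations, converged=converged,
    )


def within_participant_diet_distances(
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Per participant, diet distance for each timepoint pair."""
    dist, _ = diet_distances(records)
    rows = []
    pairs = (("W0", "W4"), ("W4", "W8"), ("W0", "W8"))
    for participant, sub in records.groupby("participant"):
        by_tp = dict(zip(sub["timepoint"], sub.index))
        for a, b in pairs:
            if a in by_tp and b in by_tp:
                rows.append(
                    (
                        participant,
                        f"{a}-{b}",
                        float(dist.loc[by_tp[a], by_tp[b]]),
                    )
                )
    return pd.DataFrame(rows, columns=["participant", "pair", "distance"])


def diet_shift_by_responder(
    records: pd.DataFrame,
    labels: ResponderLabels,
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Within-participant diet distances stratified by responder class.

    Returns the tidy distance records (with a ``responder`` column) and a
    Kruskal-Wallis (+ Dunn) result per timepoint pair.  Degenerate inputs
    (all distances identical within a pair) are reported as non-significant
    with a warning rather than an error.
    """
    distances = within_participant_diet_distances(records)
    distances["responder"] = (
        distances["participant"].map(labels.classes).fillna("NA")
    )
    distances = distances[distances["responder"] != "NA"]
    tests: dict[str, TestResult] = {}
    for pair, sub in distances.groupby("pair"):
        if sub["distance"].nunique() == 1:
            warnings.warn(
                f"pair {pair}: all diet distances identical; "
                "test degenerate, reported non-significant",
                stacklevel=2,
            )
            tests[pair] = TestResult("kruskal", 0.0, 1.0)
            continue
        tests[pair] = kruskal_dunn(
            sub["distance"].to_numpy(), sub["responder"].to_numpy()
        )
    return distances, tests
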