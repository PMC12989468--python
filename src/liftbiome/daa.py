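"""Paired, bias-corrected differential-abundance analysis (DAA) with a
permutation-subset robustness procedure.

The design is strictly within-participant: for every follow-up timepoint
(W4, W8) and every ASV, the analysis computes the participant's log2 fold
change of relative abundance versus baseline (with a pseudocount), removes
a per-participant-contrast median shift shared by all ASVs (a surrogate
for compositional / sampling-fraction bias), and tests the centered fold
changes against zero with a one-sample t-test.  The two follow-up
contrasts form a many-to-one (Dunnett-type) family, adjusted per ASV with
Holm's step-down correction.  An ASV is called significant when the
adjusted p is at most ``p_threshold`` AND |mean log2 FC| reaches
``lfc_threshold``.

Robustness: the same DAA runs on the high-responder subset and on
``n_subsets`` random, size-matched subsets of the non-high-responder pool;
the empirical p is the fraction of subsets with at least as many
significant ASVs, and each HR-significant ASV gets a Benjamini-Hochberg
q-value of its chance frequency across subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DaaConfig
from .stats import bh_adjust, holm_adjust


@dataclass
class PairedFoldChanges:
    """Per-contrast participant x ASV log2 fold-change matrices."""

    fcs: dict[str, pd.DataFrame]
    asvs: list[str]
    skipped: list[str] = field(default_factory=list)


@dataclass
class PermutationSummary:
    observed_n_sig: int
    permuted_n_sig: list[int]
    empirical_p: float
    chance_freq: dict[str, float]
    q: dict[str, float]
    n_subsets: int
    observed_asvs: list[str] = field(default_factory=list)


def paired_log2fc(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    config: Optional[DaaConfig] = None,
    participants: Optional[Iterable[str]] = None,
) -> PairedFoldChanges:
    """Within-participant log2 relative-abundance fold changes vs baseline.

    For participant p and contrast t the value is
    log2((count_t + pc) / depth_t) - log2((count_0 + pc) / depth_0)
    where depth is the sample's total read count over *all* ASVs.
    ASVs failing the prevalence filter (nonzero in fewer than
    ``prevalence_min`` of the analyzed samples) are removed.  Participants
    without a baseline sample are skipped and listed.
    """
    config = config or DaaConfig()
    config.validate()
    meta = metadata
    if participants is not None:
        wanted = set(participants)
        meta = meta[meta["participant"].isin(wanted)]
    sample_ids = [s for s in meta.index if s in counts.columns]
    meta = meta.loc[sample_ids]
    sub = counts[sample_ids]

    prevalence = (sub > 0).mean(axis=1)
    keep = prevalence >= config.prevalence_min
    asvs = list(sub.index[keep])
    depths = sub.sum(axis=0)

    pc = config.pseudocount
    log_rel = np.log2(
        (sub.loc[asvs].to_numpy(dtype=float) + pc)
        / depths.to_numpy(dtype=float)[None, :]
    )
    log_rel = pd.DataFrame(log_rel, index=asvs, columns=sample_ids)

    fcs: dict[str, dict[str, np.ndarray]] = {c: {} for c in config.contrasts}
    skipped: list[str] = []
    for participant, rows in meta.groupby("participant"):
        by_tp = dict(zip(rows["timepoint"], rows.index))
        if config.baseline not in by_tp:
            skipped.append(participant)
            continue
        base = log_rel[by_tp[config.baseline]].to_numpy()
        for contrast in config.contrasts:
            if contrast in by_tp:
                fcs[contrast][participant] = (
                    log_rel[by_tp[contrast]].to_numpy() - base
                )
    frames = {
        contrast: pd.DataFrame.from_dict(
            values, orient="index", columns=asvs
        ).sort_index()
        for contrast, values in fcs.items()
    }
    return PairedFoldChanges(fcs=frames, asvs=asvs, skipped=skipped)


def bias_correct(
    fc: PairedFoldChanges | pd.DataFrame, min_asvs: int = 10
) -> PairedFoldChanges | pd.DataFrame:
    """Remove the per-participant-contrast median fold change across ASVs.

    A shift common to every ASV in a participant's sample pair is a
    compositional/depth artifact, not differential abundance; subtracting
    the across-ASV median removes it while leaving sparse genuine effects
    intact.
    """
    if isinstance(fc, PairedFoldChanges):
        return PairedFoldChanges(
            fcs={c: bias_correct(df, min_asvs) for c, df in fc.fcs.items()},
            asvs=fc.asvs,
            skipped=fc.skipped,
        )
    if fc.shape[1] < min_asvs:
        raise ValueError(
            f"bias correction needs >= {min_asvs} ASVs, got {fc.shape[1]}"
        )
    return fc.sub(fc.median(axis=1), axis=0)


def _holm_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Holm step-down adjustment of a 2-D p-value array.

    NaN cells (contrast absent for that ASV) are ignored and returned NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    m = (~np.isnan(p)).sum(axis=1)
    order = np.argsort(np.where(np.isnan(p), np.inf, p), axis=1)
    rows = np.arange(p.shape[0])[:, None]
    sorted_p = np.take_along_axis(p, order, axis=1)
    k = np.arange(p.shape[1])[None, :]
    factor = np.maximum(m[:, None] - k, 1)
    scaled = np.minimum(sorted_p * factor, 1.0)
    adj = np.fmax.accumulate(scaled, axis=1)
    np.put_along_axis(out, order, adj, axis=1)
    out[np.isnan(p)] = np.nan
    del rows
    return out


def daa_test(
    fc: PairedFoldChanges, config: Optional[DaaConfig] = None
) -> pd.DataFrame:
    """Per-ASV, per-contrast one-sample t-tests on centered fold changes.

    Returns a tidy frame with columns asv, contrast, n, mean_log2fc, p,
    holm_p (Holm across the contrasts within each ASV) and significant.
    """
    config = config or DaaConfig()
    results = []
    for contrast, frame in fc.fcs.items():
        mat = frame.to_numpy(dtype=float)
        n_part = mat.shape[0]
        if n_part < 5:
            raise ValueError(
                f"contrast {contrast}: need >= 5 participants, got {n_part}"
            )
        mean = np.nanmean(mat, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat, p = sps.ttest_1samp(mat, 0.0, axis=0, nan_policy="omit")
        p = np.asarray(p, dtype=float)
        zero_var = np.nanstd(mat, axis=0) == 0
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance ASVs in contrast "
                f"{contrast}: p set to 1",
                stacklevel=2,
            )
            p[zero_var] = 1.0
        p = np.where(np.isnan(p), 1.0, p)
        n_obs = (~np.isnan(mat)).sum(axis=0)
        for i, asv in enumerate(frame.columns):
            results.append(
                (asv, contrast, int(n_obs[i]), float(mean[i]), float(p[i]))
            )
    table = pd.DataFrame(
        results, columns=["asv", "contrast", "n", "mean_log2fc", "p"]
    )
    # Holm step-down across the contrasts within each ASV, vectorized:
    # rows = ASVs, columns = contrasts
    pmat = table.pivot(index="asv", columns="contrast", values="p")
    adj = _holm_rows(pmat.to_numpy(dtype=float))
    holm = pd.DataFrame(adj, index=pmat.index, columns=pmat.columns).stack()
    table["holm_p"] = holm.reindex(
        pd.MultiIndex.from_frame(table[["asv", "contrast"]])
    ).to_numpy()
    table["significant"] = (table["holm_p"] <= config.p_threshold) & (
        table["mean_log2fc"].abs() >= config.lfc_threshold
    )
    return table.sort_values(["contrast", "asv"]).reset_index(drop=True)


def run_daa(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    participants: Iterable[str],
    config: Optional[DaaConfig] = None,
) -> pd.DataFrame:
    """Prevalence filter -> paired fold changes -> bias correction -> tests."""
    config = config or DaaConfig()
    fc = paired_log2fc(counts, metadata, config, participants=participants)
    centered = bias_correct(fc)
    return daa_test(centered, config)


def significant_asvs(results: pd.DataFrame) -> set[str]:
    """ASVs significant in at least one contrast (either direction)."""
    return set(results.loc[results["significant"], "asv"])


def empirical_pvalue(observed: float, permuted: Sequence[float]) -> float:
    """One-sided empirical p: fraction of permuted statistics >= observed.

    Deliberately uses k/N (no add-one): a zero count is reported downstream
    as "< 1/N" rather than 0.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size < 1:
        raise ValueError("need at least one permuted statistic")
    return float(np.mean(permuted >= observed))


def permutation_robustness(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    hr_ids: Sequence[str],
    pool_ids: Sequence[str],
    n_subsets: int = 100,
    seed: int = 0,
    config: Optional[DaaConfig] = None,
) -> PermutationSummary:
    """Compare the HR DAA signal with size-matched non-HR subsets.

    Draws ``n_subsets`` seeded subsets of len(hr_ids) participants from
    ``pool_ids`` without replacement, runs the identical DAA on each, and
    summarizes: the empirical p of the HR significant-ASV count, the
    per-ASV chance frequency of significance across subsets, and BH
    q-values over the chance frequencies of the HR-significant ASVs.
    """
    hr_ids = list(hr_ids)
    pool_ids = list(pool_ids)
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if len(pool_ids) < len(hr_ids):
        raise ValueError("pool smaller than the HR set")
    if set(hr_ids) & set(pool_ids):
        raise ValueError("pool must be disjoint from the HR set")
    config = config or DaaConfig()

    observed_results = run_daa(counts, metadata, hr_ids, config)
    observed_set = significant_asvs(observed_results)
    observed_n = len(observed_set)

    rng = np.random.default_rng(seed)
    permuted_counts: list[int] = []
    hits: dict[str, int] = {}
    for _ in range(n_subsets):
        subset = list(rng.choice(pool_ids, size=len(hr_ids), replace=False))
        res = run_daa(counts, metadata, subset, config)
        sig = significant_asvs(res)
        permuted_counts.append(len(sig))
        for asv in sig:
            hits[asv] = hits.get(asv, 0) + 1

    p_emp = empirical_pvalue(observed_n, permuted_counts)
    all_asvs = sorted(set(observed_results["asv"]))
    chance_freq = {a: hits.get(a, 0) / n_subsets for a in all_asvs}
    fig_rows = sorted(observed_set)
    q_vals = bh_adjust([chance_freq[a] for a in fig_rows])
    q = {a: float(v) for a, v in zip(fig_rows, q_vals)}
    return PermutationSummary(
        observed_n_sig=observed_n,
        permuted_n_sig=permuted_counts,
        empirical_p=p_emp,
        chance_freq=chance_freq,
        q=q,
        n_subsets=n_subsets,
        observed_asvs=fig_rows,
    )


def fig_table(
    results: pd.DataFrame,
    summary: PermutationSummary,
    taxonomy: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Heatmap-style table of HR-significant ASVs: per-contrast log2 FC,
    significance stars, and the chance q-value (zero frequencies shown as
    '< 1/n_subsets')."""
    def stars(p: float) -> str:
        if p <= 1e-5:
            return "***"
        if p <= 1e-3:
            return "**"
        if p <= 0.05:
            return "*"
        return ""

    tax = (
        taxonomy.set_index("asv")["taxonomy"]
        if taxonomy is not None
        else pd.Series(dtype=str)
    )
    rows = []
    for asv in summary.observed_asvs:
        sub = results[results["asv"] == asv].set_index("contrast")
        freq = summary.chance_freq.get(asv, 0.0)
        if freq == 0.0:
            q_str = f"< {1.0 / summary.n_subsets:g}"
        else:
            q_str = f"{summary.q[asv]:.4g}"
        row = {
            "asv": asv,
            "taxonomy": tax.get(asv, ""),
            "q": q_str,
        }
        for contrast in sub.index:
            row[f"log2fc_{contrast}"] = sub.loc[contrast, "mean_log2fc"]
            row[f"stars_{contrast}"] = stars(sub.loc[contrast, "holm_p"])
        rows.append(row)
    return pd.DataFrame(rows)
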