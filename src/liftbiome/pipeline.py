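"""End-to-end orchestration: simulate -> strength -> responders ->
diversity -> coupling -> DAA -> permutation robustness -> diet ->
prediction -> report.

Each stage reads the previous stage's TSV outputs from the run directory
and appends its own, so any stage can also be re-run in isolation from the
CLI.  All randomness flows from one global seed via a per-stage CRC32
offset, making stage outputs reproducible independently of execution
order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import daa as daa_mod
from . import diet as diet_mod
from . import diversity as div_mod
from . import responders as resp_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from . import strength as strength_mod
from .config import DaaConfig, PipelineConfig
from .io import read_counts, read_metadata, read_tsv, write_tsv


class StageError(RuntimeError):
    """A stage's required upstream output is missing."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed + CRC32(stage)) mod 2^31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class CouplingResult:
    """Pearson coupling of within-subject community shift and strength gain,
    plus the responder-stratified Kruskal-Wallis/Dunn comparison."""

    pair: str
    r: float
    p: float
    n: int
    kruskal: Optional[stats_mod.TestResult] = None


def run_coupling(
    beta_within: pd.DataFrame,
    strength_metrics: pd.DataFrame,
    labels: Optional[resp_mod.ResponderLabels] = None,
    pair: str = "W0-W8",
    metric: str = "avg_log2fc_W0W8",
) -> CouplingResult:
    """Correlate the within-participant Bray-Curtis distance of ``pair``
    with the average strength gain, and compare distances across responder
    classes when labels are given."""
    dist = beta_within[beta_within["pair"] == pair].set_index("participant")[
        "distance"
    ]
    gain = strength_metrics.set_index("participant")[metric]
    joined = pd.concat([dist, gain], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 matched participants")
    res = stats_mod.pearson_r(joined["distance"], joined[metric])
    kw = None
    if labels is not None:
        classes = pd.Series(
            joined.index.map(labels.classes), index=joined.index
        )
        mask = classes.notna()
        if mask.sum() >= 3 and classes[mask].nunique() >= 2:
            kw = stats_mod.kruskal_dunn(
                joined.loc[mask, "distance"].to_numpy(),
                classes[mask].to_numpy(),
            )
    return CouplingResult(
        pair=pair, r=res.statistic, p=res.p, n=len(joined), kruskal=kw
    )


# ---------------------------------------------------------------------------
# stages


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise StageError(f"missing upstream outputs: {missing}")


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    config.cohort.seed = stage_seed(config.seed, "simulate-cohort")
    config.training.seed = stage_seed(config.seed, "simulate-training")
    config.microbiome.seed = stage_seed(config.seed, "simulate-microbiome")
    config.diet_sim.seed = stage_seed(config.seed, "simulate-diet")
    sim_mod.simulate_study(
        out,
        cohort_config=config.cohort,
        training_config=config.training,
        microbiome_config=config.microbiome,
        diet_config=config.diet_sim,
    )


def stage_strength(config: PipelineConfig, out: Path) -> None:
    _require(out, "sessions.tsv", "fitness.tsv")
    sessions = read_tsv(out / "sessions.tsv")
    fitness = read_tsv(out / "fitness.tsv")
    table = strength_mod.strength_metrics_table(
        sessions, fitness, config.bioage
    )
    write_tsv(table, out / "strength_metrics.tsv",
              meta={"seed": config.seed})


def _final_metrics(out: Path) -> pd.DataFrame:
    """Strength metrics restricted to the analyzed (final) cohort."""
    metrics = read_tsv(out / "strength_metrics.tsv")
    participants_path = out / "participants.tsv"
    if participants_path.exists():
        cohort = read_tsv(participants_path)
        final = set(
            cohort.loc[cohort["status"] == sim_mod.STATUS_FINAL,
                       "participant"]
        )
        metrics = metrics[metrics["participant"].isin(final)]
    return metrics


def stage_responders(config: PipelineConfig, out: Path) -> None:
    _require(out, "strength_metrics.tsv")
    metrics = _final_metrics(out)
    complete = metrics.dropna(subset=["avg_log2fc_W0W8"])
    labels = resp_mod.stratify_all(
        complete, config.responder_low_q, config.responder_high_q
    )
    table = resp_mod.labels_table(labels)
    thresholds = {
        name: {"low_cut": lab.low_cut, "high_cut": lab.high_cut}
        for name, lab in labels.items()
    }
    write_tsv(
        table,
        out / "responders.tsv",
        meta={"thresholds": json.dumps(thresholds)},
    )


def stage_diversity(config: PipelineConfig, out: Path) -> None:
    _require(out, "counts.tsv", "metadata.tsv")
    counts = read_counts(out / "counts.tsv")
    metadata = read_metadata(out / "metadata.tsv")
    depth = config.rarefaction_depth or div_mod.default_depth(counts)
    seed = stage_seed(config.seed, "diversity")
    rarefied, dropped = div_mod.rarefy(counts, depth, seed=seed)
    alpha = div_mod.alpha_diversity(rarefied)
    alpha = alpha.merge(
        metadata.reset_index().rename(columns={"sample-id": "sample"}),
        on="sample", how="left",
    )
    write_tsv(
        alpha, out / "alpha.tsv",
        meta={"rarefaction_depth": depth, "seed": seed,
              "shannon_units": "nats", "dropped": ",".join(dropped)},
    )
    beta = div_mod.within_subject_distances(rarefied, metadata, dropped)
    write_tsv(
        beta, out / "beta_within.tsv",
        meta={"metric": "bray-curtis", "rarefaction_depth": depth,
              "seed": seed},
    )


def _load_labels(out: Path, metric: str = "avg_gain") -> resp_mod.ResponderLabels:
    table = read_tsv(out / "responders.tsv").set_index("participant")
    return resp_mod.ResponderLabels(
        metric=metric,
        classes=table[metric],
        low_cut=float("nan"),
        high_cut=float("nan"),
    )


def stage_coupling(config: PipelineConfig, out: Path) -> None:
    _require(out, "beta_within.tsv", "strength_metrics.tsv", "responders.tsv")
    beta = read_tsv(out / "beta_within.tsv")
    metrics = _final_metrics(out)
    labels = _load_labels(out)
    result = run_coupling(beta, metrics, labels)
    payload = {
        "pair": result.pair,
        "pearson_r": result.r,
        "p": result.p,
        "n": result.n,
    }
    if result.kruskal is not None:
        payload["kruskal_statistic"] = result.kruskal.statistic
        payload["kruskal_p"] = result.kruskal.p
        payload["dunn"] = result.kruskal.pairwise.to_dict(orient="records")
    (out / "coupling.json").write_text(json.dumps(payload, indent=1))


def _analysis_sets(out: Path) -> tuple[list[str], list[str]]:
    table = read_tsv(out / "responders.tsv").set_index("participant")
    hr = sorted(table.index[table["avg_gain"] == resp_mod.HR])
    pool = sorted(table.index[table["non_hr_pool"]])
    return hr, pool


def stage_daa(config: PipelineConfig, out: Path) -> None:
    _require(out, "counts.tsv", "metadata.tsv", "responders.tsv")
    counts = read_counts(out / "counts.tsv")
    metadata = read_metadata(out / "metadata.tsv")
    hr, _ = _analysis_sets(out)
    results = daa_mod.run_daa(counts, metadata, hr, config.daa)
    write_tsv(results, out / "daa_results.tsv",
              meta={"subset": "HR(avg_gain)", "n_participants": len(hr)})


def stage_permtest(config: PipelineConfig, out: Path) -> None:
    _require(out, "counts.tsv", "metadata.tsv", "responders.tsv",
             "daa_results.tsv")
    counts = read_counts(out / "counts.tsv")
    metadata = read_metadata(out / "metadata.tsv")
    hr, pool = _analysis_sets(out)
    seed = stage_seed(config.seed, "permtest")
    summary = daa_mod.permutation_robustness(
        counts, metadata, hr, pool,
        n_subsets=config.n_subsets, seed=seed, config=config.daa,
    )
    payload = {
        "observed_n_sig": summary.observed_n_sig,
        "permuted_n_sig": summary.permuted_n_sig,
        "empirical_p": summary.empirical_p,
        "chance_freq": summary.chance_freq,
        "q": summary.q,
        "n_subsets": summary.n_subsets,
        "seed": seed,
    }
    (out / "permutation_summary.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )
    results = read_tsv(out / "daa_results.tsv")
    taxonomy = (
        read_tsv(out / "taxonomy.tsv")
        if (out / "taxonomy.tsv").exists()
        else None
    )
    table = daa_mod.fig_table(results, summary, taxonomy)
    write_tsv(table, out / "fig4_table.tsv",
              meta={"n_subsets": summary.n_subsets, "seed": seed})


def stage_diet(config: PipelineConfig, out: Path) -> None:
    _require(out, "diet.tsv", "responders.tsv")
    records = read_tsv(out / "diet.tsv")
    labels = _load_labels(out)
    dist, _kept = diet_mod.diet_distances(records)
    embedding = diet_mod.sammon(dist.to_numpy())
    coords = pd.DataFrame(
        {
            "participant": records["participant"],
            "timepoint": records["timepoint"],
            "x": embedding.coordinates[:, 0],
            "y": embedding.coordinates[:, 1],
        }
    )
    write_tsv(coords, out / "diet_coords.tsv",
              meta={"stress": f"{embedding.stress:.6g}",
                    "iterations": embedding.iterations})
    distances, tests = diet_mod.diet_shift_by_responder(records, labels)
    rows = [
        {"pair": pair, "statistic": res.statistic, "p": res.p}
        for pair, res in tests.items()
    ]
    write_tsv(pd.DataFrame(rows), out / "diet_shift_tests.tsv")
    write_tsv(distances, out / "diet_within_distances.tsv")


def baseline_feature_table(
    out: Path, block: str = "fitness"
) -> tuple[pd.DataFrame, pd.Series]:
    """Baseline-only feature block + HR/LR labels for the prediction stage.

    Blocks: ``fitness`` (baseline strength, demographics, diet),
    ``microbiome`` (W0 relative abundances), ``metabolome`` (W0 panel).
    """
    labels_tab = read_tsv(out / "responders.tsv").set_index("participant")
    classes = labels_tab["avg_gain"]
    keep = classes.isin([resp_mod.HR, resp_mod.LR])
    classes = classes[keep]
    if block == "fitness":
        metrics = read_tsv(out / "strength_metrics.tsv").set_index(
            "participant"
        )
        participants = read_tsv(out / "participants.tsv").set_index(
            "participant"
        )
        fitness = read_tsv(out / "fitness.tsv")
        w0 = fitness[fitness["timepoint"] == "W0"].pivot_table(
            index="participant", columns="machine", values="max_strength"
        )
        w0.columns = [f"strength_W0_{c}" for c in w0.columns]
        diet = read_tsv(out / "diet.tsv")
        diet_w0 = diet[diet["timepoint"] == "W0"].set_index("participant")
        diet_w0 = diet_w0.drop(columns=["timepoint"])
        features = pd.concat(
            [
                metrics[["legpress_W0", "bioage_W0"]],
                participants[["age", "bmi"]],
                (participants["sex"] == "male").astype(float).rename("male"),
                w0,
                diet_w0,
            ],
            axis=1,
        )
    elif block == "microbiome":
        counts = read_counts(out / "counts.tsv")
        metadata = read_metadata(out / "metadata.tsv")
        w0_samples = metadata[metadata["timepoint"] == "W0"]
        rel = counts[w0_samples.index] / counts[w0_samples.index].sum(axis=0)
        features = rel.T
        features.index = w0_samples["participant"]
    elif block == "metabolome":
        met = read_tsv(out / "metabolites.tsv")
        features = met[met["timepoint"] == "W0"].set_index("participant")
        features = features.drop(columns=["timepoint"])
    else:
        raise ValueError(f"unknown feature block {block!r}")
    features = features.loc[features.index.intersection(classes.index)]
    features = features.dropna()
    classes = classes.loc[features.index]
    return features, classes


def stage_predict(config: PipelineConfig, out: Path) -> None:
    _require(out, "responders.tsv", "strength_metrics.tsv",
             "participants.tsv", "fitness.tsv", "diet.tsv")
    features, classes = baseline_feature_table(out, "fitness")
    result = resp_mod.predict_responders(
        features,
        classes,
        n_perm=config.predict.n_perm,
        seed=stage_seed(config.seed, "predict"),
        n_estimators=config.predict.n_estimators,
        n_folds=config.predict.n_folds,
    )
    payload = {
        "feature_block": "fitness",
        "auc": result.auc,
        "permutation_p": result.permutation_p,
        "n_perm": result.n_perm,
        "fold_aucs": result.fold_aucs,
        "feature_importances": result.feature_importances,
        "model": {
            "classifier": "RandomForestClassifier",
            "n_estimators": config.predict.n_estimators,
            "cv": f"stratified {config.predict.n_folds}-fold",
        },
    }
    (out / "prediction.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )


def stage_report(config: PipelineConfig, out: Path) -> None:
    _require(out, "participants.tsv", "strength_metrics.tsv")
    cohort = read_tsv(out / "participants.tsv")
    status = cohort["status"].value_counts()
    metrics = read_tsv(out / "strength_metrics.tsv")
    final_ids = set(
        cohort.loc[cohort["status"] == sim_mod.STATUS_FINAL, "participant"]
    )
    final_metrics = metrics[metrics["participant"].isin(final_ids)]
    results: dict = {
        "cohort": {
            "enrolled": int(len(cohort)),
            "dropout": int(status.get(sim_mod.STATUS_DROPOUT, 0)),
            "quality_excluded": int(status.get(sim_mod.STATUS_QUALITY, 0)),
            "validation_excluded": int(
                status.get(sim_mod.STATUS_VALIDATION, 0)
            ),
            "final": int(status.get(sim_mod.STATUS_FINAL, 0)),
        },
        "strength": {
            "mean_percent_gain": float(final_metrics["percent_gain"].mean()),
            "sd_percent_gain": float(final_metrics["percent_gain"].std()),
            "mean_legpress_W0": float(final_metrics["legpress_W0"].mean()),
            "mean_legpress_W8": float(final_metrics["legpress_W8"].mean()),
            "mean_compliance": float(final_metrics["compliance"].mean()),
        },
        "seed": config.seed,
    }
    conservation = (
        results["cohort"]["enrolled"]
        == results["cohort"]["final"]
        + results["cohort"]["dropout"]
        + results["cohort"]["quality_excluded"]
        + results["cohort"]["validation_excluded"]
    )
    results["cohort"]["conserved"] = bool(conservation)

    if (out / "alpha.tsv").exists():
        alpha = read_tsv(out / "alpha.tsv")
        wide = alpha.pivot_table(
            index="participant", columns="timepoint", values="shannon"
        ).dropna()
        if wide.shape[1] >= 2 and len(wide) >= 2:
            fr = stats_mod.friedman_conover(wide.to_numpy())
            results["alpha"] = {
                "friedman_statistic": fr.statistic, "friedman_p": fr.p
            }
    if (out / "coupling.json").exists():
        results["coupling"] = json.loads((out / "coupling.json").read_text())
        results["coupling"].pop("dunn", None)
    if (out / "daa_results.tsv").exists():
        daa = read_tsv(out / "daa_results.tsv")
        sig = daa[daa["significant"]]
        results["daa"] = {
            c: {
                "up": int(((sig["contrast"] == c)
                           & (sig["mean_log2fc"] > 0)).sum()),
                "down": int(((sig["contrast"] == c)
                             & (sig["mean_log2fc"] < 0)).sum()),
            }
            for c in sorted(daa["contrast"].unique())
        }
    if (out / "permutation_summary.json").exists():
        perm = json.loads((out / "permutation_summary.json").read_text())
        results["permutation"] = {
            "observed_n_sig": perm["observed_n_sig"],
            "empirical_p": perm["empirical_p"],
            "n_subsets": perm["n_subsets"],
        }
    if (out / "diet_coords.tsv").exists():
        header = (out / "diet_coords.tsv").read_text().splitlines()[0]
        results["diet_stress"] = float(header.split(":")[-1])
    if (out / "prediction.json").exists():
        pred = json.loads((out / "prediction.json").read_text())
        results["prediction"] = {
            "auc": pred["auc"], "permutation_p": pred["permutation_p"]
        }

    (out / "results.json").write_text(json.dumps(results, indent=1,
                                                 sort_keys=True))
    lines = [
        "# Resistance-training microbiome pipeline report",
        "",
        f"Seed: {config.seed}",
        "",
        "## Cohort flow",
        f"- enrolled: {results['cohort']['enrolled']}",
        f"- dropouts: {results['cohort']['dropout']}",
        f"- quality excluded: {results['cohort']['quality_excluded']}",
        f"- validation excluded: {results['cohort']['validation_excluded']}",
        f"- final cohort: {results['cohort']['final']}"
        f" (conserved: {results['cohort']['conserved']})",
        "",
        "## Strength",
        f"- mean gain: {results['strength']['mean_percent_gain']:.1f}%"
        f" +/- {results['strength']['sd_percent_gain']:.1f}%",
        f"- leg press W0 -> W8: {results['strength']['mean_legpress_W0']:.0f}"
        f" -> {results['strength']['mean_legpress_W8']:.0f} kg",
        f"- mean compliance: {results['strength']['mean_compliance']:.1f}%",
    ]
    if "alpha" in results:
        lines += [
            "",
            "## Alpha diversity",
            f"- Friedman p over timepoints: {results['alpha']['friedman_p']:.3g}",
        ]
    if "coupling" in results:
        lines += [
            "",
            "## Community-shift / strength coupling",
            f"- Pearson r = {results['coupling']['pearson_r']:.3f}"
            f" (p = {results['coupling']['p']:.2g},"
            f" n = {results['coupling']['n']})",
        ]
    if "daa" in results:
        lines += ["", "## Differential abundance (HR subset)"]
        for contrast, counts_ in results["daa"].items():
            lines.append(
                f"- {contrast}: {counts_['up']} up, {counts_['down']} down"
            )
    if "permutation" in results:
        lines += [
            "",
            "## Permutation robustness",
            f"- observed significant ASVs: "
            f"{results['permutation']['observed_n_sig']}",
            f"- empirical p vs {results['permutation']['n_subsets']} "
            f"non-HR subsets: {results['permutation']['empirical_p']:.3g}",
        ]
    if "diet_stress" in results:
        lines += ["", "## Diet",
                  f"- Sammon stress: {results['diet_stress']:.3g}"]
    if "prediction" in results:
        lines += [
            "",
            "## Responder prediction (baseline fitness features)",
            f"- cross-validated AUC: {results['prediction']['auc']:.3f}"
            f" (permutation p = {results['prediction']['permutation_p']:.3g})",
        ]
    (out / "report.md").write_text("\n".join(lines) + "\n")


_STAGES = {
    "simulate": stage_simulate,
    "strength": stage_strength,
    "responders": stage_responders,
    "diversity": stage_diversity,
    "coupling": stage_coupling,
    "daa": stage_daa,
    "permtest": stage_permtest,
    "diet": stage_diet,
    "predict": stage_predict,
    "report": stage_report,
}

#: immediate upstream dependencies used for skip propagation
_DEPENDS = {
    "simulate": (),
    "strength": ("simulate",),
    "responders": ("strength",),
    "diversity": ("simulate",),
    "coupling": ("diversity", "responders"),
    "daa": ("responders",),
    "permtest": ("daa",),
    "diet": ("responders",),
    "predict": ("responders",),
    "report": ("strength",),
}


def run_all(config: PipelineConfig, out_dir: str | Path,
            log=print) -> Path:
    """Execute all enabled stages in dependency order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    done: set[str] = set()
    for name in _STAGES:
        if name not in enabled:
            log(f"[skip] stage {name} disabled")
            continue
        not_run = [d for d in _DEPENDS[name] if d not in done]
        if not_run:
            log(
                f"[skip] stage {name}: upstream stage(s) {not_run} "
                "disabled or skipped"
            )
            continue
        log(f"[run ] stage {name}")
        try:
            _STAGES[name](config, out)
        except StageError:
            raise
        except FileNotFoundError as exc:
            raise StageError(f"stage {name}: missing input ({exc})") from exc
        done.add(name)
    return out


def bundle_digest(out_dir: str | Path) -> str:
    """SHA256 over every file in a run directory (names + bytes)."""
    out = Path(out_dir)
    digest = hashlib.sha256()
    for path in sorted(out.rglob("*")):
        if path.is_file():
            digest.update(path.relative_to(out).as_posix().encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
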