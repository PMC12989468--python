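"""Synthetic study generator.

Emulates a complete resistance-training / gut-microbiome intervention study
so the full analysis pipeline can run without any external data:

* an enrollment funnel (enrolled -> dropouts, quality exclusions,
  validation exclusions -> final cohort) with realistic demographics,
* session-level digital training logs following the two 4-phase machine
  programs, plus per-machine fitness-test maxima at W0/W4/W8,
* longitudinal ASV count tables (3 stool samples per completing
  participant) from a hierarchical log-normal composition -> multinomial
  read model, with "planted" responder-coupled differential ASVs,
* a null targeted metabolite panel (34 compounds, W0/W8),
* stable per-participant diet profiles (8 food + 4 drink variables).

Everything is driven by explicit seeds: the same configuration and seed
produce byte-identical output files.  A ground-truth sidecar (planted ASV
ids, per-participant true gains and effect scales) is always written so
recovery tests never have to peek at analysis outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import (
    CohortConfig,
    ConfigError,
    DietSimConfig,
    MACHINE_STRENGTH_FRACTION,
    MicrobiomeSimConfig,
    TrainingSimConfig,
)
from .io import write_tsv

STATUS_FINAL = "final"
STATUS_DROPOUT = "dropout"
STATUS_QUALITY = "quality_excluded"
STATUS_VALIDATION = "validation_excluded"


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: Optional[CohortConfig] = None) -> pd.DataFrame:
    """Participant table with demographics and exclusion status.

    Exactly ``n_enrolled`` rows; exclusion flags are assigned by a seeded
    permutation; the ``final`` subset has the configured size.  Ages are
    drawn truncated-normal on [age_min, age_max]; body weight derives from
    BMI and a sex-specific height.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_enrolled
    ids = [f"P{i + 1:03d}" for i in range(n)]
    sex = np.where(
        rng.random(n) < config.sex_fraction_male, "male", "female"
    )
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = sps.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 16.5, 35.0)
    height = np.where(
        sex == "male",
        rng.normal(1.78, 0.06, size=n),
        rng.normal(1.65, 0.06, size=n),
    )
    body_weight = bmi * height**2
    group = np.where(rng.random(n) < config.group_split, "RRT", "MBRT")

    status = np.full(n, STATUS_FINAL, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for label, count in (
        (STATUS_DROPOUT, config.n_dropout),
        (STATUS_QUALITY, config.n_quality_excluded),
        (STATUS_VALIDATION, config.n_validation_excluded),
    ):
        status[order[cursor : cursor + count]] = label
        cursor += count
    dropout_week = np.where(
        status == STATUS_DROPOUT, rng.integers(1, 8, size=n), 0
    )
    cohort = pd.DataFrame(
        {
            "participant": ids,
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "height": np.round(height, 2),
            "body_weight": np.round(body_weight, 1),
            "group": group,
            "status": status,
            "dropout_week": dropout_week,
        }
    )
    return cohort


def exclusion_log(cohort: pd.DataFrame) -> pd.DataFrame:
    """Summary of the enrollment funnel (conservation identity holds exactly)."""
    counts = cohort["status"].value_counts()
    rows = [
        ("enrolled", len(cohort)),
        (STATUS_DROPOUT, int(counts.get(STATUS_DROPOUT, 0))),
        (STATUS_QUALITY, int(counts.get(STATUS_QUALITY, 0))),
        (STATUS_VALIDATION, int(counts.get(STATUS_VALIDATION, 0))),
        (STATUS_FINAL, int(counts.get(STATUS_FINAL, 0))),
    ]
    return pd.DataFrame(rows, columns=["category", "n"])


# ---------------------------------------------------------------------------
# training logs


def _phase_of_week(week: int) -> int:
    return min((week - 1) // 2, 3)


def generate_training_logs(
    participants: pd.DataFrame,
    config: Optional[TrainingSimConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Session-level training log and per-machine fitness-test table.

    The per-participant total gain (percent) is drawn from
    N(gain_mean, gain_sd), truncated below at ``gain_floor``; baseline
    strength and gain share a Gaussian copula with correlation
    ``baseline_gain_corr`` (weaker participants improve relatively more).
    Strength at week w follows the piecewise-linear log2 trajectory through
    (0, 0), (4, w4_fraction * G), (8, G) with a per-machine deviation of sd
    ``machine_noise_sd`` log2 units.  Dropout participants train (and are
    tested) only until their dropout week.
    """
    config = config or TrainingSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    machines = list(config.machines)
    frac = MACHINE_STRENGTH_FRACTION

    session_rows: list[tuple] = []
    fitness_rows: list[tuple] = []
    for row in participants.itertuples():
        group = str(row.group)
        if group not in config.phase_schedule:
            raise ConfigError(f"unknown group label {group!r}")
        weeks_trained = (
            int(row.dropout_week)
            if row.status == STATUS_DROPOUT
            else config.weeks
        )
        # correlated (baseline, gain) via a Gaussian copula
        z1 = rng.standard_normal()
        z2 = (
            config.baseline_gain_corr * z1
            + np.sqrt(1.0 - config.baseline_gain_corr**2) * rng.standard_normal()
        )
        base_legpress = max(
            config.baseline_legpress_mean + config.baseline_legpress_sd * z1,
            config.baseline_legpress_min,
        ) * config.sex_strength_factor[str(row.sex)]
        gain_pct = max(
            config.gain_mean + config.gain_sd * z2, config.gain_floor
        )
        gain_log2 = np.log2(1.0 + gain_pct / 100.0)
        machine_base = {
            m: base_legpress
            * frac[m]
            * np.exp(rng.normal(0.0, config.machine_baseline_sd))
            for m in machines
        }
        machine_dev = {
            m: rng.normal(0.0, config.machine_noise_sd) for m in machines
        }
        miss_p = rng.beta(*config.compliance_beta)

        def strength_at(week: float, machine: str) -> float:
            f = np.interp(week, [0.0, 4.0, 8.0], [0.0, config.w4_fraction, 1.0])
            return machine_base[machine] * 2.0 ** (
                f * (gain_log2 + machine_dev[machine])
            )

        # fitness tests at W0 always, W4/W8 when still training
        for tp, week in (("W0", 0), ("W4", 4), ("W8", 8)):
            if week > weeks_trained and week > 0:
                continue
            for m in machines:
                fitness_rows.append(
                    (
                        row.participant,
                        tp,
                        (start + pd.Timedelta(weeks=week)).date().isoformat(),
                        m,
                        round(strength_at(week, m), 2),
                        row.body_weight,
                        row.age,
                        row.sex,
                    )
                )

        lo, hi = config.sessions_per_week
        weekday_pool = (0, 2, 4)  # Mon, Wed, Fri
        for week in range(1, weeks_trained + 1):
            n_sessions = int(rng.integers(lo, hi + 1))
            days = sorted(
                rng.choice(weekday_pool, size=n_sessions, replace=False)
            )
            program, reps, conc, ecc = config.phase_schedule[group][
                _phase_of_week(week)
            ]
            for day in days:
                date = (
                    start + pd.Timedelta(weeks=week - 1, days=int(day))
                ).date().isoformat()
                for m in machines:
                    smax = strength_at(week - 0.5, m)
                    weight = round(smax * conc / 100.0, 1)
                    for _ in range(config.sets_per_machine):
                        deficit = rng.binomial(reps, miss_p)
                        session_rows.append(
                            (
                                row.participant,
                                date,
                                m,
                                program,
                                weight,
                                reps,
                                reps - deficit,
                                round(smax, 2),
                            )
                        )
    sessions = pd.DataFrame(
        session_rows,
        columns=[
            "participant",
            "date",
            "machine",
            "program",
            "weight",
            "reps_target",
            "reps_done",
            "max_strength",
        ],
    )
    fitness = pd.DataFrame(
        fitness_rows,
        columns=[
            "participant",
            "timepoint",
            "date",
            "machine",
            "max_strength",
            "body_weight",
            "age",
            "sex",
        ],
    )
    return sessions, fitness


# ---------------------------------------------------------------------------
# ASV tables

#: Mock SILVA-style lineages cycled over the simulated ASVs.  Purely a
#: naming device; no claim about which synthetic ASV "is" which taxon.
_LINEAGES = (
    "Bacteria;Bacillota;Clostridia;Oscillospirales;Ruminococcaceae;Faecalibacterium;Faecalibacterium prausnitzii",
    "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Roseburia;Roseburia hominis",
    "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Agathobacter;",
    "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Lachnoclostridium;",
    "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Blautia;",
    "Bacteria;Bacillota;Clostridia;Lachnospirales;Lachnospiraceae;Coprococcus;Coprococcus eutactus",
    "Bacteria;Bacillota;Clostridia;Oscillospirales;Oscillospiraceae;NK4A214 group;",
    "Bacteria;Bacillota;Clostridia;Oscillospirales;Ruminococcaceae;Ruminococcus;",
    "Bacteria;Bacillota;Clostridia;Oscillospirales;Butyricicoccaceae;Butyricicoccus;",
    "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;Bacteroides massiliensis",
    "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella;",
    "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Rikenellaceae;Alistipes;",
    "Bacteria;Actinomycetota;Actinomycetes;Bifidobacteriales;Bifidobacteriaceae;Bifidobacterium;",
    "Bacteria;Verrucomicrobiota;Verrucomicrobiae;Verrucomicrobiales;Akkermansiaceae;Akkermansia;Akkermansia muciniphila",
    "Bacteria;Pseudomonadota;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia-Shigella;",
    "Bacteria;Bacillota;Negativicutes;Veillonellales-Selenomonadales;Veillonellaceae;Dialister;",
    "Bacteria;Bacillota;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;",
    "Bacteria;Desulfobacterota;Desulfovibrionia;Desulfovibrionales;Desulfovibrionaceae;Bilophila;",
)


def _asv_ids(n_asv: int) -> list[str]:
    return [f"ASV{i + 1:04d}" for i in range(n_asv)]


def generate_taxonomy(n_asv: int) -> pd.DataFrame:
    ids = _asv_ids(n_asv)
    taxa = [_LINEAGES[i % len(_LINEAGES)] for i in range(n_asv)]
    return pd.DataFrame({"asv": ids, "taxonomy": taxa})


def generate_asv_tables(
    participants: pd.DataFrame,
    responder_scores: Optional[pd.Series] = None,
    config: Optional[MicrobiomeSimConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Longitudinal ASV count table, sample metadata, taxonomy and truth.

    ``responder_scores`` maps participant id -> strength gain (percent);
    the planted effect of participant p is scaled by
    s_p = coupling_strength * percentile(gain_p), so high responders carry
    the largest community shift and the effect vanishes toward the bottom
    of the gain distribution (and everywhere when coupling is 0).
    Participants without a score sit at the median percentile.  Dropout
    participants contribute a W0 sample only.
    """
    config = config or MicrobiomeSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_asv = config.n_asv
    ids = _asv_ids(n_asv)

    base_log = rng.normal(0.0, config.baseline_log_abundance_sd, size=n_asv)
    if config.planted_up is not None:
        planted_up = list(config.planted_up)
        planted_down = list(config.planted_down or ())
    else:
        # plant effects among the more abundant half of the community so the
        # shift is visible at the whole-community (beta-diversity) level,
        # matching differential taxa that are common gut genera
        eligible = np.flatnonzero(base_log >= np.median(base_log))
        n_planted = config.n_planted_up + config.n_planted_down
        if n_planted > eligible.size:
            raise ConfigError(
                f"{n_planted} planted ASVs requested but only "
                f"{eligible.size} eligible (abundant-half) ASVs exist; "
                "increase n_asv or pass explicit planted sets"
            )
        chosen = rng.choice(
            eligible, size=config.n_planted_up + config.n_planted_down,
            replace=False,
        )
        planted_up = [ids[i] for i in chosen[: config.n_planted_up]]
        planted_down = [ids[i] for i in chosen[config.n_planted_up :]]
    bad = [a for a in planted_up + planted_down if a not in ids]
    if bad:
        raise ConfigError(f"planted ASV ids outside 1..n_asv: {bad}")
    up_idx = np.array([ids.index(a) for a in planted_up], dtype=int)
    down_idx = np.array([ids.index(a) for a in planted_down], dtype=int)
    rho = config.within_subject_correlation
    subject_sd = config.within_sd * np.sqrt(rho / (1.0 - rho))

    scores = responder_scores if responder_scores is not None else pd.Series(dtype=float)
    pct = scores.rank(method="average") / (len(scores) + 1.0) if len(scores) else scores
    c = config.coupling_strength

    sample_ids: list[str] = []
    meta_rows: list[tuple] = []
    columns: list[np.ndarray] = []
    scale_by_participant: dict[str, float] = {}
    effect_by_tp = {"W0": 0.0, "W4": config.effect_log2fc_w4,
                    "W8": config.effect_log2fc_w8}
    ln2 = np.log(2.0)
    for row in participants.itertuples():
        pid = str(row.participant)
        timepoints = (
            ("W0",) if row.status == STATUS_DROPOUT else ("W0", "W4", "W8")
        )
        p_pct = float(pct.get(pid, 0.5)) if len(scores) else 0.5
        scale = max(c * p_pct, 0.0)
        scale_by_participant[pid] = scale
        subject_effect = rng.normal(0.0, subject_sd, size=n_asv)
        for tp in timepoints:
            log_a = (
                base_log
                + subject_effect
                + rng.normal(0.0, config.within_sd, size=n_asv)
            )
            effect = effect_by_tp[tp] * scale * ln2
            if effect != 0.0:
                log_a[up_idx] += effect
                log_a[down_idx] -= effect
            comp = np.exp(log_a - log_a.max())
            comp /= comp.sum()
            size = config.depth_dispersion
            depth = max(
                int(
                    rng.negative_binomial(
                        size, size / (size + config.mean_depth)
                    )
                ),
                1,
            )
            counts = rng.multinomial(depth, comp)
            sample_id = f"{pid}-{tp}"
            sample_ids.append(sample_id)
            meta_rows.append((sample_id, pid, tp, row.group))
            columns.append(counts)

    counts = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(ids, name="asv"),
        columns=sample_ids,
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample-id", "participant", "timepoint", "group"]
    )
    taxonomy = generate_taxonomy(n_asv)
    truth = {
        "planted_up": planted_up,
        "planted_down": planted_down,
        "effect_log2fc_w4": config.effect_log2fc_w4,
        "effect_log2fc_w8": config.effect_log2fc_w8,
        "coupling_strength": c,
        "effect_scale": scale_by_participant,
        "gain_percent": {k: float(v) for k, v in scores.items()},
        "seed": config.seed,
    }
    return counts, metadata, taxonomy, truth


# ---------------------------------------------------------------------------
# metabolites

METABOLITES = (
    # short-chain fatty acids and related organic acids
    "acetate", "propionate", "butyrate", "isobutyrate", "valerate",
    "isovalerate", "caproate", "formate", "lactate", "succinate",
    # amino acids
    "alanine", "glycine", "glutamate", "glutamine", "leucine",
    "isoleucine", "valine", "tryptophan",
    # bile acid derivates
    "cholate", "chenodeoxycholate", "deoxycholate", "lithocholate",
    "taurocholate",
    # choline metabolites
    "choline", "betaine", "trimethylamine",
    # indole derivates
    "indole", "indole-3-acetate",
    # phenolic derivates
    "p-cresol", "4-hydroxyphenylacetate",
    # polyamines
    "putrescine", "spermidine",
    # vitamins
    "cobalamin", "riboflavin",
)


def generate_metabolites(
    participants: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Targeted panel of 34 compounds at W0 and W8, null by construction.

    Concentrations are log-normal with a participant-level intercept; the
    two timepoints are exchangeable (no time effect), mirroring a negative
    longitudinal metabolome outcome.
    """
    assert len(METABOLITES) == 34
    rng = np.random.default_rng(seed)
    final = participants[participants["status"] == STATUS_FINAL]
    compound_mu = rng.normal(3.0, 1.0, size=len(METABOLITES))
    rows = []
    for pid in final["participant"]:
        subject = rng.normal(0.0, 0.4, size=len(METABOLITES))
        for tp in ("W0", "W8"):
            noise = rng.normal(0.0, 0.3, size=len(METABOLITES))
            conc = np.exp(compound_mu + subject + noise)
            rows.append([pid, tp, *np.round(conc, 4)])
    return pd.DataFrame(
        rows, columns=["participant", "timepoint", *METABOLITES]
    )


# ---------------------------------------------------------------------------
# diet

FOOD_VARS = (
    "fruit_vegetables", "fish", "meat", "eggs", "dairy", "grains",
    "sweets", "salty_snacks",
)
DRINK_VARS = ("water_tea", "coffee", "juice_lemonade", "alcohol")
_DRINK_MEAN_ML = {"water_tea": 1500.0, "coffee": 400.0,
                  "juice_lemonade": 250.0, "alcohol": 100.0}


def generate_diet(
    participants: pd.DataFrame,
    seed: int = 0,
    config: Optional[DietSimConfig] = None,
) -> pd.DataFrame:
    """Diet survey table: 8 food frequencies (0-7 per week) + 4 drink
    volumes (ml/day) at three timepoints, stable per participant up to
    small survey noise."""
    config = config or DietSimConfig()
    rng = np.random.default_rng(seed)
    final = participants[participants["status"] == STATUS_FINAL]
    rows = []
    for pid in final["participant"]:
        food_base = rng.integers(0, 8, size=len(FOOD_VARS)).astype(float)
        drink_base = np.array(
            [
                _DRINK_MEAN_ML[v] * rng.lognormal(0.0, 0.4)
                for v in DRINK_VARS
            ]
        )
        for tp in ("W0", "W4", "W8"):
            food = food_base
            drink = drink_base
            if config.food_noise_sd > 0:
                food = np.clip(
                    np.round(
                        food_base
                        + rng.normal(0, config.food_noise_sd, len(FOOD_VARS))
                    ),
                    0,
                    7,
                )
            if config.drink_noise_frac > 0:
                drink = drink_base * np.exp(
                    rng.normal(0, config.drink_noise_frac, len(DRINK_VARS))
                )
            rows.append([pid, tp, *food.astype(int), *np.round(drink, 1)])
    return pd.DataFrame(
        rows,
        columns=["participant", "timepoint", *FOOD_VARS, *DRINK_VARS],
    )


# ---------------------------------------------------------------------------
# full-study convenience writer


def simulate_study(
    out_dir: str | Path,
    cohort_config: Optional[CohortConfig] = None,
    training_config: Optional[TrainingSimConfig] = None,
    microbiome_config: Optional[MicrobiomeSimConfig] = None,
    diet_config: Optional[DietSimConfig] = None,
) -> dict[str, Path]:
    """Generate and write every study file into ``out_dir``.

    Returns a name -> path mapping of the emitted files.  Strength gains
    from the generated fitness tests feed the responder coupling of the
    microbiome simulator.
    """
    from .strength import average_strength_gain  # local import: no cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or CohortConfig()
    training_config = training_config or TrainingSimConfig()
    microbiome_config = microbiome_config or MicrobiomeSimConfig()
    diet_config = diet_config or DietSimConfig()

    cohort = generate_cohort(cohort_config)
    sessions, fitness = generate_training_logs(cohort, training_config)

    gains = {}
    for pid, fit in fitness.groupby("participant"):
        tps = set(fit["timepoint"])
        if {"W0", "W8"} <= tps:
            base = dict(
                zip(
                    fit[fit["timepoint"] == "W0"]["machine"],
                    fit[fit["timepoint"] == "W0"]["max_strength"],
                )
            )
            follow = dict(
                zip(
                    fit[fit["timepoint"] == "W8"]["machine"],
                    fit[fit["timepoint"] == "W8"]["max_strength"],
                )
            )
            gains[pid] = average_strength_gain(base, follow)[1]
    scores = pd.Series(gains)

    counts, metadata, taxonomy, truth = generate_asv_tables(
        cohort, scores, microbiome_config
    )
    metabolites = generate_metabolites(cohort, seed=diet_config.seed + 1)
    diet = generate_diet(cohort, seed=diet_config.seed, config=diet_config)

    paths = {}
    meta_common = {"generator": "liftbiome-synthgen"}

    def _emit(name, frame, index=False, index_label=None, extra=None):
        path = out / name
        info = dict(meta_common)
        info.update(extra or {})
        write_tsv(frame, path, meta=info, index=index, index_label=index_label)
        paths[name] = path

    _emit("participants.tsv", cohort, extra={"seed": cohort_config.seed})
    _emit("exclusions.tsv", exclusion_log(cohort))
    _emit("sessions.tsv", sessions, extra={"seed": training_config.seed})
    _emit("fitness.tsv", fitness, extra={"seed": training_config.seed})
    _emit(
        "counts.tsv", counts, index=True, index_label="asv",
        extra={"seed": microbiome_config.seed},
    )
    _emit("taxonomy.tsv", taxonomy)
    # QIIME2 sample-metadata dialect: plain TSV, first column sample-id
    meta_path = out / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False, lineterminator="\n")
    paths["metadata.tsv"] = meta_path
    _emit("metabolites.tsv", metabolites, extra={"seed": diet_config.seed + 1})
    _emit("diet.tsv", diet, extra={"seed": diet_config.seed})
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth.json"] = truth_path
    return paths
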