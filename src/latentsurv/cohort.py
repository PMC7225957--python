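"""Synthetic paired RNA/miRNA cohort generator with planted subtype structure.

Emulates the statistical structure of a TCGA-style lung-adenocarcinoma
multi-omics cohort: two latent patient subtypes with distinct exponential
hazards, a minority of subtype-differential features among many nulls,
negative miRNA->target-RNA coupling on the log scale, excess zeros injected
completely at random, and subtype-associated binary clinical covariates.
Everything downstream of data acquisition is testable against the planted
truth this module records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, RNA, MIRNA, write_clinical_tsv

HIGH_RISK = "high-risk"
LOW_RISK = "low-risk"

#: Default subtype-conditional Bernoulli rates for binary covariates,
#: (p_high_risk, p_low_risk). new_tumor_event matches the 83/198 vs 48/166
#: rates and female the 115/198 vs 84/166 rates of the real LUAD subtypes.
DEFAULT_COVARIATE_PROBS: dict[str, tuple[float, float]] = {
    "new_tumor_event": (83 / 198, 48 / 166),
    "female": (115 / 198, 84 / 166),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the full-scale cohort (364 patients, 198 high-risk /
    166 low-risk); :meth:`scaled_down` gives the smaller configuration used
    throughout the test suite.
    """

    n_patients: int = 364
    prop_high_risk: float = 198 / 364
    n_rna: int = 2000
    n_mirna: int = 300
    n_diff_rna: int = 200
    n_diff_mirna: int = 30
    effect_size: float = 1.5          # standardized mean shift on the log scale
    mirna_coupling: float = -0.3      # weight of each diff miRNA on its target RNAs
    targets_per_mirna: int = 5
    baseline_hazard: float = 1 / 1200  # events per day, low-risk group
    hazard_ratio: float = 3.0          # high-risk vs low-risk
    censor_time_max: float = 3650.0    # uniform administrative censoring (days)
    zero_rate: float = 0.15            # MCAR excess-zero fraction
    covariate_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PROBS))
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prop_high_risk < 1:
            raise ValueError("prop_high_risk must be in (0, 1)")
        if self.n_diff_rna > self.n_rna:
            raise ValueError("n_diff_rna exceeds n_rna")
        if self.n_diff_mirna > self.n_mirna:
            raise ValueError("n_diff_mirna exceeds n_mirna")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must be in [0, 1)")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be positive")
        if self.n_patients < 4:
            raise ValueError("n_patients too small")
        for name, (ph, pl) in self.covariate_probs.items():
            if not (0 <= ph <= 1 and 0 <= pl <= 1):
                raise ValueError(f"covariate_probs[{name!r}] out of [0, 1]")

    @classmethod
    def scaled_down(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Small cohort (200 patients, 400 RNA, 60 miRNA) for fast pipelines."""
        params = dict(n_patients=200, n_rna=400, n_mirna=60,
                      n_diff_rna=40, n_diff_mirna=10, seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class SyntheticCohort:
    rna: ExpressionMatrix
    mirna: ExpressionMatrix
    clinical: pd.DataFrame
    true_labels: pd.Series            # patient id -> "high-risk" | "low-risk"
    truth: dict                        # differential indices and parameters

    def write(self, outdir: str | Path) -> None:
        """Write expression TSVs, clinical TSV and truth JSON to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rna.to_tsv(outdir / "rna.tsv")
        self.mirna.to_tsv(outdir / "mirna.tsv")
        write_clinical_tsv(self.clinical, outdir / "clinical.tsv")
        self.true_labels.rename("true_label").to_csv(
            outdir / "true_labels.tsv", sep="\t", index_label="patient_id")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; identical config (incl. seed) is bit-identical.

    Log-scale expression is ``base + subtype shift (differential features)
    + miRNA coupling + N(0,1) noise``; values are exponentiated, then a
    ``zero_rate`` fraction of entries is zeroed completely at random.
    Survival times are exponential with hazard ``baseline_hazard *
    hazard_ratio**is_high_risk``, censored administratively at
    ``Uniform(0, censor_time_max)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_high = int(round(config.prop_high_risk * n))
    n_high = min(max(n_high, 1), n - 1)

    patients = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    is_high = np.zeros(n, dtype=bool)
    is_high[rng.permutation(n)[:n_high]] = True
    labels = pd.Series(np.where(is_high, HIGH_RISK, LOW_RISK), index=patients)

    rna_ids = [f"gene{j:04d}" for j in range(config.n_rna)]
    mirna_ids = [f"mir{j:03d}" for j in range(config.n_mirna)]

    diff_rna = np.sort(rng.choice(config.n_rna, config.n_diff_rna, replace=False))
    diff_mirna = np.sort(rng.choice(config.n_mirna, config.n_diff_mirna, replace=False))
    # random up/down direction per differential feature
    rna_dir = rng.choice([-1.0, 1.0], size=config.n_diff_rna)
    mirna_dir = rng.choice([-1.0, 1.0], size=config.n_diff_mirna)

    def log_expr(n_feat, diff_idx, direction):
        base = rng.normal(2.0, 0.5, size=n_feat)          # per-feature level
        shift = np.zeros(n_feat)
        shift[diff_idx] = config.effect_size * direction
        noise = rng.normal(0.0, 1.0, size=(n, n_feat))
        return base[None, :] + np.outer(is_high.astype(float), shift) + noise

    log_mirna = log_expr(config.n_mirna, diff_mirna, mirna_dir)
    log_rna = log_expr(config.n_rna, diff_rna, rna_dir)

    # negative miRNA -> target-RNA coupling on the log scale
    targets: dict[str, list[int]] = {}
    if config.mirna_coupling != 0.0 and config.n_diff_mirna > 0:
        for j, mi in enumerate(diff_mirna):
            tgt = rng.choice(config.n_rna, min(config.targets_per_mirna, config.n_rna),
                             replace=False)
            targets[mirna_ids[mi]] = [int(t) for t in tgt]
            centered = log_mirna[:, mi] - log_mirna[:, mi].mean()
            log_rna[:, tgt] += config.mirna_coupling * centered[:, None]

    rna_vals = np.exp(log_rna)
    mirna_vals = np.exp(log_mirna)
    if config.zero_rate > 0:
        rna_vals[rng.random(rna_vals.shape) < config.zero_rate] = 0.0
        mirna_vals[rng.random(mirna_vals.shape) < config.zero_rate] = 0.0

    rna = ExpressionMatrix(pd.DataFrame(rna_vals, index=patients, columns=rna_ids),
                           pd.Series(RNA, index=rna_ids))
    mirna = ExpressionMatrix(pd.DataFrame(mirna_vals, index=patients, columns=mirna_ids),
                             pd.Series(MIRNA, index=mirna_ids))

    # survival: exponential hazards, uniform administrative censoring
    hazard = config.baseline_hazard * np.where(is_high, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_time_max, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)  # keep times strictly positive

    clinical = pd.DataFrame({"time_days": time, "event": event}, index=patients)
    for name, (p_high, p_low) in config.covariate_probs.items():
        p = np.where(is_high, p_high, p_low)
        clinical[name] = (rng.random(n) < p).astype(int)

    truth = {
        "diff_rna": [rna_ids[i] for i in diff_rna],
        "diff_mirna": [mirna_ids[i] for i in diff_mirna],
        "mirna_targets": {k: [rna_ids[i] for i in v] for k, v in targets.items()},
        "n_high_risk": int(n_high),
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in asdict(config).items()},
    }
    return SyntheticCohort(rna=rna, mirna=mirna, clinical=clinical,
                           true_labels=labels, truth=truth)


def simulate_gene_sets(truth: dict, n_null_sets: int, set_size: int,
                       seed: int = 0) -> dict[str, list[str]]:
    """One "signal" set of differential RNAs plus ``n_null_sets`` null sets.

    The signal set is drawn from the cohort's differential RNA features; null
    sets are drawn uniformly from the non-differential features. Returns a
    name -> member-list mapping writable as GMT.
    """
    rng = np.random.default_rng(seed)
    diff = list(truth["diff_rna"])
    all_rna = [f for f in truth_all_rna(truth)]
    null_pool = [f for f in all_rna if f not in set(diff)]
    if set_size > len(diff):
        raise ValueError(f"set_size {set_size} exceeds {len(diff)} differential features")
    if set_size > len(null_pool):
        raise ValueError(f"set_size {set_size} exceeds {len(null_pool)} null features")
    sets: dict[str, list[str]] = {}
    sets["signal_set"] = sorted(rng.choice(diff, set_size, replace=False).tolist())
    for i in range(n_null_sets):
        sets[f"null_set_{i:03d}"] = sorted(
            rng.choice(null_pool, set_size, replace=False).tolist())
    return sets


def truth_all_rna(truth: dict) -> list[str]:
    """Reconstruct the full RNA feature-id list from a cohort truth record."""
    n_rna = truth["config"]["n_rna"]
    return [f"gene{j:04d}" for j in range(n_rna)]


def simulate_cnv(labels: pd.Series, shifted_chromosomes: dict[str, float] | None = None,
                 n_chromosomes: int = 22, sd: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Per-patient per-chromosome mean log2 copy values with optional planted shifts.

    ``shifted_chromosomes`` maps chromosome name (e.g. ``"chr8"``) to the mean
    shift added for high-risk patients; all other chromosomes are null.
    """
    rng = np.random.default_rng(seed)
    shifted_chromosomes = shifted_chromosomes or {}
    chroms = [f"chr{i}" for i in range(1, n_chromosomes + 1)]
    is_high = (labels == HIGH_RISK).to_numpy()
    vals = rng.normal(0.0, sd, size=(len(labels), len(chroms)))
    for c, shift in shifted_chromosomes.items():
        if c not in chroms:
            raise ValueError(f"unknown chromosome {c!r}")
        vals[is_high, chroms.index(c)] += shift
    return pd.DataFrame(vals, index=labels.index, columns=chroms)
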