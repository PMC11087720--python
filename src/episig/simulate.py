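"""Seeded generator of Infinium-EPIC-like methylation cohorts with planted
episignatures.

The model: every probe has a baseline mean beta drawn from a bimodal
low/high mixture (array betas cluster near 0 and 1, with a minority of
intermediate probes).  A planted differentially methylated probe shifts a
case's mean by ``sign * m * delta``, where ``m`` is the sample's mosaic
fraction — the linear bulk-dilution model: a variant present in a fraction
``m`` of blood cells moves the bulk beta by ``m`` times the cell-level
shift.  Episignature-negative cases are simply cases with ``m = 0``.
Observed betas are Beta-distributed around the (clipped) mean with a common
concentration, reproducing the bounded, heteroskedastic noise of array
measurements.  Age nudges a small random subset of non-planted probes on
the M scale and a "sexlike" probe block separates the sexes, so covariate
adjustment has something real to do.

Everything planted is recorded in machine-readable truth objects so
parameter-recovery tests can grade the discovery pipeline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, ConsistencyError
from .io import beta_to_m, m_to_beta

_MEAN_FLOOR, _MEAN_CEIL = 0.01, 0.99
_BETA_EPS = 1e-6


@dataclass
class BaselineMixture:
    """Three-component mixture of baseline probe means."""

    weights: tuple[float, float, float] = (0.45, 0.45, 0.10)  # low / high / mid

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(3, size=n, p=self.weights)
        means = np.empty(n)
        n_low = int((comp == 0).sum())
        n_high = int((comp == 1).sum())
        n_mid = int((comp == 2).sum())
        means[comp == 0] = rng.beta(2.0, 18.0, size=n_low)  # mean ~ 0.1
        means[comp == 1] = 1.0 - rng.beta(2.0, 18.0, size=n_high)  # mean ~ 0.9
        means[comp == 2] = rng.uniform(0.25, 0.75, size=n_mid)
        return np.clip(means, 0.015, 0.985)


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic cohort.

    Defaults are the discovery-scale conditions: 60 cases vs 85 age- and
    sex-matched controls on a 20,000-probe EPIC-like universe with 200
    planted probes at |delta beta| = 0.10, 70% of them hypermethylated.
    """

    n_probes: int = 20_000
    n_cases: int = 60
    n_controls: int = 85
    n_true_dmps: int = 200
    delta: float = 0.10
    hyper_fraction: float = 0.7
    mosaic_fractions: dict = field(default_factory=dict)  # sample id -> m
    n_negative_cases: int = 0
    age_range: tuple[float, float] = (2.0, 40.0)
    noise_precision: float = 100.0
    seed: int = 0
    cohort: str = "cohort1"
    # covariate structure
    frac_age_probes: float = 0.01
    age_slope_sd: float = 0.01  # M-units per year
    n_sex_probes: int = 100
    sex_shift_m: float = 1.0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ArgumentError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.n_true_dmps > self.n_probes:
            raise ArgumentError(
                f"n_true_dmps ({self.n_true_dmps}) exceeds n_probes ({self.n_probes})"
            )
        if not 0.0 <= self.hyper_fraction <= 1.0:
            raise ArgumentError("hyper_fraction must be in [0, 1]")
        if self.delta < 0:
            raise ArgumentError("delta must be >= 0")
        if self.n_negative_cases > self.n_cases:
            raise ArgumentError("n_negative_cases exceeds n_cases")
        if self.noise_precision <= 0:
            raise ArgumentError("noise_precision must be positive")
        for sid, m in self.mosaic_fractions.items():
            if not 0.0 <= m <= 1.0:
                raise ArgumentError(f"mosaic fraction for {sid!r} outside [0, 1]: {m}")


@dataclass
class CohortTruth:
    """Everything the generator planted, for parameter-recovery grading."""

    probe_truths: pd.DataFrame  # probe_id, baseline_mean, precision, is_dmp, direction, delta
    planted_set: set[str]
    negative_case_ids: set[str]
    mosaic_map: dict[str, float]
    age_slopes: dict[str, float] = field(default_factory=dict)  # probe -> M-units/year
    sex_probes: list[str] = field(default_factory=list)
    age_center: float = 0.0
    config: SimulationConfig | None = None

    def hyper_set(self) -> set[str]:
        pt = self.probe_truths
        return set(pt.loc[pt["direction"] == "hyper", "probe_id"])


# ---------------------------------------------------------------------------
# baseline and effects


def simulate_baseline(
    n_probes: int, seed: int, mixture: BaselineMixture | None = None
) -> pd.DataFrame:
    """Draw per-probe baseline truths (no planted effects yet).

    Returns a DataFrame with columns ``probe_id, baseline_mean, precision,
    is_dmp, direction, delta``; deterministic under ``seed``.
    """
    if n_probes < 1:
        raise ArgumentError(f"n_probes must be >= 1, got {n_probes}")
    rng = np.random.default_rng(seed)
    mixture = mixture or BaselineMixture()
    means = mixture.draw(n_probes, rng)
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "baseline_mean": means,
            "precision": 100.0,
            "is_dmp": False,
            "direction": "none",
            "delta": 0.0,
        }
    )


def apply_case_effect(baseline_mean: float, delta: float, direction: str, m: float) -> float:
    """Mean shift for a case: ``baseline + sign * m * delta``, clipped.

    ``m`` is the mosaic fraction; the bulk signal is the cell-level shift
    diluted linearly by the fraction of affected cells.
    """
    if not 0.0 < baseline_mean < 1.0:
        raise ArgumentError(f"baseline_mean must be in (0,1), got {baseline_mean}")
    if not 0.0 <= m <= 1.0:
        raise ArgumentError(f"mosaic fraction must be in [0,1], got {m}")
    if direction == "none":
        if delta > 0:
            raise ConsistencyError("direction 'none' with a positive delta")
        return float(np.clip(baseline_mean, _MEAN_FLOOR, _MEAN_CEIL))
    if direction not in ("hyper", "hypo"):
        raise ArgumentError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "hyper" else -1.0
    return float(np.clip(baseline_mean + sign * m * delta, _MEAN_FLOOR, _MEAN_CEIL))


def _plant_signature(
    truths: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator,
    planted_ids: list[str] | None = None, directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mark ``n_true_dmps`` probes as planted, choosing probes whose baseline
    leaves room for the full shift (a hyper probe at baseline 0.95 cannot
    move up by 0.10)."""
    truths = truths.copy()
    if planted_ids is None:
        n_hyper = int(round(config.hyper_fraction * config.n_true_dmps))
        n_hypo = config.n_true_dmps - n_hyper
        room = 0.02
        hyper_ok = truths.index[
            truths["baseline_mean"] + config.delta <= _MEAN_CEIL - room
        ].to_numpy()
        hypo_ok = truths.index[
            truths["baseline_mean"] - config.delta >= _MEAN_FLOOR + room
        ].to_numpy()
        if len(hyper_ok) < n_hyper or len(hypo_ok) < n_hypo + n_hyper:
            raise ArgumentError("not enough probes with room for the planted effect")
        hyper_idx = rng.choice(hyper_ok, size=n_hyper, replace=False)
        hypo_pool = np.setdiff1d(hypo_ok, hyper_idx)
        hypo_idx = rng.choice(hypo_pool, size=n_hypo, replace=False)
        for idx, direction in ((hyper_idx, "hyper"), (hypo_idx, "hypo")):
            truths.loc[idx, ["is_dmp", "direction", "delta"]] = [True, direction, config.delta]
    else:
        id_to_idx = pd.Series(truths.index, index=truths["probe_id"])
        for pid in planted_ids:
            idx = id_to_idx[pid]
            truths.loc[idx, ["is_dmp", "direction", "delta"]] = [
                True, directions[pid], config.delta,
            ]
    return truths


# ---------------------------------------------------------------------------
# whole cohorts


def _draw_samples(
    truths: pd.DataFrame,
    sheet: pd.DataFrame,
    mosaic_map: dict[str, float],
    age_slopes: dict[str, float],
    sex_probes: list[str],
    age_center: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the beta matrix for the samples of ``sheet`` given full truth."""
    probe_ids = truths["probe_id"].to_numpy()
    baseline = truths["baseline_mean"].to_numpy()
    n_probes, n_samples = len(probe_ids), len(sheet)
    mean = np.tile(baseline[:, None], (1, n_samples))

    planted = truths["is_dmp"].to_numpy()
    sign = np.where(truths["direction"].to_numpy() == "hyper", 1.0, -1.0)
    deltas = truths["delta"].to_numpy()
    idx_of = {pid: i for i, pid in enumerate(probe_ids)}

    for j, row in enumerate(sheet.itertuples(index=False)):
        if row.group in ("case", "validation", "query"):
            m = mosaic_map.get(row.sample_id, 1.0)
            if m > 0:
                mean[planted, j] += sign[planted] * m * deltas[planted]

    # age effect on the M scale for the designated probes
    ages = sheet["age"].to_numpy(dtype=float)
    for pid, slope in age_slopes.items():
        i = idx_of[pid]
        m_vals = beta_to_m(mean[i, :]) + slope * (ages - age_center)
        mean[i, :] = m_to_beta(np.asarray(m_vals))
    # sexlike block: females shifted on the M scale
    if sex_probes:
        is_f = (sheet["sex"].to_numpy() == "F").astype(float)
        rows = [idx_of[p] for p in sex_probes]
        m_vals = beta_to_m(mean[rows, :]) + config.sex_shift_m * is_f[None, :]
        mean[rows, :] = m_to_beta(np.asarray(m_vals))

    mean = np.clip(mean, _MEAN_FLOOR, _MEAN_CEIL)
    phi = config.noise_precision
    betas = rng.beta(mean * phi, (1.0 - mean) * phi)
    betas = np.clip(betas, _BETA_EPS, 1.0 - _BETA_EPS)
    return pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sheet["sample_id"].to_numpy())


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate one cohort: (beta matrix, sample sheet, truth).

    Bit-identical output for identical config + seed.  Negative cases are
    cases with mosaic fraction forced to 0 on every planted probe; explicit
    ``mosaic_fractions`` override the default m = 1 for named samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = simulate_baseline(config.n_probes, seed=config.seed + 1)
    if config.n_true_dmps > 0:
        truths = _plant_signature(truths, config, rng)

    case_ids = [f"{config.cohort}_case{i:03d}" for i in range(1, config.n_cases + 1)]
    ctrl_ids = [f"{config.cohort}_ctrl{i:03d}" for i in range(1, config.n_controls + 1)]
    lo, hi = config.age_range
    sheet = pd.DataFrame(
        {
            "sample_id": case_ids + ctrl_ids,
            "group": ["case"] * config.n_cases + ["control"] * config.n_controls,
            "age": np.round(rng.uniform(lo, hi, size=config.n_cases + config.n_controls), 1),
            "sex": rng.choice(["F", "M"], size=config.n_cases + config.n_controls),
            "cohort": config.cohort,
        }
    )

    negative_ids = set(
        rng.choice(case_ids, size=config.n_negative_cases, replace=False).tolist()
        if config.n_negative_cases
        else []
    )
    mosaic_map = {cid: 1.0 for cid in case_ids}
    mosaic_map.update(config.mosaic_fractions)
    for cid in negative_ids:
        mosaic_map[cid] = 0.0

    # covariate-affected probes are drawn among non-planted probes
    non_planted = truths.loc[~truths["is_dmp"], "probe_id"].to_numpy()
    n_age = int(round(config.frac_age_probes * config.n_probes))
    n_age = min(n_age, max(len(non_planted) - config.n_sex_probes, 0))
    cov_probes = rng.choice(
        non_planted, size=min(n_age + config.n_sex_probes, len(non_planted)), replace=False
    )
    age_probes = cov_probes[:n_age]
    sex_probes = list(cov_probes[n_age:])
    age_slopes = dict(zip(age_probes, rng.normal(0.0, config.age_slope_sd, size=len(age_probes))))
    age_center = float((lo + hi) / 2.0)

    beta = _draw_samples(
        truths, sheet, mosaic_map, age_slopes, sex_probes, age_center, config, rng
    )
    truth = CohortTruth(
        probe_truths=truths,
        planted_set=set(truths.loc[truths["is_dmp"], "probe_id"]),
        negative_case_ids=negative_ids,
        mosaic_map=mosaic_map,
        age_slopes=age_slopes,
        sex_probes=sex_probes,
        age_center=age_center,
        config=config,
    )
    return beta, sheet, truth


def simulate_cases_from_truth(
    truth: CohortTruth,
    n: int,
    seed: int,
    m: float = 1.0,
    group: str = "validation",
    prefix: str = "val",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw fresh case-like samples carrying the same planted signature.

    Used for validation cohorts and mosaic-dilution experiments: the probe
    truths (baselines, planted set, covariate structure) are frozen, only
    the samples are new, each with mosaic fraction ``m``.
    """
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    if not 0.0 <= m <= 1.0:
        raise ArgumentError(f"mosaic fraction must be in [0,1], got {m}")
    config = truth.config
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}_{i:03d}" for i in range(1, n + 1)]
    lo, hi = config.age_range
    sheet = pd.DataFrame(
        {
            "sample_id": ids,
            "group": group,
            "age": np.round(rng.uniform(lo, hi, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "cohort": config.cohort,
        }
    )
    mosaic = {sid: m for sid in ids}
    beta = _draw_samples(
        truth.probe_truths, sheet, mosaic, truth.age_slopes, truth.sex_probes,
        truth.age_center, config, rng,
    )
    return beta, sheet


def simulate_multi_cohort(
    base_config: SimulationConfig, k_cohorts: int, overlap_fraction: float
) -> list[tuple[pd.DataFrame, pd.DataFrame, CohortTruth]]:
    """Generate ``k_cohorts`` cohorts on one probe universe with controlled
    signature overlap.

    Cohort i (i > 1) shares exactly ``round(overlap_fraction * n_true_dmps)``
    planted probes with cohort 1 (consistent direction); its remaining
    planted probes are disjoint from every other cohort's.
    """
    if k_cohorts < 2:
        raise ArgumentError(f"k_cohorts must be >= 2, got {k_cohorts}")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ArgumentError("overlap_fraction must be in [0, 1]")
    base_config.validate()
    n_shared = int(round(overlap_fraction * base_config.n_true_dmps))

    import copy

    cfg1 = copy.deepcopy(base_config)
    cfg1.cohort = "cohort1"
    beta1, sheet1, truth1 = simulate_cohort(cfg1)
    out = [(beta1, sheet1, truth1)]

    rng = np.random.default_rng(base_config.seed + 10_000)
    planted1 = sorted(truth1.planted_set)
    directions1 = truth1.probe_truths.set_index("probe_id")["direction"].to_dict()
    shared = sorted(rng.choice(planted1, size=n_shared, replace=False).tolist())
    used = set(planted1)

    truths_template = truth1.probe_truths.copy()
    truths_template[["is_dmp", "delta"]] = [False, 0.0]
    truths_template["direction"] = "none"

    for k in range(2, k_cohorts + 1):
        cfg = copy.deepcopy(base_config)
        cfg.cohort = f"cohort{k}"
        cfg.seed = base_config.seed + k
        crng = np.random.default_rng(cfg.seed)
        # fresh private probes with room for the shift, disjoint from all cohorts
        room_ok = truths_template.loc[
            (truths_template["baseline_mean"] + cfg.delta <= _MEAN_CEIL - 0.02)
            | (truths_template["baseline_mean"] - cfg.delta >= _MEAN_FLOOR + 0.02),
            "probe_id",
        ]
        pool = sorted(set(room_ok) - used)
        n_private = cfg.n_true_dmps - n_shared
        if len(pool) < n_private:
            raise ArgumentError("probe universe too small for disjoint planted sets")
        private = sorted(crng.choice(pool, size=n_private, replace=False).tolist())
        used.update(private)

        directions = {pid: directions1[pid] for pid in shared}
        baseline = truths_template.set_index("probe_id")["baseline_mean"]
        n_hyper = int(round(cfg.hyper_fraction * n_private))
        hyper_first = [p for p in private if baseline[p] + cfg.delta <= _MEAN_CEIL - 0.02]
        chosen_hyper = set(hyper_first[:n_hyper])
        for pid in private:
            if pid in chosen_hyper:
                directions[pid] = "hyper"
            elif baseline[pid] - cfg.delta >= _MEAN_FLOOR + 0.02:
                directions[pid] = "hypo"
            else:
                directions[pid] = "hyper"
        planted_ids = shared + private

        truths_k = _plant_signature(truths_template, cfg, crng, planted_ids, directions)
        case_ids = [f"{cfg.cohort}_case{i:03d}" for i in range(1, cfg.n_cases + 1)]
        ctrl_ids = [f"{cfg.cohort}_ctrl{i:03d}" for i in range(1, cfg.n_controls + 1)]
        lo, hi = cfg.age_range
        sheet = pd.DataFrame(
            {
                "sample_id": case_ids + ctrl_ids,
                "group": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
                "age": np.round(crng.uniform(lo, hi, size=len(case_ids) + len(ctrl_ids)), 1),
                "sex": crng.choice(["F", "M"], size=len(case_ids) + len(ctrl_ids)),
                "cohort": cfg.cohort,
            }
        )
        mosaic = {cid: 1.0 for cid in case_ids}
        beta = _draw_samples(truths_k, sheet, mosaic, {}, [], 0.0, cfg, crng)
        out.append(
            (
                beta,
                sheet,
                CohortTruth(
                    probe_truths=truths_k,
                    planted_set=set(planted_ids),
                    negative_case_ids=set(),
                    mosaic_map=mosaic,
                    config=cfg,
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# synthetic genomic annotation (for the comparative/annotation stage)


def simulate_annotation(
    probe_ids, seed: int, n_chroms: int = 22, chrom_length: int = 50_000_000,
    n_cgis_per_chrom: int = 60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic probe annotation and CpG-island intervals.

    Returns ``(annotation, cgi_bed)``: annotation with columns
    ``probe_id, chrom, position (1-based), gene_region``; CGI intervals as a
    BED-style frame (``chrom, start, end``; 0-based half-open).
    """
    rng = np.random.default_rng(seed)
    probe_ids = list(probe_ids)
    chroms = [f"chr{i}" for i in range(1, n_chroms + 1)]
    ann = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": rng.choice(chroms, size=len(probe_ids)),
            "position": rng.integers(1, chrom_length, size=len(probe_ids)),
            "gene_region": rng.choice(
                ["promoter", "promoter_plus", "gene_body", "intergenic"],
                size=len(probe_ids),
                p=[0.25, 0.15, 0.35, 0.25],
            ),
        }
    )
    rows = []
    for chrom in chroms:
        starts = np.sort(rng.choice(chrom_length - 5_000, size=n_cgis_per_chrom, replace=False))
        lengths = rng.integers(500, 3_000, size=n_cgis_per_chrom)
        prev_end = -10_000
        for s, ln in zip(starts, lengths):
            if s <= prev_end + 8_000:  # keep islands well separated
                continue
            rows.append({"chrom": chrom, "start": int(s), "end": int(s + ln)})
            prev_end = s + ln
    return ann, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialisation of truth


def write_truth(truth: CohortTruth, path) -> None:
    """Truth TSV: probe_id, is_dmp, direction, delta."""
    truth.probe_truths[["probe_id", "is_dmp", "direction", "delta"]].to_csv(
        path, sep="\t", index=False
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    return d
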