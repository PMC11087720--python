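"""Differential-methylation statistics and episignature probe selection.

The discovery statistic is a moderated t: per-probe ordinary least squares
of M-values on ``[intercept, group, covariates]`` followed by
empirical-Bayes shrinkage of the residual variances toward a common prior.
Residual variances are modelled as scaled F-distributed,
``s^2 ~ s0^2 F(df, d0)``; the prior ``(d0, s0^2)`` is fit by the method of
moments on ``log s^2`` and the posterior variance is the precision-weighted
blend ``s~^2 = (d0 s0^2 + df s^2) / (d0 + df)``.  The moderated t uses
``d0 + df`` degrees of freedom, so probes borrow strength from the whole
array — the standard stabilisation for small-cohort array studies.

Effect sizes are reported on the interpretable beta scale (case mean beta
minus control mean beta) while testing is done on M-values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    ArgumentError,
    DegenerateVarianceError,
    InstabilityError,
    ModelError,
    SelectionError,
)
from .io import beta_to_m

DEFAULT_COVARIATES = ("age", "sex")


# ---------------------------------------------------------------------------
# per-probe linear model


def build_design(sheet: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Design matrix ``[intercept, group(case=1), covariates...]``.

    ``sex`` is encoded F=1/M=0; numeric covariates are passed through.
    Column order is fixed so the group coefficient is always column 1.
    """
    cols = {"intercept": np.ones(len(sheet))}
    cols["group"] = (sheet["group"].to_numpy() == "case").astype(float)
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (sheet["sex"].to_numpy() == "F").astype(float)
        else:
            vals = pd.to_numeric(sheet[cov], errors="coerce").to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ArgumentError(f"covariate {cov!r} has missing values")
            cols[cov] = vals
    return pd.DataFrame(cols, index=sheet["sample_id"].to_numpy())


def fit_probe_models(
    m_values: pd.DataFrame, sheet: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """OLS of each probe's M-values on the design; vectorised across probes.

    Returns a DataFrame indexed by probe id with columns ``coef`` (group
    effect on the M scale), ``s2`` (residual mean square), ``df`` (residual
    degrees of freedom) and ``se_unit`` (``sqrt((X'X)^-1[g,g])``, the
    standard-error unit so that ``se(coef) = s * se_unit``).
    """
    design = build_design(sheet, covariates)
    x = design.to_numpy()
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # identify collinear columns by rank drop on leave-one-out
        collinear = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ModelError(f"design is rank-deficient; collinear columns: {collinear}")
    for grp, cnt in sheet["group"].value_counts().items():
        if grp in ("case", "control") and cnt < 2:
            raise ModelError(f"group {grp!r} has fewer than 2 samples")

    y = m_values[design.index].to_numpy()  # probes x samples, design order
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = y @ x @ xtx_inv  # probes x p
    resid = y - coefs @ x.T
    df = n - p
    if df < 1:
        raise ModelError(f"non-positive residual degrees of freedom ({df})")
    s2 = (resid**2).sum(axis=1) / df
    g = list(design.columns).index("group")
    se_unit = math.sqrt(xtx_inv[g, g])
    return pd.DataFrame(
        {"coef": coefs[:, g], "s2": s2, "df": float(df), "se_unit": se_unit},
        index=m_values.index,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass
class EbayesPrior:
    """Prior of the scaled-F variance model: degrees of freedom ``d0``
    (``inf`` = complete shrinkage) and prior variance ``s0_sq``."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> EbayesPrior:
    """Method-of-moments fit of ``(d0, s0^2)`` on ``log s^2``.

    Under ``s^2 ~ s0^2 F(df, d0)``:
    ``E[log s^2] = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)``
    and ``Var[log s^2] = psi'(df/2) + psi'(d0/2)``; both moments are matched
    empirically.  If the empirical variance of ``log s^2`` does not exceed
    the sampling component ``psi'(df/2)``, ``d0`` is infinite (no
    probe-to-probe variance heterogeneity beyond sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise DegenerateVarianceError("all residual variances are zero")
    z = np.log(positive)
    e_mean = float(np.mean(z)) - special.digamma(df / 2.0) + math.log(df / 2.0)
    if positive.size < 2:
        return EbayesPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return EbayesPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return EbayesPrior(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fit: pd.DataFrame, d0: float | None = None, s0_sq: float | None = None
) -> tuple[EbayesPrior, pd.DataFrame]:
    """Moderate per-probe variances and compute moderated t and p-values.

    ``fit`` is the output of :func:`fit_probe_models`.  ``d0``/``s0_sq``
    override the fitted prior (``d0=0`` recovers the ordinary t statistic;
    ``d0=inf`` forces every posterior variance to ``s0_sq``).  Returns the
    prior and a copy of ``fit`` with ``s2_post``, ``t_mod`` and ``p`` added.
    """
    df = float(fit["df"].iloc[0])
    s2 = fit["s2"].to_numpy(dtype=float)
    if d0 is None:
        prior = fit_variance_prior(s2, df)
    else:
        if d0 < 0:
            raise ArgumentError(f"d0 must be >= 0, got {d0}")
        if s0_sq is None:
            # d0=0 never uses s0_sq; otherwise fall back to the fitted prior
            s0_sq = 1.0 if d0 == 0 else fit_variance_prior(s2, df).s0_sq
        prior = EbayesPrior(d0=float(d0), s0_sq=float(s0_sq))

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    elif prior.d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fit["coef"].to_numpy() / (np.sqrt(s2_post) * fit["se_unit"].to_numpy())
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    return prior, out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ArgumentError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ArgumentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# effect size and the DMP table


def compute_delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Per-probe case mean beta minus control mean beta."""
    case_ids = sheet.loc[sheet["group"] == "case", "sample_id"].tolist()
    ctrl_ids = sheet.loc[sheet["group"] == "control", "sample_id"].tolist()
    if not case_ids or not ctrl_ids:
        raise ArgumentError("both case and control groups must be nonempty")
    return beta[case_ids].mean(axis=1) - beta[ctrl_ids].mean(axis=1)


def dmp_table(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    d0: float | None = None,
) -> pd.DataFrame:
    """Full discovery statistics table for one cohort.

    Columns: ``delta_beta, coef, s2, df, t_mod, p, q, rank_score`` where
    ``rank_score = |delta_beta| * (-log10 p)`` combines effect size and
    evidence for deterministic ranking.
    """
    m = beta_to_m(beta)
    fit = fit_probe_models(m, sheet, covariates)
    _, moderated = ebayes_moderate(fit, d0=d0)
    table = moderated[["coef", "s2", "df", "t_mod", "p"]].copy()
    table.insert(0, "delta_beta", compute_delta_beta(beta, sheet))
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["rank_score"] = table["delta_beta"].abs() * (-np.log10(table["p"]))
    return table


# ---------------------------------------------------------------------------
# probe selection


@dataclass
class SelectionParams:
    q_max: float = 0.01
    min_abs_delta: float = 0.05
    top_n: int = 500
    corr_max: float = 0.85


@dataclass
class ProbeSet:
    """An ordered episignature: selected probe ids plus the per-group
    training means/SDs (beta scale) needed to re-score new samples."""

    probe_ids: list[str]
    case_mean: dict[str, float] = field(default_factory=dict)
    case_sd: dict[str, float] = field(default_factory=dict)
    control_mean: dict[str, float] = field(default_factory=dict)
    control_sd: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.probe_ids:
            raise SelectionError("probe set is empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ArgumentError("duplicate probe ids in probe set")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "probe_ids": self.probe_ids,
                    "case_mean": self.case_mean,
                    "case_sd": self.case_sd,
                    "control_mean": self.control_mean,
                    "control_sd": self.control_sd,
                    "params": self.params,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ProbeSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def select_probes(
    table: pd.DataFrame,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    params: SelectionParams | None = None,
) -> ProbeSet:
    """Select the episignature probes from a DMP table.

    Filter ``q <= q_max`` and ``|delta_beta| >= min_abs_delta``; rank by
    ``rank_score`` descending (ties by probe id); truncate to ``top_n``;
    then greedily drop any probe whose Pearson correlation (across training
    samples, beta scale) with an already-kept probe exceeds ``corr_max``.
    The redundancy pruning keeps the signature from being dominated by one
    co-methylated block.
    """
    params = params or SelectionParams()
    passing = table[
        (table["q"] <= params.q_max) & (table["delta_beta"].abs() >= params.min_abs_delta)
    ]
    if passing.empty:
        q_min = float(table["q"].min()) if len(table) else float("nan")
        d_max = float(table["delta_beta"].abs().max()) if len(table) else float("nan")
        raise SelectionError(
            f"no probe passes q <= {params.q_max} and |delta_beta| >= "
            f"{params.min_abs_delta}; strictest passing thresholds would be "
            f"q >= {q_min:.3g}, |delta_beta| <= {d_max:.3g}"
        )
    ranked = passing.sort_values(
        ["rank_score", "delta_beta"], ascending=False, kind="mergesort"
    )
    # deterministic tie-break by probe id after rank_score
    ranked = ranked.iloc[
        np.lexsort((ranked.index.to_numpy(), -ranked["rank_score"].to_numpy()))
    ]
    candidates = ranked.index.tolist()[: params.top_n]

    sub = beta.loc[candidates].to_numpy()
    centred = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    norms[norms == 0] = 1.0
    unit = centred / norms[:, None]
    kept_idx: list[int] = []
    for i in range(len(candidates)):
        if kept_idx:
            corr = np.abs(unit[kept_idx] @ unit[i])
            if corr.max() > params.corr_max:
                continue
        kept_idx.append(i)
    kept = [candidates[i] for i in kept_idx]

    case_ids = sheet.loc[sheet["group"] == "case", "sample_id"].tolist()
    ctrl_ids = sheet.loc[sheet["group"] == "control", "sample_id"].tolist()
    case_beta = beta.loc[kept, case_ids]
    ctrl_beta = beta.loc[kept, ctrl_ids]
    return ProbeSet(
        probe_ids=kept,
        case_mean=case_beta.mean(axis=1).round(6).to_dict(),
        case_sd=case_beta.std(axis=1, ddof=1).round(6).to_dict(),
        control_mean=ctrl_beta.mean(axis=1).round(6).to_dict(),
        control_sd=ctrl_beta.std(axis=1, ddof=1).round(6).to_dict(),
        params={
            "q_max": params.q_max,
            "min_abs_delta": params.min_abs_delta,
            "top_n": params.top_n,
            "corr_max": params.corr_max,
        },
    )


# ---------------------------------------------------------------------------
# iterative pruning of episignature-negative discovery cases


@dataclass
class PruningResult:
    probe_set: ProbeSet
    removed_case_ids: list[str]
    rounds: pd.DataFrame  # columns: round, sample_id, mvp, flagged


def iterative_case_pruning(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    selection: SelectionParams | None = None,
    covariates=DEFAULT_COVARIATES,
    mvp_cutoff: float = 0.25,
    max_rounds: int = 3,
    seed: int = 0,
) -> PruningResult:
    """Iteratively remove discovery cases that do not carry the episignature.

    Per round: derive a probe set on the current cohort, then score every
    current case with a classifier trained with that case held out
    (leave-one-case-out, so a case cannot vouch for itself); cases with
    held-out MVP below ``mvp_cutoff`` are removed.  Stops when a round flags
    nobody or after ``max_rounds``.  A round that flags more than half the
    cases raises :class:`InstabilityError` — the signature itself is then
    untrustworthy.
    """
    from .classify import mvp_score, train_svm  # local import: avoid cycle

    current = sheet.copy()
    n_cases0 = int((current["group"] == "case").sum())
    n_ctrl0 = int((current["group"] == "control").sum())
    if n_cases0 < 10 or n_ctrl0 < 10:
        raise ArgumentError(
            f"pruning needs >= 10 cases and >= 10 controls (got {n_cases0}/{n_ctrl0})"
        )
    removed: list[str] = []
    records = []
    probe_set = None
    for rnd in range(1, max_rounds + 1):
        try:
            probe_set = select_probes(
                dmp_table(beta[current["sample_id"]], current, covariates),
                beta, current, selection,
            )
        except SelectionError as exc:
            # no derivable signature on the current cohort: untrustworthy
            raise InstabilityError(f"round {rnd}: {exc}") from exc
        case_ids = current.loc[current["group"] == "case", "sample_id"].tolist()
        flagged = []
        for cid in case_ids:
            loo = current[current["sample_id"] != cid]
            clf = train_svm(beta, probe_set, loo, seed=seed + rnd)
            mvp = float(mvp_score(clf, beta[[cid]]).iloc[0])
            is_flagged = mvp < mvp_cutoff
            records.append(
                {"round": rnd, "sample_id": cid, "mvp": mvp, "flagged": is_flagged}
            )
            if is_flagged:
                flagged.append(cid)
        if len(flagged) > 0.5 * len(case_ids):
            raise InstabilityError(
                f"round {rnd} flagged {len(flagged)}/{len(case_ids)} cases; "
                "episignature is unstable"
            )
        if not flagged:
            break
        removed.extend(flagged)
        current = current[~current["sample_id"].isin(flagged)]
    # final signature on the retained cohort
    probe_set = select_probes(
        dmp_table(beta[current["sample_id"]], current, covariates), beta, current, selection
    )
    return PruningResult(
        probe_set=probe_set,
        removed_case_ids=removed,
        rounds=pd.DataFrame(records, columns=["round", "sample_id", "mvp", "flagged"]),
    )
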