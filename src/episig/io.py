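"""Tabular I/O, beta/M-value transforms, and age/sex control matching.

The pipeline's universal exchange object is the *beta matrix*: a pandas
DataFrame of methylated-signal fractions in [0, 1], indexed by probe id with
one column per sample.  Sample metadata travels as a *sample sheet*
DataFrame with columns ``sample_id, group, age, sex, cohort``.

Beta values are bounded and heteroskedastic; linear modelling is done on
M-values, the logit-2 transform ``M = log2(beta / (1 - beta))``, which is
variance-stabilised away from the boundaries.  Betas are clipped to
``[epsilon, 1 - epsilon]`` before the transform so M is always finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, FormatError, MatchingError

logger = logging.getLogger(__name__)

#: Closed vocabulary of sample-sheet group labels.
GROUPS = ("case", "control", "other_disorder", "validation", "query")

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "age", "sex", "cohort")


# ---------------------------------------------------------------------------
# beta matrix


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Validate a probes x samples beta matrix, returning it unchanged.

    Raises :class:`FormatError` on duplicate probe/sample ids, non-numeric
    cells, or values outside [0, 1]; the error message names the offending
    probe and sample.
    """
    if beta.index.duplicated().any():
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids: {dups[:5]}")
    if beta.columns.duplicated().any():
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups[:5]}")
    values = beta.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        numeric = beta.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & beta.notna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric cell at probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
            )
        beta = numeric
        values = beta.to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"missing value at probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    out = (values < 0.0) | (values > 1.0)
    if out.any():
        i, j = np.argwhere(out)[0]
        raise FormatError(
            f"beta value {values[i, j]!r} outside [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a beta matrix TSV (first column probe_id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return validate_beta_matrix(df)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    """Write a beta matrix as TSV with ``%.6f`` values."""
    beta.to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id")


def drop_incomplete_probes(beta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop probes with any missing sample value; returns (matrix, n_dropped).

    The classifier needs complete probe vectors, so probes with missing
    values are removed wholesale rather than imputed.
    """
    complete = beta.dropna(axis=0)
    n_dropped = len(beta) - len(complete)
    if n_dropped:
        logger.info("dropped %d probes with missing values", n_dropped)
    return complete, n_dropped


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in sheet: {dups[:5]}")
    bad = set(sheet["group"].dropna()) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}; allowed: {GROUPS}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "group": str, "sex": str, "cohort": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, columns=list(SAMPLE_SHEET_COLUMNS))


# ---------------------------------------------------------------------------
# beta <-> M


def beta_to_m(beta, epsilon: float = 0.01):
    """Logit-2 transform ``M = log2(b / (1-b))`` with ``b`` clipped to
    ``[epsilon, 1-epsilon]``.

    Clipping makes the transform total and keeps M finite at the boundaries;
    it is strictly increasing on the clipped range.
    """
    if not 0.0 < epsilon < 0.5:
        raise ArgumentError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse of the (unclipped) logit-2 transform: ``beta = 2^M / (1 + 2^M)``."""
    m_arr = np.asarray(m, dtype=float)
    # expm-style stable form: 1 / (1 + 2^-M)
    beta = 1.0 / (1.0 + np.exp2(-m_arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta


# ---------------------------------------------------------------------------
# control matching


@dataclass
class MatchResult:
    """Outcome of greedy age/sex control matching."""

    selected: list[str]
    #: per-case mean absolute age gap of its matched controls (years)
    age_gaps: dict[str, float] = field(default_factory=dict)

    @property
    def mean_age_gap(self) -> float:
        return float(np.mean(list(self.age_gaps.values()))) if self.age_gaps else 0.0


def match_controls(cases: pd.DataFrame, control_pool: pd.DataFrame, ratio: int = 1) -> MatchResult:
    """Select age/sex-matched controls for each case, greedily and without
    replacement.

    Cases are processed in input order; within the case's sex stratum the
    ``ratio`` remaining controls with the smallest absolute age gap are
    taken, ties broken by control id lexicographic order.  A case whose sex
    stratum is exhausted raises :class:`MatchingError` listing every
    unmatched case.
    """
    if control_pool.empty:
        raise MatchingError("control pool is empty", unmatched=cases["sample_id"].tolist())
    if ratio < 1:
        raise ArgumentError(f"ratio must be >= 1, got {ratio}")
    for col in ("age", "sex"):
        if cases[col].isna().any():
            bad = cases.loc[cases[col].isna(), "sample_id"].tolist()
            raise ArgumentError(f"cases missing {col}: {bad}")

    remaining = control_pool.set_index("sample_id")[["age", "sex"]].copy()
    selected: list[str] = []
    age_gaps: dict[str, float] = {}
    unmatched: list[str] = []
    for _, case in cases.iterrows():
        stratum = remaining[remaining["sex"] == case["sex"]]
        if stratum.empty:
            unmatched.append(case["sample_id"])
            continue
        gaps = (stratum["age"] - case["age"]).abs()
        order = sorted(stratum.index, key=lambda cid: (gaps.loc[cid], cid))
        take = order[:ratio]
        selected.extend(take)
        age_gaps[case["sample_id"]] = float(gaps.loc[take].mean())
        remaining = remaining.drop(index=take)
    if unmatched:
        raise MatchingError(
            f"no controls left in the sex stratum for cases: {unmatched}", unmatched=unmatched
        )
    return MatchResult(selected=selected, age_gaps=age_gaps)
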