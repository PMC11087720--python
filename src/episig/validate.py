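"""Robustness views of an episignature: leave-25%-out cross-validation,
hierarchical clustering, and classical multidimensional scaling.

Cross-validation re-derives the probe set *inside* each round — probe
selection is part of the classifier, so holding samples out of scoring but
not out of selection would leak.  Each of the (default 20) rounds holds out
a stratified 25% of cases and controls, re-runs selection and training on
the remainder, and scores the held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .classify import classify_call, mvp_score, train_svm
from .dmp import SelectionParams, dmp_table, select_probes
from .exceptions import ArgumentError
from . import dmp as _dmp


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvRound:
    round_index: int
    held_out_cases: list[str]
    held_out_controls: list[str]
    mvp: dict[str, float]
    probe_set_size: int

    def calls(self) -> dict[str, str]:
        return {sid: classify_call(v) for sid, v in self.mvp.items()}


def _round_seed(master_seed: int, round_index: int) -> int:
    """Per-round seed by fixed arithmetic; stays below 2**31."""
    return (master_seed * 100_003 + round_index * 7_919) % (2**31 - 1)


def cross_validate(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    n_rounds: int = 20,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    selection: SelectionParams | None = None,
    covariates=_dmp.DEFAULT_COVARIATES,
) -> list[CvRound]:
    """Repeated stratified-holdout cross-validation with full re-derivation.

    Per round: hold out ``round(holdout_fraction * n)`` cases and controls
    (at least 1 each), derive the probe set and classifier on the remainder,
    and record every held-out sample's MVP.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ArgumentError(f"holdout_fraction must be in (0,1), got {holdout_fraction}")
    case_ids = sorted(sheet.loc[sheet["group"] == "case", "sample_id"])
    ctrl_ids = sorted(sheet.loc[sheet["group"] == "control", "sample_id"])
    n_hold_cases = int(round(holdout_fraction * len(case_ids)))
    n_hold_ctrls = int(round(holdout_fraction * len(ctrl_ids)))
    if n_hold_cases < 1 or n_hold_ctrls < 1:
        raise ArgumentError(
            f"cohort too small to hold out {holdout_fraction:.0%} of each group"
        )
    if len(case_ids) - n_hold_cases < 2 or len(ctrl_ids) - n_hold_ctrls < 2:
        raise ArgumentError("fewer than 2 training samples per group after holdout")

    rounds: list[CvRound] = []
    for r in range(1, n_rounds + 1):
        rng = np.random.default_rng(_round_seed(seed, r))
        hold_cases = sorted(rng.choice(case_ids, size=n_hold_cases, replace=False))
        hold_ctrls = sorted(rng.choice(ctrl_ids, size=n_hold_ctrls, replace=False))
        held = set(hold_cases) | set(hold_ctrls)
        train_sheet = sheet[~sheet["sample_id"].isin(held)]
        table = dmp_table(beta[train_sheet["sample_id"]], train_sheet, covariates)
        probe_set = select_probes(table, beta[train_sheet["sample_id"]], train_sheet, selection)
        clf = train_svm(beta, probe_set, train_sheet, seed=_round_seed(seed, r))
        scores = mvp_score(clf, beta[sorted(held)])
        rounds.append(
            CvRound(
                round_index=r,
                held_out_cases=list(hold_cases),
                held_out_controls=list(hold_ctrls),
                mvp={sid: float(v) for sid, v in scores.items()},
                probe_set_size=len(probe_set.probe_ids),
            )
        )
    return rounds


def cv_report_frame(rounds: list[CvRound]) -> pd.DataFrame:
    """Flatten a CV run into one row per held-out sample."""
    rows = []
    for rnd in rounds:
        for sid, v in rnd.mvp.items():
            rows.append(
                {
                    "round": rnd.round_index,
                    "sample_id": sid,
                    "held_out_group": "case" if sid in rnd.held_out_cases else "control",
                    "mvp": v,
                    "call": classify_call(v),
                    "probe_set_size": rnd.probe_set_size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus the (lexicographically
    tie-broken) leaf labels in input order of the linkage."""

    labels: list[str]
    linkage: np.ndarray = field(repr=False)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def two_way_split(self) -> tuple[set[str], set[str]]:
        """Leaf labels of the two top-level branches."""
        assignments = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        left = {lab for lab, a in zip(self.labels, assignments) if a == 1}
        right = {lab for lab, a in zip(self.labels, assignments) if a == 2}
        return left, right

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_cluster(beta_subset: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering of samples: Euclidean distance, Ward linkage.

    Samples (columns) are sorted lexicographically before linkage so the
    result is invariant to input column order.
    """
    if beta_subset.shape[1] < 2:
        raise ArgumentError("clustering needs at least 2 samples")
    labels = sorted(beta_subset.columns)
    x = beta_subset[labels].to_numpy().T
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    return Dendrogram(labels=labels, linkage=z)


# ---------------------------------------------------------------------------
# classical (Torgerson) MDS


def mds_embed(beta_subset: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical metric MDS of the samples on Euclidean distances.

    Double-centres the squared-distance matrix into the Gram matrix
    ``G = -1/2 J D^2 J``, takes the top ``n_dims`` eigenpairs, and scales
    eigenvectors by the square root of their (non-negative) eigenvalues.
    Coordinates are column-centred; each dimension's sign is fixed so its
    first nonzero loading is positive.
    """
    if beta_subset.shape[1] < 3:
        raise ArgumentError("MDS needs at least 3 samples")
    labels = list(beta_subset.columns)
    x = beta_subset.to_numpy().T
    d = squareform(pdist(x, metric="sqeuclidean"))
    if np.allclose(d, 0.0):
        raise ArgumentError("all pairwise distances are zero; embedding is degenerate")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d @ j
    eigval, eigvec = np.linalg.eigh(gram)
    # eigenvalues at numerical zero carry no geometry
    eigval[eigval < eigval.max() * 1e-10] = 0.0
    order = np.argsort(eigval)[::-1][:n_dims]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
    coords -= coords.mean(axis=0, keepdims=True)
    for k in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, k]) > 1e-12)[0]
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=labels, columns=[f"dim{i+1}" for i in range(n_dims)])
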