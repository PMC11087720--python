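"""Cross-cohort comparative epigenomics and genomic-context annotation.

Per cohort, the comparison unit is its *signature*: the top differentially
methylated probes at FDR < 0.05, ranked by p ascending and truncated at
500 (cohorts with fewer than 500 significant probes contribute all of
them).  Pairwise similarity is the directional percent of shared probes —
entry (y, x) is the percent of cohort y's probes also present in cohort
x's, so the matrix is generally asymmetric.  A tree-and-leaf view clusters
cohorts on the union probe space using each cohort's per-probe methylation
difference (0 where a probe is not in its signature), with node size =
signature size and node colour = mean methylation difference.

Probes are also placed in genomic context: CpG island / shore (within
0-2 kb of an island boundary) / shelf (2-4 kb) / open sea, and a
gene-region category carried through from the annotation; category
enrichment of a signature against background uses Fisher's exact test with
BH correction across categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact

from .dmp import bh_fdr
from .exceptions import ArgumentError, AnnotationError, ConsistencyError

MAX_SIGNATURE_SIZE = 500
FDR_THRESHOLD = 0.05
SHORE_BP = 2_000
SHELF_BP = 4_000

GENE_REGIONS = ("promoter", "promoter_plus", "gene_body", "intergenic")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")


# ---------------------------------------------------------------------------
# cohort signatures and overlap


@dataclass
class CohortSignature:
    """Top-DMP set of one cohort with per-probe methylation difference."""

    name: str
    probes: pd.DataFrame  # columns: probe_id, meth_diff (sorted by p at construction)
    selection_rule: str = f"q < {FDR_THRESHOLD}, top {MAX_SIGNATURE_SIZE} by p"
    empty: bool = False

    @property
    def probe_ids(self) -> list[str]:
        return self.probes["probe_id"].tolist()

    @property
    def mean_diff(self) -> float:
        return float(self.probes["meth_diff"].mean()) if len(self.probes) else 0.0


def build_cohort_signature(table: pd.DataFrame, name: str) -> CohortSignature:
    """Signature of one cohort from its DMP table.

    Keep probes with ``q < 0.05`` (strict); sort by p ascending, ties by
    |delta beta| descending then probe id; truncate at 500.  A cohort with
    no significant probe yields an empty-signature warning object rather
    than an error — downstream consumers can still place it.
    """
    if "q" not in table.columns:
        raise ArgumentError("DMP table has no q column")
    passing = table[table["q"] < FDR_THRESHOLD].copy()
    if passing.empty:
        return CohortSignature(
            name=name, probes=pd.DataFrame(columns=["probe_id", "meth_diff"]), empty=True
        )
    passing = passing.iloc[
        np.lexsort(
            (
                passing.index.to_numpy(),
                -passing["delta_beta"].abs().to_numpy(),
                passing["p"].to_numpy(),
            )
        )
    ]
    top = passing.head(MAX_SIGNATURE_SIZE)
    return CohortSignature(
        name=name,
        probes=pd.DataFrame(
            {"probe_id": top.index.to_numpy(), "meth_diff": top["delta_beta"].to_numpy()}
        ),
    )


def overlap_matrix(signatures: list[CohortSignature]) -> pd.DataFrame:
    """Directional percent-shared matrix.

    Entry (y, x) = ``100 * |S_y intersect S_x| / |S_y|``; diagonal 100.
    Exact integer set arithmetic — no tolerance is involved.
    """
    if len(signatures) < 2:
        raise ArgumentError("need at least 2 signatures")
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ArgumentError(f"duplicate cohort names: {names}")
    sets = {s.name: set(s.probe_ids) for s in signatures}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for y in names:
        for x in names:
            denom = len(sets[y])
            mat.loc[y, x] = 100.0 * len(sets[y] & sets[x]) / denom if denom else np.nan
    return mat


# ---------------------------------------------------------------------------
# tree-and-leaf aggregation


@dataclass
class CohortTree:
    """Binary merge tree over cohorts with per-leaf size/colour attributes."""

    labels: list[str]
    linkage: np.ndarray = field(repr=False)
    node_sizes: dict[str, int] = field(default_factory=dict)  # leaf -> n selected DMPs
    node_colors: dict[str, float] = field(default_factory=dict)  # leaf -> mean meth diff

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            return (
                f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                f":{parent_height - node.dist:.6g}"
            )

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": self.labels,
                "n_dmps": [self.node_sizes[c] for c in self.labels],
                "mean_meth_diff": [self.node_colors[c] for c in self.labels],
            }
        )


def cohort_tree(signatures: list[CohortSignature]) -> CohortTree:
    """Ward/Euclidean clustering of cohorts on the union probe space.

    Each cohort's feature vector holds its per-probe methylation difference,
    0 for probes outside its signature (= no differential methylation, the
    neutral value).  Cohorts are sorted by name before linkage so the tree
    is input-order invariant.
    """
    if len(signatures) < 2:
        raise ArgumentError("need at least 2 signatures")
    union: list[str] = sorted(set().union(*(s.probe_ids for s in signatures)))
    if not union:
        raise ArgumentError("union of signature probes is empty")
    ordered = sorted(signatures, key=lambda s: s.name)
    vectors = np.zeros((len(ordered), len(union)))
    pos = {pid: i for i, pid in enumerate(union)}
    for row, sig in enumerate(ordered):
        for pid, diff in zip(sig.probes["probe_id"], sig.probes["meth_diff"]):
            vectors[row, pos[pid]] = diff
    z = hierarchy.linkage(vectors, method="ward", metric="euclidean")
    return CohortTree(
        labels=[s.name for s in ordered],
        linkage=z,
        node_sizes={s.name: len(s.probes) for s in ordered},
        node_colors={s.name: s.mean_diff for s in ordered},
    )


# ---------------------------------------------------------------------------
# genomic-context annotation


def annotate_probes(
    probe_ids, annotation: pd.DataFrame, cgi_bed: pd.DataFrame
) -> pd.DataFrame:
    """Genomic context per probe: gene-region category and CGI relation.

    ``annotation`` columns: probe_id, chrom, position (1-based),
    gene_region.  ``cgi_bed``: chrom, start, end (0-based half-open).  A
    probe is *island* if its (0-based) position intersects an island;
    *shore* if the distance to the nearest island boundary is in
    (0, 2000] bp; *shelf* in (2000, 4000]; otherwise *open_sea*.
    """
    probe_ids = list(probe_ids)
    ann = annotation.set_index("probe_id")
    missing = [p for p in probe_ids if p not in ann.index]
    if missing:
        raise AnnotationError(
            f"{len(missing)} probes missing from annotation (first: {missing[:5]})",
            missing=missing,
        )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in cgi_bed.groupby("chrom"):
        starts = np.sort(grp["start"].to_numpy())
        ends = grp.sort_values("start")["end"].to_numpy()
        by_chrom[chrom] = (starts, ends)

    rows = []
    for pid in probe_ids:
        chrom = ann.loc[pid, "chrom"]
        pos0 = int(ann.loc[pid, "position"]) - 1  # 1-based -> 0-based
        relation = "open_sea"
        if chrom in by_chrom:
            starts, ends = by_chrom[chrom]
            k = int(np.searchsorted(starts, pos0, side="right")) - 1
            dist = None
            if k >= 0 and pos0 < ends[k]:
                relation = "island"
            else:
                cands = []
                if k >= 0:
                    cands.append(pos0 - ends[k] + 1)  # bp past the right boundary
                if k + 1 < len(starts):
                    cands.append(starts[k + 1] - pos0)  # bp before the next island
                if cands:
                    dist = min(cands)
            if relation != "island" and dist is not None:
                if 0 < dist <= SHORE_BP:
                    relation = "shore"
                elif SHORE_BP < dist <= SHELF_BP:
                    relation = "shelf"
        rows.append(
            {
                "probe_id": pid,
                "gene_region": ann.loc[pid, "gene_region"],
                "cgi_relation": relation,
            }
        )
    return pd.DataFrame(rows)


def context_enrichment(
    signature_contexts: pd.DataFrame, background_contexts: pd.DataFrame,
    axis: str = "gene_region",
) -> pd.DataFrame:
    """Category enrichment of a signature against the background probes.

    Per category: a 2x2 table (in/out of signature x in/out of category),
    two-sided Fisher exact p, BH correction across categories, and an odds
    ratio with Haldane (+0.5) correction when a cell is zero.  A raw-table
    infinite or undefined odds ratio is flagged in ``or_flag`` instead of
    being silently corrected away.
    """
    if axis not in ("gene_region", "cgi_relation"):
        raise ArgumentError(f"unknown context axis {axis!r}")
    n_sig = len(signature_contexts)
    n_bg = len(background_contexts)
    if n_bg <= n_sig:
        raise ArgumentError("background must be strictly larger than the signature")
    categories = GENE_REGIONS if axis == "gene_region" else CGI_RELATIONS
    rows = []
    for cat in categories:
        a = int((signature_contexts[axis] == cat).sum())  # signature, in category
        b = n_sig - a
        c = int((background_contexts[axis] == cat).sum())
        d = n_bg - c
        flag = ""
        if c == 0:
            flag = "undefined"  # category absent from background
            odds, p = np.nan, np.nan
        else:
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            if b == 0 or (a > 0 and d == 0):
                flag = "inf"
            if 0 in (a, b, c, d):
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (b * c)
        rows.append(
            {
                "category": cat,
                "proportion_signature": a / n_sig if n_sig else np.nan,
                "proportion_background": c / n_bg,
                "odds_ratio": odds,
                "or_flag": flag,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


# ---------------------------------------------------------------------------
# transcript-fraction reporting utility


def lof_transcript_fraction(
    exon_skipping: float, intron_retention: float, normal: float, nmd: float,
    tolerance: float = 0.5,
) -> float:
    """Percent of transcripts with a loss-of-function effect.

    Given the four transcript-class percentages of an mRNA splicing assay
    (mis-spliced with exon skipping, mis-spliced with intron retention,
    normally spliced, and degraded by nonsense-mediated decay), the
    mutated-but-detected classes — exon skipping plus intron retention —
    carry the loss-of-function effect.  The four fractions must sum to
    100 +- ``tolerance``.
    """
    parts = {
        "exon_skipping": exon_skipping,
        "intron_retention": intron_retention,
        "normal": normal,
        "nmd": nmd,
    }
    for name, value in parts.items():
        if not 0.0 <= value <= 100.0:
            raise ArgumentError(f"{name} must be in [0, 100], got {value}")
    total = sum(parts.values())
    if abs(total - 100.0) > tolerance:
        raise ConsistencyError(f"fractions sum to {total}, not 100 +- {tolerance}")
    return exon_skipping + intron_retention
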