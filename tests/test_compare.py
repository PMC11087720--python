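"""Cross-cohort signatures, overlap, tree aggregation, genomic-context
annotation, enrichment, and the transcript-fraction utility."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from episig.compare import (
    CohortSignature,
    annotate_probes,
    build_cohort_signature,
    cohort_tree,
    context_enrichment,
    lof_transcript_fraction,
    overlap_matrix,
)
from episig.exceptions import AnnotationError, ArgumentError, ConsistencyError


def _table(n, q_values=None, p_values=None, delta=0.1, seed=0):
    rng = np.random.default_rng(seed)
    p = p_values if p_values is not None else np.sort(rng.uniform(1e-8, 1e-3, n))
    q = q_values if q_values is not None else p * 2
    return pd.DataFrame(
        {"delta_beta": delta, "p": p, "q": q},
        index=[f"cg{i:06d}" for i in range(n)],
    )


def _sig(name, probe_ids, diffs=None):
    diffs = diffs if diffs is not None else [0.1] * len(probe_ids)
    return CohortSignature(
        name=name, probes=pd.DataFrame({"probe_id": list(probe_ids), "meth_diff": diffs})
    )


class TestCohortSignature:
    def test_truncates_at_500(self):
        sig = build_cohort_signature(_table(600), "a")
        assert len(sig.probes) == 500

    def test_fewer_than_500_passthrough(self):
        sig = build_cohort_signature(_table(120), "a")
        assert len(sig.probes) == 120

    def test_q_boundary_strict(self):
        table = _table(3, q_values=np.array([0.01, 0.05, 0.2]))
        sig = build_cohort_signature(table, "a")
        assert len(sig.probes) == 1  # q = 0.05 exactly is excluded

    def test_sorted_by_p_ascending(self):
        rng = np.random.default_rng(3)
        p = rng.permutation(np.linspace(1e-8, 1e-4, 50))
        table = _table(50, p_values=p)
        sig = build_cohort_signature(table, "a")
        kept_p = table.loc[sig.probe_ids, "p"].to_numpy()
        assert (np.diff(kept_p) >= 0).all()

    def test_empty_signature_is_warning_object(self):
        sig = build_cohort_signature(_table(5, q_values=np.full(5, 0.9)), "a")
        assert sig.empty and len(sig.probes) == 0


class TestOverlapMatrix:
    def test_directional_percentages(self):
        a_ids = [f"a{i}" for i in range(480)] + [f"sh{i}" for i in range(20)]
        b_ids = [f"b{i}" for i in range(180)] + [f"sh{i}" for i in range(20)]
        mat = overlap_matrix([_sig("A", a_ids), _sig("B", b_ids)])
        assert mat.loc["A", "B"] == pytest.approx(4.0)  # 100*20/500
        assert mat.loc["B", "A"] == pytest.approx(10.0)  # 100*20/200
        assert mat.loc["A", "A"] == 100.0 and mat.loc["B", "B"] == 100.0

    def test_identical_signatures(self):
        ids = [f"x{i}" for i in range(50)]
        mat = overlap_matrix([_sig("A", ids), _sig("B", ids)])
        assert mat.loc["A", "B"] == 100.0 and mat.loc["B", "A"] == 100.0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ArgumentError):
            overlap_matrix([_sig("A", ["x"]), _sig("A", ["y"])])


class TestCohortTree:
    def test_identical_cohorts_merge_at_zero(self):
        ids = [f"x{i}" for i in range(10)]
        tree = cohort_tree([_sig("A", ids), _sig("B", ids), _sig("C", ["z1", "z2"])])
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_direction_cohorts_carry_signed_colors(self):
        hyper = _sig("hyper", ["x1", "x2"], diffs=[0.1, 0.2])
        hypo = _sig("hypo", ["y1", "y2"], diffs=[-0.1, -0.2])
        tree = cohort_tree([hyper, hypo])
        assert tree.node_colors["hyper"] > 0 > tree.node_colors["hypo"]

    def test_leaf_size_equals_signature_size(self):
        a = _sig("A", [f"x{i}" for i in range(7)])
        b = _sig("B", [f"y{i}" for i in range(3)])
        tree = cohort_tree([a, b])
        assert tree.node_sizes == {"A": 7, "B": 3}

    def test_input_order_invariance(self):
        a = _sig("A", [f"x{i}" for i in range(7)], diffs=np.linspace(0.05, 0.2, 7))
        b = _sig("B", [f"y{i}" for i in range(3)])
        c = _sig("C", [f"x{i}" for i in range(4)], diffs=[-0.1] * 4)
        assert cohort_tree([a, b, c]).to_newick() == cohort_tree([c, a, b]).to_newick()


class TestAnnotation:
    ANN = pd.DataFrame(
        {
            "probe_id": ["inside", "shore", "shelf", "sea", "left_shore"],
            "chrom": "chr1",
            # 1-based positions; the island is [10000, 11000) in BED space
            "position": [10_501, 11_000 + 1_500, 11_000 + 3_000, 11_000 + 10_000, 8_500 + 1],
            "gene_region": ["promoter", "gene_body", "intergenic", "intergenic", "promoter"],
        }
    )
    CGI = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})

    def test_cgi_bins(self):
        ctx = annotate_probes(self.ANN["probe_id"], self.ANN, self.CGI).set_index("probe_id")
        assert ctx.loc["inside", "cgi_relation"] == "island"
        assert ctx.loc["shore", "cgi_relation"] == "shore"  # 1.5 kb from boundary
        assert ctx.loc["left_shore", "cgi_relation"] == "shore"
        assert ctx.loc["shelf", "cgi_relation"] == "shelf"  # 3 kb
        assert ctx.loc["sea", "cgi_relation"] == "open_sea"  # 10 kb

    def test_gene_region_passthrough(self):
        ctx = annotate_probes(["inside"], self.ANN, self.CGI)
        assert ctx["gene_region"].iloc[0] == "promoter"

    def test_bins_partition_all_probes(self):
        from episig.simulate import simulate_annotation

        ann, cgi = simulate_annotation([f"cg{i}" for i in range(500)], seed=2)
        ctx = annotate_probes(ann["probe_id"], ann, cgi)
        counts = ctx["cgi_relation"].value_counts()
        assert counts.sum() == 500
        assert set(counts.index) <= {"island", "shore", "shelf", "open_sea"}

    def test_missing_probe_listed(self):
        with pytest.raises(AnnotationError) as exc:
            annotate_probes(["nope"], self.ANN, self.CGI)
        assert exc.value.missing == ["nope"]


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestEnrichment:
    @staticmethod
    def _ctx(counts: dict, axis="gene_region"):
        rows = []
        for cat, n in counts.items():
            rows.extend({axis: cat} for _ in range(n))
        return pd.DataFrame(rows)

    def test_all_in_category_flagged_infinite(self):
        sig = self._ctx({"promoter": 10})
        bg = self._ctx({"promoter": 50, "gene_body": 50})
        out = context_enrichment(sig, bg).set_index("category")
        assert out.loc["promoter", "or_flag"] == "inf"
        assert out.loc["promoter", "proportion_signature"] == 1.0
        assert out.loc["promoter", "proportion_background"] == 0.5

    def test_fisher_matches_hypergeometric_oracle(self):
        sig = self._ctx({"promoter": 3, "gene_body": 7})
        bg = self._ctx({"promoter": 10, "gene_body": 90})
        out = context_enrichment(sig, bg).set_index("category")
        assert out.loc["promoter", "p"] == pytest.approx(
            fisher_oracle(3, 7, 10, 90), abs=1e-12
        )

    def test_null_resampling_rarely_significant(self):
        rng = np.random.default_rng(17)
        clean = 0
        cats = ["promoter", "promoter_plus", "gene_body", "intergenic"]
        for _ in range(10):
            bg = pd.DataFrame({"gene_region": rng.choice(cats, size=2000)})
            sig = bg.sample(100, random_state=rng.integers(1 << 30))
            out = context_enrichment(sig, bg)
            if (out["q"].dropna() > 0.05).all():
                clean += 1
        assert clean >= 8

    def test_category_absent_from_background_undefined(self):
        sig = self._ctx({"promoter": 5, "intergenic": 5})
        bg = self._ctx({"promoter": 40, "gene_body": 60})
        out = context_enrichment(sig, bg).set_index("category")
        assert out.loc["intergenic", "or_flag"] == "undefined"

    def test_background_must_be_larger(self):
        sig = self._ctx({"promoter": 10})
        with pytest.raises(ArgumentError):
            context_enrichment(sig, sig)


class TestLofTranscriptFraction:
    def test_reported_case_arithmetic(self):
        assert lof_transcript_fraction(15, 27, 8, 50) == pytest.approx(42.0)

    @pytest.mark.parametrize(
        "fractions,expected",
        [((0, 0, 50, 50), 0.0), ((50, 50, 0, 0), 100.0)],
    )
    def test_degenerate_cases(self, fractions, expected):
        assert lof_transcript_fraction(*fractions) == pytest.approx(expected)

    def test_inconsistent_sum_rejected(self):
        with pytest.raises(ConsistencyError):
            lof_transcript_fraction(15, 27, 8, 40)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            lof_transcript_fraction(-1, 51, 0, 50)
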