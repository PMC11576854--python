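"""Expression statistics, upregulation criteria, DE and the candidate funnel."""

import numpy as np
import pandas as pd
import pytest

from chromtraj.core_io import GeneAnnotation, GenomicInterval
from chromtraj.gene_link import (
    DECriteria,
    ExpressionTable,
    UpregulationCriteria,
    candidate_funnel,
    class_expression_stats,
    differential_genes,
    group_patterns,
    upregulated_genes,
)

STAGES = ["hiF-T", "d6", "d8", "d14", "d20", "d24", "iPSC"]


def make_expression(fpkm_by_gene: dict[str, list[float]], replicates: int = 3,
                    noise_sd: float = 0.0, seed: int = 0,
                    condition: str = "naive") -> ExpressionTable:
    """Stage-level FPKM targets expanded into noisy replicate columns."""
    rng = np.random.default_rng(seed)
    cols, rep_map = [], {}
    for s in STAGES:
        for r in range(replicates):
            col = f"{condition}_{s}_r{r + 1}"
            cols.append(col)
            rep_map[col] = (condition, s)
    rows = {}
    for gene, levels in fpkm_by_gene.items():
        vals = []
        for si, s in enumerate(STAGES):
            for _ in range(replicates):
                vals.append(max(0.0, levels[si] * 2 ** rng.normal(0, noise_sd)))
        rows[gene] = vals
    return ExpressionTable(fpkm=pd.DataFrame.from_dict(rows, orient="index",
                                                       columns=cols),
                           replicate_map=rep_map)


class TestClassExpressionStats:
    def test_identical_to_baseline_p_near_one(self):
        expr = make_expression({f"g{i}": [10.0] * 7 for i in range(12)})
        links = {f"r{i}": f"g{i}" for i in range(12)}
        classes = pd.Series("PO", index=[f"r{i}" for i in range(12)])
        out = class_expression_stats(links, classes, expr, "naive")
        assert (out["mwu_p"] > 0.9).all()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        base = {f"g{i}": list(rng.uniform(5, 15, 7)) for i in range(50)}
        for g in base:
            base[g] = [base[g][0]] + [v + 10 for v in base[g][1:]]
        expr = make_expression(base)
        links = {f"r{i}": f"g{i}" for i in range(50)}
        classes = pd.Series("CO", index=[f"r{i}" for i in range(50)])
        out = class_expression_stats(links, classes, expr, "naive")
        late = out[out["stage"] != "hiF-T"]
        assert (late["mwu_p"] < 0.001).all()

    def test_empty_class_warns_and_omits(self):
        expr = make_expression({"g0": [1.0] * 7})
        classes = pd.Series("OC", index=["r0"])
        with pytest.warns(UserWarning, match="no linked genes"):
            out = class_expression_stats({}, classes, expr, "naive")
        assert out.empty

    def test_directional_coupling_on_synthetic_study(self, default_study):
        """CO-linked genes rise across the course when coupling is positive."""
        study = default_study
        classes = pd.Series(study.ground_truth.region_class["naive"])
        links = study.links
        out = class_expression_stats(links, classes, study.expression, "naive")
        co = out[out["class"] == "CO"].set_index("stage")
        assert co.loc["iPSC", "median_log_fpkm"] > co.loc["hiF-T", "median_log_fpkm"]
        oc = out[out["class"] == "OC"].set_index("stage")
        assert oc.loc["iPSC", "median_log_fpkm"] < oc.loc["hiF-T", "median_log_fpkm"]


class TestUpregulated:
    def test_flat_gene_excluded(self):
        expr = make_expression({"flat": [100.0] * 7})
        assert upregulated_genes(expr) == []

    def test_low_level_stage_excludes_despite_fold(self):
        # 6-fold at every stage but dips to FPKM 3 at d14
        expr = make_expression({"g": [0.5, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0]})
        assert upregulated_genes(expr) == []
        expr2 = make_expression({"g": [2.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]},
                                noise_sd=0.01)
        assert upregulated_genes(expr2) == ["g"]

    def test_planted_forced_genes_recovered(self, default_study):
        up = upregulated_genes(default_study.expression, condition="naive")
        assert set(default_study.ground_truth.upregulated) <= set(up)

    def test_single_replicate_skips_p_with_warning(self):
        expr = make_expression({"g": [2.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]},
                               replicates=1)
        with pytest.warns(UserWarning, match="single replicate"):
            up = upregulated_genes(expr)
        assert up == ["g"]


class TestDifferential:
    def _expr_two_groups(self, values_a, values_b):
        cols = [f"a_r{i}" for i in range(values_a.shape[1])] + \
               [f"b_r{i}" for i in range(values_b.shape[1])]
        rep_map = {c: ("naive", "hiF-T") for c in cols}
        fpkm = pd.DataFrame(np.hstack([values_a, values_b]),
                            index=[f"g{i}" for i in range(values_a.shape[0])],
                            columns=cols)
        return ExpressionTable(fpkm=fpkm, replicate_map=rep_map), cols

    def test_identical_groups_no_de(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 50, size=(100, 3))
        expr, cols = self._expr_two_groups(vals, vals)
        out = differential_genes(expr, cols[:3], cols[3:])
        assert not out["de"].any()

    def test_single_shifted_gene_among_nulls(self):
        rng = np.random.default_rng(1)
        a = 10.0 * 2 ** rng.normal(0, 0.2, size=(1000, 3))
        b = 10.0 * 2 ** rng.normal(0, 0.2, size=(1000, 3))
        a[0] *= 8.0
        expr, cols = self._expr_two_groups(a, b)
        out = differential_genes(expr, cols[:3], cols[3:])
        assert out["de"]["g0"]
        assert out["de"].sum() == 1

    def test_bh_preserves_p_order(self):
        rng = np.random.default_rng(2)
        a = 10.0 * 2 ** rng.normal(0, 0.3, size=(200, 3))
        b = 10.0 * 2 ** rng.normal(0, 0.3, size=(200, 3))
        expr, cols = self._expr_two_groups(a, b)
        out = differential_genes(expr, cols[:3], cols[3:]).sort_values("p")
        q = out["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_degenerate_zero_variance_equal_means(self):
        a = np.full((5, 3), 4.0)
        expr, cols = self._expr_two_groups(a, a.copy())
        out = differential_genes(expr, cols[:3], cols[3:])
        assert (out["p"] == 1.0).all()


def build_funnel_fixture():
    """10 true candidates and 90 decoys each failing exactly one gate.

    decoyA: near a region + upregulated, missing from the factor list;
    decoyB: near a region + listed factor, not upregulated;
    decoyC: upregulated + listed factor, TSS > 10 kb from every region.
    """
    regions = [GenomicInterval("chr1", 50_000 + i * 40_000,
                               50_000 + i * 40_000 + 500) for i in range(40)]
    genes, fpkm = [], {}
    up_profile = [2.0] + [100.0] * 6
    flat_profile = [20.0] * 7

    def add_gene(gid, chrom, tss, profile):
        genes.append(GeneAnnotation(gid, chrom, "+", tss,
                                    GenomicInterval(chrom, tss, tss + 1000)))
        fpkm[gid] = profile

    for i in range(10):
        add_gene(f"HIT{i:02d}", "chr1", regions[i].start - 500, up_profile)
    for i in range(30):
        add_gene(f"DA{i:02d}", "chr1", regions[(10 + i) % 40].start - 700, up_profile)
    for i in range(30):
        add_gene(f"DB{i:02d}", "chr1", regions[(5 + i) % 40].start - 900, flat_profile)
    for i in range(30):
        add_gene(f"DC{i:02d}", "chr2", 1_000_000 + i * 50_000, up_profile)
    expr = make_expression(fpkm, noise_sd=0.01, seed=9)
    factor_list = [f"HIT{i:02d}" for i in range(10)] + \
                  [f"DB{i:02d}" for i in range(30)] + \
                  [f"DC{i:02d}" for i in range(30)]
    return regions, genes, expr, factor_list


class TestFunnel:
    def test_exact_recovery_of_planted_candidates(self):
        regions, genes, expr, factors = build_funnel_fixture()
        up = upregulated_genes(expr)
        res = candidate_funnel(regions, genes, up, factors)
        assert list(res.candidates["gene_id"]) == [f"HIT{i:02d}" for i in range(10)]
        assert res.n_candidates == 10

    def test_funnel_counts_monotone(self):
        regions, genes, expr, factors = build_funnel_fixture()
        up = upregulated_genes(expr)
        res = candidate_funnel(regions, genes, up, factors)
        assert res.n_linked >= res.n_upregulated_linked >= res.n_candidates

    def test_boundary_10001_bp_excluded(self):
        region = GenomicInterval("chr1", 100_000, 100_500)
        # TSS exactly 10,001 bp beyond the last region base
        far = GeneAnnotation("far", "chr1", "+", 100_499 + 10_001,
                             GenomicInterval("chr1", 110_500, 111_500))
        near = GeneAnnotation("near", "chr1", "+", 100_499 + 10_000,
                              GenomicInterval("chr1", 110_499, 111_499))
        expr = make_expression({"far": [2.0] + [100.0] * 6,
                                "near": [2.0] + [100.0] * 6}, noise_sd=0.01)
        up = upregulated_genes(expr)
        res = candidate_funnel([region], [far, near], up, ["far", "near"])
        assert list(res.candidates["gene_id"]) == ["near"]

    def test_disjoint_factor_list_empty(self):
        regions, genes, expr, _ = build_funnel_fixture()
        res = candidate_funnel(regions, genes, ["HIT00"], ["UNRELATED"])
        assert res.n_candidates == 0


class TestGroupPatterns:
    def test_canonical_examples(self):
        expr = make_expression({
            "mono": [1, 2, 4, 8, 16, 32, 64],
            "flat": [20] * 7,
            "surge": [1, 1, 1, 1, 1, 30, 40],
            "low": [1.5, 1.8, 1.2, 1.6, 1.4, 1.7, 1.5],
        })
        groups = group_patterns(["mono", "flat", "surge", "low"], expr)
        assert groups == {"mono": 1, "flat": 2, "surge": 3, "low": 4}
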