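import math

import numpy as np
import pytest
from scipy import stats

from arrayqtl.eqtl import (
    EqtlResult,
    EqtlScan,
    ExpressionMatrix,
    GenotypeMatrix,
    NotTestable,
    bh_fdr,
    compare_runs,
    direction_bias,
    regress,
    scan,
)

# ---------------------------------------------------------------------------
# independent oracles


def bh_oracle(pvalues):
    """Literal step-up definition: q(i) = min over ranks j >= rank(i) of m*p(j)/j."""
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    q = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvalues[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def binom_two_sided_oracle(k, n):
    """Exact two-sided binomial at p=0.5 by minimal-likelihood enumeration."""
    pmf = [math.comb(n, j) * 0.5**n for j in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# regress


class TestRegress:
    def test_hand_computed_four_points(self):
        # group means 1.5 and 3.5; SSE = 1.0, sxx = 1.0, df = 2
        res = regress([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.slope == pytest.approx(2.0)
        assert res.se == pytest.approx(math.sqrt(0.5))
        assert res.t == pytest.approx(2.0 / math.sqrt(0.5))
        assert res.p_value == pytest.approx(0.1055728090, abs=1e-9)

    def test_constant_expression_has_no_signal(self):
        res = regress([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        assert res.slope == 0.0 and res.p_value == 1.0

    def test_constant_genotype_not_testable(self):
        assert isinstance(regress([1, 2, 3, 4], [1, 1, 1, 1]), NotTestable)

    def test_too_few_pairs_not_testable(self):
        assert isinstance(regress([1, 2], [0, 1]), NotTestable)
        # missing genotypes drop pairs below the minimum
        assert isinstance(regress([1, 2, 3, 4], [0, 1, np.nan, np.nan]), NotTestable)

    def test_perfect_fit_flagged_degenerate(self):
        res = regress([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert res.degenerate
        assert res.p_value == np.finfo(float).tiny

    def test_missing_genotypes_dropped_pairwise(self):
        full = regress([1, 2, 3, 4], [0, 0, 1, 1])
        padded = regress([1, 2, 3, 4, 99.0], [0, 0, 1, 1, np.nan])
        assert padded.slope == pytest.approx(full.slope)
        assert padded.p_value == pytest.approx(full.p_value)
        assert padded.n == 4

    def test_binary_genotype_matches_pooled_t_test(self):
        # the OLS slope test and the equal-variance two-sample t-test coincide
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            g = rng.integers(0, 2, size=n).astype(float)
            if len(set(g)) < 2:
                continue
            y = rng.normal(size=n) + g * rng.normal()
            res = regress(y, g)
            t_ref = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
            assert abs(res.p_value - t_ref.pvalue) < 1e-10


# ---------------------------------------------------------------------------
# BH FDR


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(1e-8, 1, size=int(rng.integers(1, 60)))
            assert bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_permutation_equivariant(self, rng):
        p = rng.uniform(1e-6, 1, size=30)
        q = bh_fdr(p)
        perm = rng.permutation(30)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


# ---------------------------------------------------------------------------
# direction bias


def _results(ds, qs=None):
    qs = qs or [0.01] * len(ds)
    return [
        EqtlResult(f"PS{i}", "L1", 0.0, 0.01, 2.0, d, q)
        for i, (d, q) in enumerate(zip(ds, qs))
    ]


class TestDirectionBias:
    def test_three_of_three_positive(self):
        # two-sided exact: both all-positive and all-negative outcomes, 2 * (1/2)^3
        summary = direction_bias(_results([1.0, 2.0, 0.5]))
        assert summary.binomial_p == pytest.approx(0.25)

    def test_perfectly_balanced_is_mode(self):
        summary = direction_bias(_results([1.0] * 50 + [-1.0] * 50))
        assert summary.binomial_p == pytest.approx(1.0)
        assert summary.fraction_positive == pytest.approx(0.5)

    def test_seventy_six_of_hundred_is_significant(self):
        summary = direction_bias(_results([1.0] * 76 + [-1.0] * 24))
        assert summary.binomial_p < 0.001

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                ds = [1.0] * k + [-1.0] * (n - k)
                got = direction_bias(_results(ds)).binomial_p
                assert got == pytest.approx(binom_two_sided_oracle(k, n), rel=1e-12)

    def test_ties_excluded_and_tallied(self):
        summary = direction_bias(_results([1.0, -1.0, 0.0, 0.0]))
        assert summary.n_ties_excluded == 2
        assert summary.n_eqtl == 4
        assert summary.n_positive_d == 1
        assert summary.fraction_positive == pytest.approx(0.5)

    def test_fdr_filter(self):
        rs = _results([1.0, 1.0, -1.0], qs=[0.01, 0.5, 0.01])
        summary = direction_bias(rs, fdr_max=0.05)
        assert summary.n_eqtl == 2
        with pytest.raises(ValueError):
            direction_bias(rs, fdr_max=1e-9)


# ---------------------------------------------------------------------------
# scan


def _geno(codes, positions=None, design="backcross"):
    codes = np.asarray(codes, dtype=float)
    n_loci, n_samples = codes.shape
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        locus_ids=[f"L{j}" for j in range(n_loci)],
        positions=positions or [("chr1", (j + 1) * 1000) for j in range(n_loci)],
        codes=codes,
        design=design,
    )


def _expr(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix([f"PS{i}" for i in range(values.shape[0])], samples, values)


class TestScan:
    def test_best_locus_minimizes_p(self, rng):
        g = rng.integers(0, 2, size=(6, 20)).astype(float)
        y = g[3] * 1.5 + rng.normal(0, 0.5, 20)
        results = scan(_expr(y), _geno(g))
        (res,) = results
        for j in range(6):
            r = regress(y, g[j])
            if not isinstance(r, NotTestable):
                assert res.p_value <= r.p_value + 1e-15

    def test_exact_tie_breaks_by_genomic_order(self):
        g_row = [0, 0, 1, 1, 0, 1]
        y = [1.0, 2.0, 3.0, 4.0, 1.5, 3.5]
        geno = _geno(
            [g_row, g_row],
            positions=[("chr1", 5000), ("chr1", 1000)],
        )
        (res,) = scan(_expr(y), geno)
        assert res.best_locus_id == "L1"  # lower coordinate wins

    def test_cis_window_boundary_inclusive_at_one_megabase(self, rng):
        # the far locus is perfectly associated but sits 1 bp outside the window
        n = 20
        g_near = rng.integers(0, 2, size=n).astype(float)
        g_far = rng.integers(0, 2, size=n).astype(float)
        y = g_far * 3.0 + rng.normal(0, 0.1, n)
        geno = _geno([g_near, g_far],
                     positions=[("chr1", 3_000_000), ("chr1", 3_000_001)])
        tss = {"PS0": ("chr1", 2_000_000)}
        (res,) = scan(_expr(y), geno, mode="cis", tss=tss)
        assert res.best_locus_id == "L0"
        # move the window edge to include it and it wins
        (res2,) = scan(_expr(y), geno, mode="cis", cis_window_bp=1_000_001, tss=tss)
        assert res2.best_locus_id == "L1"

    def test_allele_effect_sign_convention(self):
        # code-0 samples express higher -> d > 0
        g = [[0, 0, 1, 1]]
        y = [10.0, 11.0, 4.0, 5.0]
        (res,) = scan(_expr(y), _geno(g))
        assert res.allele_effect_d == pytest.approx(10.5 - 4.5)
        assert res.neglog10p == pytest.approx(-math.log10(res.p_value))

    def test_untestable_probeset_omitted(self):
        geno = _geno([[1, 1, 1, 1]])  # constant everywhere
        assert scan(_expr([1.0, 2.0, 3.0, 4.0]), geno) == []

    def test_q_values_assigned_over_emitted_results(self, rng):
        g = rng.integers(0, 2, size=(4, 30)).astype(float)
        ys = rng.normal(size=(5, 30))
        results = scan(_expr(ys), _geno(g))
        qs = bh_fdr([r.p_value for r in results])
        assert [r.q_value for r in results] == pytest.approx(list(qs))

    def test_no_shared_samples_rejected(self):
        expr = _expr([[1.0, 2.0, 3.0]], samples=["a", "b", "c"])
        with pytest.raises(ValueError, match="share no samples"):
            scan(expr, _geno([[0, 1, 0]]))

    def test_cis_mode_requires_tss(self):
        with pytest.raises(ValueError, match="tss"):
            scan(_expr([[1.0, 2.0, 3.0]]), _geno([[0, 1, 0]]), mode="cis")


# ---------------------------------------------------------------------------
# run comparison


def _run(ps_to_p):
    rs = []
    for ps, p in ps_to_p.items():
        rs.append(EqtlResult(ps, "L1", 0.0, p, -math.log10(p), 1.0, None))
    return rs


class TestCompareRuns:
    def test_identical_runs(self):
        run = _run({"PS1": 0.01, "PS2": 0.5})
        cmp = compare_runs(run, run)
        assert cmp.fraction_decreased == 0.0
        assert all(d == 0 for d in cmp.deltas.values())
        assert cmp.pearson_r is None  # zero variance in the loss

    def test_sign_convention_everything_improves(self):
        unc = _run({"PS1": 0.5, "PS2": 0.4})
        cor = _run({"PS1": 0.001, "PS2": 0.0004})
        cmp = compare_runs(unc, cor)
        assert cmp.fraction_decreased == 0.0
        assert all(d > 0 for d in cmp.deltas.values())

    def test_one_up_one_down(self):
        unc = _run({"PS1": 1e-4, "PS2": 0.5})
        cor = _run({"PS1": 0.5, "PS2": 1e-4})
        assert compare_runs(unc, cor).fraction_decreased == 0.5

    def test_only_shared_probesets_compared(self):
        unc = _run({"PS1": 0.1, "PS2": 0.2, "PS3": 0.3})
        cor = _run({"PS2": 0.1, "PS3": 0.5, "PS9": 0.9})
        assert compare_runs(unc, cor).n_shared == 2

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError):
            compare_runs(_run({"PS1": 0.1}), _run({"PS1": 0.2}))


# ---------------------------------------------------------------------------
# model / results surface


class TestModelSurface:
    def test_fit_from_files_and_summary(self, tmp_path, rng):
        g = rng.integers(0, 2, size=(3, 40)).astype(float)
        geno = _geno(g)
        y = np.vstack([g[1] * 2 + rng.normal(0, 0.5, 40), rng.normal(8, 1, 40)])
        expr = _expr(y)
        geno.to_tsv(tmp_path / "geno.tsv")
        expr.to_tsv(tmp_path / "expr.tsv")

        model = EqtlScan.from_files(tmp_path / "expr.tsv", tmp_path / "geno.tsv")
        fitted = model.fit()
        assert fitted.results[0].best_locus_id == "L1"
        assert fitted.n_significant(0.05) >= 1
        text = fitted.summary()
        assert "probesets tested:        2" in text
        assert "binomial P" in text
        # results table round-trips through TSV
        fitted.to_tsv(tmp_path / "res.tsv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "res.tsv", sep="\t")
        assert list(back["probeset_id"]) == ["PS0", "PS1"]

    def test_missing_genotypes_na_roundtrip(self, tmp_path):
        geno = _geno([[0, 1, np.nan, 1]])
        geno.to_tsv(tmp_path / "g.tsv")
        back = GenotypeMatrix.from_tsv(tmp_path / "g.tsv")
        assert np.isnan(back.codes[0, 2])
        assert back.codes[0, 1] == 1
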