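import math

import numpy as np
import pandas as pd
import pytest

from translatome import (
    ValidationError,
    class_te_comparison,
    compute_te,
    differential_te,
    rank_abundance,
)
from translatome.quantify import ConditionTPM, TPMMatrix

from conftest import paired_sheet


def _cond(cell, assay, values, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(len(values))]
    return ConditionTPM(cell, assay, pd.Series(values, index=genes, dtype=float))


def welch_oracle(a, b):
    """Textbook Welch t with Welch-Satterthwaite degrees of freedom."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def bh_oracle(p):
    """Step-up Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestComputeTe:
    def test_simple_ratio(self):
        te = compute_te(_cond("B", "ribo", [100.0]), _cond("B", "rna", [25.0]), 0.0)
        row = te.table.iloc[0]
        assert row["te"] == 4.0 and row["log2_te"] == 2.0

    def test_equal_abundance_gives_zero_log2_te(self):
        vals = [3.0, 17.0, 250.0]
        te = compute_te(_cond("B", "ribo", vals), _cond("B", "rna", vals), 0.5)
        assert (te.table["log2_te"] == 0.0).all()

    def test_pseudocount_bounds_zero_ribo(self):
        te = compute_te(_cond("B", "ribo", [0.0]), _cond("B", "rna", [100.0]), 0.5)
        row = te.table.iloc[0]
        assert row["te"] == pytest.approx(0.5 / 100.5, rel=1e-12)
        assert row["log2_te"] == pytest.approx(math.log2(0.5 / 100.5), rel=1e-9)

    def test_zero_rna_without_pseudocount_flagged_undefined(self):
        te = compute_te(
            _cond("B", "ribo", [10.0, 5.0]), _cond("B", "rna", [0.0, 5.0]), 0.0
        )
        assert list(te.table["defined"]) == [False, True]

    def test_positive_tpm_zero_pseudocount_equals_elementwise_ratio(self):
        rng = np.random.default_rng(3)
        r, m = rng.uniform(1, 1000, 100), rng.uniform(1, 1000, 100)
        te = compute_te(_cond("B", "ribo", r), _cond("B", "rna", m), 0.0)
        np.testing.assert_allclose(te.table["te"], r / m, rtol=1e-12)

    def test_mismatched_gene_universe_names_discrepancy(self):
        with pytest.raises(ValidationError, match="gX"):
            compute_te(
                _cond("B", "ribo", [1.0], genes=["gX"]),
                _cond("B", "rna", [1.0], genes=["gY"]),
            )


def _tpm_from_log2te(l_a, l_b, n_filler=30, rna_tpm=100.0):
    """Build a TPMMatrix whose per-replicate log2 TE (pc=0.5) for gene gT
    equals the given vectors, plus well-behaved filler genes."""
    sheet = paired_sheet(n_replicates=len(l_a))
    rng = np.random.default_rng(0)
    genes = ["gT"] + [f"f{i}" for i in range(n_filler)]
    data = {}
    for cell, lvec in (("B", l_a), ("T", l_b)):
        for r, l in enumerate(lvec, start=1):
            ribo = (rna_tpm + 0.5) * 2.0**l - 0.5
            data[f"{cell}_ribo_{r}"] = [ribo] + list(rng.uniform(50, 150, n_filler))
            data[f"{cell}_rna_{r}"] = [rna_tpm] + list(rng.uniform(50, 150, n_filler))
    frame = pd.DataFrame(data, index=genes)[sheet.sample_ids]
    return TPMMatrix(tpm=frame, samples=sheet)


class TestDifferentialTe:
    def test_identical_groups_give_t_zero_p_one(self):
        tpm = _tpm_from_log2te([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        row = differential_te(tpm, "B", "T").table.set_index("gene_id").loc["gT"]
        assert row["t_statistic"] == 0.0
        assert row["p_value"] == 1.0
        assert row["delta_log2_te"] == 0.0

    def test_matches_hand_welch_oracle(self):
        la, lb = [1.0, 1.2, 1.1], [0.0, 0.1, -0.1]
        tpm = _tpm_from_log2te(la, lb)
        row = differential_te(tpm, "B", "T").table.set_index("gene_id").loc["gT"]
        t, p = welch_oracle(la, lb)
        assert row["t_statistic"] == pytest.approx(t, rel=1e-6)
        assert row["p_value"] == pytest.approx(p, rel=1e-6)
        assert row["delta_log2_te"] == pytest.approx(np.mean(la) - np.mean(lb), rel=1e-6)

    def test_q_values_match_step_up_oracle(self, default_tpm):
        table = differential_te(default_tpm, "B", "T").table
        np.testing.assert_allclose(table["q_value"], bh_oracle(table["p_value"]), rtol=1e-9)

    def test_antisymmetry_under_cell_swap(self, default_tpm):
        ab = differential_te(default_tpm, "B", "T").table.set_index("gene_id")
        ba = differential_te(default_tpm, "T", "B").table.set_index("gene_id")
        np.testing.assert_allclose(ab["delta_log2_te"], -ba["delta_log2_te"], atol=1e-12)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], rtol=1e-9)

    def test_single_replicate_cell_rejected(self):
        sheet = paired_sheet(n_replicates=1)
        frame = pd.DataFrame(
            {s: [100.0, 50.0] for s in sheet.sample_ids}, index=["g1", "g2"]
        )
        with pytest.raises(ValidationError, match="replicates"):
            differential_te(TPMMatrix(tpm=frame, samples=sheet), "B", "T")

    def test_unpaired_replicate_indices_rejected(self):
        sheet = paired_sheet(n_replicates=2)
        t = sheet.table.copy()
        t.loc[(t.sample_id == "B_rna_2"), "replicate"] = 3
        from translatome import SampleSheet

        sheet2 = SampleSheet(t)
        frame = pd.DataFrame(
            {s: [100.0, 50.0] for s in sheet2.sample_ids}, index=["g1", "g2"]
        )
        with pytest.raises(ValidationError, match="unpaired"):
            differential_te(TPMMatrix(tpm=frame, samples=sheet2), "B", "T")


class TestClassTeComparison:
    def _te(self, class_vals, bg_vals):
        genes = [f"c{i}" for i in range(len(class_vals))] + [
            f"b{i}" for i in range(len(bg_vals))
        ]
        vals = list(class_vals) + list(bg_vals)
        te = compute_te(
            _cond("B", "ribo", [2.0**v for v in vals], genes=genes),
            _cond("B", "rna", [1.0] * len(vals), genes=genes),
            0.0,
        )
        return te, [f"c{i}" for i in range(len(class_vals))]

    def test_exact_small_sample_u_and_p(self):
        te, cls = self._te([1.0, 2.0], [3.0, 4.0])
        cmp_ = class_te_comparison(te, cls, "B")
        assert cmp_.u_statistic == 0.0
        # one-sided exact P(U <= 0) = 1/6; two-sided doubles it
        assert cmp_.p_value == pytest.approx(1 / 3, rel=1e-12)
        assert cmp_.mean_difference == -2.0

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_draws = 200
        for _ in range(n_draws):
            vals = rng.normal(0, 1, 120)
            genes = [f"g{i}" for i in range(120)]
            te = compute_te(
                _cond("B", "ribo", 2.0**vals, genes=genes),
                _cond("B", "rna", np.ones(120), genes=genes),
                0.0,
            )
            cls = rng.choice(genes, 30, replace=False)
            if class_te_comparison(te, cls, "B").p_value < 0.05:
                hits += 1
        assert 0.01 <= hits / n_draws <= 0.10

    def test_recovers_planted_shift_of_minus_two(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(0, 0.5, 200)
        cls = rng.normal(-2, 0.5, 200)
        te, members = self._te(cls, bg)
        cmp_ = class_te_comparison(te, members, "B")
        assert cmp_.mean_difference == pytest.approx(-2.0, abs=0.15)
        assert cmp_.p_value < 1e-10

    def test_empty_class_is_error(self):
        te, _ = self._te([1.0], [2.0, 3.0])
        with pytest.raises(ValidationError, match="no member"):
            class_te_comparison(te, ["absent"], "B")


class TestRankAbundance:
    def test_dense_ranking_of_ties(self):
        ranking = rank_abundance(_cond("B", "rna", [5.0, 5.0, 1.0]))
        assert list(ranking.table["rank"]) == [1, 1, 2]

    def test_top_rank_has_maximal_tpm(self):
        rng = np.random.default_rng(2)
        cond = _cond("B", "rna", rng.uniform(0, 1000, 50))
        t = rank_abundance(cond).table
        assert t.loc[t["rank"] == 1, "mean_tpm"].iloc[0] == cond.mean_tpm.max()

    def test_matches_sort_oracle_on_random_table(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 50, 100).astype(float)  # force ties
        t = rank_abundance(_cond("B", "rna", vals)).table.set_index("gene_id")
        uniq = np.sort(np.unique(vals))[::-1]
        expected = {v: i + 1 for i, v in enumerate(uniq)}
        for g, row in t.iterrows():
            assert row["rank"] == expected[row["mean_tpm"]]

    def test_membership_flags(self):
        from translatome import GeneSet, GeneSetCollection

        sets = GeneSetCollection({"S": GeneSet("S", "", ("g1",))})
        t = rank_abundance(_cond("B", "rna", [5.0, 1.0]), sets).table.set_index("gene_id")
        assert bool(t.loc["g1", "in_S"]) and not bool(t.loc["g2", "in_S"])
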