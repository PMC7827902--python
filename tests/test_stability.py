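"""Filters, normalization, batch correction and the stability score."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from exoref import (
    AbundanceMatrix,
    CountMatrix,
    RankingConfig,
    SampleSheet,
    StabilityTable,
    ValidationError,
    compute_stability,
    correct_batch,
    drop_low_depth_samples,
    estimate_size_factors,
    filter_consistent_mirnas,
    normalize_log2,
    rank_select,
    select_candidates,
)

# The published top-20 ranking (miRNA, Z-score, CV%, rank) used as a
# sorting/selection fixture; mean abundance is not published, so a dummy
# descending column stands in (it only matters for tie-breaks, and the
# Z-scores here are tie-free).
TOP20 = [
    ("miR-21-5p", 8.14, 3.98, 1), ("miR-92a-3p", 6.66, 5.01, 2),
    ("miR-486-5p", 6.38, 5.78, 3), ("miR-26a-5p", 4.32, 6.49, 4),
    ("miR-423-5p", 4.31, 7.13, 5), ("miR-22-3p", 3.78, 6.40, 6),
    ("miR-30d-5p", 3.24, 7.00, 7), ("let-7f-5p", 2.44, 9.33, 8),
    ("let-7a-5p", 2.42, 8.92, 9), ("miR-151a-3p", 2.39, 5.80, 10),
    ("miR-451a-5p", 2.07, 11.10, 11), ("let-7i-5p", 1.98, 10.58, 12),
    ("miR-191-5p", 1.86, 7.34, 13), ("miR-126-3p", 1.68, 9.48, 14),
    ("let-7g-5p", 1.67, 7.68, 15), ("miR-148a-3p", 1.60, 11.46, 16),
    ("miR-101-3p", 1.25, 8.38, 17), ("miR-10a-5p", 0.89, 6.93, 18),
    ("let-7b-5p", 0.87, 9.28, 19), ("miR-320a-3p", 0.82, 9.43, 20),
]


def top20_table(shuffle_seed=None) -> StabilityTable:
    rows = list(TOP20)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(rows)
    df = pd.DataFrame(rows, columns=["mirna", "z_score", "cv_percent", "rank"])
    df["mean_abundance"] = np.linspace(18, 10, len(df))
    df["rank"] = np.arange(1, len(df) + 1)  # placeholder dense ranks
    return StabilityTable(df)


def make_cm(arr, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# Depth filter
# ---------------------------------------------------------------------------

class TestDepthFilter:
    def test_boundary_inclusive(self):
        """Exactly 2,000,000 reads is kept; one read fewer is dropped."""
        cm = make_cm([[1_999_999, 2_000_000]])
        out = drop_low_depth_samples(cm, 2_000_000)
        assert out.sample_ids == ["s1"]

    def test_toy_totals(self):
        totals = [1_000_000, 3_000_000, 2_000_000, 500_000, 4_000_000]
        cm = make_cm([totals])
        out = drop_low_depth_samples(cm, 2_000_000)
        assert out.sample_ids == ["s1", "s2", "s4"]

    def test_identity_when_all_pass(self, toy_counts):
        out = drop_low_depth_samples(toy_counts, min_reads=1)
        pd.testing.assert_frame_equal(out.counts, toy_counts.counts)

    def test_all_dropped_is_error(self, toy_counts):
        with pytest.raises(ValidationError, match="no samples pass"):
            drop_low_depth_samples(toy_counts, 10**9)


# ---------------------------------------------------------------------------
# Consistency filter
# ---------------------------------------------------------------------------

class TestConsistencyFilter:
    def test_read_sum_boundary(self):
        arr = np.zeros((2, 10), dtype=int)
        arr[0, 0] = 9    # sum 9 < 10 -> removed even if we ignore detection
        arr[1, :] = 1    # sum 10, detected in all -> kept
        out = filter_consistent_mirnas(make_cm(arr), min_sum=10, min_frac=0.0001)
        assert out.gene_ids == ["g1"]

    def test_detection_fraction_boundary(self):
        arr = np.zeros((2, 100), dtype=int)
        arr[0, :79] = 5   # 79% detected -> removed
        arr[1, :80] = 5   # 80% detected -> kept (inclusive)
        out = filter_consistent_mirnas(make_cm(arr), min_sum=10, min_frac=0.8)
        assert out.gene_ids == ["g1"]

    def test_matches_exhaustive_predicate(self):
        """Survivors equal a brute-force evaluation of both conditions."""
        arr = np.array([
            [3, 3, 3, 0, 0],    # sum 9 fails, 60% fails
            [2, 2, 2, 2, 2],    # sum 10 ok, 100% ok
            [20, 0, 0, 0, 0],   # sum ok, 20% fails
            [5, 5, 0, 5, 5],    # sum ok, 80% ok
        ])
        expected = [g for g, row in enumerate(arr)
                    if row.sum() >= 10
                    and (row > 0).sum() / len(row) >= 0.8]
        out = filter_consistent_mirnas(make_cm(arr), 10, 0.8)
        assert out.gene_ids == [f"g{g}" for g in expected]

    def test_permutation_equivariance(self, rng):
        arr = rng.integers(0, 6, size=(12, 10))
        cm = make_cm(arr)
        perm = rng.permutation(10)
        cm_p = CountMatrix(cm.counts.iloc[:, perm])
        out = filter_consistent_mirnas(cm, 10, 0.5)
        out_p = filter_consistent_mirnas(cm_p, 10, 0.5)
        assert out.gene_ids == out_p.gene_ids


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Loop-based median-of-ratios, independent of the implementation."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        if all(counts[g, j] > 0 for j in range(n_samples)):
            prod = 1.0
            for j in range(n_samples):
                prod *= counts[g, j]
            geomeans.append((g, prod ** (1.0 / n_samples)))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[g, j] / gm for g, gm in geomeans)
        k = len(ratios)
        mid = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        factors.append(mid)
    return np.array(factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm(np.tile([[10], [30], [7]], (1, 4)))
        sf = estimate_size_factors(cm)
        assert np.allclose(sf.to_numpy(), 1.0)

    def test_hand_computed_example(self):
        """geomeans sqrt(200), sqrt(1800); per-gene ratios agree, median = ratio."""
        cm = make_cm([[10, 20], [30, 60]])
        sf = estimate_size_factors(cm)
        assert sf.to_numpy() == pytest.approx([0.7071, 1.4142], abs=5e-5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 60, size=(5, 4))
            counts[0] = rng.integers(1, 60, size=4)  # ensure a positive gene
            sf = estimate_size_factors(make_cm(counts))
            expected = brute_force_size_factors(counts.astype(float))
            assert np.max(np.abs(sf.to_numpy() - expected)) < 1e-12

    def test_column_scale_equivariance(self, rng):
        """Scaling one column by k multiplies its factor by k relative to
        the others (the geometric-mean reference absorbs k^(1/n), so the
        exact invariant lives in the factor ratios); scaling every column
        by k cancels in every ratio and leaves all factors unchanged."""
        for _ in range(50):
            counts = rng.integers(1, 200, size=(6, 5))
            sf = estimate_size_factors(make_cm(counts)).to_numpy()
            k = 3
            scaled = counts.copy()
            scaled[:, 2] *= k
            sf2 = estimate_size_factors(make_cm(scaled)).to_numpy()
            others = [0, 1, 3, 4]
            assert sf2[2] / sf2[others] == pytest.approx(
                k * sf[2] / sf[others], rel=1e-12)
            sf_all = estimate_size_factors(make_cm(counts * k)).to_numpy()
            assert sf_all == pytest.approx(sf, rel=1e-12)

    def test_no_positive_gene_is_error(self):
        cm = make_cm([[0, 1], [1, 0]])
        with pytest.raises(ValidationError, match="all-positive"):
            estimate_size_factors(cm)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class TestNormalizeLog2:
    def test_closed_form_values(self):
        cm = make_cm([[30, 0]])
        sf = pd.Series([1.5, 1.0], index=["s0", "s1"])
        am = normalize_log2(cm, sf, pseudocount=1.0)
        assert am.values.iloc[0, 0] == pytest.approx(math.log2(21), abs=1e-4)
        assert am.values.iloc[0, 1] == 0.0  # log2(0/1 + 1)

    def test_unit_factors_give_log2_counts_plus_one(self, toy_counts):
        sf = pd.Series(1.0, index=toy_counts.sample_ids)
        am = normalize_log2(toy_counts, sf, 1.0)
        expected = np.log2(toy_counts.counts.to_numpy() + 1.0)
        assert np.allclose(am.values.to_numpy(), expected)
        assert am.normalized and not am.batch_corrected

    def test_missing_size_factor_is_error(self, toy_counts):
        sf = pd.Series([1.0], index=["s1"])
        with pytest.raises(ValidationError, match="missing"):
            normalize_log2(toy_counts, sf, 1.0)


# ---------------------------------------------------------------------------
# Batch correction
# ---------------------------------------------------------------------------

def make_am(values, samples=None) -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=samples)
    return AbundanceMatrix(df)


def sheet_for(samples, batches) -> SampleSheet:
    return SampleSheet(pd.DataFrame(
        {"batch": batches, "group": "HD", "timepoint": "none"},
        index=pd.Index(samples, name="sample_id")))


class TestBatchCorrection:
    def test_single_batch_is_identity(self, rng):
        am = make_am(rng.normal(10, 1, size=(5, 6)))
        sheet = sheet_for(am.sample_ids, ["b1"] * 6)
        out = correct_batch(am, sheet)
        assert np.allclose(out.values.to_numpy(), am.values.to_numpy())
        assert out.batch_corrected

    def test_planted_shift_removed_exactly(self, rng):
        base = rng.normal(12, 1, size=(8, 4))
        shifted = np.concatenate([base, base + 2.0], axis=1)  # batch2 = batch1 + 2
        am = make_am(shifted)
        sheet = sheet_for(am.sample_ids, ["b1"] * 4 + ["b2"] * 4)
        out = correct_batch(am, sheet)
        v = out.values.to_numpy()
        diff = v[:, :4].mean(axis=1) - v[:, 4:].mean(axis=1)
        assert np.max(np.abs(diff)) <= 1e-9

    def test_idempotent(self, rng):
        am = make_am(rng.normal(10, 2, size=(6, 9)))
        sheet = sheet_for(am.sample_ids, ["b1", "b2", "b3"] * 3)
        once = correct_batch(am, sheet)
        twice = correct_batch(once, sheet)
        assert np.max(np.abs(once.values.to_numpy()
                             - twice.values.to_numpy())) <= 1e-9

    def test_within_batch_deviations_preserved(self, rng):
        am = make_am(rng.normal(10, 2, size=(4, 8)))
        batches = ["b1"] * 4 + ["b2"] * 4
        sheet = sheet_for(am.sample_ids, batches)
        out = correct_batch(am, sheet)
        for cols in (slice(0, 4), slice(4, 8)):
            before = am.values.to_numpy()[:, cols]
            after = out.values.to_numpy()[:, cols]
            dev_before = before - before.mean(axis=1, keepdims=True)
            dev_after = after - after.mean(axis=1, keepdims=True)
            assert np.allclose(dev_before, dev_after)

    def test_singleton_batch_is_error(self, rng):
        am = make_am(rng.normal(10, 1, size=(3, 3)))
        sheet = sheet_for(am.sample_ids, ["b1", "b1", "b2"])
        with pytest.raises(ValidationError, match="single sample"):
            correct_batch(am, sheet)


# ---------------------------------------------------------------------------
# Stability score
# ---------------------------------------------------------------------------

def spreadsheet_stability(values: np.ndarray):
    """Cell-by-cell recomputation of mean, CV% and mz_diff score."""
    means, cvs = [], []
    for row in values:
        m = sum(row) / len(row)
        var = sum((x - m) ** 2 for x in row) / (len(row) - 1)
        means.append(m)
        cvs.append(100.0 * math.sqrt(var) / m)

    def mz(xs):
        med = statistics.median(xs)
        mad = statistics.median([abs(x - med) for x in xs])
        return [0.6745 * (x - med) / mad for x in xs]

    mzm, mzc = mz(means), mz(cvs)
    return means, cvs, [a - b for a, b in zip(mzm, mzc)]


class TestComputeStability:
    def test_matches_spreadsheet_oracle(self, rng):
        values = rng.normal(12, 2, size=(3, 4))
        am = make_am(values)
        stab = compute_stability(am).table.set_index("mirna")
        means, cvs, zs = spreadsheet_stability(values)
        for i in range(3):
            row = stab.loc[f"g{i}"]
            assert row["mean_abundance"] == pytest.approx(means[i], rel=1e-12)
            assert row["cv_percent"] == pytest.approx(cvs[i], rel=1e-12)
            assert row["z_score"] == pytest.approx(zs[i], rel=1e-12)

    def test_equal_cv_more_abundant_scores_higher(self, rng):
        """Abundance contributes to the score when variation is equal."""
        values = rng.normal(12, 1.5, size=(6, 8))
        # genes g0 and g1: identical CV (scaled copies), different means
        base = np.array([9.0, 10.0, 11.0, 10.0, 9.5, 10.5, 10.0, 10.0])
        values[0] = base
        values[1] = base * 1.5
        stab = compute_stability(make_am(values)).table.set_index("mirna")
        assert stab.loc["g0", "cv_percent"] == pytest.approx(
            stab.loc["g1", "cv_percent"], rel=1e-12)
        assert stab.loc["g1", "z_score"] > stab.loc["g0", "z_score"]

    def test_lower_sd_never_decreases_score(self, rng):
        values = rng.normal(12, 2, size=(6, 8))
        am = make_am(values)
        z0 = compute_stability(am).table.set_index("mirna")["z_score"]
        # shrink gene g2's deviations, keeping its mean fixed
        shrunk = values.copy()
        m = shrunk[2].mean()
        shrunk[2] = m + 0.5 * (shrunk[2] - m)
        z1 = compute_stability(make_am(shrunk)).table.set_index("mirna")["z_score"]
        assert z1["g2"] >= z0["g2"]

    def test_nonpositive_mean_genes_dropped(self, rng):
        values = rng.normal(10, 1, size=(3, 5))
        values[1] -= 20  # negative mean
        stab = compute_stability(make_am(values))
        assert "g1" not in set(stab.table["mirna"])

    def test_constant_matrix_is_degenerate_error(self):
        am = make_am(np.full((4, 5), 7.0))
        with pytest.raises(ValidationError, match="MAD"):
            compute_stability(am)


# ---------------------------------------------------------------------------
# Ranking and candidate selection on the published table
# ---------------------------------------------------------------------------

class TestRankSelect:
    def test_published_ranks_reproduced(self):
        ranked = rank_select(top20_table(shuffle_seed=7), top_n=20)
        by_rank = dict(zip(ranked.table["rank"], ranked.table["mirna"]))
        for name, _, _, rank in TOP20:
            assert by_rank[rank] == name
        assert by_rank[4] == "miR-26a-5p"

    def test_abundance_can_outrank_lower_cv(self):
        """miR-423-5p sits above miR-22-3p despite its higher CV."""
        ranked = rank_select(top20_table(), top_n=20).table
        pos = {m: r for m, r in zip(ranked["mirna"], ranked["rank"])}
        assert pos["miR-423-5p"] < pos["miR-22-3p"]
        cv = dict(zip(ranked["mirna"], ranked["cv_percent"]))
        assert cv["miR-423-5p"] > cv["miR-22-3p"]

    def test_top_n_beyond_size_returns_all(self):
        ranked = rank_select(top20_table(), top_n=100)
        assert len(ranked) == 20

    def test_tie_break_by_abundance_then_id(self):
        df = pd.DataFrame({
            "mirna": ["b", "a", "c"],
            "mean_abundance": [10.0, 10.0, 12.0],
            "cv_percent": [5.0, 5.0, 5.0],
            "z_score": [1.0, 1.0, 1.0],
            "rank": [1, 2, 3]})
        ranked = rank_select(StabilityTable(df), 3).table
        assert ranked["mirna"].tolist() == ["c", "a", "b"]

    def test_invalid_top_n(self):
        with pytest.raises(ValidationError):
            rank_select(top20_table(), 0)


class TestSelectCandidates:
    def test_oncomir_exclusion_gives_published_panel(self):
        panel = select_candidates(
            top20_table(), exclude=["miR-21-5p", "miR-92a-3p"], n_candidates=3)
        assert panel == ["miR-486-5p", "miR-26a-5p", "miR-423-5p"]

    def test_external_addition_completes_panel_of_four(self):
        panel = select_candidates(
            top20_table(), exclude=["miR-21-5p", "miR-92a-3p"],
            add_external=["miR-191-5p"], n_candidates=3)
        assert panel == ["miR-486-5p", "miR-26a-5p", "miR-423-5p", "miR-191-5p"]

    def test_no_exclusion_is_plain_prefix(self):
        panel = select_candidates(top20_table(), n_candidates=4)
        assert panel == [m for m, *_ in TOP20[:4]]

    def test_everything_excluded_is_error(self):
        with pytest.raises(ValidationError):
            select_candidates(top20_table(), exclude=[m for m, *_ in TOP20])
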