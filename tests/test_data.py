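"""Unit and property tests for the preprocessing pipeline."""

import numpy as np
import pandas as pd
import pytest

import synpair as sp
from synpair.data import mirror_sample

from conftest import make_toy_samples


def _matrix(values, genes=None, ccls=None, normalized=False):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    ccls = ccls or [f"c{j}" for j in range(values.shape[1])]
    return sp.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=ccls), normalized=normalized)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


class TestExpressionIO:
    def test_round_trip(self, tmp_path):
        m = _matrix([[1.0, 2.0], [3.5, 0.0], [2.2, 4.4]])
        path = tmp_path / "expr.tsv"
        sp.data.write_expression_matrix(m, path)
        back = sp.read_expression_matrix(path)
        assert back.gene_ids == m.gene_ids
        assert back.ccl_ids == m.ccl_ids
        assert not back.normalized
        np.testing.assert_allclose(back.values, m.values)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\tc1\tc2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(sp.ValidationError, match="duplicate gene"):
            sp.read_expression_matrix(path)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(sp.ParseError):
            sp.read_expression_matrix(path)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tc1\tc2\ng1\t1\t2\ng2\toops\t4\n")
        with pytest.raises(sp.ParseError, match="g2.*c1"):
            sp.read_expression_matrix(path)

    def test_csv_dialect_by_extension(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text("gene,c1,c2\ng1,1,2\n")
        m = sp.read_expression_matrix(path)
        assert m.frame.shape == (1, 2)


# ---------------------------------------------------------------------------
# gene filters and normalization
# ---------------------------------------------------------------------------


class TestFilterGenes:
    def test_boundary_and_variance_rules(self):
        # row 1: 3/4 = 75% below 1 (not strictly more) and sample variance
        # 3.3767 >= 0.8 -> retained; row 2: 4/5... (use 4 CCLs throughout)
        m = _matrix(
            [
                [0.2, 0.3, 0.5, 4.0],  # kept: 75% low is not >75%, var 3.3767
                [0.1, 0.2, 0.3, 0.4],  # removed: 100% below threshold
                [2.0, 2.0, 2.0, 2.0],  # removed: zero variance
                [5.0, 1.0, 3.0, 7.0],  # kept
            ]
        )
        out = sp.filter_genes(m)
        assert out.gene_ids == ["g0", "g3"]
        assert out.ccl_ids == m.ccl_ids
        # frozen from the sample-variance (ddof=1) oracle
        assert np.isclose(np.var([0.2, 0.3, 0.5, 4.0], ddof=1), 3.376666666666667)

    def test_expression_rule_fires_regardless_of_variance(self):
        m = _matrix([[0.1, 0.2, 0.3, 0.4, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0]])
        out = sp.filter_genes(m)
        assert out.gene_ids == ["g1"]  # 4/5 = 80% > 75% -> removed

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.gamma(2.0, 1.5, size=(30, 8)))
        once = sp.filter_genes(m)
        twice = sp.filter_genes(once)
        assert once.gene_ids == twice.gene_ids
        np.testing.assert_array_equal(once.values, twice.values)

    def test_requires_two_ccls(self):
        with pytest.raises(sp.ValidationError):
            sp.filter_genes(_matrix([[1.0], [2.0]]))


class TestZScore:
    def test_two_ccl_row_under_sample_convention(self):
        out = sp.zscore_genes(_matrix([[1.0, 3.0]]))
        np.testing.assert_allclose(out.values[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert out.normalized

    def test_population_convention(self):
        out = sp.zscore_genes(_matrix([[1.0, 3.0]]), ddof=0)
        np.testing.assert_allclose(out.values[0], [-1.0, 1.0])

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        out = sp.zscore_genes(_matrix(rng.normal(2, 3, size=(20, 9))))
        assert np.abs(out.values.mean(axis=1)).max() < 1e-9
        assert np.abs(out.values.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_zero_variance_gene_instructs_to_filter(self):
        with pytest.raises(sp.ValidationError, match="filter_genes"):
            sp.zscore_genes(_matrix([[5.0, 5.0, 5.0]]))


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


class TestSignatures:
    @pytest.mark.parametrize(
        "replicates, expected",
        [
            ([[1, 2], [3, 4]], [2, 3]),
            ([[5, 6]], [5, 6]),
            ([[1], [1], [4]], [2]),
        ],
    )
    def test_consensus_mean(self, replicates, expected):
        np.testing.assert_allclose(
            sp.consensus_signature([np.array(r, dtype=float) for r in replicates]), expected
        )

    def test_consensus_errors(self):
        with pytest.raises(sp.ValidationError):
            sp.consensus_signature([])
        with pytest.raises(sp.ValidationError, match="mismatch"):
            sp.consensus_signature([np.ones(2), np.ones(3)])

    def test_drug_feature_concatenation_order(self):
        entries = {
            ("dA", "S1", "r0"): np.array([1.0, 2.0]),
            ("dA", "S1", "r1"): np.array([3.0, 4.0]),
            ("dA", "S2", "r0"): np.array([5.0, 6.0]),
        }
        sigs = sp.DrugSignatureSet(entries, landmark_dim=2, signature_ccl_order=("S1", "S2"))
        np.testing.assert_allclose(sp.build_drug_feature(sigs, "dA"), [2.0, 3.0, 5.0, 6.0])
        assert sigs.drug_feature_dim == 4

    def test_missing_signature_names_drug_and_cell_line(self):
        sigs = sp.DrugSignatureSet(
            {("dA", "S1", "r0"): np.zeros(2)}, landmark_dim=2, signature_ccl_order=("S1", "S2")
        )
        with pytest.raises(KeyError, match="dA.*S2"):
            sp.build_drug_feature(sigs, "dA")

    def test_signature_table_round_trip(self, tmp_path, tiny_world):
        path = tmp_path / "sigs.tsv"
        sp.data.write_signature_table(tiny_world.signatures, path)
        back = sp.read_signature_table(path)
        assert back.landmark_dim == tiny_world.signatures.landmark_dim
        assert back.signature_ccl_order == tiny_world.signatures.signature_ccl_order
        for key, vec in tiny_world.signatures.entries.items():
            np.testing.assert_allclose(back.entries[key], vec)


# ---------------------------------------------------------------------------
# replicate filtering
# ---------------------------------------------------------------------------


def _records(scores, pair=("a", "b"), ccl="c1", score_type="ZIP"):
    return [
        sp.SynergyRecord(pair[0], pair[1], ccl, score_type, s, 10.0 + i, 20.0 + i, f"r{i}")
        for i, s in enumerate(scores)
    ]


def _oracle_keep(scores, cfg):
    """Independent re-evaluation of both replicate-consistency rules."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    nonneg = int((scores >= 0).sum())
    if max(nonneg, n - nonneg) / n < cfg.sign_consensus_frac:
        return False, "sign"
    std = 0.0 if n == 1 else float(np.std(scores, ddof=cfg.ddof))
    return std <= cfg.max_replicate_std, "std"


class TestReplicateFilter:
    def test_consistent_group_kept_with_median(self):
        kept, report = sp.filter_synergy_replicates(_records([0.05, 0.10, 0.12]))
        assert report.kept == 1 and report.dropped == 0
        assert kept[0].score == pytest.approx(0.10)
        assert kept[0].replicate_id == "consensus"

    def test_spread_violation_dropped_despite_sign_majority(self):
        kept, report = sp.filter_synergy_replicates(_records([5.0, 6.0, -1.0]))
        assert kept == []
        assert report.dropped_std == 1 and report.dropped_sign == 0
        assert report.details[0][-1] == "replicate_std"

    def test_singleton_kept(self):
        kept, report = sp.filter_synergy_replicates(_records([-4.0]))
        assert report.kept == 1
        assert kept[0].score == pytest.approx(-4.0)

    def test_ri_median_respects_drug_orientation(self):
        # same group reported with both drug orders; RIs must be medianed
        # per canonical drug, not per reported column
        recs = [
            sp.SynergyRecord("a", "b", "c1", "ZIP", 0.02, 1.0, 9.0, "r0"),
            sp.SynergyRecord("b", "a", "c1", "ZIP", 0.04, 9.0, 1.0, "r1"),
        ]
        kept, _ = sp.filter_synergy_replicates(recs)
        assert (kept[0].drug1_id, kept[0].drug2_id) == ("a", "b")
        assert kept[0].ri1 == pytest.approx(1.0)
        assert kept[0].ri2 == pytest.approx(9.0)

    def test_agrees_with_oracle_on_random_groups(self):
        cfg = sp.FilterConfig()
        rng = np.random.default_rng(42)
        for i in range(1000):
            n = int(rng.integers(1, 8))
            scale = rng.choice([0.03, 0.1, 1.0, 10.0])
            scores = rng.normal(rng.normal() * scale, scale, size=n)
            kept, report = sp.filter_synergy_replicates(_records(scores), cfg)
            expect_keep, _ = _oracle_keep(scores, cfg)
            assert bool(kept) == expect_keep, f"group {i}: {scores}"
            if kept:
                assert kept[0].score == pytest.approx(float(np.median(scores)))

    def test_score_types_filtered_independently(self):
        recs = _records([0.05, 0.06], score_type="ZIP") + _records([5.0, -5.0], score_type="S_mean")
        kept, report = sp.filter_synergy_replicates(recs)
        assert {r.score_type for r in kept} == {"ZIP"}
        assert report.dropped_sign == 1


# ---------------------------------------------------------------------------
# assembly, augmentation, sparsity
# ---------------------------------------------------------------------------


class TestAssembly:
    def test_feature_concatenation_and_counts(self, tiny_world):
        measurements, _ = sp.sample_measurements(tiny_world, 30)
        cfg = sp.FilterConfig()
        expr = sp.zscore_genes(sp.filter_genes(tiny_world.expression, cfg))
        consensus, _ = sp.filter_synergy_replicates(measurements, cfg)
        samples, report = sp.assemble_dataset(expr, tiny_world.signatures, consensus)
        assert report.kept == len(samples) > 0
        s = samples[0]
        assert s.x_triple.size == s.x_pair.size + expr.n_genes
        np.testing.assert_array_equal(s.x_triple[: s.x_pair.size], s.x_pair)
        assert not s.is_swap

    def test_missing_ccl_counted_not_silently_dropped(self, tiny_world):
        expr = sp.zscore_genes(sp.filter_genes(tiny_world.expression))
        d1, d2 = tiny_world.drug_ids[:2]
        good = sp.SynergyRecord(d1, d2, tiny_world.ccl_ids[0], "ZIP", 1.0, 0.5, 0.5, "consensus")
        bad = sp.SynergyRecord(d1, d2, "CCL999", "ZIP", 1.0, 0.5, 0.5, "consensus")
        samples, report = sp.assemble_dataset(expr, tiny_world.signatures, [good, bad])
        assert len(samples) == 1
        assert report.missing_ccl == 1

    def test_empty_intersection_reports_diagnostics(self, tiny_world):
        expr = sp.zscore_genes(sp.filter_genes(tiny_world.expression))
        bad = sp.SynergyRecord("nope1", "nope2", "CCL000", "ZIP", 1.0, 0.5, 0.5, "consensus")
        with pytest.raises(sp.ValidationError, match="missing_drug_feature"):
            sp.assemble_dataset(expr, tiny_world.signatures, [bad])


class TestAugmentation:
    def test_doubling_and_target_swap(self):
        samples = make_toy_samples(n_drugs=4, n_ccls=2)
        out = sp.augment_order_swap(samples)
        assert len(out) == 2 * len(samples)
        originals = [s for s in out if not s.is_swap]
        mirrors = [s for s in out if s.is_swap]
        for src, mir in zip(originals, mirrors):
            assert src.pair_key == mir.pair_key and src.ccl_id == mir.ccl_id
            assert src.y[0] == mir.y[0]
            np.testing.assert_array_equal(src.y[[1, 2]], mir.y[[2, 1]])
            m = src.drug_dim
            np.testing.assert_array_equal(mir.x_pair, np.concatenate([src.x_pair[m:], src.x_pair[:m]]))
            np.testing.assert_array_equal(mir.x_triple[2 * m:], src.x_triple[2 * m:])

    def test_mirror_is_involution(self):
        for s in make_toy_samples(n_drugs=3, n_ccls=2, seed=5):
            back = mirror_sample(mirror_sample(s))
            np.testing.assert_array_equal(back.x_pair, s.x_pair)
            np.testing.assert_array_equal(back.x_triple, s.x_triple)
            np.testing.assert_array_equal(back.y, s.y)
            assert back.is_swap == s.is_swap

    def test_rejects_already_augmented_input(self):
        out = sp.augment_order_swap(make_toy_samples(n_drugs=3, n_ccls=1))
        with pytest.raises(sp.ValidationError, match="mirror"):
            sp.augment_order_swap(out)


class TestSparsity:
    def test_printed_coverage_figure(self):
        assert round(sp.sparsity_report(43174, 670, 75), 3) == 0.128

    def test_small_cases(self):
        assert sp.sparsity_report(1, 2, 1) == pytest.approx(50.0)
        assert sp.sparsity_report(0, 2, 1) == 0.0
        with pytest.raises(sp.ValidationError):
            sp.sparsity_report(1, 1, 1)

    def test_counts_unique_unaugmented_triples(self):
        samples = sp.augment_order_swap(make_toy_samples(n_drugs=4, n_ccls=2))
        # 6 pairs x 2 ccls = 12 triples over a 4*3*2 = 24 universe
        assert sp.sparsity_report(samples, 4, 2) == pytest.approx(50.0)
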