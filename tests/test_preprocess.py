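import numpy as np
import pandas as pd
import pytest

from lfqstats import preprocess as pp
from lfqstats.io import (
    BIOREPLICATE,
    CONDITION,
    FRACTION,
    INTENSITY,
    PEPTIDE,
    PROTEIN,
    RUN,
    ValidationError,
)

from conftest import make_canonical


def ann_for(df, fraction=None):
    ann = df[[RUN, CONDITION, BIOREPLICATE]].drop_duplicates().reset_index(drop=True)
    if fraction is not None:
        ann[FRACTION] = ann[RUN].map(fraction)
    return ann


class TestSharedPeptides:
    def test_peptide_in_two_proteins_fully_removed(self):
        df = make_canonical(
            [("A", "SHARED", "r0", 1.0), ("B", "SHARED", "r0", 2.0),
             ("A", "UNIQ", "r0", 3.0)]
        )
        out, log = pp.remove_shared_peptides(df)
        assert set(out[PEPTIDE]) == {"UNIQ"}
        assert log.rows_removed == 2

    def test_unique_peptides_untouched(self):
        df = make_canonical([("A", "X", "r0", 1.0), ("B", "Y", "r0", 2.0)])
        out, _ = pp.remove_shared_peptides(df)
        pd.testing.assert_frame_equal(out, df)

    def test_all_shared_warns_and_empties(self):
        df = make_canonical([("A", "S", "r0", 1.0), ("B", "S", "r0", 2.0)])
        with pytest.warns(UserWarning, match="shared"):
            out, _ = pp.remove_shared_peptides(df)
        assert out.empty


class TestSparseFeatures:
    def test_feature_below_threshold_removed(self):
        cells = [("A", "P1", f"r{k}", 1.0 if k == 0 else np.nan) for k in range(12)]
        cells += [("A", "P2", f"r{k}", 5.0) for k in range(12)]
        df = make_canonical(cells)
        out, _ = pp.filter_sparse_features(df, 2)
        assert set(out[PEPTIDE]) == {"P2"}

    def test_threshold_zero_is_identity(self):
        df = make_canonical([("A", "P1", "r0", np.nan)])
        out, _ = pp.filter_sparse_features(df, 0)
        pd.testing.assert_frame_equal(out, df)

    def test_matches_brute_force_count_oracle(self, rng):
        cells = []
        for p in range(8):
            for f in range(3):
                for k in range(6):
                    val = float(rng.uniform(1, 100)) if rng.random() > 0.5 else np.nan
                    cells.append(("Pr%d" % p, "pep%d_%d" % (p, f), "r%d" % k, val))
        df = make_canonical(cells)
        threshold = 3
        out, _ = pp.filter_sparse_features(df, threshold)

        # oracle: direct per-feature counting over observed runs
        kept = set()
        for (prot, pep), grp in df.groupby([PROTEIN, PEPTIDE]):
            if grp[INTENSITY].notna().sum() >= threshold:
                kept.add((prot, pep))
        expected = df[[tuple(x) in kept for x in zip(df[PROTEIN], df[PEPTIDE])]]
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      expected.reset_index(drop=True))


class TestDuplicates:
    def test_max_of_two_values(self):
        df = make_canonical([("A", "P", "r0", 100.0), ("A", "P", "r0", 200.0)])
        out, _ = pp.aggregate_duplicates(df, "max")
        assert out[INTENSITY].tolist() == [200.0]

    def test_max_ignores_missing(self):
        df = make_canonical([("A", "P", "r0", 100.0), ("A", "P", "r0", np.nan)])
        out, _ = pp.aggregate_duplicates(df, "max")
        assert out[INTENSITY].tolist() == [100.0]

    def test_sum_of_two_values(self):
        df = make_canonical([("A", "P", "r0", 100.0), ("A", "P", "r0", 200.0)])
        out, _ = pp.aggregate_duplicates(df, "sum")
        assert out[INTENSITY].tolist() == [300.0]

    def test_all_missing_duplicates_stay_missing(self):
        df = make_canonical([("A", "P", "r0", np.nan), ("A", "P", "r0", np.nan)])
        for method in ("max", "sum"):
            out, _ = pp.aggregate_duplicates(df, method)
            assert out[INTENSITY].isna().all()

    def test_unknown_method_rejected(self):
        df = make_canonical([("A", "P", "r0", 1.0)])
        with pytest.raises(ValidationError):
            pp.aggregate_duplicates(df, "median")


class TestBalance:
    def test_completion_inserts_missing_cells(self):
        conds = {f"r{k}": ("C1", f"S{k}") for k in range(2)}
        df = make_canonical(
            [("A", "P1", "r0", 1.0), ("A", "P1", "r1", 2.0),
             ("A", "P2", "r0", 3.0), ("A", "P2", "r1", 4.0),
             ("A", "P3", "r0", 5.0)],
            conditions=conds,
        )
        out, _ = pp.balance_design(df, ann_for(df))
        assert len(out) == 6
        assert out[INTENSITY].isna().sum() == 1

    def test_idempotent_on_complete_table(self):
        conds = {f"r{k}": ("C1", f"S{k}") for k in range(2)}
        df = make_canonical(
            [("A", "P1", f"r{k}", float(k + 1)) for k in range(2)], conditions=conds
        )
        out1, _ = pp.balance_design(df, ann_for(df))
        out2, _ = pp.balance_design(out1, ann_for(df))
        pd.testing.assert_frame_equal(out1, out2)

    def test_row_count_is_features_times_runs_per_protein(self, rng):
        # ragged random input: drop a random subset of cells then balance
        cells = []
        for p in range(5):
            n_feat = int(rng.integers(1, 5))
            for f in range(n_feat):
                for k in range(4):
                    if rng.random() < 0.6:
                        cells.append((f"Pr{p}", f"p{p}_{f}", f"r{k}", 1.0))
        conds = {f"r{k}": ("C1", f"S{k}") for k in range(4)}
        df = make_canonical(cells, conditions=conds)
        ann = pd.DataFrame(
            {RUN: [f"r{k}" for k in range(4)], CONDITION: "C1",
             BIOREPLICATE: [f"S{k}" for k in range(4)]}
        )
        out, _ = pp.balance_design(df, ann)
        expected = sum(
            grp[[PEPTIDE]].drop_duplicates().shape[0] * 4
            for _, grp in df.groupby(PROTEIN)
        )
        assert len(out) == expected

    def test_unannotated_run_rejected(self):
        df = make_canonical([("A", "P", "r9", 1.0)])
        ann = pd.DataFrame({RUN: ["r0"], CONDITION: ["C1"], BIOREPLICATE: ["S1"]})
        with pytest.raises(ValidationError, match="r9"):
            pp.balance_design(df, ann)


class TestFractions:
    def frame(self):
        conds = {f"{s}_F{f}": ("C1", s) for s in ("S1", "S2") for f in (1, 2)}
        cells = []
        # feature P1 stronger in F2; P2 only in F1
        for s in ("S1", "S2"):
            cells += [("A", "P1", f"{s}_F1", 10.0), ("A", "P1", f"{s}_F2", 100.0)]
            cells += [("A", "P2", f"{s}_F1", 50.0)]
        df = make_canonical(cells, conditions=conds)
        ann = ann_for(df, fraction={f"{s}_F{f}": f"F{f}" for s in ("S1", "S2") for f in (1, 2)})
        return df, ann

    def test_highest_mean_fraction_wins(self):
        df, ann = self.frame()
        out, new_ann, _ = pp.handle_fractions(df, ann)
        p1 = out[out[PEPTIDE] == "P1"]
        assert (p1[INTENSITY] == 100.0).all()
        # one logical run per (condition, bioreplicate)
        assert new_ann[RUN].nunique() == 2

    def test_single_fraction_feature_retained(self):
        df, ann = self.frame()
        out, _, _ = pp.handle_fractions(df, ann)
        assert (out[PEPTIDE] == "P2").sum() == 2

    def test_unfractionated_identity(self):
        df = make_canonical([("A", "P", "r0", 1.0)])
        out, _, log = pp.handle_fractions(df, ann_for(df))
        pd.testing.assert_frame_equal(out, df)
        assert log.detail == "unfractionated"


class TestPipeline:
    def build(self):
        conds = {f"r{k}": ("C1", f"S{k}") for k in range(3)}
        cells = [
            ("A", "P1", "r0", 10.0), ("A", "P1", "r1", 20.0), ("A", "P1", "r2", 30.0),
            ("A", "P1", "r0", 15.0),            # duplicate
            ("A", "P2", "r0", 5.0),             # sparse: 1 run only
            ("B", "SH", "r0", 9.0), ("A", "SH", "r1", 9.0),  # shared
            ("B", "P3", "r0", 7.0), ("B", "P3", "r1", 8.0),
        ]
        df = make_canonical(cells, conditions=conds)
        return df, ann_for(make_canonical([("x", "y", f"r{k}", 1.0) for k in range(3)],
                                          conditions=conds))

    def test_pipeline_is_idempotent(self):
        df, ann = self.build()
        first = pp.preprocess(df, ann)
        second = pp.preprocess(first.data, first.annotation)
        pd.testing.assert_frame_equal(
            first.data.reset_index(drop=True), second.data.reset_index(drop=True)
        )

    def test_provenance_counts_balance(self):
        df, ann = self.build()
        result = pp.preprocess(df, ann)
        for entry in result.log:
            assert entry.rows_in - entry.rows_removed + entry.rows_added == entry.rows_out

    def test_shared_and_sparse_gone_and_balanced(self):
        df, ann = self.build()
        out = pp.preprocess(df, ann).data
        assert "SH" not in set(out[PEPTIDE])
        assert "P2" not in set(out[PEPTIDE])
        counts = out.groupby([PROTEIN, PEPTIDE])[RUN].count()
        assert (counts == 3).all()
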