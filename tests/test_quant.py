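"""Quantification chain: filtering rule, loess, top-k rollups, replicate CoV."""

import numpy as np
import pandas as pd
import pytest

import ftdprot as fp


def _table(records):
    return pd.DataFrame(records, columns=["peptide_id", "sample_id", "fraction",
                                          "peak_area", "qvalue"])


def _metadata(groups):
    return pd.DataFrame({"group": pd.Series(groups)}).rename_axis("sample_id")


class TestFilterPeptides:
    def test_boundary_half_of_one_condition_is_retained(self):
        # passes the cut in exactly 1 of 2 control samples: 50% inclusive
        meta = _metadata({"n1": "NDC", "n2": "NDC", "f1": "FTD", "f2": "FTD"})
        rows = [("p1", s, 0, 100.0, 1e-4 if s == "n1" else 1e-2)
                for s in ["n1", "n2", "f1", "f2"]]
        out = fp.filter_peptides(_table(rows), meta, mode="pairwise")
        assert set(out["peptide_id"]) == {"p1"}
        # failing measurements inside the retained stratum are masked
        assert out.loc[out["sample_id"] == "n2", "peak_area"].isna().all()
        # under the global rule 1/4 < 50% -> removed
        assert fp.filter_peptides(_table(rows), meta, mode="global").empty

    def test_all_failing_removed_in_both_modes(self):
        meta = _metadata({"a": "NDC", "b": "NDC", "c": "FTD", "d": "FTD"})
        rows = [("p1", s, 0, 5.0, 0.5) for s in "abcd"]
        for mode in ("global", "pairwise"):
            assert fp.filter_peptides(_table(rows), meta, mode=mode).empty

    def test_matches_brute_force_rule_on_random_tables(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(6)]
        meta = _metadata(dict(zip(samples, ["NDC"] * 3 + ["FTD"] * 3)))
        for trial in range(20):
            rows = [
                (f"p{p}", s, f, float(rng.uniform(1, 100)),
                 float(rng.choice([1e-4, 1e-2])))
                for p in range(6) for f in range(4) for s in samples
            ]
            table = _table(rows)
            for mode in ("global", "pairwise"):
                out = fp.filter_peptides(table, meta, mode=mode)
                # hand-coded oracle over every stratum
                expected = set()
                for (pep, frac), sub in table.groupby(["peptide_id", "fraction"]):
                    ok = sub[sub["qvalue"] <= 1e-3]["sample_id"]
                    if mode == "global":
                        keep = len(ok) / 6 >= 0.5
                    else:
                        shares = [
                            sum(meta.loc[s, "group"] == g for s in ok) / 3
                            for g in ("NDC", "FTD")
                        ]
                        keep = max(shares) >= 0.5
                    if keep:
                        expected.add((pep, frac))
                got = set(map(tuple, out[["peptide_id", "fraction"]].drop_duplicates()
                              .itertuples(index=False)))
                assert got == expected

    def test_idempotent(self, tiny_cohort):
        _, table, metadata, _, _ = tiny_cohort
        once = fp.filter_peptides(table, metadata, mode="pairwise")
        twice = fp.filter_peptides(once, metadata, mode="pairwise")
        pd.testing.assert_frame_equal(
            once.sort_values(["peptide_id", "sample_id", "fraction"]).reset_index(drop=True),
            twice.sort_values(["peptide_id", "sample_id", "fraction"]).reset_index(drop=True),
        )

    def test_unknown_sample_rejected(self):
        meta = _metadata({"a": "NDC", "b": "FTD"})
        with pytest.raises(ValueError):
            fp.filter_peptides(_table([("p1", "ghost", 0, 1.0, 1e-4)]), meta)

    def test_pairwise_needs_two_conditions(self):
        meta = _metadata({"a": "NDC", "b": "NDC"})
        with pytest.raises(ValueError):
            fp.filter_peptides(_table([("p1", "a", 0, 1.0, 1e-4)]), meta,
                               mode="pairwise")


class TestCyclicLoess:
    def test_identical_columns_are_unchanged(self):
        rng = np.random.default_rng(1)
        col = rng.normal(20, 2, 500)
        mat = fp.AbundanceMatrix(pd.DataFrame({"a": col, "b": col}),
                                 "peptide-fraction", "log2")
        out = fp.normalize_cyclic_loess(mat)
        assert np.allclose(out.data["a"], out.data["b"])
        assert np.allclose(out.data["a"], col, atol=1e-6)

    def test_constant_shifts_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(20, 2, size=(4000, 1))
        x = base + rng.normal(0, 0.15, size=(4000, 6)) + np.linspace(-1, 1, 6)
        mat = fp.AbundanceMatrix(pd.DataFrame(x, columns=list("abcdef")),
                                 "peptide-fraction", "log2")
        out = fp.normalize_cyclic_loess(mat).data.to_numpy()
        meds = [abs(np.median(out[:, i] - out[:, j]))
                for i in range(6) for j in range(i + 1, 6)]
        assert max(meds) < 0.01

    def test_missing_entries_survive_untouched(self):
        rng = np.random.default_rng(3)
        x = rng.normal(20, 2, size=(300, 4))
        x[::7, 1] = np.nan
        mat = fp.AbundanceMatrix(pd.DataFrame(x, columns=list("abcd")),
                                 "peptide-fraction", "log2")
        out = fp.normalize_cyclic_loess(mat)
        assert np.isnan(out.data.to_numpy()[::7, 1]).all()

    def test_single_sample_is_identity_with_warning(self):
        mat = fp.AbundanceMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                                 "peptide-fraction", "log2")
        with pytest.warns(UserWarning):
            out = fp.normalize_cyclic_loess(mat)
        assert np.allclose(out.data["a"], [1, 2, 3])


def _oracle_topk(values: pd.DataFrame, groups, k):
    """Sort-slice-sum reference implementation."""
    out = {}
    frame = values.copy()
    frame["_g"] = np.asarray(groups)
    for g, sub in frame.groupby("_g"):
        sub = sub.drop(columns="_g")
        ranked = sorted(
            sub.index,
            key=lambda i: (-np.nanmean(sub.loc[i].to_numpy(dtype=float))
                           if not np.isnan(sub.loc[i].to_numpy(dtype=float)).all()
                           else np.inf, str(i)),
        )[:k]
        chosen = sub.loc[ranked]
        sums = chosen.fillna(0.0).sum(axis=0)
        sums[chosen.notna().sum(axis=0) == 0] = np.nan
        out[g] = sums
    return pd.DataFrame(out).T.sort_index()


class TestRollups:
    def test_single_fraction_passthrough(self):
        idx = pd.MultiIndex.from_tuples([("p1", 0)], names=["peptide_id", "fraction"])
        mat = fp.AbundanceMatrix(pd.DataFrame([[4.0, 8.0]], index=idx,
                                              columns=["a", "b"]),
                                 "peptide-fraction", "linear")
        out = fp.rollup_fractions(mat, k=2)
        assert np.allclose(out.data.loc["p1"], [4.0, 8.0])

    def test_top2_fractions_hand_computed(self):
        idx = pd.MultiIndex.from_product([["p1"], range(4)],
                                         names=["peptide_id", "fraction"])
        data = pd.DataFrame(
            [[10.0, 12.0], [8.0, 9.0], [50.0, 40.0], [1.0, 2.0]],
            index=idx, columns=["a", "b"],
        )
        out = fp.rollup_fractions(
            fp.AbundanceMatrix(data, "peptide-fraction", "linear"), k=2)
        # top-2 fractions by mean are fraction 2 (45) and fraction 0 (11)
        assert np.allclose(out.data.loc["p1"], [60.0, 52.0])

    def test_fraction_order_invariance(self):
        rng = np.random.default_rng(4)
        idx = pd.MultiIndex.from_product([["p1", "p2"], range(4)],
                                         names=["peptide_id", "fraction"])
        data = pd.DataFrame(rng.uniform(1, 100, size=(8, 3)), index=idx,
                            columns=list("abc"))
        shuffled = data.sample(frac=1, random_state=1)
        a = fp.rollup_fractions(fp.AbundanceMatrix(data, "peptide-fraction", "linear"))
        b = fp.rollup_fractions(fp.AbundanceMatrix(shuffled, "peptide-fraction", "linear"))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_top5_peptides_hand_computed(self):
        peps = [f"pep{i}" for i in range(7)]
        means = [10, 9, 8, 7, 6, 5, 4]
        data = pd.DataFrame({"a": means, "b": means}, index=pd.Index(peps), dtype=float)
        mapping = pd.DataFrame({"peptide_id": peps, "protein_id": "P1"})
        out = fp.rollup_proteins(fp.AbundanceMatrix(data, "peptide", "linear"),
                                 mapping, k=5)
        assert np.allclose(out.data.loc["P1"], [40.0, 40.0])  # 10+9+8+7+6

    def test_fewer_than_k_sums_all(self):
        data = pd.DataFrame({"a": [3.0, 4.0, 5.0]}, index=pd.Index(list("xyz")))
        mapping = pd.DataFrame({"peptide_id": list("xyz"), "protein_id": "P1"})
        out = fp.rollup_proteins(fp.AbundanceMatrix(data, "peptide", "linear"),
                                 mapping, k=5)
        assert out.data.loc["P1", "a"] == 12.0

    def test_homogeneity_under_scaling(self, tiny_cohort):
        _, table, metadata, pep2prot, _ = tiny_cohort
        filt = fp.filter_peptides(table, metadata)
        mat = fp.peptide_fraction_matrix(filt)
        p1 = fp.rollup_proteins(fp.rollup_fractions(mat), pep2prot)
        scaled = fp.AbundanceMatrix(mat.data * 7.0, mat.level, "linear")
        p2 = fp.rollup_proteins(fp.rollup_fractions(scaled), pep2prot)
        pd.testing.assert_frame_equal(p2.data, p1.data * 7.0)

    def test_shared_peptide_policies(self):
        data = pd.DataFrame({"a": [5.0, 6.0]}, index=pd.Index(["x", "y"]))
        mapping = pd.DataFrame({"peptide_id": ["x", "y", "y"],
                                "protein_id": ["P1", "P1", "P2"]})
        mat = fp.AbundanceMatrix(data, "peptide", "linear")
        with pytest.raises(ValueError):
            fp.rollup_proteins(mat, mapping)
        dropped = fp.rollup_proteins(mat, mapping, shared_policy="drop")
        assert list(dropped.data.index) == ["P1"]
        assert dropped.data.loc["P1", "a"] == 5.0
        both = fp.rollup_proteins(mat, mapping, shared_policy="assign-all")
        assert both.data.loc["P2", "a"] == 6.0 and both.data.loc["P1", "a"] == 11.0

    def test_rollups_match_sort_slice_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_pep, n_frac, n_s = rng.integers(2, 8), rng.integers(2, 6), 3
            idx = pd.MultiIndex.from_product(
                [[f"p{i}" for i in range(n_pep)], range(n_frac)],
                names=["peptide_id", "fraction"])
            vals = rng.uniform(1, 100, size=(len(idx), n_s))
            vals[rng.random(vals.shape) < 0.2] = np.nan
            data = pd.DataFrame(vals, index=idx, columns=[f"s{j}" for j in range(n_s)])
            got = fp.rollup_fractions(
                fp.AbundanceMatrix(data, "peptide-fraction", "linear"), k=2).data
            exp = _oracle_topk(data.reset_index(drop=True),
                               [p for p, _ in data.index], 2).dropna(how="all")
            pd.testing.assert_frame_equal(got, exp, check_names=False)


class TestReplicateCov:
    def test_identical_replicates_zero(self):
        data = pd.DataFrame({"a": [5.0, 7.0], "a_rep": [5.0, 7.0]},
                            index=pd.Index(["P1", "P2"]))
        cov, med = fp.compute_replicate_cov(
            fp.AbundanceMatrix(data, "protein", "linear"), {"a": ["a", "a_rep"]})
        assert med == 0.0 and (cov == 0).all()

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(6)
        s = 0.3  # natural-log sigma
        cols = [f"r{j}" for j in range(12)]
        base = rng.uniform(10, 100, size=(2000, 1))
        data = base * np.exp(rng.normal(0, s, size=(2000, 12)))
        cov, med = fp.compute_replicate_cov(
            fp.AbundanceMatrix(pd.DataFrame(data, columns=cols,
                                            index=[f"P{i}" for i in range(2000)]),
                               "protein", "linear"),
            {"g": cols})
        expected = np.sqrt(np.exp(s ** 2) - 1)
        assert abs(med - expected) / expected < 0.1

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.uniform(5, 50, size=(30, 3)), columns=list("abc"))
        m1 = fp.compute_replicate_cov(
            fp.AbundanceMatrix(data, "protein", "linear"), {"g": list("abc")})[1]
        m2 = fp.compute_replicate_cov(
            fp.AbundanceMatrix(data * 1000, "protein", "linear"), {"g": list("abc")})[1]
        assert np.isclose(m1, m2)

    def test_singleton_group_skipped(self):
        data = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["P1"])
        with pytest.warns(UserWarning):
            cov, _ = fp.compute_replicate_cov(
                fp.AbundanceMatrix(data, "protein", "linear"),
                {"solo": ["a"], "pair": ["b", "c"]})
        assert len(cov) == 1
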