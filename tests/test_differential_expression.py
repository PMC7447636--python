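"""NB test calibration and power, control resampling, replicate averaging,
pathway z-scores, and a cross-check against an independent NB-GLM
implementation (DESeq2 via pydeseq2)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fusionscope.differential_expression import (
    ConfigError,
    DEConfig,
    FusionPairDE,
    PairGroup,
    build_groups,
    nb_wald_test,
    pathway_zscores,
    replicate_and_average,
    sample_controls,
)
from fusionscope.synthetic_data import SyntheticCohortSpec, generate_counts


def nb_counts(rng, n_genes, n_samples, dispersion=0.1, lfc_mask=None, lfc=0.0):
    mu = np.exp(rng.uniform(3, 8, size=n_genes))
    mu = np.tile(mu[:, None], (1, n_samples))
    if lfc_mask is not None:
        mu[lfc_mask, :] *= 2.0 ** lfc
    r = 1.0 / dispersion
    k = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(
        k, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{j}" for j in range(n_samples)]
    )


class TestConfigAndGroups:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            DEConfig(n_reps=0)
        with pytest.raises(ConfigError):
            DEConfig(q_threshold=1.5)

    def test_group_invariants(self):
        with pytest.raises(ConfigError, match=">=2"):
            PairGroup("A-B", ("s1",), ("s2", "s3"))
        with pytest.raises(ConfigError, match="leak"):
            PairGroup("A-B", ("s1", "s2"), ("s2", "s3"))

    def test_groups_recovered_from_cohort(self, cohort, annotated, domain_calls, specificity, unique):
        from fusionscope.fusion_annotation import FUSION_KEY_COLUMNS

        per_sample = annotated.drop_duplicates(
            subset=FUSION_KEY_COLUMNS + ["sample_barcode"]
        ).reset_index(drop=True)
        groups = build_groups(
            per_sample, domain_calls, specificity,
            list(cohort.counts.columns), key_table=unique,
        )
        assert groups, "cohort must yield at least one eligible pair group"
        planted = set(cohort.truth.case_samples)
        by_pair = {g.pair: g for g in groups}
        for pair in planted:
            assert pair in by_pair
            # every case sample carries the planted effect
            assert set(by_pair[pair].case_samples) <= set(cohort.truth.case_samples[pair])
        for g in groups:
            assert not set(g.case_samples) & set(g.control_pool)

    def test_single_sample_pair_excluded(self, domain_calls, specificity, unique):
        # restrict available count files so every pair has at most one case
        one_sample = [unique["sample_barcode"].iloc[0]]
        pp_other = unique[unique["protein_producing"] & (unique["category"] == "other")]
        available = one_sample + list(pp_other["sample_barcode"].unique())
        groups = build_groups(unique, domain_calls, specificity, available)
        assert all(len(g.case_samples) >= 2 for g in groups)


class TestSampleControls:
    def test_whole_pool_when_exact(self):
        g = PairGroup("A-B", ("c1", "c2"), ("p1", "p2"))
        assert sample_controls(g, 2, np.random.default_rng(0)) == ["p1", "p2"]

    def test_reproducible_given_seed(self):
        g = PairGroup("A-B", ("c1", "c2"), tuple(f"p{i}" for i in range(10)))
        a = sample_controls(g, 2, np.random.default_rng(42))
        b = sample_controls(g, 2, np.random.default_rng(42))
        assert a == b

    def test_uniform_inclusion_frequency(self):
        # drawing 2 of 10: each barcode included with probability 0.2
        g = PairGroup("A-B", ("c1", "c2"), tuple(f"p{i}" for i in range(10)))
        rng = np.random.default_rng(1)
        hits = {f"p{i}": 0 for i in range(10)}
        n = 10_000
        for _ in range(n):
            for b in sample_controls(g, 2, rng):
                hits[b] += 1
        for b, h in hits.items():
            assert 0.17 <= h / n <= 0.23

    def test_pool_too_small(self):
        g = PairGroup("A-B", ("c1", "c2", "c3"), ("p1", "p2"))
        with pytest.raises(ConfigError, match="smaller"):
            sample_controls(g, 3, np.random.default_rng(0))


class TestNbWaldTest:
    def test_exchangeable_null_yields_no_discoveries(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(20):
            counts = nb_counts(rng, 400, 8)
            cols = list(counts.columns)
            perm = rng.permutation(cols)
            res = nb_wald_test(counts, list(perm[:4]), list(perm[4:]))
            if (res["qvalue"] < 0.05).any():
                hits += 1
        assert hits <= 1  # >=95% of random label splits are clean

    def test_strong_single_gene_shift_detected(self):
        rng = np.random.default_rng(11)
        mask = np.zeros(400, dtype=bool)
        mask[0] = True
        counts = nb_counts(rng, 400, 10, dispersion=0.05)
        counts.iloc[0, :5] *= 16  # 16-fold planted shift in the case half
        res = nb_wald_test(counts, [f"s{j}" for j in range(5)], [f"s{j}" for j in range(5, 10)])
        assert res.loc["g0", "qvalue"] < 0.05

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(12)
        counts = nb_counts(rng, 200, 10)
        case, ctrl = [f"s{j}" for j in range(5)], [f"s{j}" for j in range(5, 10)]
        a = nb_wald_test(counts, case, ctrl)
        b = nb_wald_test(counts, ctrl, case)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-10)
        np.testing.assert_allclose(a["qvalue"], b["qvalue"], atol=1e-10)

    def test_all_zero_genes_excluded(self):
        rng = np.random.default_rng(13)
        counts = nb_counts(rng, 100, 6)
        counts.iloc[5] = 0
        res = nb_wald_test(counts, [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
        assert "g5" not in res.index
        assert len(res) == 99

    def test_needs_two_samples_per_side(self):
        rng = np.random.default_rng(14)
        counts = nb_counts(rng, 50, 4)
        with pytest.raises(ConfigError):
            nb_wald_test(counts, ["s0"], ["s1", "s2", "s3"])


class TestAgainstDeseq2:
    def test_effect_estimates_match_independent_implementation(self):
        """Same planted data through DESeq2 (pydeseq2): fold changes agree and
        our discovery set is consistent with its calls."""
        import warnings

        warnings.filterwarnings("ignore")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(21)
        mask = np.zeros(200, dtype=bool)
        mask[:20] = True
        case_df = nb_counts(rng, 200, 5, lfc_mask=mask, lfc=2.0)
        ctrl_df = nb_counts(rng, 200, 5)
        counts = pd.concat(
            [case_df.rename(columns=lambda s: "c" + s), ctrl_df.rename(columns=lambda s: "t" + s)],
            axis=1,
        )
        case, ctrl = list(counts.columns[:5]), list(counts.columns[5:])
        ours = nb_wald_test(counts, case, ctrl)

        meta = pd.DataFrame({"condition": ["case"] * 5 + ["ctrl"] * 5}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "case", "ctrl"], quiet=True)
        st.summary()
        ref = st.results_df

        joined = ours.join(ref[["log2FoldChange", "padj"]]).dropna()
        corr = np.corrcoef(joined["log2fc"], joined["log2FoldChange"])[0, 1]
        assert corr > 0.95
        ours_sig = set(joined.index[joined["qvalue"] < 0.05])
        ref_sig = set(joined.index[joined["padj"] < 0.05])
        planted = {f"g{i}" for i in range(20)}
        assert len(ours_sig & planted) >= 16
        assert len(ref_sig & planted) >= 16
        # our calls are not wildly different from the reference's
        assert len(ours_sig ^ ref_sig) <= 0.1 * len(joined)


class TestReplicateAndAverage:
    @staticmethod
    def _group_and_counts(seed=31, n_genes=300, k=4, pool=12, planted=0, lfc=2.0):
        case = [f"TCGA-AA-{i:04d}" for i in range(k)]
        ctrl = [f"TCGA-BB-{i:04d}" for i in range(pool)]
        pairs = {b: "P1" for b in case}
        pairs.update({b: None for b in ctrl})
        genes = tuple(f"SYNG{i:05d}" for i in range(planted))
        spec = SyntheticCohortSpec(
            n_genes=n_genes, seed=seed,
            planted_pairs=(("P1", genes, lfc),) if planted else (),
        )
        counts, _ = generate_counts(spec, pairs)
        return PairGroup("P1", tuple(case), tuple(ctrl)), counts

    def test_single_rep_equals_one_test(self):
        group, counts = self._group_and_counts(planted=30)
        cfg = DEConfig(n_reps=1, seed=5)
        avg = replicate_and_average(group, counts, cfg)
        rng = np.random.default_rng([5, 0])
        controls = sample_controls(group, len(group.case_samples), rng)
        single = nb_wald_test(counts, list(group.case_samples), controls)
        expected = single[single["qvalue"] < cfg.q_threshold]
        assert set(avg.index) == set(expected.index)
        for g in avg.index:
            assert avg.loc[g, "avg_case_mean"] == pytest.approx(single.loc[g, "case_mean"])

    def test_fixed_seed_reproducible(self):
        group, counts = self._group_and_counts(planted=30)
        cfg = DEConfig(n_reps=5, seed=9)
        a = replicate_and_average(group, counts, cfg)
        b = replicate_and_average(group, counts, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_recovery_with_replication(self):
        group, counts = self._group_and_counts(seed=41, planted=30, k=5, pool=15)
        avg = replicate_and_average(group, counts, DEConfig(n_reps=20, seed=3))
        planted = {f"SYNG{i:05d}" for i in range(30)}
        recall = len(set(avg.index) & planted) / 30
        fdp = len(set(avg.index) - planted) / max(len(avg), 1)
        assert recall >= 0.8
        assert fdp <= 0.1
        assert (avg.loc[sorted(set(avg.index) & planted), "direction"] == "over").all()

    def test_direction_matches_sign(self):
        group, counts = self._group_and_counts(seed=43, planted=30, lfc=-2.0, k=5, pool=15)
        avg = replicate_and_average(group, counts, DEConfig(n_reps=10, seed=3))
        assert len(avg)
        assert ((avg["log2fc"] > 0) == (avg["direction"] == "over")).all()

    def test_small_pool_group_skipped(self):
        group, counts = self._group_and_counts(k=4, pool=12)
        small = PairGroup("P1", group.case_samples, group.control_pool[:3])
        out = replicate_and_average(small, counts, DEConfig(n_reps=2, seed=1))
        assert len(out) == 0

    def test_model_results_surface(self):
        group, counts = self._group_and_counts(seed=47, planted=30, k=5, pool=15)
        model = FusionPairDE(counts, group, DEConfig(n_reps=5, seed=2))
        res = model.fit()
        assert len(res.degenes)
        text = res.summary()
        assert "P1" in text and "replicates" in text
        ann = pd.DataFrame(
            {"gene_id": list(res.degenes.index), "pathway_id": "pwA"}
        )
        z = res.pathway_z(ann, {"pwA"})
        assert len(z) == 1


class TestPathwayZ:
    def test_closed_form_examples(self):
        ann = pd.DataFrame(
            [{"gene_id": f"g{i}", "pathway_id": "pw"} for i in range(20)]
        )
        def z_for(n_up, n_down):
            idx = [f"g{i}" for i in range(n_up + n_down)]
            de = pd.DataFrame(
                {"direction": ["over"] * n_up + ["under"] * n_down}, index=idx
            )
            out = pathway_zscores(de, ann, {"pw"})
            return out.loc[0, "z"] if len(out) else None

        assert z_for(4, 0) == pytest.approx(2.0)
        assert z_for(9, 0) == pytest.approx(3.0)
        assert z_for(3, 3) == pytest.approx(0.0)

    def test_non_lowest_terms_ignored(self):
        ann = pd.DataFrame([{"gene_id": "g0", "pathway_id": "parent_term"}])
        de = pd.DataFrame({"direction": ["over"]}, index=["g0"])
        assert len(pathway_zscores(de, ann, lowest_terms={"leaf_term"})) == 0

    def test_empty_pathways_omitted(self):
        ann = pd.DataFrame([{"gene_id": "zzz", "pathway_id": "pw"}])
        de = pd.DataFrame({"direction": ["over"]}, index=["g0"])
        assert len(pathway_zscores(de, ann, {"pw"})) == 0
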