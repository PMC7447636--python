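"""Generator contracts: construction invariants, seed determinism, and the
statistical properties of the emitted cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fusionscope.synthetic_data import (
    InvalidSpecError,
    SyntheticCohortSpec,
    generate_counts,
    generate_fusion_cohort,
    generate_gene_models,
    generate_network_and_pathways,
)

# independent codon-loop oracle (standard table, hand-rolled scan)
_ORACLE_TABLE = {}
for _c, _a in zip(
    [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"],
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
):
    _ORACLE_TABLE[_c] = _a


def oracle_translate(seq: str) -> str:
    """Direct three-letter sliding translation, including stop symbols."""
    return "".join(_ORACLE_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


class TestGeneModels:
    def test_construction_contract(self):
        spec = SyntheticCohortSpec(n_genes=10, seed=7)
        sm = generate_gene_models(spec)
        assert len(sm.models) == 10
        for m in sm.models:
            cds = m.cds_sequence(sm.contigs)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(m.exons) >= 2

    def test_no_internal_stop_codons(self):
        sm = generate_gene_models(SyntheticCohortSpec(n_genes=15, seed=3))
        for m in sm.models:
            pep = oracle_translate(m.cds_sequence(sm.contigs))
            assert pep.count("*") == 1 and pep.endswith("*")

    def test_seed_determinism(self):
        spec = SyntheticCohortSpec(n_genes=8, seed=42)
        a, b = generate_gene_models(spec), generate_gene_models(spec)
        assert [m for m in a.models] == [m for m in b.models]
        assert a.contigs == b.contigs
        assert a.pk_genes == b.pk_genes and a.tf_genes == b.tf_genes

    def test_pk_tf_label_fractions(self):
        sm = generate_gene_models(SyntheticCohortSpec(n_genes=40, frac_pk=0.25, frac_tf=0.1, seed=1))
        assert len(sm.pk_genes) == 10
        assert len(sm.tf_genes) == 4
        assert not sm.pk_genes & sm.tf_genes

    def test_invalid_n_genes_rejected(self):
        with pytest.raises(InvalidSpecError):
            SyntheticCohortSpec(n_genes=0)


class TestFusionCohort:
    def test_all_inframe_at_boundary_fraction(self):
        spec = SyntheticCohortSpec(n_genes=20, n_fusions=50, frac_inframe=1.0, seed=5)
        sm = generate_gene_models(spec)
        _, truth = generate_fusion_cohort(sm, spec)
        assert set(truth.frame_effect.values()) == {"in-frame"}

    def test_realized_inframe_fraction_binomial(self):
        # 99% binomial interval at n=2000, p=0.5 is about [0.46, 0.54]
        spec = SyntheticCohortSpec(
            n_genes=30, n_fusions=2000, frac_inframe=0.5, seed=13,
            recurrent_pair_fraction=0.0, duplicate_call_fraction=0.0,
        )
        sm = generate_gene_models(spec)
        _, truth = generate_fusion_cohort(sm, spec)
        frac = np.mean([e == "in-frame" for e in truth.frame_effect.values()])
        assert 0.46 <= frac <= 0.54

    def test_empty_cohort(self):
        spec = SyntheticCohortSpec(n_genes=10, n_fusions=0, seed=1)
        sm = generate_gene_models(spec)
        calls, truth = generate_fusion_cohort(sm, spec)
        assert len(calls) == 0 and not truth.frame_effect

    def test_breakpoints_on_exon_boundaries(self):
        spec = SyntheticCohortSpec(n_genes=20, n_fusions=100, seed=9)
        sm = generate_gene_models(spec)
        calls, _ = generate_fusion_cohort(sm, spec)
        by_gene = sm.by_gene()
        for r in calls.itertuples(index=False):
            donors = {g for _, g in by_gene[r.gene5].donor_boundaries()}
            acceptors = {g for _, g in by_gene[r.gene3].acceptor_boundaries()}
            assert r.pos5 in donors and r.pos3 in acceptors

    def test_barcode_pattern(self):
        spec = SyntheticCohortSpec(n_genes=10, n_fusions=30, seed=2)
        sm = generate_gene_models(spec)
        calls, _ = generate_fusion_cohort(sm, spec)
        assert calls["sample_barcode"].str.fullmatch(r"TCGA-[A-Z]{2}-[A-Z0-9]{4}").all()

    def test_ground_truth_covers_every_fusion_once(self):
        spec = SyntheticCohortSpec(n_genes=15, n_fusions=80, seed=4)
        sm = generate_gene_models(spec)
        calls, truth = generate_fusion_cohort(sm, spec)
        assert set(truth.frame_effect) == set(range(len(calls)))
        assert set(truth.aa5) == set(truth.aa3) == set(truth.frame_effect)

    def test_invalid_inframe_fraction_rejected(self):
        with pytest.raises(InvalidSpecError):
            SyntheticCohortSpec(frac_inframe=1.2)


class TestCounts:
    @staticmethod
    def _pairs(n_case: int, n_ctrl: int) -> dict[str, str | None]:
        mapping: dict[str, str | None] = {f"TCGA-AA-{i:04d}": "P1" for i in range(n_case)}
        mapping.update({f"TCGA-BB-{i:04d}": None for i in range(n_ctrl)})
        return mapping

    def test_null_plant_group_ratio_centered_at_one(self):
        # Monte-Carlo under the stated NB model: lfc=0 everywhere
        spec = SyntheticCohortSpec(
            n_genes=300, seed=21,
            planted_pairs=(("P1", tuple(f"SYNG{i:05d}" for i in range(50)), 0.0),),
        )
        counts, _ = generate_counts(spec, self._pairs(50, 50))
        case = [s for s in counts.columns if s.startswith("TCGA-AA")]
        ctrl = [s for s in counts.columns if s.startswith("TCGA-BB")]
        ratio = counts[case].mean(axis=1) / counts[ctrl].mean(axis=1)
        assert 0.9 <= ratio.median() <= 1.1

    def test_poisson_limit_of_dispersion(self):
        # NB variance = m + d*m^2 -> m as d -> 0
        spec = SyntheticCohortSpec(
            n_genes=2, nb_dispersion=1e-12, nb_mean_log_range=(5.0, 5.0), seed=8
        )
        counts, _ = generate_counts(spec, {f"TCGA-CC-{i:04d}": None for i in range(10_000)})
        draws = counts.iloc[0].to_numpy(dtype=float)
        assert 0.8 <= draws.var() / draws.mean() <= 1.2

    def test_planted_fold_change_visible(self):
        genes = tuple(f"SYNG{i:05d}" for i in range(20))
        spec = SyntheticCohortSpec(n_genes=200, seed=3, planted_pairs=(("P1", genes, 2.0),))
        counts, truth = generate_counts(spec, self._pairs(30, 30))
        case = [s for s in counts.columns if s.startswith("TCGA-AA")]
        ctrl = [s for s in counts.columns if s.startswith("TCGA-BB")]
        ratio = counts.loc[list(genes), case].mean(axis=1) / counts.loc[list(genes), ctrl].mean(axis=1)
        assert 3.0 <= ratio.median() <= 5.3
        assert truth.planted_lfc[("P1", genes[0])] == 2.0

    def test_seed_determinism(self):
        spec = SyntheticCohortSpec(n_genes=50, seed=6)
        m = self._pairs(0, 10)
        a, _ = generate_counts(spec, m)
        b, _ = generate_counts(spec, m)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_pair_needs_two_samples(self):
        spec = SyntheticCohortSpec(
            n_genes=10, seed=1, planted_pairs=(("P1", ("SYNG00000",), 1.0),)
        )
        with pytest.raises(InvalidSpecError):
            generate_counts(spec, {"TCGA-AA-0000": "P1", "TCGA-BB-0000": None})


@pytest.fixture(scope="module")
def network_bundle():
    spec = SyntheticCohortSpec(n_genes=50, seed=17)
    sm = generate_gene_models(spec)
    return generate_network_and_pathways(
        sm, [f"TCGA-AA-{i:04d}" for i in range(30)], spec,
        frac_nonphysical=0.3, dag_depth=4,
    )


class TestNetworkAndPathways:
    @pytest.fixture()
    def bundle(self, network_bundle):
        return network_bundle

    def test_dag_acyclic_by_kahn_oracle(self, bundle):
        _, pw_edges, *_ = bundle
        # Kahn's algorithm: a DAG iff every node can be peeled off
        children: dict[str, list[str]] = {}
        indeg: dict[str, int] = {}
        for r in pw_edges.itertuples(index=False):
            children.setdefault(r.parent, []).append(r.child)
            indeg[r.child] = indeg.get(r.child, 0) + 1
            indeg.setdefault(r.parent, 0)
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for ch in children.get(n, ()):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        assert seen == len(indeg)
        assert any(d == 0 for d in indeg.values())  # at least one root

    def test_requested_depth_bounds_root_distance(self, bundle):
        _, pw_edges, *_ = bundle
        parents: dict[str, list[str]] = {}
        nodes = set(pw_edges["parent"]) | set(pw_edges["child"])
        for r in pw_edges.itertuples(index=False):
            parents.setdefault(r.child, []).append(r.parent)
        for node in nodes:
            depth, frontier = 0, {node}
            while not any(n not in parents for n in frontier):
                frontier = {p for n in frontier for p in parents.get(n, ())}
                depth += 1
                assert depth <= 4, f"{node} deeper than requested depth"

    def test_nonphysical_fraction_binomial(self):
        spec = SyntheticCohortSpec(n_genes=500, seed=23)
        sm = generate_gene_models(spec)
        edges, *_ , truth = generate_network_and_pathways(
            sm, [], spec, frac_nonphysical=0.3
        )
        assert len(edges) >= 900
        frac = len(truth.nonphysical_edges) / len(edges)
        assert 0.25 <= frac <= 0.35
        # the flagged edges are exactly the unsupported ones
        unsupported = {(e.protein_a, e.protein_b) for e in edges if not e.is_supported}
        assert unsupported == truth.nonphysical_edges

    def test_clinical_strings_are_dirty(self, bundle):
        *_, clinical, _ = bundle
        assert clinical["barcode"].str.fullmatch(r"TCGA-[A-Z]{2}-[A-Z0-9]{4}").all()
        raw = set(clinical["stage"])
        assert raw & {"Stage IIA", "Stage X", "Stage 0", "I/II NOS"}
        assert clinical["topography"].str.contains(r"\.").any()
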