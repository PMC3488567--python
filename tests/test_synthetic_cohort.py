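import math

import numpy as np
import pandas as pd
import pytest

from rcctriad.synthetic_cohort import (
    ABSENT_LEVEL,
    EXPRESSED_MIN,
    TOY_BAND_SIZE,
    TOY_CHROM_LENGTH,
    TOY_CHROMOSOMES,
    CohortSpec,
    generate_clinical,
    generate_cna_segments,
    generate_expression,
    generate_gene_sets,
    generate_study,
    toy_cytobands,
)


class TestSpecValidation:
    def test_group_sizes_must_sum_to_primary_count(self):
        with pytest.raises(ValueError, match="sum to n_primary"):
            CohortSpec(group_sizes=(50, 24, 24))

    def test_signature_demand_bounded_by_gene_count(self):
        with pytest.raises(ValueError, match="demand"):
            CohortSpec(n_genes=100)

    def test_cna_means_must_be_ordered(self):
        with pytest.raises(ValueError, match="ordered"):
            CohortSpec(cna_event_means=(6.0, 5.0, 2.0))


class TestCohortComposition:
    def test_default_counts(self, default_study):
        truth = default_study["truth"]
        labels = truth.sample_labels
        assert len(labels) == 97 + 15 + 34
        primaries = labels[labels.index.str.startswith("P")]
        assert primaries.value_counts().to_dict() == {"A": 49, "B": 24, "C": 24}
        assert (labels == "CELL_LINE").sum() == 34

    def test_annotation_subtype_composition(self, default_study):
        ann = default_study["annotation"].table
        truth = default_study["truth"].sample_labels
        prim = ann[ann["sample_class"] == "primary_tumor"]
        # group A is almost entirely clear-cell; group C is papillary-rich
        a_ids = truth.index[(truth == "A") & truth.index.str.startswith("P")]
        c_ids = truth.index[(truth == "C") & truth.index.str.startswith("P")]
        assert (prim.loc[a_ids, "subtype"] == "ccRCC").sum() == 48
        assert (prim.loc[c_ids, "subtype"] == "pRCC").sum() == 12

    def test_gene_role_counts(self, default_study):
        roles = default_study["truth"].gene_roles.value_counts()
        assert roles["signature_B"] == 40
        assert roles["signature_A_vs_C"] == 40
        assert roles["pathway_structured"] == 200
        assert roles["cellline_block"] == 80
        assert roles["absent"] == 50
        assert roles.sum() == 2000


class TestExpression:
    def test_determinism(self):
        m1, _, _ = generate_expression(CohortSpec(seed=5))
        m2, _, _ = generate_expression(CohortSpec(seed=5))
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_different_seeds_differ(self):
        m1, _, _ = generate_expression(CohortSpec(seed=5))
        m2, _, _ = generate_expression(CohortSpec(seed=6))
        assert not np.array_equal(m1.values, m2.values)

    def test_absent_genes_constant_below_expressed_floor(self, default_study):
        matrix = default_study["matrix"]
        truth = default_study["truth"]
        absent = truth.genes_with_role("absent")
        vals = matrix.data[absent].to_numpy()
        assert (vals == ABSENT_LEVEL).all()
        others = matrix.data.drop(columns=absent).to_numpy()
        assert others.min() >= EXPRESSED_MIN

    def test_planted_fold_changes_at_zero_noise(self):
        # with noise off, group-mean differences equal the planted effects
        spec = CohortSpec(noise_sd=0.0, seed=3)
        matrix, _, truth = generate_expression(spec)
        labels = truth.sample_labels
        means = {
            g: matrix.data.loc[labels == g].mean() for g in ("A", "B", "C")
        }
        b_lo, b_hi = spec.log2_fc_B_vs_AC_up
        bd_lo, bd_hi = spec.log2_fc_B_vs_AC_down
        for gene in truth.genes_with_role("signature_B"):
            diff = means["B"][gene] - (means["A"][gene] + means["C"][gene]) / 2
            assert diff == pytest.approx(truth.gene_effects[gene], abs=1e-9)
            mag = abs(diff)
            assert (b_lo <= mag <= b_hi) or (bd_lo <= mag <= bd_hi)
        ac_lo, ac_hi = spec.log2_fc_A_vs_C
        for gene in truth.genes_with_role("signature_A_vs_C"):
            diff = means["A"][gene] - means["C"][gene]
            assert diff == pytest.approx(truth.gene_effects[gene], abs=1e-9)
            assert ac_lo <= abs(diff) <= ac_hi
            # B sits at baseline, midway between A and C
            assert means["B"][gene] == pytest.approx(spec.baseline_mean, abs=1e-9)

    def test_cellline_block_shift(self):
        spec = CohortSpec(noise_sd=0.0, seed=4)
        matrix, _, truth = generate_expression(spec)
        labels = truth.sample_labels
        block = truth.genes_with_role("cellline_block")
        cl = matrix.data.loc[labels == "CELL_LINE", block].to_numpy()
        tu = matrix.data.loc[labels != "CELL_LINE", block].to_numpy()
        assert cl.mean() - tu.mean() == pytest.approx(spec.cellline_shift, abs=1e-9)


class TestGeneSets:
    def test_set_sizes_and_membership(self, default_study):
        sets = default_study["gene_sets"].sets
        truth = default_study["truth"]
        large = ["Wnt", "Inflammation", "Angiogenesis", "Integrin"]
        for name in large:
            assert len(sets[name]) == 200
        roles = truth.gene_roles
        for name in large:
            counts = roles.loc[sets[name]].value_counts()
            assert counts["signature_B"] == 10
            assert counts["signature_A_vs_C"] == 10
            assert counts["pathway_structured"] == 50
            assert counts["cellline_block"] == 20
        # small sets are background-only
        for name, size in zip(
            ["Apoptosis", "HIF_signaling", "Cysteine_biosynthesis"], (30, 60, 100)
        ):
            assert len(sets[name]) == size
            assert (roles.loc[sets[name]] == "background").all()

    def test_large_sets_are_disjoint(self, default_study):
        sets = default_study["gene_sets"].sets
        pooled = sum((sets[n] for n in sets), [])
        assert len(pooled) == len(set(pooled))


class TestToyGenome:
    def test_cytoband_tiling(self):
        cyto = toy_cytobands()
        per_chrom = TOY_CHROM_LENGTH // TOY_BAND_SIZE
        assert len(cyto) == per_chrom * len(TOY_CHROMOSOMES)
        one = cyto[cyto["chromosome"] == "7"].sort_values("start")
        assert one["start"].iloc[0] == 0
        assert one["end"].iloc[-1] == TOY_CHROM_LENGTH
        # contiguous, non-overlapping
        assert (one["end"].to_numpy()[:-1] == one["start"].to_numpy()[1:]).all()
        assert cyto["band"].is_unique


class TestCna:
    def test_events_respect_thresholds_and_sizes(self, default_study):
        truth = default_study["truth"]
        events = truth.cna_events
        assert (events["value"].abs() >= 0.2 - 1e-12).all()
        decoys = events[events["kind"] == "cnv_decoy"]
        focal = events[events["kind"] == "focal"]
        broad = events[events["kind"] == "broad"]
        assert ((decoys["end"] - decoys["start"]) < 100_000).all()
        assert ((focal["end"] - focal["start"]) < 5_000_000).all()
        assert ((broad["end"] - broad["start"]) >= 5_000_000).all()

    def test_group_burden_ordering(self):
        # planted event counts are Poisson with means ordered A < B <= C
        spec = CohortSpec(seed=11)
        _, _, truth = generate_expression(spec)
        _, events = generate_cna_segments(spec, truth)
        per_group = events.groupby("group").size()
        labels = truth.sample_labels
        rates = {
            g: per_group.get(g, 0) / (labels == g).sum() for g in ("A", "B", "C")
        }
        assert rates["A"] < rates["B"]
        assert rates["A"] < rates["C"]

    def test_no_cell_line_segments(self, default_study):
        seg = default_study["segments"]
        assert not seg["case_id"].str.startswith("CL").any()


class TestClinical:
    def test_schema_and_coverage(self, default_study):
        clin = default_study["clinical"]
        truth = default_study["truth"]
        assert sorted(clin.index) == sorted(truth.tumor_ids())
        assert (clin["time"] > 0).all()
        assert clin["event"].isin([0, 1]).all()

    def test_survival_ordering_in_large_cohort(self):
        spec = CohortSpec(
            n_primary=600, group_sizes=(200, 200, 200), seed=2
        )
        _, _, truth = generate_expression(spec)
        clin = generate_clinical(spec, truth)
        # uncensored mean survival follows the planted hazard ordering
        dead = clin[clin["event"] == 1]
        means = dead.groupby("true_group")["time"].mean()
        assert means["A"] > means["B"] > means["C"]

    def test_profiles_never_match_a_wrong_group(self, default_study):
        # inline restatement of the marker rule: profiles either match the
        # tumor's own group or fall in a coverage gap, never another group
        clin = default_study["clinical"]

        def rule(row):
            if row.msh6_pct <= 1:
                return "B"
            if row.dek_pct > 1:
                if row.mvd_count > 100:
                    return "A"
                if row.mvd_count < 50:
                    return "C"
            return "unassigned"

        called = clin.apply(rule, axis=1)
        assigned = called != "unassigned"
        assert (called[assigned] == clin.loc[assigned, "true_group"]).all()
        assert 0.6 <= assigned.mean() <= 0.9

    def test_assignable_fraction_bounds(self):
        spec = CohortSpec(seed=1)
        _, _, truth = generate_expression(spec)
        with pytest.raises(ValueError):
            generate_clinical(spec, truth, assignable_fraction=0.0)


def test_generate_study_is_self_consistent(default_study):
    study = default_study
    matrix = study["matrix"]
    truth = study["truth"]
    assert matrix.sample_ids == list(truth.sample_labels.index)
    assert matrix.gene_ids == list(truth.gene_roles.index)
    assert set(study["annotation"].table.index) == set(matrix.sample_ids)
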