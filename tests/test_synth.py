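"""Generator contracts: determinism, planted structure, and distributional
links between the latent Gaussian layer and the observed omics."""

import numpy as np
import pandas as pd
import pytest

from omicnets import netcompare, synth


class TestGenerateAnnotation:
    def test_counts_forced_by_parameters(self):
        genes, probes = synth.generate_annotation(2, 1, 2, seed=1)
        assert len(genes) == 2
        assert len(probes) == 4
        assert genes["is_tf"].sum() == 1

    def test_determinism(self):
        a = synth.generate_annotation(15, 5, 3, seed=7)
        b = synth.generate_annotation(15, 5, 3, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_probes_inside_and_outside_promoter_window(self):
        """Brute-force interval scan: every gene has a probe in its promoter
        window and (with >=2 probes) one outside."""
        window = 200
        genes, probes = synth.generate_annotation(50, 20, 3, seed=3, window_bp=window)
        for gid, g in genes.iterrows():
            inside = outside = 0
            for _, p in probes.iterrows():
                if p["chrom"] != g["chrom"]:
                    continue
                if g["strand"] == "+":
                    hit = g["tss"] - window <= p["pos"] < g["tss"]
                else:
                    hit = g["tss"] < p["pos"] <= g["tss"] + window
                if hit:
                    inside += 1
                else:
                    outside += 1
            assert inside >= 1, f"{gid} has no promoter probe"
            assert outside >= 1, f"{gid} has no probe outside its promoter"

    @pytest.mark.parametrize("bad", [(0, 1, 1), (5, 0, 1), (5, 6, 1), (5, 2, 0)])
    def test_parameter_errors(self, bad):
        with pytest.raises(ValueError):
            synth.generate_annotation(*bad, seed=0)


class TestBuildSubtypePrecisions:
    def test_identity_case(self, small_annotation):
        genes, _ = small_annotation
        precisions, truth = synth.build_subtype_precisions(genes, 2, seed=0)
        for s, omega in precisions.items():
            np.testing.assert_allclose(omega.to_numpy(), np.eye(len(omega)))
            rho = truth.true_partial_correlations[s].to_numpy()
            assert np.abs(rho - np.diag(np.diag(rho))).max() == 0

    def test_silenced_self_pair_negative(self, small_annotation):
        genes, _ = small_annotation
        tf = genes.index[genes["is_tf"]][0]
        precisions, truth = synth.build_subtype_precisions(
            genes, 2, silencing_spec={"S1": {tf}}, seed=0, silencing_magnitude=0.4
        )
        rho1 = truth.true_partial_correlations["S1"]
        rho2 = truth.true_partial_correlations["S2"]
        assert rho1.loc[f"M:{tf}", f"E:{tf}"] < -0.3
        assert rho2.loc[f"M:{tf}", f"E:{tf}"] >= -0.05

    def test_flip_edges_sign_opposed(self, small_annotation):
        genes, _ = small_annotation
        tfs = list(genes.index[genes["is_tf"]])
        flip = synth.FlipSpec(
            edges=((tfs[0], tfs[1]),), magnitude=0.3,
            positive_subtype="S1", negative_subtype="S2",
        )
        _, truth = synth.build_subtype_precisions(genes, 2, flip_spec=flip, seed=0)
        e = (f"M:{tfs[0]}", f"E:{tfs[1]}")
        assert truth.true_partial_correlations["S1"].loc[e] > 0
        assert truth.true_partial_correlations["S2"].loc[e] < 0

    def test_positive_definite_by_eigendecomposition(self, small_annotation):
        genes, _ = small_annotation
        tfs = set(genes.index[genes["is_tf"]][:4])
        precisions, _ = synth.build_subtype_precisions(
            genes, 3, silencing_spec={"S2": tfs}, seed=5, background_density=0.05
        )
        for omega in precisions.values():
            assert np.linalg.eigvalsh(omega.to_numpy())[0] > 0

    def test_unknown_tf_rejected(self, small_annotation):
        genes, _ = small_annotation
        with pytest.raises(ValueError, match="unknown TFs"):
            synth.build_subtype_precisions(
                genes, 2, silencing_spec={"S1": {"NOPE"}}, seed=0
            )

    def test_infeasible_magnitude_raises_not_clamps(self, small_annotation):
        genes, _ = small_annotation
        with pytest.raises(ValueError):
            synth.build_subtype_precisions(
                genes, 1, silencing_spec={"S1": set(genes.index[genes["is_tf"]])},
                seed=0, silencing_magnitude=1.5,
            )


@pytest.fixture(scope="module")
def setup():
    genes, probes = synth.generate_annotation(12, 8, 2, seed=2)
    tfs = list(genes.index[genes["is_tf"]])
    precisions, truth = synth.build_subtype_precisions(
        genes, 2, silencing_spec={"S1": set(tfs[:2])}, seed=2,
        background_density=0.03,
    )
    return genes, probes, precisions, truth


class TestSimulateCohort:

    def test_no_duplicates_unique_subjects(self, setup):
        genes, probes, precisions, _ = setup
        bundles = synth.simulate_cohort(
            precisions, (genes, probes), 10, duplicate_fraction=0.0, seed=4
        )
        for b in bundles.values():
            subjects = [s.rsplit("-V", 1)[0] for s in b.sample_ids]
            assert len(subjects) == len(set(subjects))

    def test_zero_missing_rate(self, setup):
        genes, probes, precisions, _ = setup
        bundles = synth.simulate_cohort(
            precisions, (genes, probes), 10, missing_rate=0.0, seed=4
        )
        assert not bundles["S1"].methylation_beta.isna().any().any()

    def test_duplicates_present_and_extra_missingness(self, setup):
        genes, probes, precisions, _ = setup
        bundles = synth.simulate_cohort(
            precisions, (genes, probes), 20, duplicate_fraction=0.5,
            missing_rate=0.01, seed=4,
        )
        b = bundles["S1"]
        assert sum(s.endswith("-V2") for s in b.sample_ids) == 10

    def test_latent_partial_correlations_recover_truth(self, setup):
        """At n=500 the sample partial correlations of the latent layer land
        within 0.1 of the planted values on planted edges."""
        genes, probes, precisions, truth = setup
        _, latents = synth.simulate_cohort(
            precisions, (genes, probes), 500, seed=9, return_latent=True
        )
        for s in ("S1", "S2"):
            z = latents[s].to_numpy()
            r = np.corrcoef(z)
            theta = np.linalg.inv(r)
            d = np.sqrt(np.diag(theta))
            pcor = -theta / np.outer(d, d)
            rho = truth.true_partial_correlations[s].to_numpy()
            planted = np.abs(rho - np.eye(len(rho))) > 1e-12
            np.fill_diagonal(planted, False)
            assert np.abs(pcor[planted] - rho[planted]).max() < 0.1

    def test_reproducible(self, setup):
        genes, probes, precisions, _ = setup
        a = synth.simulate_cohort(precisions, (genes, probes), 8, seed=5)
        b = synth.simulate_cohort(precisions, (genes, probes), 8, seed=5)
        pd.testing.assert_frame_equal(
            a["S1"].expression_counts, b["S1"].expression_counts
        )
        pd.testing.assert_frame_equal(
            a["S2"].methylation_beta, b["S2"].methylation_beta
        )

    def test_parameter_errors(self, setup):
        genes, probes, precisions, _ = setup
        with pytest.raises(ValueError):
            synth.simulate_cohort(precisions, (genes, probes), 3, seed=0)
        with pytest.raises(ValueError):
            synth.simulate_cohort(
                precisions, (genes, probes), 8, missing_rate=1.0, seed=0
            )


class TestGenerateBipartitePair:
    def test_zero_delta_zero_noise_identical(self):
        a, b, _, _ = synth.generate_bipartite_pair(4, 6, 2, 0, 0.0, 0.0, seed=3)
        pd.testing.assert_frame_equal(a.weights, b.weights)

    def test_noiseless_delta_gives_exact_module_size_degree(self):
        """With delta=1 and no noise the planted-module genes' in-module
        differential degree equals the number of planted-module TFs."""
        a, b, part, _ = synth.generate_bipartite_pair(6, 9, 3, 1, 1.0, 0.0, seed=3)
        dd = netcompare.differential_degree(b, a, part)
        n_tf_in = sum(
            1 for t in a.tf_ids if part.module_of(t) == 1
        )
        in_deg = dd.genes.loc[dd.genes["module"] == 1, "in_degree"]
        np.testing.assert_allclose(in_deg, n_tf_in)
        out_deg = dd.genes.loc[dd.genes["module"] != 1, "in_degree"]
        np.testing.assert_allclose(out_deg, 0.0)

    def test_reproducible(self):
        a1, b1, p1, _ = synth.generate_bipartite_pair(5, 7, 2, 0, 0.5, 0.2, seed=8)
        a2, b2, p2, _ = synth.generate_bipartite_pair(5, 7, 2, 0, 0.5, 0.2, seed=8)
        pd.testing.assert_frame_equal(a1.weights, a2.weights)
        pd.testing.assert_frame_equal(b1.weights, b2.weights)
        assert p1.assignments == p2.assignments

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            synth.generate_bipartite_pair(4, 6, 5, 0, 1.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            synth.generate_bipartite_pair(4, 6, 2, 2, 1.0, 0.1, seed=0)
        with pytest.raises(ValueError):
            synth.generate_bipartite_pair(4, 6, 2, 0, -1.0, 0.1, seed=0)


class TestGenerateGeneSets:
    def test_planted_set_overlaps_query(self):
        universe = [f"g{i}" for i in range(200)]
        query = universe[:30]
        coll, truth = synth.generate_gene_sets(universe, query, n_sets=5,
                                               set_size=20, seed=1)
        members = coll.members(truth.enriched_set)
        assert len(members & set(query)) >= 12  # 0.6 * 20

    def test_requires_query_subset(self):
        with pytest.raises(ValueError):
            synth.generate_gene_sets(["a", "b"], ["z"], seed=0)
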