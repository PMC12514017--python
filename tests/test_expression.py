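"""Donor microarray assembly: filters, mapping, probe selection, aggregation."""

import numpy as np
import pandas as pd
import pytest

import protectomap as pm
from protectomap.expression import DonorArray, DonorMicroarrayBundle


def tiny_bundle(above_fraction=1.0, n_probes=3, n_samples=10, seed=0):
    """Hand-built single-gene bundle with a controllable background rate."""
    rng = np.random.default_rng(seed)
    probes = pd.DataFrame({"gene": ["G1"] * n_probes},
                          index=[f"P{i}" for i in range(1, n_probes + 1)])
    donors = {}
    for d in (1, 2):
        samples = pd.DataFrame(
            rng.normal(0, 5, (n_samples, 3)),
            index=[f"D{d}S{i}" for i in range(n_samples)],
            columns=["mni_x", "mni_y", "mni_z"])
        inten = pd.DataFrame(2.0 ** rng.normal(8, 1, (n_probes, n_samples)),
                             index=probes.index, columns=samples.index)
        n_above = int(round(above_fraction * n_samples))
        bg = np.zeros((n_probes, n_samples), bool)
        bg[:, :n_above] = True
        donors[f"donor{d}"] = DonorArray(
            intensities=inten,
            background=pd.DataFrame(bg, index=probes.index, columns=samples.index),
            samples=samples)
    return DonorMicroarrayBundle(probes=probes, donors=donors)


def generated_bundle(geom60, n_genes=15, seed=3, **kwargs):
    ccfg = pm.CohortConfig(n_regions=60, atrophy_regions=frozenset(range(1, 16)))
    y = pm.true_interaction_map(ccfg, geom60)
    ecfg = pm.ExpressionConfig(n_genes=n_genes, planted_set_size=5, seed=seed)
    expr, _ = pm.generate_expression(ecfg, geom60, y)
    return expr, pm.generate_donor_microarrays(3, expr, geom60, seed=seed, **kwargs)


class TestBackgroundFilter:
    @pytest.mark.parametrize("fraction,kept", [
        (1.0, True),    # always above background
        (0.49, False),  # below the pooled-majority rule
        (0.5, True),    # boundary is inclusive (>= rule)
        (0.4, False),   # the documented 40% example
    ])
    def test_pooled_fraction_rule(self, fraction, kept):
        bundle = tiny_bundle(above_fraction=fraction, n_probes=1, n_samples=100)
        out = pm.filter_probes_background(bundle)
        assert (len(out.probes) == 1) is kept

    def test_all_above_removes_nothing(self):
        bundle = tiny_bundle(above_fraction=1.0)
        out = pm.filter_probes_background(bundle)
        assert list(out.probes.index) == list(bundle.probes.index)


class TestSampleAssignment:
    def test_sample_at_centroid_assigned_there(self, geom60):
        _, bundle = generated_bundle(geom60, seed=4)
        # place the first sample of donor1 exactly on centroid of region 7
        cent = geom60.loc[geom60["region_id"] == 7,
                          ["mni_x", "mni_y", "mni_z"]].to_numpy()[0]
        bundle.donors["donor1"].samples.iloc[0, :3] = cent
        bundle = pm.filter_probes_background(bundle)
        out = pm.assign_samples_to_parcels(bundle, geom60)
        assert out.donors["donor1"].samples["region"].iloc[0] == 7

    def test_far_samples_excluded(self, geom60):
        _, bundle = generated_bundle(geom60, seed=5, n_unassignable=4)
        bundle = pm.filter_probes_background(bundle)
        out = pm.assign_samples_to_parcels(bundle, geom60)
        for d in out.donor_ids:
            assert (np.abs(out.donors[d].samples["mni_x"]) <= 110).all()
            assert out.donors[d].samples["region"].notna().all()

    def test_jittered_samples_return_home(self, geom60):
        """With jitter much smaller than centroid spacing, >= 99% of retained
        samples are assigned to their source region."""
        _, bundle = generated_bundle(geom60, seed=6, jitter_mm=1.0)
        bundle = pm.filter_probes_background(bundle)
        out = pm.assign_samples_to_parcels(bundle, geom60)
        correct = total = 0
        for d in out.donor_ids:
            s = out.donors[d].samples.dropna(subset=["source_region"])
            correct += (s["region"] == s["source_region"]).sum()
            total += len(s)
        assert correct / total >= 0.99


class TestProbeSelection:
    def test_single_probe_gene_selected(self, geom60):
        _, bundle = generated_bundle(geom60, seed=7)
        bundle = pm.filter_probes_background(bundle)
        bundle = pm.assign_samples_to_parcels(bundle, geom60)
        single = bundle.probes["gene"].value_counts()
        out = pm.select_probe_per_gene(bundle)
        assert out.probes["gene"].is_unique
        assert set(out.probes["gene"]) == set(bundle.probes["gene"])

    def test_requires_assignment_first(self, geom60):
        _, bundle = generated_bundle(geom60, seed=8)
        with pytest.raises(RuntimeError, match="assign_samples"):
            pm.select_probe_per_gene(bundle)

    def test_stable_probe_beats_noise_probe(self, geom60):
        """Across seeds, the probe tracking the shared regional profile wins
        over a pure-noise probe for the same gene."""
        wins = trials = 0
        for seed in range(25):
            expr, bundle = generated_bundle(geom60, n_genes=5, seed=100 + seed,
                                            n_unassignable=0)
            bundle = pm.filter_probes_background(bundle)
            bundle = pm.assign_samples_to_parcels(bundle, geom60)
            out = pm.select_probe_per_gene(bundle)
            # generator convention: the first probe of each gene is high-fidelity
            first_probe = bundle.probes.reset_index().groupby("gene", sort=True)[
                "probe_id" if "probe_id" in bundle.probes.reset_index() else "index"
            ].min()
            multi = bundle.probes["gene"].value_counts()
            for gene, probe in out.probes.reset_index().set_index("gene").iloc[:, 0].items():
                if multi[gene] > 1:
                    trials += 1
                    wins += probe == first_probe[gene]
        assert trials >= 20
        assert wins / trials >= 0.95

    def test_identical_duplicate_probes_tie_to_lowest_id(self):
        bundle = tiny_bundle(above_fraction=1.0, n_probes=2, n_samples=12, seed=9)
        # make the two probes identical and give samples valid regions
        for d in bundle.donor_ids:
            arr = bundle.donors[d]
            arr.intensities.iloc[1] = arr.intensities.iloc[0]
            arr.samples["region"] = np.arange(len(arr.samples)) % 4 + 1
        bundle.background_filtered = True
        bundle.samples_assigned = True
        out = pm.select_probe_per_gene(bundle)
        assert list(out.probes.index) == ["P1"]


class TestConsistencyFilter:
    def test_identical_across_donors_kept_noise_dropped(self, geom60):
        expr, bundle = generated_bundle(geom60, n_genes=10, seed=10,
                                        n_unassignable=0)
        bundle = pm.filter_probes_background(bundle)
        bundle = pm.assign_samples_to_parcels(bundle, geom60)
        bundle = pm.select_probe_per_gene(bundle)
        # overwrite one gene's probe with independent noise per donor
        noisy_probe = bundle.probes.index[0]
        rng = np.random.default_rng(0)
        for d in bundle.donor_ids:
            arr = bundle.donors[d]
            arr.intensities.loc[noisy_probe] = 2.0 ** rng.normal(8, 1, arr.intensities.shape[1])
        out = pm.filter_inconsistent_genes(bundle, min_stability=0.1)
        assert noisy_probe not in out.probes.index
        assert len(out.probes) >= 5  # faithful genes survive

    def test_zero_threshold_drops_nothing(self, geom60):
        _, bundle = generated_bundle(geom60, n_genes=8, seed=11)
        bundle = pm.filter_probes_background(bundle)
        bundle = pm.assign_samples_to_parcels(bundle, geom60)
        bundle = pm.select_probe_per_gene(bundle)
        out = pm.filter_inconsistent_genes(bundle, min_stability=0.0)
        assert len(out.probes) == len(bundle.probes)


class TestAggregation:
    def run_pipeline(self, geom, bundle, method="srs"):
        bundle = pm.filter_probes_background(bundle)
        bundle = pm.assign_samples_to_parcels(bundle, geom)
        bundle = pm.select_probe_per_gene(bundle)
        bundle = pm.filter_inconsistent_genes(bundle, min_stability=0.0)
        return pm.normalize_and_aggregate(bundle, method=method)

    def test_order_enforced(self, geom60):
        _, bundle = generated_bundle(geom60, seed=12)
        with pytest.raises(RuntimeError, match="order"):
            pm.normalize_and_aggregate(bundle)

    def test_donor_scale_invariance(self, geom60):
        _, bundle = generated_bundle(geom60, n_genes=8, seed=13)
        out1 = self.run_pipeline(geom60, bundle)
        _, bundle2 = generated_bundle(geom60, n_genes=8, seed=13)
        bundle2.donors["donor1"].intensities *= 10.0
        out2 = self.run_pipeline(geom60, bundle2)
        assert np.abs(out1.to_numpy() - out2.to_numpy()).max() < 1e-6

    def test_duplicate_donor_equals_single_donor(self, geom60):
        _, bundle = generated_bundle(geom60, n_genes=6, seed=14)
        # two donors with identical arrays collapse to the single-donor result
        d1 = bundle.donors["donor1"]
        twin = DonorArray(intensities=d1.intensities.copy(),
                          background=d1.background.copy(),
                          samples=d1.samples.copy())
        dup = DonorMicroarrayBundle(probes=bundle.probes.copy(),
                                    donors={"donor1": d1, "donor2": twin})
        single = DonorMicroarrayBundle(probes=bundle.probes.copy(),
                                       donors={"donor1": d1})
        out_dup = self.run_pipeline(geom60, dup)
        out_single = self.run_pipeline(geom60, single)
        assert np.allclose(out_dup.to_numpy(), out_single.to_numpy(), atol=1e-12)

    def test_noise_free_end_to_end_recovers_truth(self, geom60):
        """A noise-free bundle reproduces the generator's regional profiles:
        near-perfectly under the linear normalization, and up to the bounded
        monotone compression of the sigmoid under the default."""
        ccfg = pm.CohortConfig(n_regions=60, atrophy_regions=frozenset(range(1, 16)))
        y = pm.true_interaction_map(ccfg, geom60)
        ecfg = pm.ExpressionConfig(n_genes=6, planted_set_size=5, seed=15)
        expr, _ = pm.generate_expression(ecfg, geom60, y)
        # noise-free: one sample exactly at each centroid, intensity = 2^(8+z)
        probes = pd.DataFrame({"gene": list(expr.columns)},
                              index=[f"P{i}" for i in range(1, 7)])
        donors = {}
        for d in (1, 2):
            samples = pd.DataFrame(
                geom60[["mni_x", "mni_y", "mni_z"]].to_numpy(),
                index=[f"D{d}S{i}" for i in range(60)],
                columns=["mni_x", "mni_y", "mni_z"])
            inten = pd.DataFrame(2.0 ** (8.0 + expr.to_numpy().T),
                                 index=probes.index, columns=samples.index)
            donors[f"donor{d}"] = DonorArray(
                intensities=inten,
                background=pd.DataFrame(True, index=probes.index,
                                        columns=samples.index),
                samples=samples)
        bundle = DonorMicroarrayBundle(probes=probes, donors=donors)
        out_lin = self.run_pipeline(geom60, bundle, method="zscore")
        for g in expr.columns:
            r = np.corrcoef(out_lin[g], expr.loc[out_lin.index, g])[0, 1]
            assert r > 0.999
        out_srs = self.run_pipeline(geom60, bundle, method="srs")
        for g in expr.columns:
            r = np.corrcoef(out_srs[g], expr.loc[out_srs.index, g])[0, 1]
            assert r > 0.95
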