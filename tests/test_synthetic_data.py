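"""Ground-truth generators: determinism, linearity, composition fidelity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import label

from ploidyscope import synthetic_data as sd


def _mono_spec(n=100, cv=0.0, seed=0, viability=1.0):
    return sd.PopulationSpec(
        n_cells_by_type={"cardiomyocyte": n},
        nucleation_probs={"cardiomyocyte": {1: 1.0, 2: 0.0}},
        nuclear_ploidy_probs={"cardiomyocyte": {1: {2: 1.0}}},
        intensity_cv=cv,
        viability_prob=viability,
        seed=seed,
    )


class TestGeneratePopulation:
    def test_noise_free_identity(self):
        """All-mononuclear all-diploid cells at cv=0 sit exactly at the reference."""
        table = sd.generate_population(_mono_spec(n=100))
        assert table["cell_id"].nunique() == 100
        assert (table["true_copies"] == 2).all()
        np.testing.assert_allclose(
            table["true_intensity"], sd.PopulationSpec.reference_intensity, rtol=0
        )

    def test_intensity_linearity_at_zero_cv(self):
        """With cv=0, intensity / reference equals copies / 2 exactly."""
        spec = sd.population_spec_for_strain(
            "BALB_cByJ", n_cells=500, n_reference=50, intensity_cv=0.0, seed=2
        )
        table = sd.generate_population(spec)
        np.testing.assert_array_equal(
            table["true_intensity"] / spec.reference_intensity,
            table["true_copies"] / 2.0,
        )

    def test_mononuclear_fraction_matches_binomial(self):
        """Empirical mononuclear share of a 10,000-cell cohort is within 3 binomial SD of 14.3%."""
        spec = sd.population_spec_for_strain(
            "BALB_cByJ", n_cells=10_000, n_reference=0, seed=4
        )
        table = sd.generate_population(spec)
        mono = (table.groupby("cell_id").size() == 1).mean()
        p = 0.143
        assert abs(mono - p) < 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_endothelial_always_mononuclear_diploid(self):
        spec = sd.PopulationSpec(n_cells_by_type={"endothelial": 50}, seed=9)
        table = sd.generate_population(spec)
        per_cell = table.groupby("cell_id").size()
        assert len(per_cell) == 50
        assert (per_cell == 1).all()
        assert (table["true_copies"] == 2).all()

    def test_determinism(self):
        spec = sd.population_spec_for_strain("BALB_cJ", n_cells=300, seed=7)
        pd.testing.assert_frame_equal(
            sd.generate_population(spec), sd.generate_population(spec)
        )

    @pytest.mark.parametrize(
        "bad, message_part",
        [
            (
                dict(nucleation_probs={"cardiomyocyte": {1: 0.6, 2: 0.6}}),
                "nucleation_probs[cardiomyocyte]",
            ),
            (
                dict(
                    nuclear_ploidy_probs={
                        "cardiomyocyte": {1: {2: 0.5, 4: 0.1, 8: 0.1}}
                    }
                ),
                "nuclear_ploidy_probs[cardiomyocyte][1]",
            ),
            (dict(intensity_cv=-0.1), "intensity_cv"),
            (dict(viability_prob=1.5), "viability_prob"),
        ],
    )
    def test_validation_names_offender(self, bad, message_part):
        base = dict(
            n_cells_by_type={"cardiomyocyte": 10},
            nucleation_probs={"cardiomyocyte": {1: 1.0}},
            nuclear_ploidy_probs={"cardiomyocyte": {1: {2: 1.0}}},
        )
        base.update(bad)
        with pytest.raises(sd.SpecValidationError, match=message_part.replace("[", r"\[")):
            sd.generate_population(sd.PopulationSpec(**base))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        mono=st.floats(0.02, 0.98),
        p2n=st.floats(0.05, 0.95),
        seed=st.integers(0, 10_000),
    )
    def test_composition_matches_spec_within_4sd(self, mono, p2n, seed):
        """Multinomial property: empirical nucleation and ploidy track any valid spec."""
        n = 10_000
        spec = sd.PopulationSpec(
            n_cells_by_type={"cardiomyocyte": n},
            nucleation_probs={"cardiomyocyte": {1: mono, 2: 1.0 - mono}},
            nuclear_ploidy_probs={
                "cardiomyocyte": {
                    1: {2: p2n, 4: 1.0 - p2n},
                    2: {2: 1.0},
                }
            },
            seed=seed,
        )
        table = sd.generate_population(spec)
        emp_mono = (table.groupby("cell_id").size() == 1).mean()
        assert abs(emp_mono - mono) <= 4 * np.sqrt(mono * (1 - mono) / n) + 1e-12
        mono_ids = table.groupby("cell_id").size().pipe(lambda s: s[s == 1]).index
        mono_nuc = table[table["cell_id"].isin(mono_ids)]
        if len(mono_nuc) >= 50:
            emp_2n = (mono_nuc["true_copies"] == 2).mean()
            bound = 4 * np.sqrt(p2n * (1 - p2n) / len(mono_nuc))
            assert abs(emp_2n - p2n) <= bound + 1e-12


class TestRenderImages:
    def test_single_cell_single_component_and_intensity(self):
        """One mononuclear cell, zero noise: one DAPI blob whose background-
        subtracted integral matches the ground-truth intensity within 1%."""
        table = sd.generate_population(_mono_spec(n=1))
        img = sd.ImagingSpec(additive_noise_sd=0.0, cells_per_frame=1)
        frames, placement = sd.render_images(table, img, seed=0)
        assert len(frames) == 1
        dapi = frames[0][0].astype(float)
        mask = dapi > img.background_level + 1.0
        assert label(mask).max() == 1
        integrated = (dapi - img.background_level).sum()
        assert integrated == pytest.approx(placement["true_intensity"].iloc[0], rel=0.01)

    def test_binuclear_two_dapi_components_one_lineage_mask(self):
        table = pd.DataFrame(
            {
                "cell_id": [0, 0],
                "cell_type": "cardiomyocyte",
                "viable": True,
                "nucleus_index": [0, 1],
                "true_copies": [2, 2],
                "true_intensity": [5e4, 5e4],
            }
        )
        img = sd.ImagingSpec(additive_noise_sd=0.0, cells_per_frame=1)
        frames, _ = sd.render_images(table, img, seed=1)
        dapi, lineage, cd31 = frames[0]
        assert label(dapi > img.background_level + 1.0).max() == 2
        assert label(lineage > 0).max() == 1
        assert cd31.max() == 0

    def test_ploidy_intensity_ratio_two(self):
        """A 4n and a 2n nucleus at zero noise integrate at ratio 2.0 +/- 0.02."""
        table = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "cell_type": "cardiomyocyte",
                "viable": True,
                "nucleus_index": [0, 0],
                "true_copies": [4, 2],
                "true_intensity": [1e5, 5e4],
            }
        )
        img = sd.ImagingSpec(additive_noise_sd=0.0, background_level=0.0)
        frames, placement = sd.render_images(table, img, seed=2)
        dapi = frames[0][0].astype(float)
        labels = label(dapi > 1.0)
        assert labels.max() == 2
        sums = sorted(dapi[labels == i].sum() for i in (1, 2))
        assert sums[1] / sums[0] == pytest.approx(2.0, abs=0.02)

    def test_placement_links_all_viable_nuclei(self, noise_free_render):
        table, _, placement = noise_free_render
        assert len(placement) == int(table["viable"].sum())
        merged = placement.merge(
            table, on=["cell_id", "nucleus_index"], suffixes=("", "_truth")
        )
        assert (merged["true_copies"] == merged["true_copies_truth"]).all()

    def test_packing_error(self):
        table = sd.generate_population(_mono_spec(n=500))
        img = sd.ImagingSpec(frame_size=128, cells_per_frame=64)
        with pytest.raises(sd.PackingError):
            sd.render_images(table, img, seed=0)

    def test_determinism(self):
        table = sd.generate_population(_mono_spec(n=30))
        img = sd.ImagingSpec()
        frames_a, pl_a = sd.render_images(table, img, seed=8)
        frames_b, pl_b = sd.render_images(table, img, seed=8)
        for fa, fb in zip(frames_a, frames_b):
            np.testing.assert_array_equal(fa, fb)
        pd.testing.assert_frame_equal(pl_a, pl_b)


class TestVariantPanel:
    def test_no_decoys_only_planted(self):
        calls, truth = sd.generate_variant_panel(n_strains=4, n_decoys=0, seed=0)
        assert (truth["label"] == "planted").all()
        focal = calls[calls["strain"] == "BALB_cByJ"]
        assert len(focal) == 2
        assert (focal["chrom"] == "X").all()
        assert (focal["genotype"] == "hom_alt").all()
        assert focal["rsid"].isna().all()

    def test_planted_records_exact(self):
        """The two planted private variants appear as homozygous-alt records."""
        calls, _ = sd.generate_variant_panel(n_strains=6, n_decoys=50, seed=1)
        focal = calls[calls["strain"] == "BALB_cByJ"]
        gdi1 = focal[(focal["chrom"] == "X") & (focal["pos"] == 74_309_969)]
        irs4 = focal[(focal["chrom"] == "X") & (focal["pos"] == 141_723_152)]
        assert len(gdi1) == 1 and len(irs4) == 1
        assert (gdi1["ref"].iloc[0], gdi1["alt"].iloc[0]) == ("C", "T")
        assert (irs4["ref"].iloc[0], irs4["alt"].iloc[0]) == ("G", "A")
        assert gdi1["genotype"].iloc[0] == "hom_alt"
        others = calls[calls["strain"] != "BALB_cByJ"]
        assert not others["pos"].isin([74_309_969, 141_723_152]).any()

    def test_byte_identical_regeneration(self, tmp_path):
        """500 decoys spanning all six classes regenerate byte-identically."""
        for sub in ("a", "b"):
            calls, _ = sd.generate_variant_panel(n_strains=8, n_decoys=500, seed=42)
            sd.write_variant_panel_vcfs(calls, tmp_path / sub)
        for vcf_a in sorted((tmp_path / "a").glob("*.vcf")):
            vcf_b = tmp_path / "b" / vcf_a.name
            assert vcf_a.read_bytes() == vcf_b.read_bytes()

    def test_colliding_planted_sites_rejected(self):
        dup = (
            sd.PlantedVariant("X", 1000, "A", "G"),
            sd.PlantedVariant("X", 1000, "A", "T"),
        )
        with pytest.raises(sd.GenerationError, match="collide"):
            sd.generate_variant_panel(n_strains=4, planted_private=dup)

    def test_decoy_counts_honoured(self):
        counts = {cls: 5 for cls in sd.DECOY_CLASSES}
        _, truth = sd.generate_variant_panel(n_strains=5, decoy_counts=counts, seed=3)
        observed = truth["label"].value_counts().to_dict()
        for cls in sd.DECOY_CLASSES:
            assert observed[cls] == 5
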