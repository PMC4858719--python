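"""Generator correctness: determinism, conservation, drawn distributions,
colocalized placement and cohort/TEM scenarios."""

import numpy as np
import pandas as pd
import pytest

import vesiq as vq
from vesiq.core import Compartment
from vesiq.synth import _sample_puncta


def test_empty_scene_has_only_background_in_cargo(small_config):
    cfg = small_config.replace(vesicle_density=0, bl_accumulation=0,
                               parenchyma_level=0, coloc_fraction=0,
                               lysosome_density=0)
    stack, manifest = vq.generate_vessel_stack(cfg)
    assert len(manifest.spots_for("cargo")) == 0
    cargo = stack.channel("cargo").astype(float)
    # background 5 photons/voxel + noise only: mean near 5, no bright objects
    assert abs(cargo.mean() - cfg.background) < 0.5
    assert cargo.max() < cfg.background + 10 * np.sqrt(cfg.background + cfg.read_noise_sd ** 2)


def test_same_seed_bitwise_identical(small_config):
    s1, m1 = vq.generate_vessel_stack(small_config)
    s2, m2 = vq.generate_vessel_stack(small_config)
    assert np.array_equal(s1.voxels, s2.voxels)
    pd.testing.assert_frame_equal(m1.true_spots, m2.true_spots)


def test_different_seed_differs(small_config):
    s1, _ = vq.generate_vessel_stack(small_config)
    s2, _ = vq.generate_vessel_stack(small_config.replace(seed=small_config.seed + 1))
    assert not np.array_equal(s1.voxels, s2.voxels)


def test_photon_conservation(small_config):
    """Pre-noise cargo photons equal placed objects plus diffuse totals."""
    stack, manifest, photons = vq.generate_vessel_stack(small_config, return_photons=True)
    cfg = small_config
    truth = vq.true_compartment_mask(cfg)
    n_shell = int(truth.mask(Compartment.BASAL_LAMINA).sum())
    n_par = int(truth.mask(Compartment.PARENCHYMA).sum())
    expected = (manifest.spots_for("cargo")["photons"].sum()
                + cfg.bl_accumulation * n_shell
                + cfg.parenchyma_level * n_par)
    total = float(photons["cargo"].sum())
    assert total == pytest.approx(expected, rel=1e-2)


def test_radius_and_intensity_laws(small_config):
    """Across >=1e4 drawn objects the log moments match the configured law,
    and the central 99.7% of intensities spans >= 2.8 decades."""
    rng = np.random.default_rng(123)
    spots = _sample_puncta(small_config, rng, density=200.0,
                           radius_ln=small_config.radius_lognormal,
                           intensity_ln=small_config.intensity_lognormal)
    assert len(spots) > 10_000
    logs = np.log(spots["radius_um"].to_numpy())
    mu, sd = small_config.radius_lognormal
    se_mu = sd / np.sqrt(len(logs))
    se_sd = sd / np.sqrt(2 * len(logs))
    assert abs(logs.mean() - mu) < 3 * se_mu
    assert abs(logs.std(ddof=1) - sd) < 3 * se_sd
    inten = spots["photons"].to_numpy()
    lo, hi = np.percentile(inten, [0.15, 99.85])
    assert np.log10(hi / lo) >= 2.8


def test_spot_centroids_inside_bounds(small_scene):
    _, manifest = small_scene
    lz, ly, lx = manifest.config.field_size_um
    ts = manifest.true_spots
    assert ((ts["z_um"] >= 0) & (ts["z_um"] <= lz)).all()
    assert ((ts["y_um"] >= 0) & (ts["y_um"] <= ly)).all()
    assert ((ts["x_um"] >= 0) & (ts["x_um"] <= lx)).all()


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_colocalized_fraction_near_target(seed):
    """Largest-first whole-object assignment lands within one-object
    granularity of the requested intensity fraction (0.20 by default)."""
    _, manifest = vq.generate_vessel_stack(vq.steadystate_config(seed=seed))
    achieved = manifest.true_metrics["coloc_fraction"]
    cargo = manifest.spots_for("cargo")
    smallest_share = cargo["photons"].min() / cargo["photons"].sum()
    assert abs(achieved - 0.20) <= max(2 * smallest_share, 0.02)


def test_coloc_requires_lysosomes(small_config):
    with pytest.raises(ValueError, match="lysosome"):
        vq.generate_vessel_stack(small_config.replace(lysosome_density=0.0,
                                                      coloc_fraction=0.2))


def test_vessel_must_fit_in_field(small_config):
    with pytest.raises(ValueError, match="vessel exceeds field"):
        vq.generate_vessel_stack(small_config.replace(vessel_inner_radius=5.0))


def test_true_metrics_recomputable(small_scene):
    stack, manifest = small_scene
    cfg = manifest.config
    cargo = manifest.spots_for("cargo")
    vol = manifest.true_compartment_volumes
    vessel_volume = vol["INTERIOR"] + vol["BASAL_LAMINA"]
    assert manifest.true_metrics["vesicles_per_um3"] == pytest.approx(
        len(cargo) / vessel_volume)
    coloc = cargo.loc[cargo["is_colocalized"], "photons"].sum() / cargo["photons"].sum()
    assert manifest.true_metrics["coloc_fraction"] == pytest.approx(coloc)


def test_manifest_json_roundtrip(small_scene, tmp_path):
    _, manifest = small_scene
    manifest.to_json(tmp_path / "m.json")
    back = vq.GroundTruthManifest.from_json(tmp_path / "m.json")
    assert back.config == manifest.config
    pd.testing.assert_frame_equal(back.true_spots, manifest.true_spots,
                                  check_dtype=False)


# ---------------------------------------------------------------------------
# cohorts


def test_cohort_shape_and_grouping(small_config):
    scenario = vq.control_scenario(master_seed=3, n_animals=3, vessels_per_animal=2)
    cohort = vq.generate_cohort(scenario, small_config)
    assert len(cohort) == 3
    assert all(len(animal) == 2 for animal in cohort)
    # per-animal jitter: intensity parameters differ between animals
    levels = [animal[0][1].config.bl_accumulation for animal in cohort]
    assert len(set(levels)) == 3


def test_cohort_deterministic(small_config):
    scenario = vq.control_scenario(master_seed=3, n_animals=2, vessels_per_animal=1)
    c1 = vq.generate_cohort(scenario, small_config)
    c2 = vq.generate_cohort(scenario, small_config)
    assert np.array_equal(c1[0][0][0].voxels, c2[0][0][0].voxels)
    assert np.array_equal(c1[1][0][0].voxels, c2[1][0][0].voxels)


def test_deficient_scenario_multipliers(small_config):
    ctrl = vq.generate_cohort(
        vq.control_scenario(master_seed=5, n_animals=3, vessels_per_animal=1,
                            animal_jitter_sd=0.0), small_config)
    defi = vq.generate_cohort(
        vq.pericyte_deficient_scenario(master_seed=5, n_animals=3, vessels_per_animal=1,
                                       animal_jitter_sd=0.0,
                                       vessel_radius_fold=1.0), small_config)
    c = ctrl[0][0][1].config
    d = defi[0][0][1].config
    assert d.bl_accumulation == pytest.approx(100 * c.bl_accumulation)
    assert d.parenchyma_level == pytest.approx(50 * c.parenchyma_level)
    assert d.vesicle_density == pytest.approx(0.3 * c.vesicle_density)
    assert d.coloc_fraction == 0.0


def test_identity_multipliers_match_control(small_config):
    a = vq.generate_cohort(vq.control_scenario(master_seed=7, n_animals=1,
                                               vessels_per_animal=1), small_config)
    b = vq.generate_cohort(
        vq.CohortScenario(name="control", master_seed=7, n_animals=1,
                          vessels_per_animal=1), small_config)
    assert np.array_equal(a[0][0][0].voxels, b[0][0][0].voxels)


# ---------------------------------------------------------------------------
# TEM counts


def test_tem_table_format_and_determinism():
    cfg = vq.TEMCountConfig(seed=4)
    t1 = vq.generate_tem_counts(cfg)
    t2 = vq.generate_tem_counts(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1.columns) == ["genotype", "animal", "capillary", "class", "count"]
    assert (t1["count"] >= 0).all()
    assert t1["count"].dtype.kind == "i"
    assert set(t1["class"]) == {"luminal", "intracellular", "abluminal"}


def test_tem_null_scenario_rarely_significant():
    """Equal means in both genotypes: Mann-Whitney at alpha=0.005 stays
    non-significant in >= 99% of replicate tables (reduced replication)."""
    means = {"control": {"intracellular": 10.0},
             "pericyte_deficient": {"intracellular": 10.0}}
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        table = vq.generate_tem_counts(
            vq.TEMCountConfig(means=means, n_capillaries=20, seed=rep))
        _, tests = vq.summarize_counts(table)
        hits += int((tests["p"] < 0.005).any())
    assert hits / n_rep <= 0.01 + 0.01  # binomial slack on 200 reps


def test_tem_effect_detected_with_power():
    """2.5-fold intracellular increase, n=20/side: p < 0.005 in >= 80%."""
    means = {"control": {"intracellular": 8.0},
             "pericyte_deficient": {"intracellular": 20.0}}
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        table = vq.generate_tem_counts(
            vq.TEMCountConfig(means=means, n_capillaries=20, seed=10_000 + rep))
        _, tests = vq.summarize_counts(table)
        hits += int((tests["p"] < 0.005).all())
    assert hits / n_rep >= 0.80


def test_tem_poisson_limit():
    """dispersion -> infinity: variance/mean -> 1 over 1e4 draws."""
    means = {"g": {"intracellular": 9.0}}
    table = vq.generate_tem_counts(
        vq.TEMCountConfig(means=means, dispersion=1e9, n_capillaries=10_000, seed=0))
    counts = table["count"].to_numpy()
    assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)


def test_tem_config_validation():
    with pytest.raises(ValueError):
        vq.TEMCountConfig(dispersion=0.0)
    with pytest.raises(ValueError):
        vq.TEMCountConfig(n_capillaries=0)
    with pytest.raises(ValueError):
        vq.TEMCountConfig(means={"g": {"luminal": -1.0}})
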