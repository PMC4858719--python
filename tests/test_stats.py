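"""Per-vessel metrics, Fisher's LSD, Mann-Whitney and TEM summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import vesiq as vq
from vesiq.core import Compartment, CompartmentMask, ImageStack, Spot, SpotSet


# ---------------------------------------------------------------------------
# quantify_vessel


def test_zero_cargo_scene_gives_zero_metrics(small_config):
    cfg = small_config.replace(vesicle_density=0, lysosome_density=0,
                               coloc_fraction=0, bl_accumulation=0,
                               parenchyma_level=0, background=0,
                               read_noise_sd=0)
    stack, _ = vq.generate_vessel_stack(cfg)
    mask = vq.true_compartment_mask(cfg)
    q = vq.quantify_vessel(stack, mask, SpotSet([]), background="none")
    assert q.bl_intensity_per_um2 == 0.0
    assert q.parenchyma_intensity_per_um3 == 0.0
    assert q.vesicles_per_um3 == 0.0


def test_metrics_match_manifest(steady_scene, steady_mask, bright_scene):
    """Pipeline metrics recover the generator's ground truth: intensity
    metrics on the standard fixture within 20%; puncta density on the
    uniformly bright fixture (where detection is near-complete) within 20%."""
    stack, manifest = steady_scene
    spots = vq.assign_compartments(vq.detect_spots(stack, "cargo"), steady_mask)
    q = vq.quantify_vessel(stack, steady_mask, spots)
    truth = manifest.true_metrics
    assert q.bl_intensity_per_um2 == pytest.approx(truth["bl_intensity_per_um2"], rel=0.2)
    assert q.parenchyma_intensity_per_um3 == pytest.approx(
        truth["parenchyma_intensity_per_um3"], rel=0.2)

    bstack, bmanifest = bright_scene
    bmask = vq.segment_stack(bstack)
    bspots = vq.assign_compartments(vq.detect_spots(bstack, "cargo"), bmask)
    bq = vq.quantify_vessel(bstack, bmask, bspots)
    assert bq.vesicles_per_um3 == pytest.approx(
        bmanifest.true_metrics["vesicles_per_um3"], rel=0.2)


def test_intensity_metrics_linear_in_cargo(steady_scene, steady_mask):
    stack, _ = steady_scene
    spots = vq.assign_compartments(vq.detect_spots(stack, "cargo"), steady_mask)
    q1 = vq.quantify_vessel(stack, steady_mask, spots)
    doubled = ImageStack(np.clip(stack.voxels.astype(np.int64) * 2, 0, 2**16 - 1
                                 ).astype(np.uint16),
                         stack.voxel_size_zyx, stack.channel_names, bit_depth=16)
    q2 = vq.quantify_vessel(doubled, steady_mask, spots)
    assert q2.bl_intensity_per_um2 == pytest.approx(2 * q1.bl_intensity_per_um2, rel=0.05)
    assert q2.parenchyma_intensity_per_um3 == pytest.approx(
        2 * q1.parenchyma_intensity_per_um3, rel=0.05)
    assert q2.vesicles_per_um3 == q1.vesicles_per_um3


def test_quantify_requires_shell_and_parenchyma():
    labels = np.full((4, 4, 4), int(Compartment.PARENCHYMA), dtype=np.uint8)
    mask = CompartmentMask(labels, (1, 1, 1))
    stack = ImageStack(np.zeros((1, 4, 4, 4), dtype=np.uint16), (1, 1, 1), ("cargo",))
    with pytest.raises(ValueError, match="shell"):
        vq.quantify_vessel(stack, mask, SpotSet([]), background="none")
    labels_all_bl = np.full((4, 4, 4), int(Compartment.BASAL_LAMINA), dtype=np.uint8)
    with pytest.raises(ValueError, match="parenchyma"):
        vq.quantify_vessel(stack, CompartmentMask(labels_all_bl, (1, 1, 1)),
                           SpotSet([]), background="none")


def test_background_estimator_recovers_offset(steady_scene, steady_mask):
    stack, manifest = steady_scene
    spots = vq.assign_compartments(vq.detect_spots(stack, "cargo"), steady_mask)
    bg = vq.estimate_background(stack, "cargo", steady_mask, exclude_spots=spots)
    assert bg == pytest.approx(manifest.config.background, abs=0.5)


def test_vessel_volume_option(steady_scene, steady_mask):
    stack, _ = steady_scene
    spots = vq.assign_compartments(vq.detect_spots(stack, "cargo"), steady_mask)
    q_filled = vq.quantify_vessel(stack, steady_mask, spots, vessel_volume="filled")
    q_shell = vq.quantify_vessel(stack, steady_mask, spots, vessel_volume="shell-only")
    assert q_shell.vesicles_per_um3 > q_filled.vesicles_per_um3


# ---------------------------------------------------------------------------
# fold change


def test_fold_change_identity_and_scaling():
    a = [1.0, 2.0, 3.0]
    assert vq.fold_change(a, a).ratio == 1.0
    assert vq.fold_change([2 * x for x in a], a).ratio == pytest.approx(2.0)
    fc1 = vq.fold_change(a, [4.0, 5.0])
    fc5 = vq.fold_change([5 * x for x in a], [4.0, 5.0])
    assert fc5.ratio == pytest.approx(5 * fc1.ratio)


def test_fold_change_ci_brackets_ratio():
    rng = np.random.default_rng(0)
    a = rng.normal(10, 1, 30)
    b = rng.normal(5, 1, 30)
    fc = vq.fold_change(a, b, seed=1)
    assert fc.ci_low < fc.ratio < fc.ci_high
    assert fc.ratio == pytest.approx(2.0, rel=0.15)


def test_fold_change_errors():
    with pytest.raises(ValueError):
        vq.fold_change([], [1.0])
    with pytest.raises(ValueError):
        vq.fold_change([1.0], [0.0])


# ---------------------------------------------------------------------------
# Fisher's LSD


def test_lsd_hand_example():
    gc = vq.fishers_lsd({"A": [1, 2, 3], "B": [2, 3, 4], "C": [3, 4, 5]})
    assert gc.ms_within == pytest.approx(1.0)
    assert gc.df_within == 6
    ac = gc.pairwise.query("group_a == 'A' and group_b == 'C'").iloc[0]
    assert abs(ac["t"]) == pytest.approx(2.449, abs=0.001)
    assert ac["p"] == pytest.approx(0.050, abs=0.001)


def test_lsd_degenerate_groups_error():
    with pytest.raises(ValueError, match="degenerate"):
        vq.fishers_lsd({"A": [2, 2, 2], "B": [2, 2, 2]})


def test_lsd_location_invariance():
    groups = {"A": [1.0, 2.5, 3.0], "B": [2.0, 4.0, 4.5], "C": [0.5, 1.0, 3.5]}
    shifted = {g: [x + 11.3 for x in v] for g, v in groups.items()}
    p1 = vq.fishers_lsd(groups).pairwise["p"].to_numpy()
    p2 = vq.fishers_lsd(shifted).pairwise["p"].to_numpy()
    assert np.allclose(p1, p2)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(2, 10), st.integers(2, 10), st.integers(0, 10_000))
def test_lsd_two_groups_equals_pooled_t(n1, n2, seed):
    """For k=2 the LSD pairwise p equals the pooled-variance two-sample
    t-test (independent oracle: scipy.stats.ttest_ind)."""
    rng = np.random.default_rng(seed)
    a, b = rng.normal(0, 1, n1), rng.normal(0.5, 1.3, n2)
    if np.std(np.concatenate([a, b])) == 0:
        return
    gc = vq.fishers_lsd({"A": a, "B": b})
    ref = sps.ttest_ind(a, b, equal_var=True)
    row = gc.pairwise.iloc[0]
    assert row["t"] == pytest.approx(ref.statistic, rel=1e-9)
    assert row["p"] == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney


def _exact_mw_p(x, y):
    """Brute-force two-sided p by full enumeration of label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(range(n))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n)]
    mu = len(x) * len(y) / 2.0
    extreme = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us)
    return extreme / len(us)


def test_mw_enumeration_example():
    u, p = vq.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)
    assert _exact_mw_p(np.array([1., 2, 3]), np.array([4., 5, 6])) == pytest.approx(0.1)


def test_mw_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = rng.permutation(20)[:4].astype(float)
        y = rng.permutation(40)[:4].astype(float) + 100 * rng.random()
        if np.unique(np.concatenate([x, y])).size < 8:
            continue
        _, p = vq.mann_whitney_u(x, y)
        assert p == pytest.approx(_exact_mw_p(x, y), abs=1e-9)


def test_mw_identical_samples_p_one():
    _, p = vq.mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
    assert p == pytest.approx(1.0)


def test_mw_u_statistics_sum():
    rng = np.random.default_rng(9)
    x, y = rng.normal(size=12), rng.normal(size=7)
    ux, _ = vq.mann_whitney_u(x, y)
    uy, _ = vq.mann_whitney_u(y, x)
    assert ux + uy == pytest.approx(len(x) * len(y))


def test_mw_asymptotic_close_to_exact():
    """The continuity-corrected normal approximation tracks the exact null:
    at n=8+8 its worst-case two-sided deviation, enumerated over all U
    values, is 0.0109 (at central U); random instances must stay within it."""
    rng = np.random.default_rng(17)
    diffs = []
    for _ in range(100):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.3, 1, 8)
        _, p_exact = vq.mann_whitney_u(x, y, mode="exact")
        _, p_asym = vq.mann_whitney_u(x, y, mode="asymptotic")
        diffs.append(abs(p_exact - p_asym))
    assert max(diffs) <= 0.011


# ---------------------------------------------------------------------------
# TEM summaries


def test_summary_median_iqr_hand_values():
    table = pd.DataFrame({
        "genotype": ["g"] * 5, "animal": ["a"] * 5, "capillary": range(5),
        "class": ["luminal"] * 5, "count": [1, 2, 3, 4, 5],
    })
    summary, _ = vq.summarize_counts(table)
    row = summary.iloc[0]
    assert row["median"] == 3
    assert row["q25"] == 2
    assert row["q75"] == 4


def test_summary_missing_class_warns():
    table = pd.DataFrame({
        "genotype": ["a"] * 3 + ["b"] * 3,
        "animal": ["x"] * 6, "capillary": list(range(3)) * 2,
        "class": ["luminal"] * 3 + ["abluminal"] * 3,
        "count": [1, 2, 3, 4, 5, 6],
    })
    with pytest.warns(UserWarning, match="missing"):
        _, tests = vq.summarize_counts(table)
    assert tests.empty
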