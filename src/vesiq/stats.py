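"""Per-vessel metrics, cohort aggregation and group statistics.

The three per-vessel metrics mirror the study's readouts: cargo intensity
per μm² of basal lamina, cargo intensity per μm³ of parenchyma, and puncta
per μm³ of (filled) vessel volume. Group comparisons use Fisher's LSD
(one-way ANOVA followed by uncorrected pooled-variance pairwise t-tests) for
the imaging metrics and Mann-Whitney U tests for the TEM vesicle counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Compartment, CompartmentGeometry, CompartmentMask, ImageStack, SpotSet, VesselQuantification
from .segmentation import measure_geometry


def estimate_background(stack: ImageStack, channel: str, mask: CompartmentMask,
                        method: str = "interior-median",
                        exclude_spots: SpotSet | None = None) -> float:
    """Per-stack background level of one channel, in counts per voxel.

    ``interior-median`` (default) takes the median over the INTERIOR *core*
    (voxels at least ``core_margin_um`` from any other compartment): the
    vessel interior carries no diffuse cargo, puncta occupy a negligible
    voxel fraction there, and staying clear of the wall avoids PSF spill from
    the basal lamina. ``mode`` uses the most frequent integer value of the
    whole channel — note that a whole-stack mode tracks the dominant
    compartment (usually parenchyma) and will absorb any diffuse signal
    there.
    """
    img = stack.channel(channel)
    if method == "interior-median":
        core = _interior_core(mask, core_margin_um=0.8)
        if exclude_spots is not None and len(exclude_spots):
            core = core & ~_spot_neighbourhoods(exclude_spots, mask)
        values = img[core]
        if values.size < 100:  # too little lumen to be robust
            values = img[mask.labels == int(Compartment.INTERIOR)]
        if values.size == 0:
            warnings.warn("empty INTERIOR; falling back to whole-stack mode background",
                          stacklevel=2)
            return _mode_background(img)
        return float(np.median(values))
    if method == "mode":
        return _mode_background(img)
    if method == "none":
        return 0.0
    raise ValueError(f"unknown background method {method!r}")


def _interior_core(mask: CompartmentMask, core_margin_um: float) -> np.ndarray:
    """INTERIOR voxels at least ``core_margin_um`` from any other label."""
    from scipy import ndimage as ndi

    interior = mask.labels == int(Compartment.INTERIOR)
    if not interior.any():
        return interior
    # crop to the interior bounding box for speed
    bbox = ndi.find_objects(interior.astype(np.uint8))[0]
    dist = ndi.distance_transform_edt(interior[bbox], sampling=mask.voxel_size_zyx)
    core = np.zeros_like(interior)
    core[bbox] = dist >= core_margin_um
    return core


def _spot_neighbourhoods(spots: SpotSet, mask: CompartmentMask,
                         radius_factor: float = 3.0, min_radius_um: float = 0.8) -> np.ndarray:
    """Voxels within ``max(radius_factor * r, min_radius_um)`` of any spot."""
    spacing = np.asarray(mask.voxel_size_zyx)
    shape = mask.labels.shape
    out = np.zeros(shape, dtype=bool)
    for c, r in zip(spots.centroids, spots.radii):
        rad = max(radius_factor * r, min_radius_um)
        lo = np.maximum(np.floor((c - rad) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + rad) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*[(np.arange(l, h) + 0.5) * d
                              for l, h, d in zip(lo, hi, spacing)], indexing="ij")
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        out[tuple(slice(l, h) for l, h in zip(lo, hi))] |= d2 <= rad ** 2
    return out


def _mode_background(img: np.ndarray) -> float:
    counts = np.bincount(np.asarray(img, dtype=np.int64).ravel())
    return float(np.argmax(counts))


def quantify_vessel(
    stack: ImageStack,
    mask: CompartmentMask,
    cargo_spots: SpotSet,
    geometry: CompartmentGeometry | None = None,
    cargo_channel: str = "cargo",
    background: float | str = "interior-median",
    vessel_volume: str = "filled",
    genotype: str = "",
    animal: str = "",
) -> VesselQuantification:
    """Compute the three normalized per-vessel metrics.

    Compartment intensities are background-subtracted sums of the cargo
    channel over that compartment's voxels (clamped at zero). ``background``
    is a constant, or an estimator name passed to
    :func:`estimate_background`. ``vessel_volume`` selects the denominator
    for puncta density: ``"filled"`` (INTERIOR + BASAL_LAMINA, the filled
    vessel — the default reading of "volume of the CollagenIV mask") or
    ``"shell-only"``.
    """
    geometry = geometry or measure_geometry(mask)
    if geometry.shell_surface_area_um2 <= 0:
        raise ValueError("zero shell surface area")
    par_vol = geometry.volume_um3[Compartment.PARENCHYMA]
    if par_vol <= 0:
        raise ValueError("zero parenchyma volume")
    if vessel_volume not in ("filled", "shell-only"):
        raise ValueError("vessel_volume must be 'filled' or 'shell-only'")

    bg = background if isinstance(background, (int, float)) \
        else estimate_background(stack, cargo_channel, mask, method=background,
                                 exclude_spots=cargo_spots)
    img = stack.channel(cargo_channel).astype(np.float64)

    def compartment_sum(comp: Compartment) -> float:
        sel = mask.labels == int(comp)
        return float(max(img[sel].sum() - bg * sel.sum(), 0.0))

    bl_sum = compartment_sum(Compartment.BASAL_LAMINA)
    par_sum = compartment_sum(Compartment.PARENCHYMA)
    n_interior_spots = len(cargo_spots.in_compartment(Compartment.INTERIOR))
    denom = geometry.volume_um3[Compartment.INTERIOR] + geometry.volume_um3[Compartment.BASAL_LAMINA] \
        if vessel_volume == "filled" else geometry.volume_um3[Compartment.BASAL_LAMINA]
    if denom <= 0:
        raise ValueError("zero vessel volume")

    return VesselQuantification(
        stack_id=stack.stack_id,
        genotype=genotype,
        animal=animal,
        bl_intensity_per_um2=bl_sum / geometry.shell_surface_area_um2,
        parenchyma_intensity_per_um3=par_sum / par_vol,
        vesicles_per_um3=n_interior_spots / denom,
        background=float(bg),
    )


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class FoldChange:
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def fold_change(a, b, n_boot: int = 2000, seed: int = 0, ci: float = 0.95) -> FoldChange:
    """Ratio of group means, mean(a)/mean(b), with a bootstrap percentile CI."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if b.mean() <= 0:
        raise ValueError("mean of the reference group must be positive")
    ratio = float(a.mean() / b.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)].mean()
        rb = b[rng.integers(0, b.size, b.size)].mean()
        boots[k] = ra / rb if rb > 0 else np.nan
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return FoldChange(ratio=ratio, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


@dataclass
class GroupComparison:
    """One-way ANOVA plus uncorrected pairwise LSD t-tests."""

    metric: str
    group_stats: pd.DataFrame  # group, n, mean, sd
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, t, p


def fishers_lsd(groups: dict, metric: str = "") -> GroupComparison:
    """Fisher's least-significant-difference procedure.

    One-way ANOVA pooled error, then for every pair
    ``t = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j))`` on ``N - k`` degrees of
    freedom, two-sided, with no multiplicity adjustment (that is the LSD).
    """
    names = list(groups)
    arrays = [np.asarray(list(groups[g]), dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    n_tot = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_tot - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        raise ValueError("degenerate groups (zero pooled variance)")
    ms_b = ss_between / df_b
    f_stat = ms_b / ms_w
    anova_p = float(sps.f.sf(f_stat, df_b, df_w))

    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(names), 2):
        diff = arrays[i].mean() - arrays[j].mean()
        se = np.sqrt(ms_w * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_w))
        rows.append({"group_a": gi, "group_b": gj, "diff": float(diff),
                     "t": float(t), "p": p})
    stats_df = pd.DataFrame({
        "group": names,
        "n": [a.size for a in arrays],
        "mean": [float(a.mean()) for a in arrays],
        "sd": [float(a.std(ddof=1)) for a in arrays],
    })
    return GroupComparison(
        metric=metric, group_stats=stats_df,
        ss_between=ss_between, ss_within=ss_within,
        df_between=df_b, df_within=df_w,
        ms_between=float(ms_b), ms_within=float(ms_w),
        f_statistic=float(f_stat), anova_p=anova_p,
        pairwise=pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "t", "p"]),
    )


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (statistic for x) with a two-sided p-value.

    ``auto`` uses the exact null distribution when the pooled sample is
    small (n_x + n_y <= 16) and tie-free, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarize_counts(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/IQR per genotype × vesicle class, plus pairwise Mann-Whitney p.

    Quartiles use linear interpolation. Classes missing in one genotype of a
    pair are skipped with a warning.
    """
    required = {"genotype", "class", "count"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    summary = (
        table.groupby(["genotype", "class"], sort=True)["count"]
        .agg(n="size", median="median",
             q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    genotypes = sorted(table["genotype"].unique())
    rows = []
    for ga, gb in itertools.combinations(genotypes, 2):
        for cls in sorted(table["class"].unique()):
            xa = table.query("genotype == @ga and `class` == @cls")["count"]
            xb = table.query("genotype == @gb and `class` == @cls")["count"]
            if xa.empty or xb.empty:
                warnings.warn(f"class {cls!r} missing in one of ({ga}, {gb}); skipped",
                              stacklevel=2)
                continue
            u, p = mann_whitney_u(xa, xb)
            rows.append({"class": cls, "group_a": ga, "group_b": gb, "U": u, "p": p})
    tests = pd.DataFrame(rows, columns=["class", "group_a", "group_b", "U", "p"])
    return summary, tests
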