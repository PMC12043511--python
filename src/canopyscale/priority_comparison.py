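"""Sampling-priority maps from prediction uncertainty, and region comparisons.

The sampling-needs map min-max standardizes each trait's standard-error map
to [0, 1] over unmasked pixels, averages the standardized maps pixelwise,
and classifies the result into terciles (low / intermediate / high future
sampling priority) at the 33.33% and 66.67% quantiles. Ties are broken by
stable rank so class sizes stay within one pixel of n/3.

Region comparisons are Welch two-sample t-tests of pixel-level trait values
between region pairs, run on the full data and on seeded 10% and 1%
subsamples (a sensitivity check against significance driven purely by pixel
count), with Bonferroni correction over all pair x trait tests per fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

CLASS_NAMES = ("low", "intermediate", "high")


@dataclass
class SamplingNeedsMap:
    mean_standardized_se: np.ndarray  # in [0, 1]; NaN where masked
    classes: np.ndarray               # int: 0 low, 1 intermediate, 2 high; -1 masked
    cutpoints: tuple[float, float]    # 33.33% and 66.67% quantiles
    traits_used: list[str]
    traits_skipped: list[str]


def sampling_needs(se_maps: dict[str, np.ndarray]) -> SamplingNeedsMap:
    """Build the field-sampling-priority map from per-trait s.e. maps.

    Each s.e. map is min-max standardized over its unmasked pixels; a
    constant map (zero range) is skipped with a warning. Classes are
    rank-based terciles of the pixelwise mean standardized s.e.
    """
    import warnings

    if not se_maps:
        raise ValueError("need at least one s.e. map")
    shapes = {m.shape for m in se_maps.values()}
    if len(shapes) > 1:
        raise ValueError("s.e. maps are not co-registered")
    used, skipped, std_layers = [], [], []
    for trait, layer in se_maps.items():
        layer = np.asarray(layer, dtype=float)
        finite = np.isfinite(layer)
        if not finite.any():
            skipped.append(trait)
            continue
        lo, hi = np.nanmin(layer), np.nanmax(layer)
        if hi - lo <= 0:
            warnings.warn(f"constant s.e. map for {trait!r}; skipped", stacklevel=2)
            skipped.append(trait)
            continue
        std_layers.append((layer - lo) / (hi - lo))
        used.append(trait)
    if not std_layers:
        raise ValueError("all s.e. maps are constant or empty")
    stacked = np.stack(std_layers)
    any_finite = np.isfinite(stacked).any(axis=0)
    mean_layer = np.full(stacked.shape[1:], np.nan)
    mean_layer[any_finite] = np.nanmean(stacked[:, any_finite], axis=0)

    classes = np.full(mean_layer.shape, -1, dtype=int)
    finite = np.isfinite(mean_layer)
    vals = mean_layer[finite]
    n = len(vals)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    k1, k2 = int(round(n / 3)), int(round(2 * n / 3))
    cls = np.where(ranks < k1, 0, np.where(ranks < k2, 1, 2))
    classes[finite] = cls
    cutpoints = (float(np.quantile(vals, 1 / 3)), float(np.quantile(vals, 2 / 3)))
    return SamplingNeedsMap(
        mean_standardized_se=np.where(finite, mean_layer, np.nan),
        classes=classes,
        cutpoints=cutpoints,
        traits_used=used,
        traits_skipped=skipped,
    )


@dataclass
class ComparisonResult:
    trait: str
    region_a: str
    region_b: str
    fraction: float
    mean_a: float
    mean_b: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int


def region_compare(
    trait_maps: dict[str, np.ndarray],
    region_masks: dict[str, np.ndarray],
    fractions: tuple[float, ...] = (1.0, 0.1, 0.01),
    seed: int = 0,
) -> list[ComparisonResult]:
    """Welch t-tests of trait values between all region pairs.

    Per fraction, every region's pixel values are subsampled (seeded) and all
    region pairs compared for every trait; p-values are Bonferroni-adjusted
    over the m = n_pairs * n_traits tests of that fraction.
    """
    regions = list(region_masks)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    for a, b in combinations(regions, 2):
        if np.any(region_masks[a] & region_masks[b]):
            raise ValueError(f"regions {a!r} and {b!r} overlap")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(regions, 2))
    results: list[ComparisonResult] = []
    for fraction in fractions:
        m = len(pairs) * len(trait_maps)
        for trait, layer in trait_maps.items():
            layer = np.asarray(layer, dtype=float)
            samples = {}
            for r in regions:
                vals = layer[region_masks[r]]
                vals = vals[np.isfinite(vals)]
                if fraction < 1.0:
                    k = max(2, int(round(fraction * len(vals))))
                    if k > len(vals):
                        raise ValueError(f"region {r!r} too small for fraction {fraction}")
                    vals = vals[rng.choice(len(vals), size=k, replace=False)]
                if len(vals) < 2:
                    raise ValueError(f"region {r!r} has fewer than 2 pixels")
                samples[r] = vals
            for a, b in pairs:
                t, p = stats.ttest_ind(samples[a], samples[b], equal_var=False)
                results.append(
                    ComparisonResult(
                        trait=trait, region_a=a, region_b=b, fraction=fraction,
                        mean_a=float(samples[a].mean()), mean_b=float(samples[b].mean()),
                        t_statistic=float(t), p_raw=float(p),
                        p_adjusted=float(min(1.0, m * p)), n_comparisons=m,
                    )
                )
    return results


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def percent_difference(a: float, b: float) -> dict[str, float]:
    """Percent difference of a relative to b: 100 (a - b) / b.

    Returns the full-precision value, its nearest-integer rounding, and the
    alternative convention relative to a (the baseline choice is ambiguous in
    informal reporting, so both are printed).
    """
    if b <= 0:
        raise ValueError("baseline b must be positive")
    rel_b = 100.0 * (a - b) / b
    rel_a = 100.0 * (a - b) / a if a > 0 else float("nan")
    return {
        "percent_vs_b": rel_b,
        "percent_vs_b_rounded": float(round(rel_b)),
        "percent_vs_a": rel_a,
    }
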