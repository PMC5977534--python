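"""Sequencing-depth requirement estimation from gene-detection saturation.

The workflow: binomially thin each library's counts down a depth ladder,
record (exonic reads, detected genes) points, fit one shared monotone
saturating curve through all points, and invert it at a detected-gene
target. Dividing the required exonic reads by a group's exonic read
fraction converts to required *total* reads, which is where library
chemistry (poly(A) capture vs ribosomal depletion) enters: a protocol with
a small exonic fraction needs proportionally more total depth for the
same number of quantified genes.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .expression import detected_genes
from .models import CountMatrix, DepthRequirement, SaturationCurve

DEFAULT_LADDER = (0.05, 0.1, 0.2, 0.4, 0.7, 1.0)


def subsample_counts(counts_column, fraction: float, rng=None) -> np.ndarray:
    """Binomial thinning: each gene's count -> Binomial(count, fraction)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    counts = np.asarray(counts_column)
    if fraction == 1.0:
        return counts.copy()
    if fraction == 0.0:
        return np.zeros_like(counts)
    rng = np.random.default_rng(rng)
    return rng.binomial(counts, fraction)


def saturation_points(
    counts: CountMatrix,
    ladder: Sequence[float] = DEFAULT_LADDER,
    n_seeds: int = 3,
    min_reads: int = 1,
    seed: int = 0,
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Depth ladder of (exonic_reads, genes_detected) points per sample."""
    rows = []
    samples = list(sample_ids) if sample_ids is not None else list(counts.sample_ids)
    for si, sample_id in enumerate(samples):
        column = counts.column(sample_id).to_numpy()
        for fi, fraction in enumerate(ladder):
            for rep in range(n_seeds):
                rng = np.random.default_rng([seed, si, fi, rep])
                thinned = subsample_counts(column, fraction, rng)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "fraction": fraction,
                        "replicate": rep,
                        "exonic_reads": int(thinned.sum()),
                        "genes_detected": detected_genes(thinned, min_reads=min_reads),
                    }
                )
    return pd.DataFrame(rows)


def _hyperbola(r, g_max, k):
    return g_max * r / (r + k)


def fit_saturation(points: pd.DataFrame, form: str = "hyperbola") -> SaturationCurve:
    """Fit the shared detected-genes vs exonic-reads curve.

    ``form='hyperbola'`` fits G(r) = G_max r / (r + K) by constrained least
    squares (two parameters, saturating, closed-form inverse);
    ``form='monotone_interpolant'`` builds a shape-preserving cubic through
    depth-averaged points (ties in exonic reads averaged), anchored at (0, 0).
    """
    r = points["exonic_reads"].to_numpy(dtype=float)
    g = points["genes_detected"].to_numpy(dtype=float)
    if np.unique(r).size < 3:
        raise ValueError("need at least 3 distinct exonic-read depths")
    if form == "hyperbola":
        g_max0 = max(g.max() * 1.05, 1.0)
        half = g_max0 / 2
        k0 = float(np.interp(half, np.sort(g), np.sort(r))) or max(r.mean(), 1.0)
        try:
            params, _ = curve_fit(
                _hyperbola,
                r,
                g,
                p0=[g_max0, k0],
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20_000,
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"saturation fit did not converge on {len(r)} points "
                f"(reads range {r.min():.3g}-{r.max():.3g}): {err}"
            )
        g_max, k = map(float, params)
        rmse = float(np.sqrt(np.mean((_hyperbola(r, g_max, k) - g) ** 2)))
        return SaturationCurve(
            form="hyperbola", g_max=g_max, k=k, rmse=rmse,
            points=points.copy(), max_observed_reads=float(r.max()),
        )
    if form == "monotone_interpolant":
        means = (
            pd.DataFrame({"r": r, "g": g}).groupby("r", as_index=False)["g"].mean()
        )
        xs = means["r"].to_numpy()
        ys = means["g"].to_numpy()
        if xs[0] > 0:
            xs = np.concatenate([[0.0], xs])
            ys = np.concatenate([[0.0], ys])
        ys = np.maximum.accumulate(ys)  # enforce monotone means
        interp = PchipInterpolator(xs, ys, extrapolate=False)
        fitted = np.clip(np.nan_to_num(interp(r)), 0, None)
        rmse = float(np.sqrt(np.mean((fitted - g) ** 2)))
        return SaturationCurve(
            form="monotone_interpolant", interpolant=interp, rmse=rmse,
            points=points.copy(), max_observed_reads=float(r.max()),
        )
    raise ValueError(f"unknown curve form {form!r}")


def estimate_exonic_fraction(
    mapping_stats: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    **group,
) -> float:
    """Mean exonic read fraction over a sample group.

    ``group`` filters the sample sheet by equality (e.g. tissue='FFPE',
    protocol='polyA'); with no filter all samples in ``mapping_stats`` are
    averaged.
    """
    if meta is not None and group:
        mask = pd.Series(True, index=meta.index)
        for key, value in group.items():
            mask &= meta[key] == value
        ids = meta.loc[mask, "sample_id"]
        if ids.empty:
            raise ValueError(f"no samples match {group}")
        stats = mapping_stats.loc[ids]
    else:
        stats = mapping_stats
    if stats.empty:
        raise ValueError("empty sample group")
    return float(stats["exon"].mean())


def required_total_reads(
    curve: SaturationCurve,
    exonic_fraction: float,
    target_genes: int = 11_000,
    group: str = "",
) -> DepthRequirement:
    """Invert the saturation curve at a detection target and scale by exonic fraction."""
    if exonic_fraction <= 0:
        raise ValueError("exonic_fraction must be positive")
    required_exonic = curve.invert(target_genes)
    return DepthRequirement(
        group=group,
        target_genes=int(target_genes),
        exonic_fraction=float(exonic_fraction),
        required_exonic_reads=float(required_exonic),
    )
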