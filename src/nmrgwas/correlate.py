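"""Annotation of chemical shifts and ratios via Spearman correlation
spectra against independently measured metabolite concentrations.

Because a plasma 1H spectrum is a superposition of many metabolites, a
genetically associated bin is identified by correlating its intensity
across subjects with metabolite concentrations measured by MS or clinical
chemistry on the same samples: the best-correlating metabolite (or, for
ratio traits, metabolite ratio) annotates the position.  Spearman's rank
correlation is used throughout, so the annotation is invariant to any
monotone transform of either readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BinnedSpectraMatrix
from .synth import MetaboliteSet

__all__ = [
    "CleanResult",
    "clean_metabolite",
    "correlation_spectrum",
    "best_correlates",
    "spearman_pairwise",
]

@dataclass
class CleanResult:
    values: np.ndarray | None
    n_nonmissing: int
    excluded: bool
    reason: str = ""


def clean_metabolite(
    values: np.ndarray, k: float = 3.0, min_n: int = 300
) -> CleanResult:
    """Apply the 3-SD outlier rule and the minimum-sample-size filter.

    Values more than ``k`` standard deviations from the mean are set
    missing (mean/SD from the pre-filter values); if fewer than ``min_n``
    non-missing values remain the metabolite is excluded with a reason.
    A constant metabolite is excluded as uninformative.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    v = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(v)
    if finite.sum() < min_n:
        return CleanResult(None, int(finite.sum()), True,
                           f"fewer than {min_n} non-missing values")
    mean = v[finite].mean()
    sd = v[finite].std(ddof=0)
    if sd == 0:
        return CleanResult(None, int(finite.sum()), True, "constant values")
    out = finite & (np.abs(v - mean) > k * sd)
    v[out] = np.nan
    n = int(np.isfinite(v).sum())
    if n < min_n:
        return CleanResult(None, n, True,
                           f"fewer than {min_n} non-missing values after outlier removal")
    return CleanResult(v, n, False)


def spearman_pairwise(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Spearman rho on pairwise-complete observations; returns (rho, n)."""
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, n
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho), n


def correlation_spectrum(
    metabolite: np.ndarray,
    binned: BinnedSpectraMatrix,
    min_n: int = 300,
    name: str = "metabolite",
) -> pd.DataFrame:
    """Per-bin Spearman correlation of a cleaned metabolite with intensities.

    Bins with fewer than ``min_n`` pairwise-complete observations, and
    excluded (water-masked) bins, are absent from the output.  Columns:
    ppm, rho, r2, n.
    """
    v = np.asarray(metabolite, dtype=float)
    if np.isfinite(v).sum() == 0 or np.nanstd(v) == 0:
        raise ValueError(f"{name}: constant or empty metabolite vector")
    rows = []
    active = binned.active_mask()
    for j in np.flatnonzero(active):
        rho, n = spearman_pairwise(v, binned.values[:, j])
        if n < min_n or not np.isfinite(rho):
            continue
        rows.append((float(binned.labels[j]), rho, rho * rho, n))
    return pd.DataFrame(rows, columns=["ppm", "rho", "r2", "n"]).assign(metabolite=name)


def _position_trait(binned: BinnedSpectraMatrix, position) -> tuple[str, np.ndarray]:
    if isinstance(position, (tuple, list)):
        num, den = position
        label = f"{float(num):.3f}/{float(den):.3f}"
        return label, binned.column(float(num)) - binned.column(float(den))
    return f"{float(position):.3f}", binned.column(float(position))


def best_correlates(
    metabolites: MetaboliteSet,
    positions: list,
    binned: BinnedSpectraMatrix,
    r2_min: float = 0.20,
    min_n: int = 300,
    k: float = 3.0,
    max_ratio_pairs: int = 10_000,
) -> pd.DataFrame:
    """Best-correlating metabolite (or metabolite ratio) per queried position.

    Positions are single ppm labels or (numerator, denominator) ppm pairs.
    Single-bin positions are annotated by the metabolite with maximal
    squared Spearman correlation at that bin.  Ratio positions compete the
    single metabolites against pairwise metabolite quotients of the
    cleaned panel (capped at ``max_ratio_pairs`` pairs, deterministic
    order).  A position where nothing reaches ``r2_min`` is reported as
    'unassigned'.  Columns: position, annotation, r2, sign, n.
    """
    cleaned: list[tuple[str, np.ndarray]] = []
    for i, name in enumerate(metabolites.names):
        res = clean_metabolite(metabolites.values[:, i], k=k, min_n=min_n)
        if not res.excluded:
            cleaned.append((name, res.values))

    def candidates(include_ratios: bool):
        for name, v in cleaned:
            yield name, v
        if include_ratios:
            n_pairs = 0
            for a in range(len(cleaned)):
                for b in range(a + 1, len(cleaned)):
                    if n_pairs >= max_ratio_pairs:
                        return
                    na, va = cleaned[a]
                    nb, vb = cleaned[b]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        q = np.where(vb != 0, va / vb, np.nan)
                    yield f"{na}/{nb}", q
                    n_pairs += 1

    rows = []
    for position in positions:
        is_ratio = isinstance(position, (tuple, list))
        label, trait = _position_trait(binned, position)
        best = ("unassigned", 0.0, "", 0)
        for name, v in candidates(is_ratio):
            rho, n = spearman_pairwise(trait, v)
            if n < min_n or not np.isfinite(rho):
                continue
            r2 = rho * rho
            if r2 >= r2_min and r2 > best[1]:
                best = (name, r2, "+" if rho >= 0 else "-", n)
        rows.append(dict(position=label, annotation=best[0], r2=best[1],
                         sign=best[2], n=best[3]))
    return pd.DataFrame(rows, columns=["position", "annotation", "r2", "sign", "n"])
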