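"""Stage-1 to stage-2 bridge: association pseudo-spectrum and bin selection.

A pseudo-spectrum plots chemical shift against strength of association
(-log10 of the best P over all SNPs).  Because a genuine signal spans
several adjacent bins that all associate with the same lead SNP, maximal
runs of adjacent same-lead-SNP bins are collapsed to their single
lowest-P bin before the top-k strongest positions are taken forward to
the pairwise ratio scan.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "build_pseudo_spectrum",
    "pick_representatives",
    "select_top_k",
]


def build_pseudo_spectrum(stage1: pd.DataFrame, snp: str | None = None) -> pd.DataFrame:
    """Per-bin minimum P over all SNPs and the lead SNP attaining it.

    ``stage1`` is the tidy scan table (columns TRAIT, SNP, P, POS,
    TESTABLE).  Bins with no testable result are dropped with a warning.
    Returns a DataFrame with columns ppm, best_p, lead_snp, strength,
    sorted by ppm.  Ties on P break deterministically by SNP position
    then SNP id.

    By default the strength is the min-P envelope over all SNPs; passing
    ``snp`` restricts to a single SNP's associations (the per-SNP
    pseudo-spectrum used for locus plots).
    """
    if snp is not None:
        stage1 = stage1[stage1["SNP"] == snp]
    ok = stage1[stage1["TESTABLE"] & np.isfinite(stage1["P"])]
    n_dropped = stage1["TRAIT"].nunique() - ok["TRAIT"].nunique()
    if n_dropped > 0:
        warnings.warn(f"{n_dropped} bin(s) had no testable association; dropped")
    if ok.empty:
        return pd.DataFrame(columns=["ppm", "best_p", "lead_snp", "strength"])
    ordered = ok.sort_values(["TRAIT", "P", "POS", "SNP"], kind="mergesort")
    best = ordered.groupby("TRAIT", sort=False).first().reset_index()
    out = pd.DataFrame({
        "ppm": best["TRAIT"].astype(float),
        "best_p": best["P"].astype(float),
        "lead_snp": best["SNP"],
    })
    out["strength"] = -np.log10(out["best_p"])
    return out.sort_values("ppm", kind="mergesort").reset_index(drop=True)


def pick_representatives(pseudo: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Collapse maximal runs of adjacent bins sharing a lead SNP.

    Bins are adjacent when their ppm labels differ by one bin width
    (within half a width of tolerance); each run keeps only the bin with
    the lowest P, ties broken toward lower ppm.  Idempotent.
    """
    if pseudo.empty:
        return pseudo.copy()
    df = pseudo.sort_values("ppm", kind="mergesort").reset_index(drop=True)
    ppm = df["ppm"].to_numpy()
    lead = df["lead_snp"].to_numpy()
    new_run = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        gap = np.diff(ppm)
        same = lead[1:] == lead[:-1]
        adjacent = gap <= bin_width * 1.5
        new_run[1:] = ~(same & adjacent)
    run_id = np.cumsum(new_run)
    df = df.assign(_run=run_id)
    # stable sort => the first row per run has lowest P, then lowest ppm
    keep = (df.sort_values(["_run", "best_p", "ppm"], kind="mergesort")
              .groupby("_run", sort=False).head(1))
    return (keep.drop(columns="_run")
                .sort_values("ppm", kind="mergesort")
                .reset_index(drop=True))


def select_top_k(pseudo: pd.DataFrame, k: int) -> list[float]:
    """The k strongest representatives, ordered by decreasing strength.

    Ties break by lower P then lower ppm; if fewer than k bins remain,
    all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pseudo) < k:
        warnings.warn(f"only {len(pseudo)} bins available; requested k={k}")
    ranked = pseudo.sort_values(["best_p", "ppm"], kind="mergesort")
    return [float(x) for x in ranked["ppm"].head(k)]
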