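"""Stage-2 GWAS on pairwise intensity ratios, p-gain scoring and the
Bonferroni threshold.

On the log10 scale a ratio between the intensities at two chemical shifts
is the difference of the two stored log-bin values, so ratio traits are
formed directly from the cleaned binned matrix with no second outlier
pass.  The p-gain of a ratio association is min(P_numerator,
P_denominator) / P_ratio — how much the ratio strengthens the best
single-shift association for the same SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc
from .preprocess import BinnedSpectraMatrix
from .synth import GenotypeSet

__all__ = [
    "enumerate_pairs",
    "make_ratio_trait",
    "ratio_label",
    "compute_pgain",
    "bonferroni_threshold",
    "run_stage2",
]


def enumerate_pairs(selected: list[float]) -> list[tuple[float, float]]:
    """All k(k-1)/2 unordered pairs, canonically ordered higher-ppm first.

    The sequence is deterministic: ascending in the lower member, then in
    the higher member.
    """
    labels = [float(x) for x in selected]
    if len(set(labels)) != len(labels):
        raise ValueError("selected ppm labels must be unique")
    ordered = sorted(labels)
    return [(ordered[j], ordered[i])
            for i in range(len(ordered))
            for j in range(i + 1, len(ordered))]


def ratio_label(pair: tuple[float, float]) -> str:
    return f"{pair[0]:.3f}/{pair[1]:.3f}"


def make_ratio_trait(
    binned: BinnedSpectraMatrix, pair: tuple[float, float]
) -> np.ndarray:
    """Per-subject log10 intensity ratio: numerator bin minus denominator bin.

    Missing in either constituent propagates; requesting an excluded
    (e.g. water-masked) bin is an error.
    """
    if not binned.log_transformed:
        raise ValueError("ratio traits are defined on the log-transformed matrix")
    num, den = pair
    labels = binned.labels
    for x in (num, den):
        idx = np.flatnonzero(np.isclose(labels, x, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"no bin labelled {x}")
        if binned.excluded[idx[0]]:
            raise ValueError(f"bin {x} is excluded from analysis")
    return binned.column(num) - binned.column(den)


def compute_pgain(p_num: float, p_den: float, p_ratio: float) -> float:
    """p-gain = min(P_num, P_den) / P_ratio."""
    for name, p in (("p_num", p_num), ("p_den", p_den), ("p_ratio", p_ratio)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return min(p_num, p_den) / p_ratio


def bonferroni_threshold(n_snps: int, n_traits: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_snps * n_traits)."""
    if n_snps < 1 or n_traits < 1:
        raise ValueError("test counts must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_snps * n_traits)


def run_stage2(
    binned: BinnedSpectraMatrix,
    genotypes: GenotypeSet,
    selected: list[float],
    covariates: pd.DataFrame,
    stage1: pd.DataFrame,
    alpha: float = 0.05,
    maf_floor: float = 0.10,
    n_single_traits: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scan all pairwise ratios among the selected bins against all SNPs.

    The Bonferroni trait count is (number of pairs) + (number of single-bin
    traits tested in stage 1), so the threshold covers both GWAS stages.
    Every QC-passed SNP is tested; the MAF floor (>10% by default) is a
    reporting filter entering only the significance flag.  Constituent
    single-bin P values for the p-gain are looked up from the stage-1
    table for the same SNP and computed on the fly when absent.

    Returns (hits table sorted by P, summary dict).
    """
    pairs = enumerate_pairs(selected)
    labels = [ratio_label(p) for p in pairs]
    if n_single_traits is None:
        n_single_traits = int(stage1["TRAIT"].nunique())
    n_traits = len(pairs) + n_single_traits
    threshold = bonferroni_threshold(genotypes.n_snps, n_traits, alpha)

    traits = np.column_stack([make_ratio_trait(binned, p) for p in pairs]) \
        if pairs else np.empty((binned.values.shape[0], 0))
    hits = assoc.scan(traits, labels, genotypes, covariates)
    hits = hits.rename(columns={"TRAIT": "RATIO"})

    # stage-1 constituent P values, merged in by (SNP, single-bin label)
    pair_of = dict(zip(labels, pairs))
    hits["_NUM"] = [f"{pair_of[l][0]:.3f}" for l in hits["RATIO"]]
    hits["_DEN"] = [f"{pair_of[l][1]:.3f}" for l in hits["RATIO"]]
    s1 = stage1.loc[stage1["TESTABLE"], ["SNP", "TRAIT", "P"]]
    hits = hits.merge(s1.rename(columns={"TRAIT": "_NUM", "P": "P_NUM"}),
                      on=["SNP", "_NUM"], how="left")
    hits = hits.merge(s1.rename(columns={"TRAIT": "_DEN", "P": "P_DEN"}),
                      on=["SNP", "_DEN"], how="left")

    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    snp_col = {sid: j for j, sid in enumerate(genotypes.snps["id"])}

    def constituent_p(snp: str, label: str) -> float:
        res = assoc.fit_additive_model(
            binned.column(float(label)), genotypes.dosage[:, snp_col[snp]],
            age, sex, snp=snp, trait_id=label)
        return float(res.p) if res.testable else np.nan

    for col, lblcol in (("P_NUM", "_NUM"), ("P_DEN", "_DEN")):
        missing = hits.index[~np.isfinite(hits[col])]
        cache: dict[tuple[str, str], float] = {}
        for i in missing:
            key = (hits.at[i, "SNP"], hits.at[i, lblcol])
            if key not in cache:
                cache[key] = constituent_p(*key)
            hits.at[i, col] = cache[key]
    hits = hits.drop(columns=["_NUM", "_DEN"])
    p_num = hits["P_NUM"].to_numpy()
    p_den = hits["P_DEN"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        hits["PGAIN"] = np.minimum(p_num, p_den) / hits["P"]
    hits["SIGNIFICANT"] = (hits["TESTABLE"]
                           & (hits["P"] <= threshold)
                           & (hits["MAF"] > maf_floor))
    hits = hits.sort_values(["P", "RATIO", "SNP"], kind="mergesort").reset_index(drop=True)
    summary = {
        "n_snps": int(genotypes.n_snps),
        "n_pairs": len(pairs),
        "n_single_traits": int(n_single_traits),
        "n_traits": int(n_traits),
        "alpha": alpha,
        "threshold": threshold,
        "maf_floor": maf_floor,
        "n_tests": int(len(hits)),
        "n_significant": int(hits["SIGNIFICANT"].sum()),
    }
    return hits, summary
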