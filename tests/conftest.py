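"""Shared fixtures: scenario pipeline runs reused across test modules.

The heavy multi-seed pipeline runs are session-scoped and slimmed to the
fields the tests consult (top hits, selection, truth, summary), so that
twenty 1,000-subject cohorts never sit in memory at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from nmrgwas import assoc, pipeline, presets
from nmrgwas.preprocess import preprocess_spectra
from nmrgwas.ratios import make_ratio_trait
from nmrgwas.synth import TruthTable, simulate_cohort

N_SCENARIO_SEEDS = 20
PYROXD2_SEEDS = 10
PYROXD2_AMPLITUDES = (25.0, 50.0, 100.0)


@dataclass
class SlimRun:
    """The parts of a pipeline run the recovery tests actually consult."""

    seed: int
    selected: list
    hits: pd.DataFrame          # top rows only, sorted by P
    summary: dict
    truth: TruthTable
    annotations: pd.DataFrame | None
    stage1_min_p: float
    stage1_n_tests: int


def _slim_run(preset: str, seed: int, **kwargs) -> SlimRun:
    cfg = pipeline.RunConfig(preset=preset, seed=seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pipeline.run_pipeline(cfg)
    return SlimRun(
        seed=seed,
        selected=list(res.selected),
        hits=res.hits.head(50).copy(),
        summary=dict(res.summary),
        truth=res.cohort.truth,
        annotations=(None if res.annotations is None else res.annotations.copy()),
        stage1_min_p=float(res.stage1["P"].min()),
        stage1_n_tests=int(len(res.stage1)),
    )


@pytest.fixture(scope="session")
def fads1_runs():
    """20 seeds of the substrate-product scenario (no annotation stage)."""
    return [_slim_run("fads1", seed, annotate=False)
            for seed in range(N_SCENARIO_SEEDS)]


@pytest.fixture(scope="session")
def gckr_runs():
    """20 seeds of the pleiotropic cross-region scenario, with annotation."""
    return [_slim_run("gckr", seed, annotate=True, max_annotated_hits=1)
            for seed in range(N_SCENARIO_SEEDS)]


@pytest.fixture(scope="session")
def null_runs():
    """20 seeds of the no-effect cohort at the desk-scale study conditions."""
    return [_slim_run("null", seed, n_subjects=500, n_snps=200, annotate=False)
            for seed in range(N_SCENARIO_SEEDS)]


@pytest.fixture(scope="session")
def pyroxd2_margins():
    """-log10 P margin (ratio minus single bin) per shoulder amplitude.

    Computed by direct model fits at the planted positions: the shoulder
    scenario's claim concerns those two traits, not the full scan.
    """
    margins: dict[float, list[float]] = {}
    for amp in PYROXD2_AMPLITUDES:
        vals = []
        for seed in range(PYROXD2_SEEDS):
            cfg = presets.get_preset("pyroxd2", seed=seed, shoulder_amplitude=amp)
            cohort = simulate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                binned = preprocess_spectra(
                    cohort.grid, cohort.spectra,
                    subjects=cohort.genotypes.subjects,
                    width=presets.DESK_BIN_WIDTH)
            j = list(cohort.genotypes.snps["id"]).index("snp_pyroxd2")
            dosage = cohort.genotypes.dosage[:, j]
            age = cohort.covariates["age"].to_numpy()
            sex = cohort.covariates["sex"].to_numpy()
            single = assoc.fit_additive_model(binned.column(2.757), dosage, age, sex)
            ratio = assoc.fit_additive_model(
                make_ratio_trait(binned, (2.757, 2.754)), dosage, age, sex)
            vals.append(float(-np.log10(ratio.p) + np.log10(single.p)))
        margins[amp] = vals
    return margins


def region_tolerance(truth: TruthTable, center: float,
                     bin_width: float = presets.DESK_BIN_WIDTH) -> float:
    """Spatial tolerance for matching a planted resonance.

    The detectable support of a Lorentzian line extends well beyond its
    half-width, and the run-collapse step keeps the lowest-P bin of the
    associated run, which often sits on a flank rather than the apex.  A
    bin within ~6 half-widths (plus one bin of quantisation) still carries
    the planted metabolite's signal and counts as the planted position.
    """
    peaks = truth.peak_assignments
    dist = (peaks["center"] - center).abs()
    hw = float(peaks.loc[dist.idxmin(), "half_width"])
    return 6.0 * hw + bin_width


def top_hit_matches(run: SlimRun) -> bool:
    """Is the top ratio hit the planted pair (causal SNP, both bins inside
    the planted resonances' support)?"""
    expected = run.truth.expected_ratio_pair
    if expected is None or run.hits.empty:
        return False
    top = run.hits.iloc[0]
    causal = set(run.truth.effects["snp"])
    if top["SNP"] not in causal:
        return False
    num, den = (float(x) for x in top["RATIO"].split("/"))
    e_hi, e_lo = max(expected), min(expected)
    return (abs(max(num, den) - e_hi) <= region_tolerance(run.truth, e_hi)
            and abs(min(num, den) - e_lo) <= region_tolerance(run.truth, e_lo))
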