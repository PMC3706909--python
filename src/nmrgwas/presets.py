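"""Named scenario presets for the synthetic cohort generator.

Each preset plants one of the mechanistic situations in which a ratio
between two NMR intensities outperforms single-bin intensities:

``fads1``
    A substrate-product pair: one metabolite pair with resonances at
    2.801 and 2.017 ppm, a causal SNP shifting their balance in opposite
    directions, and a shared "overall lipid level" factor loading both
    equally.  The ratio cancels the shared factor and approximates the
    enzymatic conversion rate.

``gckr``
    Pleiotropy across distant spectral regions: one SNP raising a
    glucose-like metabolite (3.286 ppm) while lowering a
    triglyceride-like one (1.370 ppm).  The cross-region ratio integrates
    both effects and cancels the common lipid factor.

``pyroxd2``
    A small genotype-dependent peak (2.7585 ppm) riding on the shoulder
    of a much larger genotype-independent resonance.  The ratio between
    the peak bin and its direct neighbour acts as a local baseline
    correction; its advantage over the single bin grows with the shoulder
    amplitude.

``null``
    The same spectral machinery with no genetic effects, for family-wise
    error-rate checks.

The default sizes (1,000 subjects, 200 SNPs, 0.003-ppm bins over 0-9 ppm,
top-50 selection) are desk-scale study conditions under which the planted
signals are recoverable in seconds rather than the cohort-scale hours.
"""

from __future__ import annotations

from .synth import (
    EffectSpec,
    MetaboliteSpec,
    MsReadoutSpec,
    NoiseSpec,
    PeakSpec,
    SimulationConfig,
    SnpSpec,
    WaterSpec,
)

__all__ = ["get_preset", "PRESET_NAMES", "DESK_BIN_WIDTH", "DESK_TOP_K"]

PRESET_NAMES = ("fads1", "gckr", "pyroxd2", "null")

#: Desk-scale analysis parameters matching the preset design.
DESK_BIN_WIDTH = 0.003
DESK_TOP_K = 50

_NOISE = NoiseSpec(baseline_amplitude=5.0, additive_sd=0.5, shift_jitter_sd=0.0005)
_WATER = WaterSpec(center=4.8, half_width=0.12, amplitude=800.0)


def _snp_panel(n_snps: int, causal: SnpSpec, causal_index: int = 10) -> list[SnpSpec]:
    """Causal SNP embedded in a panel of null SNPs with spread-out MAFs."""
    specs: list[SnpSpec] = []
    n_null = n_snps - 1
    for i in range(n_null):
        maf = 0.05 + 0.45 * i / max(n_null - 1, 1)
        specs.append(SnpSpec(id=f"snp{i:04d}", chrom=str(i % 22 + 1),
                             pos=1_000_000 + 50_000 * i, maf=round(maf, 4)))
    causal_index = min(causal_index, len(specs))
    specs.insert(causal_index, causal)
    return specs


_LACTATE = MetaboliteSpec("lactate", log_mean=0.5, log_sd=0.08, platform="clinical")
_LACTATE_PEAK = PeakSpec("lactate", center=1.370, half_width=0.002, amplitude=100.0)


def fads1_config(n_subjects: int = 1000, n_snps: int = 200, seed: int = 0) -> SimulationConfig:
    causal = SnpSpec(id="snp_fads1", chrom="11", pos=61_327_359, maf=0.30)
    mets = [
        _LACTATE,
        MetaboliteSpec("pufa_c20_4", log_mean=0.3, log_sd=0.05,
                       age_slope=0.001, sex_offset=0.02),
        MetaboliteSpec("pufa_c20_3", log_mean=0.3, log_sd=0.05,
                       age_slope=0.001, sex_offset=0.02),
        MetaboliteSpec("choline_pool", log_mean=0.4, log_sd=0.10),
    ]
    peaks = [
        _LACTATE_PEAK,
        PeakSpec("pufa_c20_4", center=2.801, half_width=0.002, amplitude=40.0),
        PeakSpec("pufa_c20_3", center=2.017, half_width=0.002, amplitude=40.0),
        PeakSpec("choline_pool", center=3.210, half_width=0.003, amplitude=30.0),
    ]
    return SimulationConfig(
        n_subjects=n_subjects,
        snp_specs=_snp_panel(n_snps, causal),
        metabolite_specs=mets,
        effect_specs=[
            EffectSpec("snp_fads1", "pufa_c20_4", -0.05),  # less product
            EffectSpec("snp_fads1", "pufa_c20_3", +0.05),  # more substrate
        ],
        peak_map=peaks,
        shared_loadings={"pufa_c20_4": 0.12, "pufa_c20_3": 0.12,
                         "choline_pool": 0.10, "lactate": 0.03},
        noise=_NOISE,
        water=_WATER,
        ms_readout=[
            MsReadoutSpec("pufa_c20_4", cv=0.10, missing_rate=0.05),
            MsReadoutSpec("pufa_c20_3", cv=0.10, missing_rate=0.05),
            MsReadoutSpec("lactate", cv=0.03, missing_rate=0.01),
        ],
        seed=seed,
        scenario="fads1",
        expected_ratio_pair=(2.801, 2.017),
    )


def gckr_config(n_subjects: int = 1000, n_snps: int = 200, seed: int = 0) -> SimulationConfig:
    causal = SnpSpec(id="snp_gckr", chrom="2", pos=27_594_741, maf=0.414)
    mets = [
        MetaboliteSpec("glucose", log_mean=0.3, log_sd=0.05, platform="clinical"),
        MetaboliteSpec("triglyceride", log_mean=0.5, log_sd=0.06,
                       age_slope=0.002, sex_offset=-0.04, platform="clinical"),
        MetaboliteSpec("hdl_lipid", log_mean=0.4, log_sd=0.08, platform="clinical"),
    ]
    peaks = [
        PeakSpec("glucose", center=3.286, half_width=0.0015, amplitude=50.0),
        # the triglyceride CH3 envelope doubles as the alignment anchor
        PeakSpec("triglyceride", center=1.370, half_width=0.004, amplitude=100.0),
        PeakSpec("hdl_lipid", center=0.840, half_width=0.010, amplitude=50.0),
    ]
    return SimulationConfig(
        n_subjects=n_subjects,
        snp_specs=_snp_panel(n_snps, causal),
        metabolite_specs=mets,
        effect_specs=[
            EffectSpec("snp_gckr", "glucose", +0.04),
            EffectSpec("snp_gckr", "triglyceride", -0.04),
        ],
        peak_map=peaks,
        shared_loadings={"glucose": 0.10, "triglyceride": 0.14, "hdl_lipid": 0.12},
        noise=_NOISE,
        water=_WATER,
        ms_readout=[
            MsReadoutSpec("glucose", cv=0.03, missing_rate=0.01),
            MsReadoutSpec("triglyceride", cv=0.03, missing_rate=0.01),
            MsReadoutSpec("hdl_lipid", cv=0.05, missing_rate=0.01),
        ],
        seed=seed,
        scenario="gckr",
        expected_ratio_pair=(3.286, 1.370),
    )


def pyroxd2_config(
    n_subjects: int = 1000,
    n_snps: int = 200,
    seed: int = 0,
    shoulder_amplitude: float = 50.0,
) -> SimulationConfig:
    """Shoulder-peak scenario; ``shoulder_amplitude`` scales the large
    genotype-independent resonance the small peak rides on."""
    causal = SnpSpec(id="snp_pyroxd2", chrom="10", pos=100_149_126, maf=0.343)
    mets = [
        _LACTATE,
        MetaboliteSpec("dimethylamine", log_mean=0.0, log_sd=0.10),
        MetaboliteSpec("chol_backbone", log_mean=0.301, log_sd=0.08,
                       platform="clinical"),
    ]
    peaks = [
        _LACTATE_PEAK,
        PeakSpec("dimethylamine", center=2.7585, half_width=0.0008, amplitude=25.0),
        PeakSpec("chol_backbone", center=2.740, half_width=0.010,
                 amplitude=shoulder_amplitude),
    ]
    return SimulationConfig(
        n_subjects=n_subjects,
        snp_specs=_snp_panel(n_snps, causal),
        metabolite_specs=mets,
        effect_specs=[EffectSpec("snp_pyroxd2", "dimethylamine", -0.14)],
        peak_map=peaks,
        shared_loadings={"chol_backbone": 0.15, "lactate": 0.03},
        noise=_NOISE,
        water=_WATER,
        ms_readout=[
            MsReadoutSpec("chol_backbone", cv=0.03, missing_rate=0.01),
            MsReadoutSpec("lactate", cv=0.03, missing_rate=0.01),
        ],
        seed=seed,
        scenario="pyroxd2",
        expected_ratio_pair=(2.7585, 2.7555),
    )


def null_config(n_subjects: int = 500, n_snps: int = 100, seed: int = 0) -> SimulationConfig:
    """No planted genetic effects; used for family-wise error-rate checks."""
    cfg = fads1_config(n_subjects=n_subjects, n_snps=n_snps, seed=seed)
    cfg.effect_specs = []
    # replace the causal spec with an ordinary null SNP
    cfg.snp_specs = [s if s.id != "snp_fads1"
                     else SnpSpec(id="snp_nullx", chrom="11", pos=s.pos, maf=s.maf)
                     for s in cfg.snp_specs]
    cfg.scenario = "null"
    cfg.expected_ratio_pair = None
    return cfg


def get_preset(name: str, seed: int = 0, **kwargs) -> SimulationConfig:
    """Look up a scenario preset by name."""
    builders = {
        "fads1": fads1_config,
        "gckr": gckr_config,
        "pyroxd2": pyroxd2_config,
        "null": null_config,
    }
    try:
        builder = builders[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return builder(seed=seed, **kwargs)
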