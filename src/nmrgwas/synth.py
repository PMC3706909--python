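"""Synthetic plasma-NMR cohort generator.

Produces the four linked data layers a metabolite-ratio GWAS consumes:

1. biallelic SNP genotypes drawn under Hardy-Weinberg proportions,
2. metabolite concentrations following a log-normal model with additive
   per-allele genetic effects, age/sex covariate effects, and a shared
   latent "overall lipid level" factor,
3. raw 1H-NMR spectra rendered as sums of concentration-scaled Lorentzian
   peaks with per-subject chemical-shift jitter, broad baseline humps, a
   water artifact, and additive noise,
4. noisy mass-spectrometry / clinical-chemistry readouts of a metabolite
   subset with multiplicative error and missingness.

Every planted genetic effect and every metabolite-to-ppm peak assignment
is recorded in a :class:`TruthTable` so that recovery of the planted
signal by the downstream two-stage scan can be tested mechanically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "MetaboliteSpec",
    "EffectSpec",
    "PeakSpec",
    "NoiseSpec",
    "MsReadoutSpec",
    "SimulationConfig",
    "GenotypeSet",
    "MetaboliteSet",
    "TruthTable",
    "simulate_genotypes",
    "simulate_concentrations",
    "render_spectra",
    "simulate_ms_readouts",
    "simulate_cohort",
    "CohortData",
]


# --------------------------------------------------------------------------
# specification dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: identifier, map position and minor-allele frequency."""

    id: str
    chrom: str
    pos: int
    maf: float
    allele_a: str = "A"
    allele_b: str = "G"

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"SNP {self.id}: MAF must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite of the simulated plasma mixture.

    ``log_mean``/``log_sd`` parameterise the base-10 log-normal concentration;
    ``age_slope`` is per year of age (centred at 50), ``sex_offset`` is added
    for sex == 1.  ``platform`` tags which measurement platform reports the
    metabolite ('targeted-MS', 'non-targeted-MS', 'clinical' or none).
    """

    name: str
    log_mean: float
    log_sd: float
    age_slope: float = 0.0
    sex_offset: float = 0.0
    platform: str = "targeted-MS"

    def validate(self) -> None:
        if self.log_sd < 0:
            raise ValueError(f"metabolite {self.name}: log_sd must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Additive per-minor-allele effect (log10 units) of a SNP on a metabolite."""

    snp: str
    metabolite: str
    beta: float


@dataclass(frozen=True)
class PeakSpec:
    """Lorentzian resonance(s) of a metabolite.

    ``amplitude`` is peak height per unit concentration; a multiplet is
    modelled as lines at ``center + offset`` with the amplitude split
    equally across lines.
    """

    metabolite: str
    center: float
    half_width: float
    amplitude: float
    offsets: tuple[float, ...] = (0.0,)

    def validate(self) -> None:
        if self.half_width <= 0:
            raise ValueError(f"peak for {self.metabolite}: half_width must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"peak for {self.metabolite}: amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Baseline / noise model of the spectrometer output.

    ``baseline_amplitude`` scales a fixed set of broad lipid-like humps,
    ``additive_sd`` is the i.i.d. Gaussian noise per grid point, and
    ``shift_jitter_sd`` the per-subject, per-metabolite rigid shift of all
    peak centres (ppm).  The default jitter (5e-4 ppm) sits below the bin
    width so that fixed-width binning absorbs it.
    """

    baseline_amplitude: float = 0.0
    additive_sd: float = 0.0
    shift_jitter_sd: float = 0.0005

    def validate(self) -> None:
        if self.additive_sd < 0 or self.shift_jitter_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class MsReadoutSpec:
    """Multiplicative-error readout of one metabolite on an MS-like platform."""

    metabolite: str
    cv: float = 0.1
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.cv < 0:
            raise ValueError(f"readout {self.metabolite}: CV must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"readout {self.metabolite}: missing_rate must be in [0,1)")


@dataclass(frozen=True)
class WaterSpec:
    """Broad high-amplitude artifact standing in for residual water."""

    center: float = 4.8
    half_width: float = 0.12
    amplitude: float = 0.0


@dataclass
class SimulationConfig:
    n_subjects: int
    snp_specs: list[SnpSpec] = field(default_factory=list)
    metabolite_specs: list[MetaboliteSpec] = field(default_factory=list)
    effect_specs: list[EffectSpec] = field(default_factory=list)
    peak_map: list[PeakSpec] = field(default_factory=list)
    shared_loadings: dict[str, float] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    ms_readout: list[MsReadoutSpec] = field(default_factory=list)
    water: WaterSpec = field(default_factory=WaterSpec)
    grid_lo: float = 0.0
    grid_hi: float = 9.0
    grid_step: float = 0.001
    baseline_subject_sd: float = 0.1  # log10 SD of the per-subject baseline scale
    genotype_missing_rate: float = 0.0
    seed: int = 0
    # scenario metadata, copied into the TruthTable
    scenario: str | None = None
    expected_ratio_pair: tuple[float, float] | None = None

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        """Load a simulation configuration from a YAML mapping.

        Sequence-valued sections (snps, metabolites, effects, peaks,
        readouts) are lists of mappings keyed by the corresponding spec
        dataclass fields; scalar fields map directly.
        """
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        kwargs = dict(raw)
        kwargs["snp_specs"] = [SnpSpec(**d) for d in raw.get("snp_specs", [])]
        kwargs["metabolite_specs"] = [MetaboliteSpec(**d)
                                      for d in raw.get("metabolite_specs", [])]
        kwargs["effect_specs"] = [EffectSpec(**d)
                                  for d in raw.get("effect_specs", [])]
        kwargs["peak_map"] = [
            PeakSpec(**{**d, "offsets": tuple(d.get("offsets", (0.0,)))})
            for d in raw.get("peak_map", [])]
        kwargs["ms_readout"] = [MsReadoutSpec(**d)
                                for d in raw.get("ms_readout", [])]
        if "noise" in raw:
            kwargs["noise"] = NoiseSpec(**raw["noise"])
        if "water" in raw:
            kwargs["water"] = WaterSpec(**raw["water"])
        if "expected_ratio_pair" in raw and raw["expected_ratio_pair"]:
            kwargs["expected_ratio_pair"] = tuple(raw["expected_ratio_pair"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        names = [m.name for m in self.metabolite_specs]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        snp_ids = {s.id for s in self.snp_specs}
        for s in self.snp_specs:
            s.validate()
        for m in self.metabolite_specs:
            m.validate()
        for p in self.peak_map:
            p.validate()
            if p.metabolite not in names:
                raise ValueError(f"peak references unknown metabolite {p.metabolite}")
        for e in self.effect_specs:
            if e.snp not in snp_ids:
                raise ValueError(f"effect references unknown SNP {e.snp}")
            if e.metabolite not in names:
                raise ValueError(f"effect references unknown metabolite {e.metabolite}")
        for r in self.ms_readout:
            r.validate()
            if r.metabolite not in names:
                raise ValueError(f"readout references unknown metabolite {r.metabolite}")
        for name in self.shared_loadings:
            if name not in names:
                raise ValueError(f"shared loading references unknown metabolite {name}")
        self.noise.validate()
        if self.grid_step <= 0 or self.grid_hi <= self.grid_lo:
            raise ValueError("invalid ppm grid")


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class GenotypeSet:
    """Subjects x SNPs dosage matrix counting minor alleles.

    ``dosage`` is float with entries in {0, 1, 2} and NaN for missing.
    ``snps`` carries id, chrom, pos, allele_a, allele_b, maf (observed,
    after minor-allele orientation) and call_rate.
    """

    subjects: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.snps)):
            raise ValueError("dosage matrix shape inconsistent with subjects/snps")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, snp_mask: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            subjects=list(self.subjects),
            snps=self.snps.loc[snp_mask].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(snp_mask)],
        )


@dataclass
class MetaboliteSet:
    """Subjects x metabolites concentration matrix with platform tags.

    ``values`` holds positive concentrations (platform units) with NaN for
    missing.  ``meta`` carries name, platform and, where available, cv.
    """

    subjects: list[str]
    meta: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.meta)):
            raise ValueError("values shape inconsistent with subjects/meta")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] <= 0):
                raise ValueError("concentrations must be positive or missing")
        key = list(zip(self.meta["name"], self.meta["platform"]))
        if len(set(key)) != len(key):
            raise ValueError("metabolite names must be unique within platform")

    @property
    def names(self) -> list[str]:
        return list(self.meta["name"])

    def column(self, name: str) -> np.ndarray:
        idx = self.names.index(name)
        return self.values[:, idx]


@dataclass
class TruthTable:
    """Machine-readable record of everything the simulator planted."""

    effects: pd.DataFrame        # snp, metabolite, beta
    peak_assignments: pd.DataFrame  # metabolite, center, half_width, amplitude
    scenario: str | None = None
    expected_ratio_pair: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.effects.copy()
        df["scenario"] = self.scenario or ""
        if self.expected_ratio_pair is not None:
            df["expected_ratio"] = "{:.3f}/{:.3f}".format(*self.expected_ratio_pair)
        else:
            df["expected_ratio"] = ""
        return df


@dataclass
class CohortData:
    """Bundle returned by :func:`simulate_cohort`."""

    genotypes: GenotypeSet
    covariates: pd.DataFrame
    concentrations: MetaboliteSet
    readouts: MetaboliteSet
    grid: np.ndarray
    spectra: np.ndarray
    truth: TruthTable
    config: SimulationConfig


# --------------------------------------------------------------------------
# simulation operations
# --------------------------------------------------------------------------

def _subject_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def simulate_genotypes(
    n_subjects: int,
    snp_specs: list[SnpSpec],
    seed: int | np.random.SeedSequence,
    missing_rate: float = 0.0,
) -> GenotypeSet:
    """Draw genotypes under Hardy-Weinberg proportions, independently per SNP.

    Dosages count copies of the spec's B allele; after drawing, each SNP is
    oriented so that the dosage counts the *observed* minor allele (a tie at
    50% keeps allele B as minor).
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    for s in snp_specs:
        s.validate()
    rng = np.random.default_rng(seed)
    m = len(snp_specs)
    dosage = np.empty((n_subjects, m), dtype=float)
    rows = []
    for j, s in enumerate(snp_specs):
        d = rng.binomial(2, s.maf, size=n_subjects).astype(float)
        if missing_rate > 0 and n_subjects > 0:
            miss = rng.random(n_subjects) < missing_rate
            d[miss] = np.nan
        obs = d[np.isfinite(d)]
        call_rate = 1.0 if n_subjects == 0 else obs.size / n_subjects
        freq_b = float(obs.mean() / 2.0) if obs.size else 0.0
        allele_a, allele_b = s.allele_a, s.allele_b
        if freq_b > 0.5:  # orient so dosage counts the minor allele
            d = 2.0 - d
            allele_a, allele_b = allele_b, allele_a
            freq_b = 1.0 - freq_b
        dosage[:, j] = d
        rows.append(
            dict(id=s.id, chrom=s.chrom, pos=s.pos, allele_a=allele_a,
                 allele_b=allele_b, maf=freq_b, call_rate=call_rate)
        )
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "allele_a",
                                       "allele_b", "maf", "call_rate"])
    return GenotypeSet(subjects=_subject_ids(n_subjects), snps=snps, dosage=dosage)


def simulate_concentrations(
    genotypes: GenotypeSet,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[MetaboliteSet, pd.DataFrame, TruthTable]:
    """Draw covariates and metabolite concentrations with planted effects.

    log10 concentration = base mean + sum(effect * dosage) + age/sex terms
    + shared-factor loading * latent factor + independent Gaussian noise.
    Age is uniform on [25, 74], sex Bernoulli(0.5).  Missing dosages enter
    through their Hardy-Weinberg expectation (2 * MAF) so that a sparse
    genotyping failure never makes a concentration undefined.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = genotypes.n_subjects
    age = rng.uniform(25.0, 74.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    factor = rng.standard_normal(n)

    specs = config.metabolite_specs
    logc = np.empty((n, len(specs)))
    snp_index = {sid: j for j, sid in enumerate(genotypes.snps["id"])}
    for k, mspec in enumerate(specs):
        mu = np.full(n, mspec.log_mean)
        mu += mspec.age_slope * (age - 50.0)
        mu += mspec.sex_offset * sex
        mu += config.shared_loadings.get(mspec.name, 0.0) * factor
        for eff in config.effect_specs:
            if eff.metabolite != mspec.name:
                continue
            j = snp_index[eff.snp]
            d = genotypes.dosage[:, j]
            expected = 2.0 * float(genotypes.snps["maf"].iloc[j])
            d = np.where(np.isfinite(d), d, expected)
            mu += eff.beta * d
        noise = rng.standard_normal(n) * mspec.log_sd if mspec.log_sd > 0 else 0.0
        logc[:, k] = mu + noise

    meta = pd.DataFrame(
        {"name": [m.name for m in specs],
         "platform": ["truth"] * len(specs),
         "cv": [np.nan] * len(specs)}
    )
    conc = MetaboliteSet(subjects=list(genotypes.subjects), meta=meta,
                         values=np.power(10.0, logc))
    covariates = pd.DataFrame(
        {"subject": genotypes.subjects, "age": age, "sex": sex, "factor": factor}
    )
    truth = TruthTable(
        effects=pd.DataFrame(
            [dict(snp=e.snp, metabolite=e.metabolite, beta=e.beta)
             for e in config.effect_specs],
            columns=["snp", "metabolite", "beta"],
        ),
        peak_assignments=pd.DataFrame(
            [dict(metabolite=p.metabolite, center=p.center,
                  half_width=p.half_width, amplitude=p.amplitude)
             for p in config.peak_map],
            columns=["metabolite", "center", "half_width", "amplitude"],
        ),
        scenario=config.scenario,
        expected_ratio_pair=config.expected_ratio_pair,
    )
    return conc, covariates, truth


def _lorentzian(x: np.ndarray, center: np.ndarray | float, hw: float) -> np.ndarray:
    """Unit-height Lorentzian line shape."""
    return hw * hw / ((x - center) ** 2 + hw * hw)


# Broad baseline humps emulating overlapping macromolecule/lipid envelopes:
# (center ppm, half-width ppm, relative amplitude).
_BASELINE_HUMPS = (
    (0.90, 0.20, 1.0),
    (1.30, 0.25, 1.4),
    (2.05, 0.30, 0.6),
    (3.25, 0.40, 0.5),
    (5.35, 0.30, 0.4),
)

# Evaluate a narrow line only within this many half-widths of its center.
_PEAK_WINDOW_HW = 400.0


def render_spectra(
    concentrations: MetaboliteSet,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render per-subject 1H spectra on a uniform ppm grid.

    Returns ``(spectra, grid)`` with ``spectra[i, g]`` the intensity of
    subject i at ``grid[g]``.  Each metabolite's lines are shifted rigidly
    by a per-subject jitter; a metabolite without any peak assignment is
    rendered invisible (with a warning).  Narrow lines are evaluated on a
    window of +-400 half-widths around the line, which truncates less than
    1e-5 of the Lorentzian tail and keeps rendering linear in concentration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    grid = config.grid_lo + np.arange(
        int(np.ceil((config.grid_hi - config.grid_lo) / config.grid_step - 1e-9))
    ) * config.grid_step
    n = len(concentrations.subjects)
    spectra = np.zeros((n, grid.size))

    peak_by_met: dict[str, list[PeakSpec]] = {}
    for p in config.peak_map:
        peak_by_met.setdefault(p.metabolite, []).append(p)
    for name in concentrations.names:
        if name not in peak_by_met:
            warnings.warn(f"metabolite {name!r} has no peak assignment; invisible")

    for k, name in enumerate(concentrations.names):
        peaks = peak_by_met.get(name)
        if not peaks:
            continue
        conc = np.nan_to_num(concentrations.values[:, k], nan=0.0)
        jitter = (rng.standard_normal(n) * config.noise.shift_jitter_sd
                  if config.noise.shift_jitter_sd > 0 else np.zeros(n))
        for p in peaks:
            line_amp = p.amplitude / len(p.offsets)
            for off in p.offsets:
                c0 = p.center + off
                halfwin = _PEAK_WINDOW_HW * p.half_width
                lo = np.searchsorted(grid, c0 - halfwin - 6 * config.noise.shift_jitter_sd)
                hi = np.searchsorted(grid, c0 + halfwin + 6 * config.noise.shift_jitter_sd)
                if hi <= lo:
                    continue
                x = grid[lo:hi][None, :]
                centers = (c0 + jitter)[:, None]
                spectra[:, lo:hi] += (line_amp * conc)[:, None] * _lorentzian(x, centers, p.half_width)

    if config.noise.baseline_amplitude > 0:
        shape = np.zeros_like(grid)
        for c0, hw, rel in _BASELINE_HUMPS:
            shape += rel * _lorentzian(grid, c0, hw)
        scale = np.power(10.0, rng.standard_normal(n) * config.baseline_subject_sd)
        spectra += config.noise.baseline_amplitude * scale[:, None] * shape[None, :]

    if config.water.amplitude > 0:
        spectra += config.water.amplitude * _lorentzian(
            grid, config.water.center, config.water.half_width
        )[None, :]

    if config.noise.additive_sd > 0:
        spectra += rng.standard_normal(spectra.shape) * config.noise.additive_sd

    return spectra, grid


def simulate_ms_readouts(
    concentrations: MetaboliteSet,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> MetaboliteSet:
    """Apply platform error to the true concentrations.

    readout = truth * exp(N(0, sigma)) with sigma chosen so the
    multiplicative error has the stated coefficient of variation
    (sigma = sqrt(log(1 + cv^2))); entries are then set missing
    independently with the stated probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    n = len(concentrations.subjects)
    platform = {m.name: m.platform for m in config.metabolite_specs}
    cols, meta_rows = [], []
    for spec in config.ms_readout:
        truth = concentrations.column(spec.metabolite).copy()
        if spec.cv > 0:
            sigma = np.sqrt(np.log1p(spec.cv**2))
            truth = truth * np.exp(rng.standard_normal(n) * sigma)
        if spec.missing_rate > 0:
            truth[rng.random(n) < spec.missing_rate] = np.nan
        cols.append(truth)
        meta_rows.append(dict(name=spec.metabolite,
                              platform=platform.get(spec.metabolite, "targeted-MS"),
                              cv=spec.cv))
    values = (np.column_stack(cols) if cols else np.empty((n, 0)))
    meta = pd.DataFrame(meta_rows, columns=["name", "platform", "cv"])
    return MetaboliteSet(subjects=list(concentrations.subjects), meta=meta, values=values)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortData:
    """Run the full generator with named substreams off a single seed."""
    config = replace(config, seed=config.seed if seed is None else seed)
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_conc, s_spec, s_ms = ss.spawn(4)
    genotypes = simulate_genotypes(config.n_subjects, config.snp_specs, s_geno,
                                   missing_rate=config.genotype_missing_rate)
    conc, covariates, truth = simulate_concentrations(genotypes, config, s_conc)
    spectra, grid = render_spectra(conc, config, s_spec)
    readouts = simulate_ms_readouts(conc, config, s_ms)
    return CohortData(genotypes=genotypes, covariates=covariates,
                      concentrations=conc, readouts=readouts,
                      grid=grid, spectra=spectra, truth=truth, config=config)
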