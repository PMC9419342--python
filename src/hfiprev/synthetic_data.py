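"""Generators for every non-public input of the pipeline.

The study's real inputs — carrier screens of a clinical exome cohort,
per-population allele-count tables, and a curated case series with
phenotype flags — are not publicly distributable, so this module emulates
them with the statistical structure the downstream analysis assumes:

* cohort genotypes under Hardy-Weinberg random mating (two independent
  pathogenic-allele draws per individual), with affected individuals
  (two pathogenic alleles) generated and then *excluded* from carrier
  counts, exercising the same exclusion rule applied to the real cohorts;
* gnomAD-style AC/AN tables as binomial draws around target frequencies;
* patient genotypes drawn from the panel's allele-frequency spectrum with
  a configurable homozygosity excess, and Bernoulli phenotype flags whose
  log-odds shift with genotype (zygosity, mutation-type pattern, or
  carried site), plus independent missingness.

Every generator is a pure function of ``(config, seed)``; each consumes
its own sub-stream of the seed so adding one generator call never perturbs
another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_pheno import PHENOTYPE_VOCABULARY, PatientRecord
from .panel_io import PopulationAFRecord, load_builtin_panel
from .prevalence import CohortCarrierCounts

__all__ = [
    "PhenotypeEffect",
    "SimulationConfig",
    "PopulationSpec",
    "CohortSimulation",
    "simulate_cohort",
    "simulate_af_table",
    "simulate_patient_table",
    "paperlike_config",
    "paperlike_populations",
    "paperlike_af_comparison_records",
]

# sub-stream tags so each generator owns an independent stream of the seed
_STREAM_COHORT, _STREAM_AF, _STREAM_PATIENTS = 11, 13, 17


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeEffect:
    """Generative model for one phenotype flag.

    ``baseline_rate`` is the presence probability for a patient with no
    active effect; odds ratios multiply the odds for patients matching the
    keyed genotype feature. ``missingness`` is the independent probability
    the flag is recorded as not assessed.
    """

    baseline_rate: float
    or_homozygous: float = 1.0
    or_by_pattern: Mapping[str, float] = field(default_factory=dict)
    or_by_site: Mapping[str, float] = field(default_factory=dict)
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_rate < 1.0:
            raise ConfigError("baseline_rate must be in (0, 1)")
        if not 0.0 <= self.missingness <= 1.0:
            raise ConfigError("missingness must be in [0, 1]")
        for or_ in (self.or_homozygous, *self.or_by_pattern.values(),
                    *self.or_by_site.values()):
            if not (or_ > 0 or math.isinf(or_)):
                raise ConfigError("odds ratios must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration for all generators.

    ``af_spectrum`` maps variant id to its pathogenic allele frequency;
    the sum is the total pathogenic allele frequency q and must stay below
    0.5 so carrier probability 2q(1-q) is well-formed and increasing.
    ``mutation_types`` maps variant id to mutation-type class (needed only
    for patient-table simulation). ``homozygote_excess`` is the probability
    a simulated patient's two alleles are forced identical, emulating the
    enrichment of homozygotes (consanguinity, founder alleles) seen in
    recessive case series beyond the random-mating expectation.
    """

    seed: int
    n_individuals: int
    af_spectrum: Mapping[str, float]
    male_fraction: float = 0.5
    phenotype_model: Mapping[str, PhenotypeEffect] = field(default_factory=dict)
    mutation_types: Mapping[str, str] = field(default_factory=dict)
    homozygote_excess: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must be in [0, 1]")
        if any(af < 0 for af in self.af_spectrum.values()):
            raise ConfigError("allele frequencies must be non-negative")
        if sum(self.af_spectrum.values()) >= 0.5:
            raise ConfigError(
                "total pathogenic allele frequency must be < 0.5 "
                f"(got {sum(self.af_spectrum.values()):.3f})"
            )
        if not 0.0 <= self.homozygote_excess <= 1.0:
            raise ConfigError("homozygote_excess must be in [0, 1]")

    @property
    def total_af(self) -> float:
        return float(sum(self.af_spectrum.values()))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class PopulationSpec:
    """Target for one simulated population column: a scalar multiplier on
    the whole AF spectrum and the population's typed allele number."""

    af_scaler: float
    allele_number: int

    def __post_init__(self) -> None:
        if self.af_scaler < 0:
            raise ConfigError("af_scaler must be >= 0")
        if self.allele_number < 1:
            raise ConfigError("allele_number must be >= 1")


@dataclass(frozen=True)
class CohortSimulation:
    """Carrier counts after exclusion of affected individuals, plus the
    exclusion bookkeeping and (optionally) the carriers' variant draws."""

    counts: CohortCarrierCounts
    n_generated: int
    n_affected_excluded: int
    carrier_variants: pd.DataFrame | None = None


def simulate_cohort(
    config: SimulationConfig, return_genotypes: bool = False
) -> CohortSimulation:
    """Draw a screened cohort under Hardy-Weinberg equilibrium.

    Each individual receives two independent alleles, each pathogenic with
    probability ``q = sum(af_spectrum)``. Individuals with two pathogenic
    alleles are affected: they are generated, then excluded from the
    totals and carrier counts, mirroring how diagnosed patients are
    removed from a screen before prevalence estimation. Carriers are the
    exactly-one-allele individuals. With ``return_genotypes`` the carriers'
    pathogenic alleles are assigned to panel variants by a multinomial
    draw proportional to the AF spectrum.
    """
    rng = config.rng(_STREAM_COHORT)
    q = config.total_af
    n = config.n_individuals
    n_path = rng.binomial(2, q, size=n)
    male = rng.random(n) < config.male_fraction
    affected = n_path == 2
    carrier = n_path == 1
    keep = ~affected

    counts = CohortCarrierCounts(
        n_total=int(keep.sum()),
        n_male=int((keep & male).sum()),
        n_female=int((keep & ~male).sum()),
        carriers_male=int((carrier & male).sum()),
        carriers_female=int((carrier & ~male).sum()),
    )
    carrier_variants = None
    if return_genotypes:
        ids = list(config.af_spectrum)
        weights = np.array([config.af_spectrum[i] for i in ids], dtype=float)
        if weights.sum() > 0:
            weights = weights / weights.sum()
            idx = np.flatnonzero(carrier)
            draws = rng.choice(len(ids), size=idx.size, p=weights)
            carrier_variants = pd.DataFrame(
                {
                    "individual": idx,
                    "sex": np.where(male[idx], "male", "female"),
                    "variant_id": [ids[k] for k in draws],
                }
            )
        else:
            carrier_variants = pd.DataFrame(
                columns=["individual", "sex", "variant_id"]
            )
    return CohortSimulation(
        counts=counts,
        n_generated=n,
        n_affected_excluded=int(affected.sum()),
        carrier_variants=carrier_variants,
    )


def simulate_af_table(
    config: SimulationConfig, populations: Mapping[str, PopulationSpec]
) -> list[PopulationAFRecord]:
    """Draw an AC/AN table: AC ~ Binomial(AN, af * scaler) per variant and
    population, in deterministic (population, variant) order."""
    rng = config.rng(_STREAM_AF)
    for pop, spec in populations.items():
        for vid, af in config.af_spectrum.items():
            if af * spec.af_scaler > 1.0:
                raise ConfigError(
                    f"scaled AF exceeds 1 for {vid!r} in {pop!r}"
                )
    records = []
    for pop in populations:
        spec = populations[pop]
        for vid, af in config.af_spectrum.items():
            ac = int(rng.binomial(spec.allele_number, af * spec.af_scaler))
            records.append(
                PopulationAFRecord(
                    variant_id=vid,
                    population=pop,
                    allele_count=ac,
                    allele_number=spec.allele_number,
                )
            )
    return records


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if math.isinf(x):
        return 1.0 if x > 0 else 0.0
    return 1.0 / (1.0 + math.exp(-x))


def simulate_patient_table(
    config: SimulationConfig, n_patients: int
) -> list[PatientRecord]:
    """Draw an affected case series with genotype-dependent phenotype flags.

    Alleles come from the AF spectrum normalised over the panel (every
    patient carries two pathogenic alleles); with probability
    ``homozygote_excess`` the second allele is forced equal to the first.
    Phenotype flags are Bernoulli with log-odds = logit(baseline) plus the
    log odds ratios of the matching genotype features; missingness is then
    applied independently.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if not config.phenotype_model:
        raise ConfigError("phenotype_model must define at least one phenotype")
    unknown_ph = set(config.phenotype_model) - set(PHENOTYPE_VOCABULARY)
    if unknown_ph:
        raise ConfigError(f"phenotypes outside the vocabulary: {sorted(unknown_ph)}")
    ids = list(config.af_spectrum)
    weights = np.array([config.af_spectrum[i] for i in ids], dtype=float)
    if weights.sum() <= 0:
        raise ConfigError("af_spectrum must carry positive mass")
    weights = weights / weights.sum()
    missing_types = [i for i in ids if i not in config.mutation_types]
    if missing_types:
        raise ConfigError(
            f"mutation_types missing for variant(s): {missing_types[:5]}"
        )

    rng = config.rng(_STREAM_PATIENTS)
    records: list[PatientRecord] = []
    for i in range(n_patients):
        a1 = ids[rng.choice(len(ids), p=weights)]
        if rng.random() < config.homozygote_excess:
            a2 = a1
        else:
            a2 = ids[rng.choice(len(ids), p=weights)]
        a1, a2 = sorted((a1, a2))
        zyg = "homozygous" if a1 == a2 else "compound_heterozygous"
        t1, t2 = config.mutation_types[a1], config.mutation_types[a2]
        pattern = "+".join(sorted((t1, t2)))

        phenos: dict[str, bool | None] = {}
        for ph, eff in config.phenotype_model.items():
            if rng.random() < eff.missingness:
                phenos[ph] = None
                continue
            logodds = _logit(eff.baseline_rate)
            if zyg == "homozygous":
                logodds += math.log(eff.or_homozygous)
            if pattern in eff.or_by_pattern:
                logodds += math.log(eff.or_by_pattern[pattern])
            for site in {a1, a2}:
                if site in eff.or_by_site:
                    logodds += math.log(eff.or_by_site[site])
            phenos[ph] = bool(rng.random() < _expit(logodds))
        records.append(
            PatientRecord(
                patient_id=f"SIM{i + 1:03d}",
                allele1=a1,
                allele2=a2,
                mutation_type1=t1,
                mutation_type2=t2,
                zygosity=zyg,
                phenotypes=phenos,
            )
        )
    return records


# ---------------------------------------------------------------------------
# "paperlike" preset: the fixture conditions used across the test suite

#: Ten screening hotspots with target allele frequencies in the emulated
#: pediatric cohort; the named values follow the frequencies quoted for the
#: Chinese pediatric population (A338V 1:1887, N120Kfs*32 1:3226,
#: A338G 1:8333, A150P 1:20833), the rest interpolate the observed ranking.
_HOTSPOT_AFS: dict[str, float] = {
    "A338V": 1 / 1887,
    "N120Kfs*32": 1 / 3226,
    "A338G": 1 / 8333,
    "W296*": 1.10e-4,
    "E225Rfs*5": 1.00e-4,
    "R304W": 6.00e-5,
    "A150P": 1 / 20833,
    "c.325-1G>C": 4.00e-5,
    "L289Ffs*10": 3.50e-5,
    "Q111*": 3.00e-5,
}

#: Fourteen further panel variants with AF records in the emulated tables
#: (the remaining 57 panel variants carry no AF record anywhere, matching
#: a panel in which most curated alleles are absent from population data).
_FILLER_IDS = (
    "A175D", "N335K", "R60*", "R304Q",
    "c.325-1G>A", "c.112+1delG", "c.324+1G>A", "c.380-1G>A",
    "W147R", "C134R", "V67del", "Q27*", "E84*", "c.113-2A>G",
)


def paperlike_af_spectrum() -> dict[str, float]:
    """AF spectrum calibrated so the ten hotspots carry 90% of the total
    pathogenic allele frequency (total q about 1.5e-3, carrier frequency
    about 1/326 — the regime of the emulated pediatric screen)."""
    spectrum = dict(_HOTSPOT_AFS)
    hot = sum(spectrum.values())
    # fillers share hot/9 so hotspots / total == 0.9 exactly
    per_filler = hot / 9.0 / len(_FILLER_IDS)
    for vid in _FILLER_IDS:
        spectrum[vid] = per_filler
    return spectrum


def paperlike_config(seed: int) -> SimulationConfig:
    """Study-scale defaults: a 20,919-individual pediatric screen with the
    observed male fraction, the calibrated AF spectrum, and a 24-phenotype
    null model whose four cardinal gastrointestinal phenotypes use the
    observed case-series rates and assessment completeness."""
    panel = load_builtin_panel()
    types = {v.id: v.mutation_type for v in panel}
    model: dict[str, PhenotypeEffect] = {
        "aversion_to_sweets_and_fruit": PhenotypeEffect(0.87, missingness=1 - 39 / 68),
        "vomiting": PhenotypeEffect(0.78, missingness=1 - 40 / 68),
        "nausea": PhenotypeEffect(0.54, missingness=1 - 35 / 68),
        "hepatomegaly": PhenotypeEffect(0.59, missingness=1 - 37 / 68),
    }
    for ph in PHENOTYPE_VOCABULARY:
        if ph not in model:
            model[ph] = PhenotypeEffect(0.20, missingness=0.40)
    return SimulationConfig(
        seed=seed,
        n_individuals=20_919,
        male_fraction=12_783 / 20_919,
        af_spectrum=paperlike_af_spectrum(),
        phenotype_model=model,
        mutation_types=types,
        homozygote_excess=0.42,
    )


def paperlike_populations() -> dict[str, PopulationSpec]:
    """AN and AF-scale targets for the emulated screening populations."""
    return {
        "CCGT_child": PopulationSpec(af_scaler=1.0, allele_number=41_838),
        "CCGT_parent": PopulationSpec(af_scaler=1.0, allele_number=20_062),
        "HuaBiao": PopulationSpec(af_scaler=1.34, allele_number=5_930),
    }


def paperlike_af_comparison_records() -> list[PopulationAFRecord]:
    """Deterministic AC/AN fixture for the Chinese-vs-European comparison.

    Child-cohort counts are the expected counts of the paperlike spectrum
    at AN = 41,838; the European column puts the classic Caucasian
    hotspots at high frequency (A150P at 1:189) and the Chinese hotspots
    at trace frequency, reproducing the qualitative contrast between the
    two ancestries. Not a random draw: counts are data for comparison
    tests.
    """
    an_child, an_nfe = 41_838, 129_006
    spectrum = paperlike_af_spectrum()
    child_ac = {vid: round(af * an_child) for vid, af in spectrum.items()}
    nfe_af = {
        "A150P": 1 / 189,
        "A175D": 1 / 3000,
        "N335K": 1 / 3000,
        "R60*": 1 / 3000,
        "R304Q": 1 / 3000,
        "A338V": 3 / an_nfe,
        "A338G": 0.0,
        "N120Kfs*32": 1 / 5000,
        "W296*": 8 / an_nfe,
        "E225Rfs*5": 6 / an_nfe,
        "R304W": 10 / an_nfe,
        "c.325-1G>C": 4 / an_nfe,
        "L289Ffs*10": 2 / an_nfe,
        "Q111*": 3 / an_nfe,
    }
    records = []
    for vid in spectrum:
        records.append(
            PopulationAFRecord(vid, "CCGT_child", child_ac[vid], an_child)
        )
        ac_nfe = round(nfe_af.get(vid, 0.0) * an_nfe)
        records.append(PopulationAFRecord(vid, "NFE", ac_nfe, an_nfe))
    return records
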