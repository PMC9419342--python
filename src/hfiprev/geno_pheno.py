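"""Genotype classification and genotype-phenotype association testing for a
recessive-disease case series.

Each patient carries two pathogenic alleles (homozygous or compound
heterozygous). Patients are grouped three ways — by variant site (carrying
at least one copy; a ``"<site> (homozygote)"`` label selects homozygotes
only), by unordered mutation-type pattern (e.g. ``missense+missense``), and
by zygosity — and each group is tested against the rest of the cohort for
over-representation of every phenotype, with patients not assessed for the
phenotype excluded from the 2x2 table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .af_compare import chi_square_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "PHENOTYPE_VOCABULARY",
    "PatientRecord",
    "GenotypeClass",
    "PhenotypeFrequency",
    "AssociationResult",
    "classify_genotype",
    "phenotype_frequency",
    "test_association",
    "association_screen",
    "read_patient_table",
    "write_patient_table",
    "results_to_frame",
]

#: Default 24-term clinical-manifestation vocabulary (OMIM-style common
#: features of hereditary fructose intolerance).
PHENOTYPE_VOCABULARY: tuple[str, ...] = (
    "aversion_to_sweets_and_fruit",
    "vomiting",
    "nausea",
    "hepatomegaly",
    "hypoglycemia",
    "jaundice",
    "lethargy",
    "metabolic_acidosis",
    "abnormal_liver_function",
    "liver_failure",
    "hepatic_steatosis",
    "failure_to_thrive",
    "growth_retardation",
    "irritability",
    "seizures",
    "coma",
    "abdominal_pain",
    "diarrhea",
    "anemia",
    "thrombocytopenia",
    "coagulopathy",
    "renal_tubular_acidosis",
    "proteinuria",
    "hyperuricemia",
)

PRESENT, ABSENT, NOT_ASSESSED = True, False, None


@dataclass(frozen=True)
class GenotypeClass:
    zygosity: str
    mutation_type_pattern: str


@dataclass
class PatientRecord:
    """Diallelic genotype plus phenotype flags for one case.

    ``phenotypes`` maps phenotype name to True (present), False (absent) or
    None (not assessed). Zygosity must be consistent with the alleles:
    homozygous iff allele1 == allele2.
    """

    patient_id: str
    allele1: str
    allele2: str
    mutation_type1: str
    mutation_type2: str
    zygosity: str
    phenotypes: dict[str, bool | None] = field(default_factory=dict)
    vocabulary: tuple[str, ...] = PHENOTYPE_VOCABULARY

    def __post_init__(self) -> None:
        if not self.allele1 or not self.allele2:
            raise ValueError(f"patient {self.patient_id!r}: both alleles required")
        expected = "homozygous" if self.allele1 == self.allele2 else "compound_heterozygous"
        if self.zygosity != expected:
            raise ValueError(
                f"patient {self.patient_id!r}: zygosity {self.zygosity!r} "
                f"inconsistent with alleles ({self.allele1!r}, {self.allele2!r})"
            )
        unknown = set(self.phenotypes) - set(self.vocabulary)
        if unknown:
            raise KeyError(
                f"patient {self.patient_id!r}: phenotype(s) outside the "
                f"vocabulary: {sorted(unknown)}"
            )


def classify_genotype(record: PatientRecord) -> GenotypeClass:
    """Zygosity plus the unordered mutation-type pair, e.g.
    ``missense+nonsense``."""
    pattern = "+".join(sorted((record.mutation_type1, record.mutation_type2)))
    return GenotypeClass(zygosity=record.zygosity, mutation_type_pattern=pattern)


@dataclass(frozen=True)
class PhenotypeFrequency:
    present: int
    assessed: int
    fraction: float
    percent: int


def phenotype_frequency(
    cohort: Sequence[PatientRecord], phenotype: str
) -> PhenotypeFrequency:
    """Presence rate of one phenotype among *assessed* patients only."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if phenotype not in cohort[0].vocabulary:
        raise KeyError(f"unknown phenotype {phenotype!r}")
    flags = [p.phenotypes.get(phenotype) for p in cohort]
    assessed = sum(1 for f in flags if f is not None)
    present = sum(1 for f in flags if f is PRESENT)
    if assessed == 0:
        return PhenotypeFrequency(0, 0, float("nan"), 0)
    frac = present / assessed
    return PhenotypeFrequency(present, assessed, frac, int(np.floor(100 * frac + 0.5)))


@dataclass(frozen=True)
class AssociationResult:
    """One group-vs-rest phenotype over-representation test.

    ``table`` is ((group present, group absent), (rest present, rest
    absent)); patients not assessed for the phenotype never enter it.
    Both the Fisher and chi-square p-values are retained; ``test_used``
    records which one ``p_raw`` came from.
    """

    grouping: str
    group_label: str
    phenotype: str
    table: tuple[tuple[int, int], tuple[int, int]]
    test_used: str
    p_fisher: float
    p_chi_square: float | None
    p_raw: float
    p_adjusted: float
    significant: bool


def _in_group(record: PatientRecord, grouping: str, group_label: str) -> bool:
    if grouping == "zygosity":
        return record.zygosity == group_label
    if grouping == "mutation_type_pattern":
        return classify_genotype(record).mutation_type_pattern == group_label
    if grouping == "variant_site":
        if group_label.endswith(" (homozygote)"):
            site = group_label[: -len(" (homozygote)")]
            return record.allele1 == site and record.allele2 == site
        return group_label in (record.allele1, record.allele2)
    raise ValueError(f"unknown grouping {grouping!r}")


@lru_cache(maxsize=100_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (probability-mass ordering) for
    [[a, b], [c, d]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def test_association(
    cohort: Sequence[PatientRecord],
    grouping: str,
    group_label: str,
    phenotype: str,
    adjust: str = "bonferroni",
    n_tests: int = 1,
    alpha: float = 0.05,
) -> AssociationResult:
    """Test one phenotype for over-representation in one genotype group.

    The Fisher two-sided exact p uses probability-mass ordering (the sum of
    probabilities of all tables, at the observed margins, no more probable
    than the observed one). The chi-square alternative uses the Yates-
    corrected 2x2 test. ``test_used`` follows the small-sample rule: Fisher
    whenever any expected cell count is below 5, chi-square otherwise.
    Degenerate margins (no variation in group membership or phenotype)
    yield p = 1 with a warning rather than an error.
    """
    flags = []
    for rec in cohort:
        f = rec.phenotypes.get(phenotype)
        if f is not None:
            flags.append((_in_group(rec, grouping, group_label), f))
    a = sum(1 for g, f in flags if g and f)
    b = sum(1 for g, f in flags if g and not f)
    c = sum(1 for g, f in flags if not g and f)
    d = sum(1 for g, f in flags if not g and not f)
    table = ((a, b), (c, d))

    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        warnings.warn(
            f"degenerate margin for {grouping}={group_label!r} x {phenotype!r}; "
            "association not testable, reporting p=1",
            stacklevel=2,
        )
        p_fisher, p_chi, test_used = 1.0, None, "fisher"
    else:
        p_fisher = _fisher_p(a, b, c, d)
        expected = stats.contingency.expected_freq(np.asarray(table, dtype=float))
        try:
            _, p_chi = chi_square_2x2(table)
        except ValueError:
            p_chi = None
        test_used = "fisher" if (expected < 5).any() or p_chi is None else "chi_square"

    p_raw = p_fisher if test_used == "fisher" else p_chi
    if adjust == "bonferroni":
        p_adj = min(1.0, p_raw * n_tests)
    elif adjust == "none":
        p_adj = p_raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return AssociationResult(
        grouping=grouping,
        group_label=group_label,
        phenotype=phenotype,
        table=table,
        test_used=test_used,
        p_fisher=p_fisher,
        p_chi_square=p_chi,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
    )


def _group_labels(cohort: Sequence[PatientRecord]) -> list[tuple[str, str]]:
    """Deterministic list of (grouping, label) pairs present in the cohort."""
    sites: set[str] = set()
    hom_sites: set[str] = set()
    patterns: set[str] = set()
    zygosities: set[str] = set()
    for rec in cohort:
        sites.update((rec.allele1, rec.allele2))
        if rec.zygosity == "homozygous":
            hom_sites.add(rec.allele1)
        patterns.add(classify_genotype(rec).mutation_type_pattern)
        zygosities.add(rec.zygosity)
    labels = [("variant_site", s) for s in sorted(sites)]
    labels += [("variant_site", f"{s} (homozygote)") for s in sorted(hom_sites)]
    labels += [("mutation_type_pattern", p) for p in sorted(patterns)]
    labels += [("zygosity", z) for z in sorted(zygosities)]
    return labels


def association_screen(
    cohort: Sequence[PatientRecord],
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Run every group-vs-rest x phenotype test in one batch.

    Groups are all variant sites (plus homozygote-only labels for sites
    with at least one homozygote), all mutation-type patterns, and both
    zygosity classes observed in the cohort. Tests where either margin is
    degenerate (e.g. the group is the whole cohort, or nobody was assessed)
    are dropped. The Bonferroni family is the set of tests actually
    performed by this invocation; results are ordered deterministically
    (grouping, label, phenotype) regardless of patient input order.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    labels = _group_labels(cohort)
    vocabulary = cohort[0].vocabulary

    # first pass: find testable combinations (non-degenerate tables)
    candidates: list[tuple[str, str, str]] = []
    for grouping, label in labels:
        for ph in vocabulary:
            flags = [
                (_in_group(rec, grouping, label), f)
                for rec in cohort
                if (f := rec.phenotypes.get(ph)) is not None
            ]
            n_in = sum(1 for g, _ in flags if g)
            n_out = len(flags) - n_in
            n_pres = sum(1 for _, f in flags if f)
            if n_in == 0 or n_out == 0 or n_pres == 0 or n_pres == len(flags):
                continue
            candidates.append((grouping, label, ph))
    if not candidates:
        warnings.warn("no testable group x phenotype combination in cohort",
                      stacklevel=2)
        return []
    m = len(candidates)
    results = [
        test_association(cohort, grouping, label, ph, adjust=adjust,
                         n_tests=m, alpha=alpha)
        for grouping, label, ph in sorted(candidates)
    ]
    return results


# ---------------------------------------------------------------------------
# TSV I/O

_PATIENT_FIXED_COLUMNS = (
    "patient_id", "allele1", "allele2",
    "mutation_type1", "mutation_type2", "zygosity",
)


def read_patient_table(
    path: str | Path, vocabulary: Sequence[str] = PHENOTYPE_VOCABULARY
) -> list[PatientRecord]:
    """Read a patient table TSV: fixed genotype columns then one {1,0,NA}
    column per phenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PATIENT_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    pheno_cols = [c for c in df.columns if c not in _PATIENT_FIXED_COLUMNS]
    records = []
    for _, row in df.iterrows():
        phenos: dict[str, bool | None] = {}
        for c in pheno_cols:
            v = row[c]
            phenos[c] = None if v in ("NA", "") else bool(int(v))
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                allele1=row["allele1"],
                allele2=row["allele2"],
                mutation_type1=row["mutation_type1"],
                mutation_type2=row["mutation_type2"],
                zygosity=row["zygosity"],
                phenotypes=phenos,
                vocabulary=tuple(vocabulary),
            )
        )
    return records


def write_patient_table(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    vocabulary = cohort[0].vocabulary if cohort else PHENOTYPE_VOCABULARY
    rows = []
    for rec in cohort:
        row = {
            "patient_id": rec.patient_id,
            "allele1": rec.allele1,
            "allele2": rec.allele2,
            "mutation_type1": rec.mutation_type1,
            "mutation_type2": rec.mutation_type2,
            "zygosity": rec.zygosity,
        }
        for ph in vocabulary:
            f = rec.phenotypes.get(ph)
            row[ph] = "NA" if f is None else str(int(f))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        rows.append(
            {
                "grouping": r.grouping,
                "group_label": r.group_label,
                "phenotype": r.phenotype,
                "group_present": a,
                "group_absent": b,
                "rest_present": c,
                "rest_absent": d,
                "test_used": r.test_used,
                "p_fisher": r.p_fisher,
                "p_chi_square": r.p_chi_square,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
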