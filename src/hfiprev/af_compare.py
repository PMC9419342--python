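"""Cross-population allele-frequency comparison, hotspot ranking, and
screening-panel coverage.

Comparisons are per-variant 2x2 chi-square tests on allele counts
(carrier vs non-carrier alleles in two populations), Bonferroni-adjusted
over the set of variants actually tested. Hotspot ranking orders a
population's variants by allele frequency; panel coverage measures what
fraction of the population's pathogenic alleles a top-k sub-panel captures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .panel_io import PopulationAFRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AFComparison",
    "chi_square_2x2",
    "compare_panel_across_populations",
    "rank_hotspots",
    "panel_coverage",
    "coverage_table",
]


@dataclass(frozen=True)
class AFComparison:
    """Result of one variant's AF comparison between two populations.

    ``table`` rows are (test population, reference population); columns are
    (pathogenic alleles, other alleles). ``direction`` reports where the
    test population sits relative to the reference when the comparison is
    significant, else ``"ns"``.
    """

    variant_id: str
    population_a: str
    population_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0 or not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("p-values must be in [0, 1]")
        if self.p_adjusted < self.p_raw:
            raise ValueError("adjusted p cannot be below raw p")
        if self.direction not in {"higher", "lower", "ns"}:
            raise ValueError(f"bad direction {self.direction!r}")


def chi_square_2x2(
    table: Sequence[Sequence[int]], continuity_correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-square test for a 2x2 count table.

    Yates continuity correction is applied by default, matching the stock
    behaviour of R's ``chisq.test`` on 2x2 tables; ``continuity_correction=
    False`` gives the uncorrected statistic. Returns ``(statistic, p)``
    with p from the chi-square distribution on 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "zero row or column margin: chi-square is undefined; "
            "use an exact test instead"
        )
    expected = stats.contingency.expected_freq(t)
    if (expected < 5).any():
        logger.info(
            "chi_square_2x2: an expected cell count is < 5; "
            "consider the exact test"
        )
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(stat), float(p)


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def compare_panel_across_populations(
    records: Sequence[PopulationAFRecord],
    reference_population: str,
    test_population: str,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    continuity_correction: bool = True,
    use_adjusted_for_direction: bool = True,
) -> list[AFComparison]:
    """Chi-square AF comparison for every variant typed in both populations.

    Variants with a record in only one of the two populations are skipped
    (and logged): an untyped variant carries no evidence of absence. The
    Bonferroni multiplier is the number of comparisons actually performed.
    ``direction`` is ``higher``/``lower`` for the *test* population relative
    to the reference when the (adjusted, by default) p crosses ``alpha``.
    """
    if adjust not in {"bonferroni", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    by_pop: dict[str, dict[str, PopulationAFRecord]] = {}
    for r in records:
        by_pop.setdefault(r.population, {})[r.variant_id] = r
    test = by_pop.get(test_population, {})
    ref = by_pop.get(reference_population, {})
    shared = sorted(set(test) & set(ref))
    skipped = sorted((set(test) | set(ref)) - set(shared))
    if skipped:
        logger.info("skipping %d variant(s) typed in only one population: %s",
                    len(skipped), skipped)
    if not shared:
        logger.warning(
            "no shared variants between %r and %r", test_population, reference_population
        )
        return []

    m = len(shared)
    out: list[AFComparison] = []
    for vid in shared:
        rt, rr = test[vid], ref[vid]
        table = (
            (rt.allele_count, rt.allele_number - rt.allele_count),
            (rr.allele_count, rr.allele_number - rr.allele_count),
        )
        tarr = np.asarray(table)
        if (tarr.sum(axis=0) == 0).any():
            # both populations have AC 0 (or AN==AC): no test possible
            stat, p = 0.0, 1.0
        else:
            stat, p = chi_square_2x2(table, continuity_correction)
        p_adj = _bonferroni(p, m) if adjust == "bonferroni" else p
        p_sig = p_adj if use_adjusted_for_direction else p
        if p_sig < alpha and rt.af != rr.af:
            direction = "higher" if rt.af > rr.af else "lower"
        else:
            direction = "ns"
        out.append(
            AFComparison(
                variant_id=vid,
                population_a=test_population,
                population_b=reference_population,
                table=table,
                statistic=stat,
                p_raw=p,
                p_adjusted=p_adj,
                direction=direction,
            )
        )
    return out


def rank_hotspots(records: Sequence[PopulationAFRecord]) -> list[PopulationAFRecord]:
    """Order one population's records by descending AF, ties by variant id.

    The total order is deterministic, so a top-k screening sub-panel is
    reproducible even with tied frequencies.
    """
    if not records:
        raise ValueError("records must be non-empty")
    pops = {r.population for r in records}
    if len(pops) != 1:
        raise ValueError(f"records span multiple populations: {sorted(pops)}")
    return sorted(records, key=lambda r: (-r.af, r.variant_id))


def panel_coverage(records: Sequence[PopulationAFRecord], top_k: int) -> float:
    """Fraction of observed pathogenic alleles captured by the k top-AF variants.

    ``sum(AC over top-k) / sum(AC over all records)`` for one population.
    Greedy top-k by AF maximises this sum, so the value is also the best
    achievable coverage with a k-variant sub-panel.
    """
    ranked = rank_hotspots(records)
    if not 1 <= top_k <= len(ranked):
        raise ValueError(f"top_k must be in [1, {len(ranked)}], got {top_k}")
    total = sum(r.allele_count for r in ranked)
    if total == 0:
        raise ValueError("all allele counts are zero; coverage undefined")
    return sum(r.allele_count for r in ranked[:top_k]) / total


def coverage_table(records: Sequence[PopulationAFRecord]) -> list[tuple[int, str, float]]:
    """Cumulative coverage per rank: (k, variant added at rank k, coverage)."""
    ranked = rank_hotspots(records)
    total = sum(r.allele_count for r in ranked)
    if total == 0:
        raise ValueError("all allele counts are zero; coverage undefined")
    out = []
    acc = 0
    for k, r in enumerate(ranked, start=1):
        acc += r.allele_count
        out.append((k, r.variant_id, acc / total))
    return out
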