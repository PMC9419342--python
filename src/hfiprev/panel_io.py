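"""Data model and I/O for a curated pathogenic-variant panel and per-population
allele-frequency tables.

The panel is the unit of screening for an autosomal-recessive disease gene:
one row per curated pathogenic / likely-pathogenic (P/LP) allele, identified
by its HGVS-style label, with a mutation-type class and a curation level.
Allele-frequency records attach gnomAD-style allele counts (AC) and allele
numbers (AN) to panel variants, one record per (variant, population) pair.
A (variant, population) pair with no record means *untyped in that
population*, which is deliberately distinct from an observed AC of 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of mutation-type classes used in panel curation.
MUTATION_TYPES = frozenset(
    {
        "missense",
        "frameshift",
        "splicing",
        "nonsense",
        "inframe_indel",
        "indel",
        "cnv",
        "stop_lost",
        "start_lost",
        "synonymous",
        "utr3",
    }
)

#: Curation levels admitted into a screening panel.
CURATION_LEVELS = frozenset({"P", "LP"})

PANEL_COLUMNS = ("id", "hgvs_c", "hgvs_p", "mutation_type", "curation")
AF_COLUMNS = ("variant_id", "population", "allele_count", "allele_number")


class PanelFormatError(ValueError):
    """Malformed panel / AF table file (missing columns, unreadable rows)."""


class PanelValidationError(ValueError):
    """Contents violate a panel invariant (vocabulary, uniqueness, bounds)."""


@dataclass(frozen=True)
class Variant:
    """One curated P/LP allele.

    HGVS strings are opaque labels here: the panel consumes them as
    identifiers and display names, never parses them.
    """

    id: str
    hgvs_c: str
    hgvs_p: str
    mutation_type: str
    curation: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelValidationError("variant id must be non-empty")
        if self.mutation_type not in MUTATION_TYPES:
            raise PanelValidationError(
                f"unknown mutation_type {self.mutation_type!r} for variant "
                f"{self.id!r}; expected one of {sorted(MUTATION_TYPES)}"
            )
        if self.curation not in CURATION_LEVELS:
            raise PanelValidationError(
                f"curation must be P or LP, got {self.curation!r} for {self.id!r}"
            )


@dataclass
class VariantPanel:
    """Ordered collection of unique curated variants."""

    variants: list[Variant]
    name: str = "panel"
    #: rows dropped at load time because curation was not P/LP
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if len(self.variants) < 1:
            raise PanelValidationError(f"panel {self.name!r} is empty")
        seen: set[str] = set()
        for v in self.variants:
            if v.id in seen:
                raise PanelValidationError(
                    f"duplicate variant id {v.id!r} in panel {self.name!r}"
                )
            seen.add(v.id)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.ids()

    def ids(self) -> set[str]:
        return {v.id for v in self.variants}

    def get(self, variant_id: str) -> Variant:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": v.id,
                    "hgvs_c": v.hgvs_c,
                    "hgvs_p": v.hgvs_p,
                    "mutation_type": v.mutation_type,
                    "curation": v.curation,
                }
                for v in self.variants
            ],
            columns=list(PANEL_COLUMNS),
        )


@dataclass(frozen=True)
class PopulationAFRecord:
    """Allele count / allele number for one variant in one population."""

    variant_id: str
    population: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise PanelValidationError(
                f"allele_number must be positive for {self.variant_id!r}"
                f"/{self.population!r}, got {self.allele_number}"
            )
        if not 0 <= self.allele_count <= self.allele_number:
            raise PanelValidationError(
                f"allele_count must satisfy 0 <= AC <= AN for "
                f"{self.variant_id!r}/{self.population!r}: "
                f"AC={self.allele_count}, AN={self.allele_number}"
            )

    @property
    def af(self) -> float:
        """Allele frequency AC/AN."""
        return self.allele_count / self.allele_number


def read_panel(path: str | Path, format: str = "tsv") -> VariantPanel:
    """Load a variant panel from a TSV file.

    Rows whose curation level is not P/LP are dropped (the count is kept on
    ``panel.n_rejected`` and logged); everything else is validated against
    the ``Variant`` invariants.
    """
    if format != "tsv":
        raise PanelFormatError(f"unsupported panel format {format!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"{path}: file is empty") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required column(s) {missing}")

    kept: list[Variant] = []
    rejected = 0
    for i, row in df.iterrows():
        if row["curation"] not in CURATION_LEVELS:
            rejected += 1
            continue
        try:
            kept.append(
                Variant(
                    id=row["id"],
                    hgvs_c=row["hgvs_c"],
                    hgvs_p=row["hgvs_p"],
                    mutation_type=row["mutation_type"],
                    curation=row["curation"],
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"{path}, row {i + 2}: {exc}") from exc
    if rejected:
        logger.info("%s: rejected %d non-P/LP row(s)", path, rejected)
    if not kept:
        raise PanelValidationError(f"{path}: no P/LP rows in panel file")
    return VariantPanel(variants=kept, name=path.stem, n_rejected=rejected)


def write_panel(panel: VariantPanel, path: str | Path) -> None:
    """Write a panel as TSV with the canonical five-column header."""
    panel.to_frame().to_csv(path, sep="\t", index=False)


def load_builtin_panel() -> VariantPanel:
    """The packaged 81-variant ALDOB P/LP panel.

    A synthetic emulation of a curated ALDOB panel: hotspot variants known
    from the literature (A338V, A150P, N120Kfs*32, ...) carry their real
    labels; the remaining rows are synthetic fillers that preserve the
    mutation-type composition of an 81-variant curation (21 missense,
    18 frameshift, 17 splicing, 12 nonsense, 5 in-frame indel, 2 indel,
    2 CNV, 1 each stop-lost / start-lost / synonymous / 3'-UTR).
    """
    with resources.as_file(
        resources.files("hfiprev.data").joinpath("aldob_panel_synthetic.tsv")
    ) as p:
        panel = read_panel(p)
    panel.name = "aldob_p_lp_panel"
    return panel


@dataclass(frozen=True)
class MutationTypeTally:
    count: int
    fraction: float
    percent: int


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def tally_mutation_types(panel: VariantPanel) -> dict[str, MutationTypeTally]:
    """Count panel variants per mutation-type class.

    Returns a mapping ordered by descending count (ties by class name) with
    raw fractions and whole-percent display values (round half away from
    zero). Counts sum to the panel size; fractions to 1.
    """
    counts: dict[str, int] = {}
    for v in panel:
        counts[v.mutation_type] = counts.get(v.mutation_type, 0) + 1
    n = len(panel)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        mt: MutationTypeTally(
            count=c, fraction=c / n, percent=_round_half_away(100.0 * c / n)
        )
        for mt, c in ordered
    }


def read_af_table(
    path: str | Path,
    panel: VariantPanel | None = None,
    strict: bool = True,
) -> list[PopulationAFRecord]:
    """Load per-population AC/AN records from TSV.

    When a panel is given, every ``variant_id`` must resolve against it;
    with ``strict=False`` unresolvable rows are skipped with a warning
    instead of raising. Pairs absent from the file stay absent — they are
    never materialised as zero counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "population": str})
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"{path}: file is empty") from exc
    missing = [c for c in AF_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required column(s) {missing}")

    known = panel.ids() if panel is not None else None
    records: list[PopulationAFRecord] = []
    for i, row in df.iterrows():
        vid = row["variant_id"]
        if known is not None and vid not in known:
            if strict:
                raise KeyError(
                    f"{path}, row {i + 2}: variant_id {vid!r} not in panel"
                )
            logger.warning("%s: skipping unknown variant_id %r", path, vid)
            continue
        try:
            records.append(
                PopulationAFRecord(
                    variant_id=vid,
                    population=row["population"],
                    allele_count=int(row["allele_count"]),
                    allele_number=int(row["allele_number"]),
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"{path}, row {i + 2}: {exc}") from exc
    return records


def write_af_table(records: Iterable[PopulationAFRecord], path: str | Path) -> None:
    """Write AC/AN records as TSV (one row per (variant, population) pair)."""
    df = af_records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def af_records_to_frame(records: Iterable[PopulationAFRecord]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": r.variant_id,
            "population": r.population,
            "allele_count": r.allele_count,
            "allele_number": r.allele_number,
            "af": r.af,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["variant_id", "population", "allele_count", "allele_number", "af"])


def filter_population(
    records: Iterable[PopulationAFRecord], population: str
) -> list[PopulationAFRecord]:
    """Records for one population, in input order."""
    return [r for r in records if r.population == population]
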