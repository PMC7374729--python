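"""Single-residue variant catalog for the 920-aa androgen receptor.

Parses variant tables, normalizes phenotype annotations, assigns protein
domains (NTD / DBD / hinge / LBD on the NM_000044.2 920-residue numbering)
and computes per-domain mutation statistics and three-way dataset-overlap
(Venn) counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AR_LENGTH",
    "AMINO_ACIDS",
    "MUTATION_CLASSES",
    "PHENOTYPES",
    "VariantRecord",
    "DomainMap",
    "DEFAULT_DOMAIN_MAP",
    "DEFAULT_COLUMN_MAP",
    "PHENOTYPE_SYNONYMS",
    "classify_phenotype",
    "classify_mutation",
    "parse_variant_table",
    "assign_domain",
    "domain_stats",
    "dataset_overlap",
    "VENN_REGIONS",
]

#: Reference protein length (NM_000044.2; poly-Q 23, poly-G 23).
AR_LENGTH = 920

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Symbols accepted in the alt slot beyond the 20 amino acids.
STOP_CODES = {"*", "X"}
FRAMESHIFT_CODES = {"FS"}

MUTATION_CLASSES = ("missense", "nonsense", "frameshift", "other")

PHENOTYPES = ("CAIS", "PAIS", "MAIS", "prostate_cancer", "POF", "none", "unknown")

#: Free-text phenotype annotation -> canonical label. Keys are matched
#: case-insensitively after stripping; extend via classify_phenotype(synonyms=...).
PHENOTYPE_SYNONYMS: dict[str, str] = {
    "cais": "CAIS",
    "complete ais": "CAIS",
    "complete androgen insensitivity": "CAIS",
    "complete androgen insensitivity syndrome": "CAIS",
    "pais": "PAIS",
    "partial ais": "PAIS",
    "partial androgen insensitivity": "PAIS",
    "partial androgen insensitivity syndrome": "PAIS",
    "partial androgen insensitive syndrome": "PAIS",
    "mais": "MAIS",
    "mild ais": "MAIS",
    "mild androgen insensitivity": "MAIS",
    "prostate cancer": "prostate_cancer",
    "prostate_cancer": "prostate_cancer",
    "pca": "prostate_cancer",
    "pof": "POF",
    "premature ovarian failure": "POF",
    "none": "none",
    "benign": "none",
    "polymorphism": "none",
    "not significant": "none",
}


@dataclass(frozen=True)
class VariantRecord:
    """One single-residue variant on the AR protein.

    The identity key is ``(position, ref_aa, alt_aa)``; dataset tags and
    phenotype labels are annotations on top of it.
    """

    position: int
    ref_aa: str
    alt_aa: str
    mutation_class: str = "missense"
    sources: frozenset[str] = frozenset()
    phenotype: str = "unknown"

    def __post_init__(self):
        if not (1 <= self.position <= AR_LENGTH):
            raise ValueError(
                f"position {self.position} outside 1..{AR_LENGTH}"
            )
        if self.ref_aa not in AMINO_ACIDS:
            raise ValueError(f"unknown reference amino acid {self.ref_aa!r}")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.mutation_class == "missense":
            if self.alt_aa not in AMINO_ACIDS:
                raise ValueError(f"unknown alternate amino acid {self.alt_aa!r}")
            if self.ref_aa == self.alt_aa:
                raise ValueError(
                    f"missense variant with identical ref and alt ({self.ref_aa})"
                )
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        object.__setattr__(self, "sources", frozenset(self.sources))

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class DomainMap:
    """Named, non-overlapping, inclusive 1-based residue intervals.

    The default partitions the full 920-aa receptor; the single linker
    residue 559 between NTD and DBD is counted with the NTD.
    """

    intervals: tuple[tuple[str, int, int], ...]
    annotations: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    offset: int = 0  # add to input positions (legacy 919-aa numbering: +1)

    def __post_init__(self):
        ordered = sorted(self.intervals, key=lambda t: t[1])
        prev_end = 0
        for name, start, end in ordered:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            if start != prev_end + 1:
                raise ValueError(
                    f"domain intervals must tile 1..{AR_LENGTH} without gaps "
                    f"or overlaps; problem at {name} [{start}, {end}]"
                )
            prev_end = end
        if prev_end != AR_LENGTH:
            raise ValueError(f"domain intervals must end at {AR_LENGTH}")
        object.__setattr__(self, "intervals", tuple(ordered))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def length(self, name: str) -> int:
        for n, start, end in self.intervals:
            if n == name:
                return end - start + 1
        raise KeyError(name)

    def assign(self, position: int) -> str:
        pos = position + self.offset
        if not (1 <= pos <= AR_LENGTH):
            raise ValueError(f"position {position} outside 1..{AR_LENGTH}")
        for name, start, end in self.intervals:
            if start <= pos <= end:
                return name
        raise AssertionError("unreachable: intervals tile the protein")


#: NTD 1-559 (incl. the 559 linker), DBD 560-620, hinge 621-690, LBD 691-920.
#: The bipartite nuclear localization signal spanning the DBD/hinge border
#: is kept as an annotation, not a domain.
DEFAULT_DOMAIN_MAP = DomainMap(
    intervals=(
        ("NTD", 1, 559),
        ("DBD", 560, 620),
        ("hinge", 621, 690),
        ("LBD", 691, 920),
    ),
    annotations={"NLS": (617, 634)},
)


def assign_domain(position: int, domain_map: DomainMap = DEFAULT_DOMAIN_MAP) -> str:
    """Map a 1-based residue position to its domain name."""
    return domain_map.assign(position)


def classify_phenotype(
    annotation: str | None,
    synonyms: Mapping[str, str] | None = None,
) -> str:
    """Normalize a free-text phenotype annotation to a canonical label.

    Unmapped annotations become ``"unknown"`` (the caller decides whether
    to log them); empty/missing input is ``"unknown"`` too.
    """
    table = dict(PHENOTYPE_SYNONYMS)
    if synonyms:
        table.update({k.strip().lower(): v for k, v in synonyms.items()})
    if annotation is None:
        return "unknown"
    text = str(annotation).strip().lower()
    if not text:
        return "unknown"
    if text in table:
        return table[text]
    # exact canonical labels pass through case-insensitively
    for canonical in PHENOTYPES:
        if text == canonical.lower():
            return canonical
    return "unknown"


def classify_mutation(ref_aa: str, alt_aa: str) -> str:
    """Infer the mutation class from the ref/alt amino-acid codes."""
    alt = alt_aa.strip().upper()
    if alt in STOP_CODES:
        return "nonsense"
    if alt in FRAMESHIFT_CODES:
        return "frameshift"
    if alt in AMINO_ACIDS:
        return "missense"
    return "other"


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "position": "position",
    "ref_aa": "ref_aa",
    "alt_aa": "alt_aa",
    "source": "source",
    "phenotype": "phenotype",
}


def parse_variant_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    phenotype_synonyms: Mapping[str, str] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Parse a TSV/CSV variant table into validated records.

    Returns ``(records, rejects)`` where *rejects* is a DataFrame with the
    original row number (1-based, excluding the header), the raw row and a
    rejection reason. accepted + rejected always equals the number of data
    rows; nothing is dropped silently.

    The delimiter is sniffed from the extension (``.tsv`` -> tab, else
    comma) unless given explicitly.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","

    records: list[VariantRecord] = []
    rejects: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = [
            col for col in (colmap["position"], colmap["ref_aa"], colmap["alt_aa"])
            if col not in reader.fieldnames
        ]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for rownum, row in enumerate(reader, start=1):
            try:
                position = int(str(row[colmap["position"]]).strip())
                ref_aa = str(row[colmap["ref_aa"]]).strip().upper()
                alt_aa = str(row[colmap["alt_aa"]]).strip().upper()
                source_raw = row.get(colmap["source"], "") or ""
                sources = frozenset(
                    s.strip() for s in str(source_raw).split(";") if s.strip()
                )
                phenotype = classify_phenotype(
                    row.get(colmap["phenotype"]), phenotype_synonyms
                )
                records.append(
                    VariantRecord(
                        position=position,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        mutation_class=classify_mutation(ref_aa, alt_aa),
                        sources=sources,
                        phenotype=phenotype,
                    )
                )
            except (ValueError, KeyError) as exc:
                rejects.append({"row": rownum, "raw": dict(row), "reason": str(exc)})
    rejects_df = pd.DataFrame(rejects, columns=["row", "raw", "reason"])
    return records, rejects_df


def domain_stats(
    catalog: Sequence[VariantRecord],
    domain_map: DomainMap = DEFAULT_DOMAIN_MAP,
) -> pd.DataFrame:
    """Per-domain mutation statistics.

    Counts distinct mutated residues and total variants per domain;
    ``fraction_mutated`` = mutated residues / domain length. The per-domain
    variant counts sum to the catalog size.
    """
    if not catalog:
        raise ValueError("empty catalog")
    mutated: dict[str, set[int]] = {name: set() for name in domain_map.names}
    counts: dict[str, int] = {name: 0 for name in domain_map.names}
    for rec in catalog:
        dom = domain_map.assign(rec.position)
        mutated[dom].add(rec.position)
        counts[dom] += 1
    rows = []
    for name in domain_map.names:
        total = domain_map.length(name)
        nres = len(mutated[name])
        rows.append(
            {
                "domain": name,
                "residues_total": total,
                "residues_mutated": nres,
                "fraction_mutated": nres / total,
                "variant_count": counts[name],
            }
        )
    return pd.DataFrame(rows)


#: The seven non-empty regions of a three-set Venn diagram, as frozensets of
#: the set labels that contain the region.
VENN_REGIONS = (
    ("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C"),
)


def dataset_overlap(
    catalogs: Mapping[str, Iterable[VariantRecord | tuple]],
) -> dict[tuple[str, ...], int]:
    """Three-way Venn region counts over variant identity keys.

    ``catalogs`` maps exactly three dataset labels to variant collections
    (records or raw ``(position, ref, alt)`` keys). Returns counts for each
    of the 7 exclusive regions, keyed by the sorted tuple of dataset labels
    whose intersection (and nothing else) the region is. Counts sum to the
    union size.
    """
    if len(catalogs) != 3:
        raise ValueError(f"need exactly 3 datasets, got {len(catalogs)}")
    keysets: dict[str, set] = {}
    for label, items in catalogs.items():
        keys = set()
        for item in items:
            keys.add(item.key if isinstance(item, VariantRecord) else tuple(item))
        keysets[label] = keys
    labels = sorted(keysets)
    universe = set().union(*keysets.values())
    counts: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            region = set.intersection(*(keysets[l] for l in combo))
            for other in labels:
                if other not in combo:
                    region -= keysets[other]
            counts[combo] = len(region)
    assert sum(counts.values()) == len(universe)
    return counts
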