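"""Allele nomenclature, reference-panel data model, panel augmentation and
feature-identity (ambiguity) grouping.

HLA alleles are named ``GENE*f1:f2[:f3[:f4]][suffix][G]`` — an uppercase locus
symbol, up to four colon-separated numeric fields (leading zeros significant
for display, not for ordering), an optional expression suffix (N, L, S, C, A,
Q) and an optional trailing ``G`` marking a G-group name (alleles identical
over the peptide-binding-domain exons, exons 2 and 3 for class I).

A :class:`ReferencePanel` holds full-length or exon-only allele sequences with
per-allele feature annotations (exon/intron/UTR spans, 0-based half-open).
Panels can be augmented with population-specific panels via
:func:`merge_panels`, and partitioned into exon-2/3 identity groups via
:func:`group_by_feature_identity` — the partition that determines which allele
pairs are inherently ambiguous to exon-2/3-only typing methods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

__all__ = [
    "AlleleName",
    "Feature",
    "AlleleSequence",
    "ReferencePanel",
    "AmbiguityGroup",
    "AlleleNameError",
    "FeatureError",
    "PanelConflictError",
    "parse_allele_name",
    "truncate_resolution",
    "merge_panels",
    "feature_subsequence",
    "group_by_feature_identity",
    "read_panel",
    "write_panel",
    "exon_only_panel",
    "EXON23",
]

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

#: Feature request for the class-I peptide-binding-domain exons.
EXON23: tuple[tuple[str, int], ...] = (("exon", 2), ("exon", 3))


class AlleleNameError(ValueError):
    """Raised when a string does not parse as an HLA allele name."""


class FeatureError(KeyError):
    """Raised when a requested feature is not annotated on an allele."""


class PanelConflictError(ValueError):
    """Raised when two panels disagree on the sequence of one allele name."""


@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele name.

    ``fields`` keeps the numeric fields as strings so leading zeros survive a
    render/parse round trip; ordering and equality of names use the numeric
    values via :meth:`sort_key`.
    """

    gene: str
    fields: tuple[str, ...]
    suffix: str = ""
    g_group: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlleleNameError("empty gene symbol")
        if not self.fields:
            raise AlleleNameError(f"{self.gene!r}: at least one field required")
        for f in self.fields:
            if not f or not f.isdigit():
                raise AlleleNameError(f"non-numeric field {f!r} in {self.gene}*")
        if self.suffix and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleNameError(f"unknown expression suffix {self.suffix!r}")

    def render(self) -> str:
        return (
            f"{self.gene}*{':'.join(self.fields)}{self.suffix}"
            f"{'G' if self.g_group else ''}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def resolution(self) -> int:
        """Number of numeric fields (1–4)."""
        return len(self.fields)

    def sort_key(self) -> tuple:
        return (self.gene, tuple(int(f) for f in self.fields), self.suffix, self.g_group)

    def __lt__(self, other: "AlleleName") -> bool:
        return self.sort_key() < other.sort_key()


_NAME_RE = re.compile(
    r"^\s*(?P<gene>[A-Z][A-Za-z0-9-]*)\*(?P<fields>\d+(?:\s*:\s*\d+)*)"
    r"\s*(?P<suffix>[NLSCAQ])?\s*(?P<g>G)?\s*$"
)


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``"A*02:15N"`` / ``"A*01:01:01G"`` style names.

    Whitespace between the numeric fields and the suffix (``"A*02:15 N"``,
    as typing reports often print it) is tolerated. Raises
    :class:`AlleleNameError` naming the offending token on malformed input.
    """
    if not text or not text.strip():
        raise AlleleNameError("empty allele name")
    if "*" not in text:
        raise AlleleNameError(f"{text!r}: missing '*' separator")
    m = _NAME_RE.match(text)
    if m is None:
        gene, _, rest = text.partition("*")
        for tok in re.split(r"[:\s]+", rest.strip()):
            if tok and not (tok.isdigit() or tok in EXPRESSION_SUFFIXES or tok == "G"):
                raise AlleleNameError(f"{text!r}: bad token {tok!r}")
        raise AlleleNameError(f"{text!r}: malformed allele name")
    fields = tuple(f.strip() for f in m.group("fields").split(":"))
    if len(fields) > 4:
        raise AlleleNameError(f"{text!r}: more than 4 fields")
    return AlleleName(
        gene=m.group("gene"),
        fields=fields,
        suffix=m.group("suffix") or "",
        g_group=m.group("g") is not None,
    )


def truncate_resolution(name: AlleleName, n_fields: int) -> AlleleName:
    """Truncate a name to its first ``n_fields`` fields (suffix retained).

    Two-field truncation maps e.g. A*26:03:01 to A*26:03, the resolution at
    which the encoded protein sequence is determined. Names with fewer fields
    are returned unchanged.
    """
    if not 1 <= n_fields <= 4:
        raise ValueError(f"n_fields must be in 1..4, got {n_fields}")
    if len(name.fields) <= n_fields:
        return name
    return replace(name, fields=name.fields[:n_fields])


@dataclass(frozen=True)
class Feature:
    """One annotated span (exon/intron/UTR) on an allele sequence.

    Coordinates are 0-based half-open on the allele's own sequence.
    """

    kind: str
    ordinal: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron", "UTR"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.ordinal < 1:
            raise ValueError("feature ordinal must be positive")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature span [{self.start}, {self.end})")


@dataclass
class AlleleSequence:
    """An allele sequence with feature annotations and a source tag.

    ``source`` distinguishes the base (database-side) panel from a
    population-specific augmentation panel; ``full_length`` is true when the
    annotations include introns, i.e. the sequence is genomic rather than
    exon-only.
    """

    name: AlleleName
    seq: str
    features: list[Feature] = field(default_factory=list)
    source: str = "base"
    full_length: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.name.render()}: empty sequence")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"{self.name.render()}: non-ACGTN characters {bad}")
        if self.source not in ("base", "population"):
            raise ValueError(f"unknown source {self.source!r}")
        self.features = sorted(self.features, key=lambda f: f.start)
        prev_end = 0
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"{self.name.render()}: feature {f.kind}{f.ordinal} exceeds sequence"
                )
            if f.start < prev_end:
                raise ValueError(f"{self.name.render()}: overlapping features")
            prev_end = f.end
        self.full_length = any(f.kind == "intron" for f in self.features)

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, kind: str, ordinal: int) -> Feature:
        for f in self.features:
            if f.kind == kind and f.ordinal == ordinal:
                return f
        raise FeatureError(f"{self.name.render()}: no {kind} {ordinal}")


def feature_subsequence(
    allele: AlleleSequence, kinds_ordinals: Sequence[tuple[str, int]]
) -> str:
    """Concatenate the requested feature subsequences in the given order.

    ``feature_subsequence(a, EXON23)`` yields the exon-2+3 sequence that
    exon-based typing chemistries read; alleles identical here are mutually
    ambiguous to those methods.
    """
    parts = []
    for kind, ordinal in kinds_ordinals:
        f = allele.feature(kind, ordinal)
        parts.append(allele.seq[f.start : f.end])
    return "".join(parts)


@dataclass
class ReferencePanel:
    """A set of allele sequences reads are aligned against.

    ``aliases`` maps names retired during panel merging (duplicate sequences)
    to the canonical name kept in the panel.
    """

    alleles: list[AlleleSequence] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [a.name.render() for a in self.alleles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate allele names in panel: {dupes}")
        for alias, target in self.aliases.items():
            if target not in set(names):
                raise ValueError(f"alias {alias!r} -> missing target {target!r}")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    @property
    def names(self) -> list[str]:
        return [a.name.render() for a in self.alleles]

    def by_name(self, name: str | AlleleName) -> AlleleSequence:
        key = name.render() if isinstance(name, AlleleName) else name
        key = self.aliases.get(key, key)
        for a in self.alleles:
            if a.name.render() == key:
                return a
        raise KeyError(f"allele {key!r} not in panel")

    def __contains__(self, name: str | AlleleName) -> bool:
        try:
            self.by_name(name)
            return True
        except KeyError:
            return False

    def genes(self) -> list[str]:
        return sorted({a.name.gene for a in self.alleles})

    def gene_alleles(self, gene: str) -> list[AlleleSequence]:
        return [a for a in self.alleles if a.name.gene == gene]


def merge_panels(base: ReferencePanel, population: ReferencePanel) -> ReferencePanel:
    """Augment a base panel with a population-specific panel.

    Population alleles whose sequence is byte-identical to a base allele of
    the same gene are deduplicated: the base name stays canonical and the
    population name is recorded as an alias. A rendered name present in both
    panels with *different* sequences is a conflict and raises
    :class:`PanelConflictError`. The operation is idempotent.
    """
    merged = [replace(a) for a in base.alleles]
    aliases = dict(base.aliases)
    by_name = {a.name.render(): a for a in merged}
    seq_index: dict[tuple[str, str], AlleleSequence] = {
        (a.name.gene, a.seq): a for a in merged
    }
    for pop in population.alleles:
        rendered = pop.name.render()
        if rendered in by_name:
            if by_name[rendered].seq != pop.seq:
                raise PanelConflictError(
                    f"{rendered}: different sequences in base "
                    f"({len(by_name[rendered].seq)} bp) and population "
                    f"({len(pop.seq)} bp) panels"
                )
            continue
        if rendered in aliases:
            continue
        dup = seq_index.get((pop.name.gene, pop.seq))
        if dup is not None:
            aliases[rendered] = dup.name.render()
            continue
        kept = replace(pop, source="population")
        merged.append(kept)
        by_name[rendered] = kept
        seq_index[(kept.name.gene, kept.seq)] = kept
    return ReferencePanel(alleles=merged, aliases=aliases)


@dataclass
class AmbiguityGroup:
    """Alleles of one gene with identical sequence over a feature set.

    With the default feature set (exons 2+3) these are the groups that
    exon-2/3-only typing cannot resolve — e.g. the C*04:01 / C*04:82
    situation, where full-length intron sequence is needed to tell the
    members apart.
    """

    gene: str
    members: frozenset[AlleleName]
    feature_key: tuple[tuple[str, int], ...] = EXON23

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ambiguity group")
        genes = {m.gene for m in self.members}
        if genes != {self.gene}:
            raise ValueError(f"members span genes {sorted(genes)}, expected {self.gene}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, name: AlleleName) -> bool:
        return name in self.members

    @property
    def smallest(self) -> AlleleName:
        return min(self.members, key=AlleleName.sort_key)


def group_by_feature_identity(
    panel: ReferencePanel,
    gene: str,
    kinds_ordinals: Sequence[tuple[str, int]] = EXON23,
) -> list[AmbiguityGroup]:
    """Partition one gene's alleles by identity over the requested features.

    Two alleles share a group iff their concatenated feature subsequences are
    byte-identical. Groups are sorted by their smallest member name.
    """
    buckets: dict[str, set[AlleleName]] = {}
    for allele in panel.gene_alleles(gene):
        key = feature_subsequence(allele, kinds_ordinals)
        buckets.setdefault(key, set()).add(allele.name)
    groups = [
        AmbiguityGroup(gene=gene, members=frozenset(m), feature_key=tuple(kinds_ordinals))
        for m in buckets.values()
    ]
    groups.sort(key=lambda g: g.smallest.sort_key())
    return groups


def exon_only_panel(panel: ReferencePanel) -> ReferencePanel:
    """Truncate every allele to its concatenated exons.

    Models a coding-only reference (the historical situation where a
    database carries no genomic sequence for an allele): exon features are
    re-annotated at their new coordinates and all intron/UTR annotation is
    dropped, so intronic variation can no longer separate alleles.
    """
    alleles = []
    for a in panel.alleles:
        exons = [f for f in a.features if f.kind == "exon"]
        if not exons:
            raise ValueError(f"{a.name.render()}: no exon annotations")
        parts, feats, cursor = [], [], 0
        for f in exons:
            seg = a.seq[f.start : f.end]
            feats.append(
                Feature(kind="exon", ordinal=f.ordinal, start=cursor, end=cursor + len(seg))
            )
            parts.append(seg)
            cursor += len(seg)
        alleles.append(
            AlleleSequence(name=a.name, seq="".join(parts), features=feats, source=a.source)
        )
    return ReferencePanel(alleles=alleles, aliases=dict(panel.aliases))


# ---------------------------------------------------------------------------
# Panel I/O: FASTA (">NAME description") plus a feature sidecar TSV with
# columns allele, kind, ordinal, start, end (0-based half-open).
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["allele", "kind", "ordinal", "start", "end"]


def read_features(path: str | Path) -> dict[str, list[Feature]]:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "kind": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature sidecar {path}: missing columns {sorted(missing)}")
    out: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.allele, []).append(
            Feature(kind=row.kind, ordinal=int(row.ordinal), start=int(row.start), end=int(row.end))
        )
    return out


def write_features(panel: ReferencePanel, path: str | Path) -> None:
    rows = [
        (a.name.render(), f.kind, f.ordinal, f.start, f.end)
        for a in panel.alleles
        for f in a.features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(
    fasta: str | Path,
    features: str | Path | None = None,
    source: str = "base",
) -> ReferencePanel:
    """Load a panel from FASTA (+ optional feature sidecar TSV)."""
    feats = read_features(features) if features is not None else {}
    alleles = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        name = parse_allele_name(rec.id)
        alleles.append(
            AlleleSequence(
                name=name,
                seq=str(rec.seq).upper(),
                features=feats.get(rec.id, []),
                source=source,
            )
        )
    return ReferencePanel(alleles=alleles)


def write_panel(
    panel: ReferencePanel,
    fasta: str | Path,
    features: str | Path | None = None,
    aliases: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(a.seq), id=a.name.render(), description=f"source={a.source}")
        for a in panel.alleles
    ]
    SeqIO.write(records, str(fasta), "fasta")
    if features is not None:
        write_features(panel, features)
    if aliases is not None:
        pd.DataFrame(
            sorted(panel.aliases.items()), columns=["alias", "canonical"]
        ).to_csv(aliases, sep="\t", index=False)
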