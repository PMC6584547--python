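"""Concordance evaluation of diploid calls against 'true' typings.

The evaluation unit is the *allele slot*: each sample contributes two slots
per gene (heterozygous or homozygous), so a gene typed in S samples has
n = 2S slots. Accuracy is the percentage of slots where the call matches the
truth under the best of the two possible slot pairings; a failed call counts
both of its slots as incorrect. Percentages are rounded half-up to one
decimal.

Besides the accuracy table, the module produces discordance listings (which
true types were miscalled as what, with counts) and an ambiguity report that
cross-references conflicting typings from two methods against the panel's
exon-2/3 identity groups — the mechanism behind classic ambiguities such as
C*04:01 vs C*04:82, which no exon-2/3-only method can separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .caller import GenotypeCall
from .panel import (
    AlleleName,
    AmbiguityGroup,
    parse_allele_name,
    truncate_resolution,
)

__all__ = [
    "TruthRecord",
    "AccuracyRow",
    "DiscordanceRecord",
    "AmbiguityReport",
    "match_genotype",
    "accuracy_table",
    "discordance_table",
    "ambiguity_report",
    "project_to_exon23",
    "round_pct",
]


@dataclass(frozen=True)
class TruthRecord:
    """The accepted ('true') diploid typing of one sample at one gene."""

    sample: str
    gene: str
    alleles: tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        if any(a.gene != self.gene for a in self.alleles):
            raise ValueError(f"{self.sample}/{self.gene}: truth alleles from another gene")


@dataclass(frozen=True)
class AccuracyRow:
    """Per-gene accuracy: n allele slots, n_correct matches, percentage."""

    dataset: str
    gene: str
    n: int
    n_correct: int
    accuracy_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n:
            raise ValueError("n_correct out of range")


@dataclass(frozen=True)
class DiscordanceRecord:
    """One (gene, true type, called type) discordance with counts.

    ``truth_count`` is the number of truth allele slots carrying the true
    type over the whole dataset; ``count`` the number of those slots
    miscalled as ``called_type`` (the string "fail" for failed calls).
    """

    gene: str
    true_type: AlleleName
    truth_count: int
    called_type: AlleleName | str
    count: int


@dataclass(frozen=True)
class AmbiguityReport:
    """One sample/gene conflict between two typing methods.

    ``same_exon23_group`` is True when the conflicting alleles sit in one
    exon-2/3 identity group (the conflict is explainable by exon-limited
    chemistry), False when they differ within exons 2/3, and None when a
    conflicting allele is absent from the panel so the question cannot be
    answered. ``resolving_call`` is this package's own call for the slot.
    """

    sample: str
    gene: str
    type_a: AlleleName
    type_b: AlleleName
    same_exon23_group: bool | None
    resolving_call: AlleleName | None


def round_pct(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pair(alleles) -> tuple[AlleleName, AlleleName]:
    a, b = alleles
    a = a if isinstance(a, AlleleName) else parse_allele_name(a)
    b = b if isinstance(b, AlleleName) else parse_allele_name(b)
    return (a, b)


def match_genotype(
    called: tuple[AlleleName, AlleleName] | None,
    truth: tuple[AlleleName, AlleleName],
) -> int:
    """Matched allele slots (0, 1 or 2) under the best slot pairing.

    Both pairs are unordered; the score is the maximum over the two ways of
    pairing called against truth slots. ``called=None`` (a failed call)
    matches 0.
    """
    truth = _pair(truth)
    if called is None:
        return 0
    called = _pair(called)
    genes = {a.gene for a in called} | {a.gene for a in truth}
    if len(genes) != 1:
        raise ValueError(f"genotypes span genes {sorted(genes)}")
    straight = (called[0] == truth[0]) + (called[1] == truth[1])
    crossed = (called[0] == truth[1]) + (called[1] == truth[0])
    return max(straight, crossed)


def _index_calls(
    calls: Iterable[GenotypeCall],
) -> dict[tuple[str, str], GenotypeCall]:
    index: dict[tuple[str, str], GenotypeCall] = {}
    for call in calls:
        key = (call.sample, call.gene)
        if key in index:
            raise ValueError(f"duplicate call for sample={call.sample} gene={call.gene}")
        index[key] = call
    return index


def _called_pair(
    call: GenotypeCall | None, resolution: int
) -> tuple[AlleleName, AlleleName] | None:
    if call is None or call.status != "called":
        return None
    return tuple(truncate_resolution(a, resolution) for a in call.alleles)


def _truth_pair(truth: TruthRecord, resolution: int) -> tuple[AlleleName, AlleleName]:
    return tuple(truncate_resolution(a, resolution) for a in truth.alleles)


def accuracy_table(
    calls: Iterable[GenotypeCall],
    truths: Iterable[TruthRecord],
    dataset: str = "",
    resolution: int = 2,
) -> list[AccuracyRow]:
    """Per-gene allele-level accuracy of ``calls`` against ``truths``.

    Every truth record contributes two slots; a missing or failed call for a
    truth record contributes zero matches. Raises on duplicate calls for one
    (sample, gene).
    """
    index = _index_calls(calls)
    per_gene: dict[str, list[int]] = {}
    for truth in truths:
        call = index.get((truth.sample, truth.gene))
        matched = match_genotype(
            _called_pair(call, resolution), _truth_pair(truth, resolution)
        )
        bucket = per_gene.setdefault(truth.gene, [0, 0])
        bucket[0] += 2
        bucket[1] += matched
    return [
        AccuracyRow(
            dataset=dataset,
            gene=gene,
            n=n,
            n_correct=n_correct,
            accuracy_pct=round_pct(n_correct, n),
        )
        for gene, (n, n_correct) in sorted(per_gene.items())
    ]


def discordance_table(
    calls: Iterable[GenotypeCall],
    truths: Iterable[TruthRecord],
    resolution: int = 2,
) -> list[DiscordanceRecord]:
    """Which true types were miscalled as what, with counts.

    For each truth record the two slots are matched greedily (best pairing,
    as in :func:`match_genotype`); unmatched truth slots yield one
    discordance each, with the leftover called slot — or "fail" — as the
    called type. Truth counts accumulate over all slots of that true type.
    """
    index = _index_calls(calls)
    truth_counts: dict[tuple[str, AlleleName], int] = {}
    discord: dict[tuple[str, AlleleName, AlleleName | str], int] = {}
    truths = list(truths)
    for truth in truths:
        for a in _truth_pair(truth, resolution):
            key = (truth.gene, a)
            truth_counts[key] = truth_counts.get(key, 0) + 1
    for truth in truths:
        t = list(_truth_pair(truth, resolution))
        call = index.get((truth.sample, truth.gene))
        c = _called_pair(call, resolution)
        if c is None:
            for a in t:
                key = (truth.gene, a, "fail")
                discord[key] = discord.get(key, 0) + 1
            continue
        c = list(c)
        straight = (c[0] == t[0]) + (c[1] == t[1])
        crossed = (c[0] == t[1]) + (c[1] == t[0])
        if crossed > straight:
            c = [c[1], c[0]]
        for called_a, true_a in zip(c, t):
            if called_a != true_a:
                key = (truth.gene, true_a, called_a)
                discord[key] = discord.get(key, 0) + 1
    records = [
        DiscordanceRecord(
            gene=gene,
            true_type=true_a,
            truth_count=truth_counts[(gene, true_a)],
            called_type=called_a,
            count=count,
        )
        for (gene, true_a, called_a), count in discord.items()
    ]
    records.sort(
        key=lambda r: (
            r.gene,
            r.true_type.sort_key(),
            (0, r.called_type.sort_key())
            if isinstance(r.called_type, AlleleName)
            else (1,),  # fail entries sort after named miscalls
        )
    )
    return records


def _group_of(
    name: AlleleName, groups: Sequence[AmbiguityGroup]
) -> AmbiguityGroup | None:
    for g in groups:
        if name in g:
            return g
    return None


def project_to_exon23(
    truth: TruthRecord, groups: Mapping[str, Sequence[AmbiguityGroup]] | Sequence[AmbiguityGroup]
) -> set[AlleleName]:
    """All panel alleles indistinguishable from the truth over exons 2+3.

    Union of the truth alleles' identity groups — what an exon-2/3-limited
    method could report for this sample. Raises KeyError when a truth allele
    is absent from the groups (i.e. from the panel).
    """
    gene_groups = groups[truth.gene] if isinstance(groups, Mapping) else groups
    out: set[AlleleName] = set()
    for a in truth.alleles:
        g = _group_of(a, gene_groups)
        if g is None:
            raise KeyError(f"{a.render()} not in any exon-2/3 group")
        out |= set(g.members)
    return out


def ambiguity_report(
    typings_a: Iterable[TruthRecord],
    typings_b: Iterable[TruthRecord],
    calls: Iterable[GenotypeCall],
    groups: Mapping[str, Sequence[AmbiguityGroup]],
    resolution: int = 2,
) -> list[AmbiguityReport]:
    """Cross-method conflict report.

    One row per (sample, gene) where the two typing methods disagree on at
    least one allele slot; the conflicting slot pair is tested for
    exon-2/3-group co-membership and this package's own call for the slot is
    attached as the tie-breaking third opinion.
    """
    call_index = _index_calls(calls)
    b_index = {(t.sample, t.gene): t for t in typings_b}
    reports: list[AmbiguityReport] = []
    for ta in typings_a:
        tb = b_index.get((ta.sample, ta.gene))
        if tb is None:
            continue
        pa = list(_truth_pair(ta, resolution))
        pb = list(_truth_pair(tb, resolution))
        straight = (pa[0] == pb[0]) + (pa[1] == pb[1])
        crossed = (pa[0] == pb[1]) + (pa[1] == pb[0])
        if crossed > straight:
            pb = [pb[1], pb[0]]
        call = call_index.get((ta.sample, ta.gene))
        called = _called_pair(call, resolution)
        for slot, (a, b) in enumerate(zip(pa, pb)):
            if a == b:
                continue
            gene_groups = groups.get(ta.gene, ())
            ga, gb = _group_of(a, gene_groups), _group_of(b, gene_groups)
            same: bool | None
            if ga is None or gb is None:
                same = None
            else:
                same = ga is gb
            resolving = None
            if called is not None:
                # the called slot matching one of the two disputed types, if any
                for cand in called:
                    if cand in (a, b):
                        resolving = cand
                        break
                else:
                    resolving = called[slot]
            reports.append(
                AmbiguityReport(
                    sample=ta.sample,
                    gene=ta.gene,
                    type_a=a,
                    type_b=b,
                    same_exon23_group=same,
                    resolving_call=resolving,
                )
            )
    reports.sort(key=lambda r: (r.sample, r.gene, r.type_a.sort_key()))
    return reports
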