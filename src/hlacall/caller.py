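"""Diploid genotype calls from per-allele depth of coverage.

For each gene the caller collapses allele depths to the reporting resolution
(2 fields by default — the resolution at which the protein sequence is
determined), ranks the collapsed names by depth, and applies a two-threshold
rule to the top two depths d1 >= d2:

* d1 below ``min_depth_frac`` x (half the genome mean depth)  -> **fail** —
  no allele carries enough coverage to support even one haplotype;
* otherwise heterozygous (top two) when d2 >= ``het_ratio`` x d1 and d2 also
  clears the minimum-depth bar; homozygous (top name twice) when the runner-up
  is too weak.

At whole-genome sequencing depth each of two heterozygous alleles carries
roughly half the gene's coverage, hence the defaults tau=0.4, delta=0.3.
Ties in depth break on the lexicographically smallest collapsed name so
calls are deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .inference import AbundanceEstimate
from .panel import AlleleName, ReferencePanel, parse_allele_name, truncate_resolution

__all__ = ["CallerParams", "GenotypeCall", "call_gene", "call_sample"]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for the depth-based diploid caller.

    het_ratio
        tau in (0,1]: minimum ratio of second to top depth for a
        heterozygous call.
    min_depth_frac
        delta > 0: fraction of half the genome mean depth an allele must
        reach to be accepted (each haplotype of a diploid contributes about
        mean/2 to its allele).
    resolution
        number of name fields for reporting (2 = protein-level).
    """

    het_ratio: float = 0.4
    min_depth_frac: float = 0.3
    resolution: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.het_ratio <= 1:
            raise ValueError("het_ratio must be in (0, 1]")
        if self.min_depth_frac <= 0:
            raise ValueError("min_depth_frac must be > 0")
        if not 1 <= self.resolution <= 4:
            raise ValueError("resolution must be in 1..4")


@dataclass(frozen=True)
class GenotypeCall:
    """One per-gene diploid call; ``alleles`` is None iff status == 'fail'.

    Equal allele names denote a homozygous call. ``support`` carries the
    depths of the chosen alleles (d1, d2).
    """

    sample: str
    gene: str
    status: str
    alleles: tuple[AlleleName, AlleleName] | None = None
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("called", "fail"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "called") != (self.alleles is not None):
            raise ValueError("alleles must be set exactly when status == 'called'")
        if self.alleles is not None and any(a.gene != self.gene for a in self.alleles):
            raise ValueError("called alleles must belong to the call's gene")

    @property
    def is_homozygous(self) -> bool:
        return self.status == "called" and self.alleles[0] == self.alleles[1]


def _as_name(allele: str | AlleleName) -> AlleleName:
    return allele if isinstance(allele, AlleleName) else parse_allele_name(allele)


def call_gene(
    depths: Mapping[str | AlleleName, float],
    genome_mean_depth: float,
    params: CallerParams | None = None,
    sample: str = "",
    gene: str | None = None,
) -> GenotypeCall:
    """Call one gene's diploid genotype from its per-allele depths.

    Depths of alleles that collapse to the same name at the reporting
    resolution are pooled *before* ranking, so support for 3rd/4th-field
    variants of one protein allele is not fragmented.
    """
    params = params or CallerParams()
    if not depths:
        raise ValueError("empty depth table")
    collapsed: dict[AlleleName, float] = {}
    genes = set()
    for allele, depth in depths.items():
        name = truncate_resolution(_as_name(allele), params.resolution)
        genes.add(name.gene)
        collapsed[name] = collapsed.get(name, 0.0) + float(depth)
    if gene is None:
        if len(genes) != 1:
            raise ValueError(f"depth table spans genes {sorted(genes)}; pass gene=")
        gene = next(iter(genes))
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")

    ranked = sorted(collapsed.items(), key=lambda kv: (-kv[1], kv[0].sort_key()))
    haploid_floor = params.min_depth_frac * genome_mean_depth / 2.0
    (top_name, d1) = ranked[0]
    (second_name, d2) = ranked[1] if len(ranked) > 1 else (top_name, 0.0)

    if d1 < haploid_floor:
        return GenotypeCall(sample=sample, gene=gene, status="fail")
    if d2 >= params.het_ratio * d1 and d2 >= haploid_floor:
        pair = tuple(sorted((top_name, second_name), key=AlleleName.sort_key))
        return GenotypeCall(
            sample=sample, gene=gene, status="called", alleles=pair, support=(d1, d2)
        )
    return GenotypeCall(
        sample=sample,
        gene=gene,
        status="called",
        alleles=(top_name, top_name),
        support=(d1, d1),
    )


def call_sample(
    est: AbundanceEstimate,
    panel: ReferencePanel,
    genome_mean_depth: float,
    params: CallerParams | None = None,
    sample: str = "",
) -> list[GenotypeCall]:
    """One :class:`GenotypeCall` per gene in the panel (deterministic).

    Genes with no abundance mass (no aligned reads) come out as ``fail``.
    """
    params = params or CallerParams()
    if est.depth is None:
        raise ValueError("estimate has no depths; run expected_depth first")
    depth_by_allele = est.as_mapping("depth")
    calls = []
    for gene in panel.genes():
        gene_depths = {
            a.name: depth_by_allele.get(a.name.render(), 0.0)
            for a in panel.gene_alleles(gene)
        }
        calls.append(
            call_gene(
                gene_depths, genome_mean_depth, params=params, sample=sample, gene=gene
            )
        )
    return calls
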