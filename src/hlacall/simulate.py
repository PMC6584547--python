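"""Synthetic panels and diploid read sets with ground truth.

The generator emulates the structure the genotyping problem actually has:
a handful of genes, each with many near-identical alleles (~2% pairwise
divergence) laid out as 8 exons embedded in ~3 kb of genomic sequence, and —
crucially — engineered *twin* allele pairs that are byte-identical across
all exons but differ in their introns. Twins reproduce the classic
exon-typing ambiguity (the C*04:01 / C*04:82 situation): an exon-limited
method cannot separate them, a full-length panel can.

Reads are substitution-error short reads drawn uniformly along each
haplotype of a diploid genotype, on the reference strand (the built-in
aligner is strand-unaware; a production mapper would handle orientation).
All sampling comes from one seeded generator in a fixed order, so panels
and read sets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evaluation import TruthRecord
from .evidence import ReadRecord
from .panel import (
    AlleleName,
    AlleleSequence,
    EXON23,
    Feature,
    ReferencePanel,
    group_by_feature_identity,
)

__all__ = [
    "PanelSpec",
    "ReadTruth",
    "SimTruth",
    "make_panel",
    "sample_genotypes",
    "simulate_reads",
    "write_fastq",
]

#: Class-I-like gene layout: 8 exons with introns between them, ~2.9 kb.
CLASS_I_LAYOUT: tuple[tuple[str, int], ...] = (
    ("exon", 73),
    ("intron", 130),
    ("exon", 270),
    ("intron", 241),
    ("exon", 276),
    ("intron", 599),
    ("exon", 276),
    ("intron", 102),
    ("exon", 117),
    ("intron", 444),
    ("exon", 33),
    ("intron", 142),
    ("exon", 48),
    ("intron", 168),
    ("exon", 5),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic reference panel.

    inter_allele_divergence
        expected per-site substitution distance between two alleles of one
        gene (default 0.02 — the same order as real class-I allele
        divergence).
    n_exon23_twins
        number of allele pairs per gene forced identical over every exon
        (hence over exons 2+3) while differing in at least one intron.
    """

    n_genes: int = 3
    alleles_per_gene: int = 20
    layout: tuple[tuple[str, int], ...] = CLASS_I_LAYOUT
    inter_allele_divergence: float = 0.02
    n_exon23_twins: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.alleles_per_gene < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.inter_allele_divergence <= 0.1:
            raise ValueError("divergence must be in (0, 0.1]")
        if self.n_exon23_twins < 0 or 2 * self.n_exon23_twins > self.alleles_per_gene:
            raise ValueError("n_exon23_twins exceeds alleles_per_gene / 2")
        if self.n_exon23_twins and not any(k == "intron" for k, _ in self.layout):
            raise ValueError("twins require introns to differ in; layout has none")
        kinds = {k for k, _ in self.layout}
        if not kinds <= {"exon", "intron", "UTR"}:
            raise ValueError(f"unknown layout kinds {sorted(kinds - {'exon','intron','UTR'})}")

    @property
    def gene_length(self) -> int:
        return sum(length for _, length in self.layout)

    def features(self) -> list[Feature]:
        feats, counters, cursor = [], {"exon": 0, "intron": 0, "UTR": 0}, 0
        for kind, length in self.layout:
            counters[kind] += 1
            feats.append(Feature(kind=kind, ordinal=counters[kind], start=cursor, end=cursor + length))
            cursor += length
        return feats


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated read."""

    sample: str
    source_allele: AlleleName
    position: int
    error_positions: tuple[int, ...]


@dataclass
class SimTruth:
    """Ground truth of a simulation: genotypes plus per-read provenance."""

    genotypes: list[TruthRecord]
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def sample_genotype(self, sample: str, gene: str) -> TruthRecord:
        for t in self.genotypes:
            if t.sample == sample and t.gene == gene:
                return t
        raise KeyError(f"no genotype for {sample}/{gene}")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently at ``rate`` (uniform over the
    three other bases); returns a new code array (0..3)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate a synthetic reference panel (deterministic given the seed).

    Per gene: an ancestral sequence is drawn, every allele derived from it
    by independent substitutions at half the target divergence (so allele
    pairs sit at the target distance). For each twin pair, the partner
    allele's exons are overwritten with the twin's exon bases and at least
    one intronic difference from the twin is enforced; the pair is named
    ``G*ff:01`` / ``G*ff:82``. All other allele pairs are checked — and if
    necessary forced — to be distinct over exons 2+3.
    """
    rng = np.random.default_rng(spec.seed)
    feats = spec.features()
    exon_mask = np.zeros(spec.gene_length, dtype=bool)
    for f in feats:
        if f.kind == "exon":
            exon_mask[f.start : f.end] = True
    intron_sites = np.flatnonzero(~exon_mask)
    exon23_sites = np.concatenate(
        [np.arange(f.start, f.end) for f in feats if f.kind == "exon" and f.ordinal in (2, 3)]
    ) if any(f.kind == "exon" and f.ordinal in (2, 3) for f in feats) else np.array([], dtype=int)

    alleles: list[AlleleSequence] = []
    half = spec.inter_allele_divergence / 2.0
    n_regular = spec.alleles_per_gene - spec.n_exon23_twins
    for g in range(spec.n_genes):
        gene = chr(ord("A") + g) if g < 26 else f"G{g+1}"
        ancestor = rng.integers(0, 4, size=spec.gene_length, dtype=np.int64)
        codes = [_mutate(ancestor, half, rng) for _ in range(n_regular)]
        # regular alleles must be pairwise distinct over exons 2+3 *before*
        # twin partners copy their exons, so forcing a difference here can
        # never break a twin pair
        if exon23_sites.size:
            for i in range(len(codes)):
                for j in range(i + 1, len(codes)):
                    while np.array_equal(codes[i][exon23_sites], codes[j][exon23_sites]):
                        site = int(rng.choice(exon23_sites))
                        codes[j][site] = (codes[j][site] + int(rng.integers(1, 4))) % 4
        # twin partners: exons copied from the twin, own intron mutations
        for t in range(spec.n_exon23_twins):
            partner = _mutate(ancestor, half, rng)
            partner[exon_mask] = codes[t][exon_mask]
            if intron_sites.size and np.array_equal(partner[intron_sites], codes[t][intron_sites]):
                site = int(rng.choice(intron_sites))
                partner[site] = (partner[site] + int(rng.integers(1, 4))) % 4
            codes.append(partner)
        for i, c in enumerate(codes):
            if i < n_regular:
                name = AlleleName(gene=gene, fields=(f"{i + 1:02d}", "01"))
            else:
                t = i - n_regular
                name = AlleleName(gene=gene, fields=(f"{t + 1:02d}", "82"))
            alleles.append(
                AlleleSequence(name=name, seq=_decode(c), features=list(feats), source="base")
            )
    panel = ReferencePanel(alleles=alleles)
    # construction is verified, never assumed
    for gene in panel.genes():
        groups = group_by_feature_identity(panel, gene, EXON23)
        n_multi = sum(1 for gr in groups if len(gr) > 1)
        if n_multi != spec.n_exon23_twins or any(len(gr) > 2 for gr in groups):
            raise AssertionError(f"twin construction failed for gene {gene}")
    return panel


def sample_genotypes(
    panel: ReferencePanel,
    n_samples: int,
    seed: int,
    twin_only: bool = False,
    sample_prefix: str = "S",
) -> list[TruthRecord]:
    """Draw diploid genotypes uniformly (with replacement) per gene.

    With ``twin_only=True`` both alleles are drawn from the members of the
    gene's exon-2/3 twin groups, producing the genotypes that exercise
    twin resolution.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for s in range(n_samples):
        sample = f"{sample_prefix}{s + 1:03d}"
        for gene in panel.genes():
            candidates = [a.name for a in panel.gene_alleles(gene)]
            if twin_only:
                groups = group_by_feature_identity(panel, gene, EXON23)
                candidates = sorted(
                    (m for gr in groups if len(gr) > 1 for m in gr.members),
                    key=AlleleName.sort_key,
                )
                if not candidates:
                    raise ValueError(f"gene {gene} has no twin alleles")
            pick = rng.integers(0, len(candidates), size=2)
            pair = tuple(
                sorted((candidates[pick[0]], candidates[pick[1]]), key=AlleleName.sort_key)
            )
            truths.append(TruthRecord(sample=sample, gene=gene, alleles=pair))
    return truths


def simulate_reads(
    panel: ReferencePanel,
    genotypes: Iterable[TruthRecord],
    coverage: float = 30.0,
    read_len: int = 100,
    err_rate: float = 0.005,
    paired: bool = False,
    seed: int = 0,
    insert_gap: int = 100,
) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate reads from every haplotype of every genotype.

    Per haplotype the read count is Poisson with mean
    ``(coverage / 2) * L / read_len`` (paired fragments count two reads),
    start positions uniform, substitution errors i.i.d. at ``err_rate`` with
    positions logged in the returned :class:`SimTruth`.
    """
    if not 0 <= err_rate < 1:
        raise ValueError("err_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genotypes = list(genotypes)
    reads: list[ReadRecord] = []
    truth = SimTruth(genotypes=genotypes)
    span = 2 * read_len + insert_gap if paired else read_len
    for rec in genotypes:
        for hap, allele_name in enumerate(rec.alleles):
            allele = panel.by_name(allele_name)
            L = len(allele.seq)
            if span > L:
                raise ValueError(
                    f"read span {span} exceeds allele {allele_name.render()} ({L} bp)"
                )
            codes = np.frombuffer(allele.seq.encode("ascii"), dtype=np.uint8)
            codes = np.searchsorted(_BASES, codes)  # works: _BASES sorted A<C<G<T
            mean_frags = (coverage / 2.0) * L / read_len / (2 if paired else 1)
            n_frags = int(rng.poisson(mean_frags))
            starts = rng.integers(0, L - span + 1, size=n_frags)
            for serial, start in enumerate(map(int, starts)):
                segments = (
                    [(start, 1), (start + read_len + insert_gap, 2)]
                    if paired
                    else [(start, 0)]
                )
                rid = f"{rec.sample}:{rec.gene}:{hap}:{serial}"
                for seg_start, mate in segments:
                    piece = codes[seg_start : seg_start + read_len].copy()
                    err_pos = np.flatnonzero(rng.random(read_len) < err_rate)
                    if err_pos.size:
                        piece[err_pos] = (
                            piece[err_pos] + rng.integers(1, 4, size=err_pos.size)
                        ) % 4
                    reads.append(
                        ReadRecord(id=rid, seq=_decode(piece), mate=mate)
                    )
                    truth.reads[f"{rid}/{mate}" if paired else rid] = ReadTruth(
                        sample=rec.sample,
                        source_allele=allele_name,
                        position=seg_start,
                        error_positions=tuple(int(p) for p in err_pos),
                    )
    return reads, truth


def write_fastq(reads: Sequence[ReadRecord], path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate else ""
            fh.write(f"@{r.id}{suffix}\n{r.seq}\n+\n{qual_char * len(r.seq)}\n")
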