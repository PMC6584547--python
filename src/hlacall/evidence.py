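"""Per-read, per-allele alignment evidence.

The genotyping model consumes a sparse matrix of alignment log-likelihoods:
one row per sequenced fragment, one column per panel allele, populated for
every allele the fragment aligns to (primary *and* secondary placements —
multi-mapping is the whole point in the HLA cluster, where alleles of one
gene are >95% identical). Likelihoods use a flat substitution error model:

    log L = matches * ln(1 - eps) + mismatches * ln(eps / 3)

Evidence can come from a SAM/BAM produced by any external mapper
(:func:`evidence_from_sam`), or from the built-in exact-seed ungapped
aligner (:func:`naive_align` / :func:`align_reads`) so tests and simulations
need no mapper on the PATH.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import ReferencePanel

__all__ = [
    "ReadRecord",
    "AlignmentCandidate",
    "EvidenceMatrix",
    "alignment_loglik",
    "naive_align",
    "align_reads",
    "evidence_from_sam",
    "PanelIndex",
]

logger = logging.getLogger(__name__)

DEFAULT_EPS = 0.01
DEFAULT_MIN_ALIGNED_FRAC = 0.9
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_SEED_K = 16


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced read (optionally one mate of a pair)."""

    id: str
    seq: str
    quals: tuple[float, ...] | None = None  # per-base error probabilities
    mate: int = 0  # 1, 2 or 0 for unpaired

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quals is not None:
            if len(self.quals) != len(self.seq):
                raise ValueError(f"read {self.id!r}: quals/seq length mismatch")
            if any(not 0 < q < 1 for q in self.quals):
                raise ValueError(f"read {self.id!r}: error probabilities must be in (0,1)")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentCandidate:
    """One placement of a read against one allele."""

    read_id: str
    allele_index: int
    matches: int
    mismatches: int
    aligned_length: int
    log_lik: float
    position: int = -1  # 0-based start on the allele, -1 if unknown

    def __post_init__(self) -> None:
        if self.matches + self.mismatches > self.aligned_length:
            raise ValueError("matches + mismatches exceed aligned length")
        if self.log_lik > 1e-12:
            raise ValueError("log-likelihood must be <= 0")


def alignment_loglik(matches: int, mismatches: int, eps: float = DEFAULT_EPS) -> float:
    """Log-likelihood of an ungapped alignment under a flat error rate.

    Each matching base contributes ``ln(1-eps)``, each mismatching base
    ``ln(eps/3)`` (a sequencing error hits one specific wrong base out of
    three). Strictly decreasing in ``mismatches`` at fixed aligned length.
    """
    if not 0 < eps < 1:
        raise ValueError(f"eps must be in (0,1), got {eps}")
    if matches < 0 or mismatches < 0:
        raise ValueError("negative match/mismatch count")
    return matches * math.log1p(-eps) + mismatches * math.log(eps / 3.0)


@dataclass
class EvidenceMatrix:
    """Sparse fragment x allele log-likelihood matrix.

    ``entries`` maps ``(fragment_id, allele_name)`` to a finite log-likelihood;
    every fragment listed in ``reads`` has at least one entry. ``read_bases``
    records the aligned base count per fragment, used for depth-of-coverage
    normalization downstream.
    """

    reads: list[str]
    alleles: list[str]
    entries: dict[tuple[str, str], float]
    read_bases: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        covered = {r for r, _ in self.entries}
        empty = [r for r in self.reads if r not in covered]
        if empty:
            raise ValueError(f"{len(empty)} fragments with no evidence entries")
        for key, ll in self.entries.items():
            if not math.isfinite(ll):
                raise ValueError(f"non-finite log-likelihood at {key}")

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def to_dense(self) -> np.ndarray:
        """(N, M) array of log-likelihoods, ``-inf`` where absent."""
        ridx = {r: i for i, r in enumerate(self.reads)}
        aidx = {a: j for j, a in enumerate(self.alleles)}
        dense = np.full((len(self.reads), len(self.alleles)), -np.inf)
        for (r, a), ll in self.entries.items():
            dense[ridx[r], aidx[a]] = ll
        return dense

    def bases_per_read(self) -> np.ndarray:
        return np.array([self.read_bases.get(r, 0) for r in self.reads], dtype=float)

    def to_frame(self):
        import pandas as pd

        rows = sorted(self.entries.items())
        return pd.DataFrame(
            [(r, a, ll) for (r, a), ll in rows],
            columns=["read_id", "allele", "log_lik"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Built-in aligner: exact k-mer seeding + ungapped extension.
# ---------------------------------------------------------------------------


class PanelIndex:
    """Exact k-mer index over a panel for the built-in ungapped aligner.

    Seeding takes non-overlapping k-mers along the read; each seed hit
    proposes a diagonal (allele, read-start offset), and every proposed
    placement fully contained in the allele is scored by vectorized
    mismatch counting. Gapped placements are out of scope: the evidence
    model is substitution-only.
    """

    def __init__(self, panel: ReferencePanel, k: int = DEFAULT_SEED_K):
        self.panel = panel
        self.k = k
        self.names = panel.names
        self.encoded = [
            np.frombuffer(a.seq.encode("ascii"), dtype=np.uint8) for a in panel
        ]
        self.lengths = np.array([len(a.seq) for a in panel])
        index: dict[bytes, list[tuple[int, int]]] = {}
        for ai, a in enumerate(panel):
            s = a.seq.encode("ascii")
            for pos in range(0, len(s) - k + 1):
                index.setdefault(s[pos : pos + k], []).append((ai, pos))
        self._index = index

    def candidate_placements(self, seq: str) -> set[tuple[int, int]]:
        s = seq.encode("ascii")
        k = self.k
        placements: set[tuple[int, int]] = set()
        offsets = list(range(0, max(len(s) - k, 0) + 1, k))
        for off in offsets:
            for ai, pos in self._index.get(s[off : off + k], ()):
                start = pos - off
                if 0 <= start and start + len(s) <= self.lengths[ai]:
                    placements.add((ai, start))
        return placements

    def align(
        self,
        read: ReadRecord,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        eps: float = DEFAULT_EPS,
    ) -> list[AlignmentCandidate]:
        renc = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
        L = len(renc)
        best: dict[int, tuple[int, int]] = {}  # allele -> (mismatches, start)
        for ai, start in self.candidate_placements(read.seq):
            mm = int(np.count_nonzero(self.encoded[ai][start : start + L] != renc))
            if mm <= max_mismatches and (ai not in best or (mm, start) < best[ai]):
                best[ai] = (mm, start)
        return [
            AlignmentCandidate(
                read_id=read.id,
                allele_index=ai,
                matches=L - mm,
                mismatches=mm,
                aligned_length=L,
                log_lik=alignment_loglik(L - mm, mm, eps),
                position=start,
            )
            for ai, (mm, start) in sorted(best.items())
        ]


def _panel_index(panel: ReferencePanel, k: int = DEFAULT_SEED_K) -> PanelIndex:
    cached = getattr(panel, "_kmer_index", None)
    if cached is None or cached.k != k:
        cached = PanelIndex(panel, k=k)
        panel._kmer_index = cached  # type: ignore[attr-defined]
    return cached


def naive_align(
    read: ReadRecord,
    panel: ReferencePanel,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    eps: float = DEFAULT_EPS,
) -> list[AlignmentCandidate]:
    """All ungapped placements of ``read`` with ≤ ``max_mismatches``, one best
    per allele. Requires the read to fit inside the alleles it hits; an empty
    list means the read has no panel origin at this stringency."""
    shortest = min(len(a.seq) for a in panel)
    if len(read.seq) > shortest:
        raise ValueError(
            f"read length {len(read.seq)} exceeds shortest allele ({shortest} bp)"
        )
    return _panel_index(panel).align(read, max_mismatches=max_mismatches, eps=eps)


def align_reads(
    reads: Iterable[ReadRecord],
    panel: ReferencePanel,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    eps: float = DEFAULT_EPS,
) -> EvidenceMatrix:
    """Run the built-in aligner over a read set and assemble evidence.

    Mates of a pair (same id, mate 1/2) aligning to the same allele are
    combined into one fragment row by summing their log-likelihoods; a mate
    without a placement on a given allele simply contributes nothing there.
    Reads with no placements at all are dropped (count logged).
    """
    index = _panel_index(panel)
    per_fragment: dict[str, dict[str, float]] = {}
    frag_bases: dict[str, int] = {}
    n_dropped = 0
    for read in reads:
        cands = index.align(read, max_mismatches=max_mismatches, eps=eps)
        if not cands:
            n_dropped += 1
            continue
        frag = read.id
        row = per_fragment.setdefault(frag, {})
        for c in cands:
            name = index.names[c.allele_index]
            row[name] = row.get(name, 0.0) + c.log_lik
        frag_bases[frag] = frag_bases.get(frag, 0) + len(read.seq)
    if n_dropped:
        logger.info("align_reads: dropped %d reads with no placements", n_dropped)
    return _assemble(per_fragment, frag_bases, panel.names)


def _assemble(
    per_fragment: dict[str, dict[str, float]],
    frag_bases: dict[str, int],
    allele_names: Sequence[str],
) -> EvidenceMatrix:
    frags = sorted(per_fragment)
    entries = {
        (frag, name): ll
        for frag in frags
        for name, ll in per_fragment[frag].items()
    }
    return EvidenceMatrix(
        reads=frags,
        alleles=list(allele_names),
        entries=entries,
        read_bases={f: frag_bases[f] for f in frags},
    )


# ---------------------------------------------------------------------------
# SAM/BAM ingestion.
# ---------------------------------------------------------------------------


def _aligned_and_mismatches(rec) -> tuple[int, int]:
    """Aligned length (M/=/X columns) and substitution count for one record.

    Mismatches come from the NM tag when present (indel bases subtracted so
    NM reduces to substitutions); otherwise they are recomputed from the MD
    tag. Records with neither are scored as error-free over their aligned
    span (a warning is logged once).
    """
    cigar = rec.cigartuples
    if cigar is None:
        raise ValueError(f"{rec.query_name}: missing CIGAR")
    aligned = sum(length for op, length in cigar if op in (0, 7, 8))  # M, =, X
    indel_bases = sum(length for op, length in cigar if op in (1, 2))  # I, D
    if rec.has_tag("NM"):
        mm = max(int(rec.get_tag("NM")) - indel_bases, 0)
    elif rec.has_tag("MD"):
        import re as _re

        md = rec.get_tag("MD")
        mm = sum(1 for tok in _re.findall(r"[A-Z]|\^[A-Z]+", md) if not tok.startswith("^"))
    else:
        logger.warning("%s: no NM/MD tag; assuming zero mismatches", rec.query_name)
        mm = 0
    return aligned, mm


def evidence_from_sam(
    alignments,
    panel: ReferencePanel,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    eps: float = DEFAULT_EPS,
) -> EvidenceMatrix:
    """Build the evidence matrix from SAM/BAM alignments against the panel.

    ``alignments`` is a path or an iterable of :class:`pysam.AlignedSegment`.
    Primary and secondary alignments both count; supplementary records and
    unmapped records are skipped. Alignments covering less than
    ``min_aligned_frac`` of the read are dropped as spurious partial hits
    (the HLA cluster is full of them). Mates of one template aligning to the
    same allele contribute a summed log-likelihood on one fragment row.
    """
    import pysam

    close = None
    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable = handle
        close = handle
    else:
        records = alignments

    panel_names = set(panel.names) | set(panel.aliases)
    # best log-likelihood per (fragment, mate, allele); mates sum afterwards
    per_mate: dict[tuple[str, int], dict[str, float]] = {}
    mate_lengths: dict[tuple[str, int], int] = {}
    n_dropped_frac = 0
    n_skipped_cigar = 0
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            target = rec.reference_name
            if target not in panel_names:
                raise KeyError(f"alignment target {target!r} not in panel")
            target = panel.aliases.get(target, target)
            try:
                aligned, mm = _aligned_and_mismatches(rec)
            except ValueError as exc:
                logger.warning("skipping record: %s", exc)
                n_skipped_cigar += 1
                continue
            read_len = rec.query_length or rec.infer_read_length() or aligned
            if aligned < min_aligned_frac * read_len:
                n_dropped_frac += 1
                continue
            ll = alignment_loglik(aligned - mm, mm, eps)
            mate = 2 if rec.is_read2 else 1
            key = (rec.query_name, mate)
            row = per_mate.setdefault(key, {})
            if target not in row or ll > row[target]:
                row[target] = ll
            mate_lengths[key] = max(mate_lengths.get(key, 0), read_len)
    finally:
        if close is not None:
            close.close()

    if n_dropped_frac:
        logger.info(
            "evidence_from_sam: dropped %d alignments under min_aligned_frac=%g",
            n_dropped_frac,
            min_aligned_frac,
        )
    per_fragment: dict[str, dict[str, float]] = {}
    frag_bases: dict[str, int] = {}
    for (frag, _mate), row in per_mate.items():
        out = per_fragment.setdefault(frag, {})
        for target, ll in row.items():
            out[target] = out.get(target, 0.0) + ll
    for (frag, _mate), length in mate_lengths.items():
        frag_bases[frag] = frag_bases.get(frag, 0) + length
    return _assemble(per_fragment, frag_bases, panel.names)
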