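"""End-to-end orchestration: reads -> evidence -> abundances -> calls -> reports.

Glue over the other modules; nothing here introduces new modelling. The
``end_to_end_fixture`` entry point builds a complete synthetic experiment
(panel, diploid samples, reads, calls, evaluation tables) from a seed, and
is what the command-line interface, the test-suite and the acceptance
script all run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .caller import CallerParams, GenotypeCall, call_sample
from .evaluation import (
    AccuracyRow,
    DiscordanceRecord,
    TruthRecord,
    accuracy_table,
    discordance_table,
)
from .evidence import ReadRecord, align_reads
from .inference import AbundanceEstimate, MixtureConfig, expected_depth, vb_fit
from .panel import ReferencePanel, write_panel
from .simulate import PanelSpec, SimTruth, make_panel, sample_genotypes, simulate_reads, write_fastq

__all__ = ["PipelineResult", "type_sample", "run_pipeline", "end_to_end_fixture"]

#: Mismatch cap for the built-in aligner in pipeline context: generous enough
#: to keep cross-allele candidates (the mixture needs them) and reads with a
#: few sequencing errors.
PIPELINE_MAX_MISMATCHES = 4


def type_sample(
    reads: Sequence[ReadRecord],
    panel: ReferencePanel,
    genome_mean_depth: float,
    cfg: MixtureConfig | None = None,
    params: CallerParams | None = None,
    sample: str = "",
    max_mismatches: int = PIPELINE_MAX_MISMATCHES,
) -> tuple[list[GenotypeCall], AbundanceEstimate]:
    """Type one sample's reads: align, fit the mixture, compute depths, call."""
    evidence = align_reads(reads, panel, max_mismatches=max_mismatches)
    est = vb_fit(evidence, cfg or MixtureConfig())
    expected_depth(est, evidence, panel)
    calls = call_sample(est, panel, genome_mean_depth, params=params, sample=sample)
    return calls, est


@dataclass
class PipelineResult:
    """Everything one synthetic experiment produced."""

    panel: ReferencePanel
    truths: list[TruthRecord]
    calls: list[GenotypeCall]
    accuracy: list[AccuracyRow]
    discordance: list[DiscordanceRecord]
    estimates: dict[str, AbundanceEstimate] = field(default_factory=dict)
    sim_truth: SimTruth | None = None

    @property
    def allele_accuracy_pct(self) -> float:
        n = sum(row.n for row in self.accuracy)
        n_correct = sum(row.n_correct for row in self.accuracy)
        from .evaluation import round_pct

        return round_pct(n_correct, n)

    @property
    def called_fraction(self) -> float:
        if not self.calls:
            return 0.0
        return sum(c.status == "called" for c in self.calls) / len(self.calls)


def run_pipeline(
    panel: ReferencePanel,
    truths: Iterable[TruthRecord],
    coverage: float = 30.0,
    read_len: int = 100,
    err_rate: float = 0.005,
    seed: int = 0,
    cfg: MixtureConfig | None = None,
    params: CallerParams | None = None,
    call_panel: ReferencePanel | None = None,
    dataset: str = "simulated",
) -> PipelineResult:
    """Simulate reads for given truths and genotype every sample.

    ``call_panel`` lets the calling step use a different panel than the one
    reads were simulated from (e.g. an exon-only truncation, to measure what
    full-length sequence buys).
    """
    truths = list(truths)
    reads, sim_truth = simulate_reads(
        panel, truths, coverage=coverage, read_len=read_len, err_rate=err_rate, seed=seed
    )
    target = call_panel if call_panel is not None else panel
    by_sample: dict[str, list[ReadRecord]] = {}
    for r in reads:
        by_sample.setdefault(r.id.split(":", 1)[0], []).append(r)

    calls: list[GenotypeCall] = []
    estimates: dict[str, AbundanceEstimate] = {}
    for sample in sorted(by_sample):
        sample_calls, est = type_sample(
            by_sample[sample],
            target,
            genome_mean_depth=coverage,
            cfg=cfg,
            params=params,
            sample=sample,
        )
        calls.extend(sample_calls)
        estimates[sample] = est
    accuracy = accuracy_table(calls, truths, dataset=dataset)
    discordance = discordance_table(calls, truths)
    return PipelineResult(
        panel=target,
        truths=truths,
        calls=calls,
        accuracy=accuracy,
        discordance=discordance,
        estimates=estimates,
        sim_truth=sim_truth,
    )


def end_to_end_fixture(
    spec: PanelSpec | None = None,
    n_samples: int = 50,
    coverage: float = 30.0,
    seed: int = 7,
    err_rate: float = 0.005,
    read_len: int = 100,
    twin_only: bool = False,
    out_dir: str | Path | None = None,
    call_panel: ReferencePanel | None = None,
) -> PipelineResult:
    """Build a full synthetic experiment from a seed.

    Panel generation, genotype sampling and read simulation draw from seeds
    derived deterministically from ``seed``. With ``out_dir`` set, writes
    panel FASTA + feature sidecar, reads FASTQ, truth TSV and the calls/
    accuracy/discordance tables — everything the CLI consumes.
    """
    spec = spec or PanelSpec(seed=seed)
    panel = make_panel(spec)
    truths = sample_genotypes(panel, n_samples, seed=seed + 1, twin_only=twin_only)
    result = run_pipeline(
        panel,
        truths,
        coverage=coverage,
        read_len=read_len,
        err_rate=err_rate,
        seed=seed + 2,
        call_panel=call_panel,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(panel, out / "panel.fa", features=out / "features.tsv")
        reads, _ = simulate_reads(
            panel, truths, coverage=coverage, read_len=read_len, err_rate=err_rate, seed=seed + 2
        )
        write_fastq(reads, out / "reads.fastq")
        _write_truth_tsv(truths, out / "truth.tsv")
        write_calls_tsv(result.calls, out / "calls.tsv")
        _write_accuracy_tsv(result.accuracy, out / "accuracy.tsv")
        _write_discordance_tsv(result.discordance, out / "discordance.tsv")
    return result


# ---------------------------------------------------------------------------
# TSV writers shared with the CLI.
# ---------------------------------------------------------------------------


def _write_truth_tsv(truths: Iterable[TruthRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [
        (t.sample, t.gene, t.alleles[0].render(), t.alleles[1].render()) for t in truths
    ]
    pd.DataFrame(rows, columns=["sample", "gene", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    import pandas as pd

    from .panel import parse_allele_name

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        TruthRecord(
            sample=row.sample,
            gene=row.gene,
            alleles=(parse_allele_name(row.allele1), parse_allele_name(row.allele2)),
        )
        for row in df.itertuples(index=False)
    ]


def write_calls_tsv(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        if c.status == "called":
            a1, a2 = (a.render() for a in c.alleles)
            d1, d2 = c.support
        else:
            a1 = a2 = "fail"
            d1 = d2 = float("nan")
        rows.append((c.sample, c.gene, c.status, a1, a2, d1, d2))
    pd.DataFrame(
        rows, columns=["sample", "gene", "status", "allele1", "allele2", "depth1", "depth2"]
    ).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[GenotypeCall]:
    import pandas as pd

    from .panel import parse_allele_name

    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "status": str})
    calls = []
    for row in df.itertuples(index=False):
        if row.status == "called":
            calls.append(
                GenotypeCall(
                    sample=row.sample,
                    gene=row.gene,
                    status="called",
                    alleles=(parse_allele_name(row.allele1), parse_allele_name(row.allele2)),
                    support=(float(row.depth1), float(row.depth2)),
                )
            )
        else:
            calls.append(GenotypeCall(sample=row.sample, gene=row.gene, status="fail"))
    return calls


def _write_accuracy_tsv(rows: Iterable[AccuracyRow], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.dataset, r.gene, r.n, r.n_correct, r.accuracy_pct) for r in rows],
        columns=["dataset", "gene", "n", "n_correct", "accuracy_pct"],
    ).to_csv(path, sep="\t", index=False)


def _write_discordance_tsv(records: Iterable[DiscordanceRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (
                r.gene,
                r.true_type.render(),
                r.truth_count,
                r.called_type.render() if not isinstance(r.called_type, str) else r.called_type,
                r.count,
            )
            for r in records
        ],
        columns=["gene", "true_type", "truth_count", "called_type", "count"],
    ).to_csv(path, sep="\t", index=False)
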