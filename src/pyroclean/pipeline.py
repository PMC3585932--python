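"""End-to-end orchestration of the denoising pipeline with per-step accounting.

Runs: read preparation (primer trim, length filter, dereplication), then
homopolymer correction against the consensus reference, then the
consensus-divergence filter (singleton drop, trim, ambiguity-consistent
merge), then the frequency filter, and finally artifact flagging.  Each step
appends a row to an accounting table (step, total reads, unique reads, % of
raw) whose percentages are computed against the reads above the minimum
length, on unique-sequence volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .artifacts import ArtifactFlag, flag_compensated_indels, flag_putative_numts
from .cluster_filter import ClusterParams, RemovalRecord, frequency_filter
from .corrector import CorrectionEvent, CorrectionParams, correct_uniques
from .iupac import ConsensusReference
from .read_prep import (
    Read,
    UniqueSequence,
    dereplicate,
    filter_and_truncate,
    trim_forward_primer,
)
from .reference_filter import consensus_filter, drop_low_count, merge_ambiguity_consistent

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage could not run on the given inputs."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters.

    The defaults are the test-pool parameterisation: minimum read length
    170, truncation at 300, singleton exclusion, at most 1 mismatch to the
    consensus over the first 220 bases, and step-5 removal of sequences both
    <=1% divergent from and <10% as frequent as a retained sequence.
    """

    primer: str | None = None
    trim_length: int | str = "full"
    primer_max_mismatch: int = 0
    min_length: int = 170
    max_length: int = 300
    min_count: int = 2
    max_mismatch: int = 1
    trim_to: int = 220
    max_divergence: float = 0.01
    min_freq_ratio: float = 0.10
    consensus_offset: int = 0
    edit_cap: int = 20
    flag_min_run: int = 3
    numt_max_divergence: float = 0.10
    numt_max_freq_ratio: float = 0.10
    drop_flagged: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    uniques: list[UniqueSequence]
    accounting: pd.DataFrame
    flags: list[ArtifactFlag]
    events: list[CorrectionEvent]
    removals: list[RemovalRecord]
    stages: dict[str, list[UniqueSequence]] = field(default_factory=dict)
    n_capped: int = 0


def _stage_row(step: str, uniques: Sequence[UniqueSequence], denom_unique: int):
    total = sum(u.count for u in uniques)
    pct = 100.0 * len(uniques) / denom_unique if denom_unique else float("nan")
    return {
        "step": step,
        "total_reads": total,
        "unique_reads": len(uniques),
        "pct_of_raw": round(pct, 2),
    }


def run_all(
    reads: Sequence[Read],
    consensus: ConsensusReference,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute steps 1-5 plus artifact flagging on in-memory reads."""
    cfg = config or PipelineConfig()
    if not reads:
        raise PipelineError("input FASTA contains no reads")
    if cfg.consensus_offset != consensus.offset:
        consensus = ConsensusReference(consensus.sequence, cfg.consensus_offset)

    # Step 1: primer trim, length filter/truncate, dereplicate
    if cfg.primer:
        trimmed = [
            trim_forward_primer(
                r, cfg.primer, cfg.trim_length, cfg.primer_max_mismatch
            )
            for r in reads
        ]
        kept = [r for r in trimmed if r is not None]
        n_primer_dropped = len(reads) - len(kept)
    else:
        kept, n_primer_dropped = list(reads), 0
    filtered = filter_and_truncate(kept, cfg.min_length, cfg.max_length)
    if not filtered:
        raise PipelineError(
            f"no reads of length >= {cfg.min_length} after primer trimming"
        )
    step1 = dereplicate(filtered)
    denom_unique = len(step1)

    rows = [
        {
            "step": "raw",
            "total_reads": len(reads),
            "unique_reads": len({r.sequence for r in reads}),
            "pct_of_raw": float("nan"),
        },
        _stage_row("step1_unique", step1, denom_unique),
    ]

    # Step 3: homopolymer correction (weights carried, collisions merged)
    step3, events, n_capped = correct_uniques(
        step1,
        consensus,
        CorrectionParams(max_length=cfg.max_length, edit_cap=cfg.edit_cap),
    )
    rows.append(_stage_row("step3_corrected", step3, denom_unique))

    # Step 4: singleton drop, consensus filter + trim, ambiguity merge
    surviving, _low = drop_low_count(step3, cfg.min_count)
    retained, _div = consensus_filter(
        surviving, consensus, cfg.max_mismatch, cfg.trim_to
    )
    step4 = merge_ambiguity_consistent(retained)
    rows.append(_stage_row("step4_filtered", step4, denom_unique))

    # Step 5: frequency filter within the pool
    step5, removals = frequency_filter(
        step4, ClusterParams(cfg.max_divergence, cfg.min_freq_ratio)
    )
    rows.append(_stage_row("step5_cluster_filtered", step5, denom_unique))

    # Step 6 support: advisory flags; removal only on request
    flags = flag_compensated_indels(step5, cfg.flag_min_run)
    flags += flag_putative_numts(
        step5, cfg.numt_max_divergence, cfg.numt_max_freq_ratio
    )
    final = step5
    if cfg.drop_flagged and flags:
        flagged_names = {f.name for f in flags}
        final = [u for u in step5 if u.name not in flagged_names]
        rows.append(_stage_row("step6_flag_dropped", final, denom_unique))

    accounting = pd.DataFrame(rows)
    accounting.attrs["primer_dropped"] = n_primer_dropped
    return PipelineResult(
        uniques=final,
        accounting=accounting,
        flags=flags,
        events=events,
        removals=removals,
        stages={
            "step1": step1,
            "step3": step3,
            "step4": step4,
            "step5": step5,
            "final": final,
        },
        n_capped=n_capped,
    )
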