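"""The removal-method contract shared by all HRR approaches.

A removal method flags individual reads as host; the post-processing
singleton rule then discards the un-flagged mate of any flagged read, so only
intact non-host pairs are retained. Every input read therefore ends in
exactly one of three bins: retained (both mates kept), removed (flagged), or
singleton-removed (kept by the tool but orphaned).

Three method frontends are provided:

* :func:`apply_singleton_rule` — the pair-level post-processing rule itself;
* :func:`simulated_remove` — a configurable test double that flags reads by
  their provenance class at specified per-read rates, enabling exact
  parameter-recovery tests of the evaluation engine;
* :func:`external_adapter` — a subprocess adapter that reconciles a real
  tool's retained-read output against the input names (tolerating whitespace
  truncation and /1 /2 suffixes) without ever inspecting labels.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from hrrbench.sequence_io import ReadPair, SourceClass, read_pairs, write_pairs

__all__ = [
    "PairingMode",
    "SimulatedRemoverParams",
    "RemovalResult",
    "apply_singleton_rule",
    "removal_flags",
    "simulated_remove",
    "external_adapter",
]


class PairingMode(Enum):
    """PER_READ flags each mate independently (the "unpaired mode" analogue);
    PER_PAIR draws a single Bernoulli per pair."""

    PER_READ = "PER_READ"
    PER_PAIR = "PER_PAIR"


@dataclass(frozen=True)
class SimulatedRemoverParams:
    """Per-class removal probabilities for the simulated remover.

    ``sensitivity`` is the per-HOST-read flag probability,
    ``false_positive_rate`` the per-TARGET-read flag probability, and
    ``contaminant_removal_rate`` (default: the false-positive rate) the
    per-CONTAMINANT-read flag probability — a separate knob so
    false-negative sets rich in contaminants can be constructed.
    """

    sensitivity: float
    false_positive_rate: float = 0.0
    contaminant_removal_rate: Optional[float] = None
    pairing_mode: PairingMode = PairingMode.PER_READ
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contaminant_removal_rate is not None and not (
            0.0 <= self.contaminant_removal_rate <= 1.0
        ):
            raise ValueError("contaminant_removal_rate must be in [0, 1]")

    def rate_for(self, source_class: SourceClass) -> float:
        if source_class is SourceClass.HOST:
            return self.sensitivity
        if source_class is SourceClass.CONTAMINANT:
            return (
                self.contaminant_removal_rate
                if self.contaminant_removal_rate is not None
                else self.false_positive_rate
            )
        return self.false_positive_rate


@dataclass
class RemovalResult:
    """Read fates assigned by one removal method on one input.

    Every input read appears in exactly one of ``retained_pairs`` (×2 mates),
    ``removed_reads``, or ``singleton_removed``.
    """

    retained_pairs: Set[str]
    removed_reads: Set[Tuple[str, int]]
    singleton_removed: Set[Tuple[str, int]]
    method_id: str = "unknown"
    reference_id: str = "unknown"

    @property
    def n_reads(self) -> int:
        return 2 * len(self.retained_pairs) + len(self.removed_reads) + len(
            self.singleton_removed
        )

    def fate_of(self, name: str, mate: int) -> str:
        if (name, mate) in self.removed_reads:
            return "flagged"
        if (name, mate) in self.singleton_removed:
            return "singleton"
        if name in self.retained_pairs:
            return "retained"
        raise KeyError(f"read {name!r}/{mate} unknown to this RemovalResult")

    def check_partition(self) -> None:
        """Verify the read-partition invariant."""
        seen: Set[Tuple[str, int]] = set()
        for name in self.retained_pairs:
            seen.update(((name, 1), (name, 2)))
        for bucket in (self.removed_reads, self.singleton_removed):
            overlap = seen & bucket
            if overlap:
                ex = next(iter(overlap))
                raise AssertionError(f"read {ex} appears in more than one fate bin")
            seen |= bucket

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in sorted(self.retained_pairs):
            rows.append((name, 1, "retained"))
            rows.append((name, 2, "retained"))
        rows += [(n, m, "flagged") for n, m in sorted(self.removed_reads)]
        rows += [(n, m, "singleton") for n, m in sorted(self.singleton_removed)]
        return pd.DataFrame(rows, columns=["name", "mate", "fate_source"])


def apply_singleton_rule(
    flags: Mapping[Tuple[str, int], bool],
    method_id: str = "unknown",
    reference_id: str = "unknown",
) -> RemovalResult:
    """Apply the pair-level post-processing rule to per-read removal flags.

    A pair is retained iff neither mate was flagged; a non-flagged mate of a
    flagged read goes to ``singleton_removed``; flagged reads go to
    ``removed_reads``. Idempotent by construction. ``flags`` must cover both
    mates of every pair.
    """
    mates_seen: Dict[str, Set[int]] = {}
    for (name, mate) in flags:
        if mate not in (1, 2):
            raise ValueError(f"flag references invalid mate {(name, mate)!r}")
        mates_seen.setdefault(name, set()).add(mate)
    for name, mates in mates_seen.items():
        if mates != {1, 2}:
            raise ValueError(f"flags do not cover both mates of pair {name!r}")

    retained: Set[str] = set()
    removed: Set[Tuple[str, int]] = set()
    singleton: Set[Tuple[str, int]] = set()
    for name in mates_seen:
        f1, f2 = flags[(name, 1)], flags[(name, 2)]
        if not f1 and not f2:
            retained.add(name)
        else:
            for mate, fl in ((1, f1), (2, f2)):
                (removed if fl else singleton).add((name, mate))
    return RemovalResult(retained, removed, singleton, method_id, reference_id)


def removal_flags(
    pairs: Sequence[ReadPair], params: SimulatedRemoverParams
) -> Dict[Tuple[str, int], bool]:
    """Pre-singleton per-read flags of the simulated remover (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    flags: Dict[Tuple[str, int], bool] = {}
    if params.pairing_mode is PairingMode.PER_READ:
        u = rng.random(2 * len(pairs))
        for i, pair in enumerate(pairs):
            for j, read in enumerate((pair.r1, pair.r2)):
                if read.label is None:
                    raise ValueError(f"read {read.name!r} is unlabelled; simulated_remove needs truth")
                flags[(pair.qname, read.mate)] = bool(
                    u[2 * i + j] < params.rate_for(read.label.source_class)
                )
    else:
        u = rng.random(len(pairs))
        for i, pair in enumerate(pairs):
            if pair.label is None:
                raise ValueError(f"pair {pair.name!r} is unlabelled; simulated_remove needs truth")
            hit = bool(u[i] < params.rate_for(pair.label.source_class))
            flags[(pair.qname, 1)] = hit
            flags[(pair.qname, 2)] = hit
    return flags


def simulated_remove(
    pairs: Sequence[ReadPair],
    params: SimulatedRemoverParams,
    method_id: str = "simulated",
    reference_id: str = "synthetic",
) -> RemovalResult:
    """Run the simulated remover: per-class Bernoulli flags + singleton rule."""
    return apply_singleton_rule(removal_flags(pairs, params), method_id, reference_id)


def _collect_names(fastq1: Path, fastq2: Path) -> Tuple[Set[str], Set[str]]:
    """Qnames present in each mate file (whitespace-truncated, suffix-stripped)."""
    n1: Set[str] = set()
    n2: Set[str] = set()
    for pair in read_pairs(fastq1, fastq2):
        n1.add(pair.qname)
        n2.add(pair.qname)
    return n1, n2


def external_adapter(
    command_template: str,
    fastq1: Path,
    fastq2: Path,
    workdir: Optional[Path] = None,
    method_id: str = "external",
    reference_id: str = "external",
) -> RemovalResult:
    """Run an external removal tool and reconcile its output against the input.

    ``command_template`` must contain the placeholders ``{in1} {in2} {out1}
    {out2}``; the tool is expected to write the *retained* read pairs to the
    output FASTQ files. Labels are never inspected: reconciliation is purely
    by read name, tolerating whitespace truncation and ``/1``/``/2`` mate
    suffixes. Reads absent from the output are treated as flagged, then the
    singleton rule is applied (a no-op when the tool already emits intact
    pairs only).
    """
    fastq1, fastq2 = Path(fastq1), Path(fastq2)
    input_names: List[str] = []
    seen: Set[str] = set()
    for pair in read_pairs(fastq1, fastq2):
        input_names.append(pair.qname)
        seen.add(pair.qname)

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx is not None else Path(workdir)  # type: ignore[arg-type]
    try:
        out1 = wd / "retained_1.fastq"
        out2 = wd / "retained_2.fastq"
        cmd = command_template.format(
            in1=shlex.quote(str(fastq1)),
            in2=shlex.quote(str(fastq2)),
            out1=shlex.quote(str(out1)),
            out2=shlex.quote(str(out2)),
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"removal tool exited {proc.returncode}: {cmd}\nstderr: {proc.stderr[-2000:]}"
            )
        kept1, kept2 = _collect_names(out1, out2)
    finally:
        if ctx is not None:
            ctx.cleanup()

    unknown = (kept1 | kept2) - seen
    if unknown:
        raise ValueError(
            f"tool emitted {len(unknown)} read name(s) not present in the input, "
            f"e.g. {next(iter(sorted(unknown)))!r}"
        )
    flags: Dict[Tuple[str, int], bool] = {}
    for name in input_names:
        flags[(name, 1)] = name not in kept1
        flags[(name, 2)] = name not in kept2
    return apply_singleton_rule(flags, method_id, reference_id)
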