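"""Paired FASTQ I/O with an embedded provenance label.

Every synthetic read carries a label recording its source class (host, target,
or contaminant), the donor/sample it came from, and its original identity.
The label is serialized *into the read name* so that read fate remains
recoverable after the reads have passed through any third-party removal tool:
tools may truncate names at the first whitespace and may append ``/1``/``/2``
mate suffixes, so the serialized form contains neither whitespace nor ``/``.

Quality encoding is Sanger/Phred+33 throughout.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Tuple

__all__ = [
    "SourceClass",
    "ProvenanceLabel",
    "LabelledRead",
    "ReadPair",
    "UnlabelledReadError",
    "encode_label",
    "decode_label",
    "read_pairs",
    "write_pairs",
]

#: Delimiter separating the base name from the serialized label fields.
#: Whitespace-free and uncommon in read names; configurable per call.
DEFAULT_DELIM = "#"

_MATE_SUFFIXES = ("/1", "/2")

_DNA_OK = frozenset("ACGTN")


class SourceClass(Enum):
    """Truth class of a read's genome of origin.

    HOST and CONTAMINANT reads both originate from a host (human-sample) read
    pool; TARGET reads are the viral/microbial reads of interest.  Keeping
    CONTAMINANT distinct from HOST lets the false-negative composition
    analysis use exact truth, while fate metrics collapse both to
    "truth-positive" (originating from a human sample).
    """

    HOST = "H"
    TARGET = "T"
    CONTAMINANT = "C"


_CODE_TO_CLASS = {c.value: c for c in SourceClass}


class UnlabelledReadError(ValueError):
    """Raised when a read name carries no decodable provenance label."""


def _check_label_field(value: str, field: str, delim: str) -> None:
    if not value:
        raise ValueError(f"ProvenanceLabel.{field} must be non-empty")
    if any(ch.isspace() for ch in value):
        raise ValueError(f"ProvenanceLabel.{field} contains whitespace: {value!r}")
    if "/" in value:
        raise ValueError(f"ProvenanceLabel.{field} contains '/': {value!r}")
    if delim in value:
        raise ValueError(
            f"ProvenanceLabel.{field} contains the label delimiter {delim!r}: {value!r}"
        )


@dataclass(frozen=True)
class ProvenanceLabel:
    """Ground-truth provenance of a synthetic read.

    ``origin_read_id`` records the originating fragment, by convention
    ``<contig>:<start>-<end>`` (1-based, inclusive), identical for both mates
    so the encoded pair name stays shared.
    """

    source_class: SourceClass
    donor_id: str
    origin_read_id: str

    def validate(self, delim: str = DEFAULT_DELIM) -> None:
        _check_label_field(self.donor_id, "donor_id", delim)
        _check_label_field(self.origin_read_id, "origin_read_id", delim)


def encode_label(base_name: str, label: ProvenanceLabel, delim: str = DEFAULT_DELIM) -> str:
    """Serialize ``label`` into a whitespace-free read name.

    The encoded form is ``base_name#<class-code>#<donor>#<origin>``.  It is
    deterministic and injective for distinct (base_name, label), and survives
    the common aligner behaviour of truncating names at the first whitespace.
    """
    if not base_name or any(ch.isspace() for ch in base_name):
        raise ValueError(f"base name must be non-empty and whitespace-free: {base_name!r}")
    if delim in base_name:
        raise ValueError(f"base name contains the label delimiter {delim!r}: {base_name!r}")
    label.validate(delim)
    return delim.join((base_name, label.source_class.value, label.donor_id, label.origin_read_id))


def decode_label(name: str, delim: str = DEFAULT_DELIM) -> Tuple[str, ProvenanceLabel]:
    """Invert :func:`encode_label`.

    Raises :class:`UnlabelledReadError` for names lacking the tag — needed
    when evaluating third-party outputs that rename reads.
    """
    parts = name.split(delim)
    if len(parts) != 4:
        raise UnlabelledReadError(f"read name carries no provenance label: {name!r}")
    base, code, donor, origin = parts
    if not base or code not in _CODE_TO_CLASS or not donor or not origin:
        raise UnlabelledReadError(f"read name carries a malformed provenance label: {name!r}")
    return base, ProvenanceLabel(_CODE_TO_CLASS[code], donor, origin)


def try_decode_label(
    name: str, delim: str = DEFAULT_DELIM
) -> Tuple[str, Optional[ProvenanceLabel]]:
    """Like :func:`decode_label` but returns ``(name, None)`` for unlabelled names."""
    try:
        return decode_label(name, delim)
    except UnlabelledReadError:
        return name, None


@dataclass(slots=True)
class LabelledRead:
    """One mate of a paired-end read plus its provenance truth.

    ``name`` is the tool-safe *base* identifier; the on-disk FASTQ name is
    :attr:`qname`, which embeds the label when one is present.
    """

    name: str
    mate: int
    sequence: str
    quality: str
    label: Optional[ProvenanceLabel] = None

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if not self.name or any(ch.isspace() for ch in self.name):
            raise ValueError(f"read name must be non-empty and whitespace-free: {self.name!r}")

    @property
    def qname(self) -> str:
        """The FASTQ name: base name with the label encoded, if labelled."""
        if self.label is None:
            return self.name
        return encode_label(self.name, self.label)

    def check_alphabet(self) -> None:
        bad = set(self.sequence) - _DNA_OK
        if bad:
            raise ValueError(f"read {self.name!r}: non-ACGTN characters {sorted(bad)}")


@dataclass(slots=True)
class ReadPair:
    """A mate pair. Both mates share the base name and (if any) label."""

    r1: LabelledRead
    r2: LabelledRead

    def __post_init__(self) -> None:
        if self.r1.name != self.r2.name:
            raise ValueError(f"mate names differ: {self.r1.name!r} vs {self.r2.name!r}")
        if (self.r1.mate, self.r2.mate) != (1, 2):
            raise ValueError("r1 must be mate 1 and r2 mate 2")
        l1, l2 = self.r1.label, self.r2.label
        if (l1 is None) != (l2 is None):
            raise ValueError(f"pair {self.r1.name!r}: one mate labelled, the other not")
        if l1 is not None and l2 is not None:
            if (l1.source_class, l1.donor_id) != (l2.source_class, l2.donor_id):
                raise ValueError(
                    f"pair {self.r1.name!r}: mates carry different provenance labels"
                )

    @property
    def name(self) -> str:
        return self.r1.name

    @property
    def qname(self) -> str:
        return self.r1.qname

    @property
    def label(self) -> Optional[ProvenanceLabel]:
        return self.r1.label


# ---------------------------------------------------------------------------
# FASTQ plumbing


def _open_read(path: Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path: Path, gzip_output: Optional[bool]) -> IO[str]:
    path = Path(path)
    if gzip_output is None:
        gzip_output = path.suffix == ".gz"
    if gzip_output:
        # mtime=0 keeps compressed output byte-identical across re-runs
        gz = gzip.GzipFile(str(path), mode="wb", mtime=0)
        return io.TextIOWrapper(gz, encoding="ascii")
    return open(path, "wt")


def _strip_mate_suffix(name: str) -> str:
    if name.endswith(_MATE_SUFFIXES):
        return name[:-2]
    return name


def _fastq_records(handle: IO[str], path: Path) -> Iterator[Tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a 4-line FASTQ stream."""
    idx = 0
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        idx += 1
        if not qual:
            raise ValueError(f"{path}: truncated FASTQ record at record {idx}")
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ValueError(f"{path}: record {idx} header does not start with '@'")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: record {idx} separator line does not start with '+'")
        # tools truncate at the first whitespace; the name proper is the first token
        name = header[1:].split()[0] if len(header) > 1 else ""
        seq = seq.rstrip("\n")
        qual = qual.rstrip("\n")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: record {idx} ({name!r}) quality length {len(qual)} "
                f"!= sequence length {len(seq)}"
            )
        yield name, seq, qual


def _to_read(name: str, seq: str, qual: str, mate: int, delim: str) -> LabelledRead:
    base = _strip_mate_suffix(name)
    base, label = try_decode_label(base, delim)
    return LabelledRead(name=base, mate=mate, sequence=seq, quality=qual, label=label)


def read_pairs(
    fastq1: Path,
    fastq2: Path,
    delim: str = DEFAULT_DELIM,
    require_label: bool = False,
) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two (optionally gzipped) FASTQ files.

    Pairs are yielded in file order; desynchronized names raise with the
    1-based record index. Unlabelled names yield ``label=None`` unless
    ``require_label`` is set.
    """
    fastq1, fastq2 = Path(fastq1), Path(fastq2)
    h1, h2 = _open_read(fastq1), _open_read(fastq2)
    try:
        it1, it2 = _fastq_records(h1, fastq1), _fastq_records(h2, fastq2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            idx += 1
            if rec1 is None or rec2 is None:
                short = fastq1 if rec1 is None else fastq2
                raise ValueError(
                    f"unequal record counts: {short} ran out at record {idx}"
                )
            r1 = _to_read(*rec1, mate=1, delim=delim)
            r2 = _to_read(*rec2, mate=2, delim=delim)
            if r1.name != r2.name:
                raise ValueError(
                    f"desynchronized mate names at record {idx}: "
                    f"{r1.name!r} ({fastq1}) vs {r2.name!r} ({fastq2})"
                )
            if require_label and r1.label is None:
                raise UnlabelledReadError(
                    f"record {idx} ({r1.name!r}) carries no provenance label"
                )
            yield ReadPair(r1, r2)
    finally:
        h1.close()
        h2.close()


def write_pairs(
    pairs: Iterable[ReadPair],
    fastq1: Path,
    fastq2: Path,
    gzip_output: Optional[bool] = None,
    mate_suffix: Optional[str] = None,
) -> int:
    """Write pairs to two FASTQ files; returns the number of pairs written.

    ``mate_suffix`` of ``"/"`` appends ``/1`` and ``/2`` to the names; the
    default writes bare names (mate identity carried by the file).
    """
    if mate_suffix not in (None, "/"):
        raise ValueError(f"mate_suffix must be None or '/', got {mate_suffix!r}")
    count = 0
    h1, h2 = _open_write(Path(fastq1), gzip_output), _open_write(Path(fastq2), gzip_output)
    try:
        for pair in pairs:
            qname = pair.qname
            n1 = qname + "/1" if mate_suffix else qname
            n2 = qname + "/2" if mate_suffix else qname
            h1.write(f"@{n1}\n{pair.r1.sequence}\n+\n{pair.r1.quality}\n")
            h2.write(f"@{n2}\n{pair.r2.sequence}\n+\n{pair.r2.quality}\n")
            count += 1
    except OSError as exc:
        raise OSError(f"failed writing pair files {fastq1} / {fastq2}: {exc}") from exc
    finally:
        h1.close()
        h2.close()
    return count
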