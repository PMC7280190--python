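"""Demultiplexing of MID-tagged reads and read-level quality control.

Pooled 454-style amplicon runs carry a short multiplex identifier (MID) at
the 5' end of every read identifying its sample of origin.  Demultiplexing
assigns each read to the unique sample whose MID exactly matches the read's
prefix (the MID map must be prefix-free) and trims the tag.  QC then
discards a read when any of three rules triggers, checked in order:

  (1) length below 200 nt, (2) mean Phred quality below 25,
  (3) at least one ambiguous (non-ACGT) base.

The rules are discard conditions with strict "<", so reads sitting exactly
on a boundary (length 200, mean quality 25.0) pass.  The mean is the
arithmetic mean of the Phred integers; averaging on the error-probability
scale is available behind a flag.  Reads are discarded, never trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
QC_RULES = ("length", "quality", "ambiguous")


@dataclass
class AmpliconRead:
    """One QC-tracked amplicon read."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred integers
    sample_id: str = UNASSIGNED
    qc_status: str = "unknown"  # unknown | pass | fail
    qc_reason: str | None = None

    def __post_init__(self):
        # int16 is ample for Phred scores and halves the footprint of large runs
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != self.qualities.shape[0]:
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {self.qualities.shape[0]}"
            )


def check_prefix_free(mid_map: dict[str, str]) -> None:
    """MID tags must be unique and none a prefix of another."""
    tags = list(mid_map.values())
    if len(set(tags)) != len(tags):
        raise ValueError("MID tags are not unique")
    for a in tags:
        for b in tags:
            if a != b and b.startswith(a):
                raise ValueError(f"MID {a!r} is a prefix of MID {b!r}")


def demultiplex(
    reads: list[AmpliconRead], mid_map: dict[str, str]
) -> list[AmpliconRead]:
    """Assign reads to samples by exact 5' MID prefix match and trim the tag.

    Reads matching no MID keep ``sample_id == "unassigned"`` and are left
    untrimmed.  Raises ValueError if the MID map is not prefix-free.
    """
    check_prefix_free(mid_map)
    by_tag = {tag: sample for sample, tag in mid_map.items()}
    lengths = sorted({len(t) for t in by_tag})
    out = []
    for read in reads:
        assigned = None
        for L in lengths:
            sample = by_tag.get(read.sequence[:L])
            if sample is not None:
                assigned = (sample, L)
                break
        if assigned is None:
            out.append(replace(read, sample_id=UNASSIGNED))
        else:
            sample, L = assigned
            out.append(
                replace(
                    read,
                    sample_id=sample,
                    sequence=read.sequence[L:],
                    qualities=read.qualities[L:].copy(),
                )
            )
    return out


def mean_quality(qualities: np.ndarray, error_prob_scale: bool = False) -> float:
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    if error_prob_scale:
        p = np.mean(10.0 ** (-q / 10.0))
        return float(-10.0 * np.log10(p))
    return float(q.mean())


def qc_filter(
    read: AmpliconRead,
    min_len: int = 200,
    min_meanq: float = 25.0,
    error_prob_scale: bool = False,
) -> AmpliconRead:
    """Apply the three discard rules; returns the read with qc fields set.

    The recorded failure reason is the first triggered rule in the fixed
    order length → quality → ambiguous, making logs deterministic.  An empty
    sequence fails the length rule.
    """
    if len(read.sequence) < min_len:
        return replace(read, qc_status="fail", qc_reason="length")
    if mean_quality(read.qualities, error_prob_scale) < min_meanq:
        return replace(read, qc_status="fail", qc_reason="quality")
    if set(read.sequence) - set("ACGT"):
        return replace(read, qc_status="fail", qc_reason="ambiguous")
    return replace(read, qc_status="pass", qc_reason=None)


def run_preprocess(
    reads: list[AmpliconRead],
    mid_map: dict[str, str],
    min_len: int = 200,
    min_meanq: float = 25.0,
) -> "tuple[dict[str, list[AmpliconRead]], pd.DataFrame]":
    """Demultiplex then QC-filter; returns per-sample passing reads + report.

    The report is a pandas DataFrame with one row per input read
    (read_id, sample, status, reason) where status is pass/fail/unassigned.
    """
    import pandas as pd

    demuxed = demultiplex(reads, mid_map)
    per_sample: dict[str, list[AmpliconRead]] = {s: [] for s in mid_map}
    rows = []
    for read in demuxed:
        if read.sample_id == UNASSIGNED:
            rows.append((read.read_id, UNASSIGNED, UNASSIGNED, ""))
            continue
        read = qc_filter(read, min_len=min_len, min_meanq=min_meanq)
        rows.append((read.read_id, read.sample_id, read.qc_status, read.qc_reason or ""))
        if read.qc_status == "pass":
            per_sample[read.sample_id].append(read)
    report = pd.DataFrame(rows, columns=["read_id", "sample", "status", "reason"])
    return per_sample, report


# -- FASTQ I/O (Sanger Phred+33) --------------------------------------------


def read_fastq(path: str | Path) -> list[AmpliconRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            AmpliconRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int32),
            )
        )
    return reads


def write_fastq(reads: list[AmpliconRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def write_per_sample_fastq(
    per_sample: dict[str, list[AmpliconRead]], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample, reads in per_sample.items():
        write_fastq(reads, out_dir / f"{sample}.fastq")
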