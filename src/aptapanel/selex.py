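"""SELEX round processing: quality trimming, length filtering, and
enrichment ranking.

A Cell-SELEX experiment sequences the surviving oligonucleotide pool after
each round of selection.  The analysis chain implemented here turns one
FASTQ file per round into a sequence-frequency database and nominates the
most abundant sequences of the final round as candidate aptamers:

1. sliding-window quality trimming of each read (window mean Phred below a
   threshold truncates the read at the start of the offending window);
2. a minimum-length filter that discards reads shortened below the expected
   aptamer length;
3. exact-string counting of the surviving reads per round, normalised to
   per-round frequencies;
4. ranking by final-round abundance, carrying each candidate's full
   frequency trajectory and round-over-round enrichment ratios.

Counting is exact-match only: no clustering of near-identical sequences and
no reverse-complement merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "QualityRead",
    "TrimPolicy",
    "EnrichmentTable",
    "FilterReport",
    "Candidate",
    "read_fastq",
    "write_fastq",
    "sliding_window_trim",
    "length_filter",
    "count_frequencies",
    "rank_candidates",
    "qc_summary",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class QualityRead:
    """A single sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")
        for q in self.qualities:
            if not 0 <= q <= 93:
                raise ValueError(f"read {self.id!r}: Phred score {q} outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimPolicy:
    """Sliding-window trim parameters (window:threshold, plus minimum length).

    The defaults (4-base window, mean-quality threshold 20, minimum length
    74 nt) correspond to the Trimmomatic option string ``SLIDINGWINDOW:4:20``
    combined with ``MINLEN:74`` that is customary for 76-nt aptamer libraries.
    """

    window: int = 4
    mean_quality_threshold: float = 20.0
    min_length: int = 74

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_surviving: int

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_surviving


def read_fastq(path) -> list[QualityRead]:
    """Read a Phred+33 FASTQ file into a list of :class:`QualityRead`.

    Raises ``ValueError`` naming the (0-based) record index on truncated or
    otherwise malformed records.
    """
    reads: list[QualityRead] = []
    with open(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record {len(reads)}: {exc}"
                ) from exc
            reads.append(
                QualityRead(
                    id=record.id,
                    sequence=str(record.seq).upper(),
                    qualities=tuple(record.letter_annotations["phred_quality"]),
                )
            )
    return reads


def write_fastq(reads: Iterable[QualityRead], path) -> int:
    """Write reads as 4-line Phred+33 FASTQ records; returns record count."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


def sliding_window_trim(read: QualityRead, policy: TrimPolicy) -> QualityRead:
    """Trim a read by scanning fixed-size quality windows left to right.

    At the first window whose mean quality falls below the threshold, the
    read is truncated immediately before that window's first base, and
    trailing bases of the kept prefix with quality below the threshold are
    then dropped.  Reads shorter than the window are kept whole if their
    overall mean quality meets the threshold and emptied otherwise.  The
    output is always a prefix of the input.
    """
    n = len(read)
    w = policy.window
    thr = policy.mean_quality_threshold
    if n == 0:
        return read
    q = np.asarray(read.qualities, dtype=float)
    if n < w:
        kept = n if q.mean() >= thr else 0
        return _prefix(read, kept)
    window_means = np.convolve(q, np.ones(w) / w, mode="valid")
    failing = np.nonzero(window_means < thr)[0]
    if failing.size == 0:
        return read
    kept = int(failing[0])
    while kept > 0 and q[kept - 1] < thr:
        kept -= 1
    return _prefix(read, kept)


def _prefix(read: QualityRead, n: int) -> QualityRead:
    if n == len(read):
        return read
    return replace(read, sequence=read.sequence[:n], qualities=read.qualities[:n])


def length_filter(
    reads: Iterable[QualityRead], min_length: int
) -> tuple[list[QualityRead], FilterReport]:
    """Keep reads of length >= ``min_length``; report input/survivor counts."""
    reads = list(reads)
    surviving = [r for r in reads if len(r) >= min_length]
    return surviving, FilterReport(n_input=len(reads), n_surviving=len(surviving))


class EnrichmentTable:
    """Sequence-by-round count and frequency table.

    ``counts`` is a DataFrame indexed by sequence with one integer column per
    round (in the supplied round order); ``frequencies`` divides each column
    by its round total (columns with zero total are all-zero).
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = counts.astype(int)

    @property
    def rounds(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def round_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.round_totals
        freq = self.counts / totals.replace(0, np.nan)
        return freq.fillna(0.0)

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with per-round count and frequency columns."""
        out = self.counts.copy()
        freq = self.frequencies
        for r in self.rounds:
            out[f"{r}_freq"] = freq[r]
        out.index.name = "sequence"
        return out


def count_frequencies(rounds: Mapping[str, Sequence[QualityRead]]) -> EnrichmentTable:
    """Count full-length exact sequence matches per round.

    ``rounds`` maps an ordered round label (e.g. ``"R8"``) to its surviving
    reads.  Sequences absent from a round get count 0 there.
    """
    per_round = {
        label: pd.Series([r.sequence for r in reads], dtype=str).value_counts()
        for label, reads in rounds.items()
    }
    counts = pd.DataFrame(per_round).fillna(0).astype(int)
    counts = counts.reindex(columns=list(rounds.keys()), fill_value=0)
    return EnrichmentTable(counts)


@dataclass(frozen=True)
class Candidate:
    """A ranked candidate aptamer with its enrichment trajectory."""

    sequence: str
    final_count: int
    counts: Mapping[str, int]
    frequencies: Mapping[str, float]
    #: frequency_r / frequency_{r-1}; NaN where the previous round had
    #: frequency 0 (flagged undefined rather than fabricated).
    enrichment_ratios: Mapping[str, float]


def rank_candidates(
    table: EnrichmentTable, final_round: str | None = None, k: int = 5
) -> list[Candidate]:
    """Top-``k`` sequences present in the final round, by final-round count.

    Ties are broken lexicographically by sequence.  If fewer than ``k``
    distinct sequences are present in the final round, all of them are
    returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if final_round is None:
        final_round = table.rounds[-1]
    if final_round not in table.rounds:
        raise KeyError(f"round {final_round!r} not in table rounds {table.rounds}")
    final = table.counts[final_round]
    present = final[final > 0]
    order = sorted(present.index, key=lambda s: (-present[s], s))[:k]
    freq = table.frequencies
    out = []
    for seq in order:
        f = freq.loc[seq]
        ratios: dict[str, float] = {}
        for prev, cur in zip(table.rounds, table.rounds[1:]):
            ratios[cur] = float(f[cur] / f[prev]) if f[prev] > 0 else float("nan")
        out.append(
            Candidate(
                sequence=seq,
                final_count=int(final[seq]),
                counts=table.counts.loc[seq].to_dict(),
                frequencies=f.to_dict(),
                enrichment_ratios=ratios,
            )
        )
    return out


def qc_summary(reads: Sequence[QualityRead]) -> dict:
    """FastQC-style descriptive statistics; informational only, no filtering."""
    if not reads:
        return {
            "n_reads": 0,
            "length_min": None,
            "length_max": None,
            "length_mean": None,
            "gc_percent": None,
            "mean_quality": None,
        }
    lengths = np.array([len(r) for r in reads])
    seq = "".join(r.sequence for r in reads)
    gc = (seq.count("G") + seq.count("C")) / len(seq) * 100 if seq else float("nan")
    quals = np.concatenate([np.asarray(r.qualities) for r in reads if len(r)]) if lengths.sum() else np.array([])
    return {
        "n_reads": len(reads),
        "length_min": int(lengths.min()),
        "length_max": int(lengths.max()),
        "length_mean": float(lengths.mean()),
        "gc_percent": float(gc),
        "mean_quality": float(quals.mean()) if quals.size else None,
    }
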