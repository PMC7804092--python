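"""Dereplication of amplicon reads into ranked haplotype tables.

A *haplotype* is a non-redundant (unique) read sequence; its abundance is
the number of reads carrying exactly that sequence.  This module turns a
:class:`~concerted.simulate.ReadSet` (or FASTA/FASTQ input) into a
haplotype x sample count table, applies the standard pre-processing
filters (minimum read length 350 bp, minimum mean quality 20, minimum
haplotype abundance), ranks haplotypes, and detects whether the most
abundant haplotype is *dominant*, i.e. at least one order of magnitude
more abundant than the runner-up.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 350
DEFAULT_MIN_QUAL = 20.0


@dataclass
class HaplotypeTable:
    """Haplotype sequences with per-sample read counts.

    ``counts`` rows are haplotype ids ordered by rank (total count
    descending, ties broken by lexicographic sequence order); columns are
    sample ids.  ``sample_dates`` optionally maps sample id to a 1-based
    month index.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    sample_dates: dict[str, int] | None = None
    species_label: str = ""

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("haplotype table must contain at least one haplotype")
        if set(self.counts.index) != set(self.sequences):
            raise ValueError("counts index and sequences must list the same haplotypes")
        if len(set(self.sequences.values())) != len(self.sequences):
            raise ValueError("haplotype sequences must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self._sort()

    def _sort(self) -> None:
        totals = self.counts.sum(axis=1)
        order = sorted(self.counts.index,
                       key=lambda h: (-totals[h], self.sequences[h]))
        self.counts = self.counts.loc[order]

    @property
    def S(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def totals(self) -> pd.Series:
        """Total count per haplotype, in rank order."""
        return self.counts.sum(axis=1)

    @property
    def ranks(self) -> pd.Series:
        """1-based rank per haplotype (1 = most abundant)."""
        return pd.Series(np.arange(1, self.S + 1), index=self.counts.index)

    def abundances(self) -> np.ndarray:
        """Counts in descending rank order (input to RAD fitting)."""
        return self.totals.to_numpy()

    def sequence_of(self, hap_id: str) -> str:
        return self.sequences[hap_id]

    def subset(self, hap_ids: list[str]) -> "HaplotypeTable":
        return HaplotypeTable(
            counts=self.counts.loc[hap_ids].copy(),
            sequences={h: self.sequences[h] for h in hap_ids},
            sample_dates=self.sample_dates,
            species_label=self.species_label,
        )

    def expand(self) -> ReadSet:
        """Inverse of :func:`dereplicate` up to read order."""
        seqs: list[str] = []
        samples: list[str] = []
        months: list[int] = []
        env = self.sample_dates is not None
        for hap_id, row in self.counts.iterrows():
            for sample, n in row.items():
                seqs.extend([self.sequences[hap_id]] * int(n))
                samples.extend([sample] * int(n))
                if env:
                    months.extend([self.sample_dates[sample]] * int(n))
        return ReadSet(
            sequences=seqs, sample_ids=samples,
            provenance="environmental" if env else "strain",
            month_index=months if env else None,
        )


@dataclass(frozen=True)
class DominanceReport:
    """Is the top haplotype at least one order of magnitude above the rest?"""

    dominant_id: str
    dominant_count: int
    second_count: int
    log10_ratio: float
    is_dominant: bool


def filter_reads(reads: ReadSet, min_len: int = DEFAULT_MIN_LEN,
                 min_q: float = DEFAULT_MIN_QUAL) -> ReadSet:
    """Discard reads shorter than ``min_len`` or with mean quality below
    ``min_q`` (both boundaries inclusive for retention).

    Reads without quality information (FASTA input, simulator output)
    are only subject to the length rule.
    """
    keep: list[int] = []
    n_short = n_lowq = 0
    quals = reads.mean_quals
    for i, seq in enumerate(reads.sequences):
        if len(seq) < min_len:
            n_short += 1
            continue
        if quals is not None and quals[i] < min_q:
            n_lowq += 1
            continue
        keep.append(i)
    logger.info("filter_reads: %d kept, %d discarded (length < %d), "
                "%d discarded (mean quality < %s)",
                len(keep), n_short, min_len, n_lowq, min_q)
    return ReadSet(
        sequences=[reads.sequences[i] for i in keep],
        sample_ids=[reads.sample_ids[i] for i in keep],
        provenance=reads.provenance,
        month_index=([reads.month_index[i] for i in keep]
                     if reads.month_index is not None else None),
        mean_quals=[quals[i] for i in keep] if quals is not None else None,
    )


def dereplicate(reads: ReadSet, species_label: str = "") -> HaplotypeTable:
    """Collapse reads into unique haplotypes with per-sample counts.

    Haplotype identity is exact string equality.  Ids ``hap1..hapS`` are
    assigned in rank order (total count descending, ties by sequence).
    The grand total of the table equals the number of input reads.
    """
    if len(reads) == 0:
        raise ValueError("cannot dereplicate an empty read set")
    per_sample: dict[str, Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    for seq, sample, _ in reads.records:
        per_sample[sample][seq] += 1
        totals[seq] += 1
    order = sorted(totals, key=lambda s: (-totals[s], s))
    ids = {seq: f"hap{i}" for i, seq in enumerate(order, start=1)}
    samples = sorted(per_sample)
    data = {sample: [per_sample[sample].get(seq, 0) for seq in order]
            for sample in samples}
    counts = pd.DataFrame(data, index=[ids[s] for s in order], dtype=np.int64)
    sample_dates = None
    if reads.month_index is not None:
        sample_dates = {}
        for _, sample, month in reads.records:
            sample_dates[sample] = month
    return HaplotypeTable(counts=counts,
                          sequences={ids[s]: s for s in order},
                          sample_dates=sample_dates,
                          species_label=species_label)


def top_k(table: HaplotypeTable, k: int = 50) -> HaplotypeTable:
    """Keep the ``k`` most abundant haplotypes (all, if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return table.subset(list(table.counts.index[:k]))


def min_abundance(table: HaplotypeTable, threshold: int) -> HaplotypeTable:
    """Keep haplotypes whose total count is >= ``threshold`` (inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    keep = [h for h, t in table.totals.items() if t >= threshold]
    if not keep:
        raise ValueError(f"no haplotype reaches abundance {threshold}")
    return table.subset(keep)


def dominance(table: HaplotypeTable) -> DominanceReport:
    """Compare the top haplotype with the runner-up.

    ``is_dominant`` is true when the count ratio is at least 10 (one
    order of magnitude, log10 ratio >= 1).  With a single haplotype the
    ratio is infinite and dominance holds trivially.
    """
    totals = table.totals
    dominant_id = totals.index[0]
    dominant_count = int(totals.iloc[0])
    if table.S == 1:
        return DominanceReport(dominant_id, dominant_count, 0, math.inf, True)
    second_count = int(totals.iloc[1])
    ratio = (math.inf if second_count == 0
             else math.log10(dominant_count / second_count))
    return DominanceReport(dominant_id, dominant_count, second_count,
                           ratio, ratio >= 1.0)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_reads(path: str | Path, fmt: str | None = None,
               sample_id: str | None = None,
               date_map: dict[str, int] | None = None) -> ReadSet:
    """Read FASTA or FASTQ into a :class:`ReadSet`.

    The sample of a read is taken from its header as everything before a
    trailing ``_readN`` suffix (the convention of the simulator's FASTA
    output), unless ``sample_id`` overrides it.  With a ``date_map``
    (sample -> month index) the set is environmental.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    seqs: list[str] = []
    samples: list[str] = []
    quals: list[float] = []
    for rec in SeqIO.parse(str(path), fmt):
        seqs.append(str(rec.seq).upper())
        if sample_id is not None:
            samples.append(sample_id)
        else:
            name = rec.id
            samples.append(name.rsplit("_read", 1)[0] if "_read" in name else name)
        if fmt == "fastq":
            q = rec.letter_annotations["phred_quality"]
            quals.append(float(np.mean(q)) if q else 0.0)
    if not seqs:
        raise ValueError(f"no reads in {path}")
    if date_map is not None:
        months = [date_map[s] for s in samples]
        return ReadSet(sequences=seqs, sample_ids=samples,
                       provenance="environmental", month_index=months,
                       mean_quals=quals or None)
    return ReadSet(sequences=seqs, sample_ids=samples, provenance="strain",
                   mean_quals=quals or None)


def read_date_map(path: str | Path) -> dict[str, int]:
    """Read ``sample<TAB>YYYY-MM`` and convert dates to 1-based month
    indices relative to the earliest month present."""
    entries: dict[str, tuple[int, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sample, date = line.split("\t")
        year, month = (int(x) for x in date.split("-"))
        entries[sample] = (year, month)
    if not entries:
        raise ValueError(f"empty date map: {path}")
    origin = min(y * 12 + m for y, m in entries.values())
    return {s: y * 12 + m - origin + 1 for s, (y, m) in entries.items()}


def write_haplotype_fasta(table: HaplotypeTable, path: str | Path) -> None:
    """Size-annotated haplotype FASTA (``>hapN;size=COUNT``), rank order."""
    with open(path, "w") as fh:
        for hap_id, total in table.totals.items():
            fh.write(f">{hap_id};size={int(total)}\n{table.sequences[hap_id]}\n")


def write_count_table(table: HaplotypeTable, path: str | Path) -> None:
    """Tab-separated haplotype x sample count table with sequences."""
    out = table.counts.copy()
    out.insert(0, "sequence", [table.sequences[h] for h in out.index])
    out.to_csv(path, sep="\t", index_label="haplotype_id")


def read_count_table(path: str | Path,
                     sample_dates: dict[str, int] | None = None,
                     species_label: str = "") -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="haplotype_id")
    sequences = df["sequence"].to_dict()
    counts = df.drop(columns=["sequence"]).astype(np.int64)
    return HaplotypeTable(counts=counts, sequences=sequences,
                          sample_dates=sample_dates,
                          species_label=species_label)


def write_rank_abundance(table: HaplotypeTable, path: str | Path) -> None:
    """(rank, haplotype_id, count) table, the input for log-scale
    rank-abundance plots."""
    with open(path, "w") as fh:
        fh.write("rank\thaplotype_id\tcount\n")
        for rank, (hap_id, total) in enumerate(table.totals.items(), start=1):
            fh.write(f"{rank}\t{hap_id}\t{int(total)}\n")
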