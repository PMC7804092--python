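"""Pairwise-identity statistics and the homogenisation-efficiency measure.

Three questions about near-identical amplicon haplotypes are answered
here: how similar is each query haplotype to its best match in a subject
set (e.g. environmental haplotypes vs. pooled single-strain haplotypes,
or a dominant haplotype vs. its Sanger reference); how do those best
matches distribute over similarity classes (100%, one mismatch, two,
three ...); and what percentage of a strain's *reads* falls into the
cluster founded by the dominant haplotype when haplotypes are greedily
clustered at a 99% identity threshold — the efficiency of concerted
homogenisation.

Equal-length sequences are compared by Hamming identity; unequal lengths
fall back to an end-gap-free global alignment (match +1, mismatch -1,
gap -2) with identity computed over the aligned columns between the
first and last paired residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from . import haplotypes as hp
from .simulate import ReadSet, encode_sequences

logger = logging.getLogger(__name__)

#: Lower identity bounds of the similarity classes used for 380-385 bp
#: amplicons: exact match, then 1, 2 and 3 mismatches.
DEFAULT_CLASS_BOUNDS = (100.0, 99.73, 99.47, 99.20)


@dataclass(frozen=True)
class IdentityMatch:
    query_id: str
    subject_id: str
    pct_identity: float
    mismatches: int
    aligned_len: int


@dataclass(frozen=True)
class SimilarityClassTable:
    """Cumulative percentage of queries matched at or above each identity
    bound (bounds descending, so the cumulative column is non-decreasing)."""

    boundaries: tuple[float, ...]
    cumulative_pct: tuple[float, ...]
    n_queries: int


@dataclass(frozen=True)
class HomogenisationReport:
    n_reads: int
    n_in_dominant_cluster: int
    n_clusters: int
    threshold_pct: float

    @property
    def efficiency(self) -> float:
        """Percent of reads in the dominant haplotype's cluster."""
        return 100.0 * self.n_in_dominant_cluster / self.n_reads


def _validate_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name} sequence contains characters outside ACGT")


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
# free end gaps: overhangs are not penalised and not counted as columns
try:
    _aligner.end_insertion_score = 0
    _aligner.end_deletion_score = 0
except AttributeError:  # older Biopython
    _aligner.target_end_gap_score = 0
    _aligner.query_end_gap_score = 0


def pairwise_identity(q: str, s: str, query_id: str = "query",
                      subject_id: str = "subject") -> IdentityMatch:
    """Percent identity between two nucleotide sequences.

    Equal lengths: Hamming comparison, identity = 100*(L - mismatches)/L.
    Unequal lengths: end-gap-free global alignment; identity over the
    aligned columns (internal gap columns count as differences).
    """
    _validate_seq(q, "query")
    _validate_seq(s, "subject")
    if len(q) == len(s):
        mism = sum(1 for x, y in zip(q, s) if x != y)
        length = len(q)
        return IdentityMatch(query_id, subject_id,
                             100.0 * (length - mism) / length, mism, length)
    # align in a canonical order so co-optimal alignments cannot make the
    # identity depend on which sequence is called the query
    first_seq, second_seq = sorted((q, s), key=lambda x: (len(x), x))
    aln = _aligner.align(first_seq, second_seq)[0]
    tgt, qry = str(aln[0]), str(aln[1])
    paired = [i for i, (x, y) in enumerate(zip(tgt, qry))
              if x != "-" and y != "-"]
    if not paired:
        # the optimal alignment pairs no residues (free end gaps beat
        # every mismatch): no aligned columns, zero identity
        return IdentityMatch(query_id, subject_id, 0.0, 0, 0)
    first, last = paired[0], paired[-1]
    cols = last - first + 1
    matches = sum(1 for x, y in zip(tgt[first:last + 1], qry[first:last + 1])
                  if x == y and x != "-")
    return IdentityMatch(query_id, subject_id, 100.0 * matches / cols,
                         cols - matches, cols)


def best_match(queries: hp.HaplotypeTable,
               subjects: hp.HaplotypeTable) -> list[IdentityMatch]:
    """Best-identity subject for every query haplotype.

    Ties are resolved to the lexicographically smallest subject id.  When
    all sequences share one length the comparison is a vectorised Hamming
    scan; otherwise each pair goes through the aligner.
    """
    q_ids = list(queries.counts.index)
    s_ids = sorted(subjects.counts.index)  # lexicographic tie order
    q_seqs = [queries.sequences[h] for h in q_ids]
    s_seqs = [subjects.sequences[h] for h in s_ids]
    lengths = {len(x) for x in q_seqs} | {len(x) for x in s_seqs}
    out: list[IdentityMatch] = []
    if len(lengths) == 1:
        length = lengths.pop()
        qm = encode_sequences(q_seqs)
        sm = encode_sequences(s_seqs)
        for i, qid in enumerate(q_ids):
            mism = (qm[i][None, :] != sm).sum(axis=1)
            j = int(np.argmin(mism))  # argmin takes the first = smallest id
            out.append(IdentityMatch(qid, s_ids[j],
                                     100.0 * (length - int(mism[j])) / length,
                                     int(mism[j]), length))
        return out
    for i, qid in enumerate(q_ids):
        best: IdentityMatch | None = None
        for j, sid in enumerate(s_ids):
            m = pairwise_identity(q_seqs[i], s_seqs[j], qid, sid)
            if best is None or m.pct_identity > best.pct_identity:
                best = m
        out.append(best)
    return out


def classify_similarity(
    matches: list[IdentityMatch],
    boundaries: tuple[float, ...] = DEFAULT_CLASS_BOUNDS,
) -> SimilarityClassTable:
    """Cumulative similarity-class table for a set of best matches.

    ``boundaries`` are descending lower identity bounds; entry i of the
    result is the percentage of queries whose best match is at or above
    boundary i.
    """
    if not matches:
        raise ValueError("no matches to classify")
    bounds = tuple(float(b) for b in boundaries)
    if any(nxt >= prev for prev, nxt in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly descending")
    n = len(matches)
    idents = np.array([m.pct_identity for m in matches])
    cumulative = tuple(100.0 * float((idents >= b - 1e-9).sum()) / n
                       for b in bounds)
    return SimilarityClassTable(bounds, cumulative, n)


def cluster_to_dominant(reads: ReadSet,
                        threshold_pct: float = 99.0) -> HomogenisationReport:
    """Greedy centroid clustering; percent of reads joining the dominant
    haplotype's cluster.

    Haplotypes (dereplicated reads) are visited in descending abundance
    (ties by sequence); each joins the first centroid with identity >=
    ``threshold_pct`` (inclusive) or founds a new centroid.  The report
    counts *reads*, not haplotypes, in the cluster founded by the most
    abundant haplotype — the homogenisation efficiency of the array.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold_pct must be in (0, 100]")
    table = hp.dereplicate(reads)
    ids = list(table.counts.index)
    seqs = [table.sequences[h] for h in ids]
    totals = table.totals.to_numpy()
    lengths = {len(s) for s in seqs}
    same_len = len(lengths) == 1

    centroid_rows: list[int] = []
    dominant_reads = 0
    if same_len:
        mat = encode_sequences(seqs)
        length = mat.shape[1]
        # identity >= t  <=>  mismatches <= L*(1 - t/100)
        max_mism = np.floor(length * (1.0 - threshold_pct / 100.0) + 1e-9)
        for i in range(len(ids)):
            assigned = None
            if centroid_rows:
                mism = (mat[centroid_rows] != mat[i][None, :]).sum(axis=1)
                hits = np.flatnonzero(mism <= max_mism)
                if hits.size:
                    assigned = int(hits[0])  # first-fit, founding order
            if assigned is None:
                centroid_rows.append(i)
                assigned = len(centroid_rows) - 1
            if assigned == 0:
                dominant_reads += int(totals[i])
    else:
        centroid_seqs: list[str] = []
        for i in range(len(ids)):
            assigned = None
            for ci, cseq in enumerate(centroid_seqs):
                m = pairwise_identity(seqs[i], cseq)
                if m.pct_identity >= threshold_pct - 1e-9:
                    assigned = ci
                    break
            if assigned is None:
                centroid_seqs.append(seqs[i])
                assigned = len(centroid_seqs) - 1
            if assigned == 0:
                dominant_reads += int(totals[i])
        centroid_rows = list(range(len(centroid_seqs)))
    n_reads = int(totals.sum())
    logger.info("clustered %d reads (%d haplotypes) into %d clusters at "
                ">= %.2f%% identity; %.3f%% of reads with the dominant",
                n_reads, len(ids), len(centroid_rows), threshold_pct,
                100.0 * dominant_reads / n_reads)
    return HomogenisationReport(n_reads=n_reads,
                                n_in_dominant_cluster=dominant_reads,
                                n_clusters=len(centroid_rows),
                                threshold_pct=threshold_pct)


def write_match_report(matches: list[IdentityMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tpct_identity\tmismatches\taligned_len\n")
        for m in matches:
            fh.write(f"{m.query_id}\t{m.subject_id}\t{m.pct_identity:.4f}\t"
                     f"{m.mismatches}\t{m.aligned_len}\n")


def write_class_table(table: SimilarityClassTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("min_pct_identity\tcumulative_pct_of_queries\n")
        for b, c in zip(table.boundaries, table.cumulative_pct):
            fh.write(f"{b:.2f}\t{c:.2f}\n")
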