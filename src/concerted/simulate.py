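"""Generative model of rDNA repeat-array homogenisation.

Ribosomal DNA occurs as a tandem array of near-identical repeats.  Two
molecular mechanisms keep the repeats similar to one another (concerted
evolution): *gene conversion*, the non-reciprocal copying of one repeat
over another, and *unequal crossing-over*, misaligned recombination that
duplicates or deletes blocks of repeats and thereby changes array length.
Point mutation works against homogenisation by continually creating new
variants, so a genome at mutation/homogenisation balance carries one
highly abundant repeat variant (the *dominant haplotype*) plus a cloud of
rare *minor haplotypes* a few substitutions away.

This module simulates that process for a clonal population of lineages,
each carrying one repeat array, and then emulates the two kinds of
amplicon data a sequencing study of such a system produces:

* **single-strain read sets** — deep amplicon sequencing of one isolate,
  i.e. multinomial sampling of the repeat copies of one genome plus
  substitution-type sequencing error;
* **an environmental metabarcoding time series** — monthly samples of a
  population whose total read yield follows a seasonal abundance profile,
  so minor haplotypes co-vary in time with the dominant one.

The model is deliberately stylised: repeats are fixed-length and
indel-free (haplotypes differ only by substitutions), conversion uses a
uniformly chosen donor copy, and unequal crossing-over duplicates or
deletes a contiguous block with equal probability, rejecting events that
would push the copy number outside configured bounds.  Sequencing error
is substitution-only.  All randomness derives from a single seed;
identical seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)
# ASCII byte -> 0..3 code; 255 marks an invalid character
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i

WHOLE_REPEAT = "whole-repeat"

#: Default per-month relative species abundance over one year: a spring
#: bloom, a smaller autumn bloom and low winter abundance, as is typical
#: for temperate coastal bloom-forming phytoplankton.
MONTHLY_BLOOM_WEIGHTS = (
    0.4, 0.6, 1.6, 2.2, 1.8, 1.0, 0.7, 0.6, 1.2, 1.4, 0.7, 0.4,
)


def default_seasonal_profile(n_months: int) -> np.ndarray:
    """Bimodal (spring/autumn) per-month relative abundances summing to 1."""
    w = np.array(MONTHLY_BLOOM_WEIGHTS, dtype=float)
    tiled = np.tile(w, int(np.ceil(n_months / 12)))[:n_months]
    return tiled / tiled.sum()


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length A/C/G/T strings as a (n, L) uint8 matrix of 0..3."""
    if len(seqs) == 0:
        raise ValueError("no sequences to encode")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    if (codes == 255).any():
        raise ValueError("sequences must contain only A, C, G, T")
    return codes.reshape(len(seqs), length)


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    as_bytes = _CODE_TO_BYTE[mat]
    return [row.tobytes().decode("ascii") for row in as_bytes]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the concerted-evolution simulation.

    Rates are probabilities per generation: ``mu`` per site per repeat
    copy, ``gc_rate`` per copy, ``uco_rate`` per genome, ``seq_error``
    per sequenced site.  The copy number starts at ``copy_number_init``
    and is clamped to ``copy_number_bounds`` by rejecting unequal
    crossing-over events that would leave the interval; the defaults
    reflect repeat numbers observed in planktonic diatoms (around 3600
    copies, roughly 2000-5000 across strains).

    The per-generation rate defaults are placeholders chosen so that the
    qualitative dominant/minor haplotype structure emerges within the
    default number of generations; no direct measurements of conversion
    or crossing-over rates exist for diatom rDNA (see docs/methods.md).
    """

    n_lineages: int = 10
    n_generations: int = 10000
    repeat_len: int = 380
    copy_number_init: int = 3600
    copy_number_bounds: tuple[int, int] = (2002, 5055)
    mu: float = 5e-9
    gc_rate: float = 0.5
    gc_tract_len: int | str = WHOLE_REPEAT
    uco_rate: float = 0.05
    uco_block: int = 10
    seq_error: float = 1e-3
    reads_per_strain: int = 20000
    env_total_reads: int = 40000
    n_months: int = 36
    seasonal_profile: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lineages", "n_generations", "repeat_len",
                     "copy_number_init", "uco_block"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("mu", "gc_rate", "uco_rate", "seq_error"):
            rate = float(getattr(self, name))
            if not np.isfinite(rate) or not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be a finite probability in [0, 1]")
        lo, hi = self.copy_number_bounds
        if not lo <= self.copy_number_init <= hi:
            raise ValueError("copy_number_init must lie within copy_number_bounds")
        if lo < 1:
            raise ValueError("copy number lower bound must be >= 1")
        if self.gc_tract_len != WHOLE_REPEAT:
            tract = int(self.gc_tract_len)
            if not 1 <= tract <= self.repeat_len:
                raise ValueError("gc_tract_len must be in 1..repeat_len or 'whole-repeat'")
        if self.reads_per_strain < 0 or self.env_total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_months < 1:
            raise ValueError("n_months must be positive")
        profile = self.profile()
        if profile.shape != (self.n_months,):
            raise ValueError("seasonal_profile length must equal n_months")
        if (profile < 0).any() or abs(profile.sum() - 1.0) > 1e-6:
            raise ValueError("seasonal_profile must be non-negative and sum to 1")

    def profile(self) -> np.ndarray:
        if self.seasonal_profile is None:
            return default_seasonal_profile(self.n_months)
        return np.asarray(self.seasonal_profile, dtype=float)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one randomness stream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Read a flat ``key = value`` config file ('#' starts a comment)."""
        text = Path(path).read_text()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_config_value(key, value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if isinstance(value, tuple):
                value = ",".join(repr(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_config_value(key: str, value: str):
    if key == "gc_tract_len" and value == WHOLE_REPEAT:
        return value
    if key in ("copy_number_bounds", "seasonal_profile"):
        parts = [p for p in value.replace("(", "").replace(")", "").split(",") if p.strip()]
        nums = [float(p) for p in parts]
        if key == "copy_number_bounds":
            return (int(nums[0]), int(nums[1]))
        return tuple(nums)
    if key in ("mu", "gc_rate", "uco_rate", "seq_error"):
        return float(value)
    return int(value)


@dataclass
class RepeatArrayGenome:
    """One lineage's ordered array of rDNA repeat copies (equal-length,
    indel-free, A/C/G/T)."""

    copies: list[str]
    lineage_id: str

    def __post_init__(self) -> None:
        if len(self.copies) < 1:
            raise ValueError("a repeat array has at least one copy")
        # encode validates length equality and the alphabet
        self._matrix = encode_sequences(self.copies)

    @property
    def copy_number(self) -> int:
        return len(self.copies)

    def matrix(self) -> np.ndarray:
        return self._matrix

    def haplotype_frequencies(self) -> dict[str, float]:
        """True within-genome frequency of each distinct repeat variant."""
        uniq, counts = np.unique(self._matrix, axis=0, return_counts=True)
        seqs = decode_matrix(uniq)
        total = counts.sum()
        return {s: c / total for s, c in zip(seqs, counts)}

    def modal_fraction(self) -> float:
        return max(self.haplotype_frequencies().values())


@dataclass
class ReadSet:
    """Amplicon reads with sample annotations.

    ``month_index`` (1-based) is present exactly when the reads are
    environmental; ``mean_quals`` is present when reads come from FASTQ.
    """

    sequences: list[str]
    sample_ids: list[str]
    provenance: str  # "strain" | "environmental"
    month_index: list[int] | None = None
    mean_quals: list[float] | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("strain", "environmental"):
            raise ValueError("provenance must be 'strain' or 'environmental'")
        n = len(self.sequences)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if self.provenance == "environmental":
            if self.month_index is None or len(self.month_index) != n:
                raise ValueError("environmental reads need one month_index per read")
        elif self.month_index is not None:
            raise ValueError("strain reads carry no month_index")
        if self.mean_quals is not None and len(self.mean_quals) != n:
            raise ValueError("mean_quals length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def records(self) -> Iterator[tuple[str, str, int | None]]:
        months = self.month_index or [None] * len(self)
        return iter(zip(self.sequences, self.sample_ids, months))


# ---------------------------------------------------------------------------
# population evolution
# ---------------------------------------------------------------------------


class _SequencePool:
    """Interning pool: distinct repeat sequences stored once, arrays hold ids.

    Gene conversion with a whole-repeat tract is then a single integer
    assignment, and Wright-Fisher resampling copies small id vectors
    instead of full sequence matrices.
    """

    def __init__(self) -> None:
        self.seqs: list[np.ndarray] = []
        self._index: dict[bytes, int] = {}

    def intern(self, seq: np.ndarray) -> int:
        key = seq.tobytes()
        hid = self._index.get(key)
        if hid is None:
            hid = len(self.seqs)
            self.seqs.append(seq.copy())
            self._index[key] = hid
        return hid


def ancestral_population(cfg: SimConfig) -> list[RepeatArrayGenome]:
    """Homogeneous starting population: every lineage carries
    ``copy_number_init`` identical copies of one random ancestral repeat."""
    rng = cfg.rng(0)
    ancestor = rng.integers(0, 4, size=cfg.repeat_len, dtype=np.uint8)
    seq = decode_matrix(ancestor[None, :])[0]
    return [
        RepeatArrayGenome(copies=[seq] * cfg.copy_number_init,
                          lineage_id=f"lineage{i}")
        for i in range(cfg.n_lineages)
    ]


def evolve_population(
    cfg: SimConfig,
    initial: list[RepeatArrayGenome] | None = None,
) -> list[RepeatArrayGenome]:
    """Run the Wright-Fisher concerted-evolution model.

    Per generation, in order: (1) clonal Wright-Fisher resampling of
    lineages; (2) point mutation, per copy per site at rate ``mu``;
    (3) gene conversion, per copy with probability ``gc_rate`` — a
    uniformly chosen *other* copy donates a tract (the whole repeat by
    default) that overwrites the homologous tract of the acceptor, all
    conversions of a generation reading from the pre-conversion state;
    (4) unequal crossing-over, per genome with probability ``uco_rate`` —
    a uniform block of ``uco_block`` contiguous copies is duplicated in
    place or deleted with equal probability, the event being rejected if
    it would leave ``copy_number_bounds``.

    Parameters
    ----------
    cfg
        Simulation parameters; ``cfg.seed`` drives all randomness.
    initial
        Optional starting genomes (defaults to a homogeneous ancestral
        population of ``cfg.n_lineages`` genomes).  Their number
        overrides ``cfg.n_lineages``.
    """
    if initial is None:
        initial = ancestral_population(cfg)
    pool = _SequencePool()
    arrays: list[np.ndarray] = []
    for genome in initial:
        mat = genome.matrix()
        if mat.shape[1] != cfg.repeat_len:
            raise ValueError("initial genome repeat length != cfg.repeat_len")
        arrays.append(np.array([pool.intern(row) for row in mat], dtype=np.int64))
    rng = cfg.rng(1)
    m = len(arrays)
    lo, hi = cfg.copy_number_bounds
    whole = cfg.gc_tract_len == WHOLE_REPEAT
    tract = cfg.repeat_len if whole else int(cfg.gc_tract_len)

    for _ in range(cfg.n_generations):
        # (1) Wright-Fisher resampling of lineages
        parents = rng.integers(0, m, size=m)
        arrays = [arrays[p].copy() for p in parents]
        for li in range(m):
            copies = arrays[li]
            c = len(copies)
            # (2) point mutation
            n_mut = rng.binomial(c * cfg.repeat_len, cfg.mu) if cfg.mu > 0 else 0
            for _ in range(n_mut):
                flat = int(rng.integers(c * cfg.repeat_len))
                ci, site = divmod(flat, cfg.repeat_len)
                seq = pool.seqs[copies[ci]].copy()
                seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
                copies[ci] = pool.intern(seq)
            # (3) gene conversion (synchronous: donors from the
            # pre-conversion state; donor never the acceptor itself)
            if cfg.gc_rate > 0 and c > 1:
                acceptors = np.flatnonzero(rng.random(c) < cfg.gc_rate)
                if acceptors.size:
                    donors = rng.integers(0, c - 1, size=acceptors.size)
                    donors[donors >= acceptors] += 1
                    if whole:
                        copies[acceptors] = copies[donors]
                    else:
                        snapshot = copies.copy()
                        offsets = rng.integers(0, cfg.repeat_len - tract + 1,
                                               size=acceptors.size)
                        for a, d, off in zip(acceptors, donors, offsets):
                            if snapshot[a] == snapshot[d]:
                                continue
                            seq = pool.seqs[snapshot[a]].copy()
                            seq[off:off + tract] = pool.seqs[snapshot[d]][off:off + tract]
                            copies[a] = pool.intern(seq)
            # (4) unequal crossing-over
            if cfg.uco_rate > 0 and rng.random() < cfg.uco_rate:
                b = cfg.uco_block
                if b <= c:
                    start = int(rng.integers(0, c - b + 1))
                    duplicate = rng.random() < 0.5
                    if duplicate and c + b <= hi:
                        copies = np.concatenate(
                            [copies[:start + b], copies[start:start + b],
                             copies[start + b:]])
                    elif not duplicate and c - b >= lo:
                        copies = np.concatenate(
                            [copies[:start], copies[start + b:]])
                    # else: event rejected, copy number unchanged
            arrays[li] = copies
    return _materialise(arrays, pool, initial)


def _materialise(arrays, pool, initial) -> list[RepeatArrayGenome]:
    genomes = []
    for i, copies in enumerate(arrays):
        mat = np.stack([pool.seqs[h] for h in copies])
        genomes.append(RepeatArrayGenome(copies=decode_matrix(mat),
                                         lineage_id=initial[i].lineage_id))
    return genomes

# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


def _apply_sequencing_error(reads: np.ndarray, rate: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Substitution-only sequencing error at `rate` per site, in place."""
    if rate <= 0 or reads.size == 0:
        return reads
    n_err = rng.binomial(reads.size, rate)
    if n_err:
        flat = rng.integers(0, reads.size, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        reads.ravel()[flat] = (reads.ravel()[flat] + shift) % 4
    return reads


def sample_strain_reads(
    genomes: list[RepeatArrayGenome],
    cfg: SimConfig,
    strain_ids: list[str],
) -> ReadSet:
    """Emulate deep amplicon sequencing of monoclonal strains.

    For each requested strain (one genome per strain, matched on
    ``lineage_id``), ``cfg.reads_per_strain`` reads are drawn
    multinomially over the genome's repeat copies with uniform weight
    per copy, then substitution errors are applied at ``cfg.seq_error``
    per site.  Sample ids equal the strain ids; no month annotation.
    """
    by_id = {g.lineage_id: g for g in genomes}
    missing = [s for s in strain_ids if s not in by_id]
    if missing:
        raise KeyError(f"strain ids not in population: {missing}")
    rng = cfg.rng(2)
    seqs: list[str] = []
    samples: list[str] = []
    for sid in strain_ids:
        genome = by_id[sid]
        n = cfg.reads_per_strain
        if n == 0:
            continue
        mat = genome.matrix()
        picks = rng.integers(0, genome.copy_number, size=n)
        reads = mat[picks].copy()
        _apply_sequencing_error(reads, cfg.seq_error, rng)
        seqs.extend(decode_matrix(reads))
        samples.extend([sid] * n)
    return ReadSet(sequences=seqs, sample_ids=samples, provenance="strain")


def sample_environment(
    genomes: list[RepeatArrayGenome],
    cfg: SimConfig,
) -> ReadSet:
    """Emulate a monthly environmental metabarcoding series.

    Per-month read totals are multinomial over ``cfg.seasonal_profile``
    (total ``cfg.env_total_reads``); each read picks a lineage uniformly
    from the population and then a repeat copy uniformly within that
    genome, and receives substitution errors at ``cfg.seq_error``.
    Minor repeat variants therefore rise and fall with the dominant one,
    which is the temporal signature of intragenomic (as opposed to
    interspecific) variation.
    """
    if not genomes:
        raise ValueError("cannot sample an empty population")
    rng = cfg.rng(3)
    month_totals = rng.multinomial(cfg.env_total_reads, cfg.profile())
    matrices = [g.matrix() for g in genomes]
    seqs: list[str] = []
    samples: list[str] = []
    months: list[int] = []
    for mi, n in enumerate(month_totals, start=1):
        if n == 0:
            continue
        lineages = rng.integers(0, len(genomes), size=n)
        rows = np.empty((n, cfg.repeat_len), dtype=np.uint8)
        for k, g in enumerate(lineages):
            mat = matrices[g]
            rows[k] = mat[rng.integers(0, mat.shape[0])]
        _apply_sequencing_error(rows, cfg.seq_error, rng)
        sid = f"env_m{mi:02d}"
        seqs.extend(decode_matrix(rows))
        samples.extend([sid] * n)
        months.extend([mi] * n)
    return ReadSet(sequences=seqs, sample_ids=samples,
                   provenance="environmental", month_index=months)


# ---------------------------------------------------------------------------
# text output
# ---------------------------------------------------------------------------


def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    """Write reads as FASTA with headers ``>sampleID_readN``."""
    counters: dict[str, int] = {}
    with open(path, "w") as fh:
        for seq, sample, _ in reads.records:
            counters[sample] = counters.get(sample, 0) + 1
            fh.write(f">{sample}_read{counters[sample]}\n{seq}\n")


def write_date_map(reads: ReadSet, path: str | Path,
                   start: str = "2011-01") -> None:
    """Tab-separated ``sample_id<TAB>YYYY-MM`` map for environmental reads.

    Month index 1 corresponds to `start`.
    """
    if reads.month_index is None:
        raise ValueError("date map requires environmental reads")
    y0, m0 = (int(x) for x in start.split("-"))
    rows = sorted({(s, m) for _, s, m in reads.records})
    with open(path, "w") as fh:
        for sample, month in rows:
            total = (m0 - 1) + (month - 1)
            fh.write(f"{sample}\t{y0 + total // 12}-{total % 12 + 1:02d}\n")


def write_truth_table(genomes: list[RepeatArrayGenome], path: str | Path) -> None:
    """Per-genome truth table: haplotype sequence and true array frequency."""
    with open(path, "w") as fh:
        fh.write("lineage_id\tsequence\tfrequency\n")
        for g in genomes:
            freqs = sorted(g.haplotype_frequencies().items(),
                           key=lambda kv: (-kv[1], kv[0]))
            for seq, f in freqs:
                fh.write(f"{g.lineage_id}\t{seq}\t{f:.10g}\n")


def write_reference_fasta(genomes: list[RepeatArrayGenome],
                          path: str | Path) -> None:
    """One 'Sanger reference' per genome: its modal repeat sequence.

    A Sanger chromatogram of a homogenised array reads as the consensus,
    which is carried almost entirely by the most abundant repeat variant.
    """
    with open(path, "w") as fh:
        for g in genomes:
            freqs = g.haplotype_frequencies()
            ref = min(freqs, key=lambda s: (-freqs[s], s))
            fh.write(f">ref_{g.lineage_id}\n{ref}\n")
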