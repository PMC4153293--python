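"""From raw barcoded FASTQ to per-site libraries of valid NrfA proteins.

The chain mirrors a functional-gene amplicon pipeline: barcode demultiplexing,
IUPAC-aware primer trimming, length/mean-quality filtering, a light
homopolymer denoising step, a half-split bimera screen, frame-aware
translation against a protein reference set, and exact dereplication into
per-site libraries.  Stage-by-stage retention is recorded in
:class:`FilterStats`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .synthetic_data import FWD_PRIMER, IUPAC, REV_PRIMER, revcomp

__all__ = [
    "Read",
    "SiteLibrary",
    "FilterStats",
    "demultiplex",
    "trim_primers",
    "quality_filter",
    "denoise_light",
    "chimera_screen",
    "translate_frame_select",
    "TranslationResult",
    "dereplicate",
    "read_fastq",
    "process_reads",
]


@dataclass
class Read:
    id: str
    bases: str
    quals: list[int]
    site: str | None = None

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError("quals and bases must have equal length")

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass
class SiteLibrary:
    """Dereplicated valid proteins, with counts, for one site."""

    site_id: str
    proteins: list[tuple[str, int, list[str]]]  # (protein, count, read ids)

    def __post_init__(self) -> None:
        seqs = [p for p, _, _ in self.proteins]
        if len(set(seqs)) != len(seqs):
            raise ValueError("proteins must be pairwise distinct within a library")
        if any(c < 1 for _, c, _ in self.proteins):
            raise ValueError("counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(c for _, c, _ in self.proteins)

    @property
    def n_unique(self) -> int:
        return len(self.proteins)

    def counts(self) -> dict[str, int]:
        return {p: c for p, c, _ in self.proteins}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (protein, count, _) in enumerate(self.proteins, 1):
                fh.write(f">{self.site_id}_u{i};size={count}\n{protein}\n")


_STAGES = (
    "input",
    "demultiplexed",
    "trimmed",
    "quality_passed",
    "denoised",
    "non_chimeric",
    "translated",
    "valid",
)


@dataclass
class FilterStats:
    """Retained read counts per pipeline stage (monotone non-increasing)."""

    input: int = 0
    demultiplexed: int = 0
    trimmed: int = 0
    quality_passed: int = 0
    denoised: int = 0
    non_chimeric: int = 0
    translated: int = 0
    valid: int = 0
    per_site: dict = field(default_factory=dict)

    def validate(self) -> None:
        values = [getattr(self, s) for s in _STAGES]
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError(f"stage counts must be non-increasing: {values}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": s, "retained": getattr(self, s)} for s in _STAGES]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _hamming_iupac(pattern: str, text: str) -> int:
    """Mismatches of ``text`` against IUPAC ``pattern`` (N in text mismatches)."""
    mm = 0
    for p, t in zip(pattern, text):
        if t not in IUPAC.get(p, p):
            mm += 1
    return mm


def demultiplex(
    reads: list[Read], barcode_map: dict[str, str], max_mismatch: int = 1
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Assign reads to sites by barcode prefix; strip the barcode.

    A read is assigned to the unique barcode within ``max_mismatch`` of its
    prefix; ties or no match go to the unassigned bin.  Barcodes must be
    pairwise more than ``2 * max_mismatch`` apart so assignment is unambiguous
    for conforming reads.
    """
    barcodes = list(barcode_map.items())
    lengths = {len(b) for _, b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")
    (blen,) = lengths
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            d = sum(x != y for x, y in zip(barcodes[i][1], barcodes[j][1]))
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {barcodes[i][1]!r}/{barcodes[j][1]!r} are only "
                    f"{d} apart; need > {2 * max_mismatch}"
                )
    assigned: dict[str, list[Read]] = {site: [] for site, _ in barcodes}
    unassigned: list[Read] = []
    for read in reads:
        prefix = read.bases[:blen]
        hits = []
        for site, bc in barcodes:
            d = sum(x != y for x, y in zip(bc, prefix))
            if d <= max_mismatch:
                hits.append((d, site))
        hits.sort()
        if len(hits) == 1 or (len(hits) > 1 and hits[0][0] < hits[1][0]):
            site = hits[0][1]
            assigned[site].append(
                Read(read.id, read.bases[blen:], read.quals[blen:], site=site)
            )
        else:
            unassigned.append(read)
    return assigned, unassigned


def trim_primers(
    read: Read,
    fwd_primer: str = FWD_PRIMER,
    rev_primer: str = REV_PRIMER,
    max_mismatch: int = 2,
) -> Read | None:
    """IUPAC-aware primer removal; returns None when no forward primer found.

    The forward primer must sit at the read start (the barcode is already
    stripped).  The reverse-complemented reverse primer is removed from the
    read end if present within ``max_mismatch`` at any of the last few
    offsets (homopolymer indels can shift it by a base or two); absence of
    the reverse primer is tolerated.
    """
    flen = len(fwd_primer)
    if len(read.bases) < flen or _hamming_iupac(fwd_primer, read.bases[:flen]) > max_mismatch:
        return None
    bases, quals = read.bases[flen:], read.quals[flen:]
    rc = revcomp(rev_primer)
    rlen = len(rc)
    for shift in (0, 1, 2):
        start = len(bases) - rlen - shift
        if start < 0:
            continue
        if _hamming_iupac(rc, bases[start : start + rlen]) <= max_mismatch:
            bases, quals = bases[:start], quals[:start]
            break
    if not bases:
        return None
    return Read(read.id, bases, quals, site=read.site)


def quality_filter(read: Read, min_len: int = 200, min_mean_q: float = 25.0) -> bool:
    """Keep iff length >= min_len and mean Phred >= min_mean_q (inclusive)."""
    return len(read.bases) >= min_len and read.mean_quality >= min_mean_q


def _homopolymer_runs(seq: str) -> tuple[str, tuple[int, ...]]:
    """(compressed sequence, run lengths)."""
    if not seq:
        return "", ()
    chars = [seq[0]]
    lengths = [1]
    for c in seq[1:]:
        if c == chars[-1]:
            lengths[-1] += 1
        else:
            chars.append(c)
            lengths.append(1)
    return "".join(chars), tuple(lengths)


def _single_run_off_by_one(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return len(diff) == 1 and abs(a[diff[0]] - b[diff[0]]) == 1


def denoise_light(reads: list[Read]) -> list[Read]:
    """Merge reads that differ only by one homopolymer run length of one base.

    Variants sharing a homopolymer-compressed sequence are compared; a variant
    one base off (in a single run) from a more abundant retained variant is
    rewritten to that variant's sequence.  Idempotent: the retained variants
    are pairwise non-mergeable.  Read count is conserved (merging rewrites
    bases, it never drops reads).
    """
    by_compressed: dict[str, list[Read]] = defaultdict(list)
    for read in reads:
        key, _ = _homopolymer_runs(read.bases)
        by_compressed[key].append(read)
    canonical: dict[str, str] = {}
    for group in by_compressed.values():
        counts = Counter(r.bases for r in group)
        variants = sorted(counts, key=lambda s: (-counts[s], s))
        retained: list[tuple[str, tuple[int, ...]]] = []
        for v in variants:
            _, runs = _homopolymer_runs(v)
            target = next(
                (seq for seq, rruns in retained if _single_run_off_by_one(runs, rruns)),
                None,
            )
            if target is None:
                retained.append((v, runs))
                canonical[v] = v
            else:
                canonical[v] = target
    out = []
    for read in reads:
        merged = canonical[read.bases]
        if merged == read.bases:
            out.append(read)
        else:
            # rewritten read keeps its id/site; qualities are padded/cut to fit
            q = read.quals[: len(merged)]
            q = q + [q[-1]] * (len(merged) - len(q))
            out.append(Read(read.id, merged, q, site=read.site))
    return out


def _best_identity(query: str, references: dict[str, str], mode: str) -> tuple[str, float]:
    """(best reference id, identity); identity = 1 - editDistance / len(query).

    Uses edlib's banded search (``k``): once a good reference is found, worse
    ones are abandoned early, which keeps large reference sets cheap.
    """
    best_id, best_d = None, len(query) + 1
    for rid, ref in references.items():
        d = edlib.align(query, ref, mode=mode, task="distance", k=best_d - 1)["editDistance"]
        if d != -1 and d < best_d:
            best_id, best_d = rid, d
    if best_id is None:  # everything beyond the band; rescan unbounded
        for rid, ref in references.items():
            d = edlib.align(query, ref, mode=mode, task="distance")["editDistance"]
            if d < best_d or best_id is None:
                best_id, best_d = rid, d
    return best_id, 1.0 - best_d / len(query)


def chimera_screen(
    bases: str,
    references: dict[str, str],
    margin: float = 0.05,
    min_half: int = 40,
) -> bool:
    """Half-split bimera test; True means chimeric.

    The read is split at its midpoint; if the two halves' best references
    differ and each half matches its own parent better than the full read
    matches either parent by at least ``margin`` (fractional identity),
    the read is called chimeric.  Reads shorter than ``2 * min_half`` are
    passed through unscreened.
    """
    if not references:
        raise ValueError("reference set is empty")
    if len(bases) < 2 * min_half:
        return False
    mid = len(bases) // 2
    left, right = bases[:mid], bases[mid:]
    lid, lident = _best_identity(left, references, mode="HW")
    rid, rident = _best_identity(right, references, mode="HW")
    if lid == rid:
        return False
    _, full_ident = _best_identity(bases, references, mode="NW")
    return lident >= full_ident + margin and rident >= full_ident + margin


@dataclass(frozen=True)
class TranslationResult:
    protein: str | None
    frame: int | None
    accepted: bool
    cause: str | None  # None | "length" | "internal_stop" | "low_coverage"

    @property
    def frameshift_flag(self) -> bool:
        return self.cause in ("internal_stop", "low_coverage")


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


_LOCAL = None


def translate_frame_select(
    dna: str,
    reference_proteins: dict[str, str],
    min_dna_len: int = 60,
    min_coverage: float = 0.70,
) -> TranslationResult:
    """Translate the three forward frames and pick the best against references.

    The frame whose translation is closest (edit distance) to any reference
    is selected.  The read is rejected when the best translation carries an
    internal stop, or when the best local alignment to its reference covers
    less than ``min_coverage`` of the translated length — the frame-shift
    signature of a homopolymer indel.
    """
    global _LOCAL
    if not reference_proteins:
        raise ValueError("reference protein set is empty")
    if len(dna) < min_dna_len:
        return TranslationResult(None, None, False, "length")
    dna = dna.upper().replace("U", "T")
    candidates = []
    for frame in range(3):
        sub = dna[frame : frame + 3 * ((len(dna) - frame) // 3)]
        if not sub:
            continue
        protein = str(Seq(sub).translate())
        rid, ident = _best_identity(protein, reference_proteins, mode="NW")
        candidates.append((ident, frame, protein, rid))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, frame, protein, rid = candidates[0]
    core = protein[:-1] if protein.endswith("*") else protein
    if "*" in core:
        return TranslationResult(None, frame, False, "internal_stop")
    if _LOCAL is None:
        _LOCAL = _local_aligner()
    aln = _LOCAL.align(core, reference_proteins[rid])
    if len(aln) == 0:
        return TranslationResult(None, frame, False, "low_coverage")
    best = aln[0]
    span = best.aligned[0][-1][1] - best.aligned[0][0][0] if len(best.aligned[0]) else 0
    if span / len(core) < min_coverage:
        return TranslationResult(None, frame, False, "low_coverage")
    return TranslationResult(core, frame, True, None)


def dereplicate(proteins: list[tuple[str, str]], site_id: str) -> SiteLibrary:
    """Collapse identical proteins; input is (read_id, protein) pairs.

    Output records are ordered by descending count, ties broken
    lexicographically by sequence.
    """
    members: dict[str, list[str]] = defaultdict(list)
    for read_id, protein in proteins:
        members[protein].append(read_id)
    records = [(p, len(ids), ids) for p, ids in members.items()]
    records.sort(key=lambda r: (-r[1], r[0]))
    return SiteLibrary(site_id=site_id, proteins=records)


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        )
    return reads


def process_reads(
    fastq_path: str | Path,
    barcode_map: dict[str, str],
    reference_proteins: dict[str, str],
    reference_dna: dict[str, str] | None = None,
    fwd_primer: str = FWD_PRIMER,
    rev_primer: str = REV_PRIMER,
    max_barcode_mismatch: int = 1,
    min_len: int = 200,
    min_mean_q: float = 25.0,
    chimera_margin: float = 0.05,
    min_coverage: float = 0.70,
) -> tuple[dict[str, SiteLibrary], FilterStats, dict[str, TranslationResult]]:
    """Run the full chain; returns (site libraries, stats, per-read results).

    ``reference_dna`` (for the chimera screen) defaults to back-translating
    the reference proteins.  Per-read translation outcomes are keyed by read
    id so recovery tests can compare against a truth sidecar.
    """
    from .synthetic_data import reverse_translate

    if reference_dna is None:
        reference_dna = {rid: reverse_translate(p) for rid, p in reference_proteins.items()}

    reads = read_fastq(fastq_path)
    stats = FilterStats(input=len(reads))
    assigned, _ = demultiplex(reads, barcode_map, max_mismatch=max_barcode_mismatch)
    stats.demultiplexed = sum(len(v) for v in assigned.values())

    libraries: dict[str, SiteLibrary] = {}
    results: dict[str, TranslationResult] = {}
    chimera_cache: dict[str, bool] = {}
    translate_cache: dict[str, TranslationResult] = {}
    for site, site_reads in assigned.items():
        trimmed = [t for r in site_reads if (t := trim_primers(r, fwd_primer, rev_primer)) is not None]
        stats.trimmed += len(trimmed)
        passed = [r for r in trimmed if quality_filter(r, min_len=min_len, min_mean_q=min_mean_q)]
        stats.quality_passed += len(passed)
        denoised = denoise_light(passed)
        stats.denoised += len(denoised)

        clean = []
        for r in denoised:
            if r.bases not in chimera_cache:
                chimera_cache[r.bases] = chimera_screen(
                    r.bases, reference_dna, margin=chimera_margin
                )
            if not chimera_cache[r.bases]:
                clean.append(r)
        stats.non_chimeric += len(clean)

        valid_pairs = []
        n_translated = 0
        for r in clean:
            if r.bases not in translate_cache:
                translate_cache[r.bases] = translate_frame_select(
                    r.bases, reference_proteins, min_coverage=min_coverage
                )
            res = translate_cache[r.bases]
            results[r.id] = res
            if res.cause != "internal_stop" and res.cause != "length":
                n_translated += 1
            if res.accepted:
                valid_pairs.append((r.id, res.protein))
        stats.translated += n_translated
        stats.valid += len(valid_pairs)
        if valid_pairs:
            libraries[site] = dereplicate(valid_pairs, site_id=site)
        stats.per_site[site] = {
            "demultiplexed": len(site_reads),
            "trimmed": len(trimmed),
            "quality_passed": len(passed),
            "non_chimeric": len(clean),
            "valid": len(valid_pairs),
        }
    stats.validate()
    return libraries, stats, results
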