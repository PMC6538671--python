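"""Amplicon read processing and identity-threshold taxonomic assignment.

The chain mirrors the standard USEARCH-style workflow for short-amplicon
metabarcoding, in six steps per sample:

1. quality-tail truncation (Phred < 20) and overlap merging of read pairs,
   rejecting pairs with more than 5 conflicting positions in the overlap;
2. primer stripping from both ends of the merged read;
3. expected-error filtering (expected error rate > 1% rejected) and a
   minimum-length cut (120 bp);
4. dereplication into unique sequences, discarding abundances of three or
   fewer (singletons, doubletons, tripletons);
5. UNOISE-style abundance-skew denoising into centroid sequences;
6. global identity assignment of centroids against reference amplicons at a
   97-100% identity threshold (default 98.5%), tabulated as a
   taxon x sample read-count matrix with an ``unassigned`` row.

Reads detected in declared blank (no-template control) samples mark the run
as contaminated; per-stage read-count tallies are kept for every sample so
that kept + rejected always reconciles with the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .seqio import (
    PrimerPair,
    Read,
    ReadPair,
    ReferencePanel,
    read_fastq_pair,
    reverse_complement,
)
from .markerdesign import _matches_code

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds in one place (defaults as commonly published)."""

    q_cutoff: int = 20            # tail-truncation Phred cutoff
    min_overlap: int = 16         # minimum merge overlap, bp
    max_diffs: int = 5            # max conflicting positions in the overlap
    strip_max_mm: int = 2         # mismatches tolerated per primer when stripping
    max_ee_rate: float = 0.01     # expected-error rate ceiling (EE/length)
    min_len: int = 120            # minimum core length, bp
    min_abundance: int = 4        # uniques below this are dropped (<=3 removed)
    alpha: float = 2.0            # UNOISE abundance-skew steepness
    min_identity: float = 98.5    # percent identity for assignment


DEFAULT_CONFIG = PipelineConfig()


# ---------------------------------------------------------------------------
# Step 1: tail truncation and pair merging
# ---------------------------------------------------------------------------


def truncate_tail(read: Read, q_cutoff: int = 20) -> Read:
    """Truncate at the first base whose Phred score drops below the cutoff."""
    for i, q in enumerate(read.quals):
        if q < q_cutoff:
            return Read(id=read.id, seq=read.seq[:i], quals=read.quals[:i])
    return read


@dataclass
class MergedRead:
    id: str
    seq: str
    quals: list[int]
    overlap_len: int
    overlap_diffs: int


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 16,
    max_diffs: int = 5,
) -> MergedRead | None:
    """Merge a read pair over its best ungapped overlap.

    The reverse read is reverse-complemented and slid along the forward read
    (the insert is assumed to be at least as long as each read); the offset
    maximizing the number of agreeing overlap positions wins, with ties
    going to the longer overlap.  The merge is rejected (``None``) when the
    best overlap is shorter than ``min_overlap`` or disagrees at more than
    ``max_diffs`` positions.

    Overlap consensus: agreeing positions keep the base with quality
    ``max(Q1, Q2)``; conflicts take the higher-quality base with quality
    ``|Q1 - Q2|`` (the forward base on a quality tie).
    """
    s1, q1 = pair.r1.seq, pair.r1.quals
    s2 = reverse_complement(pair.r2.seq)
    q2 = pair.r2.quals[::-1]
    n1, n2 = len(s1), len(s2)
    if min(n1, n2) < min_overlap:
        return None
    a1 = np.frombuffer(s1.encode(), dtype="S1")
    a2 = np.frombuffer(s2.encode(), dtype="S1")
    best_matches = -1
    best_off = None
    for off in range(0, n1 - min_overlap + 1):
        ov = min(n1 - off, n2)
        matches = int((a1[off : off + ov] == a2[:ov]).sum())
        if matches > best_matches:
            best_matches = matches
            best_off = off
    if best_off is None:
        return None
    off = best_off
    ov = min(n1 - off, n2)
    diffs = ov - best_matches
    if ov < min_overlap or diffs > max_diffs:
        return None
    seq = list(s1[:off])
    quals = list(q1[:off])
    for k in range(ov):
        b1, b2 = s1[off + k], s2[k]
        p1, p2 = q1[off + k], q2[k]
        if b1 == b2:
            seq.append(b1)
            quals.append(max(p1, p2))
        else:
            seq.append(b1 if p1 >= p2 else b2)
            quals.append(abs(p1 - p2))
    if n1 - off > ov:  # R1 extends past the reverse read
        seq += list(s1[off + ov :])
        quals += list(q1[off + ov :])
    else:
        seq += list(s2[ov:])
        quals += list(q2[ov:])
    return MergedRead(
        id=pair.r1.id,
        seq="".join(seq),
        quals=quals,
        overlap_len=ov,
        overlap_diffs=diffs,
    )


# ---------------------------------------------------------------------------
# Step 2: primer stripping
# ---------------------------------------------------------------------------


def _mm_count(primer_seq: str, segment: str) -> int:
    return sum(
        0 if _matches_code(p, t) else 1 for p, t in zip(primer_seq, segment)
    )


def strip_primers(
    merged: MergedRead,
    pair: PrimerPair,
    max_mm: int = 2,
) -> MergedRead | None:
    """Cut the forward primer off the 5' end and the reverse-complemented
    reverse primer off the 3' end, each within ``max_mm`` mismatches.
    Returns the inter-primer core (with its qualities) or ``None``.
    """
    kf, kr = len(pair.fwd), len(pair.rev)
    if len(merged.seq) < kf + kr + 1:
        return None
    if _mm_count(pair.fwd.seq, merged.seq[:kf]) > max_mm:
        return None
    rev_rc = reverse_complement(pair.rev.seq)
    if _mm_count(rev_rc, merged.seq[-kr:]) > max_mm:
        return None
    return MergedRead(
        id=merged.id,
        seq=merged.seq[kf : len(merged.seq) - kr],
        quals=merged.quals[kf : len(merged.quals) - kr],
        overlap_len=merged.overlap_len,
        overlap_diffs=merged.overlap_diffs,
    )


# ---------------------------------------------------------------------------
# Step 3: expected-error filtering
# ---------------------------------------------------------------------------


def expected_errors(quals: list[int]) -> float:
    return float(sum(10.0 ** (-q / 10.0) for q in quals))


def ee_filter(
    core: MergedRead,
    max_ee_rate: float = 0.01,
    min_len: int = 120,
) -> bool:
    """Keep iff the expected-error *rate* (EE/length) is at most
    ``max_ee_rate`` and the core is at least ``min_len`` bp.  The boundary
    is kept: a rate exactly at the ceiling passes (the rule rejects strictly
    greater rates)."""
    n = len(core.seq)
    if n < min_len:
        return False
    # tolerance keeps the exact boundary (e.g. all-Q20) on the accept side
    return expected_errors(core.quals) / n <= max_ee_rate + 1e-12


# ---------------------------------------------------------------------------
# Step 4: dereplication
# ---------------------------------------------------------------------------


@dataclass
class UniqueSequence:
    seq: str
    abundance: int
    sample: str


@dataclass
class DereplicationResult:
    uniques: list[UniqueSequence]       # abundance >= min_abundance, sorted
    dropped_reads: int                  # reads in discarded low-abundance uniques
    input_reads: int


def dereplicate(
    cores: list[str],
    sample: str,
    min_abundance: int = 4,
) -> DereplicationResult:
    """Collapse identical sequences, drop abundances below ``min_abundance``
    (default removes singletons through tripletons), sort by descending
    abundance then lexicographically."""
    tally = Counter(cores)
    uniques = [
        UniqueSequence(seq=s, abundance=a, sample=sample)
        for s, a in tally.items()
        if a >= min_abundance
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.seq))
    kept = sum(u.abundance for u in uniques)
    return DereplicationResult(
        uniques=uniques,
        dropped_reads=len(cores) - kept,
        input_reads=len(cores),
    )


# ---------------------------------------------------------------------------
# Step 5: UNOISE-style denoising
# ---------------------------------------------------------------------------


@dataclass
class Centroid:
    seq: str
    abundance: int        # pooled abundance (centroid + merged variants)
    own_abundance: int    # the centroid unique's own abundance
    sample: str
    members: int = 1


def _edit_distance(a: str, b: str, k: int = -1) -> int:
    res = edlib.align(a, b, task="distance", k=k)
    return res["editDistance"]


def denoise(uniques: list[UniqueSequence], alpha: float = 2.0) -> list[Centroid]:
    """Greedy abundance-skew clustering (the UNOISE rule).

    Uniques are visited in descending abundance.  A unique ``u`` merges into
    the closest existing centroid ``c`` for which
    ``abund(u)/abund(c) <= 1 / 2^(alpha*d + 1)`` with ``d`` the Levenshtein
    distance; otherwise it founds a new centroid.  Merged abundances pool
    into the centroid.  The skew test uses the centroid's own (pre-pooling)
    abundance.
    """
    centroids: list[Centroid] = []
    for u in sorted(uniques, key=lambda x: (-x.abundance, x.seq)):
        best: tuple[int, int] | None = None  # (distance, centroid index)
        for idx, c in enumerate(centroids):
            skew = u.abundance / c.own_abundance
            # largest d at which the skew test can still pass
            d_max = int(np.floor((np.log2(1.0 / skew) - 1.0) / alpha)) if skew < 0.5 else -1
            if d_max < 1:
                continue
            d = _edit_distance(u.seq, c.seq, k=d_max)
            if d == -1 or d == 0:
                continue
            if best is None or d < best[0]:
                best = (d, idx)
        if best is None:
            centroids.append(
                Centroid(
                    seq=u.seq,
                    abundance=u.abundance,
                    own_abundance=u.abundance,
                    sample=u.sample,
                )
            )
        else:
            c = centroids[best[1]]
            c.abundance += u.abundance
            c.members += 1
    return centroids


# ---------------------------------------------------------------------------
# Step 6: identity assignment
# ---------------------------------------------------------------------------


def global_identity(query: str, reference: str) -> float:
    """Percent identity of the end-gap-free global alignment.

    The denominator is the number of alignment columns excluding terminal
    gap runs but including internal gaps, so an internal indel is penalized
    while ragged ends are not.
    """
    res = edlib.align(query, reference, task="path", mode="NW")
    cigar = res["cigar"]
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    # trim terminal indel runs
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    cols = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    if cols == 0:
        return 0.0
    return 100.0 * matches / cols


@dataclass
class Assignment:
    centroid: Centroid
    taxon: str | None       # None => unassigned
    identity: float         # best identity achieved
    ambiguous: bool = False


def assign(
    centroids: list[Centroid],
    refdb: ReferencePanel,
    min_identity: float = 98.5,
) -> tuple[pd.DataFrame, list[Assignment]]:
    """Assign each centroid to the best-matching reference taxon.

    A centroid is assigned iff its best identity is at least
    ``min_identity`` percent; if several references tie for the best score
    they must share one taxon label, otherwise the centroid is counted as
    unassigned-ambiguous.  Returns the taxon x sample abundance table
    (including an ``unassigned`` row) and per-centroid details.  The result
    is invariant under permutations of the reference panel.
    """
    if not len(refdb):
        raise ValueError("empty reference panel")
    taxa = sorted({r.taxon or r.id for r in refdb.records})
    samples = sorted({c.sample for c in centroids})
    table = pd.DataFrame(0, index=taxa + [UNASSIGNED], columns=samples, dtype=int)
    details: list[Assignment] = []
    for c in centroids:
        scores = [
            (global_identity(c.seq, r.seq), r.taxon or r.id)
            for r in refdb.records
        ]
        best = max(s for s, _ in scores)
        top_taxa = {t for s, t in scores if abs(s - best) < 1e-9}
        if best >= min_identity and len(top_taxa) == 1:
            taxon = top_taxa.pop()
            details.append(Assignment(centroid=c, taxon=taxon, identity=best))
            table.loc[taxon, c.sample] += c.abundance
        else:
            ambiguous = best >= min_identity and len(top_taxa) > 1
            details.append(
                Assignment(centroid=c, taxon=None, identity=best, ambiguous=ambiguous)
            )
            table.loc[UNASSIGNED, c.sample] += c.abundance
    return table, details


# ---------------------------------------------------------------------------
# The composed pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    table: pd.DataFrame          # taxon x sample counts, 'unassigned' row last
    tallies: pd.DataFrame        # per-sample per-stage read counts
    assignments: list[Assignment]
    contaminated: bool
    flagged_blanks: list[str]


def _load_pairs(source) -> list[ReadPair]:
    if isinstance(source, (tuple, list)) and len(source) == 2 and isinstance(source[0], (str, Path)):
        return list(read_fastq_pair(source[0], source[1]))
    return list(source)


def run_pipeline(
    fastq_pairs_by_sample: dict[str, object],
    pair: PrimerPair,
    refdb: ReferencePanel,
    config: PipelineConfig = DEFAULT_CONFIG,
    blanks: set[str] | frozenset[str] = frozenset(),
) -> PipelineResult:
    """Run the six processing steps for every sample and tabulate.

    ``fastq_pairs_by_sample`` maps sample id to either a ``(r1_path,
    r2_path)`` tuple or an in-memory sequence of :class:`ReadPair`.
    Samples listed in ``blanks`` are processed identically; any read
    surviving to the final table in a blank marks the run contaminated.
    """
    blanks = set(blanks)
    unknown_blanks = blanks - set(fastq_pairs_by_sample)
    if unknown_blanks:
        raise ValueError(f"blank sample(s) not in input: {sorted(unknown_blanks)}")

    all_centroids: list[Centroid] = []
    tally_rows = []
    for sample, source in fastq_pairs_by_sample.items():
        pairs = _load_pairs(source)
        merged: list[MergedRead] = []
        for rp in pairs:
            r1 = truncate_tail(rp.r1, config.q_cutoff)
            r2 = truncate_tail(rp.r2, config.q_cutoff)
            m = merge_pair(
                ReadPair(r1=r1, r2=r2),
                min_overlap=config.min_overlap,
                max_diffs=config.max_diffs,
            )
            if m is not None:
                merged.append(m)
        stripped = [
            s for m in merged
            if (s := strip_primers(m, pair, config.strip_max_mm)) is not None
        ]
        filtered = [
            s for s in stripped
            if ee_filter(s, config.max_ee_rate, config.min_len)
        ]
        derep = dereplicate(
            [s.seq for s in filtered], sample, config.min_abundance
        )
        centroids = denoise(derep.uniques, config.alpha)
        all_centroids.extend(centroids)
        tally_rows.append(
            {
                "sample": sample,
                "input_pairs": len(pairs),
                "merged": len(merged),
                "primer_stripped": len(stripped),
                "quality_filtered": len(filtered),
                "abundance_filtered": sum(u.abundance for u in derep.uniques),
                "unique_sequences": len(derep.uniques),
                "centroids": len(centroids),
                "denoised_reads": sum(c.abundance for c in centroids),
            }
        )
    tallies = pd.DataFrame(tally_rows).set_index("sample")

    if all_centroids:
        table, details = assign(all_centroids, refdb, config.min_identity)
    else:
        taxa = sorted({r.taxon or r.id for r in refdb.records})
        table = pd.DataFrame(
            0, index=taxa + [UNASSIGNED], columns=sorted(fastq_pairs_by_sample), dtype=int
        )
        details = []
    # ensure every sample appears as a column, even if it produced nothing
    for sample in fastq_pairs_by_sample:
        if sample not in table.columns:
            table[sample] = 0
    table = table[sorted(table.columns)]

    flagged = sorted(
        s for s in blanks if s in table.columns and table[s].sum() > 0
    )
    return PipelineResult(
        table=table,
        tallies=tallies,
        assignments=details,
        contaminated=bool(flagged),
        flagged_blanks=flagged,
    )
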