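"""Synthetic fixtures: planted marker alignments and mock-community reads.

Everything here is a pure function of (spec, seed): identical inputs give
byte-identical outputs, so every downstream module can be tested without any
external data.

Planted marker alignments
-------------------------
:func:`plant_marker_alignment` builds an alignment with the exact
architecture the scanner looks for — two conserved 20-30 bp flanks around a
short variable core — and returns the ground-truth coordinates.  The
construction guarantees that the planted flanks are the *only* maximal
conserved windows at a 1-mismatch-per-template tolerance:

* background columns rotate bases across templates, so every template
  mismatches any consensus at many positions in any window;
* the first and last core columns are hyper-variable "guard" columns
  (no base covers more than ~a quarter of the templates), with the two
  designated "subspecies" templates sharing a base so the pair's
  difference count is untouched;
* adjacent "killer" column pairs, where one designated template differs
  from the consensus at both columns, recur at least every ten columns
  through the core, so any window that reaches at least three columns into
  the core puts that template over the 1-mismatch budget;
* each flank carries single mismatches in at least seven templates, placed
  centrally enough that every window overlapping a flank boundary contains
  one of them.  Without such mismatches, exact boundary recovery is
  impossible: extending a perfectly conserved window by one column can
  never push any template past one mismatch.  The forward-flank default
  (12 templates: 10 T·G wobbles, 2 A·C) mirrors a realistic primer;
  the reverse default plants 7 wobbles.

The core's minimum pairwise difference count equals ``min_core_diffs``
exactly: the two subspecies templates differ only at the second one's
private mutation sites (``min_core_diffs`` of them); every other template
carries ``min_core_diffs + 2`` private sites of its own, all at disjoint
columns.

Mock-community reads
--------------------
:func:`simulate_mock_reads` draws paired 2x150 bp reads from the amplicon
fragment (forward primer + core + reverse-complemented reverse primer) of
each taxon in a stated composition, with per-base Phred-governed
substitution errors, optional per-mismatch PCR efficiency bias, and optional
contamination spike-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import markerdesign
from .seqio import (
    PrimerPair,
    Read,
    ReadPair,
    ReferencePanel,
    SeqRecord,
    reverse_complement,
)

_BASES = np.array(["A", "C", "G", "T"])


class InfeasibleSpec(ValueError):
    """The fixture spec cannot be realized."""


@dataclass(frozen=True)
class MarkerFixtureSpec:
    """Parameters of a planted marker alignment.

    Defaults mirror the marker architecture this toolkit was built around:
    19 templates, 25 bp flanks, a 167 bp core whose closest pair differs at
    5 sites, and 12 single-mismatch templates under the forward primer
    (10 T·G wobbles, 2 A·C pairings).
    """

    n_taxa: int = 19
    flank_len: int = 25
    core_len: int = 167
    min_core_diffs: int = 5
    background_len: int = 120
    fwd_mismatch_templates: int = 12
    rev_mismatch_templates: int = 7
    win_min: int = 20  # scanner window minimum the construction defends against
    seed: int = 0

    def validate(self) -> None:
        if not (10 <= self.n_taxa <= 20):
            raise InfeasibleSpec("n_taxa must be in [10, 20] for exact planting")
        if not (self.win_min <= self.flank_len <= 2 * self.win_min - 4):
            raise InfeasibleSpec(
                f"flank_len must be in [{self.win_min}, {2 * self.win_min - 4}]"
            )
        if self.core_len >= 200:
            raise InfeasibleSpec("core_len must be < 200")
        if self.core_len < 30:
            raise InfeasibleSpec("core_len too short for the guard/killer layout")
        if self.min_core_diffs < 1:
            raise InfeasibleSpec("min_core_diffs must be >= 1")
        for k in (self.fwd_mismatch_templates, self.rev_mismatch_templates):
            if not (7 <= k <= min(18, self.n_taxa - 1)):
                raise InfeasibleSpec(
                    "flank mismatch template counts must be in "
                    f"[7, {min(18, self.n_taxa - 1)}] "
                    "(>=7 pins the window boundaries)"
                )
        if self.background_len < 30:
            raise InfeasibleSpec("background_len must be >= 30")


@dataclass
class PlantedTruth:
    """Ground truth of a planted alignment, in alignment coordinates."""

    fwd_window: tuple[int, int]
    core: tuple[int, int]
    rev_window: tuple[int, int]
    fwd_primer: str
    rev_primer: str   # 5'->3', i.e. reverse complement of the rev-window consensus
    subspecies_pair: tuple[str, str]
    killer_template: str
    min_core_diffs: int


def _balanced_groups(rng: np.random.Generator, n: int) -> np.ndarray:
    """Assign n templates to 4 base groups as evenly as possible (max <= 5
    for n <= 20), in a seed-dependent order."""
    groups = np.array([i % 4 for i in range(n)])
    rng.shuffle(groups)
    return groups


def plant_marker_alignment(
    spec: MarkerFixtureSpec,
) -> tuple[ReferencePanel, PlantedTruth]:
    """Build the planted alignment and its ground truth (see module docs)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, L, C = spec.n_taxa, spec.flank_len, spec.core_len
    m = spec.min_core_diffs
    bg = spec.background_len
    w = spec.win_min

    special = rng.choice(n, size=3, replace=False)
    t1, t2, t3 = (int(x) for x in special)  # subspecies pair and killer template

    total = 2 * bg + 2 * L + C
    aln = np.empty((n, total), dtype="U1")

    # --- background: rotating bases; every template far from any consensus
    for j in list(range(bg)) + list(range(total - bg, total)):
        perm = rng.permutation(4)
        for t in range(n):
            aln[t, j] = _BASES[perm[(t + j) % 4]]

    # --- flanks
    fwd_start, fwd_end = bg, bg + L
    core_start, core_end = fwd_end, fwd_end + C
    rev_start, rev_end = core_end, core_end + L

    def build_flank(start: int, mm_templates: int, forward: bool) -> str:
        cons = _BASES[rng.integers(0, 4, size=L)].copy()
        # mismatch columns must sit centrally so that every window that
        # overlaps a flank boundary still contains them
        if forward:
            lo, hi = L - w + 2, w - 2
        else:
            lo, hi = L - w + 1, w - 3
        span = hi - lo
        tg_cols = [start + lo + span // 4, start + lo + (3 * span) // 4]
        ac_col = start + lo + span // 2
        # plus-strand letters that turn into primer T·G / A·C pairings;
        # a reverse primer is the reverse complement of the window consensus,
        # so the letters invert relative to the forward case
        if forward:
            tg_base, tg_var, ac_base, ac_var = "T", "C", "A", "G"
        else:
            tg_base, tg_var, ac_base, ac_var = "A", "G", "T", "C"
        cons[tg_cols[0] - start] = tg_base
        cons[tg_cols[1] - start] = tg_base
        cons[ac_col - start] = ac_base
        for t in range(n):
            aln[t, start : start + L] = cons
        carriers = rng.choice(n, size=mm_templates, replace=False)
        for i, t in enumerate(carriers):
            if i < 10:
                col = tg_cols[i % 2]
                aln[t, col] = tg_var   # primer T over annealed G: the wobble
            else:
                col = ac_col
                aln[t, col] = ac_var   # primer A over annealed C
        return "".join(cons)

    fwd_consensus = build_flank(fwd_start, spec.fwd_mismatch_templates, True)
    rev_consensus = build_flank(rev_start, spec.rev_mismatch_templates, False)

    # --- core: base sequence shared by everyone, then structured deviations
    core_base = _BASES[rng.integers(0, 4, size=C)]
    for t in range(n):
        aln[t, core_start:core_end] = core_base

    def variant(b: str) -> str:
        others = [x for x in "ACGT" if x != b]
        return others[int(rng.integers(0, 3))]

    # guard columns (first and last core column): hyper-variable, with the
    # subspecies pair sharing a base
    for col in (core_start, core_end - 1):
        groups = _balanced_groups(rng, n)
        perm = rng.permutation(4)
        for t in range(n):
            aln[t, col] = _BASES[perm[groups[t]]]
        aln[t2, col] = aln[t1, col]

    # killer pairs: template t3 deviates at two adjacent columns, repeating
    # at least every ten columns and hugging the far end of the core
    killer_cols: set[int] = set()
    p = 1
    while p + 1 <= C - 4:
        killer_cols.update((p, p + 1))
        p += 10
    killer_cols.update((C - 3, C - 2))
    for rel in sorted(killer_cols):
        col = core_start + rel
        aln[t3, col] = variant(str(core_base[rel]))

    # private mutation sites: disjoint columns, subspecies pair differing at
    # exactly m of them
    free = [
        rel for rel in range(1, C - 1) if rel not in killer_cols
    ]
    priv_other = m + 2
    need = m + priv_other * (n - 2)
    if need > len(free):
        raise InfeasibleSpec(
            f"core_len {C} too short: need {need} private sites, have {len(free)}"
        )
    chosen = rng.choice(len(free), size=need, replace=False)
    sites = [free[i] for i in chosen]
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = sites[cursor : cursor + k]
        cursor += k
        return out

    for rel in take(m):  # t2's private sites: the pair's only differences
        aln[t2, core_start + rel] = variant(str(core_base[rel]))
    for t in range(n):
        if t in (t1, t2):
            continue
        for rel in take(priv_other):
            aln[t, core_start + rel] = variant(str(core_base[rel]))

    ids = [f"T{t + 1:02d}" for t in range(n)]
    taxa = [f"sp{t + 1:02d}" for t in range(n)]
    records = [
        SeqRecord(id=ids[t], seq="".join(aln[t]), taxon=taxa[t])
        for t in range(n)
    ]
    panel = ReferencePanel(records)
    truth = PlantedTruth(
        fwd_window=(fwd_start, fwd_end),
        core=(core_start, core_end),
        rev_window=(rev_start, rev_end),
        fwd_primer=fwd_consensus,
        rev_primer=reverse_complement(rev_consensus),
        subspecies_pair=(ids[t1], ids[t2]),
        killer_template=ids[t3],
        min_core_diffs=m,
    )
    return panel, truth


def planted_primer_pair(truth: PlantedTruth, max_core_len: int = 200) -> PrimerPair:
    """The primer pair matching a planted alignment's ground truth."""
    from .seqio import Primer

    return PrimerPair(
        fwd=Primer(name="planted-F", seq=truth.fwd_primer, orientation="forward"),
        rev=Primer(name="planted-R", seq=truth.rev_primer, orientation="reverse"),
        max_core_len=max_core_len,
    )


# ---------------------------------------------------------------------------
# Mock-community read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockSpec:
    """One sample's worth of simulated amplicon sequencing.

    ``composition`` maps taxon label to the nominal read count before PCR
    bias.  Qualities are drawn per base from a clipped normal (MiSeq-like
    defaults: mean Q35, sd 3, clipped to [2, 40]); substitution errors occur
    per base with probability ``10^(-Q/10)`` unless ``error_free`` is set.
    Per-template read counts are scaled by
    ``pcr_bias_per_mismatch ** (primer mismatch count)`` before rounding.
    """

    composition: dict[str, int] = field(default_factory=dict)
    read_len: int = 150
    mean_q: float = 35.0
    sd_q: float = 3.0
    pcr_bias_per_mismatch: float = 1.0
    contamination: tuple[str, int] | None = None
    error_free: bool = False
    seed: int = 0


@dataclass
class MockSample:
    pairs: list[ReadPair]
    truth: pd.DataFrame  # columns: taxon, reads_emitted, primer_mismatches


def simulate_mock_reads(
    mockspec: MockSpec,
    pair: PrimerPair,
    panel: ReferencePanel,
    max_mm: int = 1,
) -> MockSample:
    """Simulate paired-end reads for one mock community sample.

    Every taxon in the composition (and the contamination spike, if any)
    must be amplifiable by ``pair`` from its template in ``panel``.
    """
    if not (0.0 < mockspec.pcr_bias_per_mismatch <= 1.0):
        raise ValueError("pcr_bias_per_mismatch must be in (0, 1]")
    rng = np.random.default_rng(mockspec.seed)
    amplicons, _failures = markerdesign.extract_amplicons(pair, panel, max_mm=max_mm)
    cores = dict(amplicons)
    taxon_of = {r.id: (r.taxon or r.id) for r in panel.records}
    by_taxon = {taxon_of[tid]: tid for tid in cores}

    def template_mismatches(tid: str) -> int:
        template = next(r for r in panel.records if r.id == tid).degapped
        mm = 0
        for primer in (pair.fwd, pair.rev):
            sites = markerdesign.find_binding_sites(primer, tid, template, max_mm)
            mm += min(s.mismatch_count for s in sites)
        return mm

    wanted = dict(mockspec.composition)
    if mockspec.contamination is not None:
        taxon, n_reads = mockspec.contamination
        wanted[taxon] = wanted.get(taxon, 0) + n_reads

    pairs_out: list[ReadPair] = []
    truth_rows = []
    for taxon in sorted(wanted):
        count = wanted[taxon]
        if count < 0:
            raise ValueError(f"negative read count for {taxon}")
        if taxon not in by_taxon:
            raise ValueError(f"taxon {taxon!r} is not amplifiable by the primer pair")
        tid = by_taxon[taxon]
        fragment = pair.fwd.seq + cores[tid] + reverse_complement(pair.rev.seq)
        if mockspec.read_len > len(fragment):
            raise ValueError(
                f"read_len {mockspec.read_len} exceeds fragment length "
                f"{len(fragment)} for {taxon}"
            )
        mm = template_mismatches(tid)
        n_eff = int(round(count * mockspec.pcr_bias_per_mismatch ** mm))
        for i in range(n_eff):
            r1 = _draw_read(rng, fragment, mockspec, f"{taxon}.{i}/1")
            r2 = _draw_read(
                rng, reverse_complement(fragment), mockspec, f"{taxon}.{i}/2"
            )
            pairs_out.append(ReadPair(r1=r1, r2=r2))
        truth_rows.append(
            {"taxon": taxon, "reads_emitted": n_eff, "primer_mismatches": mm}
        )
    truth = pd.DataFrame(truth_rows, columns=["taxon", "reads_emitted", "primer_mismatches"])
    return MockSample(pairs=pairs_out, truth=truth)


def _draw_read(
    rng: np.random.Generator, strand: str, spec: MockSpec, read_id: str
) -> Read:
    n = spec.read_len
    # error-free reads carry qualities consistent with zero errors, so the
    # quality-gated stages cannot stochastically drop what the error model
    # promised to keep
    q_floor = 30 if spec.error_free else 2
    quals = np.clip(
        np.rint(rng.normal(spec.mean_q, spec.sd_q, size=n)), q_floor, 40
    ).astype(int)
    bases = list(strand[:n])
    if not spec.error_free:
        p_err = 10.0 ** (-quals / 10.0)
        hits = np.nonzero(rng.random(n) < p_err)[0]
        for i in hits:
            others = [b for b in "ACGT" if b != bases[i]]
            bases[i] = others[int(rng.integers(0, 3))]
    return Read(id=read_id, seq="".join(bases), quals=list(quals))


def write_mock_sample(
    sample: MockSample, out_dir: str | Path, prefix: str = "mock"
) -> dict[str, Path]:
    """Write R1/R2 FASTQ and the truth table; returns the paths."""
    from .seqio import write_fastq_pair

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1 = out_dir / f"{prefix}_R1.fastq"
    r2 = out_dir / f"{prefix}_R2.fastq"
    truth = out_dir / f"{prefix}_truth.tsv"
    write_fastq_pair(sample.pairs, r1, r2)
    sample.truth.to_csv(truth, sep="\t", index=False)
    return {"r1": r1, "r2": r2, "truth": truth}
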