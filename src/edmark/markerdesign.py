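"""Marker discovery and primer evaluation on an aligned reference panel.

The design procedure encoded here searches a multiple alignment for the
classic metabarcoding architecture: two conserved primer-sized flanks
(20-30 bp, at most one mismatch against any template) bracketing a short
(<200 bp) variable core that carries the taxonomic signal.  It also provides
the primer-side arithmetic used to evaluate a designed pair: fractional G/C
content, nearest-neighbor melting temperature, mismatch-tolerant binding-site
search on both strands, duplex mismatch classification (T·G wobble vs A·C vs
other), and in-silico amplicon extraction.

Strand conventions
------------------
A *forward* primer has the plus-strand sense: it anneals to the minus strand,
so a primer base pairs with the complement of the plus-strand template base.
A *reverse* primer anneals to the plus strand directly, so its bases pair
with plus-strand bases.  Mismatches are classified by the duplex pair the
primer base forms with the template base on the annealed strand; the
unordered pairs {T,G} and {A,C} get their own classes because they are the
thermodynamically mildest non-canonical pairings.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    GAP,
    IUPAC_SETS,
    Primer,
    PrimerPair,
    ReferencePanel,
    reverse_complement,
)

_BASES = ("A", "C", "G", "T")

# ---------------------------------------------------------------------------
# Conservation profile
# ---------------------------------------------------------------------------


@dataclass
class ConservationProfile:
    """Per-column base counts across the templates of an aligned panel.

    ``counts`` maps each of ``A C G T gap ambig`` to an integer vector over
    alignment columns; the six vectors sum to ``n_templates`` columnwise.
    """

    counts: dict[str, np.ndarray]
    n_templates: int

    @property
    def length(self) -> int:
        return len(self.counts["A"])

    def column(self, j: int) -> dict[str, int]:
        return {k: int(v[j]) for k, v in self.counts.items()}

    def is_invariant(self, j: int) -> bool:
        """A column is invariant iff one concrete base covers every template."""
        return any(int(self.counts[b][j]) == self.n_templates for b in _BASES)

    def gap_only(self, j: int) -> bool:
        return int(self.counts["gap"][j]) == self.n_templates

    def consensus(self) -> str:
        """Majority base per column; ties toward the base yielding fewer
        total mismatches, then alphabetical (equal-count ties have equal
        mismatch totals, so this reduces to the alphabetical rule).
        Columns with no concrete base (all gap/ambiguous) yield ``-``.
        """
        stack = np.vstack([self.counts[b] for b in _BASES])  # alphabetical
        best = stack.argmax(axis=0)  # argmax takes the first (alphabetical) max
        cons = np.array(_BASES, dtype="U1")[best]
        cons[stack.max(axis=0) == 0] = GAP
        return "".join(cons)


def conservation_profile(panel: ReferencePanel) -> ConservationProfile:
    """Column-wise A/C/G/T/gap/ambiguity counts for an aligned panel."""
    if not panel.aligned:
        raise ValueError("conservation profile requires an aligned panel")
    if len(panel) < 2:
        raise ValueError("need at least 2 templates")
    arr = np.array([list(r.seq) for r in panel.records])
    counts = {b: (arr == b).sum(axis=0).astype(int) for b in _BASES}
    counts["gap"] = (arr == GAP).sum(axis=0).astype(int)
    known = sum(counts.values())
    counts["ambig"] = (len(panel) - known).astype(int)
    return ConservationProfile(counts=counts, n_templates=len(panel))


# ---------------------------------------------------------------------------
# Conserved-window search
# ---------------------------------------------------------------------------


@dataclass
class ConservedWindow:
    """A gap-free alignment window whose consensus is near-identical to
    every template."""

    start: int
    end: int
    consensus: str
    per_template_mismatches: dict[str, int]

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def max_mismatches(self) -> int:
        return max(self.per_template_mismatches.values())


def _matches_code(primer_base: str, template_char: str) -> bool:
    """Primer base vs (possibly degenerate) template base.

    A degenerate reference base counts as a match only when the primer base
    is contained in its IUPAC set — the conservative call.
    """
    tset = IUPAC_SETS.get(template_char)
    return tset is not None and primer_base in tset


def find_conserved_windows(
    profile: ConservationProfile,
    panel: ReferencePanel,
    win_min: int = 20,
    win_max: int = 30,
    max_mm_per_template: int = 1,
) -> list[ConservedWindow]:
    """All *maximal* gap-free windows of width ``win_min..win_max`` whose
    consensus differs from each template by at most ``max_mm_per_template``.

    Any sub-window of a passing window also passes, so only maximal windows
    (not contained in a wider passing window) are reported, widest first.
    """
    if win_min > win_max:
        raise ValueError(f"win_min {win_min} > win_max {win_max}")
    if not panel.aligned:
        raise ValueError("window search requires an aligned panel")
    cons = profile.consensus()
    length = profile.length
    arr = np.array([list(r.seq) for r in panel.records])
    cons_arr = np.array(list(cons))
    # mismatch[t, j]: template t vs consensus at column j (IUPAC-aware)
    mism = np.ones(arr.shape, dtype=np.int32)
    for code, bases in IUPAC_SETS.items():
        hit = arr == code
        if hit.any():
            ok = np.isin(cons_arr, list(bases))
            mism[hit & ok[None, :]] = 0
    eligible = (profile.counts["gap"] == 0) & (cons_arr != GAP)

    csum = np.concatenate(
        [np.zeros((arr.shape[0], 1), dtype=np.int64), np.cumsum(mism, axis=1)],
        axis=1,
    )
    esum = np.concatenate([[0], np.cumsum(~eligible)])

    def passes(s: int, e: int) -> bool:
        if s < 0 or e > length or e - s > win_max:
            return False
        if esum[e] - esum[s] > 0:
            return False
        return bool((csum[:, e] - csum[:, s]).max() <= max_mm_per_template)

    windows: list[ConservedWindow] = []
    for w in range(win_max, win_min - 1, -1):
        for s in range(0, length - w + 1):
            e = s + w
            if not passes(s, e):
                continue
            if passes(s - 1, e) or passes(s, e + 1):
                continue  # contained in a wider passing window
            mm = (csum[:, e] - csum[:, s]).astype(int)
            windows.append(
                ConservedWindow(
                    start=s,
                    end=e,
                    consensus=cons[s:e],
                    per_template_mismatches={
                        r.id: int(mm[t]) for t, r in enumerate(panel.records)
                    },
                )
            )
    windows.sort(key=lambda win: (-win.width, win.start))
    return windows


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


@dataclass
class MarkerCandidate:
    """A primer-pair candidate: two conserved windows around a variable core."""

    fwd_window: tuple[int, int]
    rev_window: tuple[int, int]
    core: tuple[int, int]
    fwd_primer: str  # consensus of fwd window, 5'->3' plus strand
    rev_primer: str  # reverse complement of rev-window consensus
    core_lengths: dict[str, int]  # per-template ungapped core length
    fwd_mismatches: dict[str, int]
    rev_mismatches: dict[str, int]
    core_diffs_min: int = 0
    core_diffs_mean: float = 0.0
    core_diffs_max: int = 0
    fwd_tm: float = field(default=float("nan"))
    rev_tm: float = field(default=float("nan"))
    fwd_gc: float = field(default=float("nan"))
    rev_gc: float = field(default=float("nan"))


def _pairwise_core_diffs(panel: ReferencePanel, start: int, end: int) -> list[int]:
    """Hamming counts over core columns, pairwise deletion of gap columns."""
    out = []
    seqs = [r.seq[start:end] for r in panel.records]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            out.append(
                sum(
                    1
                    for x, y in zip(a, b)
                    if x != GAP and y != GAP and x != y
                )
            )
    return out


def enumerate_candidates(
    windows: list[ConservedWindow],
    panel: ReferencePanel,
    max_core_len: int = 200,
    min_core_diffs: int = 5,
    thermo: "ThermoParams | None" = None,
) -> list[MarkerCandidate]:
    """All ordered window pairs bracketing a usable variable core.

    A pair qualifies when, per template, the ungapped core between the two
    windows is non-empty and shorter than ``max_core_len``, and the minimum
    pairwise core difference count is at least ``min_core_diffs``.
    """
    candidates: list[MarkerCandidate] = []
    for wf in windows:
        for wr in windows:
            if wf.end > wr.start:
                continue
            s, e = wf.end, wr.start
            core_lens = {
                r.id: len(r.seq[s:e].replace(GAP, "")) for r in panel.records
            }
            if any(n == 0 or n >= max_core_len for n in core_lens.values()):
                continue
            diffs = _pairwise_core_diffs(panel, s, e)
            if min(diffs) < min_core_diffs:
                continue
            fwd = wf.consensus
            rev = reverse_complement(wr.consensus)
            cand = MarkerCandidate(
                fwd_window=(wf.start, wf.end),
                rev_window=(wr.start, wr.end),
                core=(s, e),
                fwd_primer=fwd,
                rev_primer=rev,
                core_lengths=core_lens,
                fwd_mismatches=dict(wf.per_template_mismatches),
                rev_mismatches=dict(wr.per_template_mismatches),
                core_diffs_min=min(diffs),
                core_diffs_mean=float(np.mean(diffs)),
                core_diffs_max=max(diffs),
                fwd_gc=gc_content(fwd),
                rev_gc=gc_content(rev),
                fwd_tm=nn_tm(fwd, thermo),
                rev_tm=nn_tm(rev, thermo),
            )
            candidates.append(cand)
    return candidates


# ---------------------------------------------------------------------------
# Primer thermodynamics
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """G+C percentage; degenerate codes contribute their G/C fraction
    (S -> 1, R/Y/K/M -> 0.5, N -> 0.5, B/V -> 2/3, D/H -> 1/3).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if GAP in seq:
        raise ValueError("gapped sequence")
    total = 0.0
    for ch in seq:
        try:
            s = IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(f"invalid base {ch!r}") from None
        total += len(s & {"G", "C"}) / len(s)
    return 100.0 * total / len(seq)


def at_content(seq: str) -> float:
    """A+T percentage, the complement of :func:`gc_content`."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    total = 0.0
    for ch in seq:
        s = IUPAC_SETS[ch]
        total += len(s & {"A", "T"}) / len(s)
    return 100.0 * total / len(seq)


# SantaLucia (1998) unified nearest-neighbor parameters.
# Signed values: dH in kcal/mol, dS in cal/(mol*K); stacking terms are
# stabilizing (negative), initiation terms destabilizing.
_NN_STACK_SL98 = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# Breslauer et al. (1986), provided as an alternative table.
_NN_STACK_BR86 = {
    "AA": (-9.1, -24.0), "AT": (-8.6, -23.9), "TA": (-6.0, -16.9),
    "CA": (-5.8, -12.9), "GT": (-6.5, -17.3), "CT": (-7.8, -20.8),
    "GA": (-5.6, -13.5), "CG": (-11.9, -27.8), "GC": (-11.1, -26.7),
    "GG": (-11.0, -26.6),
}


def _full_table(stack: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    out = dict(stack)
    for k, v in stack.items():
        out.setdefault(comp[k[1]] + comp[k[0]], v)
    return out


_NN_TABLES = {
    "santalucia98": _full_table(_NN_STACK_SL98),
    "breslauer86": _full_table(_NN_STACK_BR86),
}

_R_GAS = 1.987  # cal/(mol*K)


@dataclass(frozen=True)
class ThermoParams:
    """Frozen nearest-neighbor Tm convention.

    The default set reproduces the melting temperatures reported by the
    OligoCalc-style web calculators this toolkit was checked against:
    SantaLucia 1998 unified stacking with terminal initiation, an
    empirically calibrated duplex-initiation term, monovalent salt folded in
    as ``16.6 log10 [Na+]``, and ``Tm = dH / (dS + R ln(Ct/4)) - 273.15``.
    """

    nn_table: str = "santalucia98"
    na_molar: float = 0.05          # monovalent salt, mol/L
    primer_molar: float = 1e-7      # total strand concentration Ct, mol/L
    dh_init: float = -0.6           # duplex initiation, kcal/mol (calibrated)
    ds_init: float = 9.0            # duplex initiation, cal/(mol*K) (calibrated)
    terminal_init: bool = True      # SantaLucia terminal A/T / G/C penalties

    def __post_init__(self) -> None:
        if self.na_molar <= 0 or self.primer_molar <= 0:
            raise ValueError("concentrations must be positive")
        if self.nn_table not in _NN_TABLES:
            raise ValueError(f"unknown NN table {self.nn_table!r}")


DEFAULT_THERMO = ThermoParams()


def nn_tm(seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Requires an unambiguous, gap-free sequence of length >= 8.  The value is
    symmetric under reverse complement (the duplex is the same molecule).
    """
    params = params or DEFAULT_THERMO
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("nn_tm requires length >= 8")
    if set(seq) - set("ACGT"):
        raise ValueError("nn_tm requires unambiguous A/C/G/T sequence")
    table = _NN_TABLES[params.nn_table]
    dh = params.dh_init
    ds = params.ds_init
    for i in range(len(seq) - 1):
        h, s = table[seq[i : i + 2]]
        dh += h
        ds += s
    if params.terminal_init:
        for end in (seq[0], seq[-1]):
            if end in "AT":
                dh += 2.3
                ds += 4.1
            else:
                dh += 0.1
                ds += -2.8
    tm = (
        1000.0 * dh / (ds + _R_GAS * math.log(params.primer_molar / 4.0))
        - 273.15
        + 16.6 * math.log10(params.na_molar)
    )
    return tm


# ---------------------------------------------------------------------------
# Binding sites and in-silico PCR
# ---------------------------------------------------------------------------

WOBBLE_TG = "T·G"
PAIR_AC = "A·C"
PAIR_OTHER = "other"


@dataclass
class Mismatch:
    offset: int            # position within the primer, 5'->3'
    primer_base: str
    template_base: str     # base on the annealed template strand
    pairing_class: str


@dataclass
class BindingSite:
    template_id: str
    start: int             # 0-based plus-strand start of the matched region
    orientation: str       # 'forward' | 'reverse'
    mismatch_count: int
    mismatches: list[Mismatch]


def _classify(primer_base: str, annealed_base: str) -> str:
    pair = {primer_base, annealed_base}
    if pair == {"T", "G"}:
        return WOBBLE_TG
    if pair == {"A", "C"}:
        return PAIR_AC
    return PAIR_OTHER


_PLUS_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_binding_sites(
    primer: Primer,
    template_id: str,
    template: str,
    max_mm: int,
) -> list[BindingSite]:
    """All plus-strand positions where the primer binds with <= ``max_mm``
    mismatches.

    A forward primer is compared against the plus strand as written; a
    reverse primer is compared as its reverse complement (it anneals to the
    plus strand).  Degenerate template bases match when the primer base is
    contained in their IUPAC set.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    template = template.upper().replace(GAP, "")
    k = len(primer)
    if len(template) < k:
        return []
    query = (
        primer.seq if primer.orientation == "forward"
        else reverse_complement(primer.seq)
    )
    tarr = np.frombuffer(template.encode(), dtype="S1")
    n_starts = len(template) - k + 1
    counts = np.zeros(n_starts, dtype=np.int32)
    mm_cols: list[np.ndarray] = []
    for off in range(k):
        allowed = {
            ch for ch, s in IUPAC_SETS.items() if query[off] in s
        }
        ok = np.isin(tarr[off : off + n_starts], [c.encode() for c in allowed])
        mm_cols.append(~ok)
        counts += (~ok).astype(np.int32)
    sites: list[BindingSite] = []
    for i in np.nonzero(counts <= max_mm)[0]:
        mms: list[Mismatch] = []
        for off in range(k):
            if not mm_cols[off][i]:
                continue
            plus_base = template[i + off]
            if primer.orientation == "forward":
                p_base = primer.seq[off]
                annealed = _PLUS_COMP.get(plus_base, "N")
                p_off = off
            else:
                p_off = k - 1 - off
                p_base = primer.seq[p_off]
                annealed = plus_base
            mms.append(
                Mismatch(
                    offset=p_off,
                    primer_base=p_base,
                    template_base=annealed,
                    pairing_class=_classify(p_base, annealed),
                )
            )
        sites.append(
            BindingSite(
                template_id=template_id,
                start=int(i),
                orientation=primer.orientation,
                mismatch_count=int(counts[i]),
                mismatches=mms,
            )
        )
    return sites


def classify_mismatches(sites: list[BindingSite]) -> Counter:
    """Tally of duplex pairing classes over all mismatches in the sites."""
    tally: Counter = Counter({WOBBLE_TG: 0, PAIR_AC: 0, PAIR_OTHER: 0})
    for site in sites:
        for mm in site.mismatches:
            tally[mm.pairing_class] += 1
    return tally


@dataclass
class AmpliconFailure:
    template_id: str
    reason: str


def extract_amplicons(
    pair: PrimerPair,
    panel: ReferencePanel,
    max_mm: int = 1,
) -> tuple[list[tuple[str, str]], list[AmpliconFailure]]:
    """In-silico PCR: the inter-primer core per template, plus-strand.

    A template amplifies when there is exactly one compatible
    forward/reverse site pair whose core (primers excluded) is shorter than
    ``pair.max_core_len``.  Templates with zero or multiple products are
    reported as failures, not fatal errors.
    """
    amplicons: list[tuple[str, str]] = []
    failures: list[AmpliconFailure] = []
    for rec in panel.records:
        template = rec.degapped
        f_sites = find_binding_sites(pair.fwd, rec.id, template, max_mm)
        r_sites = find_binding_sites(pair.rev, rec.id, template, max_mm)
        products = []
        for f in f_sites:
            core_start = f.start + len(pair.fwd)
            for r in r_sites:
                core = template[core_start : r.start]
                if r.start >= core_start and 0 < len(core) < pair.max_core_len:
                    products.append(core)
        if not f_sites or not r_sites:
            missing = []
            if not f_sites:
                missing.append("forward")
            if not r_sites:
                missing.append("reverse")
            failures.append(
                AmpliconFailure(rec.id, f"no {'/'.join(missing)} primer site")
            )
        elif len(products) == 0:
            failures.append(
                AmpliconFailure(rec.id, "no compatible site pair within max_core_len")
            )
        elif len(products) > 1:
            failures.append(
                AmpliconFailure(rec.id, f"{len(products)} alternative products")
            )
        else:
            amplicons.append((rec.id, products[0]))
    return amplicons, failures
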