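"""Endogenous-target-mimic (eTM) detection.

An eTM is an lncRNA that carries a near-complementary binding site for a
miRNA and sequesters it instead of being cleaved.  A candidate site is
rendered as an antiparallel duplex — the miRNA 5'->3' against the site
read 3'->5' — and judged by three pairing rules:

1. **seed rule** — miRNA positions 2-8 (1-based from the miRNA 5' end)
   must be perfect Watson-Crick pairs; a G:U wobble there fails the rule;
2. **bulge rule** — unpaired (bulged) nucleotides are only tolerated when
   anchored within miRNA positions 9-12, and each bulge run may be at most
   ``max_bulge`` nucleotides long;
3. **mismatch budget** — across the pairing region the total number of
   mismatches plus G:U wobbles must be fewer than three (i.e. at most 2).

Terminal columns where one strand has no partner (a dangling end of either
molecule) are overhangs, not bulges: they are outside the pairing region
and are ignored by rules 2 and 3.  A mismatch at miRNA position 1 is
allowed by rule 1 (whose range starts at 2) but still counts toward the
rule-3 budget.

Position numbering is 1-based from the miRNA 5' end throughout, matching
the way plant eTM rules are conventionally stated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io_formats import Alphabet, SequenceRecord

__all__ = [
    "GAP",
    "PairClass",
    "EtmParams",
    "AlignmentColumn",
    "PairingAlignment",
    "EtmRuleReport",
    "pair_class",
    "complement_rna",
    "reverse_complement_rna",
    "alignment_from_gapped_site",
    "best_alignment",
    "evaluate_alignment",
    "scan_lncrna",
    "render_alignment",
]

GAP = "-"

_RNA = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


class PairClass(str, enum.Enum):
    watson_crick = "watson_crick"
    wobble = "wobble"
    mismatch = "mismatch"
    mirna_bulge = "mirna_bulge"  # miRNA base unpaired (gap on the site strand)
    target_bulge = "target_bulge"  # site base unpaired (gap on the miRNA strand)


def pair_class(a: str, b: str) -> PairClass:
    """Classify one duplex column of two RNA residues.

    A:U / U:A / G:C / C:G are Watson-Crick; G:U / U:G are wobbles;
    anything else is a mismatch.
    """
    if a not in _RNA or b not in _RNA:
        raise ValueError(f"invalid RNA residue pair ({a!r}, {b!r})")
    if _COMPLEMENT[a] == b:
        return PairClass.watson_crick
    if (a, b) in _WOBBLE:
        return PairClass.wobble
    return PairClass.mismatch


def complement_rna(residue: str) -> str:
    return _COMPLEMENT[residue]


def reverse_complement_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class EtmParams:
    """Tunable rule parameters; the defaults encode the canonical rules."""

    seed_start: int = 2  # first miRNA position that must be Watson-Crick
    seed_end: int = 8  # last such position (inclusive)
    bulge_anchor_start: int = 9  # bulges must be anchored in this window
    bulge_anchor_end: int = 12
    max_bulge: int = 3  # longest tolerated bulge run, nucleotides
    max_mismatch_wobble: int = 2  # rule 3: "fewer than three" => <= 2


@dataclass(frozen=True)
class AlignmentColumn:
    """One antiparallel duplex column; exactly one char may be the gap."""

    mirna_char: str
    target_char: str
    mirna_pos: int | None  # 1-based from miRNA 5' end; None for miRNA-gap columns
    pair_class: PairClass


@dataclass(frozen=True)
class PairingAlignment:
    """A rendered miRNA:site duplex.

    ``columns`` run from the miRNA 5' end to its 3' end; because the duplex
    is antiparallel, target characters therefore run from the site 3' end
    to its 5' end.  ``site_start``/``site_end`` are 0-based half-open
    offsets of the site on the lncRNA transcript (5'->3').
    """

    mirna_id: str
    lncrna_id: str
    mirna_seq: str
    site_seq: str  # lncRNA subsequence, 5'->3'
    columns: tuple[AlignmentColumn, ...]
    site_start: int = 0
    site_end: int = 0

    def __post_init__(self) -> None:
        mirna = "".join(c.mirna_char for c in self.columns if c.mirna_char != GAP)
        if mirna != self.mirna_seq:
            raise ValueError("alignment columns do not spell the miRNA sequence")
        target = "".join(c.target_char for c in self.columns if c.target_char != GAP)
        if target != self.site_seq[::-1]:
            raise ValueError(
                "alignment columns do not spell the reversed site sequence"
            )
        pos = [c.mirna_pos for c in self.columns if c.mirna_pos is not None]
        if pos != sorted(set(pos)) or (pos and pos != list(range(pos[0], pos[-1] + 1))):
            raise ValueError("miRNA positions must be strictly increasing")


@dataclass(frozen=True)
class EtmRuleReport:
    """Per-rule verdicts for one alignment."""

    rule1_ok: bool
    rule2_ok: bool
    rule3_ok: bool
    n_mismatch: int
    n_wobble: int
    mismatch_positions: tuple[int, ...]
    wobble_positions: tuple[int, ...]
    bulges: tuple[tuple[int, int, str], ...]  # (anchor miRNA pos, length, side)

    @property
    def verdict(self) -> bool:
        return self.rule1_ok and self.rule2_ok and self.rule3_ok

    @property
    def score(self) -> int:
        """Total mismatches + wobbles; lower is a tighter duplex."""
        return self.n_mismatch + self.n_wobble


def _build_columns(
    mirna_seq: str, revsite_gapped: str, mirna_gapped: str
) -> tuple[AlignmentColumn, ...]:
    """Pair two equal-length gapped strings into classified columns."""
    cols: list[AlignmentColumn] = []
    pos = 0
    for m, t in zip(mirna_gapped, revsite_gapped):
        if m == GAP and t == GAP:
            raise ValueError("double-gap column")
        if m != GAP:
            pos += 1
            mp: int | None = pos
        else:
            mp = None
        if m == GAP:
            pc = PairClass.target_bulge
        elif t == GAP:
            pc = PairClass.mirna_bulge
        else:
            pc = pair_class(m, t)
        cols.append(AlignmentColumn(m, t, mp, pc))
    return tuple(cols)


def alignment_from_gapped_site(
    mirna_seq: str,
    gapped_site_5to3: str,
    mirna_id: str = "mirna",
    lncrna_id: str = "lncrna",
    site_start: int = 0,
) -> PairingAlignment:
    """Build an alignment from a site string printed 5'->3' with ``-`` gaps.

    This is the rendering used in published eTM tables: the site is written
    5'->3' with gap characters marking unpaired miRNA bases.  The string is
    reversed into pairing orientation and paired column-by-column against
    the miRNA.  The gapped string must contain exactly as many columns as
    the miRNA has bases (only the site strand can carry gaps in this
    rendering).
    """
    revsite = gapped_site_5to3[::-1]
    if len(revsite) != len(mirna_seq):
        raise ValueError(
            f"gapped site has {len(revsite)} columns but miRNA has "
            f"{len(mirna_seq)} bases; cannot pair one-to-one"
        )
    site_seq = gapped_site_5to3.replace(GAP, "")
    cols = _build_columns(mirna_seq, revsite, mirna_seq)
    return PairingAlignment(
        mirna_id,
        lncrna_id,
        mirna_seq,
        site_seq,
        cols,
        site_start,
        site_start + len(site_seq),
    )


def evaluate_alignment(
    aln: PairingAlignment, params: EtmParams | None = None
) -> EtmRuleReport:
    """Apply the three eTM rules to one alignment.

    Leading and trailing gap runs are dangling-end overhangs: they are
    trimmed off before any counting, so they neither count as bulges
    (rule 2) nor toward the mismatch/wobble budget (rule 3).
    """
    params = params or EtmParams()
    cols = list(aln.columns)
    lo, hi = 0, len(cols)
    while lo < hi and (cols[lo].mirna_char == GAP or cols[lo].target_char == GAP):
        lo += 1
    while hi > lo and (cols[hi - 1].mirna_char == GAP or cols[hi - 1].target_char == GAP):
        hi -= 1
    region = cols[lo:hi]

    n_mm = n_wb = 0
    mm_pos: list[int] = []
    wb_pos: list[int] = []
    for c in region:
        if c.pair_class is PairClass.mismatch:
            n_mm += 1
            mm_pos.append(c.mirna_pos)  # type: ignore[arg-type]
        elif c.pair_class is PairClass.wobble:
            n_wb += 1
            wb_pos.append(c.mirna_pos)  # type: ignore[arg-type]

    # rule 1: every seed position must appear in the region as Watson-Crick
    seed = range(params.seed_start, params.seed_end + 1)
    wc_positions = {
        c.mirna_pos for c in region if c.pair_class is PairClass.watson_crick
    }
    rule1_ok = all(p in wc_positions for p in seed)

    # rule 2: collect maximal bulge runs inside the pairing region
    bulges: list[tuple[int, int, str]] = []
    rule2_ok = True
    i = 0
    while i < len(region):
        c = region[i]
        if c.pair_class in (PairClass.mirna_bulge, PairClass.target_bulge):
            side = "mirna" if c.pair_class is PairClass.mirna_bulge else "target"
            j = i
            while j < len(region) and region[j].pair_class is c.pair_class:
                j += 1
            run = region[i:j]
            length = j - i
            if side == "mirna":
                # anchor = first bulged miRNA base; whole run must sit in window
                anchor = run[0].mirna_pos
                positions = [col.mirna_pos for col in run]
                ok = all(
                    params.bulge_anchor_start <= p <= params.bulge_anchor_end
                    for p in positions
                )
            else:
                # anchor = the miRNA base 5' of the inserted site nucleotides
                anchor = region[i - 1].mirna_pos if i > 0 else 0
                ok = (
                    params.bulge_anchor_start
                    <= (anchor or 0)
                    <= params.bulge_anchor_end
                )
            if length > params.max_bulge:
                ok = False
            bulges.append((anchor or 0, length, side))
            rule2_ok = rule2_ok and ok
            i = j
        else:
            i += 1

    rule3_ok = (n_mm + n_wb) <= params.max_mismatch_wobble

    return EtmRuleReport(
        rule1_ok,
        rule2_ok,
        rule3_ok,
        n_mm,
        n_wb,
        tuple(mm_pos),
        tuple(wb_pos),
        tuple(bulges),
    )


# ---------------------------------------------------------------------------
# Candidate enumeration


def _candidate_alignments(
    mirna: str,
    lncrna_seq: str,
    site_start: int,
    params: EtmParams,
    mirna_id: str,
    lncrna_id: str,
    prefilter: bool = False,
):
    """Yield candidate alignments for one site anchor position.

    Candidates: the gapless duplex, plus every single bulge run of length
    1..max_bulge on either strand anchored at each position of the bulge
    window.  ``site_start`` fixes where the site's 3' end region begins on
    the lncRNA; the site length varies with the bulge placement.
    """
    L = len(mirna)
    n = len(lncrna_seq)
    anchors = range(params.bulge_anchor_start, params.bulge_anchor_end + 1)

    # Cheap seed prefilter: when every allowed bulge anchor lies 3' of the
    # seed window, the seed columns pair miRNA position i with revsite[i-1]
    # in every candidate, so a failed seed kills all of them identically.
    check_seed = prefilter and params.bulge_anchor_start > params.seed_end

    def seed_ok(revsite: str) -> bool:
        if not check_seed:
            return True
        for i in range(params.seed_start - 1, params.seed_end):
            if i >= len(revsite) or _COMPLEMENT[mirna[i]] != revsite[i]:
                return False
        return True

    def make(site_len: int, mirna_gapped: str, revsite_from: str | None = None):
        site_end = site_start + site_len
        if site_end > n:
            return None
        site = lncrna_seq[site_start:site_end]
        revsite = site[::-1]
        if not seed_ok(revsite):
            return None
        return site, revsite, site_end

    # gapless
    got = make(L, mirna)
    if got:
        site, revsite, site_end = got
        cols = _build_columns(mirna, revsite, mirna)
        yield PairingAlignment(
            mirna_id, lncrna_id, mirna, site, cols, site_start, site_end
        )

    for b in range(1, params.max_bulge + 1):
        # target-side bulge: b extra site bases inserted after miRNA pos p
        for p in anchors:
            if p >= L:
                continue
            got = make(L + b, mirna)
            if not got:
                continue
            site, revsite, site_end = got
            mg = mirna[:p] + GAP * b + mirna[p:]
            cols = _build_columns(mirna, revsite, mg)
            yield PairingAlignment(
                mirna_id, lncrna_id, mirna, site, cols, site_start, site_end
            )
        # miRNA-side bulge: miRNA positions q..q+b-1 unpaired; run must fit
        # entirely inside the anchor window
        for q in anchors:
            if q + b - 1 > params.bulge_anchor_end or q + b - 1 >= L:
                continue
            got = make(L - b, mirna)
            if not got:
                continue
            site, revsite, site_end = got
            rg = revsite[: q - 1] + GAP * b + revsite[q - 1 :]
            cols = _build_columns(mirna, rg, mirna)
            yield PairingAlignment(
                mirna_id, lncrna_id, mirna, site, cols, site_start, site_end
            )


def _sort_key(hit: tuple[PairingAlignment, EtmRuleReport]):
    aln, rep = hit
    n_bulge = sum(length for _, length, _ in rep.bulges)
    return (rep.score, n_bulge, rep.n_wobble, aln.site_start, aln.site_end)


def best_alignment(
    mirna_seq: str,
    site_seq: str,
    params: EtmParams | None = None,
    mirna_id: str = "mirna",
    lncrna_id: str = "lncrna",
) -> tuple[PairingAlignment, EtmRuleReport]:
    """Best-scoring alignment of a miRNA against one excised site.

    Used when a site is given without an explicit gapped rendering (for
    example a site longer than the miRNA, implying inserted nucleotides
    at an unspecified anchor).  All candidate placements whose site length
    matches are evaluated and the best is returned: passing alignments
    first, then fewest mismatches+wobbles, fewest bulged bases, fewest
    wobbles.
    """
    params = params or EtmParams()
    hits = [
        (aln, evaluate_alignment(aln, params))
        for aln in _candidate_alignments(
            mirna_seq, site_seq, 0, params, mirna_id, lncrna_id
        )
        if len(aln.site_seq) == len(site_seq)
    ]
    if not hits:
        raise ValueError(
            f"no candidate alignment pairs a {len(mirna_seq)}-nt miRNA with a "
            f"{len(site_seq)}-nt site under max_bulge={params.max_bulge}"
        )
    return min(hits, key=lambda h: (not h[1].verdict, *_sort_key(h)))


def scan_lncrna(
    mirna: SequenceRecord,
    lncrna: SequenceRecord,
    params: EtmParams | None = None,
) -> list[tuple[PairingAlignment, EtmRuleReport]]:
    """Scan an lncRNA transcript for sites satisfying all three eTM rules.

    At every transcript offset, candidate duplexes are enumerated (gapless
    plus every single bulge placement allowed by the parameters) and
    evaluated; only verdict-true hits are kept.  Overlapping hits of the
    same miRNA are deduplicated best-score-first, and the result is sorted
    by site start then by mismatch+wobble count.
    """
    params = params or EtmParams()
    if Alphabet(mirna.alphabet) is not Alphabet.RNA or Alphabet(
        lncrna.alphabet
    ) is not Alphabet.RNA:
        raise ValueError("scan_lncrna requires RNA-alphabet records")
    if len(lncrna) < len(mirna):
        raise ValueError(
            f"lncRNA {lncrna.id!r} shorter than miRNA {mirna.id!r}"
        )
    hits: list[tuple[PairingAlignment, EtmRuleReport]] = []
    for s in range(0, len(lncrna.residues) - len(mirna.residues) + params.max_bulge + 1):
        per_site: list[tuple[PairingAlignment, EtmRuleReport]] = []
        for aln in _candidate_alignments(
            mirna.residues, lncrna.residues, s, params, mirna.id, lncrna.id,
            prefilter=True,
        ):
            rep = evaluate_alignment(aln, params)
            if rep.verdict:
                per_site.append((aln, rep))
        if per_site:
            # one best alignment per site anchor
            hits.append(min(per_site, key=_sort_key))

    # deduplicate overlapping hits, best score first
    kept: list[tuple[PairingAlignment, EtmRuleReport]] = []
    for hit in sorted(hits, key=_sort_key):
        aln = hit[0]
        if any(
            aln.site_start < k.site_end and k.site_start < aln.site_end
            for k, _ in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h[0].site_start, h[1].score))
    return kept


def render_alignment(aln: PairingAlignment) -> str:
    """Three-line text rendering (miRNA 5'->3' on top, pairing marks, site)."""
    marks = {
        PairClass.watson_crick: "|",
        PairClass.wobble: "o",
        PairClass.mismatch: ".",
        PairClass.mirna_bulge: " ",
        PairClass.target_bulge: " ",
    }
    top = "".join(c.mirna_char for c in aln.columns)
    mid = "".join(marks[c.pair_class] for c in aln.columns)
    bot = "".join(c.target_char for c in aln.columns)
    return f"miRNA 5' {top} 3'\n         {mid}\nsite  3' {bot} 5'"
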