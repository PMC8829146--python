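"""Independent brute-force oracles used to cross-check the production code.

Everything here is written from scratch against the stated rules, without
importing the implementation's classification or enumeration helpers, so
that agreement between the two is informative.
"""

from __future__ import annotations

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _classify(m: str, t: str) -> str:
    """Independent column classification: wc / wobble / mm."""
    if (m, t) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return "wc"
    if (m, t) in (("G", "U"), ("U", "G")):
        return "wobble"
    return "mm"


def _check_rules(
    pairs: list[tuple[int | None, str | None]],
    mirna: str,
    max_bulge: int = 3,
) -> tuple[bool, int, int, int]:
    """Evaluate one alignment given as a list of (mirna_pos, site_char).

    ``mirna_pos`` None marks a column where only the site has a base
    (inserted site nucleotide); ``site_char`` None marks an unpaired miRNA
    base.  Returns (verdict, n_mm, n_wb, n_bulged_bases).  Written as a
    single pass with explicit run tracking, unlike the implementation.
    """
    # trim terminal one-sided columns (overhangs)
    def one_sided(col):
        return col[0] is None or col[1] is None

    lo, hi = 0, len(pairs)
    while lo < hi and one_sided(pairs[lo]):
        lo += 1
    while hi > lo and one_sided(pairs[hi - 1]):
        hi -= 1
    region = pairs[lo:hi]

    n_mm = n_wb = n_bulged = 0
    seed_wc = {p: False for p in range(2, 9)}
    rule2 = True
    i = 0
    while i < len(region):
        pos, ch = region[i]
        if pos is not None and ch is not None:
            cls = _classify(mirna[pos - 1], ch)
            if cls == "mm":
                n_mm += 1
            elif cls == "wobble":
                n_wb += 1
            elif pos in seed_wc:
                seed_wc[pos] = True
            i += 1
        elif ch is None:
            # run of unpaired miRNA bases: every one must sit in 9..12
            j = i
            run_pos = []
            while j < len(region) and region[j][1] is None:
                run_pos.append(region[j][0])
                j += 1
            if not all(9 <= p <= 12 for p in run_pos) or len(run_pos) > max_bulge:
                rule2 = False
            n_bulged += len(run_pos)
            i = j
        else:
            # run of inserted site bases: anchored after the miRNA base 5'
            j = i
            while j < len(region) and region[j][0] is None:
                j += 1
            anchor = region[i - 1][0] if i > 0 else 0
            if not (9 <= (anchor or 0) <= 12) or (j - i) > max_bulge:
                rule2 = False
            n_bulged += j - i
            i = j

    rule1 = all(seed_wc.values())
    rule3 = (n_mm + n_wb) <= 2
    return rule1 and rule2 and rule3, n_mm, n_wb, n_bulged


def brute_force_scan(
    mirna: str, lncrna: str, max_bulge: int = 3
) -> list[tuple[int, int, int, int]]:
    """All verdict-true sites of ``mirna`` on ``lncrna``.

    Enumerates, for every window, every antiparallel alignment with at
    most one contiguous gap run on either strand at ANY interior position
    (the rule check rejects badly anchored ones), evaluates it with the
    independent rule checker, keeps the best alignment per window start,
    and deduplicates overlaps best-first.  Returns sorted tuples
    (site_start, site_end, n_mm, n_wb).
    """
    L = len(mirna)
    n = len(lncrna)
    candidates: dict[int, list[tuple]] = {}

    def consider(start: int, site: str, pairs) -> None:
        verdict, n_mm, n_wb, n_bulged = _check_rules(pairs, mirna, max_bulge)
        if verdict:
            key = (n_mm + n_wb, n_bulged, n_wb, start, start + len(site))
            candidates.setdefault(start, []).append(
                (key, (start, start + len(site), n_mm, n_wb))
            )

    for start in range(n):
        # gapless
        if start + L <= n:
            site = lncrna[start : start + L]
            rev = site[::-1]
            consider(start, site, [(i + 1, rev[i]) for i in range(L)])
        for b in range(1, max_bulge + 1):
            # inserted site bases after any miRNA position p
            if start + L + b <= n:
                site = lncrna[start : start + L + b]
                rev = site[::-1]
                for p in range(1, L):
                    pairs = []
                    k = 0
                    for pos in range(1, p + 1):
                        pairs.append((pos, rev[k]))
                        k += 1
                    for _ in range(b):
                        pairs.append((None, rev[k]))
                        k += 1
                    for pos in range(p + 1, L + 1):
                        pairs.append((pos, rev[k]))
                        k += 1
                    consider(start, site, pairs)
            # unpaired miRNA bases q..q+b-1
            if start + L - b <= n and L - b > 0:
                site = lncrna[start : start + L - b]
                rev = site[::-1]
                for q in range(2, L - b + 1):
                    pairs = []
                    k = 0
                    for pos in range(1, q):
                        pairs.append((pos, rev[k]))
                        k += 1
                    for pos in range(q, q + b):
                        pairs.append((pos, None))
                    for pos in range(q + b, L + 1):
                        pairs.append((pos, rev[k]))
                        k += 1
                    consider(start, site, pairs)

    per_start = [min(lst) for lst in candidates.values()]
    kept: list[tuple] = []
    for key, hit in sorted(per_start):
        s, e = hit[0], hit[1]
        if any(s < ke and ks < e for _, (ks, ke, *_rest) in kept):
            continue
        kept.append((key, hit))
    return sorted(hit for _, hit in kept)


def all_pairs_cis(lncrnas, genes, window_bp=100_000):
    """Quadratic interval-distance oracle for cis target prediction.

    Returns sorted (lncrna_id, gene_id, distance, side) for every pair on
    a shared chromosome with nearest-edge separation <= window_bp.
    """
    out = []
    for lnc in lncrnas:
        for g in genes:
            if g.chrom != lnc.chrom or g.id == lnc.id:
                continue
            overlap = not (g.end <= lnc.start or lnc.end <= g.start)
            if overlap:
                out.append((lnc.id, g.id, 0, "overlap"))
            elif g.end <= lnc.start:
                d = lnc.start - g.end
                if d <= window_bp:
                    out.append((lnc.id, g.id, d, "upstream"))
            else:
                d = g.start - lnc.end
                if d <= window_bp:
                    out.append((lnc.id, g.id, d, "downstream"))
    return sorted(out)


def hand_pearson(x, y) -> float:
    """Textbook sum-based Pearson formula, no numpy."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den
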