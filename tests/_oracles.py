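"""Independent oracles used by the test suite.

These deliberately avoid the library's own shift/flag/classify code paths:
placements are found by brute-force enumeration and sequence application,
flags by a separate one-lambda-per-rule table, classification by a frozen
hand-evaluated case list in the test module.
"""

from __future__ import annotations

import itertools


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a 1-based anchored edit to a sequence string."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "ref allele mismatch"
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Brute-force minimal trim: try every prefix/suffix removal, keep the
    shortest allele pair that still reproduces the same edited haplotype
    (ties broken toward the smallest position, i.e. anchor kept on the
    left)."""
    context = "N" * (pos - 1) + ref  # positions 1..pos+len(ref)-1
    target = apply_edit(context, pos, ref, alt)
    best = (pos, ref, alt)
    for npre, nsuf in itertools.product(range(len(ref) + 1), range(len(ref) + 1)):
        r = ref[npre : len(ref) - nsuf] if nsuf else ref[npre:]
        a = alt[npre : len(alt) - nsuf] if nsuf else alt[npre:]
        if not r or not a or r == a:
            continue
        p = pos + npre
        if context[p - 1 : p - 1 + len(r)] != r:
            continue
        if apply_edit(context, p, r, a) != target:
            continue
        size, best_size = len(r) + len(a), len(best[1]) + len(best[2])
        if size < best_size or (size == best_size and p < best[0]):
            best = (p, r, a)
    return best


def equivalent_placements(seq: str, pos: int, ref: str, alt: str,
                          window: int = 150) -> list[tuple[int, str, str]]:
    """All anchored placements of the same pure indel that reproduce the same
    edited sequence, found by exhaustive windowed enumeration."""
    n_ref, n_alt = len(ref), len(alt)
    ws = max(1, pos - window)
    we = min(len(seq), pos + n_ref + window)
    ref_win = seq[ws - 1 : we]
    off = pos - ws
    assert ref_win[off : off + n_ref] == ref
    edited = ref_win[:off] + alt + ref_win[off + n_ref :]
    out = []
    for p in range(ws, we + 1):
        o = p - ws
        if o + n_ref > len(ref_win):
            break
        r = ref_win[o : o + n_ref]
        a = edited[o : o + n_alt]
        if r == a or not r or not a:
            continue
        if r[0] != a[0] and (n_ref > 1 or n_alt > 1):
            continue  # indels must be anchored
        if ref_win[:o] + a + ref_win[o + n_ref :] == edited:
            out.append((p, r, a))
    return out


# --- independent per-rule flag oracle --------------------------------------

FLAG_RULES = {
    "vaf": lambda d: d["vaf"] < d["min_vaf"],
    "vrd": lambda d: d["total_depth"] < 100,
    "vad": lambda d: d["alt_depth"] < 20,
    "blk": lambda d: d["blacklisted"],
    "oor": lambda d: not d["in_roi"],
    "con": lambda d: d["consequence_benign"],
    "gmaf": lambda d: d["gmaf"] > 0.01,
    "pnl": lambda d: d["panel_frac"] > 0.35,
    "sin": lambda d: d["singleton"],
}


def oracle_flags(d: dict) -> set[str]:
    fired = {name for name, rule in FLAG_RULES.items() if rule(d)}
    return fired or {"pass"}


# --- independent coding-coordinate walk ------------------------------------

def exon_walk_c(g: int, exons, strand: str, cds_start: int, cds_end: int) -> str:
    """Map an exonic genomic position to a c. coordinate by walking every
    exon base in transcript order and counting."""
    order = list(exons) if strand == "+" else list(reversed(exons))
    walked = []
    for s, e in order:
        rng = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        walked.extend(rng)
    lo, hi = sorted((cds_start, cds_end))
    cds = [p for p in walked if lo <= p <= hi]
    if g in cds:
        return str(cds.index(g) + 1)
    i = walked.index(g)
    first, last = walked.index(cds[0]), walked.index(cds[-1])
    if i < first:
        return f"-{first - i}"
    return f"*{i - last}"
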