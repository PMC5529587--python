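"""Detection of PCR recombinants (chimeras) and 1-bp substitution artifacts.

Variants are examined in order of ascending population-level frequency (an
artifact is rarer than the true sequences it derives from).  A variant is
flagged as a 1-bp artifact if some unflagged, much more abundant variant of
equal length sits at Hamming distance 1; it is flagged as a chimera if it
can be written as prefix(u1) + suffix(u2) at a single breakpoint for two
distinct, much more abundant unflagged parents.  "Much more abundant"
defaults to a 10x read-count ratio.  Variants at or above 2% population
frequency are treated as true alleles unless audit mode is requested,
mirroring the study's manual-check outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import RunMatrix

CLEAN = "clean"
ONE_BP = "one_bp"
CHIMERA = "chimera"


@dataclass
class ArtifactFlag:
    variant: str
    flag: str
    parents: tuple[str, ...] = ()
    detail: str = ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _chimera_breakpoints(child: str, p1: str, p2: str) -> list[int]:
    """Breakpoints k (1 <= k < len) with child == p1[:k] + p2[k:].

    Only equal-length parent/child triples are considered; a valid
    breakpoint must split both parental contributions non-trivially
    (child must differ from both parents).
    """
    if len(child) != len(p1) or len(child) != len(p2):
        return []
    if child == p1 or child == p2:
        return []
    n = len(child)
    # longest prefix shared with p1, longest suffix shared with p2
    pref = 0
    while pref < n and child[pref] == p1[pref]:
        pref += 1
    suf = 0
    while suf < n and child[n - 1 - suf] == p2[n - 1 - suf]:
        suf += 1
    return [k for k in range(1, n) if k <= pref and n - k <= suf]


def detect_artifacts(matrix: RunMatrix, ratio: float = 10.0,
                     popfreq_exempt: float = 0.02,
                     audit: bool = False) -> dict[str, ArtifactFlag]:
    """Flag every variant as clean, one_bp or chimera.

    Flags are assigned from the rarest variant upward; once flagged, a
    variant can no longer serve as a parent for later decisions.  Both
    artifact classes arise inside a PCR from templates present in that
    reaction, so a candidate parent must co-occur with the variant in
    every sample where the variant has reads — a true rare allele whose
    sequence merely resembles a recombinant of unrelated alleles is not
    removed.
    """
    totals = matrix.counts.sum(axis=0)
    grand = float(totals.sum())
    seqs = matrix.sequences
    present = {v: frozenset(matrix.counts.index[matrix.counts[v] > 0])
               for v in matrix.counts.columns}
    # ascending frequency; ties broken by variant id for determinism
    order = sorted(totals.index, key=lambda v: (totals[v], v))
    flags: dict[str, ArtifactFlag] = {}
    for v in order:
        flags[v] = ArtifactFlag(v, CLEAN)
    for v in order:
        popfreq = totals[v] / grand if grand else 0.0
        if not audit and popfreq >= popfreq_exempt:
            continue
        child = seqs[v]
        need = ratio * totals[v]
        parents = [u for u in order
                   if u != v and flags[u].flag == CLEAN and totals[u] >= need
                   and present[v] <= present[u]]
        hit = None
        for u in parents:
            if len(seqs[u]) == len(child) and _hamming(seqs[u], child) == 1:
                hit = ArtifactFlag(v, ONE_BP, (u,))
                break
        if hit is None:
            for i, u1 in enumerate(parents):
                for u2 in parents:
                    if u1 == u2:
                        continue
                    bps = _chimera_breakpoints(child, seqs[u1], seqs[u2])
                    if bps:
                        hit = ArtifactFlag(v, CHIMERA, (u1, u2),
                                           detail=f"breakpoint={bps[0]}")
                        break
                if hit is not None:
                    break
        if hit is not None:
            flags[v] = hit
    return flags


def remove_artifacts(matrix: RunMatrix, ratio: float = 10.0,
                     popfreq_exempt: float = 0.02,
                     audit: bool = False) -> tuple[RunMatrix, dict[str, ArtifactFlag]]:
    """Drop flagged variants from the matrix; return matrix and full flags."""
    flags = detect_artifacts(matrix, ratio=ratio, popfreq_exempt=popfreq_exempt,
                             audit=audit)
    drop = [v for v, f in flags.items() if f.flag != CLEAN]
    out = matrix.copy()
    out.counts = out.counts.drop(columns=drop)
    out.sequences = {v: s for v, s in out.sequences.items() if v not in set(drop)}
    return out.drop_empty_variants(), flags
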