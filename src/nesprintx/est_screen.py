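"""EST-to-locus alignment and alternative-transcription event calling.

EST collections are one-shot, error-prone sequencing reads of cDNA clones.
Screening them against a gene locus reveals transcript structure the
annotation lacks: reads that begin inside an intron and splice into the
downstream exon expose internal transcription start sites, reads that run
past an exon into its intron and end with a poly(A) tail (or above a
polyadenylation hexamer) expose internal terminators, and reads whose
splices skip or include optional exons expose cassettes.

The mapper here is a deliberately small seed-chain-extend aligner (exact
k-mer seeds, gapless X-drop extension, colinear chaining by dynamic
programming).  It plays the role a BLAST-style local aligner would play in
a full-scale screen; the event classifier downstream only needs approximate
block boundaries, which a junction-overhang threshold absorbs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from .errors import InputError, ParameterError
from .gene_model import GeneModel, format_utr_name
from .orf import CANONICAL_POLYA, NONCANONICAL_POLYA, validate_utr
from .variants import UTRSite

__all__ = [
    "ESTAlignment",
    "Event",
    "UTRCandidate",
    "build_index",
    "map_est",
    "screen_ests",
    "classify_events",
    "call_utr_candidates",
    "evaluate_recovery",
]

_ALL_POLYA = set(CANONICAL_POLYA) | set(NONCANONICAL_POLYA)


@dataclass(frozen=True)
class ESTAlignment:
    """One read aligned to the locus as ordered gapless blocks.

    ``blocks`` holds ``(read_start, read_end, g_start, g_end)`` tuples in
    read order (equal lengths; gapless).  ``polya_tail`` records whether a
    non-genomic adenine run (>= ``tail_min``) was trimmed from the read's 3'
    end before alignment.
    """

    read_id: str
    blocks: tuple[tuple[int, int, int, int], ...]
    identity: float
    read_len: int
    polya_tail: bool
    tail_len: int = 0

    @property
    def empty(self) -> bool:
        """True for an unmapped read (no confident placement)."""
        return not self.blocks

    @property
    def g_start(self) -> int:
        if self.empty:
            raise InputError(f"read {self.read_id} is unmapped")
        return self.blocks[0][2]

    @property
    def g_end(self) -> int:
        if self.empty:
            raise InputError(f"read {self.read_id} is unmapped")
        return self.blocks[-1][3]

    @property
    def coverage(self) -> float:
        aligned = sum(re - rs for rs, re, _, _ in self.blocks)
        return aligned / self.read_len if self.read_len else 0.0


@dataclass(frozen=True)
class Event:
    """One structural observation from a single aligned read."""

    kind: str  # retained_intron / novel_5p_start / novel_3p_end /
    #             cassette_skip / cassette_include
    read_id: str
    anchor: str  # intron name "a/b" or exon label
    labels: tuple[str, ...] = ()  # cassette labels for skip/include
    site_class: str = ""  # for novel end events
    evidence: tuple[str, ...] = ()
    g_start: int = 0
    g_end: int = 0


@dataclass(frozen=True)
class UTRCandidate:
    site: UTRSite
    support: int
    read_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def build_index(model: GeneModel, k: int = 21) -> dict[str, list[int]]:
    """Exact k-mer position index of the locus (forward strand)."""
    if k < 8:
        raise ParameterError("seed length must be at least 8")
    seq = model.locus_seq
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


def _trim_polya(seq: str, tail_min: int = 8) -> tuple[str, int]:
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    run = n - i
    if run >= tail_min:
        return seq[:i], run
    return seq, 0


def _extend(read: str, genome: str, r: int, g: int, step: int, xdrop: int = 8):
    """Gapless X-drop extension from (r, g) exclusive, in direction step.

    Returns (best_r, best_g, matches) where best_* are the last included
    positions' exclusive bounds offsets relative to the start.
    """
    score = best = 0
    best_len = 0
    matches = best_matches = 0
    length = 0
    while True:
        if step > 0:
            ri, gi = r + length, g + length
            if ri >= len(read) or gi >= len(genome):
                break
        else:
            ri, gi = r - 1 - length, g - 1 - length
            if ri < 0 or gi < 0:
                break
        if read[ri] == genome[gi]:
            score += 1
            matches += 1
        else:
            score -= 2
        length += 1
        if score > best:
            best = score
            best_len = length
            best_matches = matches
        if best - score > xdrop:
            break
    return best_len, best_matches


def _seed_hsps(read: str, model: GeneModel, index: dict, k: int):
    """Diagonal-grouped seed hits extended into gapless HSPs."""
    genome = model.locus_seq
    diagonals: dict[int, list[int]] = defaultdict(list)  # diag -> read positions
    hit_g: dict[tuple[int, int], int] = {}
    for r in range(0, len(read) - k + 1):
        kmer = read[r : r + k]
        for g in index.get(kmer, ()):
            d = g - r
            diagonals[d].append(r)

    hsps = []
    for d, rs in diagonals.items():
        rs.sort()
        # merge seed runs on the same diagonal into clusters
        clusters: list[list[int]] = [[rs[0]]]
        for r in rs[1:]:
            if r - clusters[-1][-1] <= k + 30:
                clusters[-1].append(r)
            else:
                clusters.append([r])
        for cl in clusters:
            r0, r1 = cl[0], cl[-1] + k
            g0, g1 = r0 + d, r1 + d
            # core matches: count true matches in [r0, r1)
            core_matches = sum(
                1 for i in range(r0, r1) if read[i] == genome[i + d]
            )
            ext_l, m_l = _extend(read, genome, r0, g0, -1)
            ext_r, m_r = _extend(read, genome, r1, g1, +1)
            hsps.append(
                (
                    r0 - ext_l,
                    r1 + ext_r,
                    g0 - ext_l,
                    g1 + ext_r,
                    core_matches + m_l + m_r,
                )
            )
    # dedup identical / contained-on-same-diagonal HSPs
    hsps.sort(key=lambda h: (h[2] - h[0], h[0], -(h[1] - h[0])))
    kept = []
    last_key = None
    for h in hsps:
        key = (h[2] - h[0], h[0], h[1])
        if key != last_key:
            kept.append(h)
            last_key = key
    return kept


def map_est(
    model: GeneModel,
    read_id: str,
    seq: str,
    index: dict | None = None,
    k: int = 21,
    min_identity: float = 0.9,
    min_coverage: float = 0.5,
    tail_min: int = 8,
) -> ESTAlignment:
    """Align one EST read to the locus.

    The best colinear chain of gapless HSPs is selected by total match
    count, breaking ties toward the leftmost genomic placement, then
    filtered on identity and read coverage.  A read with no confident
    placement yields an *empty* alignment (``blocks == ()``) — a value,
    not an error.
    """
    if not (0 < min_identity <= 1):
        raise ParameterError("min_identity must be in (0, 1]")
    seq = seq.upper()
    if not seq or set(seq) - set("ACGTN"):
        raise InputError(f"read {read_id} is empty or non-nucleotide")
    trimmed, tail_len = _trim_polya(seq, tail_min)

    def _empty() -> ESTAlignment:
        return ESTAlignment(
            read_id=read_id,
            blocks=(),
            identity=0.0,
            read_len=len(trimmed),
            polya_tail=tail_len >= tail_min,
            tail_len=tail_len,
        )

    if len(trimmed) < k:
        return _empty()
    if index is None:
        index = build_index(model, k)
    hsps = _seed_hsps(trimmed, model, k=k, index=index)
    if not hsps:
        return _empty()

    # Colinear chain DP over HSPs sorted by read start.
    hsps.sort(key=lambda h: (h[0], h[2]))
    n = len(hsps)
    slack = 12
    dp = [h[4] for h in hsps]
    back = [-1] * n
    for i in range(n):
        ri0, ri1, gi0, gi1, mi = hsps[i]
        for j in range(i):
            rj0, rj1, gj0, gj1, mj = hsps[j]
            if rj1 <= ri0 + slack and gj1 <= gi0 + slack and gj1 - rj1 < gi0 - ri0 + slack:
                overlap = max(0, rj1 - ri0)
                cand = dp[j] + mi - overlap
                if cand > dp[i] or (cand == dp[i] and back[i] == -1):
                    dp[i] = cand
                    back[i] = j
    best = max(range(n), key=lambda i: (dp[i], -hsps[i][2]))
    chain = []
    i = best
    while i != -1:
        chain.append(hsps[i])
        i = back[i]
    chain.reverse()

    # Trim read-coordinate overlaps between consecutive HSPs.
    blocks = []
    prev_r_end = -1
    for r0, r1, g0, g1, _ in chain:
        if r0 < prev_r_end:
            cut = prev_r_end - r0
            r0 += cut
            g0 += cut
        if r1 > r0:
            blocks.append((r0, r1, g0, g1))
            prev_r_end = r1

    genome = model.locus_seq
    aligned = sum(r1 - r0 for r0, r1, _, _ in blocks)
    matches = sum(
        1
        for r0, r1, g0, _ in blocks
        for i in range(r1 - r0)
        if trimmed[r0 + i] == genome[g0 + i]
    )
    if aligned == 0:
        return _empty()
    identity = matches / aligned
    aln = ESTAlignment(
        read_id=read_id,
        blocks=tuple(blocks),
        identity=identity,
        read_len=len(trimmed),
        polya_tail=tail_len >= tail_min,
        tail_len=tail_len,
    )
    if identity < min_identity or aln.coverage < min_coverage:
        return _empty()
    return aln


def screen_ests(
    model: GeneModel,
    reads: list[tuple[str, str]],
    k: int = 21,
    min_identity: float = 0.9,
    min_coverage: float = 0.5,
) -> list[ESTAlignment]:
    """Map a read collection against the locus (index built once).

    Unmapped reads (empty alignments) are dropped from the result.
    """
    index = build_index(model, k)
    out = []
    for rid, seq in reads:
        aln = map_est(
            model, rid, seq, index=index, k=k,
            min_identity=min_identity, min_coverage=min_coverage,
        )
        if not aln.empty:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------


def _containing_intron(model: GeneModel, pos: int):
    for name, s, e in model.introns():
        if s <= pos < e:
            return name, s, e
    return None


def classify_events(
    model: GeneModel,
    alignment: ESTAlignment,
    min_overhang: int = 12,
    gap_tol: int = 5,
    internal_priming_a: int = 13,
) -> list[Event]:
    """Interpret one alignment's block structure as transcription events.

    Rules, with ``min_overhang`` nt required on each side of any junction
    call so that extension jitter from sequencing errors cannot flip a
    classification:

    * a block covering an exon/intron junction -> ``retained_intron``
      (unless the intronic overhang is the read's own novel 5' or 3' end,
      which the two rules below claim);
    * the first block starting >= overhang inside an intron and crossing
      >= overhang into the downstream exon -> ``novel_5p_start`` anchored at
      that intron;
    * the last block ending >= overhang inside an intron, supported either
      by a trimmed poly(A) tail (rejected as internal priming when the
      genomic sequence just downstream is adenine-rich) or by a
      polyadenylation hexamer within the retained portion ->
      ``novel_3p_end``;  the same call is made for a tailed read ending
      mid-exon away from the annotated terminus (exonic site class);
    * a splice gap exactly spanning one or more cassette exons ->
      ``cassette_skip``; a block covering a cassette exon flanked by clean
      splices -> ``cassette_include``.
    """
    if alignment.empty:
        raise InputError(f"read {alignment.read_id} has an empty alignment")
    events: list[Event] = []
    rid = alignment.read_id
    blocks = alignment.blocks
    genome = model.locus_seq
    exons = model.exons
    last_exon = exons[-1]

    # --- novel 5' start -----------------------------------------------------
    first_r0, first_r1, first_g0, first_g1 = blocks[0]
    start_intron = _containing_intron(model, first_g0)
    claimed_5p_intron = None
    if start_intron is not None:
        name, istart, iend = start_intron
        if iend - first_g0 >= min_overhang and first_g1 >= iend + min_overhang:
            next_exon = next(e for e in exons if e.start == iend)
            events.append(
                Event(
                    "novel_5p_start",
                    rid,
                    anchor=name,
                    site_class="intron_retained",
                    evidence=("read_start_in_intron",),
                    g_start=first_g0,
                    g_end=iend,
                )
            )
            claimed_5p_intron = name

    # --- novel 3' end -------------------------------------------------------
    last_g1 = blocks[-1][3]
    claimed_3p_intron = None
    tail_ok = alignment.polya_tail
    if tail_ok:
        downstream = genome[last_g1 : last_g1 + 20]
        if downstream.count("A") >= internal_priming_a:
            tail_ok = False  # internal priming on a genomic A-run
    end_intron = _containing_intron(model, last_g1 - 1)
    if end_intron is not None:
        name, istart, iend = end_intron
        prev_exon = next(e for e in exons if e.end == istart)
        if last_g1 - istart >= min_overhang:
            evidence = []
            if tail_ok:
                evidence.append("polya_tail")
            retained = genome[istart:last_g1]
            if any(
                retained[i : i + 6] in _ALL_POLYA for i in range(len(retained) - 5)
            ):
                evidence.append("polya_signal")
            if evidence:
                events.append(
                    Event(
                        "novel_3p_end",
                        rid,
                        anchor=prev_exon.label,
                        site_class="intron_retained",
                        evidence=tuple(evidence),
                        g_start=istart,
                        g_end=last_g1,
                    )
                )
                claimed_3p_intron = name
    else:
        # ends inside an exon; a poly(A) tail away from the annotated
        # terminus marks an exonic novel end
        if tail_ok and last_g1 < last_exon.end - min_overhang:
            for e in exons:
                if e.start < last_g1 <= e.end:
                    events.append(
                        Event(
                            "novel_3p_end",
                            rid,
                            anchor=e.label,
                            site_class="exonic",
                            evidence=("polya_tail",),
                            g_start=e.start,
                            g_end=last_g1,
                        )
                    )
                    break

    # --- retained introns ---------------------------------------------------
    seen_retained = set()
    for r0, r1, g0, g1 in blocks:
        for name, istart, iend in model.introns():
            if name in (claimed_5p_intron, claimed_3p_intron):
                continue
            covers_donor = g0 + min_overhang <= istart and g1 >= istart + min_overhang
            covers_acceptor = g0 + min_overhang <= iend and g1 >= iend + min_overhang
            if (covers_donor or covers_acceptor) and name not in seen_retained:
                seen_retained.add(name)
                events.append(
                    Event(
                        "retained_intron",
                        rid,
                        anchor=name,
                        g_start=max(g0, istart),
                        g_end=min(g1, iend),
                    )
                )

    # --- cassette skip / include -------------------------------------------
    for (r0a, r1a, g0a, g1a), (r0b, r1b, g0b, g1b) in zip(blocks, blocks[1:]):
        if r0b - r1a > gap_tol:
            continue  # not read-contiguous; no splice call
        donor = next(
            (e for e in exons if abs(e.end - g1a) <= gap_tol), None
        )
        acceptor = next(
            (e for e in exons if abs(e.start - g0b) <= gap_tol), None
        )
        if donor is None or acceptor is None:
            continue
        i_donor = model.exon_index(donor.label)
        i_acceptor = model.exon_index(acceptor.label)
        if i_acceptor <= i_donor:
            continue
        skipped = exons[i_donor + 1 : i_acceptor]
        if skipped and all(e.cassette for e in skipped):
            events.append(
                Event(
                    "cassette_skip",
                    rid,
                    anchor=donor.label,
                    labels=tuple(e.label for e in skipped),
                    g_start=donor.end,
                    g_end=acceptor.start,
                )
            )

    for e in exons:
        if not e.cassette:
            continue
        for r0, r1, g0, g1 in blocks:
            if g0 <= e.start + gap_tol and g1 >= e.end - gap_tol:
                events.append(
                    Event(
                        "cassette_include",
                        rid,
                        anchor=e.label,
                        labels=(e.label,),
                        g_start=e.start,
                        g_end=e.end,
                    )
                )
                break
    return events


# ---------------------------------------------------------------------------
# Candidate calling and evaluation
# ---------------------------------------------------------------------------


def call_utr_candidates(
    model: GeneModel,
    events: list[Event],
    gene_short: str,
    min_support: int = 1,
    polya_window: int = 2000,
    validate: bool = True,
) -> list[UTRCandidate]:
    """Aggregate per-read novel-end events into validated UTR candidates.

    Events of the same kind and anchor pool their supporting reads; groups
    below ``min_support`` reads are dropped (the permissive default of 1
    accepts single-read candidates, as EST catalogues routinely do).  Each surviving candidate is
    named with the gene's UTR nomenclature and (optionally) passed through
    :func:`nesprintx.orf.validate_utr`.
    """
    groups: dict[tuple, list[Event]] = defaultdict(list)
    for ev in events:
        if ev.kind == "novel_5p_start":
            groups[("5'", ev.anchor, ev.site_class)].append(ev)
        elif ev.kind == "novel_3p_end":
            groups[("3'", ev.anchor, ev.site_class)].append(ev)

    out: list[UTRCandidate] = []
    for (side, anchor, site_class), evs in sorted(groups.items()):
        read_ids = tuple(sorted({e.read_id for e in evs}))
        if len(read_ids) < min_support:
            continue
        if side == "5'":
            # anchor is an intron "a/b"; the transcript's first exon is b
            anchor_exon = anchor.split("/")[1]
        else:
            anchor_exon = anchor
        evidence = tuple(sorted({tag for e in evs for tag in e.evidence}))
        site = UTRSite(
            name=format_utr_name(gene_short, side, anchor),
            side=side,
            anchor_exon=anchor_exon,
            site_class=site_class,
            evidence=evidence,
            polya_tail_evidence="polya_tail" in evidence,
        )
        if validate:
            site = validate_utr(site, model, polya_window=polya_window)
        out.append(UTRCandidate(site=site, support=len(read_ids), read_ids=read_ids))
    return out


def evaluate_recovery(truth, candidates: list[UTRCandidate]) -> dict:
    """Precision/recall of called sites against the planted discoverable ones.

    A candidate matches a planted site when side, anchor exon and site class
    agree and the candidate validated.  Returns a dict with precision,
    recall, and the matched / spurious / missed site names.
    """
    planted = {
        (p.site.side, p.site.anchor_exon, p.site.site_class): p.site.name
        for p in truth.discoverable_sites()
    }
    called = {
        (c.site.side, c.site.anchor_exon, c.site.site_class): c.site.name
        for c in candidates
        if c.site.validated
    }
    matched = sorted(planted[k] for k in planted.keys() & called.keys())
    spurious = sorted(called[k] for k in called.keys() - planted.keys())
    missed = sorted(planted[k] for k in planted.keys() - called.keys())
    precision = len(matched) / len(called) if called else 1.0
    recall = len(matched) / len(planted) if planted else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "matched": matched,
        "spurious": spurious,
        "missed": missed,
        "n_planted": len(planted),
        "n_called": len(called),
    }
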