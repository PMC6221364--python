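"""Scanning MS2 reporter sequences for putative Zelda (TAGteam) binding sites.

The ubiquitous activator Zelda binds heptameric "TAGteam" motifs (canonical
site ``CAGGTAG``) that are strongly over-represented in the enhancers of
early zygotic genes in the fly embryo.  The classic 24xMS2 stem-loop cassette
used for live transcription imaging happens to carry dozens of near-matches
to this motif in the linkers between stem loops, which is enough to turn the
cassette itself into a Zelda-responsive enhancer.  This module provides

* a position weight matrix built from the eight literature Zelda sites,
* a reconstruction of the 24xMS2 cassette as 12 tandem repeats of a
  two-loop unit (each repeat contributing one ``CAGGTCG``, one ``TAGGTAC``
  and one ``TAGGCAA`` in its linkers),
* a mismatch-rule scanner for putative sites, and
* a mutator that disrupts every detected site while leaving the stem-loop
  sequences untouched (the "delta-Zelda" cassette).

Coordinates are 0-based, half-open, on the forward strand by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CANONICAL_SITE",
    "CRITICAL_POSITIONS",
    "ZELDA_SITES",
    "MS2_LOOP",
    "MS2_UNIT",
    "SequenceRecord",
    "MotifHit",
    "build_pwm",
    "build_cassette",
    "scan_motifs",
    "motif_counts",
    "mutate_sites",
    "hits_to_frame",
    "read_fasta",
    "write_fasta",
]

#: Canonical Zelda / TAGteam heptamer.
CANONICAL_SITE = "CAGGTAG"

#: 0-based indices of the critical positions in the canonical site
#: (the bases A2, G3, G4 and A6 of C-AGG-T-A-G).
CRITICAL_POSITIONS = (1, 2, 3, 5)

#: Literature Zelda binding sites used to build the position weight matrix.
ZELDA_SITES = (
    "CAGGTAG",
    "CAGGTAA",
    "TAGGTAG",
    "CAGGTAC",
    "CAGGTAT",
    "TAGGTAA",
    "CAGGCAG",
    "CAGGCAA",
)

#: Core MS2 stem-loop sequence (the MCP-binding hairpin repeated 24x in the
#: cassette).
MS2_LOOP = "ACATGAGGATCACCCATGT"

#: Synthetic reconstruction of the two-loop repeat unit of the 24xMS2
#: cassette.  The published unit places one CAGGTCG in the short linker and
#: one TAGGTAC plus one TAGGCAA in the long linker, all between stem loops;
#: the exact linker sequence is not transcribed here, so the filler bases are
#: synthetic and chosen so that the tandem cassette carries exactly these
#: three TAGteam-like motifs per repeat and nothing else.
MS2_UNIT = (
    MS2_LOOP + "CCCC" + "CAGGTCG" + "TCTC"
    + MS2_LOOP + "TTTTT" + "TAGGTAC" + "TCTC" + "TAGGCAA" + "TTTCT"
)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
#: Transversion partner used when disrupting a site (purine <-> pyrimidine).
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence restricted to the A/C/G/T alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(_BASES)
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id + "_rc", self.sequence.translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class MotifHit:
    """A putative Zelda site found by :func:`scan_motifs`.

    ``start``/``end`` are 0-based half-open coordinates on the forward strand
    of the scanned sequence, whatever strand the match was found on.
    """

    start: int
    end: int
    strand: str
    motif: str
    mismatches: int
    critical_ok: bool

    def __post_init__(self) -> None:
        if not 0 <= self.mismatches <= 7:
            raise ValueError("mismatch count out of range")


def build_pwm(sites=ZELDA_SITES, pseudocount: float = 0.0) -> pd.DataFrame:
    """Column-normalized base frequencies of an aligned site list.

    Returns a (length x 4) DataFrame with columns A, C, G, T; each row sums
    to one.  A pseudocount may be added to every cell before normalization.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites have unequal lengths")
    counts = np.full((length, 4), float(pseudocount))
    for s in sites:
        for i, b in enumerate(s.upper()):
            counts[i, _BASES.index(b)] += 1.0
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, columns=list(_BASES))


def build_cassette(unit: SequenceRecord | str | None = None, n_repeats: int = 12,
                   name: str = "24xMS2") -> SequenceRecord:
    """Tandem-repeat the two-loop unit into the full MS2 cassette.

    With the default unit and ``n_repeats=12`` the cassette carries 24 stem
    loops and 36 putative Zelda sites (12 of each linker motif).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if unit is None:
        unit = MS2_UNIT
    seq = unit.sequence if isinstance(unit, SequenceRecord) else str(unit)
    return SequenceRecord(name, seq * n_repeats)


def _mismatches(window: str) -> int:
    return sum(a != b for a, b in zip(window, CANONICAL_SITE))


def _is_hit(window: str, max_mismatch: int, require_core: bool) -> bool:
    if require_core and window[1:4] != "AGG":
        return False
    return _mismatches(window) <= max_mismatch


def scan_motifs(seq: SequenceRecord | str, max_mismatch: int = 3,
                require_core: bool = True, strands: str = "+") -> list[MotifHit]:
    """Classify every 7-mer window against the canonical TAGteam site.

    A window is a putative Zelda site when its Hamming distance to
    ``CAGGTAG`` is at most ``max_mismatch`` and (by default) the AGG core at
    positions 2-4 is intact — the signature common to all TAGteam variants.
    The remaining critical position (A6) may mismatch; such hits are reported
    with ``critical_ok=False`` (e.g. ``CAGGTCG``, the single-but-critical
    mismatch motif of the short linker).

    ``strands`` is ``"+"`` (forward only, the default), ``"-"`` or ``"+-"``.
    Reverse-strand hits are mapped back to forward coordinates.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    n = len(s)
    hits: list[MotifHit] = []
    k = len(CANONICAL_SITE)
    if n < k:
        return hits
    for strand in strands:
        if strand not in "+-":
            raise ValueError("strands must be drawn from '+-'")
        scanned = s if strand == "+" else s.translate(_COMPLEMENT)[::-1]
        for i in range(n - k + 1):
            w = scanned[i:i + k]
            if _is_hit(w, max_mismatch, require_core):
                start = i if strand == "+" else n - k - i
                crit_ok = all(w[p] == CANONICAL_SITE[p] for p in CRITICAL_POSITIONS)
                hits.append(MotifHit(start, start + k, strand, w,
                                     _mismatches(w), crit_ok))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def motif_counts(hits: list[MotifHit]) -> dict[str, int]:
    """Per-motif hit counts; the values partition ``len(hits)``."""
    out: dict[str, int] = {}
    for h in hits:
        out[h.motif] = out.get(h.motif, 0) + 1
    return out


def hits_to_frame(hits: list[MotifHit], seq_id: str = "") -> pd.DataFrame:
    """BED-like table of hits (seq_id, start, end, motif, strand, mismatches)."""
    return pd.DataFrame(
        [(seq_id, h.start, h.end, h.motif, h.strand, h.mismatches, h.critical_ok)
         for h in hits],
        columns=["seq_id", "start", "end", "motif", "strand", "mismatches", "critical_ok"],
    )


def _loop_spans(s: str) -> list[tuple[int, int]]:
    spans, i = [], s.find(MS2_LOOP)
    while i != -1:
        spans.append((i, i + len(MS2_LOOP)))
        i = s.find(MS2_LOOP, i + 1)
    return spans


def mutate_sites(seq: SequenceRecord | str, hits: list[MotifHit] | None = None,
                 max_mismatch: int = 3) -> SequenceRecord:
    """Disrupt every putative Zelda site, leaving the stem loops untouched.

    Each hit is pushed beyond the scanner's mismatch budget by transversions
    at currently-matching critical positions (then, if needed, at permissive
    ones), so a re-scan of the result finds no site.  Length is preserved.
    A hit overlapping a stem loop raises, since in the published cassette all
    putative sites lie within the linkers.
    """
    sid = seq.id if isinstance(seq, SequenceRecord) else "mutated"
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    if hits is None:
        hits = scan_motifs(s, max_mismatch=max_mismatch)
    loops = _loop_spans(s)
    chars = list(s)
    for h in hits:
        if any(h.start < e and h.end > b for b, e in loops):
            raise ValueError(f"hit at {h.start} overlaps an MS2 stem loop")
        window = chars[h.start:h.end]
        # mutate matching positions, critical ones first, until the window
        # can no longer satisfy the mismatch rule
        order = [p for p in CRITICAL_POSITIONS if window[p] == CANONICAL_SITE[p]]
        order += [p for p in range(len(CANONICAL_SITE))
                  if p not in CRITICAL_POSITIONS and window[p] == CANONICAL_SITE[p]]
        for p in order:
            if _mismatches("".join(window)) > max_mismatch and window[1:4] != "AGG":
                break
            window[p] = _TRANSVERSION[window[p]]
        chars[h.start:h.end] = window
    out = SequenceRecord(sid + "_dZelda", "".join(chars))
    residual = scan_motifs(out, max_mismatch=max_mismatch)
    if residual:
        raise RuntimeError(f"{len(residual)} sites survived mutation")
    return out


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
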