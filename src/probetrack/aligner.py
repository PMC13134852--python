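"""Strict and pad-mode probe-to-transcriptome matching.

Strict mode reports every exact, full-length occurrence of a probe on the
forward strand of a transcript. Pad mode exempts ``pl`` bases at EACH probe
end from the matching requirement: only the central core
``probe[pl : L - pl]`` must occur exactly; the pads may disagree arbitrarily
(mismatches, indels, clipping). Pad disagreement can be annotated with a
banded edit distance but never filters hits.

Matching is implemented with a w-mer index anchored at the first core
position, verified by direct substring comparison; ``brute_force_hits`` is
the independent oracle scanning every offset. ``N`` bases never match
anything, in probes or transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .annotation import AnnotationSet, TranscriptRecord

__all__ = [
    "AlignerConfig",
    "AlignmentHit",
    "TranscriptIndex",
    "PadEdits",
    "build_index",
    "find_hits",
    "brute_force_hits",
    "pad_edit_distance",
]

STRICT = "strict"
PAD = "pad"


@dataclass(frozen=True)
class AlignerConfig:
    """Matching configuration; ``pl == 0`` is strict mode."""

    pl: int = 0
    w: Optional[int] = None  # index word length; None -> min(20, core length)

    def __post_init__(self) -> None:
        if self.pl < 0:
            raise ValueError("pad length must be >= 0")

    @property
    def mode(self) -> str:
        return STRICT if self.pl == 0 else PAD

    def core(self, sequence: str) -> str:
        if len(sequence) <= 2 * self.pl:
            raise ValueError(
                f"probe of length {len(sequence)} too short for pad length {self.pl}"
            )
        return sequence[self.pl : len(sequence) - self.pl]

    def word_length(self, core_len: int) -> int:
        w = self.w if self.w is not None else min(20, core_len)
        if w > core_len:
            raise ValueError(f"word length {w} exceeds core length {core_len}")
        return w


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """An exact, contiguous, mismatch-free match of a probe core on a transcript."""

    accession: str
    transcript_id: str
    offset: int  # transcript offset of the matched region, 0-based
    span_start: int  # probe offset of the matched region (pl in pad mode)
    span_len: int
    mode: str
    pl: int

    @property
    def locus(self) -> Tuple[str, int]:
        """(transcript, transcript offset of probe start) — pl-invariant key."""
        return (self.transcript_id, self.offset - self.span_start)


class TranscriptIndex:
    """w-mer -> [(transcript_id, offset)] lookup over a transcript set.

    w-mers containing ``N`` are not indexed.
    """

    def __init__(self, w: int) -> None:
        if w < 1:
            raise ValueError("index word length must be >= 1")
        self.w = w
        self._table: Dict[str, List[Tuple[str, int]]] = {}
        self.sequences: Dict[str, str] = {}

    def add_transcript(self, transcript_id: str, sequence: str) -> None:
        self.sequences[transcript_id] = sequence
        w = self.w
        for i in range(len(sequence) - w + 1):
            word = sequence[i : i + w]
            if "N" in word:
                continue
            self._table.setdefault(word, []).append((transcript_id, i))

    def lookup(self, word: str) -> List[Tuple[str, int]]:
        return self._table.get(word, [])


def build_index(transcripts: Iterable[TranscriptRecord] | AnnotationSet, w: int) -> TranscriptIndex:
    """Index every w-mer occurrence of every transcript sequence."""
    if isinstance(transcripts, AnnotationSet):
        transcripts = transcripts.transcripts.values()
    index = TranscriptIndex(w)
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"transcript {t.transcript_id} has no sequence")
        index.add_transcript(t.transcript_id, t.sequence)
    return index


def find_hits(probe, index: TranscriptIndex, config: AlignerConfig) -> List[AlignmentHit]:
    """All exact occurrences of the probe core in the indexed transcripts.

    ``probe`` is a ProbeRecord or a (accession, sequence) pair. One hit per
    distinct (transcript, offset); sorted by (transcript_id, offset).
    """
    accession, seq = _probe_fields(probe)
    core = config.core(seq)
    if "N" in core:
        return []
    w = index.w
    if w > len(core):
        raise ValueError(
            f"index word length {w} exceeds core length {len(core)}"
        )
    anchor = core[:w]
    hits = []
    seen = set()
    for tid, off in index.lookup(anchor):
        tseq = index.sequences[tid]
        if tseq[off : off + len(core)] == core and (tid, off) not in seen:
            seen.add((tid, off))
            hits.append(
                AlignmentHit(
                    accession=accession,
                    transcript_id=tid,
                    offset=off,
                    span_start=config.pl,
                    span_len=len(core),
                    mode=config.mode,
                    pl=config.pl,
                )
            )
    hits.sort()
    return hits


def brute_force_hits(
    probe, transcripts: Iterable[TranscriptRecord] | AnnotationSet, config: AlignerConfig
) -> List[AlignmentHit]:
    """Oracle: scan every offset of every transcript; same contract as find_hits."""
    if isinstance(transcripts, AnnotationSet):
        transcripts = transcripts.transcripts.values()
    accession, seq = _probe_fields(probe)
    core = config.core(seq)
    if "N" in core:
        return []
    hits = []
    for t in transcripts:
        tseq = t.sequence or ""
        for off in range(len(tseq) - len(core) + 1):
            window = tseq[off : off + len(core)]
            # explicit per-base comparison: N never matches, even N vs N
            if all(a == b and a != "N" for a, b in zip(core, window)):
                hits.append(
                    AlignmentHit(
                        accession=accession,
                        transcript_id=t.transcript_id,
                        offset=off,
                        span_start=config.pl,
                        span_len=len(core),
                        mode=config.mode,
                        pl=config.pl,
                    )
                )
    hits.sort()
    return hits


@dataclass(frozen=True)
class PadEdits:
    """Informational pad disagreement; never used to filter hits."""

    left: int
    right: int
    left_clipped: int = 0
    right_clipped: int = 0


def pad_edit_distance(probe, transcript_seq: str, hit: AlignmentHit, pl: int) -> PadEdits:
    """Banded edit distance between each probe pad and its flanking transcript
    sequence, with free clipping where a pad hangs off a transcript end."""
    _, seq = _probe_fields(probe)
    if pl == 0:
        return PadEdits(0, 0)
    left_pad = seq[:pl]
    right_pad = seq[len(seq) - pl :]
    core_len = hit.span_len
    # left flank: transcript bases immediately before the matched core
    avail_left = min(pl, hit.offset)
    left_clip = pl - avail_left
    left_flank = transcript_seq[hit.offset - avail_left : hit.offset]
    left = _levenshtein(left_pad[left_clip:], left_flank)
    # right flank: transcript bases immediately after the matched core
    end = hit.offset + core_len
    avail_right = min(pl, len(transcript_seq) - end)
    right_clip = pl - avail_right
    right_flank = transcript_seq[end : end + avail_right]
    right = _levenshtein(right_pad[: pl - right_clip], right_flank)
    return PadEdits(left, right, left_clipped=left_clip, right_clipped=right_clip)


def _levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cost = 0 if (ca == cb and ca != "N") else 1
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost))
        prev = cur
    return prev[-1]


def _probe_fields(probe) -> Tuple[str, str]:
    if hasattr(probe, "accession"):
        return probe.accession, probe.sequence
    accession, seq = probe
    return accession, seq.upper()
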