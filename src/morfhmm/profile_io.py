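"""Input/output for sequences, MoRF annotations, and HH-suite ``.hhm`` profiles.

An ``.hhm`` file stores per-position amino-acid emission scores ``N`` of a
profile hidden Markov model built by HHblits/hhmake. Scores relate to linear
probabilities through ``p = 2**(-N/1000)``; the special token ``*`` denotes a
vanishing emission probability. Of the 30 columns HHblits emits per match
state, only the 20 match-emission columns (one per amino acid, in the fixed
order ``A C D E F G H I K L M N P Q R S T V W Y``) carry the evolutionary
signal this predictor consumes; the 10 transition/diversity columns are
parsed past and discarded.

Annotation intervals are 1-based inclusive on disk and converted to 0-based
half-open internally; every user-facing position is reported 1-based.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: HH-suite match-emission column order, identical for every profile in a run.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel used in raw score tables for the ``*`` (zero-probability) entry.
STAR = -1

#: Scores above this bound are written as ``*`` (p below 2**-32.767).
MAX_SCORE = 32767


class HHMParseError(ValueError):
    """Raised when an ``.hhm`` file (or annotation table) cannot be parsed."""


def score_to_probability(n: int | str) -> float:
    """Transform one profile score ``N`` to a linear probability ``2**(-N/1000)``.

    The ``*`` token (or the :data:`STAR` sentinel) maps to 0.0, the limit of
    the transform for ``N -> inf``. Negative scores are rejected.
    """
    if n == "*" or n == STAR:
        return 0.0
    n = int(n)
    if n < 0:
        raise HHMParseError(f"negative profile score {n}; scores must be >= 0 or '*'")
    return 2.0 ** (-n / 1000.0)


def scores_to_probabilities(raw: np.ndarray) -> np.ndarray:
    """Vectorised transform of a raw integer score table (STAR -> 0.0)."""
    raw = np.asarray(raw)
    if np.any(raw < STAR):
        bad = np.argwhere(raw < STAR)[0]
        raise HHMParseError(
            f"negative profile score at row {bad[0] + 1}, column {bad[1] + 1}"
        )
    probs = np.where(raw == STAR, 0.0, 2.0 ** (-raw.clip(min=0) / 1000.0))
    return probs.astype(float)


def probability_to_score(p: float) -> int:
    """Invert the transform: nearest integer score, :data:`STAR` for tiny p.

    Probabilities below ``2**-32.767`` (score above 32767) quantise to ``*``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 0.0:
        return STAR
    n = round(-1000.0 * math.log2(p))
    return STAR if n > MAX_SCORE else max(n, 0)


@dataclass
class HMMProfile:
    """Per-sequence profile: L residues by 20 match-emission probabilities."""

    seq_id: str
    residues: str
    raw_scores: np.ndarray  # (L, 20) int; STAR sentinel for '*'
    probs: np.ndarray  # (L, 20) float in [0, 1]
    aa_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores)
        self.probs = np.asarray(self.probs, dtype=float)
        L = len(self.residues)
        if self.probs.shape != (L, 20):
            raise ValueError(
                f"{self.seq_id}: probs shape {self.probs.shape} != ({L}, 20)"
            )
        if self.probs.min() < 0.0 or self.probs.max() > 1.0:
            raise ValueError(f"{self.seq_id}: probabilities outside [0, 1]")
        if len(self.aa_order) != 20:
            raise ValueError("aa_order must list the 20 amino acids")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AnnotatedSequence:
    """A sequence plus its MoRF intervals (0-based half-open internally)."""

    seq_id: str
    sequence: str = ""
    morf_intervals: list[tuple[int, int]] = field(default_factory=list)
    labels: np.ndarray | None = None  # filled in by morfhmm.regions

    @property
    def intervals_1based(self) -> list[tuple[int, int]]:
        """Intervals as 1-based inclusive pairs, the on-disk convention."""
        return [(s + 1, e) for s, e in self.morf_intervals]

    def validate(self) -> None:
        """Check intervals are ordered, in-range and non-overlapping."""
        L = len(self.sequence)
        prev_end = 0
        for s, e in sorted(self.morf_intervals):
            if s < 0 or e <= s:
                raise ValueError(
                    f"{self.seq_id}: invalid interval ({s + 1}, {e}) (start > end?)"
                )
            if s < prev_end:
                raise ValueError(f"{self.seq_id}: overlapping MoRF intervals")
            if L and e > L:
                raise ValueError(
                    f"{self.seq_id}: interval ({s + 1}, {e}) outside sequence of length {L}"
                )
            if not 5 <= e - s <= 25:
                logger.warning(
                    "%s: MoRF interval length %d outside the typical 5-25 range",
                    self.seq_id,
                    e - s,
                )
            prev_end = e


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into ``(seq_id, sequence)`` pairs, order preserved.

    The id is the first whitespace-delimited token of the header. A record
    with an empty sequence is an error.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]]) -> str:
    lines = []
    for seq_id, seq in records:
        lines.append(f">{seq_id}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Annotation TSV  (seq_id <TAB> morf_start <TAB> morf_end, 1-based inclusive)
# ---------------------------------------------------------------------------

def read_annotations(text: str) -> list[AnnotatedSequence]:
    """Parse the MoRF interval table into per-sequence annotation skeletons.

    Lines starting with ``#`` are comments; a single header line is allowed.
    Intervals are grouped by seq_id, sorted and checked for overlap; the
    sequence string itself is attached later (see :func:`attach_sequences`).
    """
    per_seq: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise HHMParseError(f"annotation line {lineno}: expected 3 tab-separated columns")
        seq_id, s_tok, e_tok = parts[0], parts[1], parts[2]
        try:
            start, end = int(s_tok), int(e_tok)
        except ValueError:
            if lineno == 1 or seq_id.lower() in ("seq_id", "id"):
                continue  # header line
            raise HHMParseError(f"annotation line {lineno}: non-integer interval") from None
        if start > end:
            raise HHMParseError(
                f"annotation line {lineno} ({seq_id}): start {start} > end {end}"
            )
        if start < 1:
            raise HHMParseError(f"annotation line {lineno} ({seq_id}): start < 1")
        if seq_id not in per_seq:
            per_seq[seq_id] = []
            order.append(seq_id)
        per_seq[seq_id].append((start - 1, end))  # to 0-based half-open

    out = []
    for seq_id in order:
        ann = AnnotatedSequence(seq_id=seq_id, morf_intervals=sorted(per_seq[seq_id]))
        for (s1, e1), (s2, _) in zip(ann.morf_intervals, ann.morf_intervals[1:]):
            if s2 < e1:
                raise HHMParseError(f"{seq_id}: overlapping MoRF intervals")
        out.append(ann)
    return out


def write_annotations(seqs: list[AnnotatedSequence]) -> str:
    lines = ["seq_id\tmorf_start\tmorf_end"]
    for ann in seqs:
        for s1, e1 in ann.intervals_1based:
            lines.append(f"{ann.seq_id}\t{s1}\t{e1}")
    return "\n".join(lines) + "\n"


def attach_sequences(
    annotations: list[AnnotatedSequence], records: list[tuple[str, str]]
) -> list[AnnotatedSequence]:
    """Attach FASTA sequences to annotation skeletons and validate intervals.

    Sequences without an annotation get an empty interval list (all
    residues non-MoRF); annotations without a sequence are an error.
    """
    by_id = dict(records)
    ann_ids = {a.seq_id for a in annotations}
    out = []
    for ann in annotations:
        if ann.seq_id not in by_id:
            raise ValueError(f"annotated sequence {ann.seq_id} missing from FASTA")
        ann.sequence = by_id[ann.seq_id]
        ann.validate()
        out.append(ann)
    for seq_id, seq in records:
        if seq_id not in ann_ids:
            out.append(AnnotatedSequence(seq_id=seq_id, sequence=seq))
    return out


# ---------------------------------------------------------------------------
# HH-suite .hhm text format
# ---------------------------------------------------------------------------

def parse_hhm(text: str, seq_id: str | None = None) -> HMMProfile:
    """Parse a single-model HH-suite ``.hhm`` file into an :class:`HMMProfile`.

    Only the 20 match-emission columns are retained; residue letters come
    from the first token of each match-emission row. The model must be
    terminated by ``//``.
    """
    lines = text.splitlines()
    name = seq_id
    leng = None
    i = 0
    n = len(lines)

    # header section up to the '#' separator
    while i < n:
        line = lines[i]
        if line.startswith("NAME") and name is None:
            toks = line.split()
            name = toks[1] if len(toks) > 1 else None
        elif line.startswith("LENG"):
            toks = line.split()
            try:
                leng = int(toks[1])
            except (IndexError, ValueError):
                raise HHMParseError(f"line {i + 1}: malformed LENG line") from None
        elif line.startswith("#"):
            i += 1
            break
        i += 1
    else:
        raise HHMParseError("missing '#' separator before the emission table")

    # emission table header: NULL line, 'HMM' column line, transition header,
    # begin-state transition line — skip everything until the first match row.
    aa_cols = None
    while i < n:
        line = lines[i]
        if line.startswith("NULL"):
            i += 1
            continue
        if line.startswith("HMM"):
            aa_cols = "".join(line.split()[1:])
            i += 1
            # transition column names + begin-state transition line
            while i < n and not _looks_like_match_row(lines[i]):
                if lines[i].startswith("//"):
                    break
                i += 1
            break
        i += 1
    if aa_cols is not None and aa_cols[:20] != AA_ORDER:
        raise HHMParseError(
            f"unexpected emission column order {aa_cols[:20]!r}; expected {AA_ORDER}"
        )

    residues: list[str] = []
    raw_rows: list[list[int]] = []
    terminated = False
    while i < n:
        line = lines[i]
        if line.startswith("//"):
            terminated = True
            break
        if _looks_like_match_row(line):
            toks = line.split()
            if len(toks) < 22:
                raise HHMParseError(
                    f"line {i + 1}: match row has {len(toks) - 2} emission scores, expected 20"
                )
            residues.append(toks[0])
            row = []
            for col, tok in enumerate(toks[2:22]):
                if tok == "*":
                    row.append(STAR)
                else:
                    try:
                        val = int(tok)
                    except ValueError:
                        raise HHMParseError(
                            f"line {i + 1}, column {col + 1}: malformed score {tok!r}"
                        ) from None
                    if val < 0:
                        raise HHMParseError(
                            f"line {i + 1}, column {col + 1}: negative score {val}"
                        )
                    row.append(val)
            raw_rows.append(row)
            i += 1
            # the paired insert/transition row (10 columns) is discarded
            if i < n and not lines[i].startswith("//") and not _looks_like_match_row(lines[i]):
                i += 1
        else:
            i += 1
    if not terminated:
        raise HHMParseError("missing '//' model terminator")
    if not raw_rows:
        raise HHMParseError("no match-emission rows found")
    if leng is not None and leng != len(raw_rows):
        raise HHMParseError(
            f"LENG declares {leng} match states but {len(raw_rows)} rows parsed"
        )

    raw = np.array(raw_rows, dtype=int)
    return HMMProfile(
        seq_id=name or "unnamed",
        residues="".join(residues),
        raw_scores=raw,
        probs=scores_to_probabilities(raw),
    )


def _looks_like_match_row(line: str) -> bool:
    toks = line.split()
    return (
        len(toks) >= 22
        and len(toks[0]) == 1
        and toks[0].isalpha()
        and toks[1].isdigit()
    )


# Fixed transition/diversity columns written for every match state; the
# predictor never reads them (they are among the 10 discarded columns).
_DEFAULT_TRANSITIONS = "0\t*\t*\t0\t*\t0\t0\t1000\t0\t0"


def write_hhm(profile: HMMProfile) -> str:
    """Serialise a profile to the ``.hhm`` text dialect :func:`parse_hhm` reads."""
    L = len(profile)
    out = [
        "HHsearch 1.5",
        f"NAME  {profile.seq_id}",
        f"LENG  {L} match states, {L} columns in multiple alignment",
        "SEQ",
        f">{profile.seq_id}",
        profile.residues,
        "#",
        "NULL   " + "\t".join(["3000"] * 20),
        "HMM    " + "\t".join(profile.aa_order),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t0\t1000\t0\t0",
    ]
    for idx in range(L):
        toks = [
            "*" if s == STAR else str(int(s)) for s in profile.raw_scores[idx]
        ]
        out.append(f"{profile.residues[idx]} {idx + 1}\t" + "\t".join(toks) + f"\t{idx + 1}")
        out.append("       " + _DEFAULT_TRANSITIONS)
        out.append("")
    out.append("//")
    return "\n".join(out) + "\n"


def profile_from_probs(seq_id: str, residues: str, probs: np.ndarray) -> HMMProfile:
    """Build a profile from a probability matrix, quantising to integer scores.

    The probabilities stored on the returned profile are the quantised ones,
    so writing and re-parsing it is an exact round trip.
    """
    probs = np.asarray(probs, dtype=float)
    raw = np.array(
        [[probability_to_score(p) for p in row] for row in probs], dtype=int
    )
    return HMMProfile(
        seq_id=seq_id,
        residues=residues,
        raw_scores=raw,
        probs=scores_to_probabilities(raw),
    )
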