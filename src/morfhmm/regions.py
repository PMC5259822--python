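"""Residue region labelling: MoRF, Flank, Other.

Each training sequence is partitioned into three regions: the annotated MoRF
residues, the Flanks (by default the 12 residues on either side of each
MoRF, truncated at the termini), and the Others — everything else. Positive
training samples are windows centred on MoRF residues (segment A); negative
samples are drawn from Other residues only (segment B), keeping windows that
straddle a Flank out of the negative pool.

When two MoRFs sit closer than two flank lengths apart, the residues between
them belong to both flanks and stay FLANK — they are never returned to the
negative pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_io import AnnotatedSequence

OTHER = 0
FLANK = 1
MORF = 2

LABEL_NAMES = {OTHER: "OTHER", FLANK: "FLANK", MORF: "MORF"}

DEFAULT_FLANK_LEN = 12


@dataclass
class RegionLabels:
    """Per-residue region labels for one sequence."""

    seq_id: str
    labels: np.ndarray  # int vector over {OTHER, FLANK, MORF}
    flank_len: int = DEFAULT_FLANK_LEN

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: int) -> int:
        return int(np.sum(self.labels == label))

    @property
    def is_morf(self) -> np.ndarray:
        """Boolean mask of MoRF residues (the binary truth for evaluation)."""
        return self.labels == MORF


def annotate_regions(
    seq: AnnotatedSequence, flank_len: int = DEFAULT_FLANK_LEN
) -> RegionLabels:
    """Label every residue of ``seq`` as MORF, FLANK or OTHER.

    MoRF intervals take precedence over flanks; flanks extend ``flank_len``
    residues from each MoRF boundary and are truncated at the sequence ends.
    """
    L = len(seq.sequence)
    if L == 0:
        raise ValueError(f"{seq.seq_id}: cannot label an empty sequence")
    seq.validate()
    labels = np.full(L, OTHER, dtype=np.int8)
    for s, e in seq.morf_intervals:  # 0-based half-open
        labels[max(0, s - flank_len) : s] = np.maximum(
            labels[max(0, s - flank_len) : s], FLANK
        )
        labels[e : e + flank_len] = np.maximum(labels[e : e + flank_len], FLANK)
    for s, e in seq.morf_intervals:
        labels[s:e] = MORF
    seq.labels = labels
    return RegionLabels(seq_id=seq.seq_id, labels=labels, flank_len=flank_len)


def build_segments(labels: RegionLabels) -> tuple[np.ndarray, np.ndarray]:
    """Split a label vector into segment A and segment B positions (0-based).

    Segment A holds the MoRF residues — the centres of positive training
    windows (whose spans reach into the flanks). Segment B holds the Other
    residues, the only legal centres for negative samples.
    """
    segment_a = np.flatnonzero(labels.labels == MORF)
    segment_b = np.flatnonzero(labels.labels == OTHER)
    return segment_a, segment_b


def labels_to_tsv(region_labels: RegionLabels, sequence: str = "") -> str:
    """Dump labels as TSV (seq_id, 1-based position, residue, label name)."""
    lines = ["seq_id\tposition\tresidue\tlabel"]
    for i, lab in enumerate(region_labels.labels):
        res = sequence[i] if sequence else "."
        lines.append(
            f"{region_labels.seq_id}\t{i + 1}\t{res}\t{LABEL_NAMES[int(lab)]}"
        )
    return "\n".join(lines) + "\n"
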