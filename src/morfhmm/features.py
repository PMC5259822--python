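"""Sliding-window feature extraction from HMM profiles.

A residue is represented by the ``w x 20`` block of emission probabilities
centred on it, flattened row-major (N-terminal row first), where
``w = 2*flank + 1``. Positions that fall outside the sequence contribute
all-zero rows, so every feature vector has the fixed dimension the SVM
expects regardless of where the window sits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_io import HMMProfile


@dataclass
class FeatureVector:
    """Flattened ``w x 20`` window centred on one residue (1-based center)."""

    seq_id: str
    center: int
    flank: int
    values: np.ndarray

    @property
    def window(self) -> int:
        return 2 * self.flank + 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.window * 20,):
            raise ValueError(
                f"feature vector length {self.values.size} != {self.window * 20}"
            )


def window_matrix(profile: HMMProfile, flank: int) -> np.ndarray:
    """All L window vectors of a profile as an ``(L, (2*flank+1)*20)`` array.

    Zero-pads ``flank`` rows at each terminus, then takes each residue's
    ``2*flank+1`` consecutive rows.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    L = len(profile)
    w = 2 * flank + 1
    padded = np.zeros((L + 2 * flank, 20), dtype=float)
    padded[flank : flank + L] = profile.probs
    # sliding_window_view over rows, then flatten each window row-major
    view = np.lib.stride_tricks.sliding_window_view(padded, (w, 20))[:, 0]
    return view.reshape(L, w * 20).copy()


def extract_window(profile: HMMProfile, center: int, flank: int) -> FeatureVector:
    """Window feature vector for the residue at 1-based position ``center``."""
    L = len(profile)
    if not 1 <= center <= L:
        raise ValueError(
            f"{profile.seq_id}: center {center} outside sequence of length {L}"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")
    c = center - 1
    rows = np.zeros((2 * flank + 1, 20), dtype=float)
    lo = max(0, c - flank)
    hi = min(L, c + flank + 1)
    rows[lo - (c - flank) : hi - (c - flank)] = profile.probs[lo:hi]
    return FeatureVector(
        seq_id=profile.seq_id, center=center, flank=flank, values=rows.ravel()
    )


def extract_all(profile: HMMProfile, flank: int) -> list[FeatureVector]:
    """One :class:`FeatureVector` per residue, N- to C-terminal."""
    mat = window_matrix(profile, flank)
    return [
        FeatureVector(seq_id=profile.seq_id, center=i + 1, flank=flank, values=row)
        for i, row in enumerate(mat)
    ]


def features_to_tsv(vectors: list[FeatureVector]) -> str:
    """Dump feature vectors as TSV for inspection (one row per residue)."""
    if not vectors:
        return ""
    dim = vectors[0].values.size
    header = ["seq_id", "center"] + [f"f{j}" for j in range(dim)]
    lines = ["\t".join(header)]
    for fv in vectors:
        lines.append(
            f"{fv.seq_id}\t{fv.center}\t"
            + "\t".join(f"{v:.6g}" for v in fv.values)
        )
    return "\n".join(lines) + "\n"
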