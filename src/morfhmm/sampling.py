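"""Training-set construction: positive and negative window samples.

Positives are one window per MoRF residue (segment A) — every MoRF residue
of every training sequence contributes exactly one positive sample.
Negatives are windows centred on Other residues (segment B), drawn uniformly
without replacement from the pool of all segment-B positions across the
whole training set, ``ratio`` negatives per positive. Flank residues are
never negative centres.

Pooling segment B globally (rather than per sequence) keeps the neg:pos
ratio exact even when individual sequences have few or no Other residues.
Each ensemble member samples with its own seed, so the nine models train on
different negative sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector, extract_window
from .profile_io import HMMProfile
from .regions import RegionLabels, build_segments


@dataclass
class SamplingConfig:
    """Negative:positive ratio, RNG seed, and the model's window flank."""

    neg_pos_ratio: int = 2
    seed: int = 0
    flank: int = 3

    def __post_init__(self) -> None:
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be a positive integer")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


def sample_training_set(
    data: list[tuple[HMMProfile, RegionLabels]], cfg: SamplingConfig
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Build (positives, negatives) feature-vector lists for one model.

    Raises if the pooled segment B cannot supply ``ratio * n_positives``
    distinct negative centres.
    """
    positives: list[FeatureVector] = []
    neg_pool: list[tuple[int, int]] = []  # (sequence index, 0-based position)
    for i, (profile, labels) in enumerate(data):
        if len(profile) != len(labels):
            raise ValueError(
                f"{profile.seq_id}: profile length {len(profile)} != label length {len(labels)}"
            )
        seg_a, seg_b = build_segments(labels)
        for pos in seg_a:
            positives.append(extract_window(profile, int(pos) + 1, cfg.flank))
        neg_pool.extend((i, int(pos)) for pos in seg_b)

    n_neg = cfg.neg_pos_ratio * len(positives)
    if n_neg > len(neg_pool):
        raise ValueError(
            f"segment B holds {len(neg_pool)} residues but {n_neg} negatives "
            f"requested; lower the sampling ratio (currently 1:{cfg.neg_pos_ratio})"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(len(neg_pool), size=n_neg, replace=False)
    negatives = [
        extract_window(data[neg_pool[k][0]][0], neg_pool[k][1] + 1, cfg.flank)
        for k in sorted(chosen)
    ]
    return positives, negatives


def stack(vectors: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into a design matrix."""
    if not vectors:
        return np.empty((0, 0))
    return np.vstack([fv.values for fv in vectors])
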