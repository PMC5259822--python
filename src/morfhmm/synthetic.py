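"""Synthetic sequences and ``.hhm`` profiles with planted MoRF signal.

The generator fabricates everything the pipeline needs — FASTA, MoRF
interval annotations, and per-sequence profile files — without any external
alignment tool. Each sequence gets a background amino-acid composition drawn
from a symmetric Dirichlet prior and, inside each planted MoRF (length 5-25),
a distinct composition obtained by interpolating the background toward a
fixed contrasting profile with weight ``s`` (the signal strength):

* ``s = 0`` — MoRF and background rows come from the same distribution; no
  classifier can beat chance.
* ``s = 1`` — the MoRF composition equals the contrast profile; maximally
  distinct.

Per-residue emission rows are drawn around their region's composition with
small Dirichlet noise; flank rows blend linearly from the MoRF composition
back to background over the 12-residue flank, mimicking the soft boundaries
of real binding regions. Rows are quantised to integer hhm scores by
inverting ``p = 2**(-N/1000)``, so parsing a written file recovers the
probabilities up to the score grid's quantisation error. Residue letters are
sampled from each row's composition.

The contrast profile weights the hydrophobic/aromatic residues that real
MoRFs are enriched in (they fold into a binding interface), but no attempt
is made at evolutionary realism — no phylogeny, no secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profile_io import (
    AA_ORDER,
    AnnotatedSequence,
    HMMProfile,
    profile_from_probs,
    write_annotations,
    write_fasta,
    write_hhm,
)
from .regions import DEFAULT_FLANK_LEN

# Contrast composition: mass concentrated on hydrophobic/aromatic residues
# (F I L M V W Y), a small share spread over the rest.
_HYDROPHOBIC = set("FILMVWY")
CONTRAST_COMPOSITION = np.array(
    [0.12 if aa in _HYDROPHOBIC else 0.012 for aa in AA_ORDER]
)
CONTRAST_COMPOSITION = CONTRAST_COMPOSITION / CONTRAST_COMPOSITION.sum()


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_sequences: int = 50
    length_range: tuple[int, int] = (60, 120)
    morfs_per_sequence: int = 1
    morf_length_range: tuple[int, int] = (5, 25)
    signal_strength: float = 0.8  # s in [0, 1]
    concentration: float = 10.0  # symmetric prior on background composition
    row_concentration: float = 100.0  # per-residue Dirichlet noise (higher = less)
    flank_len: int = DEFAULT_FLANK_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if self.morf_length_range[0] > self.morf_length_range[1]:
            raise ValueError("invalid morf_length_range")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


@dataclass
class SyntheticDataset:
    """In-memory dataset: annotated sequences plus matching profiles."""

    sequences: list[AnnotatedSequence]
    profiles: list[HMMProfile]
    config: SimConfig

    def profile_by_id(self) -> dict[str, HMMProfile]:
        return {p.seq_id: p for p in self.profiles}


def _place_morfs(
    rng: np.random.Generator, L: int, k: int, mlen_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """Non-overlapping MoRF intervals (0-based half-open) by rejection."""
    lo, hi = mlen_range
    if lo > L:
        raise ValueError(f"MoRF length {lo} exceeds sequence length {L}")
    lengths = [int(m) for m in rng.integers(lo, min(hi, L) + 1, size=k)]
    if sum(lengths) + (k - 1) > L:
        raise ValueError(
            f"cannot place {k} MoRFs of total length {sum(lengths)} in {L} residues"
        )
    for _ in range(1000):
        intervals = sorted(
            (s := int(rng.integers(0, L - m + 1)), s + m) for m in lengths
        )
        if all(b[0] > a[1] for a, b in zip(intervals, intervals[1:])):
            return intervals
    raise ValueError(f"failed to pack {k} MoRFs into a {L}-residue sequence")


def _morf_weight(pos: int, intervals: list[tuple[int, int]], flank_len: int) -> float:
    """Blend weight toward the MoRF composition at one position.

    1 inside a MoRF; decays linearly over the flank (distance d from the
    nearest MoRF boundary gives weight 1 - d/(flank_len+1)); 0 elsewhere.
    """
    best = 0.0
    for s, e in intervals:
        if s <= pos < e:
            return 1.0
        d = s - pos if pos < s else pos - e + 1
        if 1 <= d <= flank_len:
            best = max(best, 1.0 - d / (flank_len + 1.0))
    return best


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset under ``cfg`` (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    sequences: list[AnnotatedSequence] = []
    profiles: list[HMMProfile] = []
    aa = np.array(list(AA_ORDER))
    for i in range(cfg.n_sequences):
        seq_id = f"syn{i + 1:04d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        background = rng.dirichlet(np.full(20, cfg.concentration))
        morf_comp = (
            (1.0 - cfg.signal_strength) * background
            + cfg.signal_strength * CONTRAST_COMPOSITION
        )
        intervals = _place_morfs(
            rng, L, cfg.morfs_per_sequence, cfg.morf_length_range
        )
        rows = np.empty((L, 20))
        letters = []
        for pos in range(L):
            w = _morf_weight(pos, intervals, cfg.flank_len)
            comp = w * morf_comp + (1.0 - w) * background
            row = rng.dirichlet(cfg.row_concentration * comp)
            rows[pos] = row
            letters.append(str(rng.choice(aa, p=row / row.sum())))
        residues = "".join(letters)
        profiles.append(profile_from_probs(seq_id, residues, rows))
        sequences.append(
            AnnotatedSequence(seq_id=seq_id, sequence=residues, morf_intervals=intervals)
        )
    return SyntheticDataset(sequences=sequences, profiles=profiles, config=cfg)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, annotation TSV and one ``.hhm`` per sequence.

    Returns the paths written: ``{"fasta": ..., "annotations": ...,
    "profile_dir": ...}``. Output is byte-identical across runs with the
    same config and seed.
    """
    out_dir = Path(out_dir)
    profile_dir = out_dir / "profiles"
    profile_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "sequences.fasta"
    ann_path = out_dir / "annotations.tsv"
    fasta_path.write_text(
        write_fasta([(s.seq_id, s.sequence) for s in dataset.sequences])
    )
    ann_path.write_text(write_annotations(dataset.sequences))
    for profile in dataset.profiles:
        (profile_dir / f"{profile.seq_id}.hhm").write_text(write_hhm(profile))
    return {"fasta": fasta_path, "annotations": ann_path, "profile_dir": profile_dir}
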