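"""The nine-model SVM ensemble and its score fusion.

Each ensemble member is a support-vector classifier over windowed HMM-profile
features; members differ in kernel (RBF or sigmoid), kernel width gamma,
window size w, and negative sampling ratio, with the penalty fixed at
C = 1000 for all. Every member draws its own negative sample set, so the
ensemble averages over both model and sampling variation. The fused
per-residue propensity is the plain arithmetic mean of the nine member
scores ("common averaging").

Member scores are Platt-scaled class probabilities rather than raw SVM
decision values: decision values of RBF and sigmoid kernels live on
incompatible scales, and averaging only makes sense after mapping both onto
[0, 1] class-membership probabilities.

The default ensemble (window w, kernel, gamma, neg:pos ratio):

====== ==== ======== ======= ======
model   w   kernel    gamma   ratio
====== ==== ======== ======= ======
1       11  rbf       0.0038  1:2
2        7  rbf       5       1:2
3        3  sigmoid   5       1:2
4       13  rbf       0.0038  1:2
5        9  rbf       5       1:1
6        5  sigmoid   5       1:2
7        7  rbf       0.0038  1:2
8       13  rbf       5       1:2
9        7  sigmoid   5       1:1
====== ==== ======== ======= ======
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from . import __version__
from .features import window_matrix
from .profile_io import HMMProfile
from .regions import RegionLabels
from .sampling import SamplingConfig, sample_training_set, stack

logger = logging.getLogger(__name__)

DEFAULT_C = 1000.0


@dataclass
class ModelSpec:
    """Hyper-parameters of one ensemble member."""

    index: int
    kernel: str  # 'rbf' | 'sigmoid'
    gamma: float
    window: int  # odd; flank = (window - 1) // 2
    ratio: int  # negatives per positive
    C: float = DEFAULT_C
    seed: int | None = None  # filled in from the master seed at training time

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "sigmoid"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer (w = 2*flank + 1)")

    @property
    def flank(self) -> int:
        return (self.window - 1) // 2


def default_ensemble_specs() -> list[ModelSpec]:
    """The nine selected models (see the module table)."""
    rows = [
        (1, "rbf", 0.0038, 11, 2),
        (2, "rbf", 5.0, 7, 2),
        (3, "sigmoid", 5.0, 3, 2),
        (4, "rbf", 0.0038, 13, 2),
        (5, "rbf", 5.0, 9, 1),
        (6, "sigmoid", 5.0, 5, 2),
        (7, "rbf", 0.0038, 7, 2),
        (8, "rbf", 5.0, 13, 2),
        (9, "sigmoid", 5.0, 7, 1),
    ]
    return [
        ModelSpec(index=i, kernel=k, gamma=g, window=w, ratio=r)
        for i, k, g, w, r in rows
    ]


@dataclass
class PredictionTrack:
    """Per-residue fused propensity scores for one sequence."""

    seq_id: str
    scores: np.ndarray  # (L,) in [0, 1]
    per_model_scores: np.ndarray | None = None  # (n_models, L)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TrainedModel:
    """One fitted member: its spec plus the underlying classifier."""

    spec: ModelSpec
    clf: CalibratedClassifierCV
    n_pos: int = 0
    n_neg: int = 0

    def score_profile(self, profile: HMMProfile) -> np.ndarray:
        """Propensity in [0, 1] for every residue of ``profile``."""
        X = window_matrix(profile, self.spec.flank)
        return self.clf.predict_proba(X)[:, 1]


def train_model(
    positives, negatives, spec: ModelSpec
) -> TrainedModel:
    """Fit one support-vector classifier on labelled window vectors.

    ``positives`` / ``negatives`` are FeatureVector lists (or 2-D arrays)
    whose dimension must equal ``spec.window * 20``. Scores are calibrated
    class probabilities (Platt scaling).
    """
    X_pos = positives if isinstance(positives, np.ndarray) else stack(positives)
    X_neg = negatives if isinstance(negatives, np.ndarray) else stack(negatives)
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("both classes must be non-empty")
    dim = spec.window * 20
    if X_pos.shape[1] != dim or X_neg.shape[1] != dim:
        raise ValueError(
            f"model {spec.index}: feature dimension {X_pos.shape[1]} != "
            f"window*20 = {dim}"
        )
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos), dtype=int), np.zeros(len(X_neg), dtype=int)])
    svc = SVC(
        kernel=spec.kernel,
        gamma=spec.gamma,
        C=spec.C,
        random_state=spec.seed if spec.seed is not None else 0,
        cache_size=500,
    )
    # sigmoid (Platt) calibration on cross-validated decision values, then a
    # final refit on all data — scores become class probabilities in [0, 1]
    clf = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    clf.fit(X, y)
    return TrainedModel(spec=spec, clf=clf, n_pos=len(X_pos), n_neg=len(X_neg))


@dataclass
class Ensemble:
    """Nine trained members plus provenance metadata."""

    models: list[TrainedModel]
    master_seed: int | None = None
    data_fingerprint: str = ""
    version: str = field(default_factory=lambda: __version__)

    def predict_sequence(self, profile: HMMProfile) -> PredictionTrack:
        return predict_sequence(self, profile)


def _fingerprint(data: list[tuple[HMMProfile, RegionLabels]]) -> str:
    h = hashlib.sha256()
    for profile, labels in data:
        h.update(profile.seq_id.encode())
        h.update(profile.probs.tobytes())
        h.update(np.asarray(labels.labels).tobytes())
    return h.hexdigest()[:16]


def train_ensemble(
    data: list[tuple[HMMProfile, RegionLabels]],
    specs: list[ModelSpec] | None = None,
    master_seed: int = 0,
) -> Ensemble:
    """Train every member on its own freshly sampled training set.

    Member ``i`` samples negatives (and seeds its classifier) with seed
    ``master_seed + i``, so all nine see different negative sets while the
    whole run stays reproducible from the single master seed.
    """
    if specs is None:
        specs = default_ensemble_specs()
    if not data:
        raise ValueError("no training sequences")
    models = []
    for spec in specs:
        spec = ModelSpec(**{**asdict(spec), "seed": master_seed + spec.index})
        cfg = SamplingConfig(
            neg_pos_ratio=spec.ratio, seed=spec.seed, flank=spec.flank
        )
        pos, neg = sample_training_set(data, cfg)
        logger.info(
            "model %d: w=%d kernel=%s gamma=%g ratio=1:%d -> %d pos / %d neg",
            spec.index, spec.window, spec.kernel, spec.gamma, spec.ratio,
            len(pos), len(neg),
        )
        models.append(train_model(pos, neg, spec))
    return Ensemble(
        models=models, master_seed=master_seed, data_fingerprint=_fingerprint(data)
    )


def fuse_scores(tracks: list[np.ndarray]) -> np.ndarray:
    """Common averaging: elementwise arithmetic mean of per-model tracks."""
    if not tracks:
        raise ValueError("no score tracks to fuse")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"score tracks have mismatched lengths {sorted(lengths)}")
    return np.mean(np.vstack(tracks), axis=0)


def predict_sequence(ensemble: Ensemble, profile: HMMProfile) -> PredictionTrack:
    """Score every residue of a sequence with the fused ensemble."""
    per_model = np.vstack([m.score_profile(profile) for m in ensemble.models])
    fused = fuse_scores(list(per_model))
    return PredictionTrack(
        seq_id=profile.seq_id, scores=fused, per_model_scores=per_model
    )


# ---------------------------------------------------------------------------
# persistence: directory with JSON manifest + one joblib file per member
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "morfhmm-ensemble",
        "version": ensemble.version,
        "master_seed": ensemble.master_seed,
        "data_fingerprint": ensemble.data_fingerprint,
        "models": [
            {**asdict(m.spec), "n_pos": m.n_pos, "n_neg": m.n_neg,
             "file": f"model_{m.spec.index}.joblib"}
            for m in ensemble.models
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for m in ensemble.models:
        joblib.dump(m.clf, path / f"model_{m.spec.index}.joblib")


def load_ensemble(path: str | Path) -> Ensemble:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    models = []
    for entry in manifest["models"]:
        clf = joblib.load(path / entry["file"])
        spec = ModelSpec(
            index=entry["index"], kernel=entry["kernel"], gamma=entry["gamma"],
            window=entry["window"], ratio=entry["ratio"], C=entry["C"],
            seed=entry["seed"],
        )
        models.append(
            TrainedModel(spec=spec, clf=clf, n_pos=entry["n_pos"], n_neg=entry["n_neg"])
        )
    return Ensemble(
        models=models,
        master_seed=manifest["master_seed"],
        data_fingerprint=manifest["data_fingerprint"],
        version=manifest["version"],
    )


def tracks_to_tsv(
    tracks: list[PredictionTrack],
    residues: dict[str, str] | None = None,
    per_model: bool = False,
) -> str:
    """Prediction TSV: seq_id, 1-based position, residue, fused score."""
    header = ["seq_id", "position", "residue", "score"]
    if per_model:
        n_models = len(tracks[0].per_model_scores) if tracks else 0
        header += [f"model_{i + 1}" for i in range(n_models)]
    lines = ["\t".join(header)]
    for track in tracks:
        seq = (residues or {}).get(track.seq_id, "")
        for i, score in enumerate(track.scores):
            res = seq[i] if i < len(seq) else "."
            row = [track.seq_id, str(i + 1), res, f"{score:.6f}"]
            if per_model and track.per_model_scores is not None:
                row += [f"{s:.6f}" for s in track.per_model_scores[:, i]]
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
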