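"""Unsupervised behavioural-mode ontology from windowed velocity features.

Each frame of each animal is described by three features — the means of
the lag-5 speed ``rho``, acceleration ``drho`` and turn ``dtheta`` over a
sliding window of [-25, +25] frames, so every observation carries
information about past and future movement. Valid observations are pooled
across animals, standardised, and a seeded subsample is clustered
hierarchically with Ward linkage. The cluster count is chosen where adding
clusters stops notably reducing the total distance of points to their
cluster centres (elbow, maximum discrete curvature). A K-nearest-neighbours
classifier trained on the clustered subsample then labels every frame of
every trace, producing per-animal ethograms.

Frames whose window underruns the trace or overlaps tracker gaps are never
clustered — they surface as the ``missing`` label in ethograms instead of
forming a degenerate edge-artifact cluster.

Clusters are relabelled in order of increasing centre speed; an 11-cluster
model receives the canonical larval mode names (Inactive 1/2, Small/Large
twitches, Collision/Deceleration, Mode change 1/2, Slow/Medium active
swimming, Fast swimming 1/2), any other count generic ``mode_XX`` labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import KNeighborsClassifier, kneighbors_graph

from .kinematics import KinematicSeries

__all__ = [
    "FeatureMatrix",
    "ModeModel",
    "Ethogram",
    "ModeDistribution",
    "MISSING",
    "CANONICAL_MODE_NAMES",
    "build_features",
    "concat_features",
    "cluster_modes",
    "elbow_select",
    "classify",
    "name_modes",
    "mode_distribution",
]

#: label used for frames that cannot be classified
MISSING = "missing"

#: half-width of the feature window, frames
HALF_WINDOW = 25

#: canonical mode names in order of increasing speed, used when k == 11
CANONICAL_MODE_NAMES = (
    "Inactive 1",
    "Inactive 2",
    "Small twitches",
    "Large twitches",
    "Collision/Deceleration",
    "Mode change 1",
    "Mode change 2",
    "Slow active swimming",
    "Medium active swimming",
    "Fast swimming 1",
    "Fast swimming 2",
)

#: feature column names, fixed order
FEATURE_NAMES = ("mean_rho", "mean_accel", "mean_turn")


@dataclass
class FeatureMatrix:
    """Per-frame 3-feature observations with validity mask and keys."""

    X: np.ndarray          # (n, 3): mean rho, mean drho, mean dtheta
    valid: np.ndarray      # (n,) bool
    animal_ids: np.ndarray  # (n,) object
    frames: np.ndarray     # (n,) int

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.valid) == len(self.animal_ids) == len(self.frames) == n):
            raise ValueError("X, valid, animal_ids and frames must align")
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must have {len(FEATURE_NAMES)} columns")
        if self.valid.any() and not np.isfinite(self.X[self.valid]).all():
            raise ValueError("valid rows must be finite")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ModeModel:
    """Fitted behavioural-mode model: clusters, scaler, classifier, names."""

    k: int
    cluster_centres: np.ndarray          # (k, 3) in feature-scaled space
    centres_raw: np.ndarray              # (k, 3) in original feature units
    scaler_mean: np.ndarray              # (3,)
    scaler_scale: np.ndarray             # (3,)
    k_nn: int
    training_X: np.ndarray               # scaled training subsample
    training_labels: np.ndarray          # (m,) int, speed-ordered
    mode_names: dict[int, str]
    wcd_curve: tuple[np.ndarray, np.ndarray]  # (k values, total distances)
    classifier: KNeighborsClassifier = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        counts = np.bincount(self.training_labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must have at least one member")
        if self.mode_names and set(self.mode_names) != set(range(self.k)):
            raise ValueError("mode_names must cover all clusters")
        if self.classifier is None:
            self.classifier = KNeighborsClassifier(n_neighbors=self.k_nn)
            self.classifier.fit(self.training_X, self.training_labels)

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    # -- persistence (versioned JSON bundle) --------------------------------

    def to_json(self, path) -> None:
        d = {
            "format": "cionetho-mode-model/1",
            "k": self.k,
            "k_nn": self.k_nn,
            "cluster_centres": self.cluster_centres.tolist(),
            "centres_raw": self.centres_raw.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "training_X": self.training_X.tolist(),
            "training_labels": self.training_labels.tolist(),
            "mode_names": {str(k): v for k, v in self.mode_names.items()},
            "wcd_k": self.wcd_curve[0].tolist(),
            "wcd": self.wcd_curve[1].tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "ModeModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "cionetho-mode-model/1":
            raise ValueError("unrecognised model format")
        return cls(
            k=d["k"],
            cluster_centres=np.asarray(d["cluster_centres"]),
            centres_raw=np.asarray(d["centres_raw"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            k_nn=d["k_nn"],
            training_X=np.asarray(d["training_X"]),
            training_labels=np.asarray(d["training_labels"], dtype=int),
            mode_names={int(k): v for k, v in d["mode_names"].items()},
            wcd_curve=(np.asarray(d["wcd_k"]), np.asarray(d["wcd"])),
        )


@dataclass
class Ethogram:
    """Per-frame behavioural-mode labels of one animal."""

    animal_id: str
    labels: np.ndarray  # (n,) object; mode name or MISSING

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def fraction_missing(self) -> float:
        return float((self.labels == MISSING).mean())


@dataclass
class ModeDistribution:
    """Per-group mode occupancy over non-missing frames."""

    counts: pd.DataFrame     # index: mode names; columns: groups; frame counts
    fractions: pd.DataFrame  # same shape; columns sum to 1

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 per group")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _window_mean(a: np.ndarray, ok: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred window mean requiring all ``w`` contributors valid."""
    s = np.convolve(np.where(ok, a, 0.0), np.ones(w), mode="same")
    c = np.convolve(ok.astype(float), np.ones(w), mode="same")
    full = c >= w - 0.5
    with np.errstate(invalid="ignore"):
        m = np.where(full, s / w, np.nan)
    return m, full


def build_features(
    kin: KinematicSeries, animal_id: str = "", half_window: int = HALF_WINDOW
) -> FeatureMatrix:
    """Windowed means of (rho, drho, dtheta) per frame for one animal.

    Each row averages the lag kinematics over frames
    ``[t - half_window, t + half_window]``; rows whose window underruns
    the trace or contains any invalid frame are flagged invalid.
    """
    w = 2 * half_window + 1
    n = len(kin.rho)
    if n < w:
        raise ValueError("trace shorter than the feature window")
    ok = kin.valid_mask & np.isfinite(kin.rho) & np.isfinite(kin.accel) & np.isfinite(kin.turn)
    m_rho, f1 = _window_mean(kin.rho, ok, w)
    m_acc, f2 = _window_mean(kin.accel, ok, w)
    m_turn, f3 = _window_mean(kin.turn, ok, w)
    valid = f1 & f2 & f3
    X = np.column_stack([m_rho, m_acc, m_turn])
    return FeatureMatrix(
        X=X,
        valid=valid,
        animal_ids=np.full(n, animal_id, dtype=object),
        frames=np.arange(n),
    )


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Pool per-animal feature matrices into one."""
    return FeatureMatrix(
        X=np.concatenate([p.X for p in parts]),
        valid=np.concatenate([p.valid for p in parts]),
        animal_ids=np.concatenate([p.animal_ids for p in parts]),
        frames=np.concatenate([p.frames for p in parts]),
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def elbow_select(wcd_curve: tuple[np.ndarray, np.ndarray]) -> int:
    """Elbow of a within-cluster-distance curve: maximum discrete curvature.

    Each step of the curve saves a drop ``mc_k = wcd(k) - wcd(k+1)``. The
    knee is the interior k that best splits the log-drop sequence into a
    "still notable" head and a "no longer notable" tail, scored by the
    two-sample (pooled-variance) t statistic

        score(k) = [mean(log mc, j < k) - mean(log mc, j >= k)]
                   / (s_pooled * sqrt(1/n_head + 1/n_tail)),

    a changepoint detector that directly formalises choosing the count
    past which further clusters no longer reduce the total
    within-cluster distance notably. Working on log drops makes the
    score scale-free, so neither one dominant top-level split nor a
    slowly decaying tail can drag the knee away; the variance
    normalisation rewards a clean separation of the two regimes. Ties
    break toward smaller k; a degenerate curve with equal drops
    everywhere (a straight line) scores ~0 at every k and returns the
    smallest interior k with a warning.
    """
    ks, wcd = np.asarray(wcd_curve[0]), np.asarray(wcd_curve[1], dtype=float)
    if len(ks) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    if np.any(np.diff(wcd) > 1e-9 * max(wcd[0], 1.0)):
        warnings.warn("within-cluster distance curve is not monotone non-increasing")
    span = wcd.max() - wcd.min()
    if span <= 1e-12 * max(abs(wcd[0]), 1.0):
        warnings.warn("flat curve; returning smallest interior k")
        return int(ks[1])
    lg = np.log(np.maximum(wcd[:-1] - wcd[1:], 1e-12 * span))
    scores = np.empty(len(lg) - 1)
    for i in range(1, len(lg)):
        head, tail = lg[:i], lg[i:]
        n1, n2 = len(head), len(tail)
        v1 = head.var(ddof=1) if n1 > 1 else 0.0
        v2 = tail.var(ddof=1) if n2 > 1 else 0.0
        dof = max(n1 - 1, 0) + max(n2 - 1, 0)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof) if dof > 0 else 0.0
        scores[i - 1] = (head.mean() - tail.mean()) / (
            sp * np.sqrt(1 / n1 + 1 / n2) + 1e-9
        )
    if np.all(scores <= 1e-3):
        warnings.warn("degenerate (straight-line) curve; returning smallest interior k")
        return int(ks[1])
    return int(ks[1:-1][int(np.argmax(scores))])


def _ward_label_sets(Z_sub: np.ndarray, ks: np.ndarray, exact_max_n: int,
                     n_neighbors: int) -> np.ndarray:
    """Labels for every k in ``ks`` from one Ward tree (columns of output)."""
    n = len(Z_sub)
    if n <= exact_max_n:
        link = linkage(Z_sub, method="ward")
        return cut_tree(link, n_clusters=list(ks))
    # larger subsamples: connectivity-constrained Ward (O(n k) memory)
    conn = kneighbors_graph(Z_sub, n_neighbors=n_neighbors, include_self=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # disconnected-graph fixups
        agg = AgglomerativeClustering(
            n_clusters=2, linkage="ward", connectivity=conn,
            compute_full_tree=True, compute_distances=True,
        ).fit(Z_sub)
    # assemble a scipy-style linkage matrix from the sklearn merge tree
    children = agg.children_
    counts = np.zeros(children.shape[0])
    sizes = {}
    for i, (a, b) in enumerate(children):
        na = 1 if a < n else sizes[a]
        nb = 1 if b < n else sizes[b]
        sizes[n + i] = na + nb
        counts[i] = na + nb
    heights = np.maximum.accumulate(agg.distances_)  # enforce monotone heights
    link = np.column_stack([children, heights, counts]).astype(float)
    return cut_tree(link, n_clusters=list(ks))


def cluster_modes(
    features: FeatureMatrix,
    k_range: range = range(2, 21),
    subsample: int = 50_000,
    seed: int = 0,
    standardize: bool = False,
    k_nn: int = 5,
    exact_max_n: int = 20_000,
    n_neighbors: int = 40,
) -> ModeModel:
    """Fit the behavioural-mode model by Ward clustering with elbow selection.

    A seeded random subsample of valid rows (default 50,000) is
    standardised and clustered hierarchically with Ward linkage; the
    within-cluster total distance is recorded for each candidate k and the
    elbow picks the final count. Clusters are relabelled by increasing
    centre speed and named; a KNN classifier fitted on the subsample
    extends the labels to arbitrary traces. Subsamples above
    ``exact_max_n`` rows use a k-nearest-neighbour connectivity graph to
    keep Ward tractable in memory.
    """
    ks = np.asarray(sorted(k_range))
    V = features.X[features.valid]
    if len(V) < ks.max():
        raise ValueError("fewer valid rows than the largest candidate k")
    rng = np.random.default_rng(seed)
    m = min(subsample, len(V))
    idx = rng.choice(len(V), size=m, replace=False) if m < len(V) else np.arange(len(V))
    S = V[idx]

    if standardize:
        mean = S.mean(axis=0)
        scale = S.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(S.shape[1])
        scale = np.ones(S.shape[1])
    Z = (S - mean) / scale

    label_sets = _ward_label_sets(Z, ks, exact_max_n, n_neighbors)
    wcd = np.empty(len(ks))
    for j, k in enumerate(ks):
        lab = label_sets[:, j]
        total = 0.0
        for c in range(k):
            pts = Z[lab == c]
            if len(pts):
                total += float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).sum())
        wcd[j] = total

    k = elbow_select((ks, wcd))
    lab = label_sets[:, int(np.flatnonzero(ks == k)[0])]

    # relabel clusters by increasing centre speed (tie-break: |mean turn|)
    centres_raw = np.vstack([S[lab == c].mean(axis=0) for c in range(k)])
    order = np.lexsort((np.abs(centres_raw[:, 2]), centres_raw[:, 0]))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    lab = remap[lab]
    centres_raw = centres_raw[order]
    centres_scaled = (centres_raw - mean) / scale

    model = ModeModel(
        k=int(k),
        cluster_centres=centres_scaled,
        centres_raw=centres_raw,
        scaler_mean=mean,
        scaler_scale=scale,
        k_nn=k_nn,
        training_X=Z,
        training_labels=lab,
        mode_names={},
        wcd_curve=(ks, wcd),
    )
    model.mode_names = name_modes(model)
    return model


def name_modes(model: ModeModel) -> dict[int, str]:
    """Cluster -> label map, ordered by centre speed.

    An 11-cluster model receives the canonical larval mode names;
    any other count gets generic ``mode_01 .. mode_k`` labels.
    """
    if model.k == len(CANONICAL_MODE_NAMES):
        return dict(enumerate(CANONICAL_MODE_NAMES))
    return {i: f"mode_{i + 1:02d}" for i in range(model.k)}


# ---------------------------------------------------------------------------
# Classification and ethograms
# ---------------------------------------------------------------------------

def classify(model: ModeModel, features: FeatureMatrix) -> dict[str, Ethogram]:
    """Label every frame of every animal; invalid rows become ``missing``.

    Returns one :class:`Ethogram` per animal_id present in ``features``.
    """
    if features.X.shape[1] != model.training_X.shape[1]:
        raise ValueError("feature dimensionality does not match the model")
    labels = np.full(len(features.X), MISSING, dtype=object)
    if features.valid.any():
        Z = model.scale(features.X[features.valid])
        pred = model.classifier.predict(Z)
        names = np.array([model.mode_names[i] for i in range(model.k)], dtype=object)
        labels[features.valid] = names[pred]
    out: dict[str, Ethogram] = {}
    for aid in pd.unique(features.animal_ids):
        sel = features.animal_ids == aid
        order = np.argsort(features.frames[sel], kind="stable")
        out[str(aid)] = Ethogram(animal_id=str(aid), labels=labels[sel][order])
    return out


def mode_distribution(groups: dict[str, list[Ethogram]]) -> ModeDistribution:
    """Per-group fraction of non-missing frames spent in each mode."""
    all_modes: list[str] = []
    counts = {}
    for gname, ethos in groups.items():
        c: dict[str, int] = {}
        for e in ethos:
            vals, cnts = np.unique(e.labels[e.labels != MISSING], return_counts=True)
            for v, n in zip(vals, cnts):
                c[str(v)] = c.get(str(v), 0) + int(n)
        if not c:
            raise ValueError(f"group {gname!r} has no non-missing frames")
        counts[gname] = c
        for mname in c:
            if mname not in all_modes:
                all_modes.append(mname)
    tab = pd.DataFrame(
        {g: [counts[g].get(m, 0) for m in all_modes] for g in groups}, index=all_modes
    )
    frac = tab / tab.sum(axis=0)
    return ModeDistribution(counts=tab, fractions=frac)
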