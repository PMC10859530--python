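"""Water-stress envirotyping: classify seasons into WW / LD / MD / ED.

Each completed season is summarised as a 100-point trajectory of the daily
supply/demand stress index waterSD (1 = no stress, 0 = full stress)
resampled onto the centesimal cumulative thermal-time axis, so seasons of
different calendar length are directly comparable.  Trajectories are
clustered with k-medoids (PAM for moderate n, CLARA-style subsampled PAM
for large n) under Euclidean distance; the number of clusters is chosen by
the mean silhouette width.  Clusters are named from their median
trajectories: the least-stressed cluster is well-watered (WW) and the rest
are late / mid-season / early drought (LD / MD / ED) by where the stressed
part of the season sits on the thermal-time axis.

Failed seasons (crop death before flowering) have truncated trajectories
and are excluded from clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

GRID = np.arange(1, 101)  # centesimal thermal-time grid, percent
ENV_NAMES = ("WW", "LD", "MD", "ED")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StressTrajectory:
    """A season's waterSD resampled to the 100-point centesimal TT grid."""

    season_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (100,):
            raise ValueError("trajectory must have exactly 100 values")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("waterSD values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def to_centesimal(
    daily_watersd: np.ndarray,
    daily_cum_tt: np.ndarray,
    season_id: str = "",
) -> StressTrajectory:
    """Resample a daily waterSD series onto the centesimal TT grid.

    Cumulative thermal time is normalised to [0, 100] percent and waterSD
    is linearly interpolated at 1..100%.  Invariant to uniform rescaling
    of the thermal-time axis.
    """
    w = np.asarray(daily_watersd, dtype=float)
    tt = np.asarray(daily_cum_tt, dtype=float)
    if w.shape != tt.shape or w.ndim != 1 or len(w) < 2:
        raise ValueError("need equal-length 1-d waterSD and cumulative TT series")
    if np.any(np.diff(tt) < 0):
        raise ValueError("cumulative thermal time must be non-decreasing")
    total = tt[-1] - tt[0]
    if total <= 0:
        raise ValueError("season accumulated no thermal time")
    pct = 100.0 * (tt - tt[0]) / total
    values = np.interp(GRID, pct, w)
    return StressTrajectory(season_id=season_id, values=np.clip(values, 0.0, 1.0))


def season_trajectory(result, season_id: str = "") -> StressTrajectory:
    """Trajectory of a :class:`~sorglt.cropmodel.SeasonResult` (non-failed)."""
    if result.failed:
        raise ValueError(
            f"failed season excluded from envirotyping: {result.fail_reason}")
    d = result.daily
    return to_centesimal(d.watersd.to_numpy(), d.cum_tt.to_numpy(), season_id)


# ---------------------------------------------------------------------------
# k-medoids (PAM) and CLARA
# ---------------------------------------------------------------------------


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    labels = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(len(D)), labels].sum())
    return labels, cost


def pam(D: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Classic PAM k-medoids on a precomputed distance matrix.

    Deterministic: the BUILD phase seeds medoids greedily and the SWAP
    phase always applies the single best-improving swap.  Returns the
    medoid indices (sorted).
    """
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(0.0, nearest[None, :] - D).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])
    medoids = np.array(sorted(medoids))
    # SWAP
    for _ in range(max_iter):
        sub = D[:, medoids]
        order = np.argsort(sub, axis=1)
        nearest_i = order[:, 0]
        d1 = sub[np.arange(n), nearest_i]
        d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            owned = nearest_i == mi
            for h in non_medoids:
                dh = D[:, h]
                delta = np.where(
                    owned, np.minimum(dh, d2) - d1, np.minimum(0.0, dh - d1)
                ).sum()
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = np.sort(medoids)
    return medoids


def clara(
    X: np.ndarray,
    k: int,
    sample_size: int = 100,
    n_draws: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """CLARA-style subsampled PAM; returns medoid indices into ``X``.

    Draws ``n_draws`` random subsamples, runs PAM on each, and keeps the
    medoid set with the lowest total assignment cost over the full data.
    Seeded, hence deterministic.
    """
    n = len(X)
    rng = np.random.default_rng([seed, k, 0xC1A4A])
    best_cost, best_medoids = np.inf, None
    size = min(n, max(sample_size, 2 * k))
    for _ in range(n_draws):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        Ds = cdist(X[idx], X[idx])
        med_local = pam(Ds, k)
        medoids = idx[med_local]
        d_to_med = cdist(X, X[medoids])
        cost = float(d_to_med.min(axis=1).sum())
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    return np.sort(best_medoids)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class EnvClassification:
    """Result of clustering stress trajectories."""

    k: int
    labels: np.ndarray                 # cluster index per trajectory
    medoid_indices: np.ndarray
    medoids: np.ndarray                # (k, 100)
    silhouette_by_k: dict[int, float]
    season_ids: list[str]
    medians: np.ndarray | None = None  # (k, 100) per-cluster median trajectory
    names: dict[int, str] = field(default_factory=dict)

    @property
    def named_labels(self) -> np.ndarray:
        if not self.names:
            raise ValueError("call name_environments first")
        return np.array([self.names[int(c)] for c in self.labels])


def cluster_trajectories(
    trajectories: list[StressTrajectory] | np.ndarray,
    k_range: range | list[int] = range(2, 9),
    seed: int = 0,
    pam_max_n: int = 500,
) -> EnvClassification:
    """k-medoids clustering over a silhouette-scanned range of k.

    Euclidean distance on the 100-point trajectories; full PAM when
    n <= ``pam_max_n``, CLARA subsampling above.  For every k in
    ``k_range`` the mean silhouette width over all points is computed and
    the k maximising it is chosen.  Deterministic under ``seed``.
    """
    if isinstance(trajectories, np.ndarray):
        X = np.asarray(trajectories, dtype=float)
        ids = [str(i) for i in range(len(X))]
    else:
        X = np.stack([t.values for t in trajectories])
        ids = [t.season_id for t in trajectories]
    n = len(X)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if n < 3 * ks[-1]:
        raise ValueError(
            f"need at least {3 * ks[-1]} trajectories for k up to {ks[-1]}, got {n}")

    use_pam = n <= pam_max_n
    D = cdist(X, X) if use_pam else None

    sil: dict[int, float] = {}
    results: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in ks:
        medoids = pam(D, k) if use_pam else clara(X, k, seed=seed)
        labels, _ = _assign(D if use_pam else cdist(X, X[medoids]),
                            medoids if use_pam else np.arange(k))
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
        results[k] = (medoids, labels)

    chosen = max(ks, key=lambda k: (sil[k], -k))
    medoids, labels = results[chosen]
    return EnvClassification(
        k=chosen, labels=labels, medoid_indices=medoids, medoids=X[medoids],
        silhouette_by_k=sil, season_ids=ids,
        medians=np.stack([np.median(X[labels == c], axis=0)
                          for c in range(chosen)]),
    )


def name_environments(classification: EnvClassification) -> EnvClassification:
    """Map cluster indices to WW / LD / MD / ED from median trajectories.

    The cluster whose median trajectory has the highest season mean (least
    stress) is WW.  The rest are ranked by the thermal-time centroid of
    their stressed portion (1 - median): latest centroid is LD, then MD,
    earliest is ED.  Clusters beyond four get generic names.  Ties are
    broken by mean stress and logged.
    """
    if classification.medians is None:
        raise ValueError("classification carries no median trajectories")
    med = classification.medians
    means = med.mean(axis=1)
    ww = int(np.argmax(means))
    names = {ww: "WW"}
    rest = [c for c in range(classification.k) if c != ww]

    def stress_centroid(c: int) -> float:
        s = 1.0 - med[c]
        total = s.sum()
        if total <= 1e-12:
            logger.info("cluster %d is unstressed; centroid tie broken by mean", c)
            return 50.0
        return float((GRID * s).sum() / total)

    keyed = sorted(rest, key=lambda c: (-stress_centroid(c), means[c]))
    for rank, c in enumerate(keyed):
        names[c] = ("LD", "MD", "ED")[rank] if rank < 3 else f"X{rank + 2}"
    classification.names = names
    return classification


def environment_frequencies(
    labels: np.ndarray | list[str],
    site_index: np.ndarray | list,
) -> pd.DataFrame:
    """Per-site relative frequency of each environment class (rows sum to 1)."""
    df = pd.DataFrame({"site": site_index, "env": labels})
    freq = pd.crosstab(df["site"], df["env"], normalize="index")
    order = [e for e in ENV_NAMES if e in freq.columns]
    order += [c for c in freq.columns if c not in order]
    return freq[order]


def label_agreement(true_labels, pred_labels) -> float:
    """Best label agreement under permutation matching (Hungarian)."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    cm = pd.crosstab(true_labels, pred_labels).to_numpy()
    r, c = linear_sum_assignment(-cm)
    return float(cm[r, c].sum()) / len(true_labels)


# ---------------------------------------------------------------------------
# Tidy I/O
# ---------------------------------------------------------------------------


def trajectories_from_csv(path) -> list[StressTrajectory]:
    """Read (season_id, day, watersd, cum_tt) tidy CSV into trajectories."""
    raw = pd.read_csv(path)
    required = {"season_id", "watersd", "cum_tt"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for sid, grp in raw.groupby("season_id", sort=True):
        out.append(to_centesimal(
            grp.watersd.to_numpy(), grp.cum_tt.to_numpy(), str(sid)))
    return out


def classification_to_csv(classification: EnvClassification, labels_path,
                          medoids_path) -> None:
    labels = (classification.named_labels if classification.names
              else classification.labels.astype(str))
    pd.DataFrame({
        "season_id": classification.season_ids,
        "cluster": classification.labels,
        "env": labels,
    }).to_csv(labels_path, index=False)
    med = pd.DataFrame(classification.medoids.T, columns=[
        classification.names.get(c, str(c)) for c in range(classification.k)])
    med.insert(0, "pct_tt", GRID)
    med.to_csv(medoids_path, index=False)


__all__ = [
    "StressTrajectory", "EnvClassification", "GRID", "ENV_NAMES",
    "to_centesimal", "season_trajectory", "pam", "clara",
    "cluster_trajectories", "name_environments", "environment_frequencies",
    "label_agreement", "trajectories_from_csv", "classification_to_csv",
]
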