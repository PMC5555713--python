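"""Analysis statistics over recorded reservoir activity and weight snapshots.

* ``separability`` — the behavioral-performance proxy: the sum of all pairwise
  Euclidean distances between the reservoir states inside a sliding window of
  one word length, input units excluded.  Higher means better-separated
  internal representations (shorter predicted reaction times).
* PCA of states and of pooled incoming weight vectors.
* Agglomerative clustering of activity patterns with a per-cluster composition
  report (how many distinct input conditions fall into each cluster, and how
  dominant the most frequent one is).
* Selectivity index of single units, the joint probability of firing under
  each input condition, and per-neuron mutual information between the binary
  response and the input condition.
* Weight-trajectory analyses: distance from the initial weight vector and the
  change in movement direction around a schedule switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA


@dataclass
class ActivityRecord:
    """Binary excitatory states over time plus per-step labels.

    ``states`` has one row per time step; labels give the input symbol, the
    0-based position within the word, the word (trial) index and the task of
    each step.  ``input_units`` lists the unit indices that receive direct
    external drive (so they can be excluded from the separability measure).
    """

    states: np.ndarray
    symbols: np.ndarray
    positions: np.ndarray
    words: np.ndarray
    tasks: np.ndarray
    input_units: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        n = self.states.shape[0]
        for name in ("symbols", "positions", "words", "tasks"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"label array {name!r} not aligned with states")

    def __len__(self) -> int:
        return self.states.shape[0]

    def slice(self, start: int, stop: int) -> "ActivityRecord":
        return ActivityRecord(
            self.states[start:stop],
            self.symbols[start:stop],
            self.positions[start:stop],
            self.words[start:stop],
            self.tasks[start:stop],
            self.input_units,
        )

    def condition_labels(self, condition: str = "symbol_position") -> np.ndarray:
        """Per-step input-condition labels.

        ``"position"`` uses position-in-word; ``"symbol"`` the input symbol;
        ``"symbol_position"`` their combination (the default for clustering).
        """
        if condition == "position":
            return self.positions.astype(str)
        if condition == "symbol":
            return self.symbols.astype(str)
        if condition == "symbol_position":
            return np.char.add(
                np.char.add(self.symbols.astype(str), "@"), self.positions.astype(str)
            )
        raise ValueError(f"unknown condition {condition!r}")


def separability(
    record: ActivityRecord,
    t: int,
    window: int = 20,
    exclude_input_units: bool = True,
) -> float:
    """Sum over all ordered pairs (n, m) in [t, t+window) of the Euclidean
    distance between the state vectors at t+n and t+m."""
    if t + window > len(record):
        raise ValueError("window extends beyond the recorded activity")
    X = record.states[t : t + window].astype(np.float64)
    if exclude_input_units and record.input_units.size:
        keep = np.setdiff1d(np.arange(X.shape[1]), record.input_units)
        X = X[:, keep]
    # pdist covers unordered pairs once; the double sum counts both orders
    return float(2.0 * pdist(X, metric="euclidean").sum())


def separability_per_word(
    record: ActivityRecord, word_length: int, exclude_input_units: bool = True
) -> np.ndarray:
    """Separability of each complete word-aligned window of the record."""
    n_words = len(record) // word_length
    return np.array(
        [
            separability(record, w * word_length, word_length, exclude_input_units)
            for w in range(n_words)
        ]
    )


def pca_states(record: ActivityRecord, n_components: int = 3):
    """Mean-centered PCA of the state matrix.

    Returns ``(components, explained_variance_ratio, coordinates)``; degenerate
    (zero-variance) components come out with explained variance 0.
    """
    X = record.states.astype(np.float64)
    if X.shape[0] <= n_components:
        raise ValueError("record must have more rows than components")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return pca.components_, pca.explained_variance_ratio_, coords


@dataclass
class ClusterReport:
    n_clusters: int
    labels: np.ndarray                     # cluster index per state
    histograms: list[dict[str, int]]       # per cluster: condition -> count
    mean_conditions_per_cluster: float
    mean_dominant_share: float             # % of each cluster in its modal condition
    mean_condition_share: float            # % contributed by an average condition


def cluster_activity(
    record: ActivityRecord,
    n_clusters: int = 20,
    linkage: str = "average",
    condition: str = "symbol_position",
    exclude_input_units: bool = True,
) -> ClusterReport:
    """Agglomerative (Euclidean) clustering of activity patterns into exactly
    ``n_clusters`` clusters, with a composition report over input conditions.

    Clustering operates on the internal state representation, i.e. the
    externally driven input units are dropped by default (as for
    separability).  ``mean_dominant_share`` averages, over clusters, the
    percentage of member patterns belonging to the cluster's most frequent
    condition; ``mean_condition_share`` averages the share of each
    *contributing* condition (both readings of "each input condition
    contributing to X%" are reported).
    """
    X = record.states.astype(np.float64)
    if exclude_input_units and record.input_units.size:
        X = X[:, np.setdiff1d(np.arange(X.shape[1]), record.input_units)]
    if X.shape[0] < n_clusters:
        raise ValueError("fewer activity patterns than requested clusters")
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, metric="euclidean", linkage=linkage
    ).fit_predict(X)
    conds = record.condition_labels(condition)

    histograms: list[dict[str, int]] = []
    n_conditions, dom_shares, cond_shares = [], [], []
    for c in range(n_clusters):
        members = conds[labels == c]
        vals, counts = np.unique(members, return_counts=True)
        histograms.append(dict(zip(vals.tolist(), counts.tolist())))
        n_conditions.append(len(vals))
        dom_shares.append(100.0 * counts.max() / counts.sum())
        cond_shares.append(100.0 * np.mean(counts / counts.sum()))
    return ClusterReport(
        n_clusters=n_clusters,
        labels=labels,
        histograms=histograms,
        mean_conditions_per_cluster=float(np.mean(n_conditions)),
        mean_dominant_share=float(np.mean(dom_shares)),
        mean_condition_share=float(np.mean(cond_shares)),
    )


def selectivity_index(rates: np.ndarray, k: int | None = None) -> float:
    """Tuning selectivity d = (k - sum(rates)/max(rates)) / (k - 1) in [0, 1].

    0 means identical responses to all k conditions, 1 means the unit responds
    to exactly one condition.  All-zero rates give NaN (undefined).
    """
    rates = np.asarray(rates, dtype=np.float64)
    if k is None:
        k = rates.size
    if k < 2:
        raise ValueError("selectivity needs at least two conditions")
    m = rates.max()
    if m <= 0:
        return float("nan")
    return float((k - rates.sum() / m) / (k - 1))


def firing_rates_by_condition(record: ActivityRecord, condition: str = "symbol") -> tuple[np.ndarray, np.ndarray]:
    """Mean firing rate of every neuron under each input condition.

    Returns ``(rates, condition_values)`` with rates of shape
    (n_neurons, n_conditions).
    """
    conds = record.condition_labels(condition)
    values = np.unique(conds)
    rates = np.stack(
        [record.states[conds == v].mean(axis=0) for v in values], axis=1
    )
    return rates, values


def joint_probability(
    record: ActivityRecord, condition: str = "position"
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical joint probability P(fire, condition) per neuron.

    Returns ``(joint, condition_values)`` where ``joint[i, s]`` is the fraction
    of all recorded steps at which neuron i fired while condition s was
    presented.  Together with the silent joint P(s) - joint[i, s] the entries
    sum to one per neuron.
    """
    conds = record.condition_labels(condition)
    values = np.unique(conds)
    T = len(record)
    joint = np.stack(
        [record.states[conds == v].sum(axis=0) / T for v in values], axis=1
    )
    return joint, values


def mutual_information(
    record: ActivityRecord, condition: str = "position", base: float = np.e
) -> np.ndarray:
    """Per-neuron mutual information between the binary response and the
    input condition, from the empirical joint distribution.

    Natural logarithm by default (pass ``base=2`` for bits).  The condition
    marginal is empirical (uniform 1/L_word when every position appears
    equally often); the response marginal per neuron is its overall firing
    probability (total spikes per word divided by the word length).
    """
    conds = record.condition_labels(condition)
    values, counts = np.unique(conds, return_counts=True)
    T = len(record)
    p_s = counts / T
    joint_fire, _ = joint_probability(record, condition)
    joint_silent = p_s[None, :] - joint_fire
    p_fire = joint_fire.sum(axis=1)

    def _terms(joint: np.ndarray, p_r: np.ndarray) -> np.ndarray:
        denom = p_r[:, None] * p_s[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(joint > 0, joint / np.where(denom > 0, denom, 1.0), 1.0)
            out = joint * np.log(ratio)
        return np.where(joint > 0, out, 0.0).sum(axis=1)

    mi = _terms(joint_fire, p_fire) + _terms(joint_silent, 1.0 - p_fire)
    return mi / np.log(base)


@dataclass
class WeightTrajectory:
    """Snapshots of the full E->E weight matrix at recorded times."""

    times: np.ndarray                     # sorted snapshot step indices
    snapshots: np.ndarray                 # (n_snapshots, N_E, N_E)

    @classmethod
    def from_dict(cls, snaps: dict[int, np.ndarray]) -> "WeightTrajectory":
        times = np.array(sorted(snaps), dtype=int)
        return cls(times, np.stack([snaps[t] for t in times]))

    def at(self, t: int) -> np.ndarray:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise KeyError(f"no weight snapshot recorded at step {t}")
        return self.snapshots[idx[0]]


def weight_distance_series(traj: WeightTrajectory) -> np.ndarray:
    """Euclidean distance of each incoming weight vector from its initial
    value, per snapshot: shape (n_snapshots, N_E)."""
    if len(traj.times) < 2:
        raise ValueError("need at least two snapshots")
    diff = traj.snapshots - traj.snapshots[0][None]
    return np.linalg.norm(diff, axis=2)


def direction_change(
    traj: WeightTrajectory, t_center: int, window: int = 1600
) -> np.ndarray:
    """Per-neuron angle (degrees) between the weight displacement over the
    ``window`` steps before ``t_center`` and the displacement over the
    ``window`` steps after it, in the full weight space.

    Neurons whose displacement is zero on either side get NaN (excluded).
    """
    u = traj.at(t_center) - traj.at(t_center - window)
    v = traj.at(t_center + window) - traj.at(t_center)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    cos = np.full(u.shape[0], np.nan)
    dots = np.einsum("ij,ij->i", u, v)
    cos[ok] = np.clip(dots[ok] / (nu[ok] * nv[ok]), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def pca_weight_trajectories(
    traj: WeightTrajectory, n_components: int = 3, center_on_initial: bool = False
):
    """PCA fitted on the pooled incoming weight vectors of all snapshots;
    every snapshot projected into the leading components.

    Returns ``(projected, explained_variance_ratio)`` with ``projected`` of
    shape (n_snapshots, N_E, n_components).  With ``center_on_initial`` the
    initial weight vectors are subtracted first, anchoring each trajectory at
    the origin.
    """
    snaps = traj.snapshots
    if center_on_initial:
        snaps = snaps - snaps[0][None]
    pooled = snaps.reshape(-1, snaps.shape[2])
    if pooled.shape[0] < n_components:
        raise ValueError("not enough pooled weight vectors for the requested components")
    pca = PCA(n_components=n_components)
    flat = pca.fit_transform(pooled)
    return flat.reshape(snaps.shape[0], snaps.shape[1], n_components), pca.explained_variance_ratio_
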