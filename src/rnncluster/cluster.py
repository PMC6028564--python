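"""The random neural-network cluster: a random-subspace ensemble.

The full dataset is split 8:2 into a stratified training and test set.
Each of ``k`` ensemble members trains an independent base network on its
own random subsample of ``n_sub`` training subjects and ``m_feat`` features
(both without replacement). A new subject is classified by majority vote
over the k member predictions. Members whose individual held-out accuracy
exceeds a cut (default 0.6) are the *significant* members; counting how
often each feature was sampled by a significant member ranks features by
discriminative importance, and rebuilding clusters restricted to the
top-m features locates the optimal significant-feature count.

Defaults mirror a 92-subject cohort with 4275 connectome features:
k = 1000 members, 70 subjects and 120 features per member, 0.6 accuracy
cut.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_X_y

from rnncluster.features import FeatureTable
from rnncluster.networks import (
    TrainConfig,
    make_base_classifier,
    model_to_dict,
    model_from_dict,
)

__all__ = [
    "ClusterConfig",
    "ClusterMember",
    "RandomNNCluster",
    "stratified_split_indices",
    "split_train_test",
    "build_cluster",
    "majority_vote",
    "ensemble_accuracy",
    "select_significant",
    "feature_frequencies",
    "top_features",
    "optimal_feature_count",
    "cluster_report",
    "save_cluster",
    "load_cluster",
]


@dataclass
class ClusterConfig:
    """Ensemble-level configuration.

    ``k`` members, each trained on ``n_sub`` subjects and ``m_feat``
    features sampled without replacement from the training set;
    ``sig_threshold`` is the strict per-member accuracy cut for the
    significant set. ``train_config`` carries the base-network
    hyper-parameters.
    """

    k: int = 1000
    n_sub: int = 70
    m_feat: int = 120
    base_kind: str = "elman"
    split_ratio: float = 0.8
    sig_threshold: float = 0.6
    seed: int = 0
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0.0 <= self.sig_threshold <= 1.0:
            raise ValueError("sig_threshold must be in [0, 1]")


@dataclass
class ClusterMember:
    """One trained ensemble member and its sampling record."""

    subject_idx: np.ndarray
    feature_idx: np.ndarray
    model: object
    seed: int
    test_accuracy: float | None = None


def stratified_split_indices(y, ratio: float = 0.8, seed: int = 0):
    """Stratified train/test indices with floor rounding.

    Each class contributes ``floor(ratio * n_class)`` subjects to the
    training set; if the total falls short of ``floor(ratio * N)`` the
    classes with the largest fractional remainders are topped up one
    subject each. The split is disjoint and exhaustive; an error is raised
    if any class would be absent from either side.
    """
    y = np.asarray(y)
    n = len(y)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    takes, remainders, per_class_idx = {}, {}, {}
    for c in classes:
        idx = np.flatnonzero(y == c)
        per_class_idx[c] = rng.permutation(idx)
        exact = ratio * len(idx)
        takes[c] = int(np.floor(exact))
        remainders[c] = exact - takes[c]
    shortfall = int(np.floor(ratio * n)) - sum(takes.values())
    if shortfall > 0:
        for c in sorted(classes, key=lambda c: (-remainders[c], str(c)))[:shortfall]:
            takes[c] += 1
    train, test = [], []
    for c in classes:
        t = takes[c]
        if t == 0 or t == len(per_class_idx[c]):
            raise ValueError(
                f"class {c!r} would be empty on one side of the split "
                f"(n={len(per_class_idx[c])}, ratio={ratio})"
            )
        train.extend(per_class_idx[c][:t])
        test.extend(per_class_idx[c][t:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def split_train_test(table: FeatureTable, ratio: float = 0.8, seed: int = 0):
    """Stratified split of a FeatureTable into (train, test) tables."""
    tr, te = stratified_split_indices(table.y, ratio=ratio, seed=seed)

    def _take(idx):
        return FeatureTable(
            X=table.X[idx],
            y=table.y[idx],
            subject_ids=[table.subject_ids[i] for i in idx],
            layout=table.layout,
            feature_names=list(table.feature_names),
        )

    return _take(tr), _take(te)


def majority_vote(member_labels):
    """Most frequent label; ties go to the lowest (first-sorted) label."""
    labels = np.asarray(member_labels)
    if labels.size == 0:
        raise ValueError("majority_vote needs at least one vote")
    uniq, counts = np.unique(labels, return_counts=True)
    return uniq[np.argmax(counts)]


class RandomNNCluster(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble of neural-network base classifiers.

    Parameters
    ----------
    base_kind : {'bp', 'pnn', 'competitive', 'lvq', 'elman'}
        Base network type (default 'elman').
    k : int
        Number of ensemble members (default 1000).
    n_sub, m_feat : int
        Subjects and features sampled (without replacement) per member.
    sig_threshold : float
        Strict per-member test-accuracy cut for the significant set.
    train_config : TrainConfig, optional
        Base-network hyper-parameters.
    random_state : int
        Master seed; member seeds are spawned deterministically from it,
        so results are independent of execution order.

    Attributes
    ----------
    members_ : list of ClusterMember
    classes_ : sorted unique class labels
    n_failed_ : members whose training failed (excluded from voting)
    """

    def __init__(self, base_kind: str = "elman", k: int = 1000,
                 n_sub: int = 70, m_feat: int = 120,
                 sig_threshold: float = 0.6,
                 train_config: TrainConfig | None = None,
                 random_state: int = 0):
        self.base_kind = base_kind
        self.k = k
        self.n_sub = n_sub
        self.m_feat = m_feat
        self.sig_threshold = sig_threshold
        self.train_config = train_config
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n, p = X.shape
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.n_sub <= n:
            raise ValueError(f"n_sub={self.n_sub} outside [1, {n}]")
        if not 1 <= self.m_feat <= p:
            raise ValueError(f"m_feat={self.m_feat} outside [1, {p}]")
        self.classes_ = np.unique(y)
        self.n_features_in_ = p
        cfg = self.train_config or TrainConfig()
        template = make_base_classifier(self.base_kind, cfg)
        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.k)
        self.members_ = []
        self.n_failed_ = 0
        for child in children:
            rng = np.random.default_rng(child)
            member_seed = int(child.generate_state(1)[0] % (2**31))
            sub_idx = np.sort(rng.choice(n, size=self.n_sub, replace=False))
            feat_idx = np.sort(rng.choice(p, size=self.m_feat, replace=False))
            model = clone(template)
            if "random_state" in model.get_params():
                model.set_params(random_state=member_seed)
            try:
                model.fit(X[np.ix_(sub_idx, feat_idx)], y[sub_idx])
            except Exception as err:  # noqa: BLE001 - member isolation
                self.n_failed_ += 1
                warnings.warn(
                    f"ensemble member failed to train and is excluded: {err}"
                )
                continue
            self.members_.append(
                ClusterMember(subject_idx=sub_idx, feature_idx=feat_idx,
                              model=model, seed=member_seed)
            )
        if not self.members_:
            raise RuntimeError("all ensemble members failed to train")
        return self

    # -- prediction --------------------------------------------------------

    def _member_votes(self, X):
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; cluster was fitted with "
                f"{self.n_features_in_}"
            )
        votes = np.empty((len(self.members_), X.shape[0]), dtype=object)
        for i, m in enumerate(self.members_):
            votes[i] = m.model.predict(X[:, m.feature_idx])
        return votes

    def predict_with_flags(self, X):
        """Majority-vote labels plus a boolean tie flag per subject."""
        votes = self._member_votes(X)
        n = votes.shape[1]
        labels = np.empty(n, dtype=self.classes_.dtype)
        ties = np.zeros(n, dtype=bool)
        for j in range(n):
            uniq, counts = np.unique(votes[:, j], return_counts=True)
            top = counts.max()
            ties[j] = int((counts == top).sum()) > 1
            labels[j] = uniq[np.argmax(counts)]
        return labels, ties

    def predict(self, X):
        return self.predict_with_flags(X)[0]

    # -- evaluation and feature importance ---------------------------------

    def member_accuracies(self, X, y) -> np.ndarray:
        """Per-member accuracy on (X, y); cached on the members."""
        y = np.asarray(y)
        votes = self._member_votes(X)
        accs = (votes == y[None, :]).mean(axis=1)
        for m, a in zip(self.members_, accs):
            m.test_accuracy = float(a)
        return accs

    def significant_members(self, X, y, threshold: float | None = None):
        """Members with held-out accuracy strictly above the cut."""
        cut = self.sig_threshold if threshold is None else threshold
        accs = self.member_accuracies(X, y)
        return [
            (i, float(a)) for i, a in enumerate(accs) if a > cut
        ]

    def feature_frequencies(self, member_indices=None) -> np.ndarray:
        """How often each feature was sampled by the given members.

        ``member_indices=None`` counts over all members. The counts sum to
        ``len(members) * m_feat``.
        """
        if member_indices is None:
            member_indices = range(len(self.members_))
        idx = [self.members_[i].feature_idx for i in member_indices]
        if not idx:
            return np.zeros(self.n_features_in_, dtype=int)
        return np.bincount(np.concatenate(idx), minlength=self.n_features_in_)


def build_cluster(train, cfg: ClusterConfig) -> RandomNNCluster:
    """Train a RandomNNCluster from a FeatureTable (or (X, y) pair)."""
    if isinstance(train, FeatureTable):
        X, y = train.X, train.y
    else:
        X, y = train
    model = RandomNNCluster(
        base_kind=cfg.base_kind, k=cfg.k, n_sub=cfg.n_sub, m_feat=cfg.m_feat,
        sig_threshold=cfg.sig_threshold, train_config=cfg.train_config,
        random_state=cfg.seed,
    )
    return model.fit(X, y)


def _as_xy(table):
    if isinstance(table, FeatureTable):
        return table.X, table.y
    return table


def ensemble_accuracy(model: RandomNNCluster, test) -> float:
    """Fraction of test subjects whose majority-vote label is correct."""
    X, y = _as_xy(test)
    return float(np.mean(model.predict(X) == np.asarray(y)))


def select_significant(model: RandomNNCluster, test, threshold: float = 0.6):
    """Members with per-member test accuracy strictly above ``threshold``."""
    X, y = _as_xy(test)
    return model.significant_members(X, y, threshold=threshold)


def feature_frequencies(model: RandomNNCluster, significant) -> np.ndarray:
    """Counts over the feature samples of the given (index, acc) members."""
    indices = [i for i, _ in significant]
    return model.feature_frequencies(indices)


def top_features(counts, m: int) -> np.ndarray:
    """Indices of the m highest counts; ties broken by ascending index."""
    counts = np.asarray(counts)
    if not 0 <= m <= len(counts):
        raise ValueError(f"m={m} outside [0, {len(counts)}]")
    order = np.lexsort((np.arange(len(counts)), -counts))
    return np.sort(order[:m])


def optimal_feature_count(train, test, cfg: ClusterConfig, candidates,
                          reps: int = 5):
    """Pick the significant-feature count with the best, most stable accuracy.

    A first cluster is built on the full feature set to obtain the
    significant-member feature frequencies. For each candidate count m*,
    ``reps`` clusters restricted to the top-m* features are rebuilt with
    distinct derived seeds and evaluated on the test set. The candidate
    with the highest mean accuracy wins; ties prefer the lower standard
    deviation, then the smaller m*.

    Returns ``(chosen_count, profile)`` where profile is a list of dicts
    with keys ``m``, ``mean_accuracy``, ``sd_accuracy``, ``accuracies``.
    """
    candidates = [int(m) for m in candidates]
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X_tr, y_tr = _as_xy(train)
    X_te, y_te = _as_xy(test)
    p = X_tr.shape[1]
    if max(candidates) > p:
        raise ValueError("candidate feature count exceeds total features")

    base = build_cluster((X_tr, y_tr), cfg)
    sig = select_significant(base, (X_te, y_te), threshold=cfg.sig_threshold)
    counts = feature_frequencies(base, sig)

    root = np.random.SeedSequence(cfg.seed).spawn(len(candidates) * reps + 1)
    profile = []
    child = 1
    for m_star in candidates:
        pool = top_features(counts, m_star)
        accs = []
        for _ in range(reps):
            rep_seed = int(root[child].generate_state(1)[0] % (2**31))
            child += 1
            rep_cfg = ClusterConfig(
                k=cfg.k, n_sub=cfg.n_sub, m_feat=min(cfg.m_feat, m_star),
                base_kind=cfg.base_kind, split_ratio=cfg.split_ratio,
                sig_threshold=cfg.sig_threshold, seed=rep_seed,
                train_config=cfg.train_config,
            )
            sub = build_cluster((X_tr[:, pool], y_tr), rep_cfg)
            accs.append(ensemble_accuracy(sub, (X_te[:, pool], y_te)))
        accs = np.asarray(accs)
        profile.append({
            "m": m_star,
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std(ddof=0)),
            "accuracies": [float(a) for a in accs],
        })
    best = min(profile, key=lambda r: (-r["mean_accuracy"], r["sd_accuracy"], r["m"]))
    return best["m"], profile


def cluster_report(model: RandomNNCluster, test, cfg: ClusterConfig | None = None) -> dict:
    """Deterministic JSON-ready evaluation report of a fitted cluster."""
    X, y = _as_xy(test)
    labels, ties = model.predict_with_flags(X)
    accs = model.member_accuracies(X, y)
    sig = [(i, a) for i, a in enumerate(accs) if a > model.sig_threshold]
    report = {
        "config": {
            "base_kind": model.base_kind,
            "k": model.k,
            "n_sub": model.n_sub,
            "m_feat": model.m_feat,
            "sig_threshold": model.sig_threshold,
            "random_state": model.random_state,
        },
        "n_members": len(model.members_),
        "n_failed": model.n_failed_,
        "ensemble_accuracy": float(np.mean(labels == np.asarray(y))),
        "mean_member_accuracy": float(accs.mean()),
        "sd_member_accuracy": float(accs.std(ddof=0)),
        "member_accuracies": [round(float(a), 10) for a in accs],
        "n_significant": len(sig),
        "significant_members": [[i, round(a, 10)] for i, a in sig],
        "n_tied_votes": int(ties.sum()),
    }
    if cfg is not None:
        report["config"]["split_ratio"] = cfg.split_ratio
        tc = asdict(cfg.train_config)
        report["config"]["train_config"] = tc
    return report


def save_cluster(model: RandomNNCluster, out_dir) -> None:
    """Serialize a fitted cluster (config + every member) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "base_kind": model.base_kind, "k": model.k, "n_sub": model.n_sub,
        "m_feat": model.m_feat, "sig_threshold": model.sig_threshold,
        "random_state": model.random_state,
        "n_features_in": int(model.n_features_in_),
        "classes": [str(c) for c in model.classes_],
        "n_failed": model.n_failed_,
        "n_members": len(model.members_),
    }
    with open(out / "cluster.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    members = []
    for m in model.members_:
        members.append({
            "subject_idx": m.subject_idx.tolist(),
            "feature_idx": m.feature_idx.tolist(),
            "seed": m.seed,
            "test_accuracy": m.test_accuracy,
            "model": model_to_dict(m.model),
        })
    with open(out / "members.json", "w") as fh:
        json.dump(members, fh, sort_keys=True)


def load_cluster(in_dir) -> RandomNNCluster:
    """Reload a cluster serialized by :func:`save_cluster`."""
    src = Path(in_dir)
    with open(src / "cluster.json") as fh:
        meta = json.load(fh)
    model = RandomNNCluster(
        base_kind=meta["base_kind"], k=meta["k"], n_sub=meta["n_sub"],
        m_feat=meta["m_feat"], sig_threshold=meta["sig_threshold"],
        random_state=meta["random_state"],
    )
    model.n_features_in_ = meta["n_features_in"]
    model.classes_ = np.asarray(meta["classes"])
    model.n_failed_ = meta["n_failed"]
    with open(src / "members.json") as fh:
        members = json.load(fh)
    model.members_ = [
        ClusterMember(
            subject_idx=np.asarray(m["subject_idx"], dtype=int),
            feature_idx=np.asarray(m["feature_idx"], dtype=int),
            model=model_from_dict(m["model"]),
            seed=m["seed"],
            test_accuracy=m["test_accuracy"],
        )
        for m in members
    ]
    return model
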