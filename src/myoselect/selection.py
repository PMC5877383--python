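"""Feature-separability criteria and selection.

Three criteria rank the feature bank:

* **EC** — entropy of class-normalized feature variances.  Per feature,
  the within-class variances are normalized to sum to one across classes
  and their Shannon entropy is the separability value; a feature whose
  variance differs strongly between classes has low entropy, so *smaller*
  is more separable and features are ranked ascending.
* **FD** — a Fisher-style discrimination ratio: mean squared Euclidean
  distance between all cross-class trial pairs over the summed mean
  within-class pair distances, averaged over one-versus-all binary
  problems.  Larger is more separable.
* **RFE** — SVM recursive feature elimination: repeatedly train a
  linear-kernel SVM and eliminate the feature whose removal least reduces
  the squared-weight margin criterion (i.e. the smallest w_i^2).  The
  elimination order, reversed, is the rank.

On top of the criteria sit the optimal-feature-number sweep (accuracy as a
function of subset size along a rank), cross-subject/channel aggregation,
and channel ranking by single-channel classification accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluate import ClassifierConfig, crossval
from .features import FeatureMatrix


@dataclass
class SeparabilityReport:
    """Per-feature separability values and the induced rank order.

    ``sv`` maps feature name -> separability value (EC/FD) or rank (RFE);
    ``order`` lists feature names from most to least separable.
    """

    method: str
    sv: dict[str, float]
    order: list[str]
    n_classes: int

    @property
    def rank(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.order)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.order,
                "sv": [self.sv[f] for f in self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def _stable_order(names: list[str], key: np.ndarray, ascending: bool) -> list[str]:
    # ties broken by position in the canonical feature list (stable sort)
    idx = np.argsort(key if ascending else -key, kind="stable")
    return [names[i] for i in idx]


def ec_score(features: FeatureMatrix) -> SeparabilityReport:
    """Entropy-criterion separability: J_i = -sum_k V_ki ln V_ki.

    V_ki is the i-th feature's variance in class k normalized so the
    variances sum to one across classes (0 ln 0 := 0).  J is bounded by
    ln(n_classes), attained when all class variances are equal; features
    are ranked ascending J.
    """
    classes = features.classes
    if len(classes) < 2:
        raise ValueError("EC needs at least 2 classes")
    var = np.empty((len(classes), features.n_features))
    for k, c in enumerate(classes):
        block = features.values[features.labels == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 windows")
        var[k] = block.var(axis=0, ddof=1)
    total = var.sum(axis=0)
    j = np.full(features.n_features, np.log(len(classes)))
    ok = total > 0
    v = var[:, ok] / total[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(v > 0, v * np.log(v), 0.0)
    j[ok] = -terms.sum(axis=0)
    names = features.feature_names
    return SeparabilityReport(
        method="EC",
        sv=dict(zip(names, j.tolist())),
        order=_stable_order(names, j, ascending=True),
        n_classes=len(classes),
    )


def fisher_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Two-class Fisher discrimination ratio of one feature.

    D2(a,b) is the mean squared difference over all |a|*|b| cross pairs;
    D2(a,a) the mean over all distinct within-class pairs.  Returns +inf
    when both within-class spreads are zero.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per class")
    # closed forms: cross mean = var_pop(a)+var_pop(b)+(mean gap)^2;
    # within mean over distinct pairs = 2*var_unbiased
    d2_ab = a.var() + b.var() + (a.mean() - b.mean()) ** 2
    within = 2 * a.var(ddof=1) + 2 * b.var(ddof=1)
    if within == 0:
        warnings.warn("zero within-class spread: infinite separability")
        return np.inf
    return float(d2_ab / within)


def fd_score(features: FeatureMatrix) -> SeparabilityReport:
    """Fisher-discrimination separability, one-versus-all over all classes.

    For each class the binary ratio (class vs rest) is computed per feature
    and the ratios are averaged; two-class inputs reduce to the plain
    binary ratio.  Features are ranked descending.
    """
    classes = features.classes
    if len(classes) < 2:
        raise ValueError("FD needs at least 2 classes")
    names = features.feature_names
    j = np.zeros(features.n_features)
    for c in classes:
        mask = features.labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 windows on each side")
        a, b = features.values[mask], features.values[~mask]
        d2_ab = a.var(axis=0) + b.var(axis=0) + (a.mean(axis=0) - b.mean(axis=0)) ** 2
        within = 2 * a.var(axis=0, ddof=1) + 2 * b.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(within > 0, d2_ab / np.where(within > 0, within, 1.0), np.inf)
        if np.any(within == 0):
            warnings.warn("zero within-class spread: infinite separability")
        j += ratio
    j /= len(classes)
    return SeparabilityReport(
        method="FD",
        sv=dict(zip(names, j.tolist())),
        order=_stable_order(names, j, ascending=False),
        n_classes=len(classes),
    )


def rfe_rank(
    features: FeatureMatrix,
    c: float = 1.0,
    standardize: bool = True,
) -> SeparabilityReport:
    """SVM recursive feature elimination.

    At each iteration a linear-kernel SVM is trained on the remaining
    features and the feature with the smallest squared weight (summed over
    the one-vs-one weight vectors in the multi-class case) is eliminated —
    removing it shrinks ||w||^2 the least, i.e. it costs the least margin.
    The last survivor gets rank 1.  ``sv`` stores each feature's rank.
    """
    classes = features.classes
    if len(classes) < 2:
        raise ValueError("RFE needs at least 2 classes")
    x, y = features.values, features.labels
    if standardize:
        x = StandardScaler().fit_transform(x)
    names = features.feature_names
    remaining = list(range(len(names)))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=c)
        svc.fit(x[:, remaining], y)
        crit = (svc.coef_**2).sum(axis=0)
        drop = int(np.argmin(crit))  # ties -> lowest canonical index
        eliminated.append(remaining.pop(drop))
    order_idx = remaining + eliminated[::-1]
    order = [names[i] for i in order_idx]
    rank = {name: i + 1 for i, name in enumerate(order)}
    return SeparabilityReport(
        method="RFE",
        sv={n: float(rank[n]) for n in names},
        order=order,
        n_classes=len(classes),
    )


@dataclass
class SelectionResult:
    """Outcome of a selection procedure: the chosen feature names plus the
    diagnostics that produced them."""

    selected: list[str]
    method: str
    ofn: int | None = None
    accuracy_curve: list[float] | None = None
    scores: dict[str, float] = field(default_factory=dict)


def ofn_sweep(
    features: FeatureMatrix,
    report: SeparabilityReport,
    classifier: ClassifierConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Cross-validated accuracy as subset size grows from 1 to d in rank order.

    The optimal feature number (OFN) is the smallest subset size attaining
    the maximum accuracy.
    """
    missing = set(features.feature_names) - set(report.order)
    if missing:
        raise ValueError(f"report does not cover features: {sorted(missing)}")
    classifier = classifier or ClassifierConfig(kind="svm")
    classifier = ClassifierConfig(**{**classifier.__dict__, "cv_folds": folds})
    curve = []
    for k in range(1, features.n_features + 1):
        res = crossval(features.select(report.order[:k]), classifier, seed=seed)
        curve.append(res.accuracy)
    ofn = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) maximum
    return SelectionResult(
        selected=report.order[:ofn],
        method=report.method,
        ofn=ofn,
        accuracy_curve=curve,
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.zeros_like(values)
    lo, hi = finite.min(), finite.max()
    clipped = np.clip(values, lo, hi)
    if hi == lo:
        return np.zeros_like(clipped)
    return (clipped - lo) / (hi - lo)


def aggregate_selection(
    reports: dict[tuple[str, str], SeparabilityReport],
    subset_size: int,
) -> SelectionResult:
    """Combine per-subject, per-channel separability reports into one subset.

    ``reports`` maps (subject, channel) -> report; all reports must share a
    method and feature set.  EC/FD: each report's SVs are min-max normalized
    to [0, 1], averaged across subjects within a channel, then summed across
    channels; the top ``subset_size`` features by the method's rank
    direction are selected.  RFE: each feature's occurrences in the
    reports' top-``subset_size`` lists are counted (max count = number of
    reports) and features are sorted by descending frequency.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    items = list(reports.items())
    method = items[0][1].method
    names = list(items[0][1].sv.keys())
    for _, rep in items:
        if rep.method != method:
            raise ValueError("all reports must use the same method")
        if set(rep.sv.keys()) != set(names):
            raise ValueError("inconsistent feature name sets")

    if method == "RFE":
        freq = {n: 0 for n in names}
        for _, rep in items:
            for n in rep.order[:subset_size]:
                freq[n] += 1
        counts = np.array([freq[n] for n in names], dtype=float)
        order = _stable_order(names, counts, ascending=False)
        return SelectionResult(
            selected=order[:subset_size],
            method=method,
            scores={n: freq[n] for n in order},
        )

    channels = sorted({ch for (_, ch) in reports})
    per_channel = []
    for ch in channels:
        mats = [
            _minmax(np.array([rep.sv[n] for n in names]))
            for (subj, c), rep in items
            if c == ch
        ]
        per_channel.append(np.mean(mats, axis=0))
    aggregate = np.sum(per_channel, axis=0)
    ascending = method == "EC"  # EC: smaller J more separable
    order = _stable_order(names, aggregate, ascending=ascending)
    return SelectionResult(
        selected=order[:subset_size],
        method=method,
        scores=dict(zip(names, aggregate.tolist())),
    )


@dataclass
class ChannelRanking:
    """Per-channel pairwise accuracies, their means, and the top channels."""

    table: pd.DataFrame  # channels x (pair columns + 'mean')
    order: list[str]
    selected: list[str]


def rank_channels(
    per_channel: dict[str, FeatureMatrix],
    classifier: ClassifierConfig | None = None,
    top_n: int = 2,
    seed: int = 0,
) -> ChannelRanking:
    """Rank channels by mean single-channel pairwise classification accuracy.

    For each channel the full 42-feature matrix is evaluated with 10-fold
    CV on each of the C(n_classes, 2) binary problems; channels are ordered
    by the mean pairwise accuracy (ties keep input order) and the top
    ``top_n`` are selected.
    """
    if len(per_channel) < 2:
        raise ValueError("need at least 2 channels to rank")
    classifier = classifier or ClassifierConfig(kind="svm")
    rows = {}
    pair_names = None
    for ch, fm in per_channel.items():
        classes = fm.classes
        if len(classes) < 2:
            raise ValueError(f"channel {ch!r} is missing classes")
        pairs = list(combinations(classes, 2))
        pair_names = [f"{a}-{b}" for a, b in pairs]
        accs = []
        for a, b in pairs:
            res = crossval(fm.subset_classes([a, b]), classifier, seed=seed)
            accs.append(res.accuracy)
        rows[ch] = accs + [float(np.mean(accs))]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=pair_names + ["mean"]
    )
    order = table["mean"].sort_values(ascending=False, kind="stable").index.tolist()
    return ChannelRanking(table=table, order=order, selected=order[:top_n])
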