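"""Parameter-sweep classification harness.

Evaluates how well multiscale entropy features separate texture classes
across the full parameter grids of both entropy measures: for every
(algorithm, parameter combination, scale prefix τ) cell, a stratified
75/25 train/test split is classified by five classifier families —
Gaussian naive Bayes, decision tree, support vector machine,
multi-layer perceptron, and k-nearest neighbours with k swept 1..9 —
and the test accuracies are aggregated into the standard summaries:

* **average accuracy** — mean of all classification results across all
  classifiers (KNN enters through its mean over k);
* **average max accuracy** — mean over the five families of each
  family's best accuracy across the whole sweep (KNN through its best k);
* **parameter optimality map** — for each parameter, how many of the
  five families achieve their best marginal average accuracy at each
  value;
* **best scale table** — per family, the τ such that gathering entropy
  values from scale 1 to τ maximizes its average accuracy (τ > 1 means
  complexity beats single-scale irregularity);
* **pairwise texture matrix** — per class pair, the winning algorithm
  and its average accuracy, banded at 85% / 70%.

Classifier hyperparameters are frozen: ``GaussianNB(priors=None,
var_smoothing=1e-9)``, ``DecisionTreeClassifier(random_state=0)``,
``SVC()`` with all defaults, ``MLPClassifier(random_state=1,
max_iter=10000)``, ``KNeighborsClassifier`` with k = 1..9.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .entropy import DispParams, FuzzyParams
from .multiscale import fuzzy_profiles_grid, multiscale_profile

logger = logging.getLogger(__name__)

FAMILIES = ("naive_bayes", "decision_tree", "svm", "mlp", "knn")

BANDS = {"high": "> 85%", "mid": "70–85%", "low": "< 70%"}


@dataclass
class SweepConfig:
    """Grids, split and roster settings for one sweep."""

    fuzzy_ms: Sequence[int] = (1, 2)
    fuzzy_ns: Sequence[float] = (2, 3, 4, 5)
    fuzzy_rs: Sequence[float] = (0.12, 0.24, 0.36, 0.48)
    disp_ms: Sequence[int] = (2, 3)
    disp_cs: Sequence[int] = (3, 4, 5, 6)
    taus: Sequence[int] = tuple(range(1, 11))
    split_ratio: float = 0.75
    split_seed: int = 0
    knn_ks: Sequence[int] = tuple(range(1, 10))
    standardize: bool = False
    algorithms: Sequence[str] = ("fuzzy", "dispersion")

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError(f"split_ratio must be in (0,1), got {self.split_ratio}")
        for name in ("fuzzy_ms", "fuzzy_ns", "fuzzy_rs", "disp_ms", "disp_cs", "taus"):
            if "fuzzy" in name and "fuzzy" not in self.algorithms:
                continue
            if "disp" in name and "dispersion" not in self.algorithms:
                continue
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def fuzzy_grid(self) -> list[FuzzyParams]:
        return [
            FuzzyParams(m, n, r)
            for m, n, r in itertools.product(self.fuzzy_ms, self.fuzzy_ns, self.fuzzy_rs)
        ]

    @property
    def disp_grid(self) -> list[DispParams]:
        return [DispParams(m, c) for m, c in itertools.product(self.disp_ms, self.disp_cs)]


@dataclass
class SweepResult:
    """Long-format accuracy records of a sweep.

    ``records`` columns: algorithm, m, n, r, c, tau, family, variant,
    class_a, class_b, accuracy (fraction in [0, 1]).  ``failures`` lists
    (cell description, error message) for cells that raised.
    """

    records: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# splitting and classification
# ---------------------------------------------------------------------------


def split_dataset(
    X: np.ndarray, y: np.ndarray, ratio: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split preserving class proportions.

    The train size is ⌊ratio·n⌋ with per-class allocation by largest
    remainder, e.g. 1376 rows (825 + 551) at ratio 0.75 give exactly
    1032 train / 344 test, and 82 rows (41 + 41) give 61 / 21.
    Deterministic given the seed; the two parts are disjoint and
    exhaustive.
    """
    X, y = np.asarray(X), np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows to split")
    # canonical row order (label, then features) makes the partition
    # invariant to how the table rows happened to be arranged
    feat = X.reshape(len(X), -1)
    order = np.lexsort(tuple(feat[:, j] for j in range(feat.shape[1] - 1, -1, -1)) + (y,))
    return train_test_split(
        X[order], y[order], train_size=ratio, stratify=y[order], random_state=seed
    )


def _roster(knn_ks: Sequence[int]):
    yield "naive_bayes", "", GaussianNB(priors=None, var_smoothing=1e-9)
    yield "decision_tree", "", DecisionTreeClassifier(random_state=0)
    yield "svm", "", SVC()
    yield "mlp", "", MLPClassifier(random_state=1, max_iter=10_000)
    for k in knn_ks:
        yield "knn", f"k={k}", KNeighborsClassifier(n_neighbors=k)


def evaluate_classifiers(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    knn_ks: Sequence[int] = tuple(range(1, 10)),
    standardize: bool = False,
) -> dict:
    """Fit the frozen roster and return test accuracies.

    Returns ``{family: accuracy}`` for the four single-estimator
    families plus ``'knn': {'per_k': {k: acc}, 'max': .., 'mean': ..}``.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature dimensionality mismatch")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set is single-class")
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    out: dict = {}
    per_k: dict[int, float] = {}
    for family, variant, est in _roster(knn_ks):
        acc = float(est.fit(X_train, y_train).score(X_test, y_test))
        if family == "knn":
            per_k[int(variant.split("=")[1])] = acc
        else:
            out[family] = acc
    out["knn"] = {
        "per_k": per_k,
        "max": max(per_k.values()),
        "mean": float(np.mean(list(per_k.values()))),
    }
    return out


# ---------------------------------------------------------------------------
# the sweep
# ---------------------------------------------------------------------------


def extract_feature_profiles(
    images: Sequence[np.ndarray], cfg: SweepConfig
) -> dict[tuple, np.ndarray]:
    """Multiscale entropy profiles for every image and parameter combo.

    Returns ``{(algorithm, params): matrix}`` with one row per image and
    one column per scale τ = 1..max(taus).  Profiles are computed once
    at the deepest scale; every τ prefix is sliced from them.
    """
    tau_max = max(cfg.taus)
    profiles: dict[tuple, np.ndarray] = {}
    n = len(images)
    if "fuzzy" in cfg.algorithms:
        grid = cfg.fuzzy_grid
        for p in grid:
            profiles[("fuzzy", p)] = np.empty((n, tau_max))
        for i, img in enumerate(images):
            for p, prof in fuzzy_profiles_grid(img, grid, tau_max).items():
                profiles[("fuzzy", p)][i] = prof.values
    if "dispersion" in cfg.algorithms:
        for p in cfg.disp_grid:
            mat = np.empty((n, tau_max))
            for i, img in enumerate(images):
                mat[i] = multiscale_profile(img, "dispersion", p, tau_max).values
            profiles[("dispersion", p)] = mat
    return profiles


def _param_cols(params: FuzzyParams | DispParams) -> dict:
    if isinstance(params, FuzzyParams):
        return {"m": params.m, "n": params.n, "r": params.r, "c": np.nan}
    return {"m": params.m, "n": np.nan, "r": np.nan, "c": params.c}


def run_sweep(
    images: Sequence[np.ndarray],
    labels: Sequence,
    cfg: SweepConfig,
    pairwise: bool | None = None,
) -> SweepResult:
    """Run the full grid × scale × classifier sweep on an image set.

    With more than two classes and ``pairwise`` unset (or True), every
    unordered class pair is evaluated separately and the records carry
    ``class_a``/``class_b``; with two classes a single binary task is
    run.  Entropy features are computed once per (algorithm, parameter
    combo) and reused across all τ prefixes and class pairs.  A failing
    cell is logged and recorded, never fatal.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if pairwise is None:
        pairwise = len(classes) > 2

    profiles = extract_feature_profiles(images, cfg)
    pairs = (
        list(itertools.combinations(sorted(classes.tolist()), 2))
        if pairwise
        else [(None, None)]
    )

    rows: list[dict] = []
    failures: list[tuple[str, str]] = []
    for (alg, params), mat in profiles.items():
        for class_a, class_b in pairs:
            if class_a is None:
                sel = np.ones(len(labels), dtype=bool)
            else:
                sel = (labels == class_a) | (labels == class_b)
            for tau in cfg.taus:
                X = mat[sel, :tau]
                cell = f"{alg} {params} tau={tau} pair=({class_a},{class_b})"
                try:
                    X_tr, X_te, y_tr, y_te = split_dataset(
                        X, labels[sel], cfg.split_ratio, cfg.split_seed
                    )
                    scores = evaluate_classifiers(
                        X_tr, y_tr, X_te, y_te, cfg.knn_ks, cfg.standardize
                    )
                except Exception as exc:  # noqa: BLE001 — per-cell isolation
                    logger.warning("sweep cell failed: %s (%s)", cell, exc)
                    failures.append((cell, str(exc)))
                    continue
                base = {
                    "algorithm": alg,
                    **_param_cols(params),
                    "tau": tau,
                    "class_a": class_a,
                    "class_b": class_b,
                }
                for fam in ("naive_bayes", "decision_tree", "svm", "mlp"):
                    rows.append(
                        {**base, "family": fam, "variant": "", "accuracy": scores[fam]}
                    )
                for k, acc in scores["knn"]["per_k"].items():
                    rows.append(
                        {**base, "family": "knn", "variant": f"k={k}", "accuracy": acc}
                    )
    records = pd.DataFrame(rows)
    return SweepResult(records, failures)


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

_CELL_KEYS = ["algorithm", "m", "n", "r", "c", "tau", "class_a", "class_b"]


def _family_cell_table(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce records to one accuracy per (cell, family).

    KNN's nine per-k accuracies collapse to their mean — the family's
    "average accuracy" reduction.
    """
    if records.empty:
        raise ValueError("empty sweep result")
    keys = [k for k in _CELL_KEYS if k in records.columns] + ["family"]
    return (
        records.groupby(keys, dropna=False, sort=False)["accuracy"]
        .mean()
        .reset_index()
    )


def average_accuracy(res: SweepResult | pd.DataFrame) -> float:
    """Mean of all classification results across all classifiers, in %."""
    records = res.records if isinstance(res, SweepResult) else res
    table = _family_cell_table(records)
    return float(table["accuracy"].mean() * 100.0)


def average_max_accuracy(res: SweepResult | pd.DataFrame) -> float:
    """Mean over families of each family's best sweep accuracy, in %.

    KNN contributes the best accuracy over both its k values and the
    grid.  Raises if any of the five families is absent.
    """
    records = res.records if isinstance(res, SweepResult) else res
    if records.empty:
        raise ValueError("empty sweep result")
    maxima = records.groupby("family")["accuracy"].max()
    missing = set(FAMILIES) - set(maxima.index)
    if missing:
        raise ValueError(f"missing classifier families: {sorted(missing)}")
    return float(maxima.loc[list(FAMILIES)].mean() * 100.0)


_GRID_PARAMS = {"fuzzy": ["m", "n", "r"], "dispersion": ["m", "c"]}


def _check_full_grid(table: pd.DataFrame, params: list[str]) -> None:
    combos = table[params + ["tau"]].drop_duplicates()
    expected = 1
    for p in params + ["tau"]:
        expected *= table[p].nunique()
    if len(combos) != expected:
        raise ValueError(
            f"incomplete grid: {len(combos)} combos, expected {expected}"
        )


def parameter_optimality_map(
    res: SweepResult | pd.DataFrame, algorithm: str
) -> dict[str, dict[float, int]]:
    """Per-parameter vote counts of which value each family favours.

    For each of the five classifier families and each parameter of the
    given algorithm's grid, the marginal average accuracy of every
    parameter value (averaged over all other parameters, scales and
    class pairs) is computed; the argmax value earns that family's vote.
    Ties resolve to the smallest value, so each parameter's votes sum to
    exactly five.
    """
    records = res.records if isinstance(res, SweepResult) else res
    sub = records[records["algorithm"] == algorithm]
    if sub.empty:
        raise ValueError(f"no records for algorithm {algorithm!r}")
    params = _GRID_PARAMS[algorithm]
    table = _family_cell_table(sub)
    _check_full_grid(table, params)
    out: dict[str, dict[float, int]] = {}
    for p in params:
        values = sorted(table[p].unique())
        tally = {v: 0 for v in values}
        for fam in FAMILIES:
            marg = table[table["family"] == fam].groupby(p)["accuracy"].mean()
            if len(marg) != len(values):
                raise ValueError(f"family {fam} missing values of {p}")
            best = marg.max()
            winner = min(v for v in values if marg.loc[v] >= best - 1e-12)
            if (marg == best).sum() > 1:
                logger.info("optimality tie on %s for %s; smallest value %s wins", p, fam, winner)
            tally[winner] += 1
        out[p] = tally
    return out


def accuracy_band(accuracy_pct: float) -> str:
    """Band an accuracy percentage: high (85, 100], mid [70, 85], low [0, 70)."""
    if accuracy_pct > 85.0:
        return "high"
    if accuracy_pct >= 70.0:
        return "mid"
    return "low"


def pairwise_texture_matrix(res: SweepResult | pd.DataFrame) -> pd.DataFrame:
    """Best algorithm and banded average accuracy per class pair.

    One row per unordered pair: the algorithm whose average accuracy
    over the whole sweep is highest for that pair, the accuracy in
    percent, and its band.  Requires pairwise-mode records covering both
    algorithms for every pair.
    """
    records = res.records if isinstance(res, SweepResult) else res
    if records.empty or records["class_a"].isna().all():
        raise ValueError("pairwise_texture_matrix needs pairwise-mode records")
    table = _family_cell_table(records)
    by_pair_alg = (
        table.groupby(["class_a", "class_b", "algorithm"])["accuracy"].mean().reset_index()
    )
    rows = []
    for (a, b), grp in by_pair_alg.groupby(["class_a", "class_b"]):
        if set(grp["algorithm"]) != set(records["algorithm"].unique()):
            raise ValueError(f"pair ({a}, {b}) missing an algorithm")
        best = grp.sort_values(["accuracy", "algorithm"], ascending=[False, True]).iloc[0]
        pct = float(best["accuracy"] * 100.0)
        rows.append(
            {
                "class_a": a,
                "class_b": b,
                "algorithm": best["algorithm"],
                "accuracy_pct": round(pct, 2),
                "band": accuracy_band(pct),
            }
        )
    return pd.DataFrame(rows)


def best_scale_table(res: SweepResult | pd.DataFrame) -> dict[str, int]:
    """Per family, the τ prefix that maximizes its average accuracy.

    τ = n means gathering entropy values from scales 1..n; τ > 1
    indicates the image set is better described by complexity than by
    single-scale irregularity.  Ties resolve to the smallest τ.
    """
    records = res.records if isinstance(res, SweepResult) else res
    table = _family_cell_table(records)
    taus = sorted(table["tau"].unique())
    out: dict[str, int] = {}
    for fam in FAMILIES:
        marg = table[table["family"] == fam].groupby("tau")["accuracy"].mean()
        if len(marg) != len(taus):
            raise ValueError(f"family {fam} missing a tau level")
        best = marg.max()
        out[fam] = int(min(t for t in taus if marg.loc[t] >= best - 1e-12))
    return out
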