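"""Two-class stimulus decoding from band power or spike counts.

For each penetration the two stimuli A and B are decoded with a linear
support-vector machine from the per-site responses of the simultaneously
recorded population, separately for four stimulus conditions:

* ``Adapter`` — adapter epochs, scored separately for repetition and
  alternation trials and then averaged;
* ``Test_rep`` — test epochs of AA vs BB trials;
* ``Test_alt`` — test epochs of AB vs BA trials (class = test stimulus);
* ``Test_sameAdapter`` — test stimuli following the same adapter (AA vs AB
  and BB vs BA, scored separately and averaged).

To make accuracies comparable across conditions, every classifier sees the
same number of trials per class, ``N_tot`` = the largest even integer not
exceeding the smallest per-class trial count over all sub-datasets.  Each of
the (default 1000) repetitions freshly draws N_tot trials per class, splits
them half/half into train and test, z-normalizes per site with training
statistics only, fits the SVM and scores the held-out half.  A label-shuffle
control re-runs the identical pipeline after randomly permuting class labels
across trials; its mean accuracy is the empirical chance level (50 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .stats import wilcoxon_matched_pairs

__all__ = [
    "PenetrationRejected",
    "SubDataset",
    "ConditionDataset",
    "DecodingResult",
    "FeatureSet",
    "build_conditions",
    "equalize_n_tot",
    "split_half",
    "z_normalize",
    "train_linear_svm",
    "decode_condition",
    "shuffle_control",
    "average_paired_scores",
    "subsample_site_indices",
    "subsample_sites",
    "decode_mua",
]

CONDITIONS = ("Adapter", "Test_rep", "Test_alt", "Test_sameAdapter")


class PenetrationRejected(ValueError):
    """Raised when a penetration cannot support the equalized analysis."""


@dataclass(frozen=True)
class SubDataset:
    """One two-class trial set: epoch plus trial ids per class label."""

    epoch: str
    ids_a: np.ndarray
    ids_b: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.ids_a) == 0 or len(self.ids_b) == 0:
            raise PenetrationRejected(
                f"sub-dataset {self.name!r} is missing a class"
            )
        if set(self.ids_a) & set(self.ids_b):
            raise ValueError(f"sub-dataset {self.name!r} has overlapping classes")

    @property
    def min_class_count(self) -> int:
        return min(len(self.ids_a), len(self.ids_b))


@dataclass(frozen=True)
class ConditionDataset:
    condition: str
    sub_datasets: tuple[SubDataset, ...]


@dataclass
class DecodingResult:
    penetration: str
    band: str
    condition: str
    mean_accuracy: float  # percent correct over test trials
    per_repetition: np.ndarray = field(repr=False)
    n_tot: int = 0
    n_sites: int = 0
    seed: int | None = None
    shuffle_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_accuracy <= 100.0:
            raise ValueError("accuracy must lie in [0, 100]")


class FeatureSet:
    """Per-epoch (trials x sites) feature frames indexed by trial_id."""

    def __init__(self, frames: dict[str, pd.DataFrame]):
        self.frames = frames

    @classmethod
    def from_band_power(cls, bpt, band: str) -> "FeatureSet":
        return cls(
            {
                epoch: bpt.matrix(band, epoch)
                for epoch in ("adapter", "test")
            }
        )

    @classmethod
    def from_spike_counts(
        cls, spikes: np.ndarray, trial_ids: np.ndarray
    ) -> "FeatureSet":
        if spikes is None:
            raise ValueError("session has no spike counts")
        return cls(
            {
                "adapter": pd.DataFrame(spikes[:, :, 0], index=trial_ids),
                "test": pd.DataFrame(spikes[:, :, 1], index=trial_ids),
            }
        )

    def select_trials(self, trial_ids) -> "FeatureSet":
        return FeatureSet(
            {e: f.loc[f.index.isin(trial_ids)] for e, f in self.frames.items()}
        )

    def select_sites(self, site_idx) -> "FeatureSet":
        return FeatureSet({e: f.iloc[:, list(site_idx)] for e, f in self.frames.items()})

    @property
    def n_sites(self) -> int:
        return next(iter(self.frames.values())).shape[1]

    def rows(self, epoch: str, ids: np.ndarray) -> np.ndarray:
        return self.frames[epoch].loc[ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# condition construction and equalization
# ---------------------------------------------------------------------------

def build_conditions(trial_table: pd.DataFrame) -> dict[str, ConditionDataset]:
    """The four stimulus-condition datasets from an analyzable trial table.

    The table must already exclude aborted and clipped trials.  Class labels
    follow the decoded stimulus: the adapter stimulus for ``Adapter`` and
    the test stimulus for the three test conditions.
    """
    t = trial_table
    if "aborted" in t.columns and t["aborted"].any():
        raise ValueError("trial table still contains aborted trials")

    def ids(seq: str) -> np.ndarray:
        return t.loc[t["sequence_type"] == seq, "trial_id"].to_numpy()

    aa, bb, ab, ba = ids("AA"), ids("BB"), ids("AB"), ids("BA")
    conditions = {
        "Adapter": ConditionDataset(
            "Adapter",
            (
                SubDataset("adapter", aa, bb, "Adapter_rep"),
                SubDataset("adapter", ab, ba, "Adapter_alt"),
            ),
        ),
        "Test_rep": ConditionDataset(
            "Test_rep", (SubDataset("test", aa, bb, "Test(AA,BB)"),)
        ),
        # class label is the *test* stimulus: AB trials show B, BA show A
        "Test_alt": ConditionDataset(
            "Test_alt", (SubDataset("test", ba, ab, "Test(AB,BA)"),)
        ),
        "Test_sameAdapter": ConditionDataset(
            "Test_sameAdapter",
            (
                SubDataset("test", aa, ab, "Test(AA,AB)"),
                SubDataset("test", bb, ba, "Test(BB,BA)"),
            ),
        ),
    }
    return conditions


def equalize_n_tot(conditions: dict[str, ConditionDataset]) -> int:
    """Largest even N_tot supported by every sub-dataset and class.

    Guarantees an exact half/half train/test split with balanced classes in
    all four conditions.  Penetrations that cannot support N_tot >= 4 are
    rejected.
    """
    minimum = min(
        sub.min_class_count
        for cond in conditions.values()
        for sub in cond.sub_datasets
    )
    n_tot = minimum - (minimum % 2)
    if n_tot < 4:
        raise PenetrationRejected(f"equalized N_tot = {n_tot} < 4")
    return n_tot


def split_half(
    class_ids: np.ndarray, n_tot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_tot`` trials of one class and split them half/half.

    Trials are drawn without replacement from the full pool, so successive
    calls realize re-sampled cross-validation rather than a fixed partition.
    """
    class_ids = np.asarray(class_ids)
    if len(class_ids) < n_tot:
        raise PenetrationRejected(
            f"class has {len(class_ids)} trials, fewer than N_tot={n_tot}"
        )
    if n_tot % 2:
        raise ValueError("n_tot must be even")
    drawn = rng.choice(class_ids, size=n_tot, replace=False)
    return drawn[: n_tot // 2], drawn[n_tot // 2 :]


def z_normalize(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize per site with training statistics only.

    The mean is taken across both classes of the training trials; test
    features are transformed with the training mean and sd.  A site with
    zero training sd carries no information and is set to 0 in both sets.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    tr = (train - mean) / sd_safe
    te = (test - mean) / sd_safe
    if zero.any():
        tr[:, zero] = 0.0
        te[:, zero] = 0.0
    return tr, te


def train_linear_svm(train: np.ndarray, labels: np.ndarray) -> SVC:
    """Maximum-margin linear classifier (soft margin, unit cost).

    Deterministic given the data; on linearly separable data with unit cost
    and standardized features the solution coincides with the hard-margin
    classifier whenever all dual coefficients stay below the cost bound.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("training set must contain exactly two classes")
    # tight optimizer tolerance: the solution should match the exact QP
    # optimum to numerical precision, not libsvm's loose default
    clf = SVC(kernel="linear", C=1.0, tol=1e-8)
    clf.fit(train, labels)
    return clf


def _score(clf: SVC, test: np.ndarray, labels: np.ndarray) -> float:
    """Fraction correct; points exactly on the boundary count 0.5."""
    dec = clf.decision_function(test)
    pos = clf.classes_[1]
    y_pm = np.where(np.asarray(labels) == pos, 1.0, -1.0)
    correct = np.where(dec == 0.0, 0.5, (np.sign(dec) == y_pm).astype(float))
    return float(correct.mean())


def _run_once(
    features: FeatureSet,
    sub: SubDataset,
    n_tot: int,
    rng: np.random.Generator,
    ids_a: np.ndarray | None = None,
    ids_b: np.ndarray | None = None,
) -> float:
    ids_a = sub.ids_a if ids_a is None else ids_a
    ids_b = sub.ids_b if ids_b is None else ids_b
    tr_a, te_a = split_half(ids_a, n_tot, rng)
    tr_b, te_b = split_half(ids_b, n_tot, rng)
    X_tr = np.vstack(
        [features.rows(sub.epoch, tr_a), features.rows(sub.epoch, tr_b)]
    )
    X_te = np.vstack(
        [features.rows(sub.epoch, te_a), features.rows(sub.epoch, te_b)]
    )
    y_tr = np.array(["A"] * len(tr_a) + ["B"] * len(tr_b))
    y_te = np.array(["A"] * len(te_a) + ["B"] * len(te_b))
    X_tr, X_te = z_normalize(X_tr, X_te)
    clf = train_linear_svm(X_tr, y_tr)
    return _score(clf, X_te, y_te)


def decode_condition(
    features: FeatureSet,
    condition: ConditionDataset,
    n_tot: int,
    n_repetitions: int = 1000,
    rng: np.random.Generator | None = None,
    band: str = "",
    penetration: str = "pen0",
    seed: int | None = None,
) -> DecodingResult:
    """Mean cross-validated accuracy of one condition, % correct.

    Each repetition draws fresh train/test trials; for conditions with two
    sub-datasets the two scores of a repetition are averaged with equal
    weight.
    """
    rng = rng or np.random.default_rng(seed)
    scores = np.empty(n_repetitions)
    for r in range(n_repetitions):
        scores[r] = np.mean(
            [
                _run_once(features, sub, n_tot, rng)
                for sub in condition.sub_datasets
            ]
        )
    per_rep = scores * 100.0
    return DecodingResult(
        penetration=penetration,
        band=band,
        condition=condition.condition,
        mean_accuracy=float(per_rep.mean()),
        per_repetition=per_rep,
        n_tot=n_tot,
        n_sites=features.n_sites,
        seed=seed,
    )


def shuffle_control(
    features: FeatureSet,
    condition: ConditionDataset,
    n_tot: int,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Label-shuffle null: chance-level accuracy distribution.

    For every permutation the class labels are randomly permuted across the
    trials of each sub-dataset before the half/half split; the pipeline is
    otherwise identical to :func:`decode_condition`.

    Returns the mean shuffled accuracy (%) and the per-permutation scores.
    """
    rng = rng or np.random.default_rng()
    scores = np.empty(n_permutations)
    for r in range(n_permutations):
        sub_scores = []
        for sub in condition.sub_datasets:
            pool = np.concatenate([sub.ids_a, sub.ids_b])
            perm = rng.permutation(pool)
            ids_a, ids_b = perm[: len(sub.ids_a)], perm[len(sub.ids_a) :]
            sub_scores.append(
                _run_once(features, sub, n_tot, rng, ids_a, ids_b)
            )
        scores[r] = np.mean(sub_scores)
    scores *= 100.0
    return float(scores.mean()), scores


def average_paired_scores(
    scores_1: np.ndarray,
    scores_2: np.ndarray,
    alpha: float = 0.025,
) -> tuple[np.ndarray, dict]:
    """Average paired per-penetration scores after testing their equality.

    A two-sided Wilcoxon matched-pairs test (Bonferroni-corrected ``alpha``)
    checks that the two score sets do not differ; the averages are returned
    regardless, with the verdict logged, and a warning is raised if the test
    rejects.
    """
    s1, s2 = np.asarray(scores_1, float), np.asarray(scores_2, float)
    if s1.shape != s2.shape:
        raise ValueError("paired score vectors must have equal length")
    try:
        res = wilcoxon_matched_pairs(s1, s2)
        report = {
            "statistic": res.statistic,
            "p": res.p,
            "alpha": alpha,
            "rejects": bool(res.p < alpha),
        }
    except ValueError:
        # too few informative pairs to test; average anyway, verdict logged
        report = {
            "statistic": np.nan,
            "p": np.nan,
            "alpha": alpha,
            "rejects": False,
            "note": "too few non-zero pairs for the equality test",
        }
    if report["rejects"]:
        warnings.warn(
            f"paired scores differ (Wilcoxon p={res.p:.4g} < {alpha}); "
            "averaging anyway",
            stacklevel=2,
        )
    return (s1 + s2) / 2.0, report


# ---------------------------------------------------------------------------
# site subsampling and MUA comparator
# ---------------------------------------------------------------------------

def subsample_site_indices(
    n_sites: int,
    fraction: float = 1.0 / 3.0,
    mode: str = "even",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of ``round(n_sites * fraction)`` sites along the probe.

    Deterministic, evenly spaced selection by default; ``mode='random'``
    draws without replacement using ``rng``.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites to subsample")
    k = round(n_sites * fraction)
    k = max(int(k), 1)
    if mode == "even":
        return np.unique(np.round(np.linspace(0, n_sites - 1, k)).astype(int))
    if mode == "random":
        rng = rng or np.random.default_rng()
        return np.sort(rng.choice(n_sites, size=k, replace=False))
    raise ValueError(f"unknown mode {mode!r}")


def subsample_sites(session, fraction: float = 1.0 / 3.0, mode: str = "even",
                    rng: np.random.Generator | None = None):
    """Reduced copy of a session keeping a fraction of the probe's sites."""
    from .simulate import SessionRecording

    idx = subsample_site_indices(session.n_sites, fraction, mode, rng)
    return SessionRecording(
        lfp=session.lfp[:, idx, :],
        trials=session.trials,
        sampling_rate=session.sampling_rate,
        spikes=None if session.spikes is None else session.spikes[:, idx, :],
        site_spacing_um=session.site_spacing_um,
        config=None,
        penetration=session.penetration,
    )


def decode_mua(
    session,
    conditions: dict[str, ConditionDataset],
    n_tot: int,
    n_repetitions: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[DecodingResult]:
    """Spike-count decoding with the identical pipeline, band label "MUA"."""
    if session.spikes is None:
        raise ValueError("session has no spike counts")
    features = FeatureSet.from_spike_counts(
        session.spikes, session.trials["trial_id"].to_numpy()
    )
    rng = rng or np.random.default_rng()
    return [
        decode_condition(
            features,
            cond,
            n_tot,
            n_repetitions,
            rng,
            band="MUA",
            penetration=session.penetration,
        )
        for cond in conditions.values()
    ]
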