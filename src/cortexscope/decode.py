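"""Condition decoding from binned cortex-wide activity.

Region traces are resampled into 10-s time bins (a 600-s session gives 60 bins
of the 12 regions); bins from the three sessions of one subject and phase are
stacked (180 rows, 60 per condition label) and a support vector machine
(C = 30, RBF kernel, gamma = scale) is trained on repeated stratified 80/20
splits.  Reported accuracy is the mean held-out accuracy across resamples.
Features are standardized with statistics fit on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .preprocess import RegionTraces
from .stats import paired_t


@dataclass(frozen=True)
class DecodeConfig:
    C: float = 30.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    train_frac: float = 0.8
    n_resamples: int = 10_000
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class DecodeResult:
    accuracy_mean: float
    accuracies: np.ndarray
    config: DecodeConfig
    labels: tuple[str, ...]
    n_redraws: int = 0
    meta: dict = field(default_factory=dict)


def bin_traces(traces: RegionTraces, bin_s: float = 10.0, max_bins: int | None = 60) -> np.ndarray:
    """Per-bin mean activity, (n_bins, n_regions); final short bin averaged.

    n_bins = ceil(n_frames / round(bin_s * fps)), capped at ``max_bins`` (60
    for a 600-s session).
    """
    values = traces.values
    if values.size == 0:
        raise ValueError("empty traces")
    block = int(round(bin_s * traces.fps))
    n = values.shape[1]
    n_bins = int(np.ceil(n / block))
    if max_bins is not None:
        n_bins = min(n_bins, max_bins)
    out = np.empty((n_bins, values.shape[0]))
    for b in range(n_bins):
        out[b] = values[:, b * block : min((b + 1) * block, n)].mean(axis=1)
    return out


def assemble_dataset(
    sessions: list[tuple[RegionTraces, str, int]],
    labels_subset: tuple[str, ...] | None = None,
    bin_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-session bins into (X, y); sessions are (traces, condition, day).

    Rows are concatenated in day order regardless of input order, so a
    shuffled session list yields an identical dataset.
    """
    ordered = sorted(sessions, key=lambda s: s[2])
    if labels_subset is not None:
        missing = [c for c in labels_subset if c not in {s[1] for s in ordered}]
        if missing:
            raise ValueError(f"missing sessions for conditions: {missing}")
        ordered = [s for s in ordered if s[1] in labels_subset]
    xs, ys = [], []
    for traces, condition, _day in ordered:
        x = bin_traces(traces, bin_s=bin_s)
        xs.append(x)
        ys.extend([condition] * len(x))
    return np.vstack(xs), np.asarray(ys)


def _stratified_split(y_codes: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx = []
    test_idx = []
    for c in np.unique(y_codes):
        idx = np.flatnonzero(y_codes == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def train_eval(
    X: np.ndarray,
    y: np.ndarray,
    config: DecodeConfig = DecodeConfig(),
    seed: int | np.random.Generator = 0,
    n_resamples: int | None = None,
    shuffle_labels: bool = False,
) -> DecodeResult:
    """Mean held-out accuracy over repeated stratified train/test splits.

    Deterministic given the seed.  A degenerate split (a class absent from the
    training set) is redrawn and counted in ``n_redraws``.  With
    ``shuffle_labels`` the labels are freshly permuted before every resample,
    which gives the chance-level calibration of the decoder: a single fixed
    permutation is not a valid null, because chance label-feature
    associations of one finite dataset appear in both the train and the test
    rows and inflate held-out accuracy above 1/k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two labels")
    counts = np.bincount(y_codes)
    if counts.min() < 5:
        raise ValueError("each label needs at least 5 rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_res = config.n_resamples if n_resamples is None else n_resamples
    accs = np.empty(n_res)
    redraws = 0
    base_codes = y_codes
    for i in range(n_res):
        if shuffle_labels:
            y_codes = rng.permutation(base_codes)
        while True:
            tr, te = _stratified_split(y_codes, config.train_frac, rng)
            if len(np.unique(y_codes[tr])) == len(classes):
                break
            redraws += 1
        xtr, xte = X[tr], X[te]
        if config.standardize:
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = SVC(C=config.C, kernel=config.kernel, gamma=config.gamma)
        clf.fit(xtr, y_codes[tr])
        accs[i] = float((clf.predict(xte) == y_codes[te]).mean())
    return DecodeResult(
        accuracy_mean=float(accs.mean()),
        accuracies=accs,
        config=config,
        labels=tuple(classes),
        n_redraws=redraws,
    )


def region_ablation(
    X: np.ndarray,
    y: np.ndarray,
    region_names: tuple[str, ...],
    mode: str,
    region: str,
    config: DecodeConfig = DecodeConfig(),
    seed: int | np.random.Generator = 0,
    n_resamples: int | None = None,
) -> DecodeResult:
    """Decode from a single region's column (``mode='single'``) or from the 11
    columns excluding it (``mode='leave_one_out'``)."""
    if region not in region_names:
        raise ValueError(f"unknown region {region!r}")
    j = list(region_names).index(region)
    if mode == "single":
        cols = [j]
    elif mode == "leave_one_out":
        cols = [i for i in range(len(region_names)) if i != j]
    else:
        raise ValueError("mode must be 'single' or 'leave_one_out'")
    res = train_eval(np.asarray(X)[:, cols], y, config, seed, n_resamples)
    res.meta.update({"mode": mode, "region": region})
    return res


def ablation_sweep(
    X: np.ndarray,
    y: np.ndarray,
    region_names: tuple[str, ...],
    mode: str = "leave_one_out",
    config: DecodeConfig = DecodeConfig(),
    seed: int = 0,
    n_resamples: int | None = None,
) -> pd.DataFrame:
    """Run the ablation over every region (12 decoders for 12 regions)."""
    rows = []
    for i, region in enumerate(region_names):
        res = region_ablation(
            X, y, region_names, mode, region, config,
            seed=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,))),
            n_resamples=n_resamples,
        )
        rows.append({"region": region, "mode": mode, "accuracy": res.accuracy_mean})
    return pd.DataFrame(rows)


def compare_phases(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject decoder accuracies (post vs pre)."""
    t, _, p = paired_t(np.asarray(post, dtype=float), np.asarray(pre, dtype=float))
    return t, p
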