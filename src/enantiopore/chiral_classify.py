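"""Enantiomer identification from event features: reference-matrix PCA,
PC2 Gaussian bands, and Monte Carlo label assignment.

The five event parameters (T_t, dI_bmin, dI_bmax, dI_b, I_bs) are
standardized with statistics learned on a fixed reference dataset (the
d-peptide recordings); the eigenvectors of the resulting correlation matrix
define PC1/PC2, and the same reference model projects every other dataset.
Each peptide's PC2 distribution is summarized by a Gaussian (mean mu,
sd sigma); events inside the band [mu - 3 sigma, mu + 3 sigma] can be
attributed to that peptide. Where the two bands overlap, an event is
assigned stochastically with probability proportional to the two Gaussian
densities at its PC2 value (equal class priors) — the Monte Carlo rule.
A logistic-regression classifier on PC1/PC2 is provided as the rejected
baseline, and labeled counts yield mixture-ratio estimates with binomial
confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from statsmodels.stats.proportion import proportion_confint

from .eventio import EventTable

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "PCAModel",
    "GaussianBand",
    "LabeledEvents",
    "ConfusionMatrix",
    "MixtureRatio",
    "fit_pca_model",
    "project_events",
    "labeled_from_pc2",
    "fit_pc2_band",
    "label_single",
    "monte_carlo_classify",
    "expected_mc_recall",
    "evaluate_confusion",
    "estimate_mixture_ratio",
    "logistic_baseline",
]

#: The five event parameters used for classification, as event-table columns.
FEATURES = ["t_t_us", "di_bmin_pA", "di_bmax_pA", "di_b_pA", "i_bs_pA"]

LABEL_D = "D"
LABEL_L = "L"
UNLABELED = "unlabeled"
LOW_SIGMA = "low_sigma"


@dataclass
class PCAModel:
    """Correlation-matrix PCA of the five event parameters.

    Normalization (per-feature center and scale) comes from the reference
    dataset and is reused verbatim for every projected dataset, so all
    analyses share the reference correlation structure. Signs are fixed:
    PC1 has a non-negative loading on dI_b, and PC2 is oriented so the
    reference population's main PC2 peak lies at negative values.
    """

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    correlation: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # shape (2, n_features): rows PC1, PC2

    def to_json(self, path) -> None:
        d = {
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "correlation": self.correlation.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["feature_names"],
            np.asarray(d["center"]),
            np.asarray(d["scale"]),
            np.asarray(d["correlation"]),
            np.asarray(d["eigenvalues"]),
            np.asarray(d["components"]),
        )


@dataclass(frozen=True)
class GaussianBand:
    """Gaussian summary of one peptide's PC2 population and its +-3 sigma band."""

    mean: float
    sd: float
    label: str
    half_width_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("band sd must be > 0")

    @property
    def lower(self) -> float:
        return self.mean - self.half_width_multiplier * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.half_width_multiplier * self.sd

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return (x >= self.lower) & (x <= self.upper)  # closed interval

    def density(self, x) -> np.ndarray:
        return norm.pdf(np.asarray(x, dtype=np.float64), self.mean, self.sd)


@dataclass
class LabeledEvents:
    """Per-event PC coordinates and class labels.

    ``data`` columns: pc1, pc2, label (one of D/L/unlabeled/low_sigma) and,
    after Monte Carlo classification, draw_prob (the probability with which
    the assigned label was drawn; 1.0 where the assignment was deterministic).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pc2(self) -> np.ndarray:
        return self.data["pc2"].to_numpy(dtype=np.float64)

    def counts(self) -> dict[str, int]:
        return self.data["label"].value_counts().to_dict()


@dataclass
class ConfusionMatrix:
    """True-class x predicted-label counts and the derived rates."""

    counts: pd.DataFrame  # index: true class; columns: D, L, unlabeled
    per_class_success: dict[str, float]
    false_positive_rate: dict[str, float]
    overall_success: float


@dataclass
class MixtureRatio:
    ratio: float
    ci_low: float
    ci_high: float
    n_l: int
    n_d: int
    defined: bool = True


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca_model(reference: EventTable) -> PCAModel:
    """Fit the reference PCA: per-feature standardization, correlation-matrix
    eigendecomposition, top-2 components with fixed sign convention."""
    df = reference.events
    missing = [f for f in FEATURES if f not in df.columns]
    if missing:
        raise ValueError(f"reference table missing feature columns {missing}")
    if len(df) < 100:
        raise ValueError(f"reference PCA needs >= 100 events, got {len(df)}")
    X = df[FEATURES].to_numpy(dtype=np.float64)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    for name, s in zip(FEATURES, scale):
        if s == 0.0:
            raise ValueError(f"feature {name!r} has zero variance in the reference set")
    Z = (X - center) / scale
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    components = eigvecs[:, order][:, :2].T.copy()

    # sign conventions: PC1 loads non-negatively on dI_b
    i_dib = FEATURES.index("di_b_pA")
    if components[0, i_dib] < 0:
        components[0] *= -1.0
    # PC2: reference main peak (median proxy, >50% of mass) at negative values
    pc2 = Z @ components[1]
    if np.median(pc2) > 0:
        components[1] *= -1.0

    return PCAModel(list(FEATURES), center, scale, corr, eigvals, components)


def project_events(events: EventTable, model: PCAModel) -> LabeledEvents:
    """Project events into the reference PC1/PC2 plane.

    Standardization uses the model's reference statistics, not the new
    dataset's own, so all datasets live in the same reference coordinates.
    Events with in-event sd below 1 pA (if still present) are marked
    ``low_sigma``; everything else starts ``unlabeled``.
    """
    df = events.events
    missing = [f for f in model.feature_names if f not in df.columns]
    if missing:
        raise ValueError(f"event table missing feature columns {missing}")
    X = df[model.feature_names].to_numpy(dtype=np.float64)
    Z = (X - model.center) / model.scale
    scores = Z @ model.components.T
    label = np.full(len(df), UNLABELED, dtype=object)
    if "i_bs_pA" in df.columns:
        label[df["i_bs_pA"].to_numpy() < 1.0] = LOW_SIGMA
    out = pd.DataFrame({"pc1": scores[:, 0], "pc2": scores[:, 1], "label": label})
    return LabeledEvents(out, dict(events.metadata))


def labeled_from_pc2(pc2, pc1=None) -> LabeledEvents:
    """Wrap raw PC2 scores (e.g. simulated band samples) as LabeledEvents."""
    pc2 = np.asarray(pc2, dtype=np.float64)
    pc1 = np.zeros_like(pc2) if pc1 is None else np.asarray(pc1, dtype=np.float64)
    df = pd.DataFrame({"pc1": pc1, "pc2": pc2, "label": UNLABELED})
    return LabeledEvents(df)


# ---------------------------------------------------------------------------
# Bands and labeling
# ---------------------------------------------------------------------------

def fit_pc2_band(pc2_values, label: str, seed: int = 0) -> GaussianBand:
    """Gaussian fit of the dominant PC2 peak.

    The fit window is mode +- 2 robust sd (1.4826 MAD), which excludes the
    minor shoulder that accompanies the open peptide conformation. Raises if
    the histogram is bimodal with comparable masses (two peaks above 60% of
    the maximum separated by more than the robust sd): per-population fitting
    should be used instead.
    """
    x = np.asarray(pc2_values, dtype=np.float64)
    if x.size < 100:
        raise ValueError(f"band fit needs >= 100 values, got {x.size}")
    med = np.median(x)
    rsd = 1.4826 * np.median(np.abs(x - med))
    if rsd == 0:
        raise ValueError("degenerate PC2 distribution")
    nbins = max(25, min(100, x.size // 40))
    counts, edges = np.histogram(x, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    bw = edges[1] - edges[0]

    smoothed = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    peaks, _ = find_peaks(
        smoothed, height=0.5 * smoothed.max(), prominence=0.3 * smoothed.max()
    )
    if len(peaks) >= 2 and (centers[peaks].max() - centers[peaks].min()) > rsd:
        raise ValueError(
            "PC2 distribution is bimodal with comparable masses; "
            "fit each population separately"
        )
    mode = centers[np.argmax(smoothed)]
    sel = (centers >= mode - 2 * rsd) & (centers <= mode + 2 * rsd) & (counts > 0)
    if sel.sum() < 5:
        raise ValueError("too few populated bins around the PC2 mode")

    def g(v, a, m, s):
        return a * np.exp(-((v - m) ** 2) / (2 * s**2))

    p0 = [counts.max(), mode, rsd]
    popt, _ = curve_fit(
        g, centers[sel], counts[sel], p0=p0,
        bounds=([0, mode - 2 * rsd, bw / 4], [np.inf, mode + 2 * rsd, 10 * rsd]),
        maxfev=20_000,
    )
    return GaussianBand(float(popt[1]), float(abs(popt[2])), label)


def label_single(events: LabeledEvents, band: GaussianBand) -> LabeledEvents:
    """Attribute in-band events to the band's peptide; others stay unlabeled."""
    df = events.data.copy()
    eligible = df["label"] != LOW_SIGMA
    inside = band.contains(df["pc2"].to_numpy())
    df.loc[eligible, "label"] = np.where(inside[eligible], band.label, UNLABELED)
    return LabeledEvents(df, dict(events.metadata))


def monte_carlo_classify(
    events: LabeledEvents,
    band_d: GaussianBand,
    band_l: GaussianBand,
    seed: int,
) -> LabeledEvents:
    """Monte Carlo two-band classification.

    Events outside both +-3 sigma bands stay unlabeled; events inside exactly
    one band take that band's label; events inside both draw their label with
    probability proportional to the two Gaussian densities at their PC2 value
    (equal class priors). Reproducible from ``seed``.
    """
    if band_d.lower == band_l.lower and band_d.upper == band_l.upper and band_d.sd == 0:
        raise ValueError("identical zero-width bands")
    rng = np.random.default_rng(seed)
    df = events.data.copy()
    eligible = (df["label"] != LOW_SIGMA).to_numpy()
    x = df["pc2"].to_numpy(dtype=np.float64)

    in_d = band_d.contains(x) & eligible
    in_l = band_l.contains(x) & eligible
    fd, fl = band_d.density(x), band_l.density(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_d = np.where(fd + fl > 0, fd / (fd + fl), 0.5)

    label = np.where(eligible, UNLABELED, LOW_SIGMA).astype(object)
    prob = np.full(x.size, np.nan)

    only_d = in_d & ~in_l
    only_l = in_l & ~in_d
    both = in_d & in_l
    label[only_d] = band_d.label
    prob[only_d] = 1.0
    label[only_l] = band_l.label
    prob[only_l] = 1.0
    u = rng.random(x.size)
    take_d = both & (u < p_d)
    label[take_d] = band_d.label
    prob[take_d] = p_d[take_d]
    take_l = both & ~take_d
    label[take_l] = band_l.label
    prob[take_l] = 1.0 - p_d[take_l]

    df["label"] = label
    df["draw_prob"] = prob
    return LabeledEvents(df, {**events.metadata, "mc_seed": seed})


def expected_mc_recall(band_own: GaussianBand, band_other: GaussianBand, n_grid: int = 20_001) -> float:
    """Numerical-integration oracle for the Monte Carlo per-class recall.

    Integrates the true-class density times the assignment probability of the
    implemented rule (deterministic in band-exclusive regions, density-
    proportional in the overlap) over the band union.
    """
    lo = min(band_own.lower, band_other.lower)
    hi = max(band_own.upper, band_other.upper)
    x = np.linspace(lo, hi, n_grid)
    f_own, f_oth = band_own.density(x), band_other.density(x)
    in_own, in_oth = band_own.contains(x), band_other.contains(x)
    p_assign = np.where(
        in_own & in_oth,
        f_own / (f_own + f_oth),
        np.where(in_own, 1.0, 0.0),
    )
    return float(np.trapezoid(f_own * p_assign, x))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_confusion(pred: LabeledEvents, truth) -> ConfusionMatrix:
    """Confusion matrix of true class vs predicted label.

    Per-class success is correct labels over all true-class events; the
    false-positive rate of class c is the fraction of the *other* class
    labeled c; overall success is all correct labels over all evaluated
    events (low_sigma events are excluded from evaluation).
    """
    truth = np.asarray(truth, dtype=object)
    if truth.size != len(pred):
        raise ValueError(f"length mismatch: {truth.size} truths vs {len(pred)} predictions")
    labels = pred.data["label"].to_numpy()
    keep = labels != LOW_SIGMA
    labels, truth = labels[keep], truth[keep]

    classes = [LABEL_D, LABEL_L]
    cols = classes + [UNLABELED]
    counts = pd.DataFrame(0, index=classes, columns=cols, dtype=int)
    for tc in classes:
        sel = truth == tc
        for pc in cols:
            counts.loc[tc, pc] = int(np.sum(sel & (labels == pc)))

    success, fp = {}, {}
    for tc in classes:
        total = counts.loc[tc].sum()
        success[tc] = counts.loc[tc, tc] / total if total else 0.0
        other = classes[1 - classes.index(tc)]
        other_total = counts.loc[other].sum()
        fp[tc] = counts.loc[other, tc] / other_total if other_total else 0.0
    evaluated = counts.to_numpy().sum()
    overall = (counts.loc[LABEL_D, LABEL_D] + counts.loc[LABEL_L, LABEL_L]) / evaluated if evaluated else 0.0
    return ConfusionMatrix(counts, success, fp, float(overall))


def estimate_mixture_ratio(labels: LabeledEvents, alpha: float = 0.05) -> MixtureRatio:
    """Ratio of l- to d-labeled events with a Wilson binomial interval on the
    labeled fraction, transformed to the ratio scale. Unlabeled events are
    excluded. A zero d count yields an undefined (flagged) ratio."""
    c = labels.counts()
    n_l, n_d = c.get(LABEL_L, 0), c.get(LABEL_D, 0)
    if n_d == 0:
        logger.warning("no d-labeled events; mixture ratio undefined")
        return MixtureRatio(float("nan"), float("nan"), float("nan"), n_l, n_d, defined=False)
    n = n_l + n_d
    p_lo, p_hi = proportion_confint(n_l, n, alpha=alpha, method="wilson")
    to_ratio = lambda p: p / (1.0 - p) if p < 1.0 else float("inf")
    return MixtureRatio(n_l / n_d, to_ratio(p_lo), to_ratio(p_hi), n_l, n_d)


def logistic_baseline(
    events: LabeledEvents,
    truth,
    train_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Logistic-regression baseline on (PC1, PC2), trained on a 20% split.

    Provided for comparison with the Monte Carlo rule; with strongly
    overlapping PC2 distributions its hard decisions carry no band notion and
    it cannot leave events unlabeled.
    """
    truth = np.asarray(truth, dtype=object)
    if truth.size != len(events):
        raise ValueError("length mismatch between events and truth")
    if len(set(truth)) < 2:
        raise ValueError("logistic baseline needs two classes")
    X = events.data[["pc1", "pc2"]].to_numpy(dtype=np.float64)
    Xtr, Xte, ytr, yte = train_test_split(
        X, truth, train_size=train_fraction, random_state=seed, stratify=truth
    )
    clf = LogisticRegression().fit(Xtr, ytr)
    ypred = clf.predict(Xte)
    acc = float(np.mean(ypred == yte))
    per_class = {
        c: float(np.mean(ypred[yte == c] == c)) for c in np.unique(truth)
    }
    return {
        "accuracy": acc,
        "per_class_recall": per_class,
        "n_train": len(ytr),
        "n_test": len(yte),
        "coef": clf.coef_.ravel().tolist(),
        "intercept": float(clf.intercept_[0]),
    }
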