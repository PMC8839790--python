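"""Chemometric models: PCA, PCA-LDA classification, PLSR regression,
replicate-blocked cross-validation, and the pretreatment / rank optimizers.

The modelling API follows the Model/Results convention: a model object is
built from a :class:`~aquahoney.spectra.SpectraSet` plus a
:class:`ModelTask`, and ``fit()`` returns a results object carrying the
cross-validated metrics, the wavelength-space weight vector, and a
``summary()`` table.

Cross-validation is leave-one-replicate-out (LOSO in the study's sense):
every fold holds out all fills and scans of one replicate bottle across
all treatment levels, so no spectra of one physical sample ever straddle
the train/validation boundary. Pretreatments with training state (MSC)
are fitted per fold on the training side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .exceptions import (
    ClassSupportError,
    DegenerateTargetError,
    DimensionError,
    FoldError,
    GroupError,
)
from .pretreat import PretreatmentSpec, apply_pretreatment, enumerate_grid, parse_spec
from .spectra import CONTROL, TEMPERATURES, TIMES, SpectraSet

__all__ = [
    "ModelTask",
    "loso_folds",
    "PCAModel",
    "fit_pca",
    "PCALDAModel",
    "PCALDAResults",
    "CVResult",
    "cross_validate",
    "optimize_pcs",
    "optimize_pretreatment",
    "PLSRModel",
    "PLSRResults",
    "cv_plsr",
    "subtraction_spectra",
]

#: numeric temperature assigned to control rows in temperature regressions
CONTROL_TEMPERATURE_C = 25.0
DEFAULT_PC_CANDIDATES = tuple(range(2, 16))
DEFAULT_MAX_LVS = 12
#: ridge factor (times the trace of the within-class scatter) in the LDA
LDA_RIDGE = 1e-8


# ----------------------------------------------------------------------
# tasks and folds


@dataclass(frozen=True)
class ModelTask:
    """What to classify or regress, and on which subset.

    family:
        ``botanical`` — honey type from the untreated controls of all types;
        ``general_temperature`` / ``general_time`` — all spectra of one
        honey type, target = temperature level / time interval;
        ``detailed_temperature`` — temperature levels within one time
        interval (control included), ``group`` = time_min;
        ``detailed_time`` — time intervals within one temperature level
        (control included), ``group`` = temperature_C.
    """

    family: str
    honey_type: str | None = None
    group: int | None = None

    def __post_init__(self):
        families = (
            "botanical",
            "general_temperature",
            "general_time",
            "detailed_temperature",
            "detailed_time",
        )
        if self.family not in families:
            raise ValueError(f"unknown task family {self.family!r}")
        if self.family.startswith("detailed") and self.group is None:
            raise ValueError(f"{self.family} task needs a group level")
        if self.family != "botanical" and self.honey_type is None:
            raise ValueError(f"{self.family} task needs a honey type")

    @property
    def target_column(self) -> str:
        if self.family == "botanical":
            return "honey_type"
        if "temperature" in self.family:
            return "temperature_C"
        return "time_min"

    def select(self, s: SpectraSet) -> SpectraSet:
        s = s.exclude_water_refs()
        if self.family == "botanical":
            return s.subset(temperature_C=CONTROL)
        s = s.subset(honey_type=self.honey_type)
        if self.family == "detailed_temperature":
            s = s.subset(time_min=[0, self.group])
        elif self.family == "detailed_time":
            s = s.subset(temperature_C=[CONTROL, self.group])
        if s.n_spectra == 0:
            raise GroupError(f"task subset is empty: {self}")
        return s

    def class_labels(self, meta: pd.DataFrame) -> np.ndarray:
        return meta[self.target_column].astype(str).to_numpy()

    def numeric_target(
        self, meta: pd.DataFrame, control_temperature: float | None = CONTROL_TEMPERATURE_C
    ) -> np.ndarray:
        """Regression coding: time in minutes (control = 0); temperature in
        degC with control coded ``control_temperature`` (``None`` drops the
        coding responsibility to the caller by returning NaN)."""
        col = meta[self.target_column]
        if self.target_column == "time_min":
            return col.to_numpy(dtype=float)
        out = np.empty(len(col), dtype=float)
        for i, v in enumerate(col):
            if v == CONTROL:
                out[i] = np.nan if control_temperature is None else control_temperature
            else:
                out[i] = float(v)
        return out

    @property
    def control_label(self) -> str | None:
        if self.family == "botanical":
            return None
        return CONTROL if self.target_column == "temperature_C" else "0"

    def describe(self) -> str:
        if self.family == "botanical":
            return "botanical origin (controls)"
        base = f"{self.honey_type}: "
        if self.family == "general_temperature":
            return base + "temperature (general)"
        if self.family == "general_time":
            return base + "time (general)"
        if self.family == "detailed_temperature":
            return base + f"temperature within {self.group} min"
        return base + f"time within {self.group} degC"


def detailed_tasks(honey_type: str) -> list[ModelTask]:
    """The eight detailed tasks of one honey type: temperature within each
    time interval and time within each temperature level."""
    return [ModelTask("detailed_temperature", honey_type, m) for m in TIMES] + [
        ModelTask("detailed_time", honey_type, t) for t in TEMPERATURES
    ]


def loso_folds(meta: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-replicate-out folds: ``(replicate id, train idx, val idx)``.

    All fills and scans of the held-out bottle, across every treatment
    level, form the validation side.
    """
    reps = sorted(meta["replicate"].astype(str).unique())
    if len(reps) < 2:
        raise FoldError("need at least two replicate ids for LOSO folds")
    rep_col = meta["replicate"].astype(str).to_numpy()
    folds = []
    for r in reps:
        val = np.flatnonzero(rep_col == r)
        train = np.flatnonzero(rep_col != r)
        folds.append((r, train, val))
    return folds


# ----------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """Mean-centred PCA with a deterministic sign convention (the largest
    |loading| element of each component is positive)."""

    mean_: np.ndarray
    loadings: np.ndarray  # (n_pcs, n_wavelengths)
    scores: np.ndarray  # (n_spectra, n_pcs)
    explained_variance_ratio: np.ndarray  # percent
    wavelengths: np.ndarray | None = None

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean_) @ self.loadings.T


def fit_pca(X: np.ndarray, n_pcs: int, wavelengths: np.ndarray | None = None) -> PCAModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 1 <= n_pcs <= min(n - 1, p):
        raise DimensionError(
            f"need 1 <= n_pcs <= min(n_spectra-1, n_wavelengths) = "
            f"{min(n - 1, p)}, got {n_pcs}"
        )
    mean_ = X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(X - mean_, full_matrices=False)
    load = Vt[:n_pcs]
    # sign convention
    flip = np.sign(load[np.arange(n_pcs), np.argmax(np.abs(load), axis=1)])
    flip[flip == 0] = 1.0
    load = load * flip[:, None]
    scores = (X - mean_) @ load.T
    var = sv**2
    evr = 100.0 * var[:n_pcs] / var.sum() if var.sum() > 0 else np.zeros(n_pcs)
    return PCAModel(mean_, load, scores, evr, wavelengths)


# ----------------------------------------------------------------------
# LDA on PCA scores


class _LDAOnScores:
    """Gaussian LDA with shared, lightly ridged within-class covariance."""

    def __init__(self, scores: np.ndarray, labels: np.ndarray):
        classes, y = np.unique(labels, return_inverse=True)
        counts = np.bincount(y)
        if (counts < 2).any():
            bad = classes[np.argmin(counts)]
            raise ClassSupportError(f"class {bad!r} has fewer than 2 training spectra")
        self.classes_ = classes
        n, d = scores.shape
        k = classes.size
        self.means_ = np.vstack([scores[y == i].mean(axis=0) for i in range(k)])
        self.priors_ = counts / n
        Sw = np.zeros((d, d))
        for i in range(k):
            Z = scores[y == i] - self.means_[i]
            Sw += Z.T @ Z
        Sw /= max(n - k, 1)
        # ridge keeps rank-deficient folds invertible; the tiny absolute
        # floor covers the perfectly-separable zero-scatter case
        Sw += (LDA_RIDGE * np.trace(Sw) + 1e-12) * np.eye(d)
        self._Sw_inv = np.linalg.inv(Sw)
        # discriminant directions: eigenvectors of Sw^-1 Sb (at most k-1)
        gm = scores.mean(axis=0)
        Sb = np.zeros((d, d))
        for i in range(k):
            diff = (self.means_[i] - gm)[:, None]
            Sb += counts[i] * diff @ diff.T
        evals, evecs = np.linalg.eig(self._Sw_inv @ Sb)
        order = np.argsort(evals.real)[::-1][: max(k - 1, 1)]
        A = evecs[:, order].real
        A /= np.maximum(np.linalg.norm(A, axis=0), 1e-300)
        self.directions_ = A  # (d, n_axes)

    def discriminant_scores(self, Z: np.ndarray) -> np.ndarray:
        # linear Gaussian discriminant per class
        W = self._Sw_inv @ self.means_.T  # (d, k)
        c = -0.5 * np.sum(self.means_ @ self._Sw_inv * self.means_, axis=1)
        c = c + np.log(self.priors_)
        return Z @ W + c

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.discriminant_scores(Z), axis=1)]


@dataclass(frozen=True)
class PCALDAFit:
    """A PCA-LDA fit on one training matrix."""

    pca: PCAModel
    lda: _LDAOnScores
    n_pcs: int

    @property
    def classes_(self) -> np.ndarray:
        return self.lda.classes_

    @property
    def wavelength_weights(self) -> np.ndarray:
        """Discriminant directions back-projected to wavelength space,
        one row per discriminant axis."""
        return (self.pca.loadings.T @ self.lda.directions_).T

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.lda.predict(self.pca.transform(X))


def fit_pca_lda(
    X: np.ndarray, y: np.ndarray, n_pcs: int, wavelengths: np.ndarray | None = None
) -> PCALDAFit:
    pca = fit_pca(X, n_pcs, wavelengths)
    lda = _LDAOnScores(pca.scores, np.asarray(y))
    return PCALDAFit(pca, lda, n_pcs)


# ----------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVResult:
    """Blocked-CV classification metrics (percent accuracies)."""

    folds: tuple  # (replicate id, confusion DataFrame) per fold
    training_accuracy: float
    validation_accuracy: float
    control_accuracy: float  # NaN when the task has no control class
    n_pcs: int
    pretreatment: str

    @property
    def pooled_confusion(self) -> pd.DataFrame:
        out = None
        for _, conf in self.folds:
            out = conf if out is None else out.add(conf, fill_value=0)
        return out.fillna(0).astype(int)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> pd.DataFrame:
    lut = {c: i for i, c in enumerate(classes)}
    it = np.fromiter((lut[v] for v in y_true), int, len(y_true))
    ip = np.fromiter((lut[v] for v in y_pred), int, len(y_pred))
    k = len(classes)
    counts = np.bincount(it * k + ip, minlength=k * k).reshape(k, k)
    df = pd.DataFrame(counts, index=classes, columns=classes)
    df.index.name = "true"
    df.columns.name = "predicted"
    return df


def _cv_classification(
    s: SpectraSet,
    labels: np.ndarray,
    spec: PretreatmentSpec,
    candidates: tuple[int, ...],
    control_label: str | None,
) -> dict[int, CVResult]:
    """Run LOSO PCA-LDA CV for every candidate rank in one pass (one PCA
    per fold at the largest rank, truncated per candidate)."""
    X = s.absorbance
    wl = s.wavelengths
    folds = loso_folds(s.meta)
    classes = np.unique(labels)
    kmax = max(candidates)
    per_k: dict[int, list] = {k: [] for k in candidates}
    for rep, tr, va in folds:
        _, Xt, Xv = apply_pretreatment(spec, X[tr], X[va], wl)
        kfit = min(kmax, Xt.shape[0] - 1, Xt.shape[1])
        pca = fit_pca(Xt, kfit, wl)
        Zt_full = pca.scores
        Zv_full = pca.transform(Xv)
        for k in candidates:
            kk = min(k, kfit)
            lda = _LDAOnScores(Zt_full[:, :kk], labels[tr])
            pred_t = lda.predict(Zt_full[:, :kk])
            pred_v = lda.predict(Zv_full[:, :kk])
            acc_t = 100.0 * float(np.mean(pred_t == labels[tr]))
            acc_v = 100.0 * float(np.mean(pred_v == labels[va]))
            conf = _confusion(labels[va], pred_v, classes)
            per_k[k].append((rep, acc_t, acc_v, conf))
    out = {}
    for k, rows in per_k.items():
        folds_out = tuple((rep, conf) for rep, _, _, conf in rows)
        pooled = None
        for _, conf in folds_out:
            pooled = conf if pooled is None else pooled + conf
        if control_label is not None and control_label in pooled.index:
            row = pooled.loc[control_label]
            ctrl = 100.0 * float(row.get(control_label, 0)) / max(float(row.sum()), 1.0)
        else:
            ctrl = float("nan")
        out[k] = CVResult(
            folds=folds_out,
            training_accuracy=float(np.mean([r[1] for r in rows])),
            validation_accuracy=float(np.mean([r[2] for r in rows])),
            control_accuracy=ctrl,
            n_pcs=k,
            pretreatment=spec.format(),
        )
    return out


def cross_validate(
    s: SpectraSet,
    task: ModelTask,
    spec: PretreatmentSpec | str = "raw",
    n_pcs: int = 10,
) -> CVResult:
    """LOSO PCA-LDA cross-validation of one task at a fixed rank."""
    if isinstance(spec, str):
        spec = parse_spec(spec)
    sub = task.select(s)
    labels = task.class_labels(sub.meta)
    return _cv_classification(sub, labels, spec, (n_pcs,), task.control_label)[n_pcs]


def optimize_pcs(
    s: SpectraSet,
    task: ModelTask,
    spec: PretreatmentSpec | str = "raw",
    candidates=DEFAULT_PC_CANDIDATES,
) -> tuple[int, pd.DataFrame]:
    """Pick the PCA rank: highest validation accuracy, then smallest
    training-validation gap, then smallest rank."""
    if isinstance(spec, str):
        spec = parse_spec(spec)
    sub = task.select(s)
    labels = task.class_labels(sub.meta)
    results = _cv_classification(sub, labels, spec, tuple(candidates), task.control_label)
    rows = []
    for k in candidates:
        r = results[k]
        rows.append(
            (k, r.training_accuracy, r.validation_accuracy,
             r.training_accuracy - r.validation_accuracy, r.control_accuracy)
        )
    table = pd.DataFrame(
        rows, columns=["n_pcs", "training", "validation", "gap", "control"]
    )
    return select_rank(table), table


def select_rank(table: pd.DataFrame) -> int:
    """Lexicographic rank choice: maximize validation accuracy, tie-break
    by smallest training-validation gap, then by smallest rank."""
    rows = table[["n_pcs", "validation", "gap"]].to_numpy()
    best = sorted(rows, key=lambda r: (-r[1], r[2], r[0]))[0][0]
    return int(best)


def optimize_pretreatment(
    s: SpectraSet,
    task: ModelTask,
    grid: list[PretreatmentSpec] | None = None,
    metric: str = "validation_accuracy",
    pc_candidates=DEFAULT_PC_CANDIDATES,
    max_lvs: int = DEFAULT_MAX_LVS,
):
    """Evaluate every pipeline of the grid on one task and return
    ``(best spec, report DataFrame)``; ties resolve to grid order.

    ``metric`` is ``validation_accuracy`` (PCA-LDA, with nested rank
    choice) or ``R2CV`` (PLSR, with nested latent-variable choice).
    """
    grid = grid if grid is not None else enumerate_grid()
    if metric not in ("validation_accuracy", "R2CV"):
        raise ValueError(f"unknown optimization metric {metric!r}")
    rows = []
    best_val = -np.inf
    best_spec = grid[0]
    sub = task.select(s)
    for spec in grid:
        if metric == "validation_accuracy":
            labels = task.class_labels(sub.meta)
            results = _cv_classification(
                sub, labels, spec, tuple(pc_candidates), task.control_label
            )
            cand = sorted(
                results.values(),
                key=lambda r: (-r.validation_accuracy,
                               r.training_accuracy - r.validation_accuracy, r.n_pcs),
            )[0]
            score = cand.validation_accuracy
            rows.append(
                {
                    "pretreatment": spec.format(),
                    "n_components": cand.n_pcs,
                    "training": cand.training_accuracy,
                    "validation": cand.validation_accuracy,
                    "control": cand.control_accuracy,
                }
            )
        else:
            rep = cv_plsr(s, task, spec, max_lvs=max_lvs, subset=sub)
            score = rep.R2CV
            rows.append(
                {
                    "pretreatment": spec.format(),
                    "n_components": rep.n_lvs,
                    "R2C": rep.R2C,
                    "R2CV": rep.R2CV,
                    "RMSEC": rep.RMSEC,
                    "RMSECV": rep.RMSECV,
                    "RPDC": rep.RPDC,
                    "RPDCV": rep.RPDCV,
                }
            )
        if score > best_val:
            best_val = score
            best_spec = spec
    return best_spec, pd.DataFrame(rows)


def permuted_null_accuracy(
    s: SpectraSet,
    task: ModelTask,
    spec: PretreatmentSpec | str = "raw",
    n_pcs: int = 10,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Chance-level reference: validation accuracies (%) of the task under
    random label permutations — should hover near 100/k for k balanced
    classes."""
    if isinstance(spec, str):
        spec = parse_spec(spec)
    sub = task.select(s)
    labels = task.class_labels(sub.meta)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        r = _cv_classification(sub, perm, spec, (n_pcs,), None)[n_pcs]
        accs.append(r.validation_accuracy)
    return np.asarray(accs)


# ----------------------------------------------------------------------
# PLSR


@dataclass(frozen=True)
class PLSRReport:
    """PLSR metrics: calibration (C) on the full fit, cross-validation
    (CV) from pooled LOSO predictions; RPD = SD(y)/RMSE."""

    n_lvs: int
    regression_vector: np.ndarray
    R2C: float
    R2CV: float
    RMSEC: float
    RMSECV: float
    RPDC: float
    RPDCV: float
    pretreatment: str
    y_true: np.ndarray
    y_pred_cv: np.ndarray
    lv_table: pd.DataFrame


def _pls_coefs_per_lv(X: np.ndarray, y: np.ndarray, max_lvs: int) -> list[np.ndarray]:
    """Regression vectors for 1..max_lvs components from one NIPALS fit
    (the NIPALS recursion is greedy, so truncation is exact)."""
    pls = PLSRegression(n_components=max_lvs, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    R = pls.x_rotations_  # (p, a)
    Q = pls.y_loadings_  # (1, a)
    return [R[:, :k] @ Q[:, :k].T for k in range(1, max_lvs + 1)]


def cv_plsr(
    s: SpectraSet,
    task: ModelTask,
    spec: PretreatmentSpec | str = "raw",
    max_lvs: int = DEFAULT_MAX_LVS,
    control_temperature: float | None = CONTROL_TEMPERATURE_C,
    subset: SpectraSet | None = None,
) -> PLSRReport:
    """LOSO-validated PLSR for one task; the number of latent variables is
    the RMSECV minimizer in 1..max_lvs."""
    if isinstance(spec, str):
        spec = parse_spec(spec)
    sub = subset if subset is not None else task.select(s)
    y = task.numeric_target(sub.meta, control_temperature)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        sub = sub.select(keep)
        y = y[keep]
    if np.ptp(y) == 0:
        raise DegenerateTargetError("target is constant on the task subset")
    X = sub.absorbance
    wl = sub.wavelengths
    folds = loso_folds(sub.meta)
    a_max = int(min(max_lvs, X.shape[1]))
    preds = np.full((len(y), a_max), np.nan)
    for rep, tr, va in folds:
        _, Xt, Xv = apply_pretreatment(spec, X[tr], X[va], wl)
        a_fold = int(min(a_max, Xt.shape[0] - 1))
        coefs = _pls_coefs_per_lv(Xt, y[tr], a_fold)
        xm = Xt.mean(axis=0)
        ym = y[tr].mean()
        for k, B in enumerate(coefs):
            preds[va, k] = ((Xv - xm) @ B).ravel() + ym
        for k in range(a_fold, a_max):
            preds[va, k] = preds[va, a_fold - 1]
    sd = float(np.std(y))
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    lv_table = pd.DataFrame(
        {"n_lvs": np.arange(1, a_max + 1), "RMSECV": rmsecv,
         "R2CV": 1.0 - rmsecv**2 / sd**2}
    )
    n_lvs = int(np.argmin(rmsecv) + 1)

    # calibration fit on all spectra
    _, Xall = apply_pretreatment(spec, X, wavelengths=wl)
    B = _pls_coefs_per_lv(Xall, y, n_lvs)[-1]
    y_fit = ((Xall - Xall.mean(axis=0)) @ B).ravel() + y.mean()
    rmsec = float(np.sqrt(np.mean((y_fit - y) ** 2)))
    rmsecv_best = float(rmsecv[n_lvs - 1])
    return PLSRReport(
        n_lvs=n_lvs,
        regression_vector=B.ravel(),
        R2C=1.0 - rmsec**2 / sd**2,
        R2CV=1.0 - rmsecv_best**2 / sd**2,
        RMSEC=rmsec,
        RMSECV=rmsecv_best,
        RPDC=sd / rmsec if rmsec > 0 else np.inf,
        RPDCV=sd / rmsecv_best if rmsecv_best > 0 else np.inf,
        pretreatment=spec.format(),
        y_true=y,
        y_pred_cv=preds[:, n_lvs - 1],
        lv_table=lv_table,
    )


# ----------------------------------------------------------------------
# Model/Results wrappers


class PCALDAModel:
    """PCA-LDA classification model for one task.

    ``fit()`` runs the LOSO cross-validation (with rank optimization when
    ``n_pcs`` is not given) and a full-data fit, and returns a
    :class:`PCALDAResults`.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        task: ModelTask,
        pretreatment: PretreatmentSpec | str = "raw",
        n_pcs: int | None = None,
        pc_candidates=DEFAULT_PC_CANDIDATES,
    ):
        self.spectra = spectra
        self.task = task
        self.pretreatment = (
            parse_spec(pretreatment) if isinstance(pretreatment, str) else pretreatment
        )
        self.n_pcs = n_pcs
        self.pc_candidates = tuple(pc_candidates)

    def fit(self) -> "PCALDAResults":
        sub = self.task.select(self.spectra)
        labels = self.task.class_labels(sub.meta)
        if self.n_pcs is None:
            n_pcs, pc_table = optimize_pcs(
                self.spectra, self.task, self.pretreatment, self.pc_candidates
            )
        else:
            n_pcs, pc_table = self.n_pcs, None
        cv = cross_validate(self.spectra, self.task, self.pretreatment, n_pcs)
        _, Xall = apply_pretreatment(
            self.pretreatment, sub.absorbance, wavelengths=sub.wavelengths
        )
        k = min(n_pcs, Xall.shape[0] - 1, Xall.shape[1])
        full_fit = fit_pca_lda(Xall, labels, k, sub.wavelengths)
        return PCALDAResults(self, cv, full_fit, pc_table)


@dataclass
class PCALDAResults:
    """Fitted PCA-LDA with its blocked-CV metrics."""

    model: PCALDAModel
    cv: CVResult
    fit: PCALDAFit
    pc_table: pd.DataFrame | None = None

    @property
    def wavelengths(self) -> np.ndarray:
        return self.fit.pca.wavelengths

    @property
    def wavelength_weights(self) -> np.ndarray:
        return self.fit.wavelength_weights

    @property
    def wavelength_importance(self) -> np.ndarray:
        """Root-sum-square of the discriminant weights across axes."""
        return np.sqrt((self.fit.wavelength_weights**2).sum(axis=0))

    def summary(self) -> str:
        t = self.model.task
        lines = [
            "PCA-LDA classification".center(58),
            "=" * 58,
            f"Task:            {t.describe()}",
            f"Pretreatment:    {self.cv.pretreatment}",
            f"PCs:             {self.cv.n_pcs}",
            f"Classes:         {', '.join(map(str, self.fit.classes_))}",
            f"CV scheme:       leave-one-replicate-out ({len(self.cv.folds)} folds)",
            "-" * 58,
            f"Training acc.:   {self.cv.training_accuracy:6.2f} %",
            f"Validation acc.: {self.cv.validation_accuracy:6.2f} %",
        ]
        if not np.isnan(self.cv.control_accuracy):
            lines.append(f"Control acc.:    {self.cv.control_accuracy:6.2f} %")
        lines.append("=" * 58)
        return "\n".join(lines)


class PLSRModel:
    """PLSR model for one task; ``fit()`` returns :class:`PLSRResults`."""

    def __init__(
        self,
        spectra: SpectraSet,
        task: ModelTask,
        pretreatment: PretreatmentSpec | str = "raw",
        max_lvs: int = DEFAULT_MAX_LVS,
        control_temperature: float | None = CONTROL_TEMPERATURE_C,
    ):
        self.spectra = spectra
        self.task = task
        self.pretreatment = (
            parse_spec(pretreatment) if isinstance(pretreatment, str) else pretreatment
        )
        self.max_lvs = max_lvs
        self.control_temperature = control_temperature

    def fit(self) -> "PLSRResults":
        report = cv_plsr(
            self.spectra,
            self.task,
            self.pretreatment,
            self.max_lvs,
            self.control_temperature,
        )
        return PLSRResults(self, report)


@dataclass
class PLSRResults:
    model: PLSRModel
    report: PLSRReport

    def __getattr__(self, name):
        return getattr(self.report, name)

    def summary(self) -> str:
        r = self.report
        unit = "degC" if "temperature" in self.model.task.family else "min"
        return "\n".join(
            [
                "PLS regression".center(58),
                "=" * 58,
                f"Task:            {self.model.task.describe()}",
                f"Pretreatment:    {r.pretreatment}",
                f"Latent vars:     {r.n_lvs}",
                "-" * 58,
                f"R2C  = {r.R2C:6.3f}   RMSEC  = {r.RMSEC:8.3f} {unit}   RPDC  = {r.RPDC:5.2f}",
                f"R2CV = {r.R2CV:6.3f}   RMSECV = {r.RMSECV:8.3f} {unit}   RPDCV = {r.RPDCV:5.2f}",
                "=" * 58,
            ]
        )


# ----------------------------------------------------------------------
# subtraction spectra


def subtraction_spectra(
    s: SpectraSet, by: str = "temperature_C", variant: str = "msc"
) -> pd.DataFrame:
    """Group mean spectra minus the control mean, after a fixed display
    pretreatment.

    ``variant="msc"`` corrects scatter against the comparison-set mean;
    ``variant="sgol_d2"`` takes the Savitzky–Golay second derivative
    (order 2, window 21). Rows are indexed by group level (control row
    omitted from the output — it is identically zero by construction).
    """
    if by not in ("temperature_C", "time_min"):
        raise ValueError("grouping must be 'temperature_C' or 'time_min'")
    control_value = CONTROL if by == "temperature_C" else 0
    groups = s.meta[by]
    if not (groups == control_value).any():
        raise GroupError("control group absent from the comparison set")
    if variant == "msc":
        _, Xt = apply_pretreatment("msc", s.absorbance, wavelengths=s.wavelengths)
    elif variant == "sgol_d2":
        _, Xt = apply_pretreatment("sgol@2-21-2", s.absorbance, wavelengths=s.wavelengths)
    else:
        raise ValueError(f"unknown subtraction variant {variant!r}")
    ctrl_mean = Xt[(groups == control_value).to_numpy()].mean(axis=0)
    rows = {}
    for g in pd.unique(groups):
        if g == control_value:
            continue
        rows[g] = Xt[(groups == g).to_numpy()].mean(axis=0) - ctrl_mean
    out = pd.DataFrame.from_dict(rows, orient="index", columns=s.wavelengths)
    out.index.name = by
    return out
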