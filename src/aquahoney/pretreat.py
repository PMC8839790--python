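"""Spectral pretreatment operators, the codec grammar, and the 41-spec grid.

A pretreatment is an ordered list of steps encoded as a compact string:
steps joined by ``_``, Savitzky–Golay rendered ``sgol@<order>-<window>-<deriv>``,
the others ``snv`` / ``msc`` / ``deTr``; the empty pipeline is ``raw``.
Example: ``"sgol@2-21-0_snv"`` smooths with a 21-point second-order window
and then applies the standard normal variate.

MSC is the one step with training state (the reference spectrum is the
column mean of the *training* spectra), so pipelines are fitted on the
training fold and applied unchanged to held-out spectra — no leakage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateRowError, DimensionError, SchemaError

__all__ = [
    "PretreatmentStep",
    "PretreatmentSpec",
    "FittedPretreatment",
    "parse_spec",
    "sgol",
    "snv",
    "msc_fit_apply",
    "detrend",
    "enumerate_grid",
    "apply_pretreatment",
]

SGOL_WINDOWS = (13, 17, 21)
SGOL_POLY_ORDER = 2
DETREND_ORDER = 2

_SGOL_RE = re.compile(r"^sgol@(\d+)-(\d+)-(\d+)$")


@dataclass(frozen=True)
class PretreatmentStep:
    """One pipeline step: ``kind`` in {sgol, snv, msc, detrend}."""

    kind: str
    window: int | None = None
    poly_order: int | None = None
    deriv: int | None = None

    def __post_init__(self):
        if self.kind == "sgol":
            if self.window is None or self.poly_order is None or self.deriv is None:
                raise SchemaError("sgol step needs window, poly_order and deriv")
            if self.window % 2 == 0 or self.window <= self.poly_order:
                raise SchemaError(
                    f"sgol window must be odd and > poly_order, got "
                    f"window={self.window}, poly_order={self.poly_order}"
                )
            if self.deriv > self.poly_order:
                raise SchemaError("sgol deriv must be <= poly_order")
        elif self.kind == "detrend":
            object.__setattr__(self, "poly_order", self.poly_order or DETREND_ORDER)
        elif self.kind not in ("snv", "msc"):
            raise SchemaError(f"unknown pretreatment step kind: {self.kind!r}")

    def format(self) -> str:
        if self.kind == "sgol":
            return f"sgol@{self.poly_order}-{self.window}-{self.deriv}"
        return {"snv": "snv", "msc": "msc", "detrend": "deTr"}[self.kind]


@dataclass(frozen=True)
class PretreatmentSpec:
    """Ordered pipeline of steps with a canonical string codec."""

    steps: tuple[PretreatmentStep, ...] = ()

    def __post_init__(self):
        n_scatter = sum(1 for s in self.steps if s.kind in ("snv", "msc"))
        if n_scatter > 1:
            raise SchemaError(
                "at most one scatter-correction step (snv or msc) per pipeline"
            )

    def format(self) -> str:
        if not self.steps:
            return "raw"
        return "_".join(s.format() for s in self.steps)

    def __str__(self) -> str:
        return self.format()


def parse_spec(codec: str) -> PretreatmentSpec:
    """Parse a codec string; ``parse_spec(spec.format()) == spec``."""
    codec = codec.strip()
    if codec in ("", "raw"):
        return PretreatmentSpec(())
    steps = []
    for token in codec.split("_"):
        m = _SGOL_RE.match(token)
        if m:
            order, window, deriv = map(int, m.groups())
            steps.append(
                PretreatmentStep("sgol", window=window, poly_order=order, deriv=deriv)
            )
        elif token == "snv":
            steps.append(PretreatmentStep("snv"))
        elif token == "msc":
            steps.append(PretreatmentStep("msc"))
        elif token.lower() in ("detr", "detrend"):
            steps.append(PretreatmentStep("detrend"))
        else:
            raise SchemaError(f"cannot parse pretreatment token {token!r} in {codec!r}")
    return PretreatmentSpec(tuple(steps))


# ----------------------------------------------------------------------
# operators (row-wise on an (n_spectra, n_wavelengths) matrix)


def sgol(X: np.ndarray, window: int, poly_order: int, deriv: int, step_nm: float = 3.0) -> np.ndarray:
    """Savitzky–Golay smoothing/derivative per row; derivatives are scaled
    by the grid step (units AU/nm^deriv). Edges use polynomial
    extrapolation within the first/last half-window."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window >= X.shape[1]:
        raise DimensionError(
            f"sgol window {window} >= {X.shape[1]} wavelengths"
        )
    if window % 2 == 0 or window <= poly_order:
        raise SchemaError("sgol window must be odd and > poly_order")
    return savgol_filter(
        X, window_length=window, polyorder=poly_order, deriv=deriv,
        delta=step_nm, axis=1, mode="interp",
    )


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, population SD 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise DegenerateRowError(f"row {zero[0]} has zero variance; SNV undefined")
    return (X - mu) / sd


def msc_fit_apply(X_train: np.ndarray, X_apply: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against the training column mean.

    Each row ``y`` is regressed as ``y ~ m*ref + b``; the corrected row is
    ``(y - b) / m``. When ``X_apply`` is given it is corrected using the
    *training* reference (leakage-free); otherwise the training set itself.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    ref = X_train.mean(axis=0)
    X = X_train if X_apply is None else np.atleast_2d(np.asarray(X_apply, dtype=float))
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateRowError("MSC reference spectrum is constant")
    Xc = X - X.mean(axis=1, keepdims=True)
    m = Xc @ ref_c / denom
    zero = np.flatnonzero(m == 0)
    if zero.size:
        raise DegenerateRowError(f"row {zero[0]} has zero slope against the MSC reference")
    b = X.mean(axis=1) - m * ref.mean()
    return (X - b[:, None]) / m[:, None]


def detrend(X: np.ndarray, wavelengths: np.ndarray, poly_order: int = DETREND_ORDER) -> np.ndarray:
    """Subtract a per-row least-squares polynomial in wavelength."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if X.shape[1] != wl.size:
        raise DimensionError("wavelength axis does not match matrix columns")
    if wl.size <= poly_order:
        raise DimensionError("need more wavelengths than the detrend order")
    # orthonormal polynomial basis for a numerically stable projection
    V = np.polynomial.polynomial.polyvander((wl - wl.mean()) / np.ptp(wl), poly_order)
    Q, _ = np.linalg.qr(V)
    return X - (X @ Q) @ Q.T


# ----------------------------------------------------------------------
# pipelines


@dataclass
class FittedPretreatment:
    """A pipeline with its trained state (MSC reference per msc step)."""

    spec: PretreatmentSpec
    step_nm: float
    wavelengths: np.ndarray
    msc_references: dict = field(default_factory=dict)  # step index -> ref row matrix

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for i, step in enumerate(self.spec.steps):
            if step.kind == "sgol":
                X = sgol(X, step.window, step.poly_order, step.deriv, self.step_nm)
            elif step.kind == "snv":
                X = snv(X)
            elif step.kind == "detrend":
                X = detrend(X, self.wavelengths, step.poly_order)
            elif step.kind == "msc":
                X = msc_fit_apply(self.msc_references[i], X)
        return X


def apply_pretreatment(
    spec: PretreatmentSpec | str,
    X_train: np.ndarray,
    X_apply: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    step_nm: float | None = None,
):
    """Fit a pipeline on ``X_train`` and transform both matrices.

    Returns ``(fitted, X_train_t)`` or ``(fitted, X_train_t, X_apply_t)``.
    Step errors are re-raised with the 1-based step index.
    """
    if isinstance(spec, str):
        spec = parse_spec(spec)
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if wavelengths is None:
        wavelengths = np.arange(X_train.shape[1], dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if step_nm is None:
        step_nm = float(wavelengths[1] - wavelengths[0]) if wavelengths.size > 1 else 1.0
    fitted = FittedPretreatment(spec, step_nm, wavelengths)
    Xt = X_train
    Xa = None if X_apply is None else np.atleast_2d(np.asarray(X_apply, dtype=float))
    for i, step in enumerate(spec.steps):
        try:
            if step.kind == "sgol":
                Xt = sgol(Xt, step.window, step.poly_order, step.deriv, step_nm)
                if Xa is not None:
                    Xa = sgol(Xa, step.window, step.poly_order, step.deriv, step_nm)
            elif step.kind == "snv":
                Xt = snv(Xt)
                if Xa is not None:
                    Xa = snv(Xa)
            elif step.kind == "detrend":
                Xt = detrend(Xt, wavelengths, step.poly_order)
                if Xa is not None:
                    Xa = detrend(Xa, wavelengths, step.poly_order)
            elif step.kind == "msc":
                fitted.msc_references[i] = Xt.mean(axis=0, keepdims=True)
                Xt_new = msc_fit_apply(Xt)
                if Xa is not None:
                    Xa = msc_fit_apply(Xt, Xa)
                Xt = Xt_new
        except Exception as exc:
            raise type(exc)(f"step {i + 1} ({step.format()}): {exc}") from exc
    if X_apply is None:
        return fitted, Xt
    return fitted, Xt, Xa


def enumerate_grid() -> list[PretreatmentSpec]:
    """The 41-combination optimization grid.

    raw; the four scatter/baseline singles (snv, msc, deTr, deTr_msc); and
    for each smoothing window w in {13, 17, 21}: sgol@2-w-0 alone or
    followed by one of {snv, msc, deTr, deTr_snv, deTr_msc} or by a second
    derivative pass sgol@2-w2-d with w2 in {13, 17, 21}, d in {1, 2}.
    1 + 4 + 3 * (1 + 5 + 6) = 41 pipelines, duplicate-free.
    """
    specs = [parse_spec("raw"), parse_spec("snv"), parse_spec("msc"),
             parse_spec("deTr"), parse_spec("deTr_msc")]
    for w in SGOL_WINDOWS:
        head = f"sgol@2-{w}-0"
        specs.append(parse_spec(head))
        for tail in ("snv", "msc", "deTr", "deTr_snv", "deTr_msc"):
            specs.append(parse_spec(f"{head}_{tail}"))
        for w2 in SGOL_WINDOWS:
            for d in (1, 2):
                specs.append(parse_spec(f"{head}_sgol@2-{w2}-{d}"))
    assert len(specs) == 41 and len({s.format() for s in specs}) == 41
    return specs
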