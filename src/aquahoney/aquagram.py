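"""Water matrix coordinates (WAMACs), wavelength voting, and classic aquagrams.

The 12 WAMACs are characteristic wavelength ranges of the first water
overtone (1300–1600 nm), each attributed to a water molecular species
(free water, solvation shells, water with 1..4 hydrogen bonds, ...). Model
weights and difference spectra vote for wavelengths; votes are bucketed
into the WAMACs and the modal wavelength per coordinate defines where the
classic aquagram is read.

A classic aquagram standardizes the (scatter-corrected) absorbance at each
selected coordinate over the whole comparison set and plots the group
means on a radar chart, so the size-weighted mean over groups is zero at
every coordinate by construction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateCoordinateError,
    DimensionError,
    GroupError,
    RenderError,
    SelectionError,
)
from .models import PCALDAResults, PCAModel, PLSRReport, PLSRResults
from .pretreat import apply_pretreatment
from .spectra import CONTROL, SpectraSet

__all__ = [
    "Wamac",
    "default_wamacs",
    "WavelengthVote",
    "collect_votes",
    "AquagramSpec",
    "select_coordinates",
    "Aquagram",
    "classic_aquagram",
    "render_radar",
]

#: pretreatment applied to the comparison set before aquagram standardization
DISPLAY_PRETREATMENT = "sgol@2-21-0_msc"
#: votes taken from each model or difference spectrum
DEFAULT_TOP_K = 20


@dataclass(frozen=True)
class Wamac:
    """One water matrix coordinate: an index, a wavelength range, and the
    water species conventionally assigned to it."""

    index: int
    lo: float
    hi: float
    label: str

    def contains(self, nm: float) -> bool:
        return self.lo <= nm <= self.hi

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


def default_wamacs() -> list[Wamac]:
    """The 12 first-overtone coordinates; C12 extends to 1520 nm so the
    1511/1513 nm strongly-bound-water anchors fall inside."""
    ranges = [
        (1, 1336, 1348, "asymmetric stretch (v3)"),
        (2, 1360, 1366, "water shells"),
        (3, 1370, 1376, "v1 + v3 combination"),
        (4, 1380, 1388, "OH-(H2O)1,2 hydration"),
        (5, 1398, 1418, "free water (S0)"),
        (6, 1421, 1430, "water hydration (H-OH)"),
        (7, 1432, 1444, "water with 1 hydrogen bond (S1)"),
        (8, 1448, 1454, "water solvation shell OH-(H2O)4,5"),
        (9, 1458, 1468, "water with 2 hydrogen bonds (S2)"),
        (10, 1472, 1482, "water with 3 hydrogen bonds (S3)"),
        (11, 1482, 1495, "water with 4 hydrogen bonds (S4)"),
        (12, 1506, 1520, "strongly hydrogen-bonded water"),
    ]
    return [Wamac(i, float(lo), float(hi), lab) for i, lo, hi, lab in ranges]


@dataclass(frozen=True)
class WavelengthVote:
    wavelength: float
    source: str
    magnitude: float


def _votes_from_weights(source, wavelengths, vector, top_k) -> list[WavelengthVote]:
    mag = np.abs(np.asarray(vector, dtype=float))
    if mag.size != len(wavelengths):
        raise DimensionError(f"source {source!r}: weights do not match the grid")
    idx = np.flatnonzero(mag > 0)
    idx = idx[np.argsort(mag[idx])[::-1][:top_k]]
    return [WavelengthVote(float(wavelengths[i]), source, float(mag[i])) for i in idx]


def _votes_from_difference(source, wavelengths, diff, top_k) -> list[WavelengthVote]:
    """Votes at local extrema of a difference spectrum, largest |value| first."""
    d = np.abs(np.asarray(diff, dtype=float))
    if d.size != len(wavelengths):
        raise DimensionError(f"source {source!r}: difference does not match the grid")
    inner = np.arange(1, d.size - 1)
    is_ext = (d[inner] >= d[inner - 1]) & (d[inner] >= d[inner + 1])
    cand = inner[is_ext]
    if d[0] > d[1]:
        cand = np.r_[0, cand]
    if d[-1] > d[-2]:
        cand = np.r_[cand, d.size - 1]
    cand = cand[d[cand] > 0]
    cand = cand[np.argsort(d[cand])[::-1][:top_k]]
    return [WavelengthVote(float(wavelengths[i]), source, float(d[i])) for i in cand]


def collect_votes(sources, wavelengths=None, top_k: int = DEFAULT_TOP_K) -> list[WavelengthVote]:
    """Pool the top-k wavelengths per source.

    ``sources`` is an iterable of (source_id, item) pairs where item is a
    PCA model (PC1 loading), PCA-LDA results (importance across
    discriminant axes), a PLSR report (|regression vector|), a difference-
    spectra DataFrame from :func:`~aquahoney.models.subtraction_spectra`
    (one source per row, votes at local extrema), or a bare weight vector
    (requires ``wavelengths``).
    """
    votes: list[WavelengthVote] = []
    for source_id, item in sources:
        if isinstance(item, PCAModel):
            wl = item.wavelengths if item.wavelengths is not None else wavelengths
            votes += _votes_from_weights(source_id, wl, item.loadings[0], top_k)
        elif isinstance(item, PCALDAResults):
            votes += _votes_from_weights(
                source_id, item.wavelengths, item.wavelength_importance, top_k
            )
        elif isinstance(item, (PLSRReport, PLSRResults)):
            if wavelengths is None:
                raise DimensionError("PLSR votes need the wavelength grid")
            votes += _votes_from_weights(
                source_id, wavelengths, item.regression_vector, top_k
            )
        elif isinstance(item, pd.DataFrame):
            wl = np.asarray(item.columns, dtype=float)
            for level, row in item.iterrows():
                votes += _votes_from_difference(
                    f"{source_id}[{level}]", wl, row.to_numpy(), top_k
                )
        else:
            if wavelengths is None:
                raise DimensionError("bare weight vectors need the wavelength grid")
            votes += _votes_from_weights(source_id, wavelengths, item, top_k)
    return votes


@dataclass(frozen=True)
class AquagramSpec:
    """Selected display coordinates: at most one wavelength per WAMAC."""

    coordinates: tuple[float, ...]
    wamac_indices: tuple[int, ...]
    wamac_labels: tuple[str, ...]
    pretreatment: str = DISPLAY_PRETREATMENT


def select_coordinates(
    votes: list[WavelengthVote], wamacs: list[Wamac] | None = None
) -> AquagramSpec:
    """Per WAMAC, the modal voted wavelength; ties break by summed vote
    magnitude, then by proximity to the range midpoint. Votes outside all
    WAMACs are discarded; WAMACs without votes are omitted."""
    wamacs = wamacs if wamacs is not None else default_wamacs()
    per_wamac: dict[int, dict[float, list[float]]] = defaultdict(lambda: defaultdict(list))
    by_index = {w.index: w for w in wamacs}
    for v in votes:
        for w in wamacs:
            if w.contains(v.wavelength):
                per_wamac[w.index][v.wavelength].append(v.magnitude)
                break
    if not per_wamac:
        raise SelectionError("no vote falls inside any WAMAC range")
    coords, idxs, labels = [], [], []
    for i in sorted(per_wamac):
        w = by_index[i]
        tally = per_wamac[i]
        best = sorted(
            tally.items(),
            key=lambda kv: (-len(kv[1]), -sum(kv[1]), abs(kv[0] - w.midpoint)),
        )[0][0]
        coords.append(best)
        idxs.append(i)
        labels.append(w.label)
    return AquagramSpec(tuple(coords), tuple(idxs), tuple(labels))


@dataclass(frozen=True)
class Aquagram:
    """Group-mean standardized absorbance at the selected coordinates."""

    groups: tuple
    coordinates: tuple[float, ...]
    wamac_indices: tuple[int, ...]
    values: np.ndarray  # (n_groups, n_coordinates)
    group_sizes: tuple[int, ...]
    title: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = [f"C{i} ({c:g} nm)" for i, c in zip(self.wamac_indices, self.coordinates)]
        return pd.DataFrame(self.values, index=list(self.groups), columns=cols)


def classic_aquagram(
    s: SpectraSet, spec: AquagramSpec, by: str = "temperature_C", title: str = ""
) -> Aquagram:
    """Classic aquagram over the comparison set ``s``.

    Spectra are display-pretreated (smoothing + MSC against the set mean),
    then at every coordinate the absorbance is z-scored over *all* spectra
    of the set and averaged per group, so groups are compared against the
    pooled mean of this specific comparison.
    """
    groups_col = s.meta[by]
    levels = pd.unique(groups_col)
    if len(levels) < 2:
        raise GroupError("an aquagram needs at least two groups")
    _, Xt = apply_pretreatment(spec.pretreatment, s.absorbance, wavelengths=s.wavelengths)
    cols = [s.grid.index_of_nearest(c) for c in spec.coordinates]
    A = Xt[:, cols]
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateCoordinateError(
            f"coordinate {spec.coordinates[dead[0]]:g} nm has zero variance"
        )
    Z = (A - mu) / sd

    def _key(g):
        return (0, 0) if str(g) == CONTROL or g == 0 else (1, float(g))

    levels = sorted(levels, key=_key)
    values = np.vstack([Z[(groups_col == g).to_numpy()].mean(axis=0) for g in levels])
    sizes = tuple(int((groups_col == g).sum()) for g in levels)
    return Aquagram(
        tuple(levels), spec.coordinates, spec.wamac_indices, values, sizes, title
    )


def render_radar(a: Aquagram, path) -> None:
    """Radar chart: one closed trace per group, coordinates ordered by
    wavelength, legend = group labels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(a.coordinates)
    if n < 3:
        raise RenderError("need at least 3 coordinates for a radar polygon")
    order = np.argsort(a.coordinates)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    theta_closed = np.r_[theta, theta[:1]]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for gi, g in enumerate(a.groups):
        vals = a.values[gi, order]
        ax.plot(theta_closed, np.r_[vals, vals[:1]], label=str(g), linewidth=1.2)
    ax.set_xticks(theta)
    ax.set_xticklabels(
        [f"{a.coordinates[i]:g}" for i in order], fontsize=8
    )
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    if a.title:
        ax.set_title(a.title, fontsize=10)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight", metadata=_static_metadata(path))
    plt.close(fig)


def _static_metadata(path) -> dict | None:
    # keep output bytes reproducible for identical inputs
    p = str(path).lower()
    if p.endswith(".png"):
        return {"Software": "aquahoney"}
    if p.endswith(".svg"):
        return {"Date": None}
    return None
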